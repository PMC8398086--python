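"""End-to-end study: six synthetic titrations (2 pH x 3 T) to a full report.

Writes the titration corpus to a temporary directory, runs the complete
pipeline (quenching fits, binding fits, van't Hoff per pH) and prints the
rendered table.
"""

import tempfile
from pathlib import Path

import specbind as sb
from specbind.pipeline import RunConfig, render_report, run_pipeline
from specbind.synthetic import DEFAULT_PEAK_CENTER

STUDY = {  # (pH, T K) -> (Kb L/mol, n)
    (7.4, 298.0): (3.98e4, 1.59),
    (7.4, 305.0): (3.90e4, 1.35),
    (7.4, 312.0): (3.41e4, 1.01),
    (2.0, 298.0): (6.48e4, 1.13),
    (2.0, 305.0): (6.17e4, 1.17),
    (2.0, 312.0): (5.73e4, 1.07),
}

with tempfile.TemporaryDirectory() as tmp:
    entries = []
    for i, ((ph, temp), (kb, n)) in enumerate(sorted(STUDY.items())):
        truth = sb.QuenchTruth(Kb=kb, n=n, lambda_center=DEFAULT_PEAK_CENTER[ph], seed=i)
        series = sb.generate_emission_titration(truth, T=temp, pH=ph)
        path = Path(tmp) / f"titr_pH{ph:g}_T{temp:g}.csv"
        sb.write_titration(series, path)
        entries.append((str(path), ph, temp))

    report = run_pipeline(RunConfig(titrations=entries))
    print(render_report(report, "table"))

# Kb and n are recovered exactly (the inputs are noiseless); the van't Hoff
# fits across the three temperatures per pH give dH < 0 and dS > 0 at both
# pH values: exothermic, entropy-favoured, electrostatically driven binding.
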