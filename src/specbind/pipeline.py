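"""End-to-end study pipeline: titrations in, binding/thermodynamics table out.

A run takes one titration file per (pH, T) condition, performs the stage-1
quenching and binding fits on each, then one van't Hoff fit per pH across
its temperatures.  The structured report is the source of truth (full
precision, deterministic, hash-stamped); the rendered table is a derived
view in the conventional column order pH, T, Ksv, Kq, n, Kb, dH, dS, dG.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

from . import __version__
from .quenching import DEFAULT_TAU0, DIFFUSION_LIMIT, analyze_titration
from .spectra import load_titration
from .thermo import run_thermo_stage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a pipeline run.

    ``titrations`` maps each input file to its study condition.  All
    thresholds must be positive; every random-number consumer must receive
    an explicit seed (none are needed by the analysis itself, but fixture
    generation is seeded through here).
    """

    titrations: tuple  # of (path, pH, T)
    tau0: float = DEFAULT_TAU0
    mechanism_threshold: float = DIFFUSION_LIMIT
    constrained_intercept: bool = False
    peak_window: float = 2.0
    hbond_d_cut: float = 3.5
    hbond_angle_cut: float = 120.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "titrations", tuple(tuple(t) for t in self.titrations))
        for v, name in (
            (self.tau0, "tau0"),
            (self.mechanism_threshold, "mechanism_threshold"),
            (self.hbond_d_cut, "hbond_d_cut"),
            (self.hbond_angle_cut, "hbond_angle_cut"),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        titr = tuple(
            (entry["path"], float(entry["pH"]), float(entry["temperature_K"]))
            for entry in raw.pop("titrations")
        )
        return cls(titrations=titr, **raw)


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class StudyReport:
    """Structured pipeline output: every fitted number plus provenance."""

    rows: tuple  # per-(pH, T) dicts in input order
    thermo: dict  # pH -> dict
    config: dict
    input_hashes: dict
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "input_hashes": self.input_hashes,
            "conditions": list(self.rows),
            "thermodynamics": self.thermo,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute quenching, binding and thermodynamic stages over all inputs.

    Deterministic: rerunning with the same config and files produces a
    byte-identical structured report.  Any stage failure propagates with
    the condition it occurred in.
    """
    rows = []
    binding_by_cond = {}
    hashes = {}
    for path, ph, temp in config.titrations:
        logger.info("stage 1: %s (pH %.1f, %g K)", path, ph, temp)
        series = load_titration(path)
        if (series.pH, series.temperature) != (ph, temp):
            raise ValueError(
                f"{path}: file says pH {series.pH}/{series.temperature} K, "
                f"config says pH {ph}/{temp} K"
            )
        try:
            q, b = analyze_titration(
                series,
                tau0=config.tau0,
                constrained_intercept=config.constrained_intercept,
                threshold=config.mechanism_threshold,
                peak_window=config.peak_window,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 1 failed for {path} (pH {ph}, {temp} K): {exc}") from exc
        hashes[str(path)] = _file_sha256(path)
        binding_by_cond[(ph, temp)] = b
        rows.append(
            {
                "pH": ph,
                "temperature_K": temp,
                "Ksv_L_per_mol": q.Ksv,
                "Ksv_se": q.Ksv_se,
                "Kq_L_per_mol_s": q.Kq,
                "sv_intercept": q.intercept,
                "sv_r2": q.r2,
                "mechanism": q.mechanism.value,
                "Kb_L_per_mol": b.Kb,
                "n": b.n,
                "n_se": b.n_se,
                "dl_r2": b.r2,
                "stoichiometry": b.stoichiometry,
            }
        )

    thermo_raw = run_thermo_stage(binding_by_cond)
    thermo = {
        str(ph): {
            "dH_kJ_per_mol": tr.dH,
            "dS_J_per_mol_K": tr.dS,
            "dH_se": tr.dH_se,
            "dS_se": tr.dS_se,
            "dG_kJ_per_mol": {str(t): g for t, g in tr.dG.items()},
            "r2": tr.r2,
            "driving_force": tr.driving_force.value,
        }
        for ph, tr in thermo_raw.items()
    }

    cfg = {
        "tau0_s": config.tau0,
        "mechanism_threshold": config.mechanism_threshold,
        "constrained_intercept": config.constrained_intercept,
        "peak_window_nm": config.peak_window,
        "seed": config.seed,
        "titrations": [[str(p), ph, t] for p, ph, t in config.titrations],
    }
    return StudyReport(rows=tuple(rows), thermo=thermo, config=cfg, input_hashes=hashes)


TABLE_COLUMNS = [
    "pH", "T_K", "Ksv_1e4", "Kq_1e12", "n", "Kb_1e4", "dH_kJ_mol", "dS_J_mol_K", "dG_kJ_mol",
]


def render_report(report: StudyReport, fmt: str = "table") -> str:
    """Render the report: ``table`` (delimited, rounded) or ``structured`` (JSON)."""
    if fmt == "structured":
        return report.to_json()
    if fmt != "table":
        raise ValueError(f"unknown format {fmt!r}")
    lines = ["\t".join(TABLE_COLUMNS)]
    for row in report.rows:
        ph = row["pH"]
        t = row["temperature_K"]
        th = report.thermo.get(str(ph))
        dh = f"{th['dH_kJ_per_mol']:.2f}" if th else ""
        ds = f"{th['dS_J_per_mol_K']:.2f}" if th else ""
        dg = f"{th['dG_kJ_per_mol'].get(str(t), float('nan')):.2f}" if th else ""
        lines.append(
            "\t".join(
                [
                    f"{ph:g}",
                    f"{t:g}",
                    f"{row['Ksv_L_per_mol'] / 1e4:.2f}",
                    f"{row['Kq_L_per_mol_s'] / 1e12:.2f}",
                    f"{row['n']:.2f}",
                    f"{row['Kb_L_per_mol'] / 1e4:.2f}",
                    dh,
                    ds,
                    dg,
                ]
            )
        )
    return "\n".join(lines) + "\n"
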