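import numpy as np
import pytest

import specbind as sb

# Study conditions: (pH, T K) -> (Ksv, Kb, n) in L/mol units
STUDY_TRUTH = {
    (7.4, 298.0): (3.67e4, 3.98e4, 1.59),
    (7.4, 305.0): (3.49e4, 3.90e4, 1.35),
    (7.4, 312.0): (3.42e4, 3.41e4, 1.01),
    (2.0, 298.0): (6.28e4, 6.48e4, 1.13),
    (2.0, 305.0): (6.17e4, 6.17e4, 1.17),
    (2.0, 312.0): (5.74e4, 5.73e4, 1.07),
}

# printed van't Hoff parameters per pH: (dH kJ/mol, dS J/(mol K))
VANT_HOFF_PRINTED = {7.4: (-8.43, 59.93), 2.0: (-6.84, 69.21)}


@pytest.fixture
def ksv_series():
    """Noiseless Stern-Volmer mode titration at the pH 2.0 / 298 K condition."""
    truth = sb.QuenchTruth(Ksv=6.28e4, lambda_center=334.0)
    return truth, sb.generate_emission_titration(truth, T=298.0, pH=2.0)


@pytest.fixture
def kbn_series():
    """Noiseless double-log mode titration at the pH 2.0 / 298 K condition."""
    truth = sb.QuenchTruth(Kb=6.48e4, n=1.13, lambda_center=334.0)
    return truth, sb.generate_emission_titration(truth, T=298.0, pH=2.0)


@pytest.fixture
def helix20():
    return sb.build_ideal_chain(20, -57.0, -47.0, 180.0)
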