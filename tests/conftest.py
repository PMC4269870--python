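import numpy as np
import pytest

from chfcea.calibration import CalibrationTargets, calibrate_soc
from chfcea.life_tables import load_bundled_life_table
from chfcea.markov_engine import StrategyInputs
from chfcea.synthetic_trial import CohortConfig, TruthParams, generate_cohort, simulate_followup


@pytest.fixture(scope="session")
def life_table():
    return load_bundled_life_table()


@pytest.fixture(scope="session")
def base_inputs(life_table):
    """Uncalibrated base-case engine inputs with the bundled life table."""
    return StrategyInputs(life_table=life_table)


@pytest.fixture(scope="session")
def calibrated(base_inputs):
    """SoC arm calibrated to the published SoC outputs (shared across tests)."""
    return calibrate_soc(CalibrationTargets(), base_inputs)


@pytest.fixture(scope="session")
def calibrated_inputs(calibrated, base_inputs):
    return calibrated.apply(base_inputs)


@pytest.fixture(scope="session")
def trial():
    """Mid-sized synthetic trial at the default truth (CV process only: no
    life table, so censoring is purely administrative)."""
    cohort = generate_cohort(CohortConfig(n_patients=8000, seed=11))
    return simulate_followup(cohort, TruthParams(), seed=12)


@pytest.fixture(scope="session")
def truth():
    return TruthParams()
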