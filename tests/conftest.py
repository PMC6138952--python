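import warnings

import pytest

from cryptdrift import CohortTable, DriftParams, tissue_preset

# arviz announces its refactor on import; irrelevant to the suite
warnings.filterwarnings("ignore", message="ArviZ is undergoing")


@pytest.fixture(scope="session")
def colon():
    return tissue_preset("colon").params


@pytest.fixture(scope="session")
def driftless():
    """Constants with a negligible replacement rate: survival stays 1 to
    machine precision, giving analytically tractable limiting cases."""
    return DriftParams(N=7, lam=1e-9, tau=0.0)


@pytest.fixture()
def homogeneous_colon_cohort():
    """Six mice at the colon's day-30 design, each with exactly 4%
    wholly populated crypts (900 scored, 36 positive)."""
    return CohortTable.from_records(
        [(f"m{i}", 900, 36, "whole_only", 30.0) for i in range(1, 7)]
    )
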