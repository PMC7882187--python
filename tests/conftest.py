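import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from pfikit import synthetic_cohort as sc
from pfikit.index_derivation import ScreeningTable

#: The printed screening p-values for the 12 deficit factors + velocity
#: (censored entries kept as "<bound" strings).
PRINTED_SCREENING = {
    "ETS": "<.0001",
    "EDA": "<.0001",
    "EPL": "<.0001",
    "CDA": "<.0001",
    "CPL": 0.001,
    "ETOF": 0.004,
    "ESW": 0.035,
    "velocity": 0.058,
    "CTOF": 0.081,
    "EIT": 0.21,
    "CTS": 0.60,
    "CIT": 0.75,
    "CSW": 0.92,
}


@pytest.fixture(scope="session")
def printed_screening_table() -> ScreeningTable:
    return ScreeningTable.from_mapping(PRINTED_SCREENING)


@pytest.fixture(scope="session")
def paper_cohort():
    """Default transection-and-repair paper-substrate cohort (seeded)."""
    profile = sc.default_profile("transect_repair", heel_strike_artifact=True)
    design = sc.paper_study_design("transect_repair", seed=11)
    return sc.simulate_tracks(design, profile, seed=11), profile, design


@pytest.fixture(scope="session")
def video_cohorts():
    """Crush + repair video-study cohorts with marker traces (seeded)."""
    out = {}
    for injury, seed in (("crush", 21), ("transect_repair", 22)):
        profile = sc.default_profile(injury)
        design = sc.video_study_design(injury, seed=seed)
        out[injury] = {
            "tracks": sc.simulate_tracks(design, profile, seed=seed),
            "markers": sc.simulate_markers(design, profile, seed=seed),
            "profile": profile,
            "design": design,
        }
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
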