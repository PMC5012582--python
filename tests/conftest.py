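import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trendmr.mr import HarmonizedInstrument

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def instrument_from_frames(exposure: pd.DataFrame, outcome: pd.DataFrame) -> HarmonizedInstrument:
    """Fast instrument construction for already-aligned simulated tables."""
    return HarmonizedInstrument(
        rsid=exposure["snp"].to_numpy(),
        x=exposure["beta"].to_numpy(dtype=float),
        se_x=exposure["se"].to_numpy(dtype=float),
        y=outcome["beta"].to_numpy(dtype=float),
        se_y=outcome["se"].to_numpy(dtype=float),
        n_input_exposure=len(exposure),
    )


@pytest.fixture
def five_study_table():
    """A fixed, mildly heterogeneous five-study collection."""
    from trendmr.meta import StudyEstimate

    rows = [
        ("a", 0.05, 0.04),
        ("b", 0.12, 0.06),
        ("c", -0.02, 0.09),
        ("d", 0.20, 0.11),
        ("e", 0.08, 0.05),
    ]
    return [StudyEstimate(study_id=s, beta=b, se=se) for s, b, se in rows]


@pytest.fixture
def toy_categorical():
    """Three-level cumulative-incidence study with adjusted RRs != crude RRs."""
    from trendmr.dose_response import CategoricalStudy, QuantileLevel

    return CategoricalStudy(
        study_id="toy",
        design="cumulative_incidence",
        levels=[
            QuantileLevel(rr=1.0, n_cases=50, n_total=1000, lower_cm=None,
                          upper_cm=165.0, is_reference=True),
            QuantileLevel(rr=1.30, n_cases=60, n_total=1000, lower_cm=165.0,
                          upper_cm=175.0, ci_low=0.92, ci_high=1.84),
            QuantileLevel(rr=1.50, n_cases=80, n_total=1000, lower_cm=175.0,
                          upper_cm=None, ci_low=1.08, ci_high=2.08),
        ],
    )
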