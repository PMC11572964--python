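import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coolscale.aggregate import UnitTable

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_table(scale_m, ptree, lst):
    """Assemble a UnitTable from raw arrays."""
    ptree = np.asarray(ptree, dtype=float)
    lst = np.asarray(lst, dtype=float)
    return UnitTable(
        scale_m=float(scale_m),
        data=pd.DataFrame(
            {
                "unit_id": np.arange(len(ptree)),
                "ptree_pct": ptree,
                "lst_mean_c": lst,
                "n_valid_px": np.ones(len(ptree), dtype=int),
                "valid_fraction": np.ones(len(ptree)),
            }
        ),
    )


def exact_power_law_estimates(k, beta, scales):
    """Per-scale CE estimates lying exactly on CE = k * S**beta."""
    from coolscale.regression import CEEstimate

    return [
        CEEstimate(
            scale_m=float(s), ce=float(k * s**beta), slope_sign="negative",
            intercept_c=40.0, se_slope=0.0, r2=1.0, p_slope=0.0, n_units=100,
        )
        for s in scales
    ]


@pytest.fixture
def scales_12():
    """The 12-step 120-2760 m ladder of unit sizes."""
    return tuple(float(120 * w) for w in range(1, 24, 2))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
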