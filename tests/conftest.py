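import numpy as np
import pandas as pd
import pytest

from mird.trial_data import TrialDataset


def make_dataset(rows, D, covariates=()):
    """Build a TrialDataset from a list of per-subject dicts."""
    df = pd.DataFrame(rows)
    return TrialDataset(df, D=D, covariates=covariates)


def simulate_rd_like(
    n=500,
    rate=0.002,
    loghr=0.0,
    horizon=1500.0,
    seed=0,
    sigma=1.0,
    all_rd=True,
):
    """Exponential (or Weibull, via sigma) two-arm data, everyone followed to
    event or the administrative cut; optionally flag all subjects as RDs."""
    rng = np.random.default_rng(seed)
    trt = (np.arange(n) % 2).astype(int)
    scale = 1.0 / (rate * np.exp(loghr * trt))
    if sigma == 1.0:
        T = rng.exponential(scale)
    else:
        # AFT: log T = log(scale) + sigma * gumbel  ->  S(t)=exp(-(t/scale)^(1/sigma))
        T = scale * rng.weibull(1.0 / sigma, size=n)
    D = horizon
    C = D + 1.0
    T_obs = np.minimum(T, C)
    E = (T < C).astype(int)
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "trt": trt,
            "R": 0.0,
            "T_obs": T_obs,
            "E": E,
            "trt_disc_day": T_obs / 2.0 if all_rd else np.nan,
            "study_disc_day": np.nan,
            "death_day": np.nan,
        }
    )
    return TrialDataset(df, D=D, covariates=[])


@pytest.fixture
def rd_exponential():
    """Moderate-size exponential RD dataset with a real treatment effect."""
    return simulate_rd_like(n=2000, rate=0.002, loghr=0.5, seed=11)


@pytest.fixture
def rd_null():
    """Null-effect exponential RD dataset."""
    return simulate_rd_like(n=1000, rate=0.002, loghr=0.0, seed=3)
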