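import numpy as np
import pandas as pd
import pytest

from bcsherd import GeneratorConfig, OutcomeBetas, add_indicators, generate_herd


def make_records(n=100, herd="A", parity_group="heifer", start="2014-01-01",
                 bcs=3.0, bcs_release=None, anestrus=None, seed=0, spread_days=400):
    """Small hand-controllable cow-record table for unit tests."""
    rng = np.random.default_rng(seed)
    dates = pd.to_datetime(start) + pd.to_timedelta(
        np.sort(rng.integers(0, spread_days, size=n)), unit="D")
    bcs = np.full(n, bcs, dtype=float) if np.isscalar(bcs) else np.asarray(bcs, float)
    rel = bcs - 0.25 if bcs_release is None else (
        np.full(n, bcs_release, float) if np.isscalar(bcs_release)
        else np.asarray(bcs_release, float))
    an = rng.integers(0, 2, size=n) if anestrus is None else (
        np.full(n, anestrus, int) if np.isscalar(anestrus) else np.asarray(anestrus, int))
    parity = 1 if parity_group == "heifer" else 2
    return pd.DataFrame({
        "cow_id": [f"{herd}-{i}" for i in range(n)],
        "herd": herd, "parity": parity, "parity_group": parity_group,
        "calving_date": dates.date, "bcs_calving": bcs, "bcs_release": rel,
        "anestrus": an, "metritis": 0, "mastitis": 0, "ai80": 1, "pre100": 1,
        "milk_kg": rng.normal(28, 4, size=n).round(3),
        "milk_dim": rng.integers(30, 41, size=n),
    })


@pytest.fixture(scope="session")
def herd_20k():
    """One 20,000-cow single-stratum herd with zero covariate effects.

    Intercept-only outcomes (anestrus at 20%), reused by calibration and
    null-recovery tests.
    """
    from scipy.special import logit
    cfg = GeneratorConfig(
        herd_id="Z", n_cows_per_year=5000, parity_mix={1: 1.0},
        outcome_betas={"anestrus": OutcomeBetas(intercept=float(logit(0.2)))},
        seed=42)
    return cfg, add_indicators(generate_herd(cfg))
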