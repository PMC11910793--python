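import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import waitflow as wf

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def study_config() -> wf.SyntheticConfig:
    """Default study-scale generator conditions with a fixed seed."""
    return wf.SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def study_panel(study_config) -> wf.WaitlistPanel:
    return wf.generate_panel(study_config)


def noiseless_config(**overrides) -> wf.SyntheticConfig:
    """A single-stratum, zero-noise, zero-season, no-shock baseline config."""
    base = dict(
        n_quarters=8,
        baseline_additions=1000.0,
        baseline_removals=1000.0,
        inflow_trend=0.0,
        seasonal_additions=(0.0, 0.0, 0.0, 0.0),
        seasonal_removals=(0.0, 0.0, 0.0, 0.0),
        shock_quarter=None,
        noise_sd_additions=0.0,
        noise_sd_removals=0.0,
        initial_pending=5000.0,
        strata=(wf.Stratum("all", "Scotland", "all", 1.0),),
        seed=0,
    )
    base.update(overrides)
    return wf.SyntheticConfig(**base)


@pytest.fixture
def toy_panel() -> wf.WaitlistPanel:
    """Hand-built 3-quarter panel: additions (100,100,100), removals
    (80,90,100), pending start 50 -> pending (70,80,80)."""
    return wf.WaitlistPanel(
        pd.DataFrame(
            {
                "quarter": pd.period_range("2020Q1", periods=3, freq="Q-DEC"),
                "elective_type": "all",
                "hb_code": "Scotland",
                "specialty": "all",
                "additions": [100, 100, 100],
                "removals": [80, 90, 100],
                "pending": [70, 80, 80],
            }
        ),
        strict_conservation=True,
    )


@pytest.fixture(scope="session")
def identity_model() -> wf.VARX:
    """The pure accounting identity: pending[t] = pending[t-1] + A - R."""
    return wf.VARX.from_params(phi={1: 1.0}, coef_exog=(1.0, -1.0), sigma=0.0)
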