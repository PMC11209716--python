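import numpy as np
import pandas as pd
import pytest

import depscreen as d


@pytest.fixture
def tiny_cohort() -> d.Cohort:
    """Three-animal cohort with hand-picked values for round-trip tests."""
    df = pd.DataFrame(
        {
            "mouse_id": ["C001", "S001", "S002"],
            "group": ["Ctrl", "CUMS", "CUMS"],
            "spt_pref_pct": [90.0, 70.123456, 60.0],
            "epm_open_time_s": [80.0, 30.5, 20.0],
            "fst_immobility_s": [90.0, 180.0, 200.25],
            "latent": [None, "susceptible", "resilient"],
        }
    )
    return d.Cohort(df, d.DEFAULT_MEASURES, provenance="fixture")


@pytest.fixture
def default_cohort() -> d.Cohort:
    """One draw from the documented default generator configuration."""
    return d.generate_cohort(d.default_paper_params(seed=11))


@pytest.fixture
def paper_criteria() -> list[d.CutoffCriterion]:
    """The published cutoff triple, as frozen criteria (operating
    characteristics are placeholders; only measure/direction/cutoff are used
    for scoring)."""
    mk = lambda m, dir_, cut: d.CutoffCriterion(
        measure=m, direction=dir_, cutoff_original_scale=cut,
        sensitivity=np.nan, specificity=np.nan, youden_j=np.nan, auc=np.nan,
    )
    return [
        mk("spt_pref_pct", "low", 76.51),
        mk("epm_open_time_s", "low", 46.87),
        mk("fst_immobility_s", "high", 147.3),
    ]


def separated_params(seed: int = 0) -> d.GeneratorParams:
    """Generator configuration with effectively non-overlapping supports:
    every susceptible animal lies past every control on every measure."""
    ctrl = d.ComponentParams(
        loc={"spt_pref_pct": 90.0, "epm_open_time_s": 80.0, "fst_immobility_s": 60.0},
        scale={"spt_pref_pct": 1.0, "epm_open_time_s": 2.0, "fst_immobility_s": 2.0},
    )
    susc = d.ComponentParams(
        loc={"spt_pref_pct": 30.0, "epm_open_time_s": 15.0, "fst_immobility_s": 200.0},
        scale={"spt_pref_pct": 1.0, "epm_open_time_s": 2.0, "fst_immobility_s": 2.0},
    )
    R = np.eye(3)
    return d.GeneratorParams(
        n_ctrl=10, n_cums=20, susceptible_prop=1.0,
        ctrl_params=ctrl, resilient_params=ctrl, susceptible_params=susc,
        correlation=R, seed=seed,
    )
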