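"""Synthetic behavioral cohort generator.

Emulates the statistical structure the screening procedure assumes: a
control group, and a chronically stressed (CUMS) group that is a latent
two-component mixture of *resilient* animals (control-like) and
*susceptible* animals shifted toward the depressive direction on every
measure.

Within an animal, measures are joined by a Gaussian copula and given
truncated-normal marginals, so bounded supports ("%" scales, timed tests)
are respected exactly without clipping. The copula correlation is specified
on *oriented* scales — the depressive direction made positive — so a single
positive-definite matrix expresses "depressive measures co-vary" regardless
of each measure's raw direction.

The distributional form and the effect sizes here are implementer-chosen
calibration stand-ins for testing the pipeline; they are not estimates of
any real cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .cohort import DEFAULT_MEASURES, Cohort, MeasureSpec


@dataclass(frozen=True)
class ComponentParams:
    """Truncated-normal marginal parameters (one ``(loc, scale)`` pair per
    measure) for one mixture component. ``loc``/``scale`` parameterize the
    parent normal before truncation to the measure's bounds."""

    loc: Mapping[str, float]
    scale: Mapping[str, float]

    def validate(self, measures: Sequence[MeasureSpec]) -> None:
        for m in measures:
            if m.name not in self.loc or m.name not in self.scale:
                raise ValueError(f"component lacks parameters for measure {m.name!r}")
            if not np.isfinite(self.loc[m.name]):
                raise ValueError(f"non-finite location for measure {m.name!r}")
            if not self.scale[m.name] > 0:
                raise ValueError(
                    f"degenerate scale {self.scale[m.name]} for measure {m.name!r}; "
                    "scale must be > 0"
                )


@dataclass(frozen=True)
class GeneratorParams:
    """Full configuration of a synthetic cohort draw.

    Parameters
    ----------
    n_ctrl, n_cums : int
        Group sizes.
    susceptible_prop : float
        Per-animal probability that a CUMS animal is drawn from the
        susceptible component (a Bernoulli expectation, not a fixed count,
        unless ``exact_count`` is set).
    ctrl_params, resilient_params, susceptible_params : ComponentParams
        Marginals of the three components; resilient is typically identical
        to control.
    correlation : ndarray
        Copula correlation matrix over measures, on oriented scales
        (depressive direction positive); unit diagonal, positive definite.
    seed : int
        Master seed; per-group sub-streams are derived from it.
    exact_count : bool
        If True, exactly ``round(susceptible_prop * n_cums)`` CUMS animals
        are susceptible (a random subset), for exact-fraction fixtures.
    """

    n_ctrl: int
    n_cums: int
    susceptible_prop: float
    ctrl_params: ComponentParams
    resilient_params: ComponentParams
    susceptible_params: ComponentParams
    correlation: np.ndarray
    seed: int = 0
    measures: tuple[MeasureSpec, ...] = DEFAULT_MEASURES
    exact_count: bool = False

    def validate(self) -> None:
        if self.n_ctrl <= 0 or self.n_cums <= 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.susceptible_prop <= 1.0:
            raise ValueError("susceptible_prop must lie in [0, 1]")
        for comp in (self.ctrl_params, self.resilient_params, self.susceptible_params):
            comp.validate(self.measures)
        R = np.asarray(self.correlation, dtype=float)
        k = len(self.measures)
        if R.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {R.shape} does not match "
                f"{k} measures"
            )
        if not np.allclose(R, R.T):
            raise ValueError(f"correlation matrix is not symmetric:\n{R}")
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError(f"correlation matrix diagonal is not unit:\n{R}")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"correlation matrix is not positive definite:\n{R}"
            ) from None


def _truncnorm(spec: MeasureSpec, loc: float, scale: float) -> stats.rv_frozen:
    a = (spec.lower_bound - loc) / scale
    b = (spec.upper_bound - loc) / scale
    return stats.truncnorm(a, b, loc=loc, scale=scale)


def _sample_component(
    n: int,
    comp: ComponentParams,
    params: GeneratorParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n rows: Gaussian copula on oriented scales, truncated-normal
    marginals on raw scales."""
    k = len(params.measures)
    if n == 0:
        return np.empty((0, k))
    L = np.linalg.cholesky(np.asarray(params.correlation, dtype=float))
    z = rng.standard_normal((n, k)) @ L.T
    # z_j is the oriented (depressive-positive) latent coordinate
    u = stats.norm.cdf(z)
    out = np.empty((n, k))
    for j, spec in enumerate(params.measures):
        marginal = _truncnorm(spec, comp.loc[spec.name], comp.scale[spec.name])
        # direction "low": more depressive latent -> lower raw value
        uj = 1.0 - u[:, j] if spec.direction == "low" else u[:, j]
        out[:, j] = marginal.ppf(uj)
    return out


def generate_cohort(params: GeneratorParams) -> Cohort:
    """Generate a synthetic cohort.

    Deterministic in ``params.seed``: per-group sub-streams (control
    measures, CUMS latent assignment, CUMS measures) are spawned from the
    master seed so the same seed always yields a byte-identical cohort.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    ctrl_ss, latent_ss, cums_ss = ss.spawn(3)

    ctrl_rng = np.random.Generator(np.random.PCG64(ctrl_ss))
    ctrl_vals = _sample_component(params.n_ctrl, params.ctrl_params, params, ctrl_rng)

    latent_rng = np.random.Generator(np.random.PCG64(latent_ss))
    if params.exact_count:
        k_susc = int(round(params.susceptible_prop * params.n_cums))
        susceptible = np.zeros(params.n_cums, dtype=bool)
        susceptible[latent_rng.choice(params.n_cums, size=k_susc, replace=False)] = True
    else:
        susceptible = latent_rng.random(params.n_cums) < params.susceptible_prop

    cums_rng = np.random.Generator(np.random.PCG64(cums_ss))
    # one joint draw per animal in record order, switching component by tag
    cums_vals = np.empty((params.n_cums, len(params.measures)))
    for i in range(params.n_cums):
        comp = params.susceptible_params if susceptible[i] else params.resilient_params
        cums_vals[i] = _sample_component(1, comp, params, cums_rng)[0]

    names = [m.name for m in params.measures]
    rows = []
    for i in range(params.n_ctrl):
        rows.append(
            {"mouse_id": f"C{i + 1:03d}", "group": "Ctrl", "latent": None}
            | dict(zip(names, ctrl_vals[i]))
        )
    for i in range(params.n_cums):
        rows.append(
            {
                "mouse_id": f"S{i + 1:03d}",
                "group": "CUMS",
                "latent": "susceptible" if susceptible[i] else "resilient",
            }
            | dict(zip(names, cums_vals[i]))
        )
    df = pd.DataFrame(rows, columns=["mouse_id", "group", *names, "latent"])
    return Cohort(df, params.measures, provenance=f"generated-with-seed:{params.seed}")


def default_paper_params(
    seed: int = 0, susceptible_shift_sd: float = 1.75
) -> GeneratorParams:
    """Documented default generator configuration.

    Group sizes are n_ctrl=25, n_cums=50 (the two-group design the screen
    targets). The remaining values — susceptible proportion 0.35, a
    susceptible component shifted ``susceptible_shift_sd`` (default 1.75)
    pooled-SD toward the depressive direction on each measure, pairwise
    copula correlation 0.5 on oriented scales — are calibration stand-ins
    chosen to produce a plausibly noisy but recoverable mixture; they are
    not measurements of any real cohort.
    """
    ctrl_loc = {"spt_pref_pct": 85.0, "epm_open_time_s": 60.0, "fst_immobility_s": 100.0}
    scale = {"spt_pref_pct": 8.0, "epm_open_time_s": 20.0, "fst_immobility_s": 30.0}
    ctrl = ComponentParams(loc=ctrl_loc, scale=dict(scale))
    # susceptible: shifted toward the depressive direction of each measure
    susc_loc = {
        "spt_pref_pct": ctrl_loc["spt_pref_pct"] - susceptible_shift_sd * scale["spt_pref_pct"],
        "epm_open_time_s": ctrl_loc["epm_open_time_s"] - susceptible_shift_sd * scale["epm_open_time_s"],
        "fst_immobility_s": ctrl_loc["fst_immobility_s"] + susceptible_shift_sd * scale["fst_immobility_s"],
    }
    susc = ComponentParams(loc=susc_loc, scale=dict(scale))
    R = np.full((3, 3), 0.5)
    np.fill_diagonal(R, 1.0)
    return GeneratorParams(
        n_ctrl=25,
        n_cums=50,
        susceptible_prop=0.35,
        ctrl_params=ctrl,
        resilient_params=ctrl,
        susceptible_params=susc,
        correlation=R,
        seed=seed,
    )


def gaussian_copula_spearman(rho: float) -> float:
    """Spearman correlation implied by a Gaussian copula with parameter rho:
    ``6/pi * asin(rho/2)``."""
    return 6.0 / np.pi * np.arcsin(rho / 2.0)


# --- configuration files -------------------------------------------------

def params_to_dict(params: GeneratorParams) -> dict:
    return {
        "n_ctrl": params.n_ctrl,
        "n_cums": params.n_cums,
        "susceptible_prop": params.susceptible_prop,
        "ctrl_params": {"loc": dict(params.ctrl_params.loc), "scale": dict(params.ctrl_params.scale)},
        "resilient_params": {"loc": dict(params.resilient_params.loc), "scale": dict(params.resilient_params.scale)},
        "susceptible_params": {"loc": dict(params.susceptible_params.loc), "scale": dict(params.susceptible_params.scale)},
        "correlation": np.asarray(params.correlation, dtype=float).tolist(),
        "seed": params.seed,
        "measures": [m.name for m in params.measures],
        "exact_count": params.exact_count,
    }


def params_from_dict(d: Mapping) -> GeneratorParams:
    from .cohort import get_measure

    measures = tuple(get_measure(n) for n in d.get("measures", [m.name for m in DEFAULT_MEASURES]))
    comp = lambda key: ComponentParams(loc=dict(d[key]["loc"]), scale=dict(d[key]["scale"]))
    return GeneratorParams(
        n_ctrl=int(d["n_ctrl"]),
        n_cums=int(d["n_cums"]),
        susceptible_prop=float(d["susceptible_prop"]),
        ctrl_params=comp("ctrl_params"),
        resilient_params=comp("resilient_params"),
        susceptible_params=comp("susceptible_params"),
        correlation=np.asarray(d["correlation"], dtype=float),
        seed=int(d.get("seed", 0)),
        measures=measures,
        exact_count=bool(d.get("exact_count", False)),
    )


def load_params(path: str | Path) -> GeneratorParams:
    """Load generator configuration from a YAML or JSON file."""
    text = Path(path).read_text()
    d = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return params_from_dict(d)
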