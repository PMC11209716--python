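"""Pure calculators for the printed biochemical arithmetic.

Sucrose preference, ATP production from 340-nm kinetic absorbance, electron
transport chain (ETC) complex activity with blank correction, their
relative (%-of-control) normalizations, and delta-delta-Ct relative
quantification for qPCR / mtDNA content.

The kit constants (0.625 for the ATP assay, 1099 for the complex assays)
are treated as opaque printed values that already absorb path length,
extinction coefficient and kinetic timing; the calculators take the raw
absorbances as given and never rescale per minute. Citrate synthase control
activity uses the same complex-activity arithmetic, as no separate formula
applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ATP_KIT_CONSTANT = 0.625  # μmol/g per unit of ΔA_test/(ΔA_standard · W_test)
COMPLEX_KIT_CONSTANT = 1099.0  # U/mg prot per unit of ΔA/W_protein


@dataclass(frozen=True)
class IntakePair:
    """Sucrose and water consumption over the test window (same unit)."""

    sucrose_intake: float
    water_intake: float


@dataclass(frozen=True)
class AbsorbanceKinetics:
    """Two-timepoint kinetic absorbances with optional blanks.

    For the ATP assay the blanks are zero (ΔA = A2 - A1 on the test well
    directly) and ``standard_delta`` is the ΔA of the ATP standard; for the
    ETC complex assays the blank pair corrects the test pair and
    ``standard_delta`` is unused. ``sample_weight`` is grams of tissue (ATP)
    or mg protein (complexes)."""

    a1_test: float
    a2_test: float
    a1_blank: float = 0.0
    a2_blank: float = 0.0
    sample_weight: float = 1.0
    standard_delta: float = 1.0


@dataclass(frozen=True)
class CtQuadruple:
    """Ct values of target and reference gene in treated and control
    samples. Values outside 5-40 cycles trigger a warning (plausible-range
    check), non-finite values an error."""

    ct_target_treated: float
    ct_ref_treated: float
    ct_target_control: float
    ct_ref_control: float

    def __post_init__(self) -> None:
        vals = (
            self.ct_target_treated,
            self.ct_ref_treated,
            self.ct_target_control,
            self.ct_ref_control,
        )
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite Ct value in {vals}")
        if any(not 5.0 <= v <= 40.0 for v in vals):
            warnings.warn(
                f"Ct value outside the typical 5-40 cycle range: {vals}",
                stacklevel=2,
            )


def sucrose_preference(intake: IntakePair | None = None, *,
                       sucrose: float | None = None,
                       water: float | None = None) -> float:
    """Sucrose preference in percent: 100 * sucrose / (sucrose + water)."""
    if intake is not None:
        sucrose, water = intake.sucrose_intake, intake.water_intake
    if sucrose < 0 or water < 0:
        raise ValueError("intakes must be non-negative")
    total = sucrose + water
    if total <= 0:
        raise ValueError("total intake must be positive")
    return 100.0 * sucrose / total


def atp_production(k: AbsorbanceKinetics) -> float:
    """ATP production in μmol per g tissue.

    ΔA_test = A2 - A1 on the test well (3-min kinetics at 340 nm); the
    result is 0.625 · ΔA_test / (ΔA_standard · W_test)."""
    if k.sample_weight <= 0:
        raise ValueError("sample weight must be positive")
    if k.standard_delta == 0:
        raise ValueError("standard ΔA must be nonzero")
    delta_a = k.a2_test - k.a1_test
    return ATP_KIT_CONSTANT * delta_a / (k.standard_delta * k.sample_weight)


def complex_activity(k: AbsorbanceKinetics) -> float:
    """ETC complex activity in U per mg protein.

    ΔA1 = A1_test - A2_test, ΔA2 = A1_blank - A2_blank, ΔA = ΔA1 - ΔA2
    (1-min kinetics at 550 nm); activity = 1099 · ΔA / W_protein. A negative
    ΔA is returned as computed, with a warning — kinetics from a noisy blank
    can cross the test trace."""
    if k.sample_weight <= 0:
        raise ValueError("protein weight must be positive")
    delta_a = (k.a1_test - k.a2_test) - (k.a1_blank - k.a2_blank)
    if delta_a < 0:
        warnings.warn(
            f"negative blank-corrected ΔA ({delta_a:.4g}); returning the "
            "computed (negative) activity",
            stacklevel=2,
        )
    return COMPLEX_KIT_CONSTANT * delta_a / k.sample_weight


def relative_percent(test: float, control: float) -> float:
    """Plain percent-of-control ratio: 100 * test / control."""
    if control <= 0:
        raise ValueError("control value must be positive")
    return 100.0 * test / control


#: Relative ATP production (% of control).
relative_atp = relative_percent
#: Relative mitochondrial complex activity (% of control).
relative_activity = relative_percent


def ddct_fold_change(q: CtQuadruple) -> float:
    """Relative expression by the delta-delta-Ct method.

    ΔCt = Ct_target - Ct_reference within each sample, ΔΔCt = ΔCt_treated -
    ΔCt_control, fold change = 2^(-ΔΔCt). Used both for mRNA (GAPDH
    reference) and mtDNA content (nuclear reference)."""
    d_treated = q.ct_target_treated - q.ct_ref_treated
    d_control = q.ct_target_control - q.ct_ref_control
    return float(2.0 ** -(d_treated - d_control))


# --- batch mode ----------------------------------------------------------

_BATCH = {
    "sucrose": (
        ("sucrose_intake", "water_intake"),
        lambda r: sucrose_preference(IntakePair(r.sucrose_intake, r.water_intake)),
        "sucrose_preference_pct",
    ),
    "atp": (
        ("a1_test", "a2_test", "sample_weight", "standard_delta"),
        lambda r: atp_production(
            AbsorbanceKinetics(
                a1_test=r.a1_test, a2_test=r.a2_test,
                sample_weight=r.sample_weight, standard_delta=r.standard_delta,
            )
        ),
        "atp_umol_per_g",
    ),
    "complex": (
        ("a1_test", "a2_test", "a1_blank", "a2_blank", "sample_weight"),
        lambda r: complex_activity(
            AbsorbanceKinetics(
                a1_test=r.a1_test, a2_test=r.a2_test,
                a1_blank=r.a1_blank, a2_blank=r.a2_blank,
                sample_weight=r.sample_weight,
            )
        ),
        "activity_u_per_mg",
    ),
    "ddct": (
        ("ct_target_treated", "ct_ref_treated", "ct_target_control", "ct_ref_control"),
        lambda r: ddct_fold_change(
            CtQuadruple(
                r.ct_target_treated, r.ct_ref_treated,
                r.ct_target_control, r.ct_ref_control,
            )
        ),
        "fold_change",
    ),
}


def batch_calculate(assay: str, readouts: pd.DataFrame) -> pd.DataFrame:
    """Apply one calculator to every row of a readout table.

    Row order and count are preserved; the result column is appended.
    ``assay`` is one of "sucrose", "atp", "complex", "ddct"; the required
    input columns are named exactly after the calculator's fields."""
    if assay not in _BATCH:
        raise ValueError(f"unknown assay {assay!r}; choose from {sorted(_BATCH)}")
    cols, fn, out_col = _BATCH[assay]
    missing = [c for c in cols if c not in readouts.columns]
    if missing:
        raise ValueError(f"readout table lacks columns {missing} for assay {assay!r}")
    out = readouts.copy()
    out[out_col] = [fn(row) for row in readouts.itertuples(index=False)]
    return out
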