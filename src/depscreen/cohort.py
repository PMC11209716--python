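"""Cohort container, behavioral measure definitions, and CSV round-trip.

A cohort is one row per animal: a ``mouse_id``, a group label (``Ctrl`` or
``CUMS``), one column per behavioral measure, and — for synthetic animals
only — an optional latent susceptibility tag (``resilient`` / ``susceptible``)
recording the mixture component the animal was drawn from.

Each measure carries a :class:`MeasureSpec` stating its units, its valid
range, and its *depressive direction*: whether low values (sucrose
preference, open-arm time) or high values (immobility time) indicate a
depressive-like phenotype.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    CohortSchemaError,
    DuplicateMouseIdError,
    UnknownGroupError,
)

GROUPS = ("Ctrl", "CUMS")
LATENT_TAGS = ("resilient", "susceptible")

Direction = Literal["low", "high"]


@dataclass(frozen=True)
class MeasureSpec:
    """Definition of one behavioral measure.

    Parameters
    ----------
    name : str
        Column name of the measure in cohort tables.
    units : str
        Physical units ("%" or "s").
    lower_bound, upper_bound : float
        Closed support of valid values; samples must lie strictly inside.
    direction : {"low", "high"}
        "low" if smaller values indicate a depressive-like phenotype
        (sucrose preference, open-arm time), "high" if larger values do
        (immobility time).
    """

    name: str
    units: str
    lower_bound: float
    upper_bound: float
    direction: Direction

    def __post_init__(self) -> None:
        if not self.lower_bound < self.upper_bound:
            raise ValueError(
                f"measure {self.name!r}: lower_bound ({self.lower_bound}) must be "
                f"< upper_bound ({self.upper_bound})"
            )
        if self.direction not in ("low", "high"):
            raise ValueError(
                f"measure {self.name!r}: direction must be 'low' or 'high', "
                f"got {self.direction!r}"
            )

    def check_values(self, values: Iterable[float], ids: Sequence[str] | None = None) -> None:
        """Raise :class:`BoundsError` naming the first offending record."""
        arr = np.asarray(list(values), dtype=float)
        bad = np.where((arr < self.lower_bound) | (arr > self.upper_bound))[0]
        if bad.size:
            i = int(bad[0])
            who = ids[i] if ids is not None else f"record {i}"
            raise BoundsError(
                f"{who}: {self.name} = {arr[i]} outside [{self.lower_bound}, "
                f"{self.upper_bound}] {self.units}"
            )


#: Sucrose preference (%), 12-h two-bottle test; anhedonia lowers it.
SPT = MeasureSpec("spt_pref_pct", "%", 0.0, 100.0, "low")
#: Open-arm time (s) in the 5-min elevated plus maze; anxiety lowers it.
EPM = MeasureSpec("epm_open_time_s", "s", 0.0, 300.0, "low")
#: Immobility time (s) in the scored last 4 min of the forced swim test;
#: behavioral despair raises it.
FST = MeasureSpec("fst_immobility_s", "s", 0.0, 240.0, "high")
#: Latency to feed (s) in novelty-suppressed feeding; a validation measure.
NSF = MeasureSpec("nsf_latency_s", "s", 0.0, 600.0, "high")

DEFAULT_MEASURES: tuple[MeasureSpec, ...] = (SPT, EPM, FST)

_MEASURE_REGISTRY = {m.name: m for m in (SPT, EPM, FST, NSF)}


def get_measure(name: str) -> MeasureSpec:
    """Look up a built-in measure spec by column name."""
    try:
        return _MEASURE_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; known: {sorted(_MEASURE_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class MouseRecord:
    """One animal: id, group, measure values, optional latent mixture tag."""

    mouse_id: str
    group: str
    measures: dict[str, float]
    latent: str | None = None


@dataclass
class Cohort:
    """Ordered collection of animals sharing a common measure set.

    Thin wrapper around a :class:`pandas.DataFrame` (``mouse_id``, ``group``,
    one column per measure, optional ``latent``) plus the measure specs and a
    free-text provenance string.
    """

    data: pd.DataFrame
    measure_specs: tuple[MeasureSpec, ...] = DEFAULT_MEASURES
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        validate_cohort_frame(self.data, self.measure_specs)

    @property
    def measure_names(self) -> list[str]:
        return [m.name for m in self.measure_specs]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise UnknownGroupError(f"unknown group {group!r}; expected one of {GROUPS}")
        return self.data[self.data["group"] == group]

    def records(self) -> list[MouseRecord]:
        out = []
        for _, row in self.data.iterrows():
            latent = row.get("latent")
            if isinstance(latent, float) and np.isnan(latent):
                latent = None
            out.append(
                MouseRecord(
                    mouse_id=str(row["mouse_id"]),
                    group=str(row["group"]),
                    measures={m: float(row[m]) for m in self.measure_names},
                    latent=latent if latent else None,
                )
            )
        return out


def validate_cohort_frame(
    df: pd.DataFrame, measure_specs: Sequence[MeasureSpec]
) -> None:
    """Validate schema, id uniqueness, group labels and measure bounds."""
    required = ["mouse_id", "group"] + [m.name for m in measure_specs]
    for col in required:
        if col not in df.columns:
            raise CohortSchemaError(f"cohort table lacks required column {col!r}")
    dup = df["mouse_id"][df["mouse_id"].duplicated()]
    if len(dup):
        raise DuplicateMouseIdError(f"duplicate mouse_id: {dup.iloc[0]!r}")
    bad_group = df.loc[~df["group"].isin(GROUPS), "group"]
    if len(bad_group):
        raise UnknownGroupError(
            f"unknown group label {bad_group.iloc[0]!r}; expected one of {GROUPS}"
        )
    if "latent" in df.columns:
        tags = df["latent"].dropna()
        tags = tags[tags != ""]
        bad = tags[~tags.isin(LATENT_TAGS)]
        if len(bad):
            raise CohortSchemaError(
                f"unknown latent tag {bad.iloc[0]!r}; expected one of {LATENT_TAGS}"
            )
    ids = df["mouse_id"].astype(str).tolist()
    for spec in measure_specs:
        vals = pd.to_numeric(df[spec.name], errors="coerce")
        if vals.isna().any():
            i = int(vals.index[vals.isna()][0])
            raise CohortSchemaError(
                f"{ids[i]}: non-numeric value in column {spec.name!r}"
            )
        spec.check_values(vals.to_numpy(), ids)


def write_cohort(cohort: Cohort, destination: str | Path | io.TextIOBase) -> None:
    """Write a cohort to CSV (UTF-8, '.' decimal separator).

    Values round-trip at full precision (shortest repr that parses back to
    the same float).
    """
    df = cohort.data.copy()
    if "latent" in df.columns:
        df["latent"] = df["latent"].fillna("")
    # repr is the shortest decimal string that parses back to the same float
    df.to_csv(destination, index=False, float_format=lambda v: repr(float(v)))


def read_cohort(
    source: str | Path | io.TextIOBase,
    measure_specs: Sequence[MeasureSpec] | None = None,
) -> Cohort:
    """Read and validate a cohort CSV.

    If ``measure_specs`` is None, specs are inferred from the header via the
    built-in measure registry (unknown measure columns are an error).
    """
    df = pd.read_csv(source, dtype={"mouse_id": str}, float_precision="round_trip")
    if measure_specs is None:
        known = set(_MEASURE_REGISTRY)
        measure_specs = tuple(
            _MEASURE_REGISTRY[c] for c in df.columns if c in known
        )
        if not measure_specs:
            raise CohortSchemaError(
                "no recognized measure columns in header "
                f"{list(df.columns)}; known: {sorted(known)}"
            )
    if "latent" in df.columns:
        df["latent"] = df["latent"].replace("", np.nan)
    src = getattr(source, "name", str(source))
    return Cohort(df, tuple(measure_specs), provenance=f"loaded-from-file:{src}")
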