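"""Domain types and CSV I/O for paired device-vs-reference hemodynamic observations.

The unit of data is a *paired observation*: at one protocol time point, for one
animal and one hemodynamic variable, the value recorded by the invasive
reference (arterial line for SBP/DBP/HR, Swan-Ganz thermodilution for CO) and
the value reported by the non-invasive test device. A :class:`Dataset` holds a
long-format table of such pairs; a :class:`MeasurementSeries` is the
time-ordered slice for one animal x variable, the unit on which outlier
screening and successive-change (trending) analysis operate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "VARIABLES",
    "BP_VARIABLES",
    "UNITS",
    "COLUMNS",
    "SchemaError",
    "ValidationError",
    "PairedObservation",
    "MeasurementSeries",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "split_series",
]

#: Study phases in protocol order: baseline, controlled 35% blood-volume
#: withdrawal, untreated follow-up.
PHASES: tuple[str, ...] = ("pre_bleeding", "bleeding", "post_bleeding")

#: Hemodynamic variables compared between device and invasive reference.
VARIABLES: tuple[str, ...] = ("SBP", "DBP", "HR", "CO")

#: Blood-pressure variables (mmHg); these get the ±5/10/15 mmHg error bins.
BP_VARIABLES: tuple[str, ...] = ("SBP", "DBP")

UNITS: dict[str, str] = {
    "SBP": "mmHg",
    "DBP": "mmHg",
    "HR": "beats/min",
    "CO": "l/min",
}

#: Canonical CSV column order.
COLUMNS: tuple[str, ...] = (
    "animal_id",
    "phase",
    "time_min",
    "variable",
    "reference_value",
    "device_value",
)

_PHASE_ORDER = {p: i for i, p in enumerate(PHASES)}


class SchemaError(ValueError):
    """A table is missing required columns or has unusable structure."""


class ValidationError(ValueError):
    """Row-level contents violate a dataset invariant."""


@dataclass(frozen=True)
class PairedObservation:
    """One timestamped (reference, device) value pair.

    ``time_min`` is minutes since protocol start for that animal; both values
    are strictly positive and share the variable's unit (mmHg for SBP/DBP,
    beats/min for HR, l/min for CO).
    """

    animal_id: str
    phase: str
    time_min: float
    variable: str
    reference_value: float
    device_value: float

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.variable not in VARIABLES:
            raise ValidationError(f"unknown variable {self.variable!r}")
        for name in ("reference_value", "device_value"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v}")
        if not np.isfinite(self.time_min) or self.time_min < 0:
            raise ValidationError(f"time_min must be finite and >= 0, got {self.time_min}")


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce types and enforce all Dataset invariants; return a clean copy."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.loc[:, list(COLUMNS)].copy()
    df["animal_id"] = df["animal_id"].astype(str)
    df["phase"] = df["phase"].astype(str)
    df["variable"] = df["variable"].astype(str)
    for col in ("time_min", "reference_value", "device_value"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"column {col!r} is not numeric: {exc}") from exc
        df[col] = df[col].astype(float)

    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        idx = int(df.index[bad_phase][0])
        raise ValidationError(
            f"row {idx}: unknown phase {df.loc[idx, 'phase']!r} "
            f"(expected one of {PHASES})"
        )
    bad_var = ~df["variable"].isin(VARIABLES)
    if bad_var.any():
        idx = int(df.index[bad_var][0])
        raise ValidationError(
            f"row {idx}: unknown variable {df.loc[idx, 'variable']!r} "
            f"(expected one of {VARIABLES})"
        )
    for col in ("reference_value", "device_value"):
        bad = ~np.isfinite(df[col]) | (df[col] <= 0)
        if bad.any():
            idx = int(df.index[bad][0])
            raise ValidationError(
                f"row {idx}: {col} = {df.loc[idx, col]} is not finite and > 0"
            )
    bad_t = ~np.isfinite(df["time_min"]) | (df["time_min"] < 0)
    if bad_t.any():
        idx = int(df.index[bad_t][0])
        raise ValidationError(f"row {idx}: time_min = {df.loc[idx, 'time_min']} invalid")

    dup = df.duplicated(subset=["animal_id", "variable", "time_min"])
    if dup.any():
        idx = int(df.index[dup][0])
        key = tuple(df.loc[idx, ["animal_id", "variable", "time_min"]])
        raise ValidationError(f"duplicate (animal_id, variable, time_min) key {key}")

    # Phase membership must respect time ordering within an animal: every
    # pre-bleeding time precedes every bleeding time, which precedes every
    # post-bleeding time. Phase boundaries differ between animals, so this is
    # checked per animal, pooled over variables.
    for animal, sub in df.groupby("animal_id", sort=False):
        bounds = sub.groupby("phase")["time_min"].agg(["min", "max"])
        present = [p for p in PHASES if p in bounds.index]
        for earlier, later in zip(present[:-1], present[1:]):
            if bounds.loc[earlier, "max"] >= bounds.loc[later, "min"]:
                raise ValidationError(
                    f"animal {animal!r}: {earlier} times overlap {later} times"
                )
    return df


def _canonical_sort(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["animal_id", "variable", "time_min"], kind="mergesort"
    ).reset_index(drop=True)


class Dataset:
    """A validated long-format collection of paired observations.

    Parameters
    ----------
    data : pandas.DataFrame or iterable of PairedObservation
        Long-format table with columns ``animal_id, phase, time_min, variable,
        reference_value, device_value`` (extra columns are dropped).
    provenance : str
        Free-text origin ("simulated", a file path, ...).
    metadata : dict, optional
        Side information (e.g. ground-truth spike locations for a fixture).
        Never serialized to CSV.
    """

    def __init__(
        self,
        data: pd.DataFrame | Iterable[PairedObservation],
        provenance: str = "",
        metadata: dict | None = None,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            df = data
        else:
            rows = list(data)
            df = pd.DataFrame(
                [
                    (o.animal_id, o.phase, o.time_min, o.variable,
                     o.reference_value, o.device_value)
                    for o in rows
                ],
                columns=list(COLUMNS),
            )
        if df.empty:
            df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                COLUMNS, (str, str, float, str, float, float))})
            self._df = df
        else:
            self._df = _validate_frame(df).reset_index(drop=True)
        self.provenance = provenance
        self.metadata: dict = dict(metadata or {})

    @property
    def df(self) -> pd.DataFrame:
        """The underlying long-format table (treat as read-only)."""
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        a = _canonical_sort(self._df)
        b = _canonical_sort(other._df)
        return a.equals(b)

    def __repr__(self) -> str:
        n_animals = self._df["animal_id"].nunique() if len(self) else 0
        return (
            f"<Dataset: {len(self)} paired observations, "
            f"{n_animals} animals, provenance={self.provenance!r}>"
        )

    def observations(self) -> list[PairedObservation]:
        return [
            PairedObservation(
                r.animal_id, r.phase, r.time_min, r.variable,
                r.reference_value, r.device_value,
            )
            for r in self._df.itertuples(index=False)
        ]

    def counts(self) -> pd.DataFrame:
        """Pair counts per variable x phase (long-format)."""
        out = (
            self._df.groupby(["variable", "phase"], sort=False)
            .size()
            .rename("n")
            .reset_index()
        )
        return out

    def select(
        self,
        variable: str | None = None,
        phase: str | None = None,
        animal_id: str | None = None,
    ) -> pd.DataFrame:
        sub = self._df
        if variable is not None:
            sub = sub[sub["variable"] == variable]
        if phase is not None:
            sub = sub[sub["phase"] == phase]
        if animal_id is not None:
            sub = sub[sub["animal_id"] == animal_id]
        return sub


@dataclass
class MeasurementSeries:
    """Time-ordered observations for one animal x variable."""

    animal_id: str
    variable: str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.df):
            t = self.df["time_min"].to_numpy()
            if not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"series ({self.animal_id}, {self.variable}): "
                    "time_min not strictly increasing"
                )
            if not (self.df["animal_id"] == self.animal_id).all():
                raise ValidationError("series rows mix animal_id values")
            if not (self.df["variable"] == self.variable).all():
                raise ValidationError("series rows mix variable values")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["time_min"].to_numpy()

    @property
    def reference(self) -> np.ndarray:
        return self.df["reference_value"].to_numpy()

    @property
    def device(self) -> np.ndarray:
        return self.df["device_value"].to_numpy()


def split_series(dataset: Dataset) -> list[MeasurementSeries]:
    """Partition a dataset into per-(animal, variable) time-ordered series.

    Every observation lands in exactly one series; the sum of series lengths
    equals ``len(dataset)``.
    """
    out: list[MeasurementSeries] = []
    if len(dataset) == 0:
        return out
    for (animal, var), sub in dataset.df.groupby(["animal_id", "variable"], sort=True):
        sub = sub.sort_values("time_min", kind="mergesort").reset_index(drop=True)
        out.append(MeasurementSeries(animal_id=animal, variable=var, df=sub))
    return out


def read_dataset(path: str | Path) -> Dataset:
    """Read and validate a paired-observation CSV.

    The header must name the six canonical columns. A file with a header but
    no data rows yields an empty Dataset with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing: values written with shortest-repr serialization
    # must re-read bit-identically for the round-trip identity to hold
    df = pd.read_csv(path, dtype={"animal_id": str}, float_precision="round_trip")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
    return Dataset(df, provenance=str(path))


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV with deterministic column and row order.

    Rows are sorted by (animal_id, variable, time_min); repeated writes of the
    same dataset are byte-identical, and ``read_dataset`` round-trips exactly
    (float64 values are serialized with shortest round-trip repr).
    """
    path = Path(path)
    df = _canonical_sort(dataset.df) if len(dataset) else dataset.df
    df.to_csv(path, index=False, columns=list(COLUMNS), lineterminator="\n")
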