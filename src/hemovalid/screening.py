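"""Outlier screening of the invasive reference series before analysis.

The screen targets single-point artifacts (catheter flushes, transducer
knocks, mis-timed thermodilution runs): for every interior point of each
animal x variable series, the percentage difference of the reference value
from its preceding and its following neighbour is computed. Per variable,
pooled across animals, the SD of all these signed percentage differences sets
a band of +/- k*SD (k = 2 by default); a point is eliminated only when its
percentage difference exceeds the band against BOTH neighbours — a genuine
spike sticks out on both sides, whereas a step change or a steady decline does
not. Screening is single-pass, never touches endpoints, and removes the paired
device value together with the reference value so downstream pairs stay
aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Dataset, MeasurementSeries, VARIABLES, split_series

__all__ = ["OutlierReport", "percent_deltas", "screen_outliers"]


@dataclass
class OutlierReport:
    """Outcome of one screening pass."""

    removed: list[tuple[str, str, float]] = field(default_factory=list)
    per_variable_counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    total_screened: int = 0

    def __post_init__(self) -> None:
        assert sum(self.per_variable_counts.values()) == len(self.removed)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    @property
    def removed_fraction(self) -> float:
        if self.total_screened == 0:
            return 0.0
        return len(self.removed) / self.total_screened

    def to_dict(self) -> dict:
        return {
            "removed": [
                {"animal_id": a, "variable": v, "time_min": t}
                for a, v, t in self.removed
            ],
            "per_variable_counts": dict(self.per_variable_counts),
            "thresholds": dict(self.thresholds),
            "total_screened": self.total_screened,
            "n_removed": self.n_removed,
        }


def percent_deltas(series: MeasurementSeries) -> pd.DataFrame:
    """Signed percentage differences of each interior reference value from
    its neighbours.

    Returns a frame with one row per interior point: ``time_min``,
    ``delta_prev`` = 100*(x_i - x_{i-1})/x_{i-1} and
    ``delta_next`` = 100*(x_i - x_{i+1})/x_{i+1}. Endpoints yield no row; a
    zero neighbour makes the corresponding delta undefined (NaN, flagged with
    a warning) and the point is skipped by the screen.
    """
    x = series.reference
    t = series.times
    if len(x) < 3:
        return pd.DataFrame(columns=["time_min", "delta_prev", "delta_next"])
    prev, cur, nxt = x[:-2], x[1:-1], x[2:]
    with np.errstate(divide="ignore", invalid="ignore"):
        d_prev = np.where(prev != 0, 100.0 * (cur - prev) / prev, np.nan)
        d_next = np.where(nxt != 0, 100.0 * (cur - nxt) / nxt, np.nan)
    if np.isnan(d_prev).any() or np.isnan(d_next).any():
        warnings.warn(
            f"series ({series.animal_id}, {series.variable}): zero neighbour "
            "value, delta undefined for some points", stacklevel=2)
    return pd.DataFrame({
        "time_min": t[1:-1],
        "delta_prev": d_prev,
        "delta_next": d_next,
    })


def screen_outliers(dataset: Dataset, k: float = 2.0) -> tuple[Dataset, OutlierReport]:
    """Apply the two-sided percentage-difference screen to a dataset.

    Per variable, pooled across animals: threshold T = k * SD of all signed
    interior percentage differences (prev and next combined); a point is
    removed iff |delta_prev| > T and |delta_next| > T. Single pass; surviving
    rows are returned unaltered.

    Returns the screened dataset and an :class:`OutlierReport`.
    """
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    series_list = split_series(dataset)
    deltas_by_var: dict[str, list[pd.DataFrame]] = {}
    for s in series_list:
        d = percent_deltas(s)
        if len(d):
            d = d.assign(animal_id=s.animal_id)
            deltas_by_var.setdefault(s.variable, []).append(d)

    thresholds: dict[str, float] = {}
    removed: list[tuple[str, str, float]] = []
    per_var: dict[str, int] = {}
    total_screened = 0

    for var in VARIABLES:
        parts = deltas_by_var.get(var)
        if not parts:
            if len(dataset.select(variable=var)):
                warnings.warn(
                    f"variable {var}: no series with >= 3 points, screening skipped",
                    stacklevel=2)
            continue
        tab = pd.concat(parts, ignore_index=True)
        pooled = np.concatenate([
            tab["delta_prev"].to_numpy(), tab["delta_next"].to_numpy()])
        pooled = pooled[np.isfinite(pooled)]
        if len(pooled) < 2:
            warnings.warn(f"variable {var}: too few deltas, screening skipped",
                          stacklevel=2)
            continue
        sd = float(np.std(pooled, ddof=1))
        t_cut = k * sd
        thresholds[var] = t_cut
        total_screened += len(tab)

        hit = (
            np.isfinite(tab["delta_prev"]) & np.isfinite(tab["delta_next"])
            & (tab["delta_prev"].abs() > t_cut)
            & (tab["delta_next"].abs() > t_cut)
        )
        n_hit = int(hit.sum())
        per_var[var] = n_hit
        for _, row in tab.loc[hit].iterrows():
            removed.append((row["animal_id"], var, float(row["time_min"])))

    report = OutlierReport(
        removed=sorted(removed),
        per_variable_counts={v: per_var.get(v, 0) for v in per_var},
        thresholds=thresholds,
        total_screened=total_screened,
    )

    if removed:
        df = dataset.df
        key = pd.MultiIndex.from_frame(df[["animal_id", "variable", "time_min"]])
        drop = key.isin(pd.MultiIndex.from_tuples(
            [(a, v, t) for a, v, t in removed]))
        clean = Dataset(df.loc[~drop], provenance=dataset.provenance,
                        metadata=dataset.metadata)
    else:
        clean = Dataset(dataset.df, provenance=dataset.provenance,
                        metadata=dataset.metadata)
    return clean, report
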