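"""Trending (successive-change) analysis: four-quadrant concordance.

A monitor can be biased yet still track *changes* faithfully, which is what
matters when titrating therapy. For each animal's series the change between
every pair of consecutive surviving observations is computed on both channels
over the same interval; the scatter of device changes against reference
changes is the four-quadrant plot. Small changes inside a central exclusion
zone (|change| <= 2 mmHg for the pressures, 0.5 l/min for cardiac output on
both axes) carry no directional information and are excluded; among the rest,
the concordance rate is the percentage falling in the agreeing quadrants
(both channels moved the same direction, strict signs — a zero on either axis
belongs to no quadrant and never counts as concordant). The Pearson
correlation of the change pairs is reported alongside.

Analysed variables are SBP, DBP and CO; heart-rate trending is not part of
the standard panel. Changes chain across phase boundaries within an animal,
so intervals may differ in duration after screening.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Dataset, MeasurementSeries, split_series

__all__ = [
    "DEFAULT_ZONES",
    "TRENDED_VARIABLES",
    "ChangePair",
    "TrendingResult",
    "successive_changes",
    "four_quadrant",
    "TrendingAnalysis",
    "TrendingResults",
    "trending_table",
]

#: Exclusion-zone half-widths, units of each variable.
DEFAULT_ZONES: dict[str, float] = {"SBP": 2.0, "DBP": 2.0, "CO": 0.5}

#: Variables included in the trending panel.
TRENDED_VARIABLES: tuple[str, ...] = ("SBP", "DBP", "CO")


@dataclass
class ChangePair:
    """Change over one interval of consecutive observations, both channels."""

    animal_id: str
    variable: str
    t_from: float
    t_to: float
    d_ref: float
    d_dev: float
    excluded: bool = False
    reason: str = ""


@dataclass
class TrendingResult:
    """Four-quadrant summary for one variable."""

    variable: str
    zone: float
    n_changes_total: int
    n_excluded: int
    n_concordant: int
    concordance_rate: float  # percent; NaN when every pair is excluded
    change_r: float
    p_value: float
    all_excluded: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def successive_changes(series: MeasurementSeries) -> list[ChangePair]:
    """One :class:`ChangePair` per consecutive observation pair of a series.

    A series of n observations yields exactly n-1 change pairs; series shorter
    than 2 yield none.
    """
    if len(series) < 2:
        return []
    t = series.times
    r = series.reference
    d = series.device
    return [
        ChangePair(
            animal_id=series.animal_id,
            variable=series.variable,
            t_from=float(t[i]),
            t_to=float(t[i + 1]),
            d_ref=float(r[i + 1] - r[i]),
            d_dev=float(d[i + 1] - d[i]),
        )
        for i in range(len(t) - 1)
    ]


def four_quadrant(
    change_pairs: list[ChangePair],
    zone: float,
    include_excluded_in_denominator: bool = False,
) -> TrendingResult:
    """Four-quadrant concordance with a central exclusion square.

    A pair is excluded iff |d_ref| <= zone AND |d_dev| <= zone (inclusive
    boundary). Among non-excluded pairs, concordant iff
    sign(d_ref)*sign(d_dev) > 0; the rate is 100 * concordant / retained
    (or / total with the literal all-points denominator). ``change_r`` is the
    Pearson correlation over non-excluded pairs.
    """
    if not change_pairs:
        raise ValueError("no change pairs supplied")
    variables = {p.variable for p in change_pairs}
    if len(variables) > 1:
        raise ValueError(f"change pairs mix variables: {sorted(variables)}")
    variable = change_pairs[0].variable
    if zone < 0:
        raise ValueError(f"zone must be >= 0, got {zone}")

    d_ref = np.array([p.d_ref for p in change_pairs])
    d_dev = np.array([p.d_dev for p in change_pairs])
    excl = (np.abs(d_ref) <= zone) & (np.abs(d_dev) <= zone)
    for p, e in zip(change_pairs, excl):
        p.excluded = bool(e)
        p.reason = "inside exclusion zone" if e else ""

    n_total = len(change_pairs)
    n_excl = int(excl.sum())
    keep = ~excl
    conc = keep & (np.sign(d_ref) * np.sign(d_dev) > 0)
    n_conc = int(conc.sum())

    denom = n_total if include_excluded_in_denominator else n_total - n_excl
    all_excluded = n_total == n_excl
    if denom == 0:
        rate = float("nan")
    else:
        rate = 100.0 * n_conc / denom

    if keep.sum() >= 3 and np.ptp(d_ref[keep]) > 0 and np.ptp(d_dev[keep]) > 0:
        r, p = stats.pearsonr(d_ref[keep], d_dev[keep])
    else:
        r, p = float("nan"), float("nan")

    return TrendingResult(
        variable=variable,
        zone=zone,
        n_changes_total=n_total,
        n_excluded=n_excl,
        n_concordant=n_conc,
        concordance_rate=rate,
        change_r=float(r),
        p_value=float(p),
        all_excluded=all_excluded,
    )


class TrendingAnalysis:
    """Model object: trending ability of the device over a dataset.

    Parameters
    ----------
    dataset : Dataset
        Screened paired-observation dataset.
    zones : mapping, optional
        Exclusion half-width per variable (defaults: 2 mmHg BP, 0.5 l/min CO).
    variables : sequence, optional
        Variables to analyse (default SBP, DBP, CO).
    include_excluded_in_denominator : bool
        Use the literal all-points denominator instead of the retained-points
        denominator.
    """

    def __init__(
        self,
        dataset: Dataset,
        zones: dict[str, float] | None = None,
        variables: tuple[str, ...] = TRENDED_VARIABLES,
        include_excluded_in_denominator: bool = False,
    ) -> None:
        self.dataset = dataset
        self.zones = dict(DEFAULT_ZONES)
        if zones:
            self.zones.update(zones)
        self.variables = tuple(variables)
        self.include_excluded_in_denominator = include_excluded_in_denominator

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TrendingAnalysis":
        return cls(Dataset(df, provenance="dataframe"), **kwargs)

    def changes(self, variable: str) -> list[ChangePair]:
        out: list[ChangePair] = []
        for s in split_series(self.dataset):
            if s.variable == variable:
                out.extend(successive_changes(s))
        return out

    def fit(self) -> "TrendingResults":
        results: list[TrendingResult] = []
        change_map: dict[str, list[ChangePair]] = {}
        for var in self.variables:
            pairs = self.changes(var)
            if not pairs:
                warnings.warn(f"variable {var}: no successive changes, skipped",
                              stacklevel=2)
                continue
            res = four_quadrant(
                pairs, self.zones[var],
                include_excluded_in_denominator=self.include_excluded_in_denominator,
            )
            results.append(res)
            change_map[var] = pairs
        return TrendingResults(results, change_map)


class TrendingResults:
    """Fitted trending panel: one :class:`TrendingResult` per variable."""

    def __init__(self, results: list[TrendingResult],
                 changes: dict[str, list[ChangePair]] | None = None) -> None:
        self.results = results
        self.changes = changes or {}

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def get(self, variable: str) -> TrendingResult:
        for r in self.results:
            if r.variable == variable:
                return r
        raise KeyError(f"no trending result for {variable}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def summary(self) -> str:
        lines = [
            "Four-quadrant trending concordance",
            "=" * 64,
            f"{'var':<5}{'zone':>6}{'changes':>9}{'excluded':>10}"
            f"{'concordant':>12}{'rate %':>8}{'r':>7}",
            "-" * 64,
        ]
        for r in self.results:
            rate = f"{r.concordance_rate:7.1f}" if np.isfinite(r.concordance_rate) else "      -"
            lines.append(
                f"{r.variable:<5}{r.zone:>6.1f}{r.n_changes_total:>9}"
                f"{r.n_excluded:>10}{r.n_concordant:>12}{rate:>8}{r.change_r:7.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def plot_four_quadrant(self, variable: str, ax=None):
        from .plots import four_quadrant_plot
        if variable not in self.changes:
            raise KeyError(f"no change pairs stored for {variable}")
        return four_quadrant_plot(self.changes[variable], self.get(variable), ax=ax)


def trending_table(dataset: Dataset, zones: dict[str, float] | None = None,
                   **kwargs) -> list[TrendingResult]:
    """Convenience: fit :class:`TrendingAnalysis` and return the result list."""
    return TrendingAnalysis(dataset, zones=zones, **kwargs).fit().results
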