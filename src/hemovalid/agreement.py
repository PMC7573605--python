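"""Static (point-wise) agreement between a test device and an invasive reference.

For each hemodynamic variable and stratum (each protocol phase, plus all
phases combined) the analysis reports the classical method-comparison suite:

- Pearson correlation and the device-on-reference OLS regression line, with
  two-sided tests that the slope and the intercept are zero;
- the intraclass correlation coefficient in its two-way random-effects,
  absolute-agreement, single-measurement form (McGraw & Wong ICC(A,1),
  Shrout-Fleiss ICC(2,1)), computed from the two-way ANOVA mean squares, and
  the standard error of measurement SEM = pooled SD * sqrt(1 - ICC);
- Bland-Altman bias (mean of device - reference differences), SD of the
  differences and the 95% limits of agreement bias +/- 1.96*SD;
- the Critchley percentage error for cardiac output,
  100 * 1.96 * SD(diff) / mean(reference CO), conventionally acceptable up
  to 30% for CO monitors;
- for the blood pressures, the share of pairs within +/-5, 10 and 15 mmHg
  (the binning used by cuff-device validation protocols);
- Kolmogorov-Smirnov (Lilliefors) and Shapiro-Wilk normality p-values on the
  differences (reported, never used as a gate).

Use :class:`AgreementAnalysis` (model) -> :class:`AgreementResults` for the
full table, or the module-level functions for single statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .data_model import Dataset, PHASES, VARIABLES, BP_VARIABLES

__all__ = [
    "DegenerateInputError",
    "AgreementResult",
    "AgreementAnalysis",
    "AgreementResults",
    "pearson_regression",
    "icc_sem",
    "bland_altman",
    "percentage_error",
    "bp_error_bins",
    "normality_tests",
    "agreement_table",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


class DegenerateInputError(ValueError):
    """Input has no variance (or too few pairs) for the requested statistic."""


def _as_arrays(reference: Sequence[float], device: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(reference, dtype=float)
    d = np.asarray(device, dtype=float)
    if r.shape != d.shape or r.ndim != 1:
        raise ValueError("reference and device must be 1-d sequences of equal length")
    return r, d


def pearson_regression(reference: Sequence[float], device: Sequence[float]) -> dict:
    """Pearson r and the device-on-reference OLS line.

    Returns ``{"r", "p", "slope", "intercept", "p_slope", "p_intercept"}``;
    the p-values test slope = 0 and intercept = 0 (two-sided).
    """
    r_arr, d_arr = _as_arrays(reference, device)
    n = len(r_arr)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 pairs, got {n}")
    if np.ptp(r_arr) == 0 or np.ptp(d_arr) == 0:
        raise DegenerateInputError("zero variance on one channel; r undefined")
    r, p = stats.pearsonr(r_arr, d_arr)
    ols = sm.OLS(d_arr, sm.add_constant(r_arr)).fit()
    return {
        "r": float(r),
        "p": float(p),
        "slope": float(ols.params[1]),
        "intercept": float(ols.params[0]),
        "p_slope": float(ols.pvalues[1]),
        "p_intercept": float(ols.pvalues[0]),
    }


def icc_sem(reference: Sequence[float], device: Sequence[float]) -> dict:
    """ICC(A,1) and the standard error of measurement for paired methods.

    Two-way random-effects, absolute-agreement, single-measurement ICC from
    the two-way ANOVA mean squares, with the n subjects = pairs and k = 2
    raters = {reference, device}:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE))

    SEM = pooled SD of all 2n measurements * sqrt(1 - ICC). A negative ICC
    estimate is clamped to 0 and flagged (``clamped``); zero between-subject
    variance flags ``degenerate``.
    """
    r_arr, d_arr = _as_arrays(reference, device)
    n = len(r_arr)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 pairs, got {n}")
    k = 2
    table = np.column_stack([r_arr, d_arr])
    grand = table.mean()
    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = table - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))

    degenerate = np.ptp(row_means) == 0  # no between-subject variance
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        icc = 0.0
        clamped = True
    else:
        icc = float((msr - mse) / denom)
        clamped = icc < 0
        icc = max(icc, 0.0)
    pooled_sd = float(np.std(table, ddof=1))
    sem = pooled_sd * float(np.sqrt(1.0 - min(icc, 1.0)))
    return {"icc": icc, "sem_measurement": sem, "clamped": clamped,
            "degenerate": bool(degenerate)}


def bland_altman(reference: Sequence[float], device: Sequence[float]) -> dict:
    """Bias, SD of differences and 95% limits of agreement.

    Differences are device - reference; SD uses the n-1 denominator; limits
    are bias +/- 1.96*SD.
    """
    r_arr, d_arr = _as_arrays(reference, device)
    if len(r_arr) < 2:
        raise DegenerateInputError(f"need >= 2 pairs, got {len(r_arr)}")
    diff = d_arr - r_arr
    bias = float(diff.mean())
    sd = float(np.std(diff, ddof=1))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_lower": bias - LOA_MULTIPLIER * sd,
        "loa_upper": bias + LOA_MULTIPLIER * sd,
    }


def percentage_error(reference: Sequence[float], device: Sequence[float]) -> float:
    """Critchley percentage error: 100 * 1.96 * SD(diff) / mean(reference).

    Scale-invariant under a common unit change of both channels; intended for
    cardiac output, where <= 30% is the conventional acceptability bound.
    """
    r_arr, d_arr = _as_arrays(reference, device)
    if len(r_arr) < 2:
        raise DegenerateInputError(f"need >= 2 pairs, got {len(r_arr)}")
    mean_ref = float(r_arr.mean())
    if mean_ref <= 0:
        raise DegenerateInputError("mean reference value must be > 0")
    sd = float(np.std(d_arr - r_arr, ddof=1))
    return 100.0 * LOA_MULTIPLIER * sd / mean_ref


def bp_error_bins(reference: Sequence[float], device: Sequence[float]) -> dict:
    """Share of pairs with |device - reference| within 5, 10 and 15 mmHg.

    Boundaries are inclusive; returns percentages, which are nested
    (within_5 <= within_10 <= within_15).
    """
    r_arr, d_arr = _as_arrays(reference, device)
    if len(r_arr) == 0:
        raise DegenerateInputError("no pairs")
    adiff = np.abs(d_arr - r_arr)
    n = len(adiff)
    return {
        "within_5": 100.0 * np.count_nonzero(adiff <= 5.0) / n,
        "within_10": 100.0 * np.count_nonzero(adiff <= 10.0) / n,
        "within_15": 100.0 * np.count_nonzero(adiff <= 15.0) / n,
    }


def normality_tests(values: Sequence[float]) -> dict:
    """Kolmogorov-Smirnov (Lilliefors) and Shapiro-Wilk p-values.

    Applied to the device-reference differences of a stratum. Constant input
    is flagged degenerate (p-values NaN). The KS test uses the Lilliefors
    correction for estimated mean/SD, as statistics packages do.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise DegenerateInputError(f"need >= 3 values, got {len(v)}")
    if np.ptp(v) == 0:
        return {"ks_p": float("nan"), "sw_p": float("nan"), "degenerate": True}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, ks_p = lilliefors(v, dist="norm")
        _, sw_p = stats.shapiro(v)
    return {"ks_p": float(ks_p), "sw_p": float(sw_p), "degenerate": False}


@dataclass
class AgreementResult:
    """All static agreement statistics for one variable x stratum."""

    variable: str
    stratum: str
    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    p_slope: float
    p_intercept: float
    icc: float
    icc_clamped: bool
    sem_measurement: float
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    percentage_error: float | None
    within_5: float | None
    within_10: float | None
    within_15: float | None
    ks_p: float
    sw_p: float
    normality_degenerate: bool

    def to_dict(self) -> dict:
        return asdict(self)


def _fit_stratum(variable: str, stratum: str, sub: pd.DataFrame) -> AgreementResult:
    ref = sub["reference_value"].to_numpy()
    dev = sub["device_value"].to_numpy()
    reg = pearson_regression(ref, dev)
    icc = icc_sem(ref, dev)
    ba = bland_altman(ref, dev)
    norm = normality_tests(dev - ref)
    pe = percentage_error(ref, dev) if variable == "CO" else None
    bins = bp_error_bins(ref, dev) if variable in BP_VARIABLES else {}
    return AgreementResult(
        variable=variable,
        stratum=stratum,
        n=len(sub),
        pearson_r=reg["r"],
        p_value=reg["p"],
        slope=reg["slope"],
        intercept=reg["intercept"],
        p_slope=reg["p_slope"],
        p_intercept=reg["p_intercept"],
        icc=icc["icc"],
        icc_clamped=icc["clamped"],
        sem_measurement=icc["sem_measurement"],
        bias=ba["bias"],
        sd_diff=ba["sd_diff"],
        loa_lower=ba["loa_lower"],
        loa_upper=ba["loa_upper"],
        percentage_error=pe,
        within_5=bins.get("within_5"),
        within_10=bins.get("within_10"),
        within_15=bins.get("within_15"),
        ks_p=norm["ks_p"],
        sw_p=norm["sw_p"],
        normality_degenerate=norm["degenerate"],
    )


class AgreementAnalysis:
    """Model object: static agreement of device vs reference on a dataset.

    Parameters
    ----------
    dataset : Dataset
        A (screened) paired-observation dataset.
    min_pairs : int
        Strata with fewer pairs are skipped with a warning.
    """

    def __init__(self, dataset: Dataset, min_pairs: int = 3) -> None:
        self.dataset = dataset
        self.min_pairs = int(min_pairs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AgreementAnalysis":
        return cls(Dataset(df, provenance="dataframe"), **kwargs)

    def fit(self) -> "AgreementResults":
        results: list[AgreementResult] = []
        df = self.dataset.df
        for var in VARIABLES:
            dvar = df[df["variable"] == var]
            if dvar.empty:
                continue
            for stratum in (*PHASES, "all"):
                sub = dvar if stratum == "all" else dvar[dvar["phase"] == stratum]
                if len(sub) < self.min_pairs:
                    if len(sub):
                        warnings.warn(
                            f"{var}/{stratum}: only {len(sub)} pairs "
                            f"(< {self.min_pairs}), stratum skipped", stacklevel=2)
                    continue
                try:
                    results.append(_fit_stratum(var, stratum, sub))
                except DegenerateInputError as exc:
                    warnings.warn(f"{var}/{stratum}: {exc}; stratum skipped",
                                  stacklevel=2)
        return AgreementResults(results, dataset=self.dataset)


class AgreementResults:
    """Fitted agreement table; one :class:`AgreementResult` per variable x stratum."""

    def __init__(self, results: list[AgreementResult], dataset: Dataset | None = None) -> None:
        self.results = results
        self.dataset = dataset

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def get(self, variable: str, stratum: str = "all") -> AgreementResult:
        for r in self.results:
            if r.variable == variable and r.stratum == stratum:
                return r
        raise KeyError(f"no result for ({variable}, {stratum})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.results])

    def summary(self) -> str:
        """Human-readable per-stratum table."""
        lines = [
            "Agreement of device vs invasive reference",
            "=" * 78,
            f"{'var':<5}{'stratum':<14}{'n':>5}{'r':>7}{'ICC':>7}{'SEM':>7}"
            f"{'bias':>8}{'LOA lo':>8}{'LOA hi':>8}{'PE%':>7}{'<=15':>6}",
            "-" * 78,
        ]
        for r in self.results:
            pe = f"{r.percentage_error:6.1f}" if r.percentage_error is not None else "     -"
            w15 = f"{r.within_15:5.1f}" if r.within_15 is not None else "    -"
            lines.append(
                f"{r.variable:<5}{r.stratum:<14}{r.n:>5}{r.pearson_r:7.3f}"
                f"{r.icc:7.3f}{r.sem_measurement:7.2f}{r.bias:8.2f}"
                f"{r.loa_lower:8.2f}{r.loa_upper:8.2f}{pe:>7}{w15:>6}"
            )
        lines.append("=" * 78)
        return "\n".join(lines)

    def plot_bland_altman(self, variable: str, ax=None):
        from .plots import bland_altman_plot
        if self.dataset is None:
            raise ValueError("results carry no dataset; cannot plot")
        return bland_altman_plot(self.dataset, self.get(variable, "all"), ax=ax)

    def plot_regression(self, variable: str, ax=None):
        from .plots import regression_plot
        if self.dataset is None:
            raise ValueError("results carry no dataset; cannot plot")
        return regression_plot(self.dataset, self.get(variable, "all"), ax=ax)


def agreement_table(dataset: Dataset, min_pairs: int = 3) -> list[AgreementResult]:
    """Convenience: fit :class:`AgreementAnalysis` and return the result list."""
    return AgreementAnalysis(dataset, min_pairs=min_pairs).fit().results
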