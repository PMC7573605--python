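"""End-to-end validation pipeline and structured report.

:class:`ValidationStudy` sequences the stages the way a validation analysis
runs them — ingest or simulate, screen outliers, static agreement, trending —
and its :meth:`fit` returns a :class:`ValidationReport` carrying every stage's
output plus convenience pass/fail flags against published acceptability
bounds (cardiac-output percentage error <= 30%; BP within +/-15 mmHg of the
reference for at least a configurable share of pairs). The flags reference
conventional thresholds; they are not regulatory claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import Dataset, read_dataset, BP_VARIABLES
from .synthetic_cohort import SimConfig, simulate_experiment
from .screening import OutlierReport, screen_outliers
from .agreement import AgreementAnalysis, AgreementResults
from .trending import TrendingAnalysis, TrendingResults

__all__ = ["ValidationStudy", "ValidationReport", "run_pipeline"]

SCHEMA_VERSION = 1


@dataclass
class ValidationReport:
    """Structured output of one full pipeline run."""

    provenance: str
    n_observations: int
    n_after_screening: int
    counts_per_stratum: dict[str, dict[str, int]]
    outliers: OutlierReport
    agreement: AgreementResults
    trending: TrendingResults
    flags: dict[str, bool] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "provenance": self.provenance,
            "n_observations": self.n_observations,
            "n_after_screening": self.n_after_screening,
            "counts_per_stratum": self.counts_per_stratum,
            "outliers": self.outliers.to_dict(),
            "agreement": [r.to_dict() for r in self.agreement],
            "trending": [r.to_dict() for r in self.trending],
            "flags": dict(self.flags),
            "thresholds": dict(self.thresholds),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        def _default(o):
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            raise TypeError(f"not JSON serializable: {type(o)}")

        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          allow_nan=True, default=_default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def summary(self) -> str:
        lines = [
            f"Validation report ({self.provenance})",
            f"observations: {self.n_observations}  "
            f"after screening: {self.n_after_screening}  "
            f"outliers removed: {self.outliers.n_removed} "
            f"({100 * self.outliers.removed_fraction:.2f}%)",
            "",
            self.agreement.summary(),
            "",
            self.trending.summary(),
            "",
            "Acceptability flags:",
        ]
        for name, ok in sorted(self.flags.items()):
            lines.append(f"  {name}: {'PASS' if ok else 'FAIL'}")
        return "\n".join(lines)


class ValidationStudy:
    """Model object for the full validation pipeline.

    Parameters
    ----------
    dataset : Dataset
        Input paired observations (use :meth:`from_csv` or :meth:`from_config`
        to ingest or simulate).
    k : float
        Outlier-screen SD multiplier.
    zones : mapping, optional
        Trending exclusion half-widths per variable.
    pe_limit : float
        Acceptable cardiac-output percentage error (percent).
    bp_within15_min : float
        Minimum share (percent) of BP pairs within +/-15 mmHg for the BP flag.
    """

    def __init__(
        self,
        dataset: Dataset,
        k: float = 2.0,
        zones: dict[str, float] | None = None,
        pe_limit: float = 30.0,
        bp_within15_min: float = 85.0,
        min_pairs: int = 3,
    ) -> None:
        self.dataset = dataset
        self.k = k
        self.zones = zones
        self.pe_limit = pe_limit
        self.bp_within15_min = bp_within15_min
        self.min_pairs = min_pairs

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ValidationStudy":
        return cls(read_dataset(path), **kwargs)

    @classmethod
    def from_config(cls, config: SimConfig, **kwargs) -> "ValidationStudy":
        return cls(simulate_experiment(config), **kwargs)

    def fit(self) -> ValidationReport:
        clean, outliers = screen_outliers(self.dataset, k=self.k)
        agreement = AgreementAnalysis(clean, min_pairs=self.min_pairs).fit()
        trending = TrendingAnalysis(clean, zones=self.zones).fit()

        counts: dict[str, dict[str, int]] = {}
        for row in clean.counts().itertuples(index=False):
            counts.setdefault(row.variable, {})[row.phase] = int(row.n)

        flags: dict[str, bool] = {}
        try:
            pe = agreement.get("CO", "all").percentage_error
            flags["co_percentage_error_acceptable"] = bool(pe is not None
                                                           and pe <= self.pe_limit)
        except KeyError:
            pass
        for var in BP_VARIABLES:
            try:
                w15 = agreement.get(var, "all").within_15
                flags[f"{var.lower()}_within_15_acceptable"] = bool(
                    w15 is not None and w15 >= self.bp_within15_min)
            except KeyError:
                pass

        return ValidationReport(
            provenance=self.dataset.provenance,
            n_observations=len(self.dataset),
            n_after_screening=len(clean),
            counts_per_stratum=counts,
            outliers=outliers,
            agreement=agreement,
            trending=trending,
            flags=flags,
            thresholds={"pe_limit": self.pe_limit,
                        "bp_within15_min": self.bp_within15_min,
                        "screen_k": self.k},
        )


def run_pipeline(
    source: Dataset | SimConfig | str | Path,
    plots_dir: str | Path | None = None,
    **kwargs,
) -> ValidationReport:
    """Run ingest/simulate -> screen -> agreement -> trending in one call.

    ``source`` may be a Dataset, a :class:`SimConfig` (simulated input), or a
    CSV path. With ``plots_dir``, Bland-Altman, regression and four-quadrant
    figures are written there as PNG side artifacts.
    """
    if isinstance(source, SimConfig):
        study = ValidationStudy.from_config(source, **kwargs)
    elif isinstance(source, (str, Path)):
        study = ValidationStudy.from_csv(source, **kwargs)
    elif isinstance(source, Dataset):
        study = ValidationStudy(source, **kwargs)
    else:
        raise TypeError(f"unsupported source type {type(source)!r}")
    report = study.fit()

    if plots_dir is not None:
        import matplotlib.pyplot as plt
        out = Path(plots_dir)
        out.mkdir(parents=True, exist_ok=True)
        for r in report.agreement:
            if r.stratum != "all":
                continue
            ax = report.agreement.plot_bland_altman(r.variable)
            ax.figure.savefig(out / f"bland_altman_{r.variable}.png", dpi=120)
            plt.close(ax.figure)
            ax = report.agreement.plot_regression(r.variable)
            ax.figure.savefig(out / f"regression_{r.variable}.png", dpi=120)
            plt.close(ax.figure)
        for r in report.trending:
            ax = report.trending.plot_four_quadrant(r.variable)
            ax.figure.savefig(out / f"four_quadrant_{r.variable}.png", dpi=120)
            plt.close(ax.figure)
    return report
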