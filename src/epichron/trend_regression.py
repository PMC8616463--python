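"""Per-gene OLS regressions of expression / histone signal against age.

Each gene's signal — log2(TPM + 1) expression, or promoter peak intensity of
one histone mark — is regressed on developmental age in days (embryonic
labels at their literal day values, P0 coded as day 22).  The slope beta is
the change in signal per day of development: beta_Ex, beta_K4 and beta_K27
for the three signal kinds.  Coefficient distributions are then summarized
per (region, signal kind, cluster trend).

Expression regressions use log2(TPM + 1), never Z-scores; Z-scores exist
only for clustering.  Histone matrices carry a presence mask: cells with no
peak are either included as zero signal (default) or dropped from the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epichron.ages import AGE_DAYS, days_for
from epichron.clustering import ClusterAssignment
from epichron.promoter_signal import PromoterSignalMatrix

logger = logging.getLogger(__name__)

SIGNAL_KINDS = ("Ex", "K4", "K27")

MASK_POLICIES = ("zero", "drop")


@dataclass(frozen=True)
class RegressionResult:
    """One gene's age-regression fit."""

    gene_id: str
    signal_kind: str
    beta: float
    intercept: float
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("regression needs at least two points")
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError(f"r_squared out of range: {self.r_squared}")


def fit_age_regression(
    values: Sequence[float],
    days: Sequence[float],
    signal_kind: str,
    gene_id: str = "",
) -> RegressionResult:
    """Closed-form OLS of one signal vector against age in days.

    ``days`` carries the numeric age coding (see :mod:`epichron.ages`).
    Fewer than two points, or zero age variance, is an error.
    """
    if signal_kind not in SIGNAL_KINDS:
        raise ValueError(f"signal_kind must be one of {SIGNAL_KINDS}")
    y = np.asarray(values, dtype=float)
    x = np.asarray(days, dtype=float)
    if y.shape != x.shape:
        raise ValueError("values and days differ in length")
    if len(y) < 2:
        raise ValueError(f"{gene_id or 'gene'}: need >=2 points, got {len(y)}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in ages")
    fit = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue) ** 2
    return RegressionResult(
        gene_id=gene_id,
        signal_kind=signal_kind,
        beta=float(fit.slope),
        intercept=float(fit.intercept),
        n_points=len(y),
        r_squared=min(r2, 1.0),
    )


def fit_expression_matrix(
    log_matrix: pd.DataFrame,
    genes: Iterable[str] | None = None,
) -> list[RegressionResult]:
    """beta_Ex fits for every (selected) gene of a log2(TPM+1) age matrix.

    Columns must be age labels (single region, replicate-averaged).
    """
    ages = [c[1] if isinstance(c, tuple) else c for c in log_matrix.columns]
    days = days_for(ages)
    selected = list(genes) if genes is not None else list(log_matrix.index)
    results = []
    for g in selected:
        row = log_matrix.loc[g].to_numpy(dtype=float)
        results.append(fit_age_regression(row, days, "Ex", gene_id=g))
    return results


def fit_signal_matrix(
    signal: PromoterSignalMatrix,
    genes: Iterable[str] | None = None,
    mask_policy: str = "zero",
) -> list[RegressionResult]:
    """beta_K4 / beta_K27 fits for a promoter-signal matrix.

    ``mask_policy='zero'`` treats peak-less ages as zero intensity (no peak =
    no signal); ``'drop'`` excludes them from the fit.  Genes left with fewer
    than two usable points — in particular genes that never peaked — are
    skipped with a log message.
    """
    if mask_policy not in MASK_POLICIES:
        raise ValueError(f"mask_policy must be one of {MASK_POLICIES}")
    kind = "K4" if signal.mark == "H3K4me3" else "K27"
    days = np.asarray(days_for(signal.values.columns), dtype=float)
    selected = list(genes) if genes is not None else list(signal.values.index)
    results = []
    skipped = 0
    for g in selected:
        if g not in signal.values.index:
            skipped += 1
            continue
        y = signal.values.loc[g].to_numpy(dtype=float)
        m = signal.mask.loc[g].to_numpy(dtype=bool)
        if mask_policy == "drop":
            y, x = y[m], days[m]
        else:
            x = days
            if not m.any():
                skipped += 1  # never peaked: all-absent row is excluded
                continue
        if len(y) < 2 or np.ptp(x) == 0:
            skipped += 1
            continue
        results.append(fit_age_regression(y, x, kind, gene_id=g))
    if skipped:
        logger.info(
            "%s/%s: skipped %d gene(s) with insufficient promoter signal",
            signal.mark, signal.region, skipped,
        )
    return results


def results_frame(results: Iterable[RegressionResult], region: str) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, region, r.signal_kind, r.beta, r.intercept, r.n_points, r.r_squared)
            for r in results
        ],
        columns=["gene_id", "region", "signal_kind", "beta", "intercept",
                 "n_points", "r_squared"],
    )


def summarize_betas(
    results: Sequence[RegressionResult],
    assignment: ClusterAssignment,
    trend: str,
) -> dict[str, float]:
    """Distribution summary of betas over genes in clusters of one trend.

    Returns median, quartiles (linear interpolation), the fraction of
    negative betas, and the selection size.  An empty selection is an error.
    """
    genes = assignment.genes_with_trend(trend)
    betas = np.array([r.beta for r in results if r.gene_id in genes], dtype=float)
    if betas.size == 0:
        raise ValueError(
            f"no regression results for trend {trend!r} in region {assignment.region!r}"
        )
    q1, med, q3 = np.percentile(betas, [25, 50, 75])
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "fraction_negative": float((betas < 0).mean()),
        "n": int(betas.size),
    }


def write_results(frames: Iterable[pd.DataFrame], path: str | Path) -> None:
    pd.concat(list(frames), ignore_index=True).to_csv(path, sep="\t", index=False)
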