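"""Pathway-level regulatory-group tabulation and pro-vs-anti contrasts.

Genes of a curated pathway (e.g. the KEGG classical apoptosis pathway,
hsa04210) are cross-tabulated by regulatory direction (pro- / anti-apoptotic
from GO) and temporal trend (membership in a down- or upregulation cluster in
*any* brain region).  The four-cell table {pro_down, pro_up, anti_up,
anti_down} yields the largest-group fraction.  The pro-vs-anti fold-change
contrast uses a one-sided rank test: the default is the unpaired rank-sum
(Mann-Whitney) with full-enumeration exact p-values for small samples; a
signed-rank compatibility mode (pairing the two samples by rank order) is
available behind an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from epichron.clustering import ClusterAssignment

GROUPS = ("pro_down", "pro_up", "anti_up", "anti_down")

#: largest combined sample size for which the rank-sum p-value is computed
#: by full enumeration of assignments
EXACT_ENUMERATION_MAX_N = 20


@dataclass
class RankTestReport:
    """Machine-readable outcome of the pro-vs-anti contrast."""

    median_pro: float
    median_anti: float
    statistic: float
    p_value: float
    alternative: str
    variant: str           # "ranksum" or "signed_rank"
    exact: bool
    n_pro: int
    n_anti: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def read_pathway_list(path: str | Path) -> pd.DataFrame:
    """Read a pathway gene-list TSV with columns (pathway_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("pathway_id", "gene_id") if c not in df.columns]
    if missing:
        raise ValueError(f"pathway list missing columns: {missing}")
    return df


def any_region_trend(
    gene_id: str, assignments: Mapping[str, ClusterAssignment]
) -> tuple[str, bool]:
    """Trend label under the any-region rule, plus a conflict flag.

    A gene is "down" if it sits in a downregulation cluster of at least one
    region, "up" analogously, "none" otherwise.  A gene down in one region
    and up in another is flagged conflicting and reported with the label of
    the first region (in the mapping's order) that clustered it.
    """
    seen: list[str] = []
    for a in assignments.values():
        if not a.trend:
            raise ValueError(f"region {a.region!r} clusters are not trend-labeled")
        cid = a.membership.get(gene_id)
        if cid is None:
            continue
        lab = a.trend[cid]
        if lab in ("down", "up"):
            seen.append(lab)
    if not seen:
        return "none", False
    conflict = len(set(seen)) > 1
    return seen[0], conflict


def build_pathway_table(
    pathway: pd.DataFrame,
    direction: Mapping[str, str],
    assignments: Mapping[str, ClusterAssignment],
) -> pd.DataFrame:
    """One row per pathway gene: direction, any-region trend, conflict flag.

    Genes absent from the direction map are labeled "unknown"; duplicated
    pathway rows collapse to one row per gene.
    """
    genes = list(dict.fromkeys(pathway["gene_id"]))
    rows = []
    for g in genes:
        trend, conflict = any_region_trend(g, assignments)
        rows.append((g, direction.get(g, "unknown"), trend, conflict))
    return pd.DataFrame(rows, columns=["gene_id", "direction", "trend", "conflict"])


def tabulate_regulatory_groups(table: pd.DataFrame) -> tuple[dict[str, int], str, float]:
    """Count the four direction x trend regulatory groups.

    Only rows with direction pro/anti and trend down/up contribute ("both"
    and "unknown" direction genes, and genes outside down/up clusters, are
    excluded).  Returns the counts, the largest group's name, and its
    fraction of the four-group total as a percentage.
    """
    sub = table[table["direction"].isin(["pro", "anti"]) & table["trend"].isin(["down", "up"])]
    counts = {
        g: int(((sub["direction"] == g.split("_")[0]) & (sub["trend"] == g.split("_")[1])).sum())
        for g in GROUPS
    }
    total = sum(counts.values())
    if total == 0:
        raise ValueError("regulatory-group table is empty (no pro/anti down/up rows)")
    largest = max(GROUPS, key=lambda g: counts[g])
    return counts, largest, 100.0 * counts[largest] / total


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """One-sided rank-sum p by full enumeration over group assignments.

    Midranks handle ties, so the enumeration remains exact on tied data.
    Returns (rank-sum statistic of x, p-value).
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, k = len(pooled), len(x)
    observed = float(ranks[:k].sum())
    count = 0
    for idx in combinations(range(n), k):
        s = ranks[list(idx)].sum()
        if alternative == "less":
            count += s <= observed + 1e-9
        else:
            count += s >= observed - 1e-9
    return observed, count / comb(n, k)


def compare_fold_changes(
    pro_fc: Sequence[float],
    anti_fc: Sequence[float],
    alternative: str = "less",
    variant: str = "ranksum",
) -> RankTestReport:
    """Compare pro- vs anti-apoptotic fold-change distributions.

    ``alternative='less'`` tests whether the pro values are stochastically
    smaller than the anti values (pro genes more strongly downregulated).
    With the default ``ranksum`` variant the p-value is exact by full
    enumeration when the combined sample size is <= 20, otherwise the normal
    approximation with tie correction is used.  ``variant='signed_rank'`` is
    a compatibility mode that pairs the two samples by rank order and runs a
    one-sided Wilcoxon signed-rank test; it truncates to the shorter sample.
    """
    x = np.asarray(pro_fc, dtype=float)
    y = np.asarray(anti_fc, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both fold-change lists must be non-empty")
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if variant == "ranksum":
        if x.size + y.size <= EXACT_ENUMERATION_MAX_N:
            statistic, p = _exact_ranksum_p(x, y, alternative)
            exact = True
        else:
            res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
            statistic, p, exact = float(res.statistic), float(res.pvalue), False
    elif variant == "signed_rank":
        m = min(x.size, y.size)
        xs, ys = np.sort(x)[:m], np.sort(y)[:m]
        diffs = xs - ys
        if np.all(diffs == 0):
            statistic, p, exact = 0.0, 1.0, False
        else:
            res = stats.wilcoxon(xs, ys, alternative=alternative)
            statistic, p, exact = float(res.statistic), float(res.pvalue), False
    else:
        raise ValueError("variant must be 'ranksum' or 'signed_rank'")
    return RankTestReport(
        median_pro=med_x,
        median_anti=med_y,
        statistic=statistic,
        p_value=float(p),
        alternative=alternative,
        variant=variant,
        exact=exact,
        n_pro=int(x.size),
        n_anti=int(y.size),
    )


def write_regulatory_groups(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sorted(counts.items()), columns=["group", "count"]).to_csv(
        path, sep="\t", index=False
    )
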