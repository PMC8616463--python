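"""UPGMA clustering against a brute-force oracle; trend labels; overlaps."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from epichron.ages import AGE_DAYS, AGE_LABELS
from epichron.clustering import (
    ClusterAssignment,
    label_trend,
    overlap_analysis,
    to_newick,
    upgma_cluster,
)
from epichron.expression import ExpressionMatrix


def zmat(rows, region="forebrain"):
    """Wrap raw row vectors as a 'zscore' matrix (tests bypass normalization)."""
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    cols = [(region, age) for age in AGE_LABELS[: arr.shape[1]]]
    df = pd.DataFrame(arr, index=[f"g{i}" for i in range(len(arr))],
                      columns=pd.MultiIndex.from_tuples(cols, names=["region", "age"]))
    return ExpressionMatrix(df, "zscore")


def brute_force_upgma(X):
    """Exhaustive average-linkage agglomeration over Euclidean distances.

    Inter-cluster distance is recomputed each step as the mean over all
    inter-item pairs — no Lance-Williams recursion — so it is an independent
    route to the same mathematical definition.  Returns merge heights in
    order and the flat partition (frozenset of frozensets) at every k.
    """
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = {i: [i] for i in range(n)}
    heights = []
    partitions = {n: frozenset(frozenset(v) for v in clusters.values())}
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
        partitions[len(clusters)] = frozenset(frozenset(v) for v in clusters.values())
    return heights, partitions


def test_two_well_separated_pairs_split_cleanly():
    m = zmat([[0.0], [1.0], [10.0], [11.0]])
    a = upgma_cluster(m, k=2)
    parts = frozenset(frozenset(a.genes_in(c)) for c in set(a.membership.values()))
    assert parts == frozenset({frozenset({"g0", "g1"}), frozenset({"g2", "g3"})})


def test_two_items_forced_into_singletons():
    a = upgma_cluster(zmat([[0.0, 1.0], [0.0, 1.0]]), k=2)
    assert sorted(a.sizes().values()) == [1, 1]


def test_merge_heights_match_brute_force_oracle_up_to_six_items():
    rng = np.random.default_rng(3)
    for _ in range(25):
        n = int(rng.integers(2, 7))
        X = rng.normal(size=(n, 4))
        heights, partitions = brute_force_upgma(X)
        m = zmat(X)
        a = upgma_cluster(m, k=2)
        np.testing.assert_allclose(
            np.sort(a.linkage_matrix[:, 2]), np.sort(heights), rtol=1e-9
        )
        for k in range(2, n + 1):
            a = upgma_cluster(m, k=k)
            got = frozenset(frozenset(a.genes_in(c)) for c in set(a.membership.values()))
            want = frozenset(
                frozenset(f"g{i}" for i in grp) for grp in partitions[k]
            )
            assert got == want, f"partition mismatch at n={n}, k={k}"


def test_row_permutation_yields_identical_partition():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(20, 8))
    m = zmat(X)
    a = upgma_cluster(m, k=4)
    perm = rng.permutation(20)
    mp = ExpressionMatrix(m.values.iloc[perm], "zscore")
    b = upgma_cluster(mp, k=4)
    parts_a = frozenset(frozenset(a.genes_in(c)) for c in set(a.membership.values()))
    parts_b = frozenset(frozenset(b.genes_in(c)) for c in set(b.membership.values()))
    assert parts_a == parts_b


def test_k_bounds_and_metric_are_validated():
    m = zmat(np.eye(3))
    with pytest.raises(ValueError):
        upgma_cluster(m, k=4)
    with pytest.raises(ValueError):
        upgma_cluster(m, k=2, metric="manhattan")


def test_cut_by_height_is_exposed():
    m = zmat([[0.0], [1.0], [10.0], [11.0]])
    a = upgma_cluster(m, k=2, cut_height=5.0)
    assert a.k == 2


DAYS = [AGE_DAYS[a] for a in AGE_LABELS]


def test_trend_labels_from_mean_profile_slopes():
    days = np.array(DAYS)
    centered = days - days.mean()
    profiles = {
        1: -0.1 * centered,                                  # monotone down
        2: np.where(days <= 16.5, -0.05 * (days - 10.5),
                    -0.3 + 0.3 * (days - 16.5)),             # late reversal up
        3: np.zeros(8),                                      # tiny / flat
        4: 0.1 * centered,                                   # monotone up
        5: np.where(days <= 16.5, 0.02 * (days - 10.5),
                    0.12 - 0.14 * (days - 16.5)),            # late reversal down
    }
    a = ClusterAssignment(
        region="forebrain", k=5,
        membership={f"g{c}": c for c in profiles},
        mean_profile={c: np.asarray(p, dtype=float) for c, p in profiles.items()},
        ages=list(AGE_LABELS),
    )
    label_trend(a, DAYS)
    # slope oracle: OLS sign with the dead-band
    expected = {}
    for c, p in profiles.items():
        slope = np.polyfit(days, p, 1)[0]
        expected[c] = "down" if slope < -0.01 else ("up" if slope > 0.01 else "other")
    assert a.trend == expected
    assert expected[1] == "down" and expected[4] == "up" and expected[3] == "other"


def _assignment(region, gene_lists):
    """Build a trend-labeled assignment: {trend: genes} per region."""
    membership, trend, mean_profile = {}, {}, {}
    for cid, (t, genes) in enumerate(gene_lists.items(), start=1):
        trend[cid] = t
        mean_profile[cid] = np.zeros(8)
        for g in genes:
            membership[g] = cid
    return ClusterAssignment(region=region, k=len(gene_lists), membership=membership,
                             mean_profile=mean_profile, ages=list(AGE_LABELS), trend=trend)


def test_overlap_worked_example_and_degenerate_cases():
    a1 = _assignment("forebrain", {"down": {"A", "B", "C"}, "up": {"X"}})
    a2 = _assignment("midbrain", {"down": {"B", "C", "D"}, "up": {"X"}})
    a3 = _assignment("hindbrain", {"down": {"C", "B"}, "up": {"X"}})
    o = overlap_analysis({"forebrain": a1, "midbrain": a2, "hindbrain": a3}, "down")
    assert o.intersection_all == 2 and o.union == 4
    assert o.shared_fraction == pytest.approx(0.5)
    same = overlap_analysis({"f": a1, "m": a1, "h": a1}, "down")
    assert same.shared_fraction == 1.0
    b1 = _assignment("f", {"down": {"A"}, "up": {"X"}})
    b2 = _assignment("m", {"down": {"B"}, "up": {"X"}})
    assert overlap_analysis({"f": b1, "m": b2}, "down").shared_fraction == 0.0


def test_overlap_errors_name_the_trendless_region():
    a1 = _assignment("forebrain", {"down": {"A"}, "up": {"X"}})
    a2 = _assignment("midbrain", {"up": {"X"}})
    with pytest.raises(ValueError, match="midbrain"):
        overlap_analysis({"forebrain": a1, "midbrain": a2}, "down")


@given(
    st.tuples(
        st.sets(st.integers(0, 15), min_size=1),
        st.sets(st.integers(0, 15), min_size=1),
        st.sets(st.integers(0, 15), min_size=1),
    )
)
def test_overlap_obeys_inclusion_exclusion(sets):
    s1, s2, s3 = ({str(i) for i in s} for s in sets)
    a = {
        "r1": _assignment("r1", {"down": s1, "up": {"zz"}}),
        "r2": _assignment("r2", {"down": s2, "up": {"zz"}}),
        "r3": _assignment("r3", {"down": s3, "up": {"zz"}}),
    }
    o = overlap_analysis(a, "down")
    lhs = o.union
    rhs = sum(o.sizes.values()) - sum(o.pairwise.values()) + o.intersection_all
    assert lhs == rhs


def test_newick_export_has_all_leaves():
    rng = np.random.default_rng(5)
    m = zmat(rng.normal(size=(6, 8)))
    a = upgma_cluster(m, k=2)
    nwk = to_newick(a)
    assert nwk.endswith(";")
    for g in m.values.index:
        assert g in nwk
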