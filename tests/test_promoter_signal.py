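"""narrowPeak parsing, promoter-window assignment, max-intensity rule."""

import numpy as np
import pandas as pd
import pytest

from epichron.promoter_signal import (
    NarrowPeakParseError,
    PeakRecord,
    assign_promoter_peaks,
    build_signal_matrix,
    max_intensity_per_promoter,
    read_narrowpeak,
)


def genes_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "tss"])


def brute_force_assign(peaks, genes, window):
    """All-pairs interval-overlap scan (independent oracle).

    Checked both in BED half-open coordinates and, equivalently, after
    converting window and peaks to 1-based closed intervals.
    """
    out = {}
    for g in genes.itertuples(index=False):
        hits = [
            p for p in peaks
            if p.chrom == g.chrom and p.start < g.tss + window and p.end > g.tss - window
        ]
        closed = [
            p for p in peaks
            if p.chrom == g.chrom
            and p.start + 1 <= g.tss + window          # 1-based closed window end
            and p.end >= g.tss - window + 1            # 1-based closed window start
        ]
        assert {id(p) for p in hits} == {id(p) for p in closed}
        out[g.gene_id] = sorted(hits, key=lambda p: (p.start, p.end))
    return out


def test_parse_single_line_field_mapping(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t200\t.\t0\t.\t8.5\t-1\t-1\t50\n")
    (rec,) = read_narrowpeak(p)
    assert rec == PeakRecord("chr1", 100, 200, 8.5, 50)


def test_parse_empty_file_and_file_order(tmp_path):
    empty = tmp_path / "empty.narrowPeak"
    empty.write_text("")
    assert read_narrowpeak(empty) == []
    fixture = tmp_path / "three.narrowPeak"
    fixture.write_text(
        "chr1\t0\t10\t.\t5\t.\t1.0\t-1\t-1\t5\n"
        "chr2\t50\t80\t.\t9\t.\t2.5\t-1\t-1\t15\n"
        "chr1\t30\t40\t.\t1\t.\t0.5\t-1\t-1\t5\n"
    )
    recs = read_narrowpeak(fixture)
    assert [(r.chrom, r.start, r.end, r.intensity) for r in recs] == [
        ("chr1", 0, 10, 1.0), ("chr2", 50, 80, 2.5), ("chr1", 30, 40, 0.5)
    ]  # hand-parsed oracle, in file order


@pytest.mark.parametrize(
    "line,msg",
    [
        ("chr1\t100\t200\t.\t0\t.\t8.5\t-1\t-1\n", "10 columns"),
        ("chr1\t-5\t200\t.\t0\t.\t8.5\t-1\t-1\t50\n", "line 1"),
        ("chr1\t300\t200\t.\t0\t.\t8.5\t-1\t-1\t50\n", "line 1"),
        ("chr1\t100\t200\t.\t0\t.\tnotanumber\t-1\t-1\t50\n", "line 1"),
    ],
)
def test_malformed_lines_are_rejected_with_line_numbers(tmp_path, line, msg):
    p = tmp_path / "bad.narrowPeak"
    p.write_text(line)
    with pytest.raises(NarrowPeakParseError, match=msg):
        read_narrowpeak(p)


def test_window_boundaries_are_half_open():
    genes = genes_frame([("g", "chr1", 10_000)])
    left_edge = PeakRecord("chr1", 8000, 8001, 1.0)        # overlaps at 8000
    beyond_right = PeakRecord("chr1", 12_000, 12_500, 1.0)  # window ends at 12000
    just_inside = PeakRecord("chr1", 11_999, 12_500, 1.0)
    just_outside_left = PeakRecord("chr1", 7000, 8000, 1.0)
    assigned = assign_promoter_peaks(
        [left_edge, beyond_right, just_inside, just_outside_left], genes, window=2000
    )
    assert assigned["g"] == [left_edge, just_inside]


def test_assignment_matches_all_pairs_scan_on_random_instances():
    rng = np.random.default_rng(6)
    for _ in range(30):
        n_genes, n_peaks = int(rng.integers(3, 15)), int(rng.integers(5, 60))
        genes = genes_frame(
            [(f"g{i}", f"chr{rng.integers(1, 3)}", int(rng.integers(0, 60_000)))
             for i in range(n_genes)]
        )
        peaks = []
        for _ in range(n_peaks):
            start = int(rng.integers(0, 60_000))
            peaks.append(PeakRecord(f"chr{rng.integers(1, 3)}", start,
                                    start + int(rng.integers(1, 4000)),
                                    float(rng.uniform(0, 10))))
        window = int(rng.integers(100, 4000))
        got = assign_promoter_peaks(peaks, genes, window=window)
        want = brute_force_assign(peaks, genes, window)
        assert {g: [id(p) for p in v] for g, v in got.items()} == \
            {g: [id(p) for p in v] for g, v in want.items()}


def test_enlarging_window_never_removes_assignments():
    rng = np.random.default_rng(7)
    genes = genes_frame([(f"g{i}", "chr1", int(rng.integers(0, 50_000))) for i in range(8)])
    peaks = [
        PeakRecord("chr1", int(s), int(s) + 300, 1.0)
        for s in rng.integers(0, 50_000, size=40)
    ]
    small = assign_promoter_peaks(peaks, genes, window=500)
    large = assign_promoter_peaks(peaks, genes, window=5000)
    for g in small:
        assert {id(p) for p in small[g]} <= {id(p) for p in large[g]}


def test_max_intensity_rule_and_tie_break():
    a = PeakRecord("chr1", 100, 200, 5.0)
    b = PeakRecord("chr1", 300, 400, 9.0)
    best, source = max_intensity_per_promoter({"g1": [a, b], "g2": []})
    assert best == {"g1": 9.0} and source["g1"] is b
    assert "g2" not in best  # absent, not zero
    t1 = PeakRecord("chr1", 300, 400, 7.0)
    t2 = PeakRecord("chr1", 100, 200, 7.0)
    best, source = max_intensity_per_promoter({"g": [t1, t2]})
    assert best["g"] == 7.0 and source["g"] is t2  # leftmost start wins the tie
    # permutation invariance in peak order
    best2, source2 = max_intensity_per_promoter({"g": [t2, t1]})
    assert best2 == best and source2["g"] is t2


def test_signal_matrix_composes_the_pieces(tmp_path):
    genes = pd.DataFrame(
        {"gene_id": ["g1", "g2"], "chrom": ["chr1", "chr1"], "tss": [10_000, 50_000]}
    )
    ages = ["E10.5", "E11.5", "E12.5"]
    per_age = {
        "E10.5": [("chr1", 9000, 9500, 4.0), ("chr1", 9600, 9700, 6.0),
                  ("chr1", 49_500, 49_900, 2.0)],
        "E11.5": [("chr1", 9000, 9500, 3.0)],
        "E12.5": [],
    }
    files = {}
    for age, peaks in per_age.items():
        p = tmp_path / f"{age}.narrowPeak"
        p.write_text("".join(
            f"{c}\t{s}\t{e}\t.\t0\t.\t{v}\t-1\t-1\t-1\n" for c, s, e, v in peaks
        ))
        files[age] = p
    sm = build_signal_matrix(files, genes, "H3K4me3", "forebrain", window=2000)
    expected = pd.DataFrame(
        [[6.0, 3.0, 0.0], [2.0, 0.0, 0.0]], index=["g1", "g2"], columns=ages
    )
    pd.testing.assert_frame_equal(sm.values, expected)
    assert sm.mask.loc["g1"].tolist() == [True, True, False]
    assert sm.mask.loc["g2"].tolist() == [True, False, False]


def test_missing_age_file_is_reported_up_front(tmp_path):
    genes = pd.DataFrame({"gene_id": ["g1"], "chrom": ["chr1"], "tss": [1000]})
    ok = tmp_path / "ok.narrowPeak"
    ok.write_text("")
    files = {"E10.5": ok, "E11.5": tmp_path / "gone.narrowPeak"}
    with pytest.raises(FileNotFoundError, match="E11.5"):
        build_signal_matrix(files, genes, "H3K4me3", "forebrain")
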