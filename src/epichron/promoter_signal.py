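"""narrowPeak parsing and promoter-window histone-signal matrices.

Peaks come from ENCODE "bed narrowPeak" files (BED6+4: chrom, start, end,
name, score, strand, signalValue, pValue, qValue, peak).  A peak is a
promoter signal for a gene when it overlaps the +/-2 kb window around the
gene's TSS by at least 1 bp; all interval logic is 0-based half-open, so the
window is [tss - w, tss + w).  Strand decides only which coordinate is the
TSS — the window itself is symmetric.  When several peaks hit one promoter,
the one with maximum intensity (signalValue by default) is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 2000

NARROWPEAK_COLUMNS = (
    "chrom", "start", "end", "name", "score", "strand",
    "signalValue", "pValue", "qValue", "peak",
)

MARKS = ("H3K4me3", "H3K27me3")


@dataclass(frozen=True)
class PeakRecord:
    """One narrowPeak call; coordinates are BED half-open [start, end)."""

    chrom: str
    start: int
    end: int
    intensity: float
    summit_offset: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty/inverted interval [{self.start}, {self.end})")
        if self.intensity < 0:
            raise ValueError(f"negative peak intensity {self.intensity}")


@dataclass
class PromoterSignalMatrix:
    """Gene x age max-peak intensities for one histone mark in one region.

    ``mask`` is True where a promoter peak was found; absent cells carry
    ``absent_value`` (default 0) in ``values``.
    """

    mark: str
    region: str
    values: pd.DataFrame
    mask: pd.DataFrame
    absent_value: float = 0.0

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValueError("values and mask are not aligned")


class NarrowPeakParseError(ValueError):
    pass


def read_narrowpeak(path: str | Path, intensity_column: str = "signalValue") -> list[PeakRecord]:
    """Parse a narrowPeak file into PeakRecords, in file order.

    Malformed lines (wrong column count, negative or inverted coordinates,
    non-numeric fields) are rejected with their 1-based line numbers.
    ``intensity_column`` selects which numeric column is carried as the peak
    intensity (signalValue, score, pValue or qValue).
    """
    if intensity_column not in NARROWPEAK_COLUMNS[4:5] + NARROWPEAK_COLUMNS[6:9]:
        raise ValueError(f"unsupported intensity column {intensity_column!r}")
    path = Path(path)
    records: list[PeakRecord] = []
    errors: list[str] = []
    idx = {name: i for i, name in enumerate(NARROWPEAK_COLUMNS)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                errors.append(f"line {lineno}: expected 10 columns, got {len(fields)}")
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
                intensity = float(fields[idx[intensity_column]])
                summit = int(fields[9])
                if start < 0:
                    raise ValueError("negative start coordinate")
                records.append(PeakRecord(fields[0], start, end, intensity, summit))
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise NarrowPeakParseError(
            f"{path.name}: {len(errors)} malformed line(s): " + "; ".join(errors[:5])
        )
    return records


def assign_promoter_peaks(
    peaks: Sequence[PeakRecord],
    genes: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> dict[str, list[PeakRecord]]:
    """Map each gene to the peaks overlapping its promoter window.

    The window is [tss - window, tss + window), half-open; a peak overlaps
    when ``peak.start < tss + window`` and ``peak.end > tss - window`` on the
    same chromosome.  One peak may serve several genes.  Peaks on
    chromosomes absent from the annotation are logged and left unassigned.

    ``genes`` is a parsed annotation frame with gene_id, chrom, tss columns.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    trees: dict[str, IntervalTree] = {}
    for i, p in enumerate(peaks):
        trees.setdefault(p.chrom, IntervalTree())[p.start:p.end] = i
    known_chroms = set(genes["chrom"])
    orphan = set(trees) - known_chroms
    if orphan:
        logger.warning("peaks on chromosomes absent from annotation: %s", sorted(orphan))
    assigned: dict[str, list[PeakRecord]] = {}
    for gene_id, chrom, tss in zip(genes["gene_id"], genes["chrom"], genes["tss"]):
        lo, hi = max(0, int(tss) - window), int(tss) + window
        tree = trees.get(chrom)
        if tree is None:
            assigned[gene_id] = []
            continue
        hits = sorted(tree.overlap(lo, hi), key=lambda iv: (iv.begin, iv.end, iv.data))
        assigned[gene_id] = [peaks[iv.data] for iv in hits]
    return assigned


def max_intensity_per_promoter(
    assigned: Mapping[str, Iterable[PeakRecord]],
) -> tuple[dict[str, float], dict[str, PeakRecord]]:
    """Per gene, the maximum intensity among its promoter peaks.

    Genes with no peak are omitted from the returned maps (absent).  Ties go
    to the leftmost-start peak, which is recorded as the source.
    """
    best: dict[str, float] = {}
    source: dict[str, PeakRecord] = {}
    for gene_id, peaks in assigned.items():
        chosen: PeakRecord | None = None
        for p in sorted(peaks, key=lambda p: (p.start, p.end)):
            if chosen is None or p.intensity > chosen.intensity:
                chosen = p
        if chosen is not None:
            best[gene_id] = chosen.intensity
            source[gene_id] = chosen
    return best, source


def build_signal_matrix(
    peak_files: Mapping[str, str | Path],
    genes: pd.DataFrame,
    mark: str,
    region: str,
    window: int = DEFAULT_WINDOW,
    absent_value: float = 0.0,
    intensity_column: str = "signalValue",
) -> PromoterSignalMatrix:
    """Compose parsing, promoter assignment and the max rule over all ages.

    ``peak_files`` maps every age label to its narrowPeak path; a missing
    file raises listing the offending ages up front.
    """
    missing = [age for age, p in peak_files.items() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing narrowPeak files for {mark}/{region} at ages: {sorted(missing)}"
        )
    gene_ids = list(genes["gene_id"])
    ages = list(peak_files)
    values = pd.DataFrame(absent_value, index=gene_ids, columns=ages, dtype=float)
    mask = pd.DataFrame(False, index=gene_ids, columns=ages)
    for age, path in peak_files.items():
        peaks = read_narrowpeak(path, intensity_column=intensity_column)
        assigned = assign_promoter_peaks(peaks, genes, window=window)
        best, _ = max_intensity_per_promoter(assigned)
        for gene_id, intensity in best.items():
            values.loc[gene_id, age] = intensity
            mask.loc[gene_id, age] = True
    return PromoterSignalMatrix(
        mark=mark, region=region, values=values, mask=mask, absent_value=absent_value
    )


def write_signal_matrix(matrix: PromoterSignalMatrix, values_path: str | Path,
                        mask_path: str | Path) -> None:
    matrix.values.to_csv(values_path, sep="\t", index_label="gene_id")
    matrix.mask.astype(int).to_csv(mask_path, sep="\t", index_label="gene_id")
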