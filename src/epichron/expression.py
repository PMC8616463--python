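"""TPM expression matrices: replicate averaging, filtering, normalization.

The matrix container tracks its transform state explicitly:

* ``raw_tpm``  — non-negative TPM values, columns (region, age[, replicate]);
* ``log2p1``   — log2(TPM + 1);
* ``zscore``   — per-gene standardized log2(TPM + 1) across the columns.

Replicates are arithmetic-averaged on the TPM scale.  The expressed-gene
filter keeps a gene when TPM >= 1 in at least one third of the data points
(ceiling semantics) and the maximum TPM is >= 5; "data points" are the columns
of the matrix handed in, so running it on one region's eight replicate-
averaged age columns applies the rule per region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from epichron.ages import AGE_LABELS

logger = logging.getLogger(__name__)

TRANSFORM_STATES = ("raw_tpm", "log2p1", "zscore")

#: pseudocount applied to fold changes with a zero baseline
FOLD_CHANGE_EPS = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid with an explicit transform state.

    ``values`` is a DataFrame indexed by gene_id.  Columns are tuples
    (region, age_label) or (region, age_label, replicate) as a MultiIndex.
    """

    values: pd.DataFrame
    transform_state: str = "raw_tpm"

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValueError(f"unknown transform_state {self.transform_state!r}")
        if self.transform_state == "raw_tpm" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw TPM matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[tuple]:
        return list(self.values.columns)

    def region(self, region: str) -> "ExpressionMatrix":
        """Sub-matrix for one region (columns keep their remaining levels)."""
        sub = self.values.xs(region, axis=1, level=0, drop_level=False)
        return ExpressionMatrix(sub, self.transform_state)

    def regions(self) -> list[str]:
        return list(dict.fromkeys(c[0] for c in self.values.columns))


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV with columns: file, region, age, replicate."""
    sheet = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    required = ["file", "region", "age", "replicate"]
    missing = [c for c in required if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    bad_age = set(sheet["age"]) - set(AGE_LABELS)
    if bad_age:
        raise ValueError(f"sample sheet has unknown age labels: {sorted(bad_age)}")
    return sheet


def load_tpm_tables(sample_sheet: pd.DataFrame, base_dir: str | Path) -> ExpressionMatrix:
    """Assemble per-sample two-column TPM files into one replicate-level matrix.

    Every file must quantify the same gene list; a mismatch names the
    offending sample.  Column order follows region order of appearance, then
    developmental age order, then replicate number.
    """
    base = Path(base_dir)
    columns: dict[tuple, pd.Series] = {}
    ref_genes: pd.Index | None = None
    ref_name = ""
    for row in sample_sheet.itertuples(index=False):
        tab = pd.read_csv(base / row.file, sep="\t")
        if list(tab.columns[:2]) != ["gene_id", "tpm"]:
            raise ValueError(f"{row.file}: expected columns (gene_id, tpm)")
        series = tab.set_index("gene_id")["tpm"].astype(float)
        if ref_genes is None:
            ref_genes, ref_name = series.index, row.file
        elif not series.index.equals(ref_genes):
            raise ValueError(
                f"gene list of sample {row.file} does not match {ref_name}"
            )
        columns[(row.region, row.age, int(row.replicate))] = series
    if not columns:
        raise ValueError("sample sheet is empty")
    region_order = list(dict.fromkeys(sample_sheet["region"]))
    ordered = sorted(
        columns,
        key=lambda c: (region_order.index(c[0]), AGE_LABELS.index(c[1]), c[2]),
    )
    df = pd.DataFrame({c: columns[c] for c in ordered})
    df.columns = pd.MultiIndex.from_tuples(ordered, names=["region", "age", "replicate"])
    return ExpressionMatrix(df, "raw_tpm")


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate TPM columns into one column per (region, age)."""
    if matrix.transform_state != "raw_tpm":
        raise ValueError("replicate averaging operates on raw TPM")
    df = matrix.values
    if df.columns.nlevels != 3:
        raise ValueError("matrix has no replicate level to average")
    region_order = list(dict.fromkeys(c[0] for c in df.columns))
    avg = df.T.groupby(level=["region", "age"]).mean().T
    ordered = sorted(
        avg.columns, key=lambda c: (region_order.index(c[0]), AGE_LABELS.index(c[1]))
    )
    return ExpressionMatrix(avg[ordered], "raw_tpm")


def filter_expressed(
    matrix: ExpressionMatrix,
    tpm_min: float = 1.0,
    min_fraction: float = 1 / 3,
    max_floor: float = 5.0,
) -> list[str]:
    """Expressed-gene filter over the columns of the given matrix.

    A gene is retained iff it has TPM >= ``tpm_min`` in at least
    ``ceil(min_fraction * n_columns)`` columns and its maximum TPM is
    >= ``max_floor``.
    """
    if matrix.transform_state != "raw_tpm":
        raise ValueError("expression filter operates on raw TPM")
    vals = matrix.values.to_numpy()
    n = vals.shape[1]
    need = math.ceil(min_fraction * n)
    keep = ((vals >= tpm_min).sum(axis=1) >= need) & (vals.max(axis=1) >= max_floor)
    kept = [g for g, k in zip(matrix.values.index, keep) if k]
    if not kept:
        logger.warning("expression filter removed every gene")
    return kept


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform."""
    if matrix.transform_state != "raw_tpm":
        raise ValueError("log transform operates on raw TPM")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), "log2p1")


def normalize(matrix: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Per-gene Z-score of log2(TPM + 1) across columns.

    Genes whose log profile has zero variance cannot be standardized and are
    dropped with a warning listing them.  The sample (n-1) standard deviation
    is the default; set ``ddof=0`` for the population form.
    """
    if matrix.transform_state != "raw_tpm":
        raise ValueError("normalize operates on raw TPM")
    logm = np.log2(matrix.values + 1.0)
    sd = logm.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        dropped = list(logm.index[constant])
        logger.warning(
            "dropping %d constant (zero-variance) genes before Z-scoring: %s%s",
            len(dropped), dropped[:10], "..." if len(dropped) > 10 else "",
        )
        logm = logm.loc[~constant]
        sd = sd[~constant]
    z = logm.sub(logm.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, "zscore")


def fold_change(
    matrix: ExpressionMatrix,
    gene: str,
    age_from: str,
    age_to: str,
    region: str | None = None,
) -> tuple[float, bool]:
    """TPM ratio ``age_to / age_from`` for one gene.

    Operates on a replicate-averaged raw TPM matrix.  When the baseline TPM
    is zero the ratio is computed with a pseudocount of 1 on both endpoints
    and the second return element flags the gene; otherwise the flag is
    False and the ratio is the plain quotient.
    """
    if matrix.transform_state != "raw_tpm":
        raise ValueError("fold change operates on raw TPM")
    if gene not in matrix.values.index:
        raise KeyError(f"unknown gene {gene!r}")
    df = matrix.values
    if region is not None:
        df = df.xs(region, axis=1, level=0, drop_level=False)
    cols = {c[1]: c for c in df.columns}
    for age in (age_from, age_to):
        if age not in cols:
            raise KeyError(f"age {age!r} not present in matrix")
    v_from = float(df.loc[gene, cols[age_from]])
    v_to = float(df.loc[gene, cols[age_to]])
    if v_from == 0.0:
        return (v_to + FOLD_CHANGE_EPS) / (v_from + FOLD_CHANGE_EPS), True
    return v_to / v_from, False


def write_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as a wide TSV; column tuples joined with '|'."""
    out = matrix.values.copy()
    out.columns = ["|".join(str(p) for p in c) for c in out.columns]
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path: str | Path, transform_state: str) -> ExpressionMatrix:
    """Read a wide TSV written by :func:`write_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    tuples = []
    for c in df.columns:
        parts = c.split("|")
        if len(parts) == 3:
            tuples.append((parts[0], parts[1], int(parts[2])))
        else:
            tuples.append(tuple(parts))
    names = ["region", "age", "replicate"][: len(tuples[0])]
    df.columns = pd.MultiIndex.from_tuples(tuples, names=names)
    return ExpressionMatrix(df, transform_state)
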