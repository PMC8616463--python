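"""Apoptosis gene-set construction from GO term names.

A gene belongs to the apoptosis set iff at least one of its GO term *names*
contains a keyword (default ``"apopt"``, matching e.g. "apoptosis" and
"apoptotic") as a case-insensitive substring.  Matching is on term names only
— no ontology DAG reasoning, no synonym expansion.

Each member gene is further classified by regulatory direction: *pro* if its
matching terms indicate solely positive regulation of apoptosis, *anti* for
solely negative regulation, *both* if terms of both directions are present
(such genes stay in the set but are excluded from pro-vs-anti contrasts), and
*unknown* when no direction is annotated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_KEYWORD = "apopt"

DIRECTIONS = ("pro", "anti", "both", "unknown")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's identity, TSS locus, strand and GO term names."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    strand: str
    go_terms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative TSS {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")


@dataclass
class ApoptosisGeneSet:
    """Keyword-selected gene set with per-gene regulatory direction labels."""

    members: set[str]
    direction: dict[str, str]
    keyword: str = DEFAULT_KEYWORD

    def __post_init__(self) -> None:
        extra = set(self.direction) - self.members
        if extra:
            raise ValueError(f"direction labels for non-members: {sorted(extra)[:5]}")

    def genes_with_direction(self, label: str) -> set[str]:
        return {g for g, d in self.direction.items() if d == label}

    def counts(self) -> dict[str, int]:
        out = {d: 0 for d in DIRECTIONS}
        for d in self.direction.values():
            out[d] += 1
        return out


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a flattened annotation TSV (BioMart-style export).

    Expected header columns: gene_id, symbol, chrom, tss, strand, go_terms
    (';'-delimited GO term names; empty string allowed).

    Returns a DataFrame indexed by gene_id with ``go_terms`` parsed into
    frozensets of term-name strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["gene_id", "symbol", "chrom", "tss", "strand", "go_terms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id in annotation: {dups[:5]}")
    df["tss"] = df["tss"].astype(int)
    if (df["tss"] < 0).any():
        raise ValueError("negative TSS coordinate in annotation")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"invalid strand values: {df.loc[bad, 'strand'].unique().tolist()}")
    df["go_terms"] = [
        frozenset(t for t in terms.split(";") if t) for terms in df["go_terms"]
    ]
    return df.set_index("gene_id", drop=False)


def annotation_records(df: pd.DataFrame) -> list[GeneAnnotation]:
    """Materialize a parsed annotation DataFrame as GeneAnnotation records."""
    return [
        GeneAnnotation(r.gene_id, r.symbol, r.chrom, int(r.tss), r.strand,
                       frozenset(r.go_terms))
        for r in df.itertuples(index=False)
    ]


def classify_direction(gene_terms: Iterable[str], keyword: str = DEFAULT_KEYWORD) -> str:
    """Classify a member gene's regulatory direction from its GO term names.

    A term counts as positive (negative) evidence when its name contains
    "positive regulation" ("negative regulation") together with the apoptosis
    keyword, case-insensitively.  Returns one of ``pro``, ``anti``, ``both``,
    ``unknown``.
    """
    kw = keyword.lower()
    has_pos = has_neg = False
    for term in gene_terms:
        t = term.lower()
        if kw not in t:
            continue
        if "positive regulation" in t:
            has_pos = True
        if "negative regulation" in t:
            has_neg = True
    if has_pos and has_neg:
        return "both"
    if has_pos:
        return "pro"
    if has_neg:
        return "anti"
    return "unknown"


def select_apoptosis_genes(
    annotations: pd.DataFrame, keyword: str = DEFAULT_KEYWORD
) -> ApoptosisGeneSet:
    """Select genes whose GO term names contain *keyword* (case-insensitive).

    Parameters
    ----------
    annotations
        Parsed annotation table from :func:`read_annotation` (or any frame
        with ``gene_id`` and set-valued ``go_terms`` columns).
    keyword
        Non-empty substring searched in every GO term name.

    Returns
    -------
    ApoptosisGeneSet with every member direction-labeled.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    if len(annotations) == 0:
        raise ValueError("annotation table is empty — nothing to select from")
    kw = keyword.lower()
    members: set[str] = set()
    direction: dict[str, str] = {}
    for gene_id, terms in zip(annotations["gene_id"], annotations["go_terms"]):
        if any(kw in t.lower() for t in terms):
            members.add(gene_id)
            direction[gene_id] = classify_direction(terms, keyword)
    logger.info("selected %d/%d genes with keyword %r", len(members), len(annotations), keyword)
    return ApoptosisGeneSet(members=members, direction=direction, keyword=keyword)


def write_gene_set(gene_set: ApoptosisGeneSet, path: str | Path) -> None:
    """Write members with direction labels as a two-column TSV."""
    rows = sorted(gene_set.direction.items())
    pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(path, sep="\t", index=False)


def direction_map(gene_set: ApoptosisGeneSet) -> Mapping[str, str]:
    return dict(gene_set.direction)
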