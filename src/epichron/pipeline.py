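"""End-to-end orchestration: gene set -> expression -> clustering -> overlap
-> promoter signal -> age regressions -> pathway analysis.

Every stage writes its intermediate tables under the output directory; a
JSON summary gathers the headline numbers (cluster sizes and trends, overlap
counts, fold-change and beta medians, regulatory-group counts, rank-test
report) and a provenance log records parameters, package version and input
checksums.  A stage failure aborts with the stage name; tables already
written stay on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from epichron import __version__
from epichron.ages import AGE_LABELS, days_for
from epichron import expression as expr
from epichron import clustering as clus
from epichron import gene_set as gs
from epichron import pathway_analysis as pw
from epichron import promoter_signal as ps
from epichron import trend_regression as tr

logger = logging.getLogger(__name__)

STAGES = (
    "gene_set", "expression", "clustering", "overlap",
    "promoter_signal", "trend_regression", "pathway_analysis",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths and parameters for one pipeline run.

    ``k`` may be one integer for all regions or a region -> k mapping.
    """

    annotation: str
    sample_sheet: str
    tpm_dir: str
    peak_dir: str
    pathway: str
    out_dir: str
    keyword: str = gs.DEFAULT_KEYWORD
    tpm_min: float = 1.0
    min_fraction: float = 1 / 3
    max_floor: float = 5.0
    k: int | dict[str, int] = 5
    metric: str = "euclidean"
    window: int = 2000
    mask_policy: str = "zero"
    tau: float = clus.DEFAULT_TREND_TAU
    test_variant: str = "ranksum"
    fold_from: str = "E10.5"
    fold_to: str = "P0"
    intensity_column: str = "signalValue"
    marks: tuple[str, ...] = ps.MARKS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        for key, val in raw.items():
            if key in ("paths", "params") and isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        if "marks" in flat:
            flat["marks"] = tuple(flat["marks"])
        return cls(**flat)

    def k_for(self, region: str) -> int:
        if isinstance(self.k, dict):
            if region not in self.k:
                raise KeyError(f"no cluster count configured for region {region!r}")
            return int(self.k[region])
        return int(self.k)


def _md5(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the JSON-ready summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {}
    timings: dict[str, float] = {}

    def stage(name):
        if name not in STAGES:
            raise ValueError(name)

        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s: failed (%s)", name, exc)
                    raise PipelineError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Ctx()

    with stage("gene_set"):
        ann = gs.read_annotation(config.annotation)
        apoptosis = gs.select_apoptosis_genes(ann, config.keyword)
        gs.write_gene_set(apoptosis, out / "gene_set.tsv")
        summary["gene_set"] = {
            "n_members": len(apoptosis.members),
            "direction_counts": apoptosis.counts(),
        }

    with stage("expression"):
        sheet = expr.read_sample_sheet(config.sample_sheet)
        raw = expr.load_tpm_tables(sheet, config.tpm_dir)
        present = [g for g in raw.values.index if g in apoptosis.members]
        missing = apoptosis.members - set(raw.values.index)
        if missing:
            logger.warning(
                "%d gene-set members absent from expression tables; dropped", len(missing)
            )
        raw = expr.ExpressionMatrix(raw.values.loc[present], "raw_tpm")
        averaged = expr.average_replicates(raw)
        (out / "expression").mkdir(exist_ok=True)
        expr.write_matrix(averaged, out / "expression" / "tpm_averaged.tsv")
        regions = averaged.regions()
        per_region: dict[str, dict[str, Any]] = {}
        for region in regions:
            sub = averaged.region(region)
            kept = expr.filter_expressed(sub, config.tpm_min, config.min_fraction,
                                         config.max_floor)
            filtered = expr.ExpressionMatrix(sub.values.loc[kept], "raw_tpm")
            logm = expr.log_transform(filtered)
            zm = expr.normalize(filtered)
            expr.write_matrix(logm, out / "expression" / f"{region}_log2.tsv")
            expr.write_matrix(zm, out / "expression" / f"{region}_zscore.tsv")
            per_region[region] = {"filtered": filtered, "log": logm, "z": zm}
        summary["expression"] = {
            "n_genes_quantified": len(present),
            "n_expressed": {r: len(d["z"].values) for r, d in per_region.items()},
        }

    with stage("clustering"):
        (out / "clusters").mkdir(exist_ok=True)
        assignments: dict[str, clus.ClusterAssignment] = {}
        for region in regions:
            zm = per_region[region]["z"]
            a = clus.upgma_cluster(zm, k=config.k_for(region), metric=config.metric)
            days = days_for(a.ages)
            clus.label_trend(a, days, tau=config.tau)
            clus.write_membership(a, out / "clusters" / f"{region}_membership.tsv")
            (out / "clusters" / f"{region}_dendrogram.nwk").write_text(clus.to_newick(a))
            assignments[region] = a
        summary["clustering"] = {
            r: {
                "k": a.k,
                "sizes": {str(c): s for c, s in sorted(a.sizes().items())},
                "trend": {str(c): t for c, t in sorted(a.trend.items())},
            }
            for r, a in assignments.items()
        }

    with stage("overlap"):
        overlap: dict[str, Any] = {}
        for trend in ("down", "up"):
            o = clus.overlap_analysis(assignments, trend)
            overlap[trend] = {
                "sizes": o.sizes,
                "pairwise": {f"{a}&{b}": v for (a, b), v in o.pairwise.items()},
                "intersection_all": o.intersection_all,
                "union": o.union,
                "shared_fraction": round(o.shared_fraction, 6),
            }
        pd.DataFrame(
            [(t, json.dumps(v, sort_keys=True)) for t, v in overlap.items()],
            columns=["trend", "summary"],
        ).to_csv(out / "overlap.tsv", sep="\t", index=False)
        summary["overlap"] = overlap

    with stage("promoter_signal"):
        (out / "signal").mkdir(exist_ok=True)
        peak_dir = Path(config.peak_dir)
        if not peak_dir.is_dir():
            raise FileNotFoundError(f"peak directory not found: {peak_dir}")
        ann_present = ann.loc[[g for g in present if g in ann.index]]
        signals: dict[tuple[str, str], ps.PromoterSignalMatrix] = {}
        for mark in config.marks:
            for region in regions:
                files = {
                    age: peak_dir / f"{mark}_{region}_{age}.narrowPeak"
                    for age in AGE_LABELS
                }
                sm = ps.build_signal_matrix(
                    files, ann_present, mark, region,
                    window=config.window, intensity_column=config.intensity_column,
                )
                ps.write_signal_matrix(
                    sm,
                    out / "signal" / f"{mark}_{region}_matrix.tsv",
                    out / "signal" / f"{mark}_{region}_mask.tsv",
                )
                signals[(mark, region)] = sm

    with stage("trend_regression"):
        (out / "betas").mkdir(exist_ok=True)
        frames = []
        beta_summaries: dict[str, Any] = {}
        results_by: dict[tuple[str, str], list[tr.RegressionResult]] = {}
        for region in regions:
            clustered = list(assignments[region].membership)
            ex_res = tr.fit_expression_matrix(per_region[region]["log"].values, clustered)
            results_by[("Ex", region)] = ex_res
            frames.append(tr.results_frame(ex_res, region))
            for mark in config.marks:
                kind = "K4" if mark == "H3K4me3" else "K27"
                res = tr.fit_signal_matrix(
                    signals[(mark, region)], clustered, mask_policy=config.mask_policy
                )
                results_by[(kind, region)] = res
                frames.append(tr.results_frame(res, region))
            for kind in ("Ex", "K4", "K27"):
                for trend in ("down", "up"):
                    try:
                        s = tr.summarize_betas(results_by[(kind, region)],
                                               assignments[region], trend)
                    except ValueError:
                        continue
                    beta_summaries[f"{region}.{kind}.{trend}"] = {
                        k: round(v, 6) for k, v in s.items()
                    }
        tr.write_results(frames, out / "betas" / "betas.tsv")
        pd.DataFrame(
            [
                dict(key=k, **v) for k, v in sorted(beta_summaries.items())
            ]
        ).to_csv(out / "betas" / "summary.tsv", sep="\t", index=False)
        summary["betas"] = beta_summaries

    with stage("pathway_analysis"):
        (out / "pathway").mkdir(exist_ok=True)
        pathway = pw.read_pathway_list(config.pathway)
        table = pw.build_pathway_table(pathway, apoptosis.direction, assignments)
        table.to_csv(out / "pathway" / "pathway_table.tsv", sep="\t", index=False)
        counts, largest, fraction = pw.tabulate_regulatory_groups(table)
        pw.write_regulatory_groups(counts, out / "pathway" / "regulatory_groups.tsv")

        # fold changes (first region's replicate-averaged TPM) for genes the
        # any-region rule puts in the down cluster, split pro vs anti
        region0 = regions[0]
        fc_by_dir: dict[str, list[float]] = {"pro": [], "anti": []}
        fc_all: dict[str, list[float]] = {"down": [], "up": []}
        avg0 = expr.ExpressionMatrix(
            per_region[region0]["filtered"].values, "raw_tpm"
        )
        for g, trend in zip(table["gene_id"], table["trend"]):
            if g not in avg0.values.index or trend not in ("down", "up"):
                continue
            fc, _flag = expr.fold_change(avg0, g, config.fold_from, config.fold_to,
                                         region=region0)
            fc_all[trend].append(fc)
            d = table.loc[table["gene_id"] == g, "direction"].iloc[0]
            if trend == "down" and d in fc_by_dir:
                fc_by_dir[d].append(fc)
        report = pw.compare_fold_changes(
            fc_by_dir["pro"], fc_by_dir["anti"], alternative="less",
            variant=config.test_variant,
        )
        with open(out / "pathway" / "test_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        summary["pathway"] = {
            "counts": counts,
            "largest_group": largest,
            "largest_group_pct": round(fraction, 4),
            "fold_change_median": {
                t: (round(float(np.median(v)), 6) if v else None)
                for t, v in fc_all.items()
            },
            "rank_test": report.to_dict(),
        }

    summary["timings_s"] = timings
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    provenance = {
        "version": __version__,
        "config": {k: (dict(v) if isinstance(v, dict) else (list(v) if isinstance(v, tuple) else v))
                   for k, v in asdict(config).items()},
        "inputs": {
            "annotation_md5": _md5(Path(config.annotation)),
            "sample_sheet_md5": _md5(Path(config.sample_sheet)),
            "pathway_md5": _md5(Path(config.pathway)),
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return summary
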