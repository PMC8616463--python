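"""Ground-truthed synthetic datasets emulating the study design.

The generator emits every input the pipeline consumes — gene annotation with
GO term names, per-sample TPM tables with a sample sheet, narrowPeak files
per (mark, region, age), and a pathway gene list — together with the ground
truth used by recovery tests.

Statistical structure (defaults):

* two dominant gene groups whose log2(TPM+1) decreases / increases linearly
  across the eight ages E10.5..P0 (days 10.5..22), plus two minor groups that
  reverse direction at E16.5 and one flat group;
* coupled promoter histone dynamics — the down group loses H3K4me3
  (beta_K4 ~ N(-0.3, 0.05) intensity units/day) with static H3K27me3, the up
  group loses H3K27me3 with static H3K4me3;
* lognormal replicate noise (additive Gaussian on the log2 scale, sd 0.1) and
  independent per-cell peak dropout;
* a KEGG-style pathway list whose pro/anti x down/up composition defaults to
  28/13/8/9, with pro genes drawn from the steeper and anti genes from the
  shallower down slopes so pro genes are the more strongly downregulated.

Everything is drawn from one seeded generator: a fixed seed reproduces the
dataset bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from epichron.ages import AGE_DAYS, AGE_LABELS
from epichron.expression import ExpressionMatrix
from epichron.promoter_signal import MARKS, PeakRecord

GROUP_NAMES = ("down", "up", "late_up", "late_down", "flat", "decoy")

#: breakpoint (coded day) where the late-reversal groups change slope sign
LATE_BREAK_DAY = 16.5

_TERM_APOPT = "apoptotic process"
_TERM_PRO = "positive regulation of apoptotic process"
_TERM_ANTI = "negative regulation of apoptotic process"
_TERMS_DECOY = ("cell cycle", "DNA repair")


@dataclass
class GeneratorConfig:
    """Study-shaped generator settings; defaults are the test conditions."""

    n_down: int = 300
    n_up: int = 250
    n_late_up: int = 50
    n_late_down: int = 50
    n_flat: int = 100
    n_decoy: int = 25
    n_both: int = 10                      # flat genes carrying both direction terms
    ages: tuple[str, ...] = AGE_LABELS
    regions: tuple[str, ...] = ("forebrain", "midbrain", "hindbrain")
    n_replicates: int = 2
    noise_sd: float = 0.1                 # replicate noise, log2(TPM+1) units
    slope_down: tuple[float, float] = (-0.5, -0.05)   # log2 units / day
    slope_up: tuple[float, float] = (0.05, 0.5)
    k4_down: tuple[float, float] = (-0.3, 0.05)       # (mean, sd) units/day
    k27_down: tuple[float, float] = (0.0, 0.02)
    k4_up: tuple[float, float] = (0.0, 0.02)
    k27_up: tuple[float, float] = (-0.3, 0.05)
    histone_noise_sd: float = 0.2
    peak_dropout: float = 0.05
    baseline_intensity: tuple[float, float] = (6.0, 12.0)
    low_intensity: tuple[float, float] = (1.0, 3.0)
    pathway_id: str = "hsa04210"
    pathway_counts: tuple[int, int, int, int] = (28, 13, 8, 9)  # pro_down, pro_up, anti_up, anti_down
    adversarial_peaks: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.histone_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 <= self.peak_dropout <= 1:
            raise ValueError("peak_dropout must lie in [0, 1]")
        for name in ("n_down", "n_up", "n_late_up", "n_late_down", "n_flat", "n_decoy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pathway_counts[0] + self.pathway_counts[3] > self.n_down:
            raise ValueError("pathway down-counts exceed n_down")
        if self.pathway_counts[1] + self.pathway_counts[2] > self.n_up:
            raise ValueError("pathway up-counts exceed n_up")


@dataclass
class SyntheticDataset:
    """In-memory dataset plus the ground truth it was generated from."""

    config: GeneratorConfig
    annotation: pd.DataFrame              # parsed form (set-valued go_terms)
    tpm: ExpressionMatrix                 # replicate-level raw TPM
    sample_sheet: pd.DataFrame
    peaks: dict[tuple[str, str, str], list[PeakRecord]]   # (mark, region, age)
    pathway: pd.DataFrame
    truth: pd.DataFrame


def _mu_profiles(groups: list[str], rng: np.random.Generator, cfg: GeneratorConfig,
                 days: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Noiseless log2(TPM+1) per gene x age, plus early/late true slopes.

    Intercepts are constrained so noiseless profiles never clip at zero:
    fitted slopes then equal true slopes exactly in the noise-free limit.
    """
    n = len(groups)
    mu = np.zeros((n, len(days)))
    slope_early = np.zeros(n)
    slope_late = np.zeros(n)
    d0 = days[0]
    span = days[-1] - days[0]
    for i, grp in enumerate(groups):
        if grp == "down":
            beta = rng.uniform(*cfg.slope_down)
            start = rng.uniform(max(4.0, 0.6 + abs(beta) * span), 8.5)
            mu[i] = start + beta * (days - d0)
            slope_early[i] = slope_late[i] = beta
        elif grp == "up":
            beta = rng.uniform(*cfg.slope_up)
            end = rng.uniform(max(3.0, 1.3 + 6.5 * beta, 0.05 + beta * span), 6.0)
            mu[i] = end + beta * (days - days[-1])
            slope_early[i] = slope_late[i] = beta
        elif grp == "late_up":
            s1, s2 = -rng.uniform(0.1, 0.3), rng.uniform(0.2, 0.6)
            start = rng.uniform(3.0, 6.0)
            mu[i] = start + s1 * np.minimum(days - d0, LATE_BREAK_DAY - d0) \
                + s2 * np.maximum(days - LATE_BREAK_DAY, 0.0)
            slope_early[i], slope_late[i] = s1, s2
        elif grp == "late_down":
            s1, s2 = rng.uniform(0.05, 0.2), -rng.uniform(0.3, 0.8)
            lo = max(2.0, 0.2 - s1 * (LATE_BREAK_DAY - d0) - s2 * (days[-1] - LATE_BREAK_DAY))
            start = rng.uniform(lo, 5.5)
            mu[i] = start + s1 * np.minimum(days - d0, LATE_BREAK_DAY - d0) \
                + s2 * np.maximum(days - LATE_BREAK_DAY, 0.0)
            slope_early[i], slope_late[i] = s1, s2
        elif grp == "flat":
            mu[i] = rng.uniform(1.0, 5.0)
        else:  # decoy
            mu[i] = rng.uniform(0.2, 2.0)
    return mu, slope_early, slope_late


def _histone_params(groups: list[str], rng: np.random.Generator,
                    cfg: GeneratorConfig) -> dict[str, np.ndarray]:
    """Per-gene baseline and true slope for each mark; slopes truncated at
    three sd so noiseless intensities stay positive over the full age span."""
    n = len(groups)
    out = {
        "k4_base": np.zeros(n), "k4_beta": np.zeros(n),
        "k27_base": np.zeros(n), "k27_beta": np.zeros(n),
    }

    def draw(mean_sd: tuple[float, float]) -> float:
        mean, sd = mean_sd
        return float(np.clip(rng.normal(mean, sd), mean - 3 * sd, mean + 3 * sd))

    for i, grp in enumerate(groups):
        if grp == "down":
            out["k4_base"][i] = rng.uniform(*cfg.baseline_intensity)
            out["k4_beta"][i] = draw(cfg.k4_down)
            out["k27_base"][i] = rng.uniform(*cfg.low_intensity)
            out["k27_beta"][i] = draw(cfg.k27_down)
        elif grp == "up":
            out["k4_base"][i] = rng.uniform(3.0, 6.0)
            out["k4_beta"][i] = draw(cfg.k4_up)
            out["k27_base"][i] = rng.uniform(*cfg.baseline_intensity)
            out["k27_beta"][i] = draw(cfg.k27_up)
        else:
            out["k4_base"][i] = rng.uniform(1.0, 4.0)
            out["k4_beta"][i] = draw((0.0, 0.02))
            out["k27_base"][i] = rng.uniform(1.0, 4.0)
            out["k27_beta"][i] = draw((0.0, 0.02))
    return out


def _assign_roles(groups: list[str], slope_early: np.ndarray,
                  cfg: GeneratorConfig, rng: np.random.Generator) -> tuple[list[str], list[str]]:
    """Direction label and pathway role per gene.

    Pathway pro-down genes take the steepest down slopes and anti-down the
    shallowest (mirrored for the up group), so the pro-vs-anti fold-change
    contrast carries the intended direction.  A few flat genes get both
    direction terms; remaining members stay direction-unknown.
    """
    n = len(groups)
    direction = ["unknown"] * n
    role = [""] * n
    n_pro_down, n_pro_up, n_anti_up, n_anti_down = cfg.pathway_counts
    down_idx = [i for i, g in enumerate(groups) if g == "down"]
    up_idx = [i for i, g in enumerate(groups) if g == "up"]
    down_sorted = sorted(down_idx, key=lambda i: slope_early[i])        # steepest first
    up_sorted = sorted(up_idx, key=lambda i: -slope_early[i])
    for i in down_sorted[:n_pro_down]:
        direction[i], role[i] = "pro", "pro_down"
    for i in down_sorted[len(down_sorted) - n_anti_down:]:
        direction[i], role[i] = "anti", "anti_down"
    for i in up_sorted[:n_pro_up]:
        direction[i], role[i] = "pro", "pro_up"
    for i in up_sorted[len(up_sorted) - n_anti_up:]:
        direction[i], role[i] = "anti", "anti_up"
    flat_idx = [i for i, g in enumerate(groups) if g == "flat"]
    for i in flat_idx[: cfg.n_both]:
        direction[i] = "both"
    for i, g in enumerate(groups):
        if g == "decoy":
            direction[i] = "none"
    return direction, role


def _go_terms(direction: str) -> frozenset[str]:
    if direction == "pro":
        return frozenset({_TERM_APOPT, _TERM_PRO})
    if direction == "anti":
        return frozenset({_TERM_APOPT, _TERM_ANTI})
    if direction == "both":
        return frozenset({_TERM_APOPT, _TERM_PRO, _TERM_ANTI})
    if direction == "none":
        return frozenset(_TERMS_DECOY)
    return frozenset({_TERM_APOPT})


def generate_dataset(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Generate a full in-memory dataset from a seeded configuration."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    groups: list[str] = []
    for name, count in zip(GROUP_NAMES, (cfg.n_down, cfg.n_up, cfg.n_late_up,
                                         cfg.n_late_down, cfg.n_flat, cfg.n_decoy)):
        groups.extend([name] * count)
    n = len(groups)
    days = np.array([AGE_DAYS[a] for a in cfg.ages])

    gene_ids = [f"G{i:04d}" for i in range(n)]
    chroms = [f"chr{(i % 3) + 1}" for i in range(n)]
    tss = [100_000 + (i // 3) * 10_000 for i in range(n)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(n)]

    mu, slope_early, slope_late = _mu_profiles(groups, rng, cfg, days)
    hist = _histone_params(groups, rng, cfg)
    direction, role = _assign_roles(groups, slope_early, cfg, rng)

    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "symbol": [f"Gene{i:04d}" for i in range(n)],
            "chrom": chroms,
            "tss": tss,
            "strand": strands,
            "go_terms": [_go_terms(d) for d in direction],
        }
    ).set_index("gene_id", drop=False)

    # replicate-level TPM: lognormal noise on the log2(TPM+1) scale
    n_reg, n_age, n_rep = len(cfg.regions), len(cfg.ages), cfg.n_replicates
    noise = rng.normal(0.0, cfg.noise_sd, size=(n, n_reg, n_age, n_rep)) \
        if cfg.noise_sd > 0 else np.zeros((n, n_reg, n_age, n_rep))
    log_rep = mu[:, None, :, None] + noise
    tpm_vals = np.maximum(np.exp2(log_rep) - 1.0, 0.0)
    columns = [
        (reg, age, rep + 1)
        for r, reg in enumerate(cfg.regions)
        for a, age in enumerate(cfg.ages)
        for rep in range(n_rep)
    ]
    flat_vals = tpm_vals.reshape(n, n_reg * n_age * n_rep)
    tpm_df = pd.DataFrame(flat_vals, index=gene_ids,
                          columns=pd.MultiIndex.from_tuples(
                              columns, names=["region", "age", "replicate"]))
    tpm = ExpressionMatrix(tpm_df, "raw_tpm")
    sample_sheet = pd.DataFrame(
        [
            (f"tpm_{reg}_{age}_rep{rep}.tsv", reg, age, rep)
            for reg, age, rep in columns
        ],
        columns=["file", "region", "age", "replicate"],
    )

    # histone peaks: one in-window peak per (gene, mark, region, age), minus dropout
    hnoise = rng.normal(0.0, cfg.histone_noise_sd, size=(n, 2, n_reg, n_age)) \
        if cfg.histone_noise_sd > 0 else np.zeros((n, 2, n_reg, n_age))
    drop = rng.random(size=(n, 2, n_reg, n_age)) < cfg.peak_dropout
    peaks: dict[tuple[str, str, str], list[PeakRecord]] = {}
    for m, mark in enumerate(MARKS):
        base = hist["k4_base"] if mark == "H3K4me3" else hist["k27_base"]
        beta = hist["k4_beta"] if mark == "H3K4me3" else hist["k27_beta"]
        for r, reg in enumerate(cfg.regions):
            for a, age in enumerate(cfg.ages):
                recs: list[PeakRecord] = []
                for i in range(n):
                    if drop[i, m, r, a]:
                        continue
                    val = base[i] + beta[i] * (days[a] - days[0]) + hnoise[i, m, r, a]
                    val = max(val, 0.0)
                    recs.append(PeakRecord(chroms[i], tss[i] - 500, tss[i] + 500,
                                           float(val), 500))
                if cfg.adversarial_peaks:
                    recs.extend(_adversarial_peaks(rng, chroms, tss))
                peaks[(mark, reg, age)] = recs

    # pathway list: the four regulatory groups plus both/unknown rows to
    # exercise the exclusion rules downstream
    path_rows = [gene_ids[i] for i in range(n) if role[i]]
    extra_unknown = [gene_ids[i] for i, g in enumerate(groups)
                     if g == "down" and not role[i]][:5]
    extra_both = [gene_ids[i] for i, d in enumerate(direction) if d == "both"][:3]
    pathway = pd.DataFrame(
        {"pathway_id": cfg.pathway_id,
         "gene_id": path_rows + extra_unknown + extra_both}
    )

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group": groups,
            "slope_early": slope_early,
            "slope_late": slope_late,
            "beta_k4": hist["k4_beta"],
            "beta_k27": hist["k27_beta"],
            "direction": direction,
            "pathway_role": role,
            "is_member": [d != "none" for d in direction],
        }
    ).set_index("gene_id", drop=False)

    return SyntheticDataset(cfg, annotation, tpm, sample_sheet, peaks, pathway, truth)


def _adversarial_peaks(rng: np.random.Generator, chroms: list[str],
                       tss: list[int]) -> list[PeakRecord]:
    """Decoy peaks in gene deserts plus one wide peak spanning two promoters."""
    out = []
    desert = max(tss) + 1_000_000
    for j in range(5):
        start = desert + int(rng.integers(0, 500_000))
        out.append(PeakRecord("chr1", start, start + 400, float(rng.uniform(1, 20)), 200))
    if len(tss) >= 6:
        lo = min(tss[0], tss[3]) - 1000
        hi = max(tss[0], tss[3]) + 1000
        out.append(PeakRecord(chroms[0], lo, hi, float(rng.uniform(1, 20)), (hi - lo) // 2))
    return out


def write_fixture_files(dataset: SyntheticDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write the dataset in the exact on-disk formats the pipeline reads.

    Layout: annotation.tsv, sample_sheet.tsv, pathway.tsv, ground_truth.tsv,
    tpm/<sample>.tsv (two columns), peaks/<mark>_<region>_<age>.narrowPeak.
    Returns (and writes) a manifest of every file with md5 checksum and size.
    """
    out = Path(out_dir)
    (out / "tpm").mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ann = dataset.annotation.copy()
    ann["go_terms"] = [";".join(sorted(t)) for t in ann["go_terms"]]
    ann_path = out / "annotation.tsv"
    ann.to_csv(ann_path, sep="\t", index=False)
    written.append(ann_path)

    sheet_path = out / "sample_sheet.tsv"
    dataset.sample_sheet.to_csv(sheet_path, sep="\t", index=False)
    written.append(sheet_path)

    for row in dataset.sample_sheet.itertuples(index=False):
        col = (row.region, row.age, int(row.replicate))
        series = dataset.tpm.values[col]
        p = out / "tpm" / row.file
        with open(p, "w") as fh:
            fh.write("gene_id\ttpm\n")
            for g, v in series.items():
                fh.write(f"{g}\t{v:.6f}\n")
        written.append(p)

    for (mark, region, age), recs in dataset.peaks.items():
        p = out / "peaks" / f"{mark}_{region}_{age}.narrowPeak"
        with open(p, "w") as fh:
            for r in recs:
                score = int(min(1000, round(r.intensity * 10)))
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t.\t{score}\t.\t"
                    f"{r.intensity:.6f}\t-1\t-1\t{r.summit_offset}\n"
                )
        written.append(p)

    path_path = out / "pathway.tsv"
    dataset.pathway.to_csv(path_path, sep="\t", index=False)
    written.append(path_path)

    truth_path = out / "ground_truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.8f")
    written.append(truth_path)

    rows = []
    for p in written:
        data = p.read_bytes()
        rows.append((str(p.relative_to(out)), hashlib.md5(data).hexdigest(), len(data)))
    manifest = pd.DataFrame(rows, columns=["path", "md5", "bytes"])
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def peak_file_map(out_dir: str | Path, mark: str, region: str,
                  ages: tuple[str, ...] = AGE_LABELS) -> dict[str, Path]:
    """Conventional narrowPeak path for every age of one (mark, region)."""
    out = Path(out_dir)
    return {age: out / "peaks" / f"{mark}_{region}_{age}.narrowPeak" for age in ages}
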