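"""Shared fixtures: a small fast dataset and one full default-scale run."""

from types import SimpleNamespace

import pandas as pd
import pytest
from hypothesis import settings

from epichron.cli import default_pipeline_config
from epichron.pipeline import run_pipeline
from epichron.synthetic_data import GeneratorConfig, generate_dataset, write_fixture_files

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def small_generator_config(**overrides) -> GeneratorConfig:
    base = dict(
        n_down=40, n_up=30, n_late_up=8, n_late_down=8, n_flat=12, n_decoy=5,
        n_both=4, pathway_counts=(6, 4, 3, 3), seed=7,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_generator_config())


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """Small dataset written to disk and pushed through the whole pipeline."""
    root = tmp_path_factory.mktemp("small")
    ds = generate_dataset(small_generator_config())
    write_fixture_files(ds, root / "data")
    cfg = default_pipeline_config(root / "data", root / "out", seed=7)
    summary = run_pipeline(cfg)
    return SimpleNamespace(dataset=ds, config=cfg, summary=summary, out=root / "out")


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Generator defaults (the study-shaped conditions) run end to end."""
    root = tmp_path_factory.mktemp("default")
    ds = generate_dataset(GeneratorConfig(seed=0))
    write_fixture_files(ds, root / "data")
    cfg = default_pipeline_config(root / "data", root / "out", seed=0)
    summary = run_pipeline(cfg)
    membership = {
        region: pd.read_csv(root / "out" / "clusters" / f"{region}_membership.tsv", sep="\t")
        for region in ds.config.regions
    }
    betas = pd.read_csv(root / "out" / "betas" / "betas.tsv", sep="\t")
    return SimpleNamespace(
        dataset=ds, config=cfg, summary=summary, out=root / "out",
        membership=membership, betas=betas,
    )
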