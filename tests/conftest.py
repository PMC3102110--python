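"""Shared fixtures: a synthetic screen run reused across test modules."""

from __future__ import annotations

import pytest

from coralscreen.io_core import PipelineConfig
from coralscreen.pipeline import run_pipeline
from coralscreen.synthetic import generate_bundle

N_GENES_E2E = 24


def make_config(sim_dir, out_dir, seed=11, n_genes=N_GENES_E2E) -> PipelineConfig:
    cfg = PipelineConfig(seed=seed, out_dir=str(out_dir))
    cfg.simulate.n_genes = n_genes
    for key, fname in [
        ("species_a", "speciesA.fasta"),
        ("species_b", "speciesB.fasta"),
        ("proteins", "proteins.fasta"),
        ("mito", "mito.fasta"),
        ("ontology", "ontology.obo"),
        ("go_map", "go_map.tsv"),
        ("clusters", "clusters.tsv"),
    ]:
        setattr(cfg.inputs, key, str(sim_dir / fname))
    return cfg


@pytest.fixture(scope="session")
def screen_run(tmp_path_factory):
    """One full synthetic generate->screen round trip (24 genes)."""
    sim_dir = tmp_path_factory.mktemp("sim")
    out_dir = tmp_path_factory.mktemp("screen")
    cfg = make_config(sim_dir, out_dir)
    bundle = generate_bundle(cfg.simulate, cfg.seed, sim_dir)
    out = run_pipeline(cfg)
    return {"cfg": cfg, "bundle": bundle, "out": out}
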