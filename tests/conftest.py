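import pandas as pd
import pytest

from tribescreen import editing
from tribescreen.simulate import (
    ScreenSimConfig,
    TribeSimConfig,
    simulate_hypertribe,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_screen():
    """Small planted screen: 200 genes, 5% each essential/sensitizer/resistance."""
    cfg = ScreenSimConfig(n_genes=200, n_nontargeting=100, n_safe_harbor=100, seed=11)
    manifest, counts, truth = simulate_screen(cfg)
    return cfg, manifest, counts, truth


@pytest.fixture(scope="session")
def small_tribe():
    """Small HyperTRIBE simulation with planted targets and SNP contaminants."""
    cfg = TribeSimConfig(n_genes=80, sites_per_gene=4, seed=12)
    return cfg, simulate_hypertribe(cfg)


@pytest.fixture(scope="session")
def tribe_pipeline(small_tribe):
    """Detected sites, per-condition FPKM and differential tests for small_tribe."""
    cfg, sim = small_tribe
    sites = editing.detect_edit_sites(sim.pileup, sim.annotation, sim.snp_set)
    lengths = (sim.annotation["end"] - sim.annotation["start"]).groupby(
        sim.annotation["gene"]).sum()
    fpkm = editing.condition_fpkm(editing.compute_fpkm(sim.gene_counts, lengths))
    samples_a = [s for s in sim.samples if s.startswith(cfg.conditions[0])]
    samples_b = [s for s in sim.samples if s.startswith(cfg.conditions[1])]
    tests = editing.differential_editing(sites, samples_a, samples_b, fpkm=fpkm)
    return sim, sites, fpkm, tests


@pytest.fixture
def toy_manifest():
    return pd.DataFrame({
        "guide_id": ["g1", "g2", "g3", "n1"],
        "sequence": ["ACGT" * 5] * 4,
        "gene": ["GENE1", "GENE1", "GENE2", None],
        "class": ["targeting", "targeting", "targeting", "non-targeting"],
    })
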