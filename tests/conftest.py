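import numpy as np
import pandas as pd
import pytest

from cortexmeth import (
    AssocEffects,
    CytosineMatrix,
    FeatureLayout,
    SimulationConfig,
    make_sample_meta,
    simulate_methylome,
)


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared by read-only tests."""
    cfg = SimulationConfig(seed=8)
    matrix, meta, truth = simulate_methylome(cfg)
    return cfg, matrix, meta, truth


@pytest.fixture(scope="session")
def dmr_study():
    """DMR-only landscape at the 2-Mb study scale (30 cell + 20 interaction)."""
    layout = FeatureLayout(n_umr=0, n_lmr=0, n_dmv=0, n_pmd=0,
                           n_dmr_cell=30, n_dmr_inter=20)
    cfg = SimulationConfig(
        seed=5, genome_length=2_000_000, n_gaps=0, layout=layout,
        assoc=AssocEffects(n_genes=0, n_gene_assoc=0, n_exon_assoc=0,
                           n_psi_assoc=0),
    )
    matrix, meta, truth = simulate_methylome(cfg)
    return cfg, matrix, meta, truth


def hand_matrix():
    """Ten CpG/CpH sites x 3 samples with fully known counts."""
    sites = pd.DataFrame({
        "chrom": ["chr1"] * 10,
        "pos": [11, 25, 40, 58, 73, 90, 120, 155, 170, 201],
        "strand": ["+", "-", "+", "+", "-", "+", "+", "-", "+", "+"],
        "context": ["CpG", "CpG", "CHH", "CpG", "CHG", "CpG", "CHH",
                    "CpG", "CHG", "CpG"],
        "trinucleotide": ["CGA", "CGT", "CAC", "CGC", "CAG", "CGG", "CTT",
                          "CGA", "CCG", "CGT"],
    })
    rng = np.random.default_rng(42)
    total = rng.integers(0, 20, size=(10, 3))
    meth = rng.binomial(total, 0.6)
    return CytosineMatrix(sites, meth, total, ["a", "b", "c"])


@pytest.fixture
def tiny_matrix():
    return hand_matrix()


@pytest.fixture
def meta24():
    ages = list(np.linspace(0, 23, 12))
    return make_sample_meta(
        [f"N{i:02d}" for i in range(12)] + [f"G{i:02d}" for i in range(12)],
        ["neuron"] * 12 + ["glia"] * 12,
        ages + ages,
    )
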