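import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bescan.gene_model import GeneModel
from bescan.simulate import (
    SimulationConfig,
    simulate_gene_and_library,
    simulate_screen_counts,
)

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def single_exon_model() -> GeneModel:
    """One exon, CDS ATG GCA TGT TAA -> protein MAC."""
    return GeneModel(
        gene_id="toy",
        contig_id="c1",
        contig_seq="CCC" + "ATGGCATGTTAA" + "GGG",
        strand="+",
        exons=[(3, 15)],
        cds=[(3, 15)],
    )


@pytest.fixture
def two_exon_model() -> GeneModel:
    """ATGGCA | GTAAGTTAG | TGTTAA: canonical GT..AG intron, protein MAC."""
    return GeneModel(
        gene_id="toy2",
        contig_id="c2",
        contig_seq="CC" + "ATGGCA" + "GTAAGTTAG" + "TGTTAA" + "CC",
        strand="+",
        exons=[(2, 8), (17, 23)],
        cds=[(2, 8), (17, 23)],
    )


def small_sim_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A fast, fully featured simulation for pipeline-level tests."""
    kwargs = dict(
        seed=seed,
        n_exons=3,
        exon_length=120,
        intron_length=40,
        promoter_length=60,
        flank=30,
        coverage=300.0,
        n_non_targeting=10,
        n_intergenic=10,
        n_essential_stop=30,
        n_nonessential_stop=10,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def default_study():
    """One full default-config simulated study (seed 1), session-shared."""
    cfg = SimulationConfig(seed=1)
    model, manifest, truth = simulate_gene_and_library(cfg)
    counts = simulate_screen_counts(manifest, truth, cfg)
    return cfg, model, manifest, truth, counts


def random_small_gene(rng: np.random.Generator) -> GeneModel:
    """Random 3-exon gene with promoter for oracle cross-checks."""
    from bescan.simulate import _random_gene

    cfg = SimulationConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_exons=3,
        exon_length=90,
        intron_length=30,
        promoter_length=40,
        flank=25,
    )
    return _random_gene(cfg, np.random.default_rng(cfg.seed))
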