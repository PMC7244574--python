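import numpy as np
import pytest

from tifiso import (
    GeneModel,
    GenomicInterval,
    run_cluster_pipeline,
    simulate_end_pairs,
    simulate_genome,
    truth_tss_support,
)


def make_gene(gene_id, chrom, start, end, strand, overlaps=False):
    g = GeneModel(gene_id=gene_id, interval=GenomicInterval(chrom, start, end, strand))
    g.overlaps_other_gene = overlaps
    return g


@pytest.fixture(scope="session")
def small_scenario():
    """A modest fully-simulated scenario shared across test modules."""
    sim = simulate_genome(n_genes=120, seed=101)
    pairs, truth = simulate_end_pairs(sim, depth=15_000, seed=102)
    support = truth_tss_support(truth)
    clusters, report = run_cluster_pipeline(pairs, sim.genome, support)
    return {
        "sim": sim,
        "pairs": pairs,
        "truth": truth,
        "support": support,
        "clusters": clusters,
        "report": report,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
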