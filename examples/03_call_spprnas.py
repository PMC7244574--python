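"""Call short promoter-proximal RNAs (sppRNAs).

sppRNAs are clusters shorter than 350 nt starting within 40 nt of an
annotated TSS and covering no annotated termination site.  The example
prints the fraction of expressed genes with a call and the median call
width, next to the simulated truth.
"""
import numpy as np

from tifiso import (
    call_spprna,
    run_cluster_pipeline,
    simulate_end_pairs,
    simulate_genome,
    truth_tss_support,
)
from tifiso.classification import classify_clusters, expressed_genes
from tifiso.spprna import spprna_gene_stats

sim = simulate_genome(n_genes=500, seed=1)
pairs, truth = simulate_end_pairs(
    sim, depth=50_000, spprna_gene_fraction=0.14, spprna_length_median=93.0, seed=2
)
clusters, _ = run_cluster_pipeline(pairs, sim.genome, truth_tss_support(truth))
classify_clusters(clusters, sim.genes)
calls = call_spprna(clusters, sim.genes)
stats = spprna_gene_stats(calls, expressed_genes(clusters))

true_widths = [abs(i.pas - i.tss) + 1 for i in truth.isoforms if i.kind == "spprna"]
print(f"sppRNA calls: {stats['n_calls']}")
print(
    f"fraction of expressed genes with sppRNA: "
    f"{stats['fraction_expressed_genes_with_spprna']:.3f} "
    f"(simulated truth {len(truth.spprna_genes) / len(sim.genes):.3f})"
)
print(
    f"median sppRNA width: {stats['median_width']:.0f} nt "
    f"(simulated truth {np.median(true_widths):.0f} nt)"
)
print(
    "A call marks a gene whose transcription frequently terminates just "
    "after initiation, producing a short capped, polyadenylated RNA."
)
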