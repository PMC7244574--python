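"""Scan promoter windows for IUPAC cis-elements.

Extracts TSS-anchored windows (-200/+150 nt, strand-oriented), plants the
GAGA-box motif (GAGAR) downstream of the TSS in one gene set, and shows
that per-window density separates the two sets.
"""
import numpy as np

from tifiso import extract_windows, motif_density, simulate_genome
from tifiso.nascent import compare_distributions
from tifiso.motifs import WINDOW_PRESETS

sim = simulate_genome(n_genes=200, seed=1)
genome_seqs = dict(sim.sequences)
# plant GAGAG ~30 nt downstream of the TSS of the first 100 genes
planted = {g.gene_id for g in sim.genes[:100]}
chrom = sim.genes[0].chrom
seq = list(genome_seqs[chrom])
for g in sim.genes[:100]:
    pos = g.annotated_tss + 30 if g.strand == "+" else g.annotated_tss - 34
    seq[pos : pos + 5] = list("GAGAG" if g.strand == "+" else "CTCTC")
genome_seqs[chrom] = "".join(seq)

from tifiso.io import Genome

genome = Genome(genome_seqs)
up, down = WINDOW_PRESETS["heatmap"]
w_planted = extract_windows(genome, [g for g in sim.genes if g.gene_id in planted], up, down)
w_control = extract_windows(genome, [g for g in sim.genes if g.gene_id not in planted], up, down)

freq, dens_planted = motif_density(w_planted, "GAGAR")
_, dens_control = motif_density(w_control, "GAGAR")
print(f"match-start frequency at TSS+30: {freq[up + 30]:.2f} (planted set)")
cmp = compare_distributions(dens_planted, dens_control)
print(
    f"mean GAGAR density per nt: planted {dens_planted.mean():.4f}, "
    f"control {dens_control.mean():.4f}, rank-sum p = {cmp['p_value']:.2e}"
)
print(
    "The frequency vector localises the element relative to the TSS; the "
    "density comparison tests set-level enrichment."
)
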