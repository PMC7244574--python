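# Methods

This note records the models, rules and numerical choices behind
`tifiso`, including the places where the procedure was genuinely open and
a design decision had to be made.

## Coordinates and data model

All internal coordinates are 0-based, intervals half-open. GFF3 (1-based
inclusive) is converted on read; BED/BEDPE/bedGraph are consumed and
emitted 0-based half-open. Single-base features — the capped 5′ end, the
last templated base before the poly(A) tail, annotated gene boundaries —
are stored as the position of that base. A "gene" is the outermost
annotated gene interval; transcript-level annotation features are
ignored because all classification is against gene boundaries.

## Clustering model

Pre-clusters collapse read pairs identical at both ends; their support is
the multiplicity. Merging is the **single-linkage transitive closure**
of the relation |ΔTSS| < w AND |ΔPAS| < w with w = 20 nt (strict: 19
merges, 20 does not). Closure is used rather than sequential
merge-into-existing because the latter depends on input order; closure is
deterministic, order-independent, and agrees with sequential merging
whenever that is unambiguous. The representative TSS and PAS of a merged
cluster are the read-support **mode** of each end, ties broken toward the
outermost base (5′-most for the TSS, 3′-most for the PAS, strand-aware);
the mode preserves the dominant molecule in the cluster.

Filters, in order:

* **support** — keep clusters with ≥ 3 read pairs;
* **mispriming** — discard a cluster when the sense-strand genome within
  ±10 nt of its PAS contains ≥ 6 consecutive A (a T-run on the forward
  reference for minus-strand clusters). Any run ≥ 6 discards: a longer
  run contains a 6-mer. The ±10 nt scan window is a package parameter
  (`polya_scan_flank`); the window within which artifact 3′ ends fall is
  not fixed by the upstream protocol, so it is exposed rather than
  hard-coded.
* **TSS support** — keep clusters whose TSS lies inside a TSS-seq support
  interval extended by ±10 nt. This removes the known artifactual bias
  of paired-end-derived TSSs toward gene 3′ ends. The filter is a direct
  containment test against user-supplied intervals; it does not re-run a
  peak caller, because its contract is only overlap with independently
  supported TSSs.

Invariants verified by the test suite: merge output equals a brute-force
connected-components oracle exactly; output is invariant to input
permutation; summed support is conserved; cluster counts are monotone in
the merge window and support threshold.

## Classification

A cluster is assigned to the **non-overlapping** gene (either-strand
intersection defines "overlapping"; genes that overlap another gene are
excluded from assignment entirely, trading coverage for unambiguous
calls) with maximal overlap, sense strand preferred; antisense-only
intersections are recorded as antisense, no intersection as intergenic.
Signed interior distances dT (cluster TSS vs annotated TSS) and dP
(cluster PAS vs annotated PAS; positive = inside the gene) feed an
explicit rule table with tolerance τ = 100 nt (configurable):

| condition | category |
|---|---|
| dT > τ, dP ≤ τ | internal_initiation |
| dP > τ, dT ≤ τ | internal_termination |
| dT > τ, dP > τ | internal_both |
| dT < −τ, \|dP\| ≤ τ | five_prime_extended |
| dP < −τ, \|dT\| ≤ τ | three_prime_extended |
| otherwise | full_span |

The eight-way segregation behind published pie charts of this kind is
not usually printed as explicit rules; the τ-based table is this
package's explicit, testable reconstruction.

"Expressed gene" means a gene with ≥ 1 sense-assigned final cluster —
the weakest self-contained definition, used for isoforms-per-gene and
sppRNA gene fractions. In two-sample category comparisons, a zero
proportion is replaced by half the minimum observable proportion of its
set (0.5/n) before log2 fold-change, keeping the comparison finite.
Width distributions are summarised for widths strictly below 6,000 nt
with Tukey 1.5×IQR whiskers.

## sppRNA calling

A final cluster is called an sppRNA when (i) width < 350 nt (strict),
(ii) its TSS lies within ±40 nt of a same-strand annotated TSS, and
(iii) its span covers no annotated termination site. "Termination
sites" are taken as same-strand annotated gene PASs — the conservative
reading that removes internal-termination look-alikes at short genes; a
`termination_strand="both"` option also tests opposite-strand PASs.
Cross-condition labels (selective termination vs co-induction) use a
1.5-fold threshold on mRNA and sppRNA signal ratios with a +1 pseudocount
only when a denominator is zero; the thresholds are package choices, the
upstream observation being qualitative.

## Nascent-coverage quantities

TPM is the per-kilobase rate normalised to the per-kilobase-rate sum over
the analysed gene set, × 10⁶ (the standard construction; the normalising
set is always the gene table passed in). Gene-body signal trims 200 nt
from each gene end to avoid TSS- and PAS-proximal coverage peaks; genes
shorter than 2 × 200 nt are excluded with a logged reason. The 5′
pausing index is the promoter rate (annotated TSS ± 150 nt) over the
body rate (gene shrunk 300 nt at each end); the library-size factor
cancels, so the index is scale-invariant. Eligibility: non-overlapping
genes longer than 1,000 nt within the top 75% by gene-body raw signal on
the provided track — the ranking source being otherwise unspecified,
the package ranks on the same track it quantifies.

Control genes are matched on gene-body signal by decile binning of the
target distribution and seeded per-bin sampling without replacement
(bins short of candidates are filled as far as possible with a logged
deficit). Metagene profiles average strand-oriented windows around
anchors, dropping windows that cross a chromosome edge; the band is the
normal-approximation 95% interval (mean ± 1.96 × SEM), adequate at the
anchor counts used (hundreds). Distribution comparisons are two-sided
Wilcoxon rank-sum (scipy's Mann–Whitney U, exact at small n); an
all-tied degenerate input returns p = 1 with a warning.

## Motif scanning

Patterns are IUPAC class strings; a position matches when every pattern
symbol's class contains the window base, N matches nothing, overlapping
matches all count, and only the given strand is scanned — a pattern and
its reverse complement (e.g. RGCCCAW / WTGGGCY) are paired explicitly by
the caller. Window presets: "heatmap" −200/+150 nt around the TSS for
display, "discovery_promoter" −300/+50 and "discovery_downstream"
−20/+250 for motif-search regions. Windows anchor on the annotated TSS
by default; a per-gene measured anchor (e.g. a dominant experimental TSS)
may be supplied. De novo discovery is out of scope: the package scans
given motifs only.

## Simulator

The generator's defaults are the study conditions the pipeline targets,
not tuning knobs: mean 4.3 isoforms per gene (zero-truncated Poisson),
14% sppRNA genes, sppRNA lengths lognormal with median 93 nt (σ = 0.5 on
the log scale) truncated to [20, 349] nt, per-end dispersion a rounded
zero-mean normal with sd 5 nt clipped at 3 sd, mispriming rate 5%,
antisense transcripts at 10% and intergenic transcripts at 5% of genes.
Genes alternate strands with 1,000–3,000 nt lengths and 300–800 nt gaps;
A-tracts of 6–9 bases are planted at 0.2 tracts/kb and recorded.
Within a gene, alternative ends sit on a 100-nt grid ≥ 150 nt inside the
gene, so distinct isoforms never fall within the merge window — end
dispersion, not end ambiguity, is the modelled noise. Isoform weights
mix a uniform floor with a Dirichlet draw (each isoform keeps at least
half the uniform share) so that truth isoforms are detectable at the
simulated depths; gene expression is lognormal (σ = 0.5). The sppRNA
isoform takes a fixed 25% share of its gene's molecules, consistent with
these short RNAs being abundant when the degradation pathway that
normally removes them is inactive.

Misprimed molecules keep their 5′ end and terminate immediately beside
the nearest reachable planted same-sense A-tract; molecules with no
reachable tract stay clean, so in very small genomes the realised
mispriming rate can fall slightly below the nominal one. Coverage is
per-base Poisson at a body rate over each gene extended by a 200-nt
margin (emulating promoter-region and read-through signal), with sppRNA
genes drawn at gain × body rate over the first 150 nt downstream of the
TSS.

What the simulator does **not** model: splicing, sequence-dependent read
errors, chromatin-driven end selection, overlapping genes, and
nonuniform within-gene coverage profiles. Passing recovery tests
therefore demonstrates the correctness of the algorithms under dispersed
but well-separated end sites — not performance on real libraries, where
end heterogeneity is richer.

## Problem sizes and tolerances

Recovery checks run at 2,000 genes × 200,000 molecules (full noisy
scenario) and 1,000 genes × 150,000 molecules (clean isoform-count
scenario); calibration and power analyses use 100 seeds at 1,000 and 600
genes respectively. These sizes give stable estimates (binomial
standard errors well inside the stated tolerances) while keeping the
whole validation run in tens of seconds. Recovery tolerances: sppRNA
gene fraction within 2 percentage points of realised truth, median
sppRNA width within 5 nt, cluster precision/recall ≥ 0.95 with a 20-nt
end-matching tolerance (the merge window). Floating-point comparisons
elsewhere use exact equality where the arithmetic is exact (counting,
order statistics) and relative tolerances ~1e-12 for ratio identities.

## Known limitations

* Cluster-to-gene assignment ignores genes flagged as overlapping
  another gene; in gene-dense genomes this discards real signal.
* The TSS-support filter is only as good as the supplied interval set;
  an empty set removes everything (prominently warned).
* The pausing-index expression filter ranks genes on the same track it
  quantifies, which slightly favours genes with promoter peaks when
  peaks are large.
* BAM ingestion assumes name-grouped records with read1 carrying the 5′
  block; SAM/BAM files not matching that convention should be reduced to
  BEDPE upstream.
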