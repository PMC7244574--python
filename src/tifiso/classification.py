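"""Gene assignment and isoform categorisation of final TIF-clusters.

Clusters are assigned to non-overlapping annotated genes and sorted into
eight mutually exclusive categories (full span, internal initiation,
internal termination, internal both, 5'/3' extended, antisense,
intergenic) by comparing cluster boundaries with annotated gene boundaries
under a tolerance ``tau``.  Genome-wide summaries -- normalised
boundary-distance tables, isoforms per expressed gene, category
proportions with log2 fold-changes, and cluster size distributions --
are computed from the classified set.
"""
from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GeneModel, IsoformCategory, TIFCluster

CATEGORY_ORDER = [c.value for c in IsoformCategory]


class GeneIndex:
    """Interval index over the assignable (non-overlapping) genes."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.overlaps_other_gene:
                continue
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree.addi(g.interval.start, g.interval.end, g)

    def candidates(self, cluster: TIFCluster) -> list[GeneModel]:
        tree = self._trees.get(cluster.chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(cluster.start, cluster.end)]
        hits.sort(key=lambda g: g.gene_id)
        return hits


def assign_cluster_to_gene(
    cluster: TIFCluster, index: GeneIndex
) -> tuple[Optional[GeneModel], bool]:
    """Assign a cluster to the maximal-overlap non-overlapping gene.

    Sense-strand candidates win over antisense ones; if only antisense
    genes intersect, the best antisense gene is returned with the
    antisense flag set.  Returns (gene, is_antisense) or (None, False).
    """
    candidates = index.candidates(cluster)
    if not candidates:
        return None, False
    civ = cluster.interval

    def best(cands: list[GeneModel]) -> Optional[GeneModel]:
        if not cands:
            return None
        return max(cands, key=lambda g: (civ.overlap_length(g.interval), g.gene_id))

    sense = best([g for g in candidates if g.strand == cluster.strand])
    if sense is not None:
        return sense, False
    return best([g for g in candidates if g.strand != cluster.strand]), True


def interior_distances(cluster: TIFCluster, gene: GeneModel) -> tuple[int, int]:
    """Signed (dTSS, dPAS) of cluster boundaries vs annotated boundaries;
    positive values point into the gene interior."""
    if gene.strand == "+":
        d_tss = cluster.tss - gene.annotated_tss
        d_pas = gene.annotated_pas - cluster.pas
    else:
        d_tss = gene.annotated_tss - cluster.tss
        d_pas = cluster.pas - gene.annotated_pas
    return d_tss, d_pas


def classify_cluster(
    cluster: TIFCluster,
    gene: Optional[GeneModel],
    antisense: bool = False,
    tau: int = 100,
) -> IsoformCategory:
    """Apply the category rule table with boundary tolerance ``tau``."""
    if tau <= 0:
        raise ValueError("category tolerance tau must be > 0")
    if gene is None:
        return IsoformCategory.INTERGENIC
    if antisense:
        return IsoformCategory.ANTISENSE
    d_tss, d_pas = interior_distances(cluster, gene)
    if d_tss > tau and d_pas <= tau:
        return IsoformCategory.INTERNAL_INITIATION
    if d_pas > tau and d_tss <= tau:
        return IsoformCategory.INTERNAL_TERMINATION
    if d_tss > tau and d_pas > tau:
        return IsoformCategory.INTERNAL_BOTH
    if d_tss < -tau and abs(d_pas) <= tau:
        return IsoformCategory.FIVE_PRIME_EXTENDED
    if d_pas < -tau and abs(d_tss) <= tau:
        return IsoformCategory.THREE_PRIME_EXTENDED
    return IsoformCategory.FULL_SPAN


def classify_clusters(
    clusters: Sequence[TIFCluster],
    genes: Sequence[GeneModel],
    tau: int = 100,
) -> list[TIFCluster]:
    """Assign and classify every cluster in place; returns the same list."""
    index = GeneIndex(genes)
    for c in clusters:
        gene, antisense = assign_cluster_to_gene(c, index)
        c.gene_id = gene.gene_id if gene is not None else None
        c.antisense_gene = antisense
        c.category = classify_cluster(c, gene, antisense, tau)
    return list(clusters)


def boundary_distance_table(
    clusters: Sequence[TIFCluster], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """Per sense-assigned cluster: boundary distances to the annotated gene
    boundaries, signed (positive = interior) and normalised to gene length.

    Antisense and intergenic clusters are excluded.  This is the table
    behind the genome-wide TSS/PAS 2D density scatter.
    """
    gene_map = {g.gene_id: g for g in genes}
    rows = []
    for c in clusters:
        if c.gene_id is None or c.antisense_gene:
            continue
        gene = gene_map[c.gene_id]
        if gene.length <= 0:
            raise ValueError(f"zero-length gene {gene.gene_id}")
        d_tss, d_pas = interior_distances(c, gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "d_tss_norm": d_tss / gene.length,
                "d_pas_norm": d_pas / gene.length,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "d_tss_norm", "d_pas_norm"])


def expressed_genes(clusters: Sequence[TIFCluster]) -> set[str]:
    """Genes with at least one sense-assigned final cluster."""
    return {
        c.gene_id for c in clusters if c.gene_id is not None and not c.antisense_gene
    }


def isoforms_per_gene(
    clusters: Sequence[TIFCluster],
) -> tuple[pd.Series, float]:
    """Distinct final clusters per expressed gene and the arithmetic mean.

    An expressed gene is one with >= 1 sense-assigned final cluster.  With
    no expressed genes the mean is reported as NaN.
    """
    counts: dict[str, int] = {}
    for c in clusters:
        if c.gene_id is None or c.antisense_gene:
            continue
        counts[c.gene_id] = counts.get(c.gene_id, 0) + 1
    series = pd.Series(counts, dtype=int).sort_index()
    mean = float(series.mean()) if len(series) else math.nan
    return series, mean


def category_proportions(clusters: Sequence[TIFCluster]) -> pd.Series:
    """Fraction of classified clusters in each of the eight categories."""
    labels = [c.category.value for c in clusters if c.category is not None]
    counts = pd.Series(labels).value_counts().reindex(CATEGORY_ORDER, fill_value=0)
    total = counts.sum()
    return counts / total if total else counts.astype(float)


def category_summary(
    clusters_a: Sequence[TIFCluster],
    clusters_b: Optional[Sequence[TIFCluster]] = None,
) -> pd.DataFrame:
    """Category proportions, and per-category log2 fold-change b vs a when a
    second classified set is given.

    Zero proportions are replaced by half the minimum observable proportion
    of their set (0.5 / n) before taking the ratio, so the fold-change is
    always finite.
    """
    out = pd.DataFrame({"proportion_a": category_proportions(clusters_a)})
    if clusters_b is not None:
        out["proportion_b"] = category_proportions(clusters_b)
        n_a = max(sum(1 for c in clusters_a if c.category is not None), 1)
        n_b = max(sum(1 for c in clusters_b if c.category is not None), 1)
        pa = out.proportion_a.replace(0.0, 0.5 / n_a)
        pb = out.proportion_b.replace(0.0, 0.5 / n_b)
        out["log2_fold_change"] = np.log2(pb / pa)
    return out


def size_distribution(
    clusters: Sequence[TIFCluster], size_dist_max: int = 6000
) -> dict:
    """Summary of cluster widths strictly below ``size_dist_max``.

    Reports median, quartiles, Tukey 1.5x-IQR whisker bounds and a
    histogram (100 equal bins over [0, size_dist_max)).
    """
    widths = np.array(
        [c.width for c in clusters if c.width < size_dist_max], dtype=float
    )
    if widths.size == 0:
        return {"n": 0, "median": math.nan, "q1": math.nan, "q3": math.nan,
                "iqr": math.nan, "whisker_low": math.nan, "whisker_high": math.nan,
                "histogram": None}
    q1, med, q3 = np.percentile(widths, [25, 50, 75])
    iqr = q3 - q1
    counts, edges = np.histogram(widths, bins=100, range=(0, size_dist_max))
    return {
        "n": int(widths.size),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(widths[widths >= q1 - 1.5 * iqr].min()),
        "whisker_high": float(widths[widths <= q3 + 1.5 * iqr].max()),
        "histogram": (counts.tolist(), edges.tolist()),
    }
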