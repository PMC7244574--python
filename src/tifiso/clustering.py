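"""End-pair clustering: from observed TSS/PAS pairs to final TIF-clusters.

The pipeline follows the published order: exact-coordinate pre-clusters,
two-dimensional single-linkage merging of pre-clusters whose 5' and 3'
positions each differ by fewer than ``merge_window`` nucleotides, a minimum
read-pair support filter, removal of clusters whose PAS sits in a genomic
A-tract (oligo(dT) mispriming artifacts), and removal of clusters whose TSS
lacks independent TSS-seq support.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import (
    CoverageTrack,  # noqa: F401  (re-exported convenience)
    EndPair,
    PipelineParams,
    TIFCluster,
    TSSSupportSet,
)
from .io import Genome

logger = logging.getLogger(__name__)


@dataclass
class ClusterReport:
    """Per-stage bookkeeping of the clustering pipeline."""

    n_input_pairs: int = 0
    n_preclusters: int = 0
    n_merged: int = 0
    n_after_support: int = 0
    n_after_mispriming: int = 0
    n_after_tss_support: int = 0
    notes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "input_pairs": self.n_input_pairs,
            "preclusters": self.n_preclusters,
            "merged_clusters": self.n_merged,
            "after_support_filter": self.n_after_support,
            "after_mispriming_filter": self.n_after_mispriming,
            "after_tss_support_filter": self.n_after_tss_support,
        }


def build_preclusters(pairs: Sequence[EndPair]) -> list[TIFCluster]:
    """Merge read pairs overlapping exactly at both ends.

    One pre-cluster per distinct (chrom, strand, five_prime, three_prime);
    its support is the multiplicity of that pair in the input.
    """
    counts = Counter((p.chrom, p.strand, p.five_prime, p.three_prime) for p in pairs)
    clusters = [
        TIFCluster(
            chrom=chrom,
            strand=strand,
            tss=fp,
            pas=tp,
            support=n,
            members=[(fp, tp, n)],
        )
        for (chrom, strand, fp, tp), n in counts.items()
    ]
    clusters.sort(key=lambda c: (c.chrom, c.strand, c.tss, c.pas))
    return clusters


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _representative_end(
    positions: Counter, strand: str, end: str
) -> int:
    """Read-support mode of an end; ties broken toward the outermost base
    (5'-most for the TSS end, 3'-most for the PAS end, strand-aware)."""
    best = max(positions.values())
    candidates = [pos for pos, n in positions.items() if n == best]
    outermost_is_min = (strand == "+") == (end == "tss")
    return min(candidates) if outermost_is_min else max(candidates)


def merge_preclusters(
    preclusters: Sequence[TIFCluster], merge_window: int = 20
) -> list[TIFCluster]:
    """Single-linkage transitive closure of pre-clusters under the relation
    |dTSS| < merge_window AND |dPAS| < merge_window (both strict).

    Merged support is the sum of member supports; representative TSS and
    PAS are the read-support mode of each end (ties to the outermost base).
    Output is sorted by (chrom, strand, tss, pas) and is independent of
    input order.
    """
    groups: dict[tuple[str, str], list[TIFCluster]] = {}
    for c in preclusters:
        groups.setdefault((c.chrom, c.strand), []).append(c)
    merged: list[TIFCluster] = []
    for (chrom, strand), group in groups.items():
        group.sort(key=lambda c: (c.tss, c.pas))
        tss = np.array([c.tss for c in group], dtype=np.int64)
        pas = np.array([c.pas for c in group], dtype=np.int64)
        n = len(group)
        uf = _UnionFind(n)
        for i in range(n):
            j = i + 1
            ti, pi = tss[i], pas[i]
            while j < n and tss[j] - ti < merge_window:
                if abs(int(pas[j]) - int(pi)) < merge_window:
                    uf.union(i, j)
                j += 1
        components: dict[int, list[int]] = {}
        for i in range(n):
            components.setdefault(uf.find(i), []).append(i)
        for idxs in components.values():
            members: list[tuple[int, int, int]] = []
            for i in idxs:
                members.extend(group[i].members)
            members.sort()
            tss_counts: Counter = Counter()
            pas_counts: Counter = Counter()
            support = 0
            for fp, tp, cnt in members:
                tss_counts[fp] += cnt
                pas_counts[tp] += cnt
                support += cnt
            merged.append(
                TIFCluster(
                    chrom=chrom,
                    strand=strand,
                    tss=_representative_end(tss_counts, strand, "tss"),
                    pas=_representative_end(pas_counts, strand, "pas"),
                    support=support,
                    members=members,
                )
            )
    merged.sort(key=lambda c: (c.chrom, c.strand, c.tss, c.pas))
    return merged


def filter_support(
    clusters: Sequence[TIFCluster], min_support: int = 3
) -> list[TIFCluster]:
    """Keep clusters with read-pair support >= min_support."""
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kept = [c for c in clusters if c.support >= min_support]
    logger.info(
        "support filter: kept %d of %d clusters", len(kept), len(clusters)
    )
    return kept


def is_misprimed(
    cluster: TIFCluster,
    genome: Genome,
    polya_min_run: int = 6,
    polya_scan_flank: int = 10,
) -> bool:
    """True when the sense-strand genome within +/- flank of the cluster PAS
    carries a run of >= polya_min_run consecutive adenosines.

    For minus-strand clusters the sense A-run appears as a T-run on the
    forward reference within the same window.  Windows past a chromosome
    edge are truncated.
    """
    window = genome.fetch(
        cluster.chrom,
        cluster.pas - polya_scan_flank,
        cluster.pas + polya_scan_flank + 1,
    )
    needle = ("A" if cluster.strand == "+" else "T") * polya_min_run
    return needle in window


def filter_mispriming(
    clusters: Sequence[TIFCluster],
    genome: Genome,
    polya_min_run: int = 6,
    polya_scan_flank: int = 10,
) -> list[TIFCluster]:
    """Discard clusters whose PAS lies in/next to a genomic poly(A) tract."""
    kept = [
        c
        for c in clusters
        if not is_misprimed(c, genome, polya_min_run, polya_scan_flank)
    ]
    logger.info(
        "mispriming filter: kept %d of %d clusters", len(kept), len(clusters)
    )
    return kept


def filter_tss_support(
    clusters: Sequence[TIFCluster],
    tss_support: TSSSupportSet,
    tss_support_flank: int = 10,
) -> list[TIFCluster]:
    """Keep clusters whose TSS falls within a same-strand TSS-seq support
    interval extended by ``tss_support_flank`` on each side.

    This removes the 3'-biased artifactual cluster TSSs that lack
    independent 5'-end evidence.
    """
    if len(tss_support) == 0:
        logger.warning(
            "TSS support set is EMPTY: the TSS-support filter removes all "
            "%d clusters", len(clusters),
        )
        return []
    kept = [
        c
        for c in clusters
        if tss_support.contains(c.chrom, c.strand, c.tss, tss_support_flank)
    ]
    logger.info(
        "TSS-support filter: kept %d of %d clusters", len(kept), len(clusters)
    )
    return kept


def run_cluster_pipeline(
    pairs: Sequence[EndPair],
    genome: Optional[Genome],
    tss_support: Optional[TSSSupportSet],
    params: Optional[PipelineParams] = None,
) -> tuple[list[TIFCluster], ClusterReport]:
    """Full clustering pipeline in the published order.

    preclusters -> 2D merge -> support filter -> mispriming filter ->
    TSS-support filter.  Passing ``genome=None`` or ``tss_support=None``
    skips the corresponding filter (noted in the report).
    """
    params = params or PipelineParams()
    report = ClusterReport(n_input_pairs=len(pairs))
    pre = build_preclusters(pairs)
    report.n_preclusters = len(pre)
    merged = merge_preclusters(pre, params.merge_window)
    report.n_merged = len(merged)
    supported = filter_support(merged, params.min_support)
    report.n_after_support = len(supported)
    if genome is not None:
        supported = filter_mispriming(
            supported, genome, params.polya_min_run, params.polya_scan_flank
        )
    else:
        report.notes.append("mispriming filter skipped: no genome provided")
    report.n_after_mispriming = len(supported)
    if tss_support is not None:
        supported = filter_tss_support(
            supported, tss_support, params.tss_support_flank
        )
    else:
        report.notes.append("TSS-support filter skipped: no support set provided")
    report.n_after_tss_support = len(supported)
    return supported, report
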