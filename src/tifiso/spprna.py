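"""Short promoter-proximal RNA (sppRNA) calling and statistics.

An sppRNA is a final TIF-cluster shorter than ``spprna_max_len`` (strict)
whose TSS lies within ``tss_flank`` nt of a same-strand annotated gene TSS
and whose span overlaps no annotated termination site (same-strand gene
PAS).  These are the capped, polyadenylated products of promoter-proximal
transcriptional termination that accumulate in nuclear-exosome mutants.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, TIFCluster


@dataclass(slots=True)
class SppRNACall:
    cluster: TIFCluster
    gene_id: str
    distance_to_annotated_tss: int  # signed nt, positive = downstream of TSS

    @property
    def width(self) -> int:
        return self.cluster.width


def _end_index(
    genes: Sequence[GeneModel], which: str
) -> dict[tuple[str, str], tuple[np.ndarray, list[str]]]:
    grouped: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for g in genes:
        pos = g.annotated_tss if which == "tss" else g.annotated_pas
        grouped.setdefault((g.chrom, g.strand), []).append((pos, g.gene_id))
    out = {}
    for key, entries in grouped.items():
        entries.sort()
        out[key] = (
            np.array([e[0] for e in entries], dtype=np.int64),
            [e[1] for e in entries],
        )
    return out


def call_spprna(
    clusters: Sequence[TIFCluster],
    genes: Sequence[GeneModel],
    spprna_max_len: int = 350,
    tss_flank: int = 40,
    termination_strand: str = "sense",
) -> list[SppRNACall]:
    """Call sppRNAs from the final cluster set.

    Rules (all must hold):
      * cluster width < spprna_max_len (strict);
      * cluster TSS within [annotated_tss - tss_flank, annotated_tss +
        tss_flank] of a same-strand gene (the nearest such gene is linked);
      * the cluster interval covers no annotated gene PAS
        (``termination_strand``: 'sense' tests same-strand PASs only,
        'both' also tests opposite-strand PASs).
    """
    if termination_strand not in ("sense", "both"):
        raise ValueError("termination_strand must be 'sense' or 'both'")
    tss_index = _end_index(genes, "tss")
    pas_index = _end_index(genes, "pas")
    calls: list[SppRNACall] = []
    for c in clusters:
        if c.width >= spprna_max_len:
            continue
        key = (c.chrom, c.strand)
        if key not in tss_index:
            continue
        positions, ids = tss_index[key]
        i = int(np.searchsorted(positions, c.tss))
        best_gene = None
        best_dist = None
        for j in (i - 1, i):
            if 0 <= j < positions.size and abs(int(positions[j]) - c.tss) <= tss_flank:
                d = abs(int(positions[j]) - c.tss)
                if best_dist is None or d < best_dist:
                    best_dist = d
                    best_gene = j
        if best_gene is None:
            continue
        strands = ("+", "-") if termination_strand == "both" else (c.strand,)
        overlaps_pas = False
        for strand in strands:
            pk = (c.chrom, strand)
            if pk not in pas_index:
                continue
            pas_positions, _ = pas_index[pk]
            lo = int(np.searchsorted(pas_positions, c.start, side="left"))
            hi = int(np.searchsorted(pas_positions, c.end - 1, side="right"))
            if hi > lo:
                overlaps_pas = True
                break
        if overlaps_pas:
            continue
        gene_pos = int(positions[best_gene])
        signed = c.tss - gene_pos if c.strand == "+" else gene_pos - c.tss
        calls.append(
            SppRNACall(
                cluster=c,
                gene_id=ids[best_gene],
                distance_to_annotated_tss=signed,
            )
        )
    return calls


def spprna_gene_stats(
    calls: Sequence[SppRNACall], expressed: Iterable[str]
) -> dict:
    """Gene-level sppRNA summary.

    Returns the fraction of expressed genes with >= 1 call, the median call
    width in nt, and a per-gene call table.  The expressed-gene set comes
    from the classification stage (>= 1 sense-assigned final cluster).
    """
    expressed = set(expressed)
    if not expressed:
        raise ValueError("expressed gene set is empty")
    per_gene: dict[str, int] = {}
    widths = []
    for call in calls:
        per_gene[call.gene_id] = per_gene.get(call.gene_id, 0) + 1
        widths.append(call.width)
    genes_with_calls = set(per_gene) & expressed
    table = pd.DataFrame(
        sorted(per_gene.items()), columns=["gene_id", "n_spprna"]
    )
    return {
        "fraction_expressed_genes_with_spprna": len(genes_with_calls) / len(expressed),
        "median_width": float(np.median(widths)) if widths else float("nan"),
        "n_calls": len(calls),
        "per_gene": table,
    }


def calls_to_bed(calls: Sequence[SppRNACall]) -> list[tuple[str, int, int, str, int, str]]:
    """BED6 rows (name = gene_id, score = read-pair support) for export."""
    return [
        (
            c.cluster.chrom,
            c.cluster.start,
            c.cluster.end,
            c.gene_id,
            c.cluster.support,
            c.cluster.strand,
        )
        for c in calls
    ]


def compare_conditions(
    spprna_a: Mapping[str, float],
    mrna_a: Mapping[str, float],
    spprna_b: Mapping[str, float],
    mrna_b: Mapping[str, float],
    fold: float = 1.5,
) -> pd.Series:
    """Label each gene's cross-condition behaviour.

    selective_termination: mRNA up >= fold while sppRNA down <= 1/fold
    (mRNA gain at the expense of the sppRNA); coinduced: both up >= fold;
    other: anything else.  A zero denominator gets a +1 pseudocount on both
    terms of that ratio.
    """

    def ratio(b: float, a: float) -> float:
        return b / a if a > 0 else (b + 1.0) / (a + 1.0)

    genes = sorted(set(spprna_a) & set(mrna_a) & set(spprna_b) & set(mrna_b))
    labels = {}
    for g in genes:
        values = [spprna_a[g], mrna_a[g], spprna_b[g], mrna_b[g]]
        if any(v < 0 for v in values):
            raise ValueError(f"negative signal for gene {g}")
        mrna_ratio = ratio(mrna_b[g], mrna_a[g])
        spp_ratio = ratio(spprna_b[g], spprna_a[g])
        if mrna_ratio >= fold and spp_ratio <= 1.0 / fold:
            labels[g] = "selective_termination"
        elif mrna_ratio >= fold and spp_ratio >= fold:
            labels[g] = "coinduced"
        else:
            labels[g] = "other"
    return pd.Series(labels, dtype=object)
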