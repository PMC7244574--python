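"""Nascent-transcription (pNET-seq-style) coverage analyses.

Gene-body signal, TPM normalisation, the 5' pausing index, expression-
matched control-gene selection, anchored metagene profiles with a 95%
confidence band, and rank-sum distribution comparisons.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CoverageTrack, GeneModel, PipelineParams

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RegionSignal:
    raw_count: float
    tpm: float
    length: int


def genebody_region(gene: GeneModel, shrink: int = 200) -> Optional[tuple[int, int]]:
    """[TSS + shrink, PAS - shrink) in genomic coordinates, or None when the
    gene is too short (length must exceed 2 x shrink)."""
    if gene.length <= 2 * shrink:
        return None
    return gene.interval.start + shrink, gene.interval.end - shrink


def genebody_signal(
    track: CoverageTrack, gene: GeneModel, shrink: int = 200
) -> Optional[float]:
    """Raw nascent signal over the shrunken gene body; None if the gene is
    too short (trimming avoids the TSS- and PAS-proximal coverage peaks)."""
    region = genebody_region(gene, shrink)
    if region is None:
        logger.debug("gene %s too short for body signal", gene.gene_id)
        return None
    return track.window_sum(gene.chrom, gene.strand, region[0], region[1])


def add_tpm(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``tpm`` column: per-kb rate normalised to the rate sum over the
    analysed gene set, scaled to one million."""
    rate = table.raw_count / (table.length / 1000.0)
    total = rate.sum()
    table = table.copy()
    table["tpm"] = rate / total * 1e6 if total > 0 else 0.0
    return table


def genebody_signal_table(
    track: CoverageTrack, genes: Sequence[GeneModel], shrink: int = 200
) -> pd.DataFrame:
    """Gene-body raw signal and TPM for every eligible gene."""
    rows = []
    for g in genes:
        raw = genebody_signal(track, g, shrink)
        if raw is None:
            continue
        rows.append({"gene_id": g.gene_id, "raw_count": raw, "length": g.length - 2 * shrink})
    return add_tpm(pd.DataFrame(rows, columns=["gene_id", "raw_count", "length"]))


def pausing_index(
    track: CoverageTrack,
    gene: GeneModel,
    promoter_halfwidth: int = 150,
    body_shrink: int = 300,
) -> Optional[float]:
    """Promoter per-kb rate over gene-body per-kb rate.

    Promoter window is the +/- halfwidth around the annotated TSS; body is
    the gene shrunk by ``body_shrink`` at each end.  The library-size term
    of TPM cancels in the ratio, so per-kb rates are compared directly.
    Returns None (gene excluded) when the body has zero signal or no
    positive length.
    """
    tss = gene.annotated_tss
    prom_start, prom_end = tss - promoter_halfwidth, tss + promoter_halfwidth
    body_start = gene.interval.start + body_shrink
    body_end = gene.interval.end - body_shrink
    if body_end <= body_start:
        logger.debug("gene %s too short for pausing index", gene.gene_id)
        return None
    prom = track.window_sum(gene.chrom, gene.strand, prom_start, prom_end)
    body = track.window_sum(gene.chrom, gene.strand, body_start, body_end)
    if body == 0:
        logger.debug("gene %s has zero body signal; index undefined", gene.gene_id)
        return None
    prom_rate = prom / (prom_end - prom_start)
    body_rate = body / (body_end - body_start)
    return prom_rate / body_rate


def eligible_pausing_genes(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    params: Optional[PipelineParams] = None,
) -> list[GeneModel]:
    """Genes eligible for pausing-index analysis: non-overlapping, longer
    than ``pi_min_gene_len`` nt, and within the top ``pi_expr_fraction``
    most expressed by gene-body raw signal on this track."""
    params = params or PipelineParams()
    pool = [
        g
        for g in genes
        if not g.overlaps_other_gene and g.length > params.pi_min_gene_len
    ]
    signals = np.array(
        [genebody_signal(track, g, params.genebody_shrink) or 0.0 for g in pool]
    )
    if signals.size == 0:
        return []
    cutoff = np.quantile(signals, 1.0 - params.pi_expr_fraction)
    return [g for g, s in zip(pool, signals) if s >= cutoff]


def pausing_index_table(
    track: CoverageTrack,
    genes: Sequence[GeneModel],
    params: Optional[PipelineParams] = None,
) -> pd.DataFrame:
    """Pausing index for every eligible gene (undefined indices dropped)."""
    params = params or PipelineParams()
    rows = []
    for g in eligible_pausing_genes(track, genes, params):
        pi = pausing_index(
            track, g, params.pi_promoter_halfwidth, params.pi_body_shrink
        )
        if pi is not None:
            rows.append({"gene_id": g.gene_id, "pausing_index": pi})
    return pd.DataFrame(rows, columns=["gene_id", "pausing_index"])


def match_control_genes(
    target_genes: Sequence[str],
    candidate_genes: Sequence[str],
    body_signal: Mapping[str, float],
    n_bins: int = 10,
    seed: int = 1,
) -> list[str]:
    """Sample a control gene set matching the targets' body-signal
    distribution by quantile binning.

    Targets are split into ``n_bins`` quantile bins of their signal; from
    each bin an equal number of candidates falling in that signal range is
    drawn without replacement (seeded).  Bins short of candidates are
    filled as far as possible with a logged deficit.
    """
    if len(candidate_genes) < len(target_genes):
        raise ValueError(
            f"{len(candidate_genes)} candidates cannot match "
            f"{len(target_genes)} targets"
        )
    rng = np.random.default_rng(seed)
    t_sig = np.array([body_signal[g] for g in target_genes], dtype=float)
    edges = np.quantile(t_sig, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    cand = sorted(candidate_genes)
    c_sig = np.array([body_signal[g] for g in cand], dtype=float)
    t_bins = np.clip(np.searchsorted(edges, t_sig, side="right") - 1, 0, n_bins - 1)
    c_bins = np.clip(np.searchsorted(edges, c_sig, side="right") - 1, 0, n_bins - 1)
    chosen: list[str] = []
    for b in range(n_bins):
        need = int(np.sum(t_bins == b))
        pool = [g for g, cb in zip(cand, c_bins) if cb == b]
        if need == 0 or not pool:
            if need:
                logger.warning("control bin %d empty: deficit %d genes", b, need)
            continue
        take = min(need, len(pool))
        if take < need:
            logger.warning("control bin %d short: deficit %d genes", b, need - take)
        chosen.extend(rng.choice(pool, size=take, replace=False).tolist())
    return chosen


def metagene(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, str, int]],
    flank: int,
) -> pd.DataFrame:
    """Mean coverage profile around stranded anchor positions.

    Each anchor (chrom, strand, pos) contributes its strand-oriented
    window [-flank, +flank] (minus-strand windows are reversed so positive
    offsets point downstream in transcription direction).  Windows that
    run past a chromosome edge are dropped and counted.  The confidence
    band is the normal-approximation 95% interval, mean +/- 1.96 x SEM.
    """
    rows = []
    dropped = 0
    for chrom, strand, pos in anchors:
        vals = track.window_values(chrom, strand, pos - flank, pos + flank + 1)
        if vals is None:
            dropped += 1
            continue
        rows.append(vals[::-1] if strand == "-" else vals)
    if dropped:
        logger.info("metagene: dropped %d anchors past chromosome edges", dropped)
    positions = np.arange(-flank, flank + 1)
    if not rows:
        return pd.DataFrame(
            {"position": positions, "mean": np.nan, "ci_low": np.nan,
             "ci_high": np.nan, "n_anchors": 0}
        )
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    if mat.shape[0] > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    else:
        sem = np.zeros_like(mean)
    return pd.DataFrame(
        {
            "position": positions,
            "mean": mean,
            "ci_low": mean - 1.96 * sem,
            "ci_high": mean + 1.96 * sem,
            "n_anchors": mat.shape[0],
        }
    )


def compare_distributions(
    values_a: Sequence[float], values_b: Sequence[float]
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison with medians reported.

    Degenerate all-tied input returns p = 1 with a warning rather than an
    error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        warnings.warn("all values tied; rank-sum p-value set to 1")
        return {
            "p_value": 1.0,
            "statistic": float("nan"),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
        }
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return {
        "p_value": float(res.pvalue),
        "statistic": float(res.statistic),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def tpm_at_pas(
    track: CoverageTrack, genes: Sequence[GeneModel], halfwidth: int
) -> pd.DataFrame:
    """Signal in the +/- halfwidth window around each gene's annotated PAS,
    TPM-normalised over the gene set; feeds the sppRNA-vs-control
    3'-end-usage comparison."""
    rows = []
    for g in genes:
        pas = g.annotated_pas
        raw = track.window_sum(g.chrom, g.strand, pas - halfwidth, pas + halfwidth)
        rows.append({"gene_id": g.gene_id, "raw_count": raw, "length": 2 * halfwidth})
    return add_tpm(pd.DataFrame(rows, columns=["gene_id", "raw_count", "length"]))
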