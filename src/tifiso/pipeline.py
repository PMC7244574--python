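"""End-to-end orchestration: cluster -> classify -> sppRNA -> nascent -> motifs.

``run_all`` wires the stages in order on already-loaded inputs and returns
a machine-readable report of per-stage counts and headline summaries.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .core import (
    CoverageTrack,
    EndPair,
    GeneModel,
    PipelineParams,
    TSSSupportSet,
)
from .io import Genome
from . import classification, clustering, motifs, nascent, spprna

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated file-path configuration for a full pipeline run."""

    pairs: Path
    genes: Path
    genome: Optional[Path] = None
    tss_support: Optional[Path] = None
    coverage_plus: Optional[Path] = None
    coverage_minus: Optional[Path] = None
    out_dir: Path = Path("tifiso_out")
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        for name in ("pairs", "genes", "genome", "tss_support",
                     "coverage_plus", "coverage_minus"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} input does not exist: {p}")


def run_all(
    pairs: Sequence[EndPair],
    genes: Sequence[GeneModel],
    genome: Optional[Genome] = None,
    tss_support: Optional[TSSSupportSet] = None,
    track: Optional[CoverageTrack] = None,
    motif_patterns: Sequence[str] = ("GAGAR", "RGCCCAW"),
    params: Optional[PipelineParams] = None,
) -> dict:
    """Run every analysis stage and assemble a JSON-serialisable report.

    Stages that lack their optional input (coverage, genome) are recorded
    as skipped rather than failing; the clustering counts always satisfy
    preclusters >= merged >= support >= mispriming >= tss-filtered.
    """
    import dataclasses

    params = params or PipelineParams()
    report: dict = {
        "params": {f.name: getattr(params, f.name) for f in dataclasses.fields(params)}
    }

    clusters, cluster_report = clustering.run_cluster_pipeline(
        pairs, genome, tss_support, params
    )
    report["clustering"] = cluster_report.as_dict()
    report["clustering"]["notes"] = cluster_report.notes

    classification.classify_clusters(clusters, genes, params.category_tolerance)
    summary = classification.category_summary(clusters)
    per_gene, mean_iso = classification.isoforms_per_gene(clusters)
    expressed = classification.expressed_genes(clusters)
    report["classification"] = {
        "n_classified": len(clusters),
        "category_proportions": summary.proportion_a.to_dict(),
        "n_expressed_genes": len(expressed),
        "mean_isoforms_per_gene": mean_iso,
        "size_distribution": classification.size_distribution(
            clusters, params.size_dist_max
        ),
    }

    calls = spprna.call_spprna(
        clusters, genes, params.spprna_max_len, params.tss_flank
    )
    if expressed:
        stats = spprna.spprna_gene_stats(calls, expressed)
        report["spprna"] = {
            "n_calls": stats["n_calls"],
            "fraction_expressed_genes_with_spprna": stats[
                "fraction_expressed_genes_with_spprna"
            ],
            "median_width": stats["median_width"],
        }
    else:
        report["spprna"] = {"skipped": "no expressed genes"}

    if track is not None:
        pi_table = nascent.pausing_index_table(track, genes, params)
        report["nascent"] = {
            "n_genes_with_pausing_index": int(len(pi_table)),
            "median_pausing_index": (
                float(pi_table.pausing_index.median()) if len(pi_table) else None
            ),
        }
    else:
        report["nascent"] = {"skipped": "no coverage track"}

    if genome is not None:
        up, down = motifs.WINDOW_PRESETS["heatmap"]
        windows = motifs.extract_windows(genome, genes, up, down)
        motif_report = {}
        for pat in motif_patterns:
            freq, density = motifs.motif_density(windows, pat)
            motif_report[pat] = {
                "mean_density_per_nt": float(density.mean()) if density.size else 0.0,
                "peak_frequency": float(freq.max()) if freq.size else 0.0,
            }
        report["motifs"] = motif_report
    else:
        report["motifs"] = {"skipped": "no genome"}

    report["counts_consistent"] = (
        report["clustering"]["preclusters"]
        >= report["clustering"]["merged_clusters"]
        >= report["clustering"]["after_support_filter"]
        >= report["clustering"]["after_mispriming_filter"]
        >= report["clustering"]["after_tss_support_filter"]
    )
    report["_clusters"] = clusters
    report["_spprna_calls"] = calls
    return report
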