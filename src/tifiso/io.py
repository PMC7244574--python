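"""Readers and writers for the external formats the pipeline consumes.

Internal convention is 0-based half-open throughout; GFF3 (1-based
inclusive) is converted at this boundary by pyranges.  BED/BEDPE/bedGraph
are consumed and emitted 0-based half-open.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .core import (
    CoverageTrack,
    EndPair,
    GeneModel,
    GenomicInterval,
    TIFCluster,
    TSSSupportSet,
    IsoformCategory,
)

logger = logging.getLogger(__name__)

CLUSTER_TSV_COLUMNS = ["chrom", "strand", "tss", "pas", "width", "support"]


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation input."""


# ---------------------------------------------------------------------------
# genome sequence


class Genome:
    """Genome sequence with clipped or N-padded window access.

    Wraps either an in-memory dict of sequences or an indexed FASTA
    (pyfaidx) so callers never care which backing store is used.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path))
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @property
    def chromosomes(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence over [start, end), clipped to the
        chromosome (windows past an edge are truncated, not an error)."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._seqs[chrom]
        return seq[max(start, 0) : min(end, len(seq))]

    def fetch_padded(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence over [start, end) with N-padding where the
        window extends past a chromosome edge."""
        if chrom not in self._seqs:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        seq = self._seqs[chrom]
        left = "N" * max(0, -start)
        right = "N" * max(0, end - len(seq))
        return left + seq[max(start, 0) : min(end, len(seq))] + right


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# gene annotation


def _validate_tsv_lines(path: Path, min_fields: int, fmt: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise AnnotationError(
                    f"{fmt} parse error at line {lineno} of {path}: expected at "
                    f"least {min_fields} tab-separated fields, got {len(fields)}"
                )


def flag_overlapping_genes(genes: Sequence[GeneModel]) -> None:
    """Set overlaps_other_gene (either-strand intersection) in place via a
    sweep over start-sorted intervals."""
    for g in genes:
        g.overlaps_other_gene = False
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for group in by_chrom.values():
        group.sort(key=lambda g: g.interval.start)
        max_end = -1
        max_holder: Optional[GeneModel] = None
        for g in group:
            if max_holder is not None and g.interval.start < max_end:
                g.overlaps_other_gene = True
                max_holder.overlaps_other_gene = True
            if g.interval.end > max_end:
                max_end = g.interval.end
                max_holder = g


def read_gene_annotation(path: str | Path) -> list[GeneModel]:
    """Read gene-level models from GFF3 (``gene`` features) or BED6.

    overlaps_other_gene is set for every gene whose interval intersects any
    other gene's interval on either strand.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3", ".gtf"}:
        genes = _read_genes_gff3(path)
    elif suffix == ".bed":
        genes = _read_genes_bed(path)
    else:
        raise AnnotationError(f"unrecognised annotation format: {path}")
    if not genes:
        raise AnnotationError(f"no genes found in {path}")
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.interval.end))
    flag_overlapping_genes(genes)
    return genes


def _read_genes_gff3(path: Path) -> list[GeneModel]:
    _validate_tsv_lines(path, 9, "GFF3")
    df = pr.read_gff3(str(path)).df
    if df.empty or "Feature" not in df.columns:
        return []
    gene_rows = df[df.Feature == "gene"]
    cds_by_parent: dict[str, tuple[int, int]] = {}
    if "Parent" in df.columns:
        cds_rows = df[df.Feature == "CDS"]
        for parent, sub in cds_rows.groupby("Parent"):
            cds_by_parent[str(parent)] = (int(sub.Start.min()), int(sub.End.max()))
    genes = []
    for _, row in gene_rows.iterrows():
        gene_id = str(row.get("ID", "") or f"gene_{len(genes)}")
        interval = GenomicInterval(
            str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand)
        )
        cds = None
        if gene_id in cds_by_parent:
            s, e = cds_by_parent[gene_id]
            cds = GenomicInterval(interval.chrom, s, e, interval.strand)
        genes.append(GeneModel(gene_id=gene_id, interval=interval, cds=cds))
    return genes


def _read_genes_bed(path: Path) -> list[GeneModel]:
    _validate_tsv_lines(path, 6, "BED")
    df = pr.read_bed(str(path)).df
    genes = []
    for i, row in df.iterrows():
        name = str(row.get("Name", "") or f"gene_{i}")
        interval = GenomicInterval(
            str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand)
        )
        genes.append(GeneModel(gene_id=name, interval=interval))
    return genes


# ---------------------------------------------------------------------------
# end pairs


def read_end_pairs(path: str | Path) -> tuple[list[EndPair], dict[str, int]]:
    """Read paired transcript ends from BEDPE (or a name-sorted paired BAM).

    BEDPE convention: mate1 block covers the 5' end, mate2 block the 3'
    end, strand1 is the transcript strand.  Cross-chromosome pairs are
    dropped and counted; unpaired records ('.') are skipped with a warning.

    Returns the pairs together with a stats dict
    {'read': n, 'cross_chromosome': n, 'skipped_unpaired': n}.
    """
    path = Path(path)
    if path.suffix.lower() == ".bam":
        return _read_end_pairs_bam(path)
    pairs: list[EndPair] = []
    stats = {"read": 0, "cross_chromosome": 0, "skipped_unpaired": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise AnnotationError(
                    f"BEDPE parse error at line {lineno} of {path}: need 10 fields"
                )
            chrom1, start1, end1, chrom2, start2, end2 = f[0], f[1], f[2], f[3], f[4], f[5]
            strand1, strand2 = f[8], f[9]
            if chrom1 == "." or chrom2 == ".":
                stats["skipped_unpaired"] += 1
                continue
            if strand1 not in ("+", "-"):
                raise AnnotationError(
                    f"invalid strand {strand1!r} at line {lineno} of {path}"
                )
            if chrom1 != chrom2:
                stats["cross_chromosome"] += 1
                continue
            s1, e1, s2, e2 = int(start1), int(end1), int(start2), int(end2)
            if strand1 == "+":
                five_prime, three_prime = s1, e2 - 1
            else:
                five_prime, three_prime = e1 - 1, s2
            pairs.append(EndPair(chrom1, strand1, five_prime, three_prime))
            stats["read"] += 1
    if stats["cross_chromosome"]:
        logger.info("dropped %d cross-chromosome pairs", stats["cross_chromosome"])
    if stats["skipped_unpaired"]:
        logger.warning("skipped %d unpaired records", stats["skipped_unpaired"])
    return pairs, stats


def _read_end_pairs_bam(path: Path) -> tuple[list[EndPair], dict[str, int]]:
    import pysam

    pairs: list[EndPair] = []
    stats = {"read": 0, "cross_chromosome": 0, "skipped_unpaired": 0}
    pending: dict[str, "pysam.AlignedSegment"] = {}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            r1, r2 = (rec, mate) if rec.is_read1 else (mate, rec)
            if r1.reference_name != r2.reference_name:
                stats["cross_chromosome"] += 1
                continue
            strand = "-" if r1.is_reverse else "+"
            if strand == "+":
                five_prime, three_prime = r1.reference_start, r2.reference_end - 1
            else:
                five_prime, three_prime = r1.reference_end - 1, r2.reference_start
            pairs.append(EndPair(r1.reference_name, strand, five_prime, three_prime))
            stats["read"] += 1
    stats["skipped_unpaired"] = len(pending)
    if pending:
        logger.warning("skipped %d unpaired BAM records", len(pending))
    return pairs, stats


def write_bedpe(pairs: Iterable[EndPair], path: str | Path) -> None:
    """Write end-pairs in the BEDPE convention read_end_pairs expects
    (mate1 = 1-nt 5' block, mate2 = 1-nt 3' block)."""
    with open(path, "w") as fh:
        for i, p in enumerate(pairs):
            fp, tp = p.five_prime, p.three_prime
            fh.write(
                f"{p.chrom}\t{fp}\t{fp + 1}\t{p.chrom}\t{tp}\t{tp + 1}\t"
                f"pair_{i}\t0\t{p.strand}\t{'-' if p.strand == '+' else '+'}\n"
            )


# ---------------------------------------------------------------------------
# TSS support and coverage


def read_tss_support(path: str | Path) -> TSSSupportSet:
    """Read TSS-seq support intervals from BED6."""
    path = Path(path)
    _validate_tsv_lines(path, 6, "BED")
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]))
    return TSSSupportSet(intervals)


def write_bed6(
    intervals: Iterable[tuple[str, int, int, str, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


def read_coverage(path: str | Path, strand: str) -> CoverageTrack:
    """Expand a 4-column bedGraph into a per-base CoverageTrack on ``strand``.

    Negative values and overlapping intervals (ambiguous signal) are errors;
    an empty file yields an empty track with total_signal 0.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"invalid strand {strand!r}")
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        return CoverageTrack()
    if df.empty:
        return CoverageTrack()
    if (df.value < 0).any():
        raise ValueError(f"negative coverage value in {path}")
    track = CoverageTrack()
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub.start.values[1:] < sub.end.values[:-1]).any():
            raise ValueError(f"overlapping bedGraph intervals on {chrom} in {path}")
        arr = np.zeros(int(sub.end.max()), dtype=float)
        for s, e, v in zip(sub.start.values, sub.end.values, sub.value.values):
            arr[s:e] = v
        track.set(str(chrom), strand, arr)
    return track


def read_stranded_coverage(plus_path: str | Path, minus_path: str | Path) -> CoverageTrack:
    """Combine per-strand bedGraph files into one stranded track."""
    track = CoverageTrack()
    for path, strand in ((plus_path, "+"), (minus_path, "-")):
        part = read_coverage(path, strand)
        for (chrom, s), arr in part.arrays.items():
            track.set(chrom, s, arr)
    return track


def write_bedgraph(track: CoverageTrack, strand: str, path: str | Path) -> None:
    """Write one strand of a track as run-length-compressed bedGraph."""
    with open(path, "w") as fh:
        for (chrom, s), arr in sorted(track.arrays.items()):
            if s != strand:
                continue
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for a, b in zip(starts, ends):
                v = arr[a]
                if v != 0:
                    fh.write(f"{chrom}\t{a}\t{b}\t{v:g}\n")


# ---------------------------------------------------------------------------
# clusters


def clusters_to_frame(clusters: Sequence[TIFCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        rows.append(
            {
                "chrom": c.chrom,
                "strand": c.strand,
                "tss": c.tss,
                "pas": c.pas,
                "width": c.width,
                "support": c.support,
                "gene_id": c.gene_id if c.gene_id is not None else ".",
                "category": c.category.value if c.category is not None else ".",
            }
        )
    return pd.DataFrame(
        rows, columns=CLUSTER_TSV_COLUMNS + ["gene_id", "category"]
    )


def write_clusters_tsv(clusters: Sequence[TIFCluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def read_clusters_tsv(path: str | Path) -> list[TIFCluster]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    clusters = []
    for _, row in df.iterrows():
        c = TIFCluster(
            chrom=str(row.chrom),
            strand=str(row.strand),
            tss=int(row.tss),
            pas=int(row.pas),
            support=int(row.support),
        )
        if "gene_id" in df.columns and str(row.gene_id) != ".":
            c.gene_id = str(row.gene_id)
        if "category" in df.columns and str(row.category) != ".":
            c.category = IsoformCategory(str(row.category))
        clusters.append(c)
    return clusters


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene (and optional CDS) features; converts to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\ttifiso\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            if g.cds is not None:
                fh.write(
                    f"{iv.chrom}\ttifiso\tCDS\t{g.cds.start + 1}\t{g.cds.end}\t.\t"
                    f"{iv.strand}\t0\tParent={g.gene_id}\n"
                )
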