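"""Core genomic value types shared by every stage of the pipeline.

All coordinates are 0-based; intervals are half-open ``[start, end)``.
Single-base features (a TSS, a PAS, a transcript end) are stored as the
0-based position of that base.  GFF3 input is converted to this convention
at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import numpy as np

STRANDS = ("+", "-")

# IUPAC degenerate nucleotide alphabet
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A stranded half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True, slots=True)
class EndPair:
    """Observed cap end and poly(A)-junction position of one RNA molecule.

    ``five_prime`` is the capped 5' base; ``three_prime`` the last templated
    base before the poly(A) tail.  On the minus strand the 5' end has the
    larger genomic coordinate.
    """

    chrom: str
    strand: str
    five_prime: int
    three_prime: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.strand == "+" and self.five_prime > self.three_prime:
            raise ValueError("plus-strand pair must have five_prime <= three_prime")
        if self.strand == "-" and self.three_prime > self.five_prime:
            raise ValueError("minus-strand pair must have three_prime <= five_prime")


@dataclass(slots=True)
class GeneModel:
    """An annotated gene reduced to its outermost interval.

    ``annotated_tss`` / ``annotated_pas`` are the strand-aware 5' and 3'
    boundary bases of the gene.  ``overlaps_other_gene`` flags genes whose
    interval intersects any other gene on either strand; such genes are
    excluded from cluster-to-gene assignment.
    """

    gene_id: str
    interval: GenomicInterval
    cds: Optional[GenomicInterval] = None
    overlaps_other_gene: bool = False

    def __post_init__(self) -> None:
        if self.cds is not None:
            if not (
                self.cds.chrom == self.interval.chrom
                and self.interval.start <= self.cds.start
                and self.cds.end <= self.interval.end
            ):
                raise ValueError(f"CDS of {self.gene_id} outside gene interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def annotated_tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def annotated_pas(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return self.interval.length


class TSSSupportSet:
    """Stranded intervals with independent TSS-seq support.

    Backed by per-(chrom, strand) sorted arrays so containment queries do
    not depend on input order.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals = list(intervals)
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for iv in self.intervals:
            grouped.setdefault((iv.chrom, iv.strand), []).append((iv.start, iv.end))
        for key, pairs in grouped.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self._index[key] = (starts, ends)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, strand: str, pos: int, flank: int = 0) -> bool:
        """True if ``pos`` falls inside some same-strand interval extended by
        ``flank`` on each side (extension makes the check boundary-inclusive)."""
        key = (chrom, strand)
        if key not in self._index:
            return False
        starts, ends = self._index[key]
        # candidate intervals are those starting at or before pos + flank
        i = int(np.searchsorted(starts, pos + flank, side="right"))
        if i == 0:
            return False
        # intervals are not guaranteed non-overlapping: check running max of ends
        return bool(np.any(ends[:i] + flank > pos))


class CoverageTrack:
    """Per-base stranded coverage over a genome.

    Values are stored as one float vector per (chrom, strand); positions past
    the stored vector are zero.  ``total_signal`` is the library size used
    for normalisation.
    """

    def __init__(self, arrays: dict[tuple[str, str], np.ndarray] | None = None):
        self.arrays: dict[tuple[str, str], np.ndarray] = {}
        if arrays:
            for key, arr in arrays.items():
                self.set(key[0], key[1], arr)

    def set(self, chrom: str, strand: str, values: np.ndarray) -> None:
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("coverage vector must be one-dimensional")
        if np.any(arr < 0):
            raise ValueError("coverage values must be nonnegative")
        self.arrays[(chrom, strand)] = arr

    @property
    def total_signal(self) -> float:
        return float(sum(arr.sum() for arr in self.arrays.values()))

    def window_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Sum of per-base signal over half-open [start, end), clipped to the
        stored vector (absent positions contribute zero)."""
        arr = self.arrays.get((chrom, strand))
        if arr is None or end <= 0 or start >= arr.size:
            return 0.0
        return float(arr[max(start, 0) : min(end, arr.size)].sum())

    def window_values(
        self, chrom: str, strand: str, start: int, end: int
    ) -> Optional[np.ndarray]:
        """Per-base values over [start, end), or None if the window extends
        past the stored vector on either side."""
        arr = self.arrays.get((chrom, strand))
        if arr is None or start < 0 or end > arr.size:
            return None
        return arr[start:end]


class IsoformCategory(str, Enum):
    """The eight mutually exclusive TIF-cluster classes."""

    FULL_SPAN = "full_span"
    INTERNAL_INITIATION = "internal_initiation"
    INTERNAL_TERMINATION = "internal_termination"
    INTERNAL_BOTH = "internal_both"
    FIVE_PRIME_EXTENDED = "five_prime_extended"
    THREE_PRIME_EXTENDED = "three_prime_extended"
    ANTISENSE = "antisense"
    INTERGENIC = "intergenic"


@dataclass(slots=True)
class TIFCluster:
    """A merged TSS/PAS pair supported by one or more read pairs.

    ``tss`` and ``pas`` are the representative end positions (the
    read-support mode of each end); ``members`` records the contributing
    (five_prime, three_prime, count) triples of the merged pre-clusters.
    """

    chrom: str
    strand: str
    tss: int
    pas: int
    support: int
    members: list[tuple[int, int, int]] = field(default_factory=list)
    category: Optional[IsoformCategory] = None
    gene_id: Optional[str] = None
    antisense_gene: bool = False

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("cluster support must be >= 1")
        if self.strand == "+" and self.tss > self.pas:
            raise ValueError("plus-strand cluster must have tss <= pas")
        if self.strand == "-" and self.pas > self.tss:
            raise ValueError("minus-strand cluster must have pas <= tss")

    @property
    def width(self) -> int:
        return abs(self.pas - self.tss) + 1

    @property
    def start(self) -> int:
        return min(self.tss, self.pas)

    @property
    def end(self) -> int:
        return max(self.tss, self.pas) + 1

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(slots=True)
class MotifPattern:
    """An IUPAC degenerate nucleotide pattern such as GAGAR or RGCCCAW."""

    pattern: str

    def __post_init__(self) -> None:
        self.pattern = self.pattern.upper()
        bad = [c for c in self.pattern if c not in IUPAC_CODES]
        if bad or not self.pattern:
            raise ValueError(f"invalid IUPAC pattern {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def sets(self) -> list[frozenset[str]]:
        return [IUPAC_CODES[c] for c in self.pattern]

    def reverse_complement(self) -> "MotifPattern":
        comp = {
            "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
            "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
            "D": "H", "H": "D", "N": "N",
        }
        return MotifPattern("".join(comp[c] for c in reversed(self.pattern)))


@dataclass(slots=True)
class PipelineParams:
    """All numeric knobs of the analysis, with their published defaults.

    merge_window
        two pre-clusters merge when both end distances are strictly below
        this many nucleotides (default 20).
    min_support
        minimum read pairs for a final cluster (default 3).
    polya_min_run / polya_scan_flank
        a cluster is a mispriming artifact when the sense-strand genome
        within +/- flank of its PAS carries a run of at least this many A's
        (defaults 6 and 10).
    spprna_max_len
        strict upper bound on sppRNA cluster width in nt (default 350).
    tss_flank
        sppRNA cluster TSS must fall within this many nt of an annotated
        TSS (default 40).
    genebody_shrink
        nt trimmed off each gene end for gene-body signal (default 200).
    pi_promoter_halfwidth / pi_body_shrink
        pausing-index promoter half-window (150) and gene-body shrink (300).
    pi_min_gene_len / pi_expr_fraction
        pausing-index eligibility: genes longer than 1000 nt within the top
        75% by expression.
    size_dist_max
        width cut for size-distribution summaries (default 6000, strict).
    tss_support_flank
        slack around TSS-seq support intervals (default 10).
    category_tolerance
        boundary tolerance in nt separating full-span from internal or
        extended categories (default 100).
    """

    merge_window: int = 20
    min_support: int = 3
    polya_min_run: int = 6
    polya_scan_flank: int = 10
    spprna_max_len: int = 350
    tss_flank: int = 40
    genebody_shrink: int = 200
    pi_promoter_halfwidth: int = 150
    pi_body_shrink: int = 300
    pi_min_gene_len: int = 1000
    pi_expr_fraction: float = 0.75
    size_dist_max: int = 6000
    tss_support_flank: int = 10
    category_tolerance: int = 100
    random_seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "merge_window", "min_support", "polya_min_run", "polya_scan_flank",
            "spprna_max_len", "tss_flank", "genebody_shrink",
            "pi_promoter_halfwidth", "pi_body_shrink", "pi_min_gene_len",
            "size_dist_max", "tss_support_flank", "category_tolerance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.pi_expr_fraction <= 1):
            raise ValueError("pi_expr_fraction must be in (0, 1]")
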