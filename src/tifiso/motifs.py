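"""TSS-anchored promoter windows and IUPAC motif scanning.

Windows are strand-oriented (upstream is always 5' of the anchor; minus-
strand windows are reverse-complemented on extraction).  Scanning tests
each offset against the IUPAC character classes of the pattern; N in the
sequence matches nothing, overlapping matches are all reported, and only
the given strand is scanned -- callers pair a pattern with its reverse
complement explicitly (e.g. HTGGGCY with RGCCCAW).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .core import GeneModel, MotifPattern
from .io import Genome, reverse_complement

#: named (upstream, downstream) presets: "heatmap" for the -200/+150
#: TSS-centred display window; "discovery_promoter" (-300/+50) and
#: "discovery_downstream" (-20/+250) for motif-search regions.
WINDOW_PRESETS: dict[str, tuple[int, int]] = {
    "heatmap": (200, 150),
    "discovery_promoter": (300, 50),
    "discovery_downstream": (20, 250),
}


@dataclass(slots=True)
class PromoterWindow:
    gene_id: str
    sequence: str
    anchor_offset: int


def extract_windows(
    genome: Genome,
    genes: Sequence[GeneModel],
    upstream: int,
    downstream: int,
    anchors: Optional[Mapping[str, int]] = None,
) -> list[PromoterWindow]:
    """Extract strand-oriented windows [anchor - upstream, anchor + downstream).

    The anchor defaults to the annotated TSS; a measured per-gene anchor
    (e.g. the dominant TSS-seq position) can be supplied instead.  Windows
    running past a chromosome edge are N-padded; a gene on a chromosome
    missing from the genome is an error naming the chromosome.
    """
    windows = []
    for g in genes:
        if g.chrom not in genome:
            raise KeyError(f"chromosome {g.chrom!r} missing from genome")
        anchor = anchors.get(g.gene_id, g.annotated_tss) if anchors else g.annotated_tss
        if g.strand == "+":
            seq = genome.fetch_padded(g.chrom, anchor - upstream, anchor + downstream)
        else:
            seq = reverse_complement(
                genome.fetch_padded(g.chrom, anchor - downstream + 1, anchor + upstream + 1)
            )
        windows.append(PromoterWindow(g.gene_id, seq, upstream))
    return windows


def scan_motif(
    window: Union[str, PromoterWindow], pattern: Union[str, MotifPattern]
) -> list[int]:
    """All start offsets where the pattern's IUPAC classes match the
    sequence.  Overlapping matches are reported; N never matches."""
    seq = window.sequence if isinstance(window, PromoterWindow) else window
    if not isinstance(pattern, MotifPattern):
        pattern = MotifPattern(pattern)
    sets = pattern.sets()
    k = len(sets)
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            hits.append(i)
    return hits


def match_matrix(
    windows: Sequence[PromoterWindow], pattern: Union[str, MotifPattern]
) -> np.ndarray:
    """(n_windows, window_length) 0/1 match-start indicator matrix (the
    heatmap input).  Mixed window lengths are an error."""
    if not windows:
        return np.zeros((0, 0), dtype=np.int8)
    lengths = {len(w.sequence) for w in windows}
    if len(lengths) != 1:
        raise ValueError("windows have mixed lengths")
    mat = np.zeros((len(windows), lengths.pop()), dtype=np.int8)
    for i, w in enumerate(windows):
        for j in scan_motif(w, pattern):
            mat[i, j] = 1
    return mat


def motif_density(
    windows: Sequence[PromoterWindow], pattern: Union[str, MotifPattern]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position match-start frequency across windows, and per-window
    density (matches per nt).

    frequency[i] is the fraction of windows with a match starting at offset
    i; the two outputs feed the positional heatmap and the set-level
    rank-sum density comparison respectively.
    """
    mat = match_matrix(windows, pattern)
    if mat.size == 0:
        return np.zeros(0), np.zeros(0)
    return mat.mean(axis=0), mat.sum(axis=1) / mat.shape[1]
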