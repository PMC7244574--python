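"""Ground-truth simulator for end-pair clustering and downstream analyses.

Generates a toy genome of alternating-strand, non-overlapping genes with
planted oligo(dT)-mispriming A-tracts, per-gene transcript isoform sets
(zero-truncated-Poisson counts, dispersed TSS/PAS ends), an sppRNA
subpopulation with a lognormal length model, antisense and intergenic
transcripts, observed end-pairs with per-end jitter and mispriming
artifacts, TSS-seq support intervals, and promoter-peaked nascent
coverage.  Every emitted molecule maps to exactly one truth record, so
recovery by the pipeline can be scored exactly.

Defaults mirror the study conditions the pipeline targets: a mean of 4.3
isoforms per gene, ~14% of genes producing sppRNAs with a median length
of 93 nt, per-end dispersion of 5 nt, and a 5% mispriming rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import CoverageTrack, EndPair, GeneModel, GenomicInterval, TIFCluster, TSSSupportSet
from .io import (
    Genome,
    write_bed6,
    write_bedgraph,
    write_bedpe,
    write_fasta,
    write_gff3,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(slots=True)
class Isoform:
    """One true transcript species with its emission weight."""

    chrom: str
    strand: str
    tss: int
    pas: int
    weight: float
    gene_id: Optional[str]
    kind: str  # canonical | variant | spprna | antisense | intergenic


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    genes: list[GeneModel]
    a_tracts: list[tuple[str, int, int, str]]  # chrom, start, length, sense strand
    seed: int

    @property
    def genome(self) -> Genome:
        return Genome(self.sequences)


@dataclass
class SyntheticTruth:
    genes: list[GeneModel]
    isoforms: list[Isoform]
    spprna_genes: set[str]
    molecules: pd.DataFrame  # columns: isoform, misprimed
    params: dict = field(default_factory=dict)

    def isoform_table(self, min_support: int = 1) -> pd.DataFrame:
        """Per-isoform molecule bookkeeping: total emitted and clean
        (non-misprimed) molecule counts."""
        n = len(self.isoforms)
        total = np.bincount(self.molecules.isoform.values, minlength=n)
        clean = np.bincount(
            self.molecules.isoform.values[~self.molecules.misprimed.values],
            minlength=n,
        )
        df = pd.DataFrame(
            {
                "chrom": [i.chrom for i in self.isoforms],
                "strand": [i.strand for i in self.isoforms],
                "tss": [i.tss for i in self.isoforms],
                "pas": [i.pas for i in self.isoforms],
                "gene_id": [i.gene_id for i in self.isoforms],
                "kind": [i.kind for i in self.isoforms],
                "n_molecules": total,
                "n_clean": clean,
            }
        )
        return df[df.n_molecules >= min_support].reset_index(drop=True)


def ztp_rate_for_mean(mean: float) -> float:
    """Rate of the zero-truncated Poisson whose mean is ``mean``."""
    if mean <= 1:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    return float(brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, 100.0))


def sample_ztp(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson sample by redrawing zeros."""
    out = rng.poisson(lam, size=size)
    while True:
        zeros = out == 0
        if not zeros.any():
            return out
        out[zeros] = rng.poisson(lam, size=int(zeros.sum()))


def simulate_genome(
    n_genes: int = 2000,
    gene_len_range: tuple[int, int] = (1000, 3000),
    intergenic_len_range: tuple[int, int] = (300, 800),
    a_tract_rate: float = 0.2,
    seed: int = 1,
    chrom: str = "chr1",
) -> SyntheticGenome:
    """Random genome of alternating-strand genes separated by intergenic
    gaps, with A-tracts of length 6-9 planted at ``a_tract_rate`` tracts
    per kilobase (recorded with their sense strand: a minus-strand tract
    is written as a T-run on the forward reference)."""
    if gene_len_range[0] <= 0 or intergenic_len_range[0] <= 0:
        raise ValueError("length ranges must be positive")
    rng = np.random.default_rng(seed)
    gene_lens = rng.integers(gene_len_range[0], gene_len_range[1] + 1, size=n_genes)
    gap_lens = rng.integers(
        intergenic_len_range[0], intergenic_len_range[1] + 1, size=n_genes + 1
    )
    total = int(gap_lens.sum() + gene_lens.sum())
    seq = BASES[rng.integers(0, 4, size=total)].copy()
    genes: list[GeneModel] = []
    pos = int(gap_lens[0])
    for i in range(n_genes):
        start, end = pos, pos + int(gene_lens[i])
        strand = "+" if i % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_id=f"g{i:05d}",
                interval=GenomicInterval(chrom, start, end, strand),
            )
        )
        pos = end + int(gap_lens[i + 1])
    a_tracts: list[tuple[str, int, int, str]] = []
    n_tracts = int(rng.poisson(a_tract_rate * total / 1000.0))
    if n_tracts:
        starts = np.sort(rng.integers(0, max(total - 10, 1), size=n_tracts))
        lengths = rng.integers(6, 10, size=n_tracts)
        strands = rng.choice(["+", "-"], size=n_tracts)
        for s, ln, st in zip(starts, lengths, strands):
            base = ord("A") if st == "+" else ord("T")
            seq[int(s) : int(s) + int(ln)] = base
            a_tracts.append((chrom, int(s), int(ln), str(st)))
    return SyntheticGenome(
        sequences={chrom: seq.tobytes().decode("ascii")},
        genes=genes,
        a_tracts=a_tracts,
        seed=seed,
    )


def _interior_offsets(gene_len: int, margin: int = 150, step: int = 100) -> list[int]:
    """Candidate interior end offsets, kept >= margin from each boundary and
    spaced so distinct isoforms never fall within the merge window."""
    hi = gene_len - 3 * margin
    return list(range(margin, max(hi, margin), step))


def build_isoforms(
    sim: SyntheticGenome,
    rng: np.random.Generator,
    mean_isoforms: float = 4.3,
    spprna_gene_fraction: float = 0.14,
    spprna_length_median: float = 93.0,
    spprna_length_sigma: float = 0.5,
    spprna_weight: float = 0.25,
    spprna_tss_jitter: int = 20,
    antisense_gene_fraction: float = 0.10,
    intergenic_gene_fraction: float = 0.05,
) -> tuple[list[Isoform], set[str]]:
    """Draw the true isoform set per gene.

    Each gene gets a zero-truncated-Poisson number of isoforms (the first
    always the canonical full-span one); interior alternative ends sit on
    a 100-nt grid at least 150 nt inside the gene.  sppRNA genes receive
    an extra short isoform starting within +/- ``spprna_tss_jitter`` nt of
    the gene TSS with a lognormal length (median ``spprna_length_median``)
    truncated to [20, 349] nt and a fixed ``spprna_weight`` share of the
    gene's molecules.
    """
    if not (0 <= spprna_gene_fraction <= 1):
        raise ValueError("spprna_gene_fraction must be in [0, 1]")
    lam = ztp_rate_for_mean(mean_isoforms)
    isoforms: list[Isoform] = []
    spprna_genes: set[str] = set()
    n = len(sim.genes)
    counts = sample_ztp(rng, lam, n)
    spprna_flags = rng.random(n) < spprna_gene_fraction
    antisense_flags = rng.random(n) < antisense_gene_fraction
    intergenic_flags = rng.random(n) < intergenic_gene_fraction
    sigma_ln = spprna_length_sigma
    mu_ln = np.log(spprna_length_median)
    for gi, gene in enumerate(sim.genes):
        L = gene.length
        sign = 1 if gene.strand == "+" else -1
        tss0, pas0 = gene.annotated_tss, gene.annotated_pas
        combos: list[tuple[int, int]] = [(0, 0)]
        tss_opts = [0] + _interior_offsets(L)
        pas_opts = [0] + _interior_offsets(L)
        k_target = int(counts[gi])
        attempts = 0
        while len(combos) < k_target and attempts < 50 * k_target:
            attempts += 1
            t_off = 0 if rng.random() < 0.45 else int(rng.choice(tss_opts[1:] or [0]))
            p_off = 0 if rng.random() < 0.45 else int(rng.choice(pas_opts[1:] or [0]))
            if t_off + p_off > L - 200:
                continue
            if (t_off, p_off) not in combos:
                combos.append((t_off, p_off))
        k = len(combos)
        # mixture of a uniform floor and a Dirichlet draw keeps every
        # isoform at a detectable share while still heterogeneous
        weights = 0.5 / k + 0.5 * rng.dirichlet(np.ones(k))
        gene_iso: list[Isoform] = []
        for (t_off, p_off), w in zip(combos, weights):
            gene_iso.append(
                Isoform(
                    chrom=gene.chrom,
                    strand=gene.strand,
                    tss=tss0 + sign * t_off,
                    pas=pas0 - sign * p_off,
                    weight=float(w),
                    gene_id=gene.gene_id,
                    kind="canonical" if (t_off, p_off) == (0, 0) else "variant",
                )
            )
        if spprna_flags[gi]:
            spprna_genes.add(gene.gene_id)
            width = int(
                np.clip(np.round(np.exp(rng.normal(mu_ln, sigma_ln))), 20, 349)
            )
            s_tss = tss0 + sign * int(
                rng.integers(-spprna_tss_jitter, spprna_tss_jitter + 1)
            )
            for iso in gene_iso:
                iso.weight *= 1.0 - spprna_weight
            gene_iso.append(
                Isoform(
                    chrom=gene.chrom,
                    strand=gene.strand,
                    tss=s_tss,
                    pas=s_tss + sign * (width - 1),
                    weight=spprna_weight,
                    gene_id=gene.gene_id,
                    kind="spprna",
                )
            )
        if antisense_flags[gi] and L >= 600:
            anti_strand = "-" if gene.strand == "+" else "+"
            a_sign = -sign
            a_tss = pas0 - sign * int(rng.integers(50, 150))
            a_len = int(rng.integers(300, max(L - 300, 301)))
            for iso in gene_iso:
                iso.weight *= 1.0 - 0.1
            gene_iso.append(
                Isoform(
                    chrom=gene.chrom,
                    strand=anti_strand,
                    tss=a_tss,
                    pas=a_tss + a_sign * (a_len - 1),
                    weight=0.1,
                    gene_id=gene.gene_id,
                    kind="antisense",
                )
            )
        isoforms.extend(gene_iso)
        if intergenic_flags[gi] and gi + 1 < n:
            gap_start = gene.interval.end
            gap_end = sim.genes[gi + 1].interval.start
            gap = gap_end - gap_start
            if gap >= 250:
                i_len = int(rng.integers(150, min(gap - 50, 400)))
                i_start = gap_start + int(rng.integers(0, gap - i_len))
                i_strand = str(rng.choice(["+", "-"]))
                if i_strand == "+":
                    i_tss, i_pas = i_start, i_start + i_len - 1
                else:
                    i_tss, i_pas = i_start + i_len - 1, i_start
                isoforms.append(
                    Isoform(
                        chrom=gene.chrom,
                        strand=i_strand,
                        tss=i_tss,
                        pas=i_pas,
                        weight=0.05,
                        gene_id=None,
                        kind="intergenic",
                    )
                )
    return isoforms, spprna_genes


def simulate_end_pairs(
    sim: SyntheticGenome,
    mean_isoforms: float = 4.3,
    tss_dispersion: float = 5.0,
    pas_dispersion: float = 5.0,
    spprna_gene_fraction: float = 0.14,
    spprna_length_median: float = 93.0,
    spprna_length_sigma: float = 0.5,
    depth: int = 200_000,
    mispriming_rate: float = 0.05,
    antisense_gene_fraction: float = 0.10,
    intergenic_gene_fraction: float = 0.05,
    gene_expression_sigma: float = 0.5,
    seed: int = 1,
) -> tuple[list[EndPair], SyntheticTruth]:
    """Emit ``depth`` observed end-pairs with molecule-level truth.

    Genes receive lognormal expression weights; molecules are multinomial
    over (gene x isoform) weights.  Each end is jittered by rounded
    zero-mean normal noise (sd = dispersion, clipped at 3 sd).  Misprimed
    molecules keep their 5' end but terminate beside the nearest planted
    same-sense A-tract downstream; molecules with no reachable tract stay
    clean.  The number of emitted pairs always equals ``depth``.
    """
    if not (0 <= spprna_gene_fraction <= 1):
        raise ValueError("spprna_gene_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    isoforms, spprna_genes = build_isoforms(
        sim,
        rng,
        mean_isoforms=mean_isoforms,
        spprna_gene_fraction=spprna_gene_fraction,
        spprna_length_median=spprna_length_median,
        spprna_length_sigma=spprna_length_sigma,
        antisense_gene_fraction=antisense_gene_fraction,
        intergenic_gene_fraction=intergenic_gene_fraction,
    )
    if not isoforms:
        empty = pd.DataFrame({"isoform": [], "misprimed": []})
        return [], SyntheticTruth(sim.genes, [], set(), empty)
    # global emission weights: gene expression x within-gene isoform share
    gene_expr = {
        g.gene_id: w
        for g, w in zip(
            sim.genes,
            rng.lognormal(0.0, gene_expression_sigma, size=len(sim.genes)),
        )
    }
    glob = np.array(
        [iso.weight * (gene_expr[iso.gene_id] if iso.gene_id else 1.0) for iso in isoforms]
    )
    glob /= glob.sum()
    counts = rng.multinomial(depth, glob)
    iso_idx = np.repeat(np.arange(len(isoforms)), counts)
    tss = np.array([i.tss for i in isoforms])[iso_idx]
    pas = np.array([i.pas for i in isoforms])[iso_idx]
    strands = np.array([i.strand for i in isoforms])[iso_idx]
    chroms = np.array([i.chrom for i in isoforms])[iso_idx]

    def jitter(positions: np.ndarray, sd: float) -> np.ndarray:
        if sd <= 0:
            return positions
        noise = np.clip(np.round(rng.normal(0, sd, size=positions.size)), -3 * sd, 3 * sd)
        return positions + noise.astype(np.int64)

    tss_obs = jitter(tss, tss_dispersion)
    pas_obs = jitter(pas, pas_dispersion)
    # mispriming relocates the 3' end beside a planted same-sense tract
    mis = rng.random(iso_idx.size) < mispriming_rate
    tract_targets: dict[tuple[str, str], np.ndarray] = {}
    for chrom, start, length, strand in sim.a_tracts:
        key = (chrom, strand)
        target = start - 1 if strand == "+" else start + length
        tract_targets.setdefault(key, []).append(target)  # type: ignore[arg-type]
    tract_targets = {
        k: np.sort(np.array(v, dtype=np.int64)) for k, v in tract_targets.items()
    }
    for i in np.flatnonzero(mis):
        key = (chroms[i], strands[i])
        targets = tract_targets.get(key)
        if targets is None or targets.size == 0:
            mis[i] = False
            continue
        if strands[i] == "+":
            j = int(np.searchsorted(targets, tss_obs[i] + 1, side="left"))
            if j >= targets.size:
                mis[i] = False
                continue
            pas_obs[i] = targets[j]
        else:
            j = int(np.searchsorted(targets, tss_obs[i], side="right")) - 1
            if j < 0:
                mis[i] = False
                continue
            pas_obs[i] = targets[j]
    # clamp to chromosome bounds and restore strand-consistent ordering
    chrom_lens = {c: len(s) for c, s in sim.sequences.items()}
    lens = np.array([chrom_lens[c] for c in chroms])
    tss_obs = np.clip(tss_obs, 0, lens - 1)
    pas_obs = np.clip(pas_obs, 0, lens - 1)
    plus = strands == "+"
    lo = np.minimum(tss_obs, pas_obs)
    hi = np.maximum(tss_obs, pas_obs)
    five = np.where(plus, lo, hi)
    three = np.where(plus, hi, lo)
    pairs = [
        EndPair(str(c), str(s), int(f), int(t))
        for c, s, f, t in zip(chroms, strands, five, three)
    ]
    molecules = pd.DataFrame({"isoform": iso_idx, "misprimed": mis})
    truth = SyntheticTruth(
        genes=sim.genes,
        isoforms=isoforms,
        spprna_genes=spprna_genes,
        molecules=molecules,
        params={
            "depth": depth,
            "mean_isoforms": mean_isoforms,
            "spprna_gene_fraction": spprna_gene_fraction,
            "spprna_length_median": spprna_length_median,
            "mispriming_rate": mispriming_rate,
            "seed": seed,
        },
    )
    return pairs, truth


def truth_tss_support(truth: SyntheticTruth, halfwidth: int = 10) -> TSSSupportSet:
    """TSS-seq-like support intervals around every true isoform TSS."""
    intervals = [
        GenomicInterval(i.chrom, max(i.tss - halfwidth, 0), i.tss + halfwidth + 1, i.strand)
        for i in truth.isoforms
    ]
    return TSSSupportSet(intervals)


def simulate_coverage(
    genes: Sequence[GeneModel],
    spprna_genes: set[str],
    promoter_peak_gain: float = 10.0,
    body_rate: float = 1.0,
    peak_len: int = 150,
    margin: int = 200,
    chrom_lengths: Optional[dict[str, int]] = None,
    seed: int = 1,
) -> tuple[CoverageTrack, dict]:
    """Poisson nascent coverage over gene bodies, with promoter peaks.

    Each gene (extended by ``margin`` nt on both sides, emulating the
    promoter-region and read-through signal real nascent data carries)
    gets per-base Poisson counts at ``body_rate``; sppRNA genes
    additionally have the first ``peak_len`` nt downstream of the TSS
    drawn at ``promoter_peak_gain`` x ``body_rate``.  gain = 1 means no
    peak anywhere.
    """
    if body_rate <= 0 or promoter_peak_gain <= 0:
        raise ValueError("rates must be strictly positive")
    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {}
        for g in genes:
            chrom_lengths[g.chrom] = max(
                chrom_lengths.get(g.chrom, 0), g.interval.end + 500
            )
    arrays = {
        (chrom, strand): np.zeros(length, dtype=float)
        for chrom, length in chrom_lengths.items()
        for strand in ("+", "-")
    }
    gains = {}
    for g in genes:
        arr = arrays[(g.chrom, g.strand)]
        s = max(g.interval.start - margin, 0)
        e = min(g.interval.end + margin, arr.size)
        arr[s:e] += rng.poisson(body_rate, size=e - s)
        if g.gene_id in spprna_genes:
            if g.strand == "+":
                ps, pe = g.interval.start, min(g.interval.start + peak_len, e)
            else:
                ps, pe = max(g.interval.end - peak_len, s), g.interval.end
            extra_rate = (promoter_peak_gain - 1.0) * body_rate
            if extra_rate > 0:
                arr[ps:pe] += rng.poisson(extra_rate, size=pe - ps)
            gains[g.gene_id] = promoter_peak_gain
        else:
            gains[g.gene_id] = 1.0
    track = CoverageTrack(arrays)
    return track, {"gains": gains, "body_rate": body_rate, "seed": seed}


def evaluate_cluster_recovery(
    clusters: Sequence[TIFCluster],
    truth: SyntheticTruth,
    min_support: int = 3,
    tolerance: int = 20,
) -> dict:
    """Score final clusters against molecule-level truth.

    A truth isoform is recoverable when at least ``min_support`` clean
    (non-misprimed) molecules were emitted for it.  Recall is the fraction
    of recoverable isoforms matched by some final cluster with both end
    distances <= tolerance; precision is the fraction of final clusters
    matching some truth isoform under the same rule.
    """
    table = truth.isoform_table()
    recoverable = table[table.n_clean >= min_support]
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for row in recoverable.itertuples():
        by_key.setdefault((row.chrom, row.strand), []).append((row.tss, row.pas))

    def matches(c: TIFCluster) -> bool:
        for t_tss, t_pas in by_key.get((c.chrom, c.strand), []):
            if abs(c.tss - t_tss) <= tolerance and abs(c.pas - t_pas) <= tolerance:
                return True
        return False

    n_matched_clusters = sum(1 for c in clusters if matches(c))
    cluster_keys: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    for key in by_key:
        sub = [(c.tss, c.pas) for c in clusters if (c.chrom, c.strand) == key]
        cluster_keys[key] = (
            np.array([s[0] for s in sub], dtype=np.int64),
            np.array([s[1] for s in sub], dtype=np.int64),
        )
    n_recovered = 0
    for key, isos in by_key.items():
        ctss, cpas = cluster_keys[key]
        for t_tss, t_pas in isos:
            if ctss.size and bool(
                np.any(
                    (np.abs(ctss - t_tss) <= tolerance)
                    & (np.abs(cpas - t_pas) <= tolerance)
                )
            ):
                n_recovered += 1
    n_recoverable = int(len(recoverable))
    return {
        "n_clusters": len(clusters),
        "n_recoverable_isoforms": n_recoverable,
        "precision": n_matched_clusters / len(clusters) if clusters else float("nan"),
        "recall": n_recovered / n_recoverable if n_recoverable else float("nan"),
    }


def write_scenario(
    outdir: str | Path,
    sim: SyntheticGenome,
    pairs: Sequence[EndPair],
    truth: SyntheticTruth,
    track: Optional[CoverageTrack] = None,
) -> None:
    """Write a complete simulated scenario as plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.sequences, outdir / "genome.fa")
    write_gff3(sim.genes, outdir / "genes.gff3")
    write_bedpe(pairs, outdir / "pairs.bedpe")
    support = truth_tss_support(truth)
    write_bed6(
        [
            (iv.chrom, iv.start, iv.end, f"tss_{i}", 0, iv.strand)
            for i, iv in enumerate(support.intervals)
        ],
        outdir / "tss_support.bed",
    )
    truth.isoform_table().to_csv(outdir / "truth.tsv", sep="\t", index=False)
    if track is not None:
        write_bedgraph(track, "+", outdir / "coverage_plus.bedgraph")
        write_bedgraph(track, "-", outdir / "coverage_minus.bedgraph")
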