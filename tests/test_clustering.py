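"""Clustering semantics: pre-clusters, 2D merging, and the three filters."""
import itertools

import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from tifiso import (
    EndPair,
    PipelineParams,
    TSSSupportSet,
    GenomicInterval,
    build_preclusters,
    filter_mispriming,
    filter_support,
    filter_tss_support,
    merge_preclusters,
    run_cluster_pipeline,
)
from tifiso.clustering import is_misprimed
from tifiso.io import Genome


def pairs_from_tuples(tuples, chrom="chr1", strand="+"):
    return [EndPair(chrom, strand, fp, tp) for fp, tp in tuples]


def oracle_partition(preclusters, window):
    """Independent transitive-closure oracle: dense pairwise adjacency +
    scipy connected components."""
    tss = np.array([c.tss for c in preclusters])
    pas = np.array([c.pas for c in preclusters])
    adj = (np.abs(tss[:, None] - tss[None, :]) < window) & (
        np.abs(pas[:, None] - pas[None, :]) < window
    )
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    parts = {}
    for lab, c in zip(labels, preclusters):
        parts.setdefault(lab, set()).add((c.tss, c.pas))
    return {frozenset(p) for p in parts.values()}


def merged_partition(merged):
    return {frozenset((fp, tp) for fp, tp, _ in c.members) for c in merged}


class TestPreclusters:
    def test_identical_pairs_merge_exactly(self):
        pre = build_preclusters(pairs_from_tuples([(100, 600), (100, 600)]))
        assert len(pre) == 1 and pre[0].support == 2

    def test_one_nt_difference_stays_separate(self):
        pre = build_preclusters(pairs_from_tuples([(100, 600), (100, 601)]))
        assert len(pre) == 2 and all(c.support == 1 for c in pre)

    def test_multiset_counting_oracle(self, rng):
        coords = [
            (int(a), int(a) + int(w))
            for a, w in zip(rng.integers(0, 300, 50), rng.integers(1, 200, 50))
        ]
        pre = build_preclusters(pairs_from_tuples(coords))
        from collections import Counter

        expected = Counter(coords)
        got = {(c.tss, c.pas): c.support for c in pre}
        assert got == dict(expected)

    def test_empty_input(self):
        assert build_preclusters([]) == []


class TestMerge:
    def test_nineteen_nt_merges_with_mode_representative(self):
        pre = build_preclusters(
            pairs_from_tuples([(100, 500), (100, 500), (119, 519)])
        )
        merged = merge_preclusters(pre, 20)
        assert len(merged) == 1
        c = merged[0]
        assert (c.tss, c.pas, c.support) == (100, 500, 3)

    def test_twenty_nt_does_not_merge(self):
        pre = build_preclusters(pairs_from_tuples([(100, 500), (120, 500)]))
        assert len(merge_preclusters(pre, 20)) == 2

    def test_chain_merges_transitively(self):
        pre = build_preclusters(
            pairs_from_tuples([(100, 500), (115, 515), (130, 530)])
        )
        assert len(merge_preclusters(pre, 20)) == 1

    def test_representative_tie_breaks_outermost(self):
        # equal support at both TSS positions: the 5'-most wins on +
        pre = build_preclusters(pairs_from_tuples([(100, 500), (110, 505)]))
        c = merge_preclusters(pre, 20)[0]
        assert c.tss == 100 and c.pas == 505

    def test_minus_strand_tie_breaks_outermost(self):
        pairs = [EndPair("chr1", "-", 500, 100), EndPair("chr1", "-", 510, 105)]
        c = merge_preclusters(build_preclusters(pairs), 20)[0]
        # 5'-most on minus strand is the larger coordinate; 3'-most the smaller
        assert c.tss == 510 and c.pas == 100

    @pytest.mark.parametrize("seed", range(12))
    def test_partition_equals_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 400))
        tss = rng.integers(0, 2000, n)
        width = rng.integers(1, 400, n)
        pre = build_preclusters(
            pairs_from_tuples([(int(t), int(t + w)) for t, w in zip(tss, width)])
        )
        merged = merge_preclusters(pre, 20)
        assert merged_partition(merged) == oracle_partition(pre, 20)

    def test_order_independence(self, rng):
        coords = [
            (int(t), int(t) + int(w))
            for t, w in zip(rng.integers(0, 500, 80), rng.integers(1, 100, 80))
        ]
        ref = merge_preclusters(build_preclusters(pairs_from_tuples(coords)), 20)
        perm = list(coords)
        rng.shuffle(perm)
        alt = merge_preclusters(build_preclusters(pairs_from_tuples(perm)), 20)
        assert [(c.tss, c.pas, c.support) for c in ref] == [
            (c.tss, c.pas, c.support) for c in alt
        ]

    def test_support_conservation(self, rng):
        coords = [
            (int(t), int(t) + int(w))
            for t, w in zip(rng.integers(0, 500, 120), rng.integers(1, 100, 120))
        ]
        pre = build_preclusters(pairs_from_tuples(coords))
        merged = merge_preclusters(pre, 20)
        assert sum(c.support for c in merged) == len(coords)

    def test_monotonicity_in_window_and_support(self, rng):
        coords = [
            (int(t), int(t) + int(w))
            for t, w in zip(rng.integers(0, 800, 150), rng.integers(1, 150, 150))
        ]
        pre = build_preclusters(pairs_from_tuples(coords))
        n_narrow = len(merge_preclusters(pre, 10))
        n_wide = len(merge_preclusters(pre, 40))
        assert n_wide <= n_narrow
        merged = merge_preclusters(pre, 20)
        assert len(filter_support(merged, 5)) <= len(filter_support(merged, 3))


class TestFilters:
    def test_support_boundary(self):
        pre = build_preclusters(
            pairs_from_tuples([(100, 500)] * 3 + [(300, 700)] * 2)
        )
        kept = filter_support(merge_preclusters(pre, 20), 3)
        assert [(c.tss, c.support) for c in kept] == [(100, 3)]

    def test_support_all_singletons_empty(self):
        pre = build_preclusters(pairs_from_tuples([(1, 10), (50, 90), (200, 400)]))
        assert filter_support(pre, 3) == []

    def test_min_support_below_one_rejected(self):
        with pytest.raises(ValueError):
            filter_support([], 0)

    def test_mispriming_plus_strand_a_run_downstream(self):
        # AAAAAA begins right after the PAS at position 51
        seq = "C" * 51 + "AAAAAA" + "C" * 43
        genome = Genome({"chr1": seq})
        from tifiso import TIFCluster

        cluster = TIFCluster("chr1", "+", 10, 50, 3)
        assert is_misprimed(cluster, genome)
        assert filter_mispriming([cluster], genome) == []

    def test_mispriming_five_a_run_kept(self):
        seq = "C" * 51 + "AAAAA" + "C" * 44
        genome = Genome({"chr1": seq})
        from tifiso import TIFCluster

        cluster = TIFCluster("chr1", "+", 10, 50, 3)
        assert not is_misprimed(cluster, genome)

    def test_mispriming_minus_strand_t_run(self):
        # minus-strand cluster with PAS at 50: TTTTTT on the forward strand
        # at 47 sits inside the +/-10 window (sense-strand A-run)
        seq = "G" * 47 + "TTTTTT" + "G" * 47
        genome = Genome({"chr1": seq})
        from tifiso import TIFCluster

        cluster = TIFCluster("chr1", "-", 90, 50, 3)
        assert is_misprimed(cluster, genome)
        # same sequence is NOT mispriming for a plus-strand cluster
        plus = TIFCluster("chr1", "+", 10, 50, 3)
        assert not is_misprimed(plus, genome)

    def test_mispriming_window_truncated_at_chromosome_edge(self):
        from tifiso import TIFCluster

        genome = Genome({"chr1": "CCCCCCCC"})
        cluster = TIFCluster("chr1", "+", 0, 5, 3)
        assert not is_misprimed(cluster, genome)

    def test_tss_support_containment_and_flank_boundary(self):
        support = TSSSupportSet([GenomicInterval("chr1", 100, 120, "+")])
        from tifiso import TIFCluster

        inside = TIFCluster("chr1", "+", 110, 400, 3)
        at_flank = TIFCluster("chr1", "+", 90, 400, 3)  # 10 nt outside
        beyond = TIFCluster("chr1", "+", 89, 400, 3)
        wrong_strand = TIFCluster("chr1", "-", 400, 110, 3)
        kept = filter_tss_support([inside, at_flank, beyond, wrong_strand], support, 10)
        assert kept == [inside, at_flank]

    def test_tss_support_brute_force_oracle(self, rng):
        from tifiso import TIFCluster

        ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(w), str(st))
            for s, w, st in zip(
                rng.integers(0, 5000, 40),
                rng.integers(5, 60, 40),
                rng.choice(["+", "-"], 40),
            )
        ]
        support = TSSSupportSet(ivs)
        clusters = []
        for s, st in zip(rng.integers(0, 5200, 200), rng.choice(["+", "-"], 200)):
            tss = int(s)
            if st == "+":
                clusters.append(TIFCluster("chr1", "+", tss, tss + 100, 3))
            else:
                clusters.append(TIFCluster("chr1", "-", tss + 100, tss, 3))
        flank = 10
        kept = filter_tss_support(clusters, support, flank)
        expected = [
            c
            for c in clusters
            if any(
                iv.strand == c.strand
                and iv.start - flank <= c.tss < iv.end + flank
                for iv in ivs
            )
        ]
        assert kept == expected

    def test_empty_support_set_removes_everything(self, caplog):
        from tifiso import TIFCluster

        clusters = [TIFCluster("chr1", "+", 1, 100, 3)]
        with caplog.at_level("WARNING"):
            assert filter_tss_support(clusters, TSSSupportSet([]), 10) == []
        assert any("EMPTY" in r.message for r in caplog.records)


class TestPipeline:
    def test_empty_pairs_give_empty_output(self):
        clusters, report = run_cluster_pipeline([], None, None)
        assert clusters == [] and report.n_preclusters == 0

    def test_noiseless_scenario_filters_are_noops(self):
        from tifiso import simulate_genome, simulate_end_pairs, truth_tss_support
        from tifiso.clustering import merge_preclusters as mp

        sim = simulate_genome(n_genes=30, a_tract_rate=0.0, seed=7)
        pairs, truth = simulate_end_pairs(
            sim,
            depth=3000,
            tss_dispersion=0,
            pas_dispersion=0,
            mispriming_rate=0.0,
            seed=8,
        )
        support = truth_tss_support(truth)
        clusters, report = run_cluster_pipeline(pairs, sim.genome, support)
        merged_supported = filter_support(
            mp(build_preclusters(pairs), 20), 3
        )
        assert report.n_after_support == len(merged_supported)
        # mispriming and TSS filters may only remove the occasional cluster
        # that happens to sit on a random genomic A-run; with no planted
        # tracts and full support the pipeline keeps the merged set
        assert report.n_after_tss_support == report.n_after_support

    def test_stage_counts_are_monotone(self, small_scenario):
        r = small_scenario["report"]
        assert (
            r.n_preclusters
            >= r.n_merged
            >= r.n_after_support
            >= r.n_after_mispriming
            >= r.n_after_tss_support
        )
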