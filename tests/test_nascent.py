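"""Nascent-coverage quantification: gene-body signal, pausing index,
control matching, metagene profiles, rank-sum comparisons."""
import itertools

import numpy as np
import pytest
from scipy import stats as sps

from tifiso import CoverageTrack, match_control_genes, metagene, pausing_index
from tifiso.nascent import (
    add_tpm,
    compare_distributions,
    genebody_signal,
    genebody_signal_table,
    pausing_index_table,
    tpm_at_pas,
)
from conftest import make_gene


def uniform_track(length=12000, value=1.0, strand="+"):
    return CoverageTrack({("chr1", strand): np.full(length, value)})


class TestGeneBody:
    def test_uniform_track_shrunk_sum(self):
        g = make_gene("g", "chr1", 2000, 3000, "+")
        assert genebody_signal(uniform_track(), g, shrink=200) == 600.0

    def test_zero_track(self):
        g = make_gene("g", "chr1", 2000, 3000, "+")
        assert genebody_signal(uniform_track(value=0.0), g) == 0.0

    def test_short_gene_excluded(self):
        g = make_gene("g", "chr1", 2000, 2400, "+")
        assert genebody_signal(uniform_track(), g, shrink=200) is None

    def test_step_function_matches_per_base_oracle(self, rng):
        arr = np.zeros(5000)
        arr[2500:3200] = 4.0
        arr[3200:4000] = 1.5
        track = CoverageTrack({("chr1", "-"): arr})
        g = make_gene("g", "chr1", 2400, 4100, "-")
        got = genebody_signal(track, g, shrink=200)
        expected = sum(arr[i] for i in range(2600, 3900))
        assert got == expected

    def test_tpm_sums_to_one_million(self):
        genes = [
            make_gene("a", "chr1", 1000, 3000, "+"),
            make_gene("b", "chr1", 4000, 5500, "+"),
            make_gene("c", "chr1", 6000, 9000, "+"),
        ]
        track = uniform_track()
        table = genebody_signal_table(track, genes)
        assert table.tpm.sum() == pytest.approx(1e6)


class TestPausingIndex:
    def test_uniform_coverage_gives_one(self):
        g = make_gene("g", "chr1", 2000, 4000, "+")
        assert pausing_index(uniform_track(), g) == pytest.approx(1.0)

    def test_promoter_enrichment_matches_per_base_oracle(self):
        arr = np.ones(12000)
        g = make_gene("g", "chr1", 2000, 4000, "+")
        arr[1850:2150] = 10.0
        track = CoverageTrack({("chr1", "+"): arr})
        got = pausing_index(track, g)
        prom = arr[1850:2150].sum() / 300
        body = arr[2300:3700].sum() / 1400
        assert got == pytest.approx(prom / body)

    def test_scale_invariance(self):
        arr = np.ones(12000)
        arr[1850:2150] = 10.0
        g = make_gene("g", "chr1", 2000, 4000, "+")
        a = pausing_index(CoverageTrack({("chr1", "+"): arr}), g)
        b = pausing_index(CoverageTrack({("chr1", "+"): arr * 7}), g)
        assert a == pytest.approx(b)

    def test_zero_body_undefined(self):
        arr = np.zeros(12000)
        arr[1850:2150] = 5.0
        g = make_gene("g", "chr1", 2000, 4000, "+")
        assert pausing_index(CoverageTrack({("chr1", "+"): arr}), g) is None

    def test_eligibility_short_gene_excluded(self):
        genes = [
            make_gene("short", "chr1", 2000, 2900, "+"),   # 900 nt
            make_gene("long", "chr1", 4000, 6000, "+"),
        ]
        table = pausing_index_table(uniform_track(), genes)
        assert table.gene_id.tolist() == ["long"]

    def test_minus_strand_promoter_window(self):
        arr = np.ones(12000)
        g = make_gene("g", "chr1", 2000, 4000, "-")   # TSS at 3999
        arr[3849:4149] = 8.0
        track = CoverageTrack({("chr1", "-"): arr})
        got = pausing_index(track, g)
        prom = arr[3849:4149].sum() / 300
        body = arr[2300:3700].sum() / 1400
        assert got == pytest.approx(prom / body)


class TestControlMatching:
    def test_identical_candidates_full_match(self, rng):
        targets = [f"t{i}" for i in range(50)]
        candidates = [f"c{i}" for i in range(50)]
        sig = {g: float(i % 10) for i, g in enumerate(targets)}
        sig.update({g: float(i % 10) for i, g in enumerate(candidates)})
        chosen = match_control_genes(targets, candidates, sig, seed=3)
        assert len(chosen) == len(targets)

    def test_too_few_candidates_error(self):
        with pytest.raises(ValueError):
            match_control_genes(["a", "b"], ["c"], {"a": 1, "b": 2, "c": 1})

    def test_empty_bin_partial_fill(self, caplog):
        targets = ["t0", "t1", "t2", "t3"]
        candidates = ["c0", "c1", "c2", "c3"]
        sig = {"t0": 0.0, "t1": 1.0, "t2": 10.0, "t3": 11.0,
               "c0": 0.0, "c1": 1.0, "c2": 0.5, "c3": 0.7}
        with caplog.at_level("WARNING"):
            chosen = match_control_genes(targets, candidates, sig, n_bins=2, seed=1)
        assert len(chosen) == 2  # high bin empty
        assert any("deficit" in r.message for r in caplog.records)

    def test_seeded_reproducibility(self, rng):
        targets = [f"t{i}" for i in range(100)]
        candidates = [f"c{i}" for i in range(300)]
        sig = {g: float(rng.lognormal(0, 1)) for g in targets + candidates}
        a = match_control_genes(targets, candidates, sig, seed=11)
        b = match_control_genes(targets, candidates, sig, seed=11)
        assert a == b
        c = match_control_genes(targets, candidates, sig, seed=12)
        assert set(a) != set(c)

    def test_matched_distribution_passes_ks(self):
        rng = np.random.default_rng(77)
        targets = [f"t{i}" for i in range(500)]
        candidates = [f"c{i}" for i in range(3000)]
        sig = {g: float(rng.lognormal(0.3, 0.9)) for g in targets}
        sig.update({g: float(rng.lognormal(0.0, 1.0)) for g in candidates})
        chosen = match_control_genes(targets, candidates, sig, seed=5)
        p = sps.ks_2samp([sig[g] for g in targets], [sig[g] for g in chosen]).pvalue
        assert p > 0.1


class TestMetagene:
    def test_constant_track_zero_ci_width(self):
        track = uniform_track(value=2.0)
        anchors = [("chr1", "+", p) for p in (3000, 4000, 5000)]
        prof = metagene(track, anchors, flank=50)
        assert np.allclose(prof["mean"], 2.0)
        assert np.allclose(prof.ci_high - prof.ci_low, 0.0)

    def test_two_anchor_closed_form(self):
        arr = np.zeros(1000)
        arr[100] = 0.0
        arr[500] = 2.0
        track = CoverageTrack({("chr1", "+"): arr})
        prof = metagene(track, [("chr1", "+", 100), ("chr1", "+", 500)], flank=5)
        centre = prof[prof.position == 0].iloc[0]
        assert centre["mean"] == 1.0
        # sem = sd/sqrt(2) = sqrt(2)/sqrt(2) = 1 -> ci half-width 1.96
        assert centre.ci_high - centre["mean"] == pytest.approx(1.96)

    def test_edge_windows_dropped(self):
        track = uniform_track(length=200)
        prof = metagene(track, [("chr1", "+", 10), ("chr1", "+", 100)], flank=50)
        assert prof.n_anchors.iloc[0] == 1

    def test_fifty_anchor_brute_force_oracle(self, rng):
        arr = rng.random(20_000)
        track = CoverageTrack({("chr1", "+"): arr.copy()})
        anchors = [("chr1", "+", int(p)) for p in rng.integers(200, 19_800, 50)]
        prof = metagene(track, anchors, flank=100)
        for offset in (-100, -3, 0, 42, 100):
            expected = np.mean([arr[p + offset] for _, _, p in anchors])
            got = float(prof.loc[prof.position == offset, "mean"].iloc[0])
            assert got == pytest.approx(expected)

    def test_minus_strand_orientation(self):
        arr = np.zeros(1000)
        arr[495] = 5.0  # 5 nt downstream of a minus-strand anchor at 500
        track = CoverageTrack({("chr1", "-"): arr})
        prof = metagene(track, [("chr1", "-", 500)], flank=10)
        assert float(prof.loc[prof.position == 5, "mean"].iloc[0]) == 5.0

    def test_symmetric_peak_symmetric_profile(self, rng):
        arr = np.zeros(50_000)
        anchors = []
        kernel = np.exp(-0.5 * (np.arange(-30, 31) / 10.0) ** 2)
        for p in rng.integers(500, 49_500, 40):
            arr[p - 30 : p + 31] += kernel
            anchors.append(("chr1", "+", int(p)))
        prof = metagene(CoverageTrack({("chr1", "+"): arr}), anchors, flank=40)
        left = prof.loc[prof.position < 0, "mean"].values[::-1]
        right = prof.loc[prof.position > 0, "mean"].values
        assert np.allclose(left, right, atol=0.05)


class TestCompareDistributions:
    def test_identical_samples_high_p(self, rng):
        x = rng.normal(size=40)
        out = compare_distributions(x, x)
        assert out["p_value"] > 0.9

    def test_well_separated_groups_tiny_p(self):
        out = compare_distributions(list(range(1, 21)), list(range(101, 121)))
        assert out["p_value"] < 1e-5
        assert out["median_a"] == 10.5 and out["median_b"] == 110.5

    def test_three_vs_three_exact_enumeration_oracle(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 3.0, 7.0]
        out = compare_distributions(a, b)
        # full enumeration of the rank-sum null at n=m=3
        pooled = a + b
        obs = sum(sorted(pooled).index(v) + 1 for v in a)
        stats_null = []
        for comb in itertools.combinations(range(6), 3):
            ranks = [r + 1 for r in comb]
            stats_null.append(sum(ranks))
        obs_dev = abs(obs - np.mean(stats_null))
        p_exact = np.mean(
            [abs(s - np.mean(stats_null)) >= obs_dev for s in stats_null]
        )
        assert out["p_value"] == pytest.approx(p_exact)

    def test_all_tied_degenerate_p_one(self):
        with pytest.warns(UserWarning):
            out = compare_distributions([3.0, 3.0], [3.0, 3.0, 3.0])
        assert out["p_value"] == 1.0


class TestTpmAtPas:
    def test_uniform_track_equal_values(self):
        genes = [
            make_gene("a", "chr1", 1000, 3000, "+"),
            make_gene("b", "chr1", 5000, 8000, "+"),
        ]
        table = tpm_at_pas(uniform_track(), genes, halfwidth=100)
        assert table.tpm.iloc[0] == pytest.approx(table.tpm.iloc[1])

    def test_zero_coverage_zero(self):
        genes = [make_gene("a", "chr1", 1000, 3000, "+")]
        table = tpm_at_pas(uniform_track(value=0.0), genes, halfwidth=100)
        assert table.raw_count.iloc[0] == 0.0

    def test_fixture_matches_per_base_oracle(self, rng):
        arr = rng.random(10_000)
        track = CoverageTrack({("chr1", "-"): arr.copy()})
        g = make_gene("a", "chr1", 2000, 6000, "-")  # PAS at 2000
        table = tpm_at_pas(track, [g], halfwidth=150)
        assert table.raw_count.iloc[0] == pytest.approx(arr[1850:2150].sum())
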