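import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from k9diff import (
    BinnedTrack,
    EnrichmentConfig,
    GenomeModel,
    Region,
    RepeatElement,
    filter_repeats_with_signal,
    obs_exp_enrichment,
    obs_exp_ttest,
    overlap_annotate,
    percent_associated,
    repeat_composition,
    shuffle_intervals,
)

from oracles import count_associated, one_sided_t_p, per_base_overlap


def elem(chrom, start, end, cls, sub=None, name="e"):
    return RepeatElement(chrom, start, end, name=name, repeat_name=name,
                         repeat_class=cls, repeat_subfamily=sub or cls)


class TestOverlapAnnotate:
    def test_union_coverage_not_double_counted(self, genome):
        regions = [Region("chrA", 0, 400)]
        annotation = [Region("chrA", 100, 200), Region("chrA", 150, 300)]
        ((bp, frac, assoc),) = overlap_annotate(regions, annotation)
        assert (bp, frac, assoc) == (200, 0.5, True)

    def test_disjoint_gives_zero(self, genome):
        ((bp, frac, assoc),) = overlap_annotate(
            [Region("chrA", 0, 100)], [Region("chrA", 500, 600)])
        assert (bp, frac, assoc) == (0, 0.0, False)

    def test_full_coverage(self, genome):
        ((bp, frac, assoc),) = overlap_annotate(
            [Region("chrA", 100, 300)], [Region("chrA", 0, 10_000)])
        assert (bp, frac, assoc) == (200, 1.0, True)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        regions = [Region("chrA", int(s), int(s) + int(l))
                   for s, l in zip(rng.integers(0, 900, 8), rng.integers(1, 120, 8))]
        annotation = [Region("chrA", int(s), int(s) + int(l))
                      for s, l in zip(rng.integers(0, 950, 12), rng.integers(1, 80, 12))]
        got = overlap_annotate(regions, annotation)
        for r, (bp, frac, assoc) in zip(regions, got):
            expected = per_base_overlap((r.chrom, r.start, r.end),
                                        [(a.chrom, a.start, a.end) for a in annotation])
            assert bp == expected
            assert assoc == (expected > 0)


class TestPercentAssociated:
    def test_three_of_four(self):
        regions = [Region("chrA", i * 100, i * 100 + 50) for i in range(4)]
        annotation = [Region("chrA", 0, 260)]
        assert percent_associated(regions, annotation) == 75.0

    def test_extremes(self):
        regions = [Region("chrA", 0, 100)]
        assert percent_associated(regions, []) == 0.0
        assert percent_associated(regions, [Region("chrA", 0, 100)]) == 100.0

    def test_empty_regions_rejected(self):
        with pytest.raises(ValueError):
            percent_associated([], [])


class TestShuffleIntervals:
    def test_forced_placement_on_exact_fit(self):
        g = GenomeModel([("chrA", 1_000)])
        rng = np.random.default_rng(0)
        (out,) = shuffle_intervals([Region("chrA", 0, 1_000)], g, rng)
        assert (out.chrom, out.start, out.end) == ("chrA", 0, 1_000)

    def test_lengths_preserved_and_in_bounds(self, genome, rng):
        regions = [Region("chrA", 0, int(l)) for l in rng.integers(50, 3000, 40)]
        out = shuffle_intervals(regions, genome, rng)
        assert sorted(len(r) for r in out) == sorted(len(r) for r in regions)
        for r in out:
            assert 0 <= r.start < r.end <= genome.length(r.chrom)

    def test_chromosome_weighting_matches_start_slots(self):
        # slots: chrA 9000-999=8001, chrB 1000-999=1; P(chrA) = 8001/8002
        g = GenomeModel([("chrA", 9_000), ("chrB", 1_000)])
        rng = np.random.default_rng(7)
        n = 10_000
        out = shuffle_intervals([Region("chrA", 0, 1_000)] * n, g, rng)
        on_a = sum(r.chrom == "chrA" for r in out)
        p = 8001 / 8002
        se = np.sqrt(p * (1 - p) * n)
        assert abs(on_a - p * n) < 5 * se + 1

    def test_oversized_region_rejected(self):
        g = GenomeModel([("chrA", 499)])
        with pytest.raises(ValueError, match="exceeds"):
            shuffle_intervals([Region("chrA", 0, 500)], g, np.random.default_rng(0))


class TestObsExpTtest:
    def test_worked_example_ratios(self):
        # observed 168 against expected counts 140/120/105 gives the ratio
        # triple 1.2, 1.4, 1.6
        res = obs_exp_ttest("LTR", 168, [140, 120, 105])
        assert np.allclose(res.ratios, [1.2, 1.4, 1.6])
        assert np.isclose(res.mean_ratio, 1.4)
        assert np.isclose(res.sd_ratio, 0.2)
        assert np.isclose(res.t_stat, (1.4 - 1) / (0.2 / np.sqrt(3)))
        assert np.isclose(res.t_stat, 3.4641016, atol=1e-6)
        assert res.df == 2
        assert np.isclose(res.p_one_sided, 0.0371, atol=5e-4)
        # independent check: numerically integrated t density
        assert np.isclose(res.p_one_sided, one_sided_t_p(res.t_stat, 2), atol=1e-5)

    def test_zero_expected_flagged(self):
        res = obs_exp_ttest("g", 5, [0, 2, 3])
        assert res.flag == "expected-zero" and res.p_one_sided is None

    def test_zero_spread_flagged(self):
        res = obs_exp_ttest("g", 10, [5, 5, 5])
        assert res.flag == "sd-zero" and res.t_stat is None


class TestObsExpEnrichment:
    def test_saturating_annotation_gives_unit_ratios_flagged(self, genome):
        annotation = [elem("chrA", 0, 10_000, "ALL"), elem("chrB", 0, 5_000, "ALL")]
        regions = [Region("chrA", 100, 600), Region("chrB", 0, 900)]
        (res,) = obs_exp_enrichment(regions, annotation,
                                    EnrichmentConfig(seed=5), genome=genome)
        assert res.observed == 2
        assert res.expected == [2, 2, 2]
        assert res.ratios == [1.0, 1.0, 1.0]
        assert res.flag == "sd-zero"

    def test_counts_match_per_base_oracle_on_tiny_genome(self):
        g = GenomeModel([("chrA", 800), ("chrB", 400)])
        rng = np.random.default_rng(31)
        annotation = [elem("chrA", 100, 250, "LTR"), elem("chrA", 500, 700, "SINE"),
                      elem("chrB", 50, 120, "LTR")]
        regions = [Region("chrA", 200, 320), Region("chrA", 600, 650),
                   Region("chrB", 0, 60), Region("chrB", 300, 390)]
        results = obs_exp_enrichment(regions, annotation,
                                     EnrichmentConfig(seed=9), genome=g)
        for res in results:
            members = [(e.chrom, e.start, e.end) for e in annotation
                       if e.repeat_class == res.group]
            expected_obs = count_associated(
                [(r.chrom, r.start, r.end) for r in regions], members)
            assert res.observed == expected_obs

    def test_groups_without_any_overlap_dropped(self, genome):
        annotation = [elem("chrA", 0, 100, "HIT"), elem("chrB", 4_900, 5_000, "MISS")]
        regions = [Region("chrA", 0, 50)]
        results = obs_exp_enrichment(regions, annotation,
                                     EnrichmentConfig(seed=1), genome=genome)
        groups = {r.group for r in results}
        assert "HIT" in groups
        # MISS can only appear if a shuffled region happened to land on it
        for r in results:
            if r.group == "MISS":
                assert max(r.expected) > 0

    def test_planted_ltr_enrichment_detected(self):
        from k9diff.benchmark import run_planted_benchmark
        score = run_planted_benchmark(2)
        assert score.target_mean_ratio > 1.5
        assert score.target_significant
        assert not score.neutral_significant

    def test_too_few_shuffles_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentConfig(n_shuffles=1)


class TestRepeatComposition:
    def test_element_count_percentages(self):
        catalogue = [elem("chrA", i * 100, i * 100 + 50, "SINE", s, name=f"e{i}")
                     for i, s in enumerate(["Alu", "Alu", "Alu", "MIR"])]
        assert repeat_composition(catalogue, "SINE") == {"Alu": 75.0, "MIR": 25.0}

    def test_single_subfamily_class(self):
        catalogue = [elem("chrA", 0, 50, "Satellite")]
        assert repeat_composition(catalogue, "Satellite") == {"Satellite": 100.0}

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            repeat_composition([elem("chrA", 0, 50, "SINE")], "LINE")


class TestFilterRepeatsWithSignal:
    def test_keeps_only_elements_over_positive_bins(self):
        g = GenomeModel([("chrA", 1_000)])
        track = BinnedTrack(g, 200, {"chrA": np.array([0.0, 4.0, 0.0, 0.0, 2.0])})
        elements = [elem("chrA", 0, 150, "SINE", name="dead"),
                    elem("chrA", 150, 250, "SINE", name="live"),
                    elem("chrA", 400, 750, "SINE", name="dead2"),
                    elem("chrA", 900, 1_000, "SINE", name="live2")]
        kept = filter_repeats_with_signal(elements, track)
        assert [e.repeat_name for e in kept] == ["live", "live2"]
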