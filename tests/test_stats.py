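"""Statistical battery: decay fits, group tests, positional statistics."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from srna_signature.errors import (
    ConfigError,
    InsufficientDataError,
    NormalizationError,
    SrnaSignatureError,
)
from srna_signature.readproc import MappedRead, count_by_size_and_region
from srna_signature.sequences import ANTISENSE, SENSE, Region
from srna_signature.simulate import simulate_dcl_reads, simulate_degradation_reads
from srna_signature.stats import (
    AnalysisParams,
    compare_size_classes_raw,
    detect_transitivity,
    fit_length_decay,
    functional_normalize,
    long_short_ratio_test,
    normalize_to_control,
    one_way_anova_cld,
    phasing_score,
    pooled_t_test,
    sliding_window_profile,
)

TABLE1_22NT_16CDS = [186, 276, 202]
TABLE1_22NT_WTDS = [275, 246, 209]


class TestDecayFit:
    def test_exact_log_linear_counts_recover_rate(self):
        counts = {L: round(1000 * math.exp(-0.3 * (L - 17))) for L in range(17, 30)}
        fit = fit_length_decay(counts)
        assert fit.rate == pytest.approx(-0.3, abs=0.005)
        assert abs(fit.pearson_r) >= 0.999

    def test_constant_counts_define_zero_rate_and_r(self):
        fit = fit_length_decay({L: 50 for L in range(17, 30)})
        assert fit.rate == 0.0
        assert fit.pearson_r == 0.0

    def test_too_few_nonzero_lengths_error(self):
        with pytest.raises(InsufficientDataError):
            fit_length_decay({20: 5, 21: 7})

    def test_zero_lengths_excluded_and_counted(self):
        counts = {L: round(1000 * math.exp(-0.3 * (L - 17))) for L in range(17, 28)}
        counts[28] = 0
        counts[29] = 0
        fit = fit_length_decay(counts)
        assert fit.excluded_zero_lengths == 2
        assert fit.n_points == 11

    def test_simulated_degradation_sample_fits_cleanly(self, ref):
        region = Region("target", 1, ref.length)
        reads = simulate_degradation_reads(ref, region, 100_000, 0.25, seed=1)
        lengths, ns = np.unique([r.length for r in reads], return_counts=True)
        fit = fit_length_decay({int(L): int(n) for L, n in zip(lengths, ns)})
        assert abs(fit.pearson_r) > 0.99
        assert -fit.rate == pytest.approx(0.25, rel=0.1)


class TestRawComparison:
    def test_identical_groups_give_p_one_everywhere(self):
        group = {L: [10.0, 20.0, 30.0] for L in range(20, 26)}
        result = compare_size_classes_raw(group, group)
        for rec in result.records:
            assert rec["p_value"] == pytest.approx(1.0)
            assert rec["direction"] == "none"

    def test_printed_22nt_counts_not_significant_and_depleted(self):
        result = compare_size_classes_raw(
            {22: TABLE1_22NT_16CDS}, {22: TABLE1_22NT_WTDS}
        )
        rec = result.records[0]
        assert rec["p_value"] > 0.05
        assert rec["direction"] == "depleted"

    def test_zero_variance_equal_means_p_one(self):
        assert pooled_t_test([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_zero_variance_unequal_means_certain(self):
        t, p = pooled_t_test([5, 5, 5], [9, 9, 9])
        assert p == 0.0 and t < 0

    def test_unequal_replicate_structure_allowed(self):
        result = compare_size_classes_raw({20: [1, 2, 3, 4]}, {20: [2, 3]})
        assert 0 <= result.records[0]["p_value"] <= 1

    def test_single_replicate_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            compare_size_classes_raw({20: [1]}, {20: [2, 3]})

    def test_type_one_error_calibrated_under_shared_poisson_null(self):
        # 3 vs 3 replicates from the same Poisson(200), 10,000 repetitions
        rng = np.random.default_rng(2024)
        reps = 10_000
        rejections = 0
        draws_a = rng.poisson(200, size=(reps, 3))
        draws_b = rng.poisson(200, size=(reps, 3))
        for a, b in zip(draws_a, draws_b):
            _, p = pooled_t_test(a, b)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.015)


class TestNormalization:
    def test_printed_count_ratio(self):
        ratios, undefined = normalize_to_control({22: 186}, {22: 37})
        assert ratios[22] == pytest.approx(5.027, abs=0.001)
        assert undefined == set()

    def test_identity_when_counts_equal_control(self):
        counts = {L: float(L) for L in range(20, 26)}
        ratios, _ = normalize_to_control(counts, counts)
        assert all(v == 1.0 for v in ratios.values())

    def test_control_zero_flags_cell_without_poisoning_others(self):
        ratios, undefined = normalize_to_control({20: 4, 21: 6}, {20: 0, 21: 3})
        assert undefined == {20}
        assert math.isnan(ratios[20])
        assert ratios[21] == 2.0

    def test_all_zero_control_is_error(self):
        with pytest.raises(NormalizationError):
            normalize_to_control({20: 4}, {20: 0})

    def test_functional_normalize_unit_denominator_is_identity(self):
        counts = {21: 7.0, 22: 9.0}
        assert functional_normalize(counts, 1.0, "mir159") == counts

    def test_functional_normalize_depth_invariance(self):
        shallow = functional_normalize({22: 50.0}, 100.0, "all_24nt")
        deep = functional_normalize({22: 100.0}, 200.0, "all_24nt")
        assert shallow == deep

    def test_zero_denominator_names_scheme(self):
        with pytest.raises(NormalizationError, match="mir159"):
            functional_normalize({22: 5.0}, 0.0, "mir159")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ConfigError):
            functional_normalize({22: 5.0}, 1.0, "spike_in")


class TestAnova:
    def test_identical_groups_share_a_letter(self):
        result = one_way_anova_cld({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert result["letters"]["a"] == result["letters"]["b"]

    def test_strongly_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, size=3)
        groups = {
            "g1": base,
            "g2": rng.normal(0, 1, size=3),
            "g3": rng.normal(10, 1, size=3),  # ten pooled SDs away
        }
        result = one_way_anova_cld(groups)
        assert result["letters"]["g3"] not in (
            result["letters"]["g1"],
            result["letters"]["g2"],
        )
        assert result["p_value"] < 0.05

    def test_single_group_is_error(self):
        with pytest.raises(InsufficientDataError):
            one_way_anova_cld({"only": [1.0, 2.0]})


class TestSlidingWindow:
    def test_single_read_spreads_over_window(self):
        reads = [MappedRead("r", 100, SENSE, 1)]
        profile = sliding_window_profile(reads, 720, window=10, total_reads=1)
        nonzero = np.flatnonzero(profile) + 1
        assert list(nonzero) == list(range(95, 105))
        assert np.allclose(profile[nonzero - 1], 0.1)

    def test_uniform_counts_give_constant_profile(self):
        positions = np.repeat(np.arange(1, 101), 3)
        profile = sliding_window_profile(positions, 100, window=10, total_reads=300)
        interior = profile[10:-10]
        assert np.allclose(interior, 3 / 300)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(8)
        positions = rng.integers(1, 201, size=500)
        profile = sliding_window_profile(positions, 200, window=10, total_reads=500)
        counts = np.bincount(positions, minlength=201)[1:]
        for p in range(1, 201):
            lo, hi = max(1, p - 4), min(200, p + 5)
            expected = counts[lo - 1 : hi].mean() / 500
            assert profile[p - 1] == pytest.approx(expected, abs=1e-12)

    def test_edge_shrinkage_accounting_identity(self):
        rng = np.random.default_rng(9)
        positions = rng.integers(1, 301, size=1000)
        window = 10
        profile = sliding_window_profile(positions, 300, window=window, total_reads=1000)
        counts = np.bincount(positions, minlength=301)[1:]
        weights = np.zeros(300)
        for p in range(1, 301):
            lo, hi = max(1, p - 4), min(300, p + 5)
            weights[lo - 1 : hi] += 1.0 / (hi - lo + 1)
        assert profile.sum() * 1000 == pytest.approx((counts * weights).sum(), abs=1e-9)

    def test_zero_total_reads_is_error(self):
        with pytest.raises(InsufficientDataError):
            sliding_window_profile([], 100, total_reads=0)


def _flank_table(sample_id, condition, antisense_flank, sense_flank=0):
    counts = {
        (region, strand, L): 0
        for region in ("trigger", "flank5", "flank3")
        for strand in (SENSE, ANTISENSE)
        for L in range(20, 26)
    }
    counts[("flank5", ANTISENSE, 21)] = antisense_flank
    counts[("flank5", SENSE, 21)] = sense_flank
    counts[("trigger", SENSE, 21)] = 100
    from srna_signature.readproc import SizeClassTable

    total = sum(counts.values())
    return SizeClassTable(
        sample_id=sample_id,
        counts=counts,
        total_reads=total,
        mapped_reads=total,
        condition=condition,
    )


class TestTransitivity:
    def test_zero_antisense_flanks_is_the_null_outcome(self):
        tables = [_flank_table(f"t{i}", "target_ds", 0) for i in range(3)]
        tables += [_flank_table(f"w{i}", "wildtype_ds", 0) for i in range(3)]
        result = detect_transitivity(tables)
        assert result.p_value == 1.0
        assert result.verdict is False

    def test_sense_flank_reads_do_not_trigger_a_verdict(self):
        # mRNA decay gives sense flank reads in reporter samples only
        tables = [_flank_table(f"t{i}", "target_ds", 0, sense_flank=200) for i in range(3)]
        tables += [_flank_table(f"w{i}", "wildtype_ds", 0) for i in range(3)]
        result = detect_transitivity(tables)
        assert result.verdict is False

    def test_strong_antisense_flank_signal_detected(self):
        tables = [_flank_table(f"t{i}", "target_ds", 40) for i in range(3)]
        tables += [_flank_table(f"w{i}", "wildtype_ds", 1) for i in range(3)]
        result = detect_transitivity(tables)
        assert result.verdict is True
        assert result.p_value < 0.05

    def test_minimum_read_floor_blocks_stray_reads(self):
        tables = [_flank_table(f"t{i}", "target_ds", 2) for i in range(3)]
        tables += [_flank_table(f"w{i}", "wildtype_ds", 0) for i in range(3)]
        result = detect_transitivity(tables)
        assert result.verdict is False  # significant exceedance but < 5 reads/sample

    def test_missing_control_condition_is_error(self):
        tables = [_flank_table("t1", "target_ds", 0), _flank_table("t2", "target_ds", 0)]
        with pytest.raises(InsufficientDataError):
            detect_transitivity(tables)


class TestPhasing:
    def test_single_register_occupancy_is_maximal_and_significant(self, trigger):
        reads = [MappedRead(f"r{i}", 294 + 22 * (i % 6), SENSE, 22) for i in range(12)]
        result = phasing_score(reads, trigger, 22)
        assert result.score == 1.0
        assert result.p_value < 0.05

    def test_uniform_placements_score_near_reciprocal_register(self, trigger):
        rng = np.random.default_rng(12)
        starts = rng.integers(trigger.start, trigger.end - 22 + 2, size=10_000)
        reads = [MappedRead(f"r{i}", int(s), SENSE, 22) for i, s in enumerate(starts)]
        result = phasing_score(reads, trigger, 22)
        assert result.score == pytest.approx(1 / 22, abs=0.01)
        assert result.p_value > 0.05

    def test_uniform_null_rejection_rate_calibrated(self, trigger):
        rng = np.random.default_rng(77)
        rejections = 0
        runs = 120
        for _ in range(runs):
            starts = rng.integers(trigger.start, trigger.end - 22 + 2, size=400)
            reads = [MappedRead("r", int(s), SENSE, 22) for s in starts]
            if phasing_score(reads, trigger, 22).p_value < 0.05:
                rejections += 1
        assert rejections / runs < 0.1  # Bonferroni over offsets is conservative

    def test_generator_fully_phased_reads_score_one(self, ref, trigger):
        reads = simulate_dcl_reads(ref, trigger, 300, {22: 1.0}, 1.0, seed=6)
        table, mapped = count_by_size_and_region(
            reads, ref, [trigger], count_range=(17, 29), collect_mapped=True
        )
        result = phasing_score(mapped, trigger, 22)
        assert result.score == 1.0
        assert result.p_value < 0.05

    def test_underpowered_sample_reports_score_without_p(self, trigger):
        reads = [MappedRead(f"r{i}", 294, SENSE, 22) for i in range(5)]
        result = phasing_score(reads, trigger, 22)
        assert result.score == 1.0
        assert result.p_value is None


def _two_region_table(long_in, short_in, long_out, short_out):
    from srna_signature.readproc import SizeClassTable

    counts = {}
    for region, long, short in (
        ("trigger", long_in, short_in),
        ("flank5", long_out, short_out),
    ):
        counts[(region, SENSE, 25)] = long
        counts[(region, SENSE, 22)] = short
    total = sum(counts.values())
    return SizeClassTable("s", counts, total, total, count_range=(20, 25))


class TestLongShortRatio:
    def test_proportional_table_is_null(self):
        result = long_short_ratio_test(_two_region_table(10, 10, 10, 10))
        assert result.odds_ratio == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0)

    def test_p_matches_brute_force_hypergeometric(self):
        result = long_short_ratio_test(_two_region_table(9, 1, 1, 9))
        # enumerate all 2x2 tables with the same margins
        from math import comb

        n, row_out, col_long = 20, 10, 10
        p_obs = comb(row_out, 1) * comb(n - row_out, col_long - 1) / comb(n, col_long)
        total = sum(
            comb(row_out, k) * comb(n - row_out, col_long - k)
            for k in range(max(0, col_long - (n - row_out)), min(row_out, col_long) + 1)
            if comb(row_out, k) * comb(n - row_out, col_long - k) / comb(n, col_long)
            <= p_obs * (1 + 1e-9)
        ) / comb(n, col_long)
        assert result.p_value == pytest.approx(total, rel=1e-9)

    def test_zero_margin_leaves_odds_undefined(self):
        result = long_short_ratio_test(_two_region_table(0, 10, 0, 10))
        assert result.odds_ratio is None
        assert result.p_value == 1.0

    def test_flatter_decay_outside_gives_or_above_one(self, ref, trigger):
        # steeper decay inside the trigger, flatter outside (endogenous mRNA)
        inside = simulate_degradation_reads(ref, trigger, 25_000, 0.4, seed=21)
        outside = simulate_degradation_reads(
            ref, Region("flank3", trigger.end + 1, ref.length), 25_000, 0.1, seed=22
        )
        table = count_by_size_and_region(
            inside + outside,
            ref,
            [trigger, Region("flank5", 1, trigger.start - 1),
             Region("flank3", trigger.end + 1, ref.length)],
            count_range=(17, 29),
        )
        result = long_short_ratio_test(table)
        assert result.odds_ratio > 1
        assert result.p_value < 0.05


class TestParams:
    def test_bad_alpha_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisParams(alpha=1.5)

    def test_bad_window_rejected(self):
        with pytest.raises(ConfigError):
            AnalysisParams(window=0)
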