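"""Generator behaviour: determinism, placement laws, design semantics."""

import numpy as np
import pytest
from scipy import stats as sps

from srna_signature.errors import ConfigError, ConflictError, CoordinateError, DesignError
from srna_signature.sequences import Region, reverse_complement
from srna_signature.simulate import (
    GFP139_F_CORE,
    TRIGGER_MIDGFP,
    SimulationConfig,
    build_reference,
    default_design,
    default_reference,
    negative_scenario_configs,
    simulate_dcl_reads,
    simulate_degradation_reads,
    simulate_experiment,
    simulate_experiment_reads,
    simulate_sample,
)


class TestBuildReference:
    def test_motif_embedded_verbatim_at_printed_coordinate(self):
        ref = build_reference(720, 0, [(GFP139_F_CORE, 294)])
        assert ref.sequence[293 : 293 + len(GFP139_F_CORE)] == GFP139_F_CORE

    def test_no_motif_case_gives_acgt_string_of_requested_length(self):
        ref = build_reference(10, 123)
        assert len(ref.sequence) == 10
        assert set(ref.sequence) <= set("ACGT")

    def test_deterministic_for_fixed_inputs(self):
        a = build_reference(720, 7, [(GFP139_F_CORE, 294)])
        b = build_reference(720, 7, [(GFP139_F_CORE, 294)])
        assert a.sequence == b.sequence

    def test_motif_overrun_is_coordinate_error(self):
        with pytest.raises(CoordinateError):
            build_reference(300, 0, [(GFP139_F_CORE, 295)])

    def test_overlapping_motifs_conflict(self):
        with pytest.raises(ConflictError):
            build_reference(720, 0, [("AAAAAAAA", 10), ("CCCCCCCC", 15)])

    def test_default_reference_carries_both_trigger_primer_cores(self):
        ref = default_reference()
        assert ref.subseq(294, 313) == GFP139_F_CORE
        # reverse primer core appears as its reverse complement, ending at 432
        assert ref.subseq(413, 432) == reverse_complement("GATCCTGTTGACGAGGGTGT")


class TestDegradationReads:
    def test_zero_reads_is_empty(self, ref, trigger):
        assert simulate_degradation_reads(ref, trigger, 0, 0.25) == []

    def test_zero_rate_gives_uniform_length_histogram(self, ref):
        region = Region("target", 1, ref.length)
        reads = simulate_degradation_reads(ref, region, 50_000, 0.0, seed=3)
        lengths = np.array([r.length for r in reads])
        observed = np.bincount(lengths, minlength=30)[17:30]
        chi2 = sps.chisquare(observed)
        assert chi2.pvalue > 0.01

    def test_length_law_matches_exponential_rate(self, ref):
        # interior count ratios count(L)/count(L+1) ~ e^lambda
        region = Region("target", 1, ref.length)
        reads = simulate_degradation_reads(ref, region, 100_000, 0.25, seed=1)
        counts = np.bincount([r.length for r in reads], minlength=30)
        ratios = counts[18:28] / counts[19:29]
        assert np.allclose(ratios, np.exp(0.25), rtol=0.08)

    def test_reads_are_exact_substrings_on_recorded_strand(self, ref, trigger):
        reads = simulate_degradation_reads(
            ref, trigger, 500, 0.25, strand_mode="both", seed=11
        )
        for read in reads:
            assert (
                read.sequence in ref.sequence
                or reverse_complement(read.sequence) in ref.sequence
            )

    def test_sense_only_mode_emits_no_antisense_sequences(self, ref, trigger):
        reads = simulate_degradation_reads(
            ref, trigger, 300, 0.25, strand_mode="sense_only", seed=5
        )
        assert all(r.sequence in ref.sequence for r in reads)

    def test_region_shorter_than_min_length_is_infeasible(self, ref):
        with pytest.raises(CoordinateError):
            simulate_degradation_reads(ref, Region("tiny", 1, 10), 5, 0.25)

    def test_log_linear_fit_quality_at_scale(self, ref):
        from srna_signature.stats import fit_length_decay

        region = Region("target", 1, ref.length)
        reads = simulate_degradation_reads(ref, region, 100_000, 0.25, seed=1)
        counts = dict(zip(*np.unique([r.length for r in reads], return_counts=True)))
        fit = fit_length_decay({int(k): int(v) for k, v in counts.items()})
        assert abs(fit.pearson_r) > 0.99


class TestDclReads:
    def test_fully_phased_22mers_sit_on_the_six_registers(self, ref, trigger):
        reads = simulate_dcl_reads(ref, trigger, 400, {22: 1.0}, 1.0, seed=2)
        registers = {294 + 22 * k for k in range(6)}
        for read in reads:
            if read.sequence in ref.sequence:  # sense-strand read
                start = ref.sequence.index(read.sequence) + 1
                assert start in registers

    def test_zero_reads_is_empty(self, ref, trigger):
        assert simulate_dcl_reads(ref, trigger, 0, {22: 1.0}, 1.0) == []

    def test_unphased_starts_are_uniform(self, ref, trigger):
        reads = simulate_dcl_reads(ref, trigger, 30_000, {22: 1.0}, 0.0, seed=4)
        starts = []
        for read in reads:
            seq = read.sequence
            if seq not in ref.sequence:
                seq = reverse_complement(seq)
            starts.append(ref.sequence.index(seq) + 1)
        observed = np.bincount(starts, minlength=trigger.end + 1)[
            trigger.start : trigger.end - 22 + 2
        ]
        assert sps.chisquare(observed).pvalue > 0.01

    def test_bad_size_probs_rejected(self, ref, trigger):
        with pytest.raises(ConfigError):
            simulate_dcl_reads(ref, trigger, 10, {21: 0.6, 22: 0.6}, 0.5)


class TestExperiment:
    def test_seven_fastq_files_with_requested_counts(self, tmp_path, ref, trigger):
        configs = negative_scenario_configs(n_reads=200)
        paths = simulate_experiment(
            default_design(), configs, ref, trigger, tmp_path, seed=0
        )
        assert len(paths) == 7
        for path in paths.values():
            assert sum(1 for _ in open(path)) == 4 * 200

    def test_fastq_bytes_deterministic_in_seed(self, tmp_path, ref, trigger):
        configs = negative_scenario_configs(n_reads=100)
        a = simulate_experiment(default_design(), configs, ref, trigger, tmp_path / "a", seed=9)
        b = simulate_experiment(default_design(), configs, ref, trigger, tmp_path / "b", seed=9)
        for sample_id in a:
            assert a[sample_id].read_bytes() == b[sample_id].read_bytes()

    def test_water_sample_has_no_antisense_target_reads(self, ref, trigger):
        config = SimulationConfig(n_reads=500, strand_mode="sense_only")
        reads = simulate_sample("w", "target_water", config, ref, trigger, seed=1)
        for read in reads:
            # antisense target reads would reverse-complement onto the reference
            if reverse_complement(read.sequence) in ref.sequence:
                assert read.sequence in ref.sequence  # palindromic corner only

    def test_wildtype_reads_confined_to_trigger(self, ref, trigger):
        config = SimulationConfig(n_reads=500, background_fraction=0.0)
        reads = simulate_sample("wt", "wildtype_ds", config, ref, trigger, seed=2)
        for read in reads:
            seq = read.sequence
            if seq not in ref.sequence:
                seq = reverse_complement(seq)
            start = ref.sequence.index(seq) + 1
            assert trigger.start <= start
            assert start + len(seq) - 1 <= trigger.end

    def test_wildtype_with_transitive_fraction_rejected(self, ref, trigger):
        config = SimulationConfig(n_reads=10, transitive_fraction=0.1)
        with pytest.raises(DesignError):
            simulate_sample("wt", "wildtype_ds", config, ref, trigger)

    def test_water_with_dcl_fraction_rejected(self, ref, trigger):
        config = SimulationConfig(
            n_reads=10, dcl_fraction=0.1, strand_mode="sense_only"
        )
        with pytest.raises(DesignError):
            simulate_sample("w", "target_water", config, ref, trigger)

    def test_missing_condition_config_is_design_error(self, ref, trigger):
        with pytest.raises(DesignError):
            simulate_experiment_reads(
                default_design(), {"target_ds": SimulationConfig(n_reads=10)},
                ref, trigger,
            )

    def test_unknown_condition_label_rejected(self):
        from srna_signature.simulate import ExperimentDesign, SampleSpec

        with pytest.raises(DesignError):
            ExperimentDesign((SampleSpec("x", "mystery", 1),))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dcl_fraction": 1.5},
            {"dcl_fraction": 0.5, "transitive_fraction": 0.4, "background_fraction": 0.3},
            {"size_probs": {21: 0.5, 22: 0.4}},
            {"decay_rate": -0.1},
            {"strand_mode": "upside_down"},
            {"length_window": (20, 10)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)
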