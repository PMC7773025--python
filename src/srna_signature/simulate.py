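"""Seeded generator for small-RNA read sets with known signature structure.

The generator emulates a spray experiment on a GFP reporter line: a
double-stranded trigger covering part of the target transcript, three
sample conditions (reporter + dsRNA, wild type + dsRNA, reporter +
water), and four read sources:

* **degradation** — fragment lengths follow a truncated exponential
  (geometric) law, so shorter reads are more abundant; sense-only for
  mRNA turnover, both strands for extracellular dsRNA decay;
* **DCL products** — reads at the canonical silencing sizes (21/22/24 nt)
  inside the trigger, optionally placed on a fixed phased register;
* **transitive reads** — silencing-size reads on the antisense strand of
  the regions flanking the trigger, the fingerprint of RDR6-driven
  secondary siRNA production (only biologically possible when the target
  transcript is present);
* **background** — reads from an off-target pool, half of them exact
  copies of a fixed 21-nt miR159-like decoy so that functional
  normalization has a depth-proportional denominator.

Every emitted read is an exact substring of its source sequence (or the
reverse complement of one), so the exact mapper can place it back; fixing
the seed fixes the byte content of every FASTQ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, ConflictError, CoordinateError, DesignError
from .reads import SmallRNARead, write_fastq
from .sequences import ReferenceSequence, Region, derive_flanks, reverse_complement

# Printed primer cores (T7 promoter and restriction tails stripped) of the
# amplicons used to transcribe the two trigger dsRNAs.
T7_PROMOTER = "TAATACGACTCACTATAGGGAGA"
GFP139_F_CORE = "TATGAAGCGGCACGACTTCT"  # forward primer core, anneals at 294
GFP139_R_CORE = "GATCCTGTTGACGAGGGTGT"  # reverse primer core, amplicon ends 432
GFP5P_F_CORE = "ATGAAGACTAATCTTTTTCTCTTT"  # 5'GFP amplicon starts at 1
GFP5P_R_CORE = "CTCAGGCATGGCGCTCTTGA"  # 5'GFP amplicon ends at 322

#: midGFP trigger interval on the target, 139 nt.
TRIGGER_MIDGFP = Region("trigger", 294, 432)
#: 5'GFP interval (the longer, 322-nt trigger).
REGION_5PGFP = Region("gfp5p", 1, 322)

#: Positive-control siRNA metadata as printed: the stated length (22 nt)
#: and the stated coordinates (164-187, a 24-nt span) disagree; both are
#: recorded verbatim and deliberately not reconciled.
SIRNA_164 = {"label": "siRNA#164", "stated_length_nt": 22, "start": 164, "end": 187}

#: Synthetic 21-nt decoy standing in for the abundant miR159 microRNA in
#: the background pool (not the real miR159 sequence).
MIR159_DECOY = "TTTGGATTGAAGGGAGCTCTA"
_MIR159_BACKGROUND_WEIGHT = 0.5  # fraction of background reads that are decoy copies

CONDITIONS = ("target_ds", "wildtype_ds", "target_water")


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    condition: str
    replicate: int


@dataclass(frozen=True)
class ExperimentDesign:
    """Sample roster: ids, condition labels and replicate indices."""

    samples: tuple[SampleSpec, ...]

    def __post_init__(self):
        for spec in self.samples:
            if spec.condition not in CONDITIONS:
                raise DesignError(
                    f"unknown condition {spec.condition!r} for sample "
                    f"{spec.sample_id!r}; expected one of {CONDITIONS}"
                )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise DesignError("duplicate sample ids in design")

    def condition_of(self, sample_id: str) -> str:
        for spec in self.samples:
            if spec.sample_id == sample_id:
                return spec.condition
        raise DesignError(f"sample {sample_id!r} not in design")


def default_design() -> ExperimentDesign:
    """The 7-sample roster: 3x reporter+dsRNA, 3x wild type+dsRNA, 1x water."""
    samples = [SampleSpec(f"16C-ds_{i}", "target_ds", i) for i in (1, 2, 3)]
    samples += [SampleSpec(f"WT-ds_{i}", "wildtype_ds", i) for i in (1, 2, 3)]
    samples += [SampleSpec("16C-w", "target_water", 1)]
    return ExperimentDesign(tuple(samples))


@dataclass(frozen=True)
class SimulationConfig:
    """Per-condition generator settings.

    ``decay_rate`` is the per-nucleotide exponential rate of the fragment
    length law; ``dcl_fraction``, ``transitive_fraction`` and
    ``background_fraction`` partition reads among sources (the remainder
    is degradation); ``size_probs`` is the silencing-size distribution of
    DCL products.
    """

    n_reads: int = 50_000
    decay_rate: float = 0.25
    dcl_fraction: float = 0.0
    size_probs: dict[int, float] = field(
        default_factory=lambda: {21: 0.3, 22: 0.4, 24: 0.3}
    )
    phase_fraction: float = 0.5
    transitive_fraction: float = 0.0
    strand_mode: str = "both"
    length_window: tuple[int, int] = (17, 29)
    background_fraction: float = 0.2

    def __post_init__(self):
        fracs = {
            "dcl_fraction": self.dcl_fraction,
            "transitive_fraction": self.transitive_fraction,
            "background_fraction": self.background_fraction,
            "phase_fraction": self.phase_fraction,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        shares = self.dcl_fraction + self.transitive_fraction + self.background_fraction
        if shares > 1.0 + 1e-9:
            raise ConfigError(
                f"dcl + transitive + background fractions exceed 1 ({shares:.3f})"
            )
        if abs(sum(self.size_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("size_probs must sum to 1")
        if self.decay_rate < 0:
            raise ConfigError("decay_rate must be >= 0")
        if self.strand_mode not in ("sense_only", "both"):
            raise ConfigError(f"unknown strand_mode {self.strand_mode!r}")
        lo, hi = self.length_window
        if lo > hi or lo < 1:
            raise ConfigError(f"bad length_window {self.length_window}")
        if self.n_reads < 0:
            raise ConfigError("n_reads must be >= 0")


def build_reference(
    length: int,
    seed: int,
    motifs: list[tuple[str, int]] | None = None,
    name: str = "ref",
) -> ReferenceSequence:
    """Seeded pseudorandom ACGT reference with motifs embedded verbatim.

    Motifs are (sequence, 1-based start) pairs; they must fit on the
    reference and must not overlap each other. Deterministic for a fixed
    (length, seed, motifs).
    """
    motifs = motifs or []
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    chars = rng.choice(bases, size=length)
    occupied: list[tuple[int, int]] = []
    for seq, start in motifs:
        end = start + len(seq) - 1
        if start < 1 or end > length:
            raise CoordinateError(
                f"motif at {start} (length {len(seq)}) overruns reference "
                f"of length {length}"
            )
        for o_start, o_end in occupied:
            if start <= o_end and end >= o_start:
                raise ConflictError(
                    f"motif at [{start}, {end}] overlaps motif at "
                    f"[{o_start}, {o_end}]"
                )
        occupied.append((start, end))
        chars[start - 1 : end] = list(seq)
    return ReferenceSequence(name, "".join(chars))


def default_reference(length: int = 720, seed: int = 16) -> ReferenceSequence:
    """Shipped stand-in for the unprinted GFP transgene sequence.

    A seeded pseudorandom 720-nt sequence with the printed primer cores
    embedded at their printed amplicon boundaries: the 5'GFP forward core
    at position 1, the midGFP forward core at 294, and the reverse
    complement of the midGFP reverse core ending at 432. (The 5'GFP
    reverse core would overlap the midGFP forward core and is omitted.)
    Synthetic: coordinates are real, the sequence between motifs is not.
    """
    motifs = [
        (GFP5P_F_CORE, 1),
        (GFP139_F_CORE, TRIGGER_MIDGFP.start),
        (
            reverse_complement(GFP139_R_CORE),
            TRIGGER_MIDGFP.end - len(GFP139_R_CORE) + 1,
        ),
    ]
    return build_reference(length, seed, motifs, name="GFP-16C-synthetic")


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _emit(
    ref: ReferenceSequence,
    starts: np.ndarray,
    lengths: np.ndarray,
    antisense: np.ndarray,
    id_prefix: str,
    id_offset: int = 0,
) -> list[SmallRNARead]:
    seq = ref.sequence
    out = []
    for i, (start, L, anti) in enumerate(zip(starts, lengths, antisense)):
        s = seq[start - 1 : start - 1 + L]
        if anti:
            s = reverse_complement(s)
        out.append(SmallRNARead(f"{id_prefix}{id_offset + i}", s))
    return out


def degradation_length_probs(
    decay_rate: float, lengths: np.ndarray
) -> np.ndarray:
    """P(L) proportional to exp(-rate * (L - min)) on the allowed lengths."""
    weights = np.exp(-decay_rate * (lengths - lengths.min()))
    return weights / weights.sum()


def simulate_degradation_reads(
    ref: ReferenceSequence,
    region: Region,
    n: int,
    decay_rate: float,
    strand_mode: str = "both",
    length_window: tuple[int, int] = (17, 29),
    seed=0,
    id_prefix: str = "deg",
) -> list[SmallRNARead]:
    """Degradation fragments: exponential length decay, uniform placement.

    Lengths are sampled first (truncated exponential on the window,
    capped by the region length), then a start position uniform over all
    placements fitting inside the region; so the length histogram follows
    the stated law exactly, independent of region size.
    """
    region.validate_against(ref)
    if decay_rate < 0:
        raise ConfigError("decay_rate must be >= 0")
    if n == 0:
        return []
    min_len, max_len = length_window
    if region.length < min_len:
        raise CoordinateError(
            f"region {region.name!r} (length {region.length}) shorter than "
            f"minimum read length {min_len}"
        )
    rng = _as_rng(seed)
    lengths_allowed = np.arange(min_len, min(max_len, region.length) + 1)
    probs = degradation_length_probs(decay_rate, lengths_allowed)
    lengths = rng.choice(lengths_allowed, size=n, p=probs)
    starts = region.start + rng.integers(0, region.length - lengths + 1)
    if strand_mode == "sense_only":
        antisense = np.zeros(n, dtype=bool)
    elif strand_mode == "both":
        antisense = rng.random(n) < 0.5
    else:
        raise ConfigError(f"unknown strand_mode {strand_mode!r}")
    return _emit(ref, starts, lengths, antisense, id_prefix)


def phased_register_starts(trigger: Region, register_length: int) -> np.ndarray:
    """Sense-coordinate 5' starts of the phased register: start + k*L.

    A trigger of length T holds floor(T / L) full registers (the 139-nt
    midGFP trigger holds 6 phased 22-mers).
    """
    n_registers = trigger.length // register_length
    return trigger.start + register_length * np.arange(n_registers)


def simulate_dcl_reads(
    ref: ReferenceSequence,
    trigger: Region,
    n: int,
    size_probs: dict[int, float],
    phase_fraction: float,
    seed=0,
    id_prefix: str = "dcl",
) -> list[SmallRNARead]:
    """DCL products: silencing-size reads inside the trigger.

    A ``phase_fraction`` of reads start on the phased register
    (trigger.start + k * length); the rest start uniformly over valid
    placements. Strands are drawn with equal probability. Phasing is
    modelled on 5'-end registers only; duplex 2-nt overhang geometry is
    not modelled.
    """
    trigger.validate_against(ref)
    if abs(sum(size_probs.values()) - 1.0) > 1e-9:
        raise ConfigError("size_probs must sum to 1")
    if trigger.length < 24:
        raise CoordinateError(
            f"trigger length {trigger.length} too short for DCL sizes"
        )
    if n == 0:
        return []
    rng = _as_rng(seed)
    sizes = np.array(sorted(size_probs))
    probs = np.array([size_probs[s] for s in sizes])
    lengths = rng.choice(sizes, size=n, p=probs)
    phased = rng.random(n) < phase_fraction
    starts = np.empty(n, dtype=int)
    for L in sizes:
        on_register = phased & (lengths == L)
        registers = phased_register_starts(trigger, L)
        starts[on_register] = rng.choice(registers, size=int(on_register.sum()))
        off_register = ~phased & (lengths == L)
        n_off = int(off_register.sum())
        starts[off_register] = trigger.start + rng.integers(
            0, trigger.length - L + 1, size=n_off
        )
    antisense = rng.random(n) < 0.5
    return _emit(ref, starts, lengths, antisense, id_prefix)


def simulate_transitive_reads(
    ref: ReferenceSequence,
    flanks: list[Region],
    n: int,
    size_probs: dict[int, float],
    seed=0,
    id_prefix: str = "trans",
) -> list[SmallRNARead]:
    """Secondary-siRNA reads: antisense, silencing sizes, in the flanks."""
    if n == 0:
        return []
    rng = _as_rng(seed)
    usable = [f for f in flanks if f.length >= max(size_probs)]
    if not usable:
        raise CoordinateError("no flank long enough for transitive reads")
    weights = np.array([f.length for f in usable], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(usable), size=n, p=weights)
    sizes = np.array(sorted(size_probs))
    probs = np.array([size_probs[s] for s in sizes])
    lengths = rng.choice(sizes, size=n, p=probs)
    starts = np.empty(n, dtype=int)
    for i, flank in enumerate(usable):
        mask = which == i
        starts[mask] = flank.start + rng.integers(
            0, flank.length - lengths[mask] + 1
        )
    antisense = np.ones(n, dtype=bool)
    return _emit(ref, starts, lengths, antisense, id_prefix)


def background_reference(seed: int = 905) -> ReferenceSequence:
    """Off-target pool sequence for background degradation reads."""
    return build_reference(500, seed, name="background-synthetic")


def _simulate_background(
    config: SimulationConfig, n: int, bg_ref: ReferenceSequence, rng
) -> list[SmallRNARead]:
    n_decoy = int(round(n * _MIR159_BACKGROUND_WEIGHT))
    reads = [SmallRNARead(f"mir{i}", MIR159_DECOY) for i in range(n_decoy)]
    reads += simulate_degradation_reads(
        bg_ref,
        Region("background", 1, bg_ref.length),
        n - n_decoy,
        config.decay_rate,
        "sense_only",
        config.length_window,
        rng,
        id_prefix="bg",
    )
    return reads


def simulate_sample(
    sample_id: str,
    condition: str,
    config: SimulationConfig,
    ref: ReferenceSequence,
    trigger: Region,
    seed=0,
    bg_ref: ReferenceSequence | None = None,
) -> list[SmallRNARead]:
    """All reads of one sample, composed per its condition.

    ``target_ds``: dsRNA decay in the trigger (both strands), mRNA decay
    over the whole target (sense), DCL and transitive reads per config.
    ``wildtype_ds``: no target transcript, so only dsRNA decay confined
    to the trigger (plus DCL products if configured); transitive reads
    are impossible and rejected. ``target_water``: only sense mRNA decay
    and background.
    """
    if condition not in CONDITIONS:
        raise DesignError(f"unknown condition {condition!r}")
    if condition == "wildtype_ds" and config.transitive_fraction > 0:
        raise DesignError(
            "wildtype_ds cannot produce transitive reads (no target "
            "transcript for RDR6); set transitive_fraction = 0"
        )
    if condition == "target_water":
        if config.dcl_fraction > 0 or config.transitive_fraction > 0:
            raise DesignError(
                "target_water has no dsRNA trigger; dcl_fraction and "
                "transitive_fraction must be 0"
            )
        if config.strand_mode != "sense_only":
            raise DesignError(
                "target_water degradation is mRNA decay; strand_mode must "
                "be 'sense_only'"
            )
    rng = _as_rng(seed)
    if bg_ref is None:
        bg_ref = background_reference()
    flanks = derive_flanks(trigger, ref.length)
    n = config.n_reads
    n_bg = int(round(n * config.background_fraction))
    n_dcl = int(round(n * config.dcl_fraction))
    n_trans = int(round(n * config.transitive_fraction))
    n_deg = n - n_bg - n_dcl - n_trans

    reads: list[SmallRNARead] = []
    if condition == "target_ds":
        n_trigger_deg = n_deg // 2  # dsRNA decay vs mRNA decay, half each
        reads += simulate_degradation_reads(
            ref, trigger, n_trigger_deg, config.decay_rate,
            config.strand_mode, config.length_window, rng, "dsdeg",
        )
        reads += simulate_degradation_reads(
            ref, Region("target", 1, ref.length), n_deg - n_trigger_deg,
            config.decay_rate, "sense_only", config.length_window, rng, "mdeg",
        )
    elif condition == "wildtype_ds":
        reads += simulate_degradation_reads(
            ref, trigger, n_deg, config.decay_rate,
            config.strand_mode, config.length_window, rng, "dsdeg",
        )
    else:  # target_water
        reads += simulate_degradation_reads(
            ref, Region("target", 1, ref.length), n_deg, config.decay_rate,
            "sense_only", config.length_window, rng, "mdeg",
        )
    if n_dcl:
        reads += simulate_dcl_reads(
            ref, trigger, n_dcl, config.size_probs, config.phase_fraction,
            rng, "dcl",
        )
    if n_trans:
        reads += simulate_transitive_reads(
            ref, flanks, n_trans, config.size_probs, rng, "trans",
        )
    reads += _simulate_background(config, n_bg, bg_ref, rng)
    return [
        SmallRNARead(f"{sample_id}:{i}", r.sequence) for i, r in enumerate(reads)
    ]


def simulate_experiment_reads(
    design: ExperimentDesign,
    configs: dict[str, SimulationConfig],
    ref: ReferenceSequence,
    trigger: Region,
    seed: int = 0,
) -> dict[str, list[SmallRNARead]]:
    """In-memory experiment: sample_id -> reads, deterministic in seed."""
    for spec in design.samples:
        if spec.condition not in configs:
            raise DesignError(f"no SimulationConfig for condition {spec.condition!r}")
    bg_ref = background_reference()
    out = {}
    for index, spec in enumerate(design.samples):
        sample_rng = np.random.default_rng([seed, index])
        out[spec.sample_id] = simulate_sample(
            spec.sample_id, spec.condition, configs[spec.condition],
            ref, trigger, sample_rng, bg_ref,
        )
    return out


def simulate_experiment(
    design: ExperimentDesign,
    configs: dict[str, SimulationConfig],
    ref: ReferenceSequence,
    trigger: Region,
    outdir: str | Path,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate the experiment and write one FASTQ per sample."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_reads = simulate_experiment_reads(design, configs, ref, trigger, seed)
    paths = {}
    for sample_id, reads in all_reads.items():
        path = outdir / f"{sample_id}.fastq"
        write_fastq(reads, path)
        paths[sample_id] = path
    return paths


def negative_scenario_configs(
    n_reads: int = 50_000, **overrides
) -> dict[str, SimulationConfig]:
    """Degradation-only study conditions: no DCL products, no transitivity."""
    base = SimulationConfig(n_reads=n_reads, **overrides)
    return {
        "target_ds": base,
        "wildtype_ds": base,
        "target_water": replace(base, strand_mode="sense_only"),
    }


def positive_scenario_configs(
    n_reads: int = 50_000,
    dcl_fraction: float = 0.3,
    transitive_fraction: float = 0.05,
    **overrides,
) -> dict[str, SimulationConfig]:
    """A genuine-RNAi scenario: DCL products and transitivity in the
    reporter line; the wild type still sees only dsRNA decay."""
    base = SimulationConfig(n_reads=n_reads, **overrides)
    return {
        "target_ds": replace(
            base,
            dcl_fraction=dcl_fraction,
            transitive_fraction=transitive_fraction,
        ),
        "wildtype_ds": base,
        "target_water": replace(base, strand_mode="sense_only"),
    }
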