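"""End-to-end orchestration: simulate/count -> statistics -> verdict.

Two entry points, mirroring how the underlying question can arrive:

* :func:`run_pipeline` — from a :class:`RunConfig` (YAML-backed): either
  simulates a full experiment or ingests FASTQ files, then counts, runs
  the statistical battery and writes a JSON report plus per-analysis
  TSVs to the output directory.
* :func:`analyze_tables` — from pre-counted size-class tables (the
  shipped seven-sample fixture, or tables derived from deposited data),
  running every statistic that does not need per-read positions.

Machine output goes to files; logging goes to stderr.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, StageError
from .readproc import (
    DEFAULT_LENGTH_WINDOW,
    ReferenceIndex,
    SizeClassTable,
    count_by_size_and_region,
    filter_by_length,
    trim_adapter,
)
from .reads import read_fastq
from .sequences import (
    ANTISENSE,
    SENSE,
    ReferenceSequence,
    Region,
    derive_flanks,
    read_fasta,
)
from .simulate import (
    TRIGGER_MIDGFP,
    ExperimentDesign,
    SampleSpec,
    SimulationConfig,
    default_design,
    default_reference,
    negative_scenario_configs,
    positive_scenario_configs,
    simulate_experiment_reads,
)
from .stats import (
    AnalysisParams,
    SignatureReport,
    classify_signature,
    compare_normalized_anova,
    compare_size_classes_raw,
    detect_transitivity,
    fit_length_decay,
    long_short_ratio_test,
    normalize_to_control,
    phasing_score,
    sliding_window_profile,
)

logger = logging.getLogger("srna_signature")


# ---------------------------------------------------------------------------
# Table 1 fixture


def load_table1_fixture() -> dict[str, SizeClassTable]:
    """The embedded seven-sample count fixture.

    Printed per-length ROI counts live on the trigger/sense cells; flank
    regions are present with zero counts (the deposited profiles showed
    no antisense flank reads), so table-level statistics including the
    transitivity test run unchanged.
    """
    path = resources.files("srna_signature").joinpath("data/table1_roi_counts.tsv")
    frame = pd.read_csv(path, sep="\t", comment="#")
    tables: dict[str, SizeClassTable] = {}
    lengths = range(20, 26)
    for row in frame.itertuples():
        counts = {
            (region, strand, L): 0
            for region in ("trigger", "flank5", "flank3", "outside")
            for strand in (SENSE, ANTISENSE)
            for L in lengths
        }
        for L in lengths:
            counts[("trigger", SENSE, L)] = int(getattr(row, f"len{L}"))
        mapped = sum(counts.values())
        tables[row.sample] = SizeClassTable(
            sample_id=row.sample,
            counts=counts,
            total_reads=int(row.total_reads),
            mapped_reads=mapped,
            count_range=(20, 25),
            unmapped=int(row.total_reads) - mapped,
            condition=row.condition,
            regions=("trigger", "flank5", "flank3", "outside"),
        )
    return tables


# ---------------------------------------------------------------------------
# table-level statistics


def pool_tables(tables: list[SizeClassTable], sample_id: str) -> SizeClassTable:
    """Sum counts across replicates into one table."""
    counts: dict = {}
    for table in tables:
        for key, n in table.counts.items():
            counts[key] = counts.get(key, 0) + n
    return SizeClassTable(
        sample_id=sample_id,
        counts=counts,
        total_reads=sum(t.total_reads for t in tables),
        mapped_reads=sum(t.mapped_reads for t in tables),
        count_range=tables[0].count_range,
        condition=tables[0].condition,
        regions=tables[0].regions,
    )


def _by_condition(tables: dict[str, SizeClassTable]) -> dict[str, list[SizeClassTable]]:
    grouped: dict[str, list[SizeClassTable]] = {}
    for table in tables.values():
        grouped.setdefault(table.condition, []).append(table)
    return grouped


def analyze_tables(
    tables: dict[str, SizeClassTable],
    params: AnalysisParams | None = None,
    phasing=None,
) -> SignatureReport:
    """Full table-level battery and verdict.

    Needs at least two replicates each of ``target_ds`` and
    ``wildtype_ds``; the single water control, when present, drives the
    control normalization (flagged as single-replicate in the report
    notes). ``phasing`` results from per-read positional data may be
    passed through; table-only inputs leave them unassessed.
    """
    params = params or AnalysisParams()
    grouped = _by_condition(tables)
    for condition in ("target_ds", "wildtype_ds"):
        if len(grouped.get(condition, [])) < 2:
            raise StageError(
                "stats", f"need >= 2 replicates of condition {condition!r}"
            )
    sizes = [L for L in params.size_classes]

    def sample_length_counts(table: SizeClassTable) -> dict[int, int]:
        return table.length_counts()

    group_a = {
        L: [sample_length_counts(t)[L] for t in grouped["target_ds"]] for L in sizes
    }
    group_b = {
        L: [sample_length_counts(t)[L] for t in grouped["wildtype_ds"]] for L in sizes
    }
    enrichment_raw = compare_size_classes_raw(
        group_a, group_b, params.alpha, "target_ds", "wildtype_ds"
    )

    decay_fits = {}
    for sample_id, table in tables.items():
        if table.condition not in ("target_ds", "wildtype_ds"):
            continue
        decay_fits[sample_id] = fit_length_decay(
            sample_length_counts(table), params.decay_fit_range
        )
    pooled_decay = {
        condition: fit_length_decay(
            sample_length_counts(pool_tables(members, condition)),
            params.decay_fit_range,
        )
        for condition, members in grouped.items()
        if condition in ("target_ds", "wildtype_ds")
    }

    notes_extra = []
    enrichment_normalized = None
    water = grouped.get("target_water", [])
    if water:
        if len(water) == 1:
            notes_extra.append(
                "control normalization uses a single water replicate "
                "(statistically fragile denominator)"
            )
        control_counts = sample_length_counts(pool_tables(water, "water"))
        normalized: dict[str, dict[int, list[float]]] = {}
        for condition in ("target_ds", "wildtype_ds"):
            normalized[condition] = {L: [] for L in sizes}
            for table in grouped[condition]:
                ratios, _undefined = normalize_to_control(
                    {L: sample_length_counts(table)[L] for L in sizes},
                    {L: control_counts[L] for L in sizes},
                )
                for L in sizes:
                    normalized[condition][L].append(ratios[L])
        enrichment_normalized = compare_normalized_anova(
            normalized, params.alpha, "between_conditions"
        ) + compare_normalized_anova(normalized, params.alpha, "across_lengths")

    transitivity = detect_transitivity(
        list(tables.values()),
        alpha=params.alpha,
        min_reads=params.min_transitivity_reads,
    )
    long_short = long_short_ratio_test(
        pool_tables(grouped["target_ds"], "target_ds_pooled")
    )

    report = classify_signature(
        enrichment_raw,
        transitivity,
        decay_fits,
        pooled_decay,
        params,
        phasing=phasing,
        enrichment_normalized=enrichment_normalized,
        long_short=long_short,
    )
    report.notes.extend(notes_extra)
    report.provenance["samples"] = {
        sid: t.condition for sid, t in tables.items()
    }
    report.provenance["version"] = __version__
    return report


# ---------------------------------------------------------------------------
# in-memory experiment analysis (simulate -> count -> stats)


def analyze_experiment(
    design: ExperimentDesign,
    configs: dict[str, SimulationConfig],
    ref: ReferenceSequence | None = None,
    trigger: Region = TRIGGER_MIDGFP,
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> SignatureReport:
    """Simulate, count and classify without touching the filesystem."""
    params = params or AnalysisParams()
    ref = ref or default_reference()
    regions = [trigger] + derive_flanks(trigger, ref.length)
    window = next(iter(configs.values())).length_window
    index = ReferenceIndex(ref, window)
    all_reads = simulate_experiment_reads(design, configs, ref, trigger, seed)
    tables: dict[str, SizeClassTable] = {}
    mapped_target: list = []
    for spec in design.samples:
        table, mapped = count_by_size_and_region(
            all_reads[spec.sample_id],
            ref,
            regions,
            count_range=window,
            length_window=window,
            sample_id=spec.sample_id,
            condition=spec.condition,
            index=index,
            collect_mapped=True,
        )
        tables[spec.sample_id] = table
        if spec.condition == "target_ds":
            mapped_target.extend(mapped)
    phasing = [
        phasing_score(mapped_target, trigger, register_length=L)
        for L in (21, 22)
    ]
    report = analyze_tables(tables, params, phasing=phasing)
    report.provenance["seed"] = seed
    return report


# ---------------------------------------------------------------------------
# config-driven pipeline


@dataclass
class RunConfig:
    """Validated run configuration (see ``validate_config``)."""

    outdir: Path
    seed: int = 0
    mode: str = "simulate"  # or "fastq"
    scenario: str = "negative"  # simulate mode: negative | positive
    n_reads: int = 50_000
    reference: Path | None = None
    trigger: Region = TRIGGER_MIDGFP
    adapter: str | None = None
    samples: list[dict] = field(default_factory=list)  # fastq mode
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        validate_config(raw)
        trigger_raw = raw.get("trigger")
        trigger = (
            Region(
                trigger_raw.get("name", "trigger"),
                trigger_raw["start"],
                trigger_raw["end"],
            )
            if trigger_raw
            else TRIGGER_MIDGFP
        )
        analysis = raw.get("analysis", {})
        params = AnalysisParams(
            **{k: v for k, v in analysis.items() if k in AnalysisParams.__dataclass_fields__}
        )
        simulation = raw.get("simulation", {})
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            mode=raw.get("mode", "simulate"),
            scenario=simulation.get("scenario", "negative"),
            n_reads=int(simulation.get("n_reads", 50_000)),
            reference=Path(raw["reference"]) if raw.get("reference") else None,
            trigger=trigger,
            adapter=raw.get("adapter"),
            samples=raw.get("samples", []),
            params=params,
        )


def validate_config(raw: dict) -> None:
    """Schema-style validation: fail before any compute, naming the key."""
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    if "outdir" not in raw:
        raise ConfigError("missing required key 'outdir'")
    mode = raw.get("mode", "simulate")
    if mode not in ("simulate", "fastq"):
        raise ConfigError(f"mode: expected 'simulate' or 'fastq', got {mode!r}")
    if mode == "fastq":
        samples = raw.get("samples")
        if not samples:
            raise ConfigError("samples: required in fastq mode")
        for i, entry in enumerate(samples):
            for key in ("sample_id", "condition", "fastq"):
                if key not in entry:
                    raise ConfigError(f"samples[{i}]: missing {key!r}")
    simulation = raw.get("simulation", {})
    if simulation.get("scenario", "negative") not in ("negative", "positive"):
        raise ConfigError("simulation.scenario: expected 'negative' or 'positive'")
    trigger = raw.get("trigger")
    if trigger is not None:
        if "start" not in trigger or "end" not in trigger:
            raise ConfigError("trigger: needs 'start' and 'end'")
    analysis = raw.get("analysis", {})
    alpha = analysis.get("alpha", 0.05)
    if not 0 < alpha < 1:
        raise ConfigError("analysis.alpha: must be in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the report body (also written to
    ``outdir/report.json`` with per-analysis TSVs alongside)."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}

    # --- reference ---------------------------------------------------
    try:
        if config.reference is not None:
            ref = read_fasta(config.reference)
            digests[str(config.reference)] = _sha256(config.reference)
        else:
            ref = default_reference()
    except FileNotFoundError as exc:
        raise StageError("reference", f"cannot read {config.reference}: {exc}")
    trigger = config.trigger
    regions = [trigger] + derive_flanks(trigger, ref.length)
    window = DEFAULT_LENGTH_WINDOW

    # --- reads -------------------------------------------------------
    logger.info("stage reads: mode=%s", config.mode)
    raw_reads: dict[str, list] = {}
    conditions: dict[str, str] = {}
    if config.mode == "simulate":
        design = default_design()
        scenario = (
            negative_scenario_configs(config.n_reads)
            if config.scenario == "negative"
            else positive_scenario_configs(config.n_reads)
        )
        raw_reads = simulate_experiment_reads(
            design, scenario, ref, trigger, config.seed
        )
        conditions = {s.sample_id: s.condition for s in design.samples}
    else:
        for entry in config.samples:
            path = Path(entry["fastq"])
            if not path.exists():
                raise StageError("reads", f"FASTQ not found: {path}")
            raw_reads[entry["sample_id"]] = read_fastq(path)
            conditions[entry["sample_id"]] = entry["condition"]
            digests[str(path)] = _sha256(path)
        design = ExperimentDesign(
            tuple(
                SampleSpec(sid, cond, i + 1)
                for i, (sid, cond) in enumerate(conditions.items())
            )
        )

    # --- trim + filter + count ---------------------------------------
    index = ReferenceIndex(ref, window)
    tables: dict[str, SizeClassTable] = {}
    mapped_by_sample: dict[str, list] = {}
    qc_rows = []
    for sample_id, reads in raw_reads.items():
        total = len(reads)
        if config.adapter:
            reads = [
                trimmed
                for read in reads
                if (trimmed := trim_adapter(read, config.adapter)) is not None
            ]
        reads, discards = filter_by_length(reads, *window)
        histogram = {L: 0 for L in range(window[0], window[1] + 1)}
        for read in reads:
            histogram[read.length] += 1
        for L, n in histogram.items():
            qc_rows.append({"sample": sample_id, "length": L, "count": n})
        table, mapped = count_by_size_and_region(
            reads,
            ref,
            regions,
            count_range=window,
            length_window=window,
            sample_id=sample_id,
            condition=conditions[sample_id],
            total_reads=total,
            index=index,
            collect_mapped=True,
        )
        logger.info(
            "sample %s: %d reads, %d mapped, %d ambiguous, discards=%s",
            sample_id, total, table.mapped_reads, table.ambiguous, discards,
        )
        tables[sample_id] = table
        mapped_by_sample[sample_id] = mapped
        table.to_tsv(outdir / f"counts_{sample_id}.tsv")

    # --- statistics --------------------------------------------------
    mapped_target = [
        m
        for sid, ms in mapped_by_sample.items()
        if conditions[sid] == "target_ds"
        for m in ms
    ]
    phasing = [
        phasing_score(mapped_target, trigger, register_length=L) for L in (21, 22)
    ]
    try:
        report = analyze_tables(tables, config.params, phasing=phasing)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context for any failure
        raise StageError("stats", str(exc))

    # --- per-figure outputs ------------------------------------------
    report.enrichment_raw.to_frame().to_csv(
        outdir / "fig2a_raw.tsv", sep="\t", index=False
    )
    if report.enrichment_normalized is not None:
        pd.DataFrame(
            [
                {
                    "orientation": rec["orientation"],
                    "length": rec.get("length"),
                    "condition": rec.get("condition"),
                    "f_statistic": rec["f_statistic"],
                    "p_value": rec["p_value"],
                    "letters": json.dumps(rec["letters"]),
                }
                for rec in report.enrichment_normalized
            ]
        ).to_csv(outdir / "fig2b_normalized.tsv", sep="\t", index=False)
    profile_rows = []
    for sample_id, mapped in mapped_by_sample.items():
        profile = sliding_window_profile(
            mapped, ref.length, config.params.window,
            total_reads=tables[sample_id].total_reads,
        )
        for position, value in enumerate(profile, start=1):
            profile_rows.append(
                {"sample": sample_id, "position": position, "coverage": value}
            )
    pd.DataFrame(profile_rows).to_csv(
        outdir / "fig3_profiles.tsv", sep="\t", index=False
    )
    transitivity_frame = pd.DataFrame(
        [
            {
                "sample": sid,
                "antisense_flank": report.transitivity.antisense_flank_counts.get(sid),
                "sense_flank": report.transitivity.sense_flank_counts.get(sid),
            }
            for sid in tables
        ]
    )
    transitivity_frame.to_csv(outdir / "transitivity.tsv", sep="\t", index=False)
    pd.DataFrame(qc_rows).to_csv(outdir / "qc_lengths.tsv", sep="\t", index=False)

    body = {
        "signature": report.to_dict(),
        "qc": {
            sid: {
                "total_reads": t.total_reads,
                "mapped_reads": t.mapped_reads,
                "ambiguous": t.ambiguous,
                "unmapped": t.unmapped,
                "mir159_reads": t.mir159_reads,
            }
            for sid, t in tables.items()
        },
        "config": {
            "mode": config.mode,
            "scenario": config.scenario if config.mode == "simulate" else None,
            "seed": config.seed,
            "n_reads": config.n_reads,
            "trigger": asdict(config.trigger),
            "alpha": config.params.alpha,
            "window": config.params.window,
        },
        "input_digests": digests,
        "version": __version__,
    }
    (outdir / "report.json").write_text(json.dumps(body, indent=2, sort_keys=True))
    logger.info("classification: %s", report.classification)
    return body
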