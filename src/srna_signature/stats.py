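"""Statistical battery for the DCL-processing vs. degradation question.

Given size-class count tables for the three conditions (reporter line +
dsRNA, wild type + dsRNA, reporter + water), this module asks whether
the sprayed dsRNA shows any fingerprint of the RNAi machinery:

* size-class enrichment of 21/22/24-nt reads in the reporter line over
  the wild type (raw per-length Student t; control-normalized one-way
  ANOVA with Bonferroni post test and compact letter display);
* transitivity — antisense reads in the regions flanking the trigger,
  against a Poisson background estimated from the wild type, which
  cannot produce secondary siRNAs;
* phasing — over-occupancy of a fixed 5'-end register inside the
  trigger;
* an exponential length-decay fit, whose quality is the positive
  evidence for plain degradation;
* a Fisher exact test comparing the long/short read ratio inside vs.
  outside the trigger (exogenous dsRNA decay vs. endogenous mRNA decay).

The verdict is DCL_PROCESSED if any silencing fingerprint is present,
DEGRADATION_ONLY if none is and the decay fits are clean, else
INCONCLUSIVE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigError,
    InsufficientDataError,
    NormalizationError,
    SrnaSignatureError,
)
from .readproc import MappedRead, SizeClassTable
from .sequences import ANTISENSE, SENSE, Region

SILENCING_SIZES = (21, 22, 24)

DCL_PROCESSED = "DCL_PROCESSED"
DEGRADATION_ONLY = "DEGRADATION_ONLY"
INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class AnalysisParams:
    window: int = 10
    alpha: float = 0.05
    size_classes: tuple[int, ...] = (20, 21, 22, 23, 24, 25)
    silencing_sizes: tuple[int, ...] = SILENCING_SIZES
    decay_fit_range: tuple[int, int] = (17, 29)
    decay_r_threshold: float = 0.9
    min_transitivity_reads: int = 5

    def __post_init__(self):
        if self.window < 1:
            raise ConfigError("window must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


# ---------------------------------------------------------------------------
# length-decay fit


@dataclass
class DecayFit:
    """OLS of ln(count) on read length over nonzero lengths.

    ``rate`` is the slope (negative for decay); ``pearson_r`` the
    correlation of log-counts with length (sign kept); ``pearson_r_raw``
    the same on the raw counts, since either reading of an "R" fit
    quality is defensible.
    """

    rate: float
    intercept: float
    pearson_r: float
    pearson_r_raw: float
    n_points: int
    excluded_zero_lengths: int

    def to_dict(self) -> dict:
        return {
            "rate": self.rate,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "pearson_r_raw": self.pearson_r_raw,
            "n_points": self.n_points,
            "excluded_zero_lengths": self.excluded_zero_lengths,
        }


def fit_length_decay(
    counts: dict[int, float], fit_range: tuple[int, int] = (17, 29)
) -> DecayFit:
    """Exponential decay fit of a read-length histogram.

    Zero-count lengths cannot enter a log regression; they are excluded
    and their number reported.
    """
    lo, hi = fit_range
    pairs = [
        (L, n) for L, n in sorted(counts.items()) if lo <= L <= hi and n > 0
    ]
    excluded = sum(1 for L, n in counts.items() if lo <= L <= hi and n <= 0)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"decay fit needs >= 3 nonzero lengths in [{lo}, {hi}], "
            f"got {len(pairs)}"
        )
    lengths = np.array([p[0] for p in pairs], dtype=float)
    values = np.array([p[1] for p in pairs], dtype=float)
    logs = np.log(values)
    if np.allclose(logs, logs[0]):
        return DecayFit(0.0, float(logs[0]), 0.0, 0.0, len(pairs), excluded)
    fit = sps.linregress(lengths, logs)
    r_raw = float(np.corrcoef(lengths, values)[0, 1])
    return DecayFit(
        rate=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        pearson_r_raw=r_raw,
        n_points=len(pairs),
        excluded_zero_lengths=excluded,
    )


# ---------------------------------------------------------------------------
# per-length group comparisons


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student t. Degenerate zero-variance
    inputs: equal means -> (0, 1); unequal -> (+-inf, 0)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=0) == 0 and b.var(ddof=0) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class EnrichmentResult:
    """Per-length comparison of two groups (e.g. 16C-ds vs WT-ds)."""

    method: str
    group_a: str
    group_b: str
    alpha: float
    records: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def significant_enriched(self, sizes: Sequence[int] | None = None) -> list[int]:
        out = []
        for rec in self.records:
            if sizes is not None and rec["length"] not in sizes:
                continue
            if rec["significant"] and rec["direction"] == "enriched":
                out.append(rec["length"])
        return out

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "alpha": self.alpha,
            "records": self.records,
        }


def compare_size_classes_raw(
    group_a: dict[int, Sequence[float]],
    group_b: dict[int, Sequence[float]],
    alpha: float = 0.05,
    label_a: str = "target_ds",
    label_b: str = "wildtype_ds",
) -> EnrichmentResult:
    """Raw per-length Student t between two replicate groups.

    No multiplicity correction: the per-length annotation style of the
    figure this mirrors tests each size class on its own. Direction is
    enrichment/depletion of group A relative to group B.
    """
    result = EnrichmentResult("student_t_raw", label_a, label_b, alpha)
    for length in sorted(set(group_a) & set(group_b)):
        a, b = list(group_a[length]), list(group_b[length])
        if len(a) < 2 or len(b) < 2:
            raise InsufficientDataError(
                f"need >= 2 replicates per group at length {length}"
            )
        t, p = pooled_t_test(a, b)
        diff = float(np.mean(a) - np.mean(b))
        significant = bool(p < alpha)
        direction = "none"
        if diff > 0:
            direction = "enriched"
        elif diff < 0:
            direction = "depleted"
        result.records.append(
            {
                "length": length,
                "mean_a": float(np.mean(a)),
                "mean_b": float(np.mean(b)),
                "statistic": t,
                "p_value": p,
                "significant": significant,
                "direction": direction if p < 1 else "none",
            }
        )
    return result


def normalize_to_control(
    counts: dict[int, float], control: dict[int, float]
) -> tuple[dict[int, float], set[int]]:
    """Element-wise ratio to a control sample's counts.

    Control zeros yield NaN cells, returned in the flagged set; an
    all-zero control is a hard error.
    """
    if all(v == 0 for v in control.values()):
        raise NormalizationError("control counts are all zero")
    ratios: dict[int, float] = {}
    undefined: set[int] = set()
    for length, value in counts.items():
        denom = control.get(length, 0)
        if denom == 0:
            ratios[length] = float("nan")
            undefined.add(length)
        else:
            ratios[length] = value / denom
    return ratios, undefined


def _compact_letter_display(
    means: dict[str, float], distinct: set[tuple[str, str]]
) -> dict[str, str]:
    """Letters such that two groups share one iff not significantly
    different; maximal cliques of the 'not distinct' graph, ordered by
    descending clique mean."""
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(means)
    for a in means:
        for b in means:
            if a < b and (a, b) not in distinct and (b, a) not in distinct:
                graph.add_edge(a, b)
    cliques = list(nx.find_cliques(graph))
    cliques.sort(key=lambda c: -np.mean([means[g] for g in c]))
    letters: dict[str, str] = {g: "" for g in means}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for g in clique:
            letters[g] += letter
    return {g: "".join(sorted(s)) for g, s in letters.items()}


def one_way_anova_cld(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> dict:
    """One-way ANOVA plus Bonferroni pairwise t post test with a compact
    letter display."""
    if len(groups) < 2:
        raise InsufficientDataError("ANOVA needs >= 2 groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise InsufficientDataError(
                f"ANOVA needs >= 2 replicates per group ({name!r})"
            )
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if all(a.var(ddof=0) == 0 for a in arrays.values()) and (
        len({a.mean() for a in arrays.values()}) == 1
    ):
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = sps.f_oneway(*arrays.values())
    names = sorted(arrays)
    n_pairs = len(names) * (len(names) - 1) // 2
    adjusted_alpha = alpha / max(n_pairs, 1)
    distinct: set[tuple[str, str]] = set()
    pairwise = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            t, p = pooled_t_test(arrays[a], arrays[b])
            is_distinct = p < adjusted_alpha
            if is_distinct:
                distinct.add((a, b))
            pairwise.append(
                {"a": a, "b": b, "statistic": t, "p_value": p,
                 "distinct": bool(is_distinct)}
            )
    means = {k: float(a.mean()) for k, a in arrays.items()}
    return {
        "f_statistic": float(f_stat),
        "p_value": float(p_value),
        "means": means,
        "pairwise": pairwise,
        "letters": _compact_letter_display(means, distinct),
        "adjusted_alpha": adjusted_alpha,
    }


def compare_normalized_anova(
    data: dict[str, dict[int, Sequence[float]]],
    alpha: float = 0.05,
    orientation: str = "between_conditions",
) -> list[dict]:
    """ANOVA over control-normalized ratios, in either orientation.

    ``between_conditions``: for each length, compare conditions (one
    record per length). ``across_lengths``: for each condition, compare
    lengths (one record per condition) — the orientation in which a
    depleted size class stands out against its neighbours. Both are
    computed by the pipeline and labelled, since either reading of the
    published comparison is defensible.
    """
    records = []
    if orientation == "between_conditions":
        lengths = sorted({L for d in data.values() for L in d})
        for L in lengths:
            groups = {cond: data[cond][L] for cond in data if L in data[cond]}
            groups = {
                k: [x for x in v if not math.isnan(x)] for k, v in groups.items()
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            rec = one_way_anova_cld(groups, alpha)
            rec["length"] = L
            rec["orientation"] = orientation
            records.append(rec)
    elif orientation == "across_lengths":
        for cond, by_length in data.items():
            groups = {
                str(L): [x for x in v if not math.isnan(x)]
                for L, v in by_length.items()
            }
            groups = {k: v for k, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                continue
            rec = one_way_anova_cld(groups, alpha)
            rec["condition"] = cond
            rec["orientation"] = orientation
            records.append(rec)
    else:
        raise ConfigError(f"unknown orientation {orientation!r}")
    return records


# ---------------------------------------------------------------------------
# positional statistics


def sliding_window_profile(
    mapped: Sequence[MappedRead] | np.ndarray,
    ref_length: int,
    window: int = 10,
    total_reads: int | None = None,
) -> np.ndarray:
    """Per-position normalized coverage of biological 5' ends.

    Value at p = mean per-position 5'-end count over the window centred
    at p (shrunk at the reference edges), divided by the sample's total
    read count. Output has one value per reference position.
    """
    if window < 1:
        raise ConfigError("window must be >= 1")
    if isinstance(mapped, np.ndarray):
        positions = mapped.astype(int)
    else:
        positions = np.array([m.five_prime for m in mapped], dtype=int)
    if total_reads is None:
        total_reads = len(positions)
    if total_reads <= 0:
        raise InsufficientDataError("total read count must be > 0")
    counts = np.bincount(positions, minlength=ref_length + 1)[1:].astype(float)
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    pos = np.arange(1, ref_length + 1)
    lo = np.maximum(1, pos - (window - 1) // 2)
    hi = np.minimum(ref_length, pos + window // 2)
    sums = csum[hi] - csum[lo - 1]
    return sums / (hi - lo + 1) / total_reads


@dataclass
class TransitivityResult:
    antisense_flank_counts: dict[str, int]
    sense_flank_counts: dict[str, int]
    background_rate: float
    observed_total: int
    p_value: float
    verdict: bool
    min_reads_floor: int

    def to_dict(self) -> dict:
        return {
            "antisense_flank_counts": self.antisense_flank_counts,
            "sense_flank_counts": self.sense_flank_counts,
            "background_rate": self.background_rate,
            "observed_total": self.observed_total,
            "p_value": self.p_value,
            "verdict": self.verdict,
            "min_reads_floor": self.min_reads_floor,
        }


def detect_transitivity(
    tables: Sequence[SizeClassTable],
    flank_names: Sequence[str] = ("flank5", "flank3"),
    alpha: float = 0.05,
    min_reads: int = 5,
) -> TransitivityResult:
    """Antisense flank reads in the reporter line vs. a wild-type Poisson
    background.

    Wild-type samples carry no target transcript, so their antisense
    flank counts (expected zero) estimate the spray/degradation
    background. The verdict requires both a significant exceedance and a
    mean of at least ``min_reads`` antisense flank reads per reporter
    sample — one or two stray reads never count as transitivity. Sense
    flank reads are mRNA decay and never contribute.
    """
    target = [t for t in tables if t.condition == "target_ds"]
    control = [t for t in tables if t.condition == "wildtype_ds"]
    if not target or not control:
        raise InsufficientDataError(
            "transitivity needs target_ds samples and wildtype_ds controls"
        )

    def flank_count(table: SizeClassTable, strand: str) -> int:
        return sum(table.region_strand_total(f, strand) for f in flank_names)

    anti = {t.sample_id: flank_count(t, ANTISENSE) for t in target}
    anti.update({t.sample_id: flank_count(t, ANTISENSE) for t in control})
    sense = {
        t.sample_id: flank_count(t, SENSE) for t in list(target) + list(control)
    }
    background_rate = float(
        np.mean([flank_count(t, ANTISENSE) for t in control])
    )
    observed = int(sum(flank_count(t, ANTISENSE) for t in target))
    mu = background_rate * len(target)
    if observed == 0:
        p_value = 1.0
    elif mu == 0:
        p_value = 0.0
    else:
        p_value = float(sps.poisson.sf(observed - 1, mu))
    mean_target = observed / len(target)
    verdict = bool(p_value < alpha and mean_target >= min_reads)
    return TransitivityResult(
        antisense_flank_counts=anti,
        sense_flank_counts=sense,
        background_rate=background_rate,
        observed_total=observed,
        p_value=p_value,
        verdict=verdict,
        min_reads_floor=min_reads,
    )


@dataclass
class PhasingResult:
    register_length: int
    score: float
    p_value: float | None
    n_reads: int
    best_offset: int

    def to_dict(self) -> dict:
        return {
            "register_length": self.register_length,
            "score": self.score,
            "p_value": self.p_value,
            "n_reads": self.n_reads,
            "best_offset": self.best_offset,
        }


def phasing_score(
    mapped: Sequence[MappedRead],
    trigger: Region,
    register_length: int = 22,
    min_reads: int = 10,
) -> PhasingResult:
    """Register occupancy inside the trigger.

    Registers live on sense coordinates: every read of the register
    length collapses to its leftmost reference base, so the two strands
    of a diced duplex (whose 2-nt overhangs are not modelled here) share
    one offset. Score is the maximal fraction of reads sharing one phase
    offset (mod register length). The p-value is a binomial test of that
    offset's occupancy against its expectation under uniform placement,
    Bonferroni-corrected for the register_length offsets searched. The
    null probability accounts for the finite trigger (valid placements
    are not equidistributed across offsets unless the register divides
    the trigger length evenly). Below ``min_reads`` eligible reads the
    score is still reported but the p-value is suppressed as
    underpowered.
    """
    L = register_length
    eligible = [
        m for m in mapped
        if m.length == L and trigger.contains(m.start)
    ]
    n = len(eligible)
    if n == 0:
        return PhasingResult(L, 0.0, None, 0, 0)
    offsets = np.array([(m.start - trigger.start) % L for m in eligible])
    observed = np.bincount(offsets, minlength=L)

    # valid left-end placements per offset under uniform placement
    n_places = trigger.length - L + 1
    left_ends = np.arange(trigger.start, trigger.end - L + 2)
    m_left = np.bincount((left_ends - trigger.start) % L, minlength=L)
    null_probs = m_left / n_places

    best = int(np.argmax(observed))
    score = float(observed[best] / n)
    if n < min_reads:
        return PhasingResult(L, score, None, n, best)
    tail = sps.binomtest(
        int(observed[best]), n, float(null_probs[best]), alternative="greater"
    ).pvalue
    p_value = float(min(1.0, tail * L))
    return PhasingResult(L, score, p_value, n, best)


@dataclass
class LongShortResult:
    odds_ratio: float | None
    p_value: float
    table: list[list[int]]

    def to_dict(self) -> dict:
        return {
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
            "table": self.table,
        }


def long_short_ratio_test(
    table: SizeClassTable,
    inside_names: Sequence[str] = ("trigger",),
    outside_names: Sequence[str] = ("flank5", "flank3"),
    length_cut: int = 24,
) -> LongShortResult:
    """Fisher exact test: long (>24 nt) vs short (<25 nt) reads, outside
    vs inside the trigger.

    The 2x2 table is oriented (outside, inside) x (long, short), so an
    odds ratio > 1 means long reads are over-represented outside the
    trigger — degradation of the endogenous transcript runs flatter than
    decay of the sprayed dsRNA. A zero row or column leaves the odds
    ratio undefined and p = 1.
    """

    def split(region_names) -> tuple[int, int]:
        long = short = 0
        for (region, _strand, length), n in table.counts.items():
            if region not in region_names:
                continue
            if length > length_cut:
                long += n
            else:
                short += n
        return long, short

    long_out, short_out = split(tuple(outside_names))
    long_in, short_in = split(tuple(inside_names))
    contingency = [[long_out, short_out], [long_in, short_in]]
    rows = [long_out + short_out, long_in + short_in]
    cols = [long_out + long_in, short_out + short_in]
    if 0 in rows or 0 in cols:
        return LongShortResult(None, 1.0, contingency)
    odds, p = sps.fisher_exact(contingency, alternative="two-sided")
    cross = (
        (long_out * short_in) / (short_out * long_in)
        if short_out * long_in > 0
        else math.inf
    )
    return LongShortResult(float(cross), float(p), contingency)


def functional_normalize(
    counts: dict[int, float], reference_count: float, scheme: str
) -> dict[int, float]:
    """Divide counts by a functional denominator.

    ``mir159``: reads mapping to the miR159 reference; ``all_24nt``: the
    sample's total 24-nt read count — both are products of the same
    dicing machinery, so they track how much RNAi throughput the sample
    had, independent of spray efficiency.
    """
    if scheme not in ("mir159", "all_24nt"):
        raise ConfigError(f"unknown normalization scheme {scheme!r}")
    if reference_count <= 0:
        raise NormalizationError(
            f"zero denominator for functional normalization scheme {scheme!r}"
        )
    return {L: v / reference_count for L, v in counts.items()}


# ---------------------------------------------------------------------------
# verdict


@dataclass
class SignatureReport:
    classification: str
    enrichment_raw: EnrichmentResult
    transitivity: TransitivityResult
    decay_fits: dict[str, DecayFit]
    pooled_decay_fits: dict[str, DecayFit]
    phasing: list[PhasingResult] | None
    enrichment_normalized: list[dict] | None = None
    long_short: LongShortResult | None = None
    params: AnalysisParams | None = None
    provenance: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "enrichment_raw": self.enrichment_raw.to_dict(),
            "transitivity": self.transitivity.to_dict(),
            "decay_fits": {k: f.to_dict() for k, f in self.decay_fits.items()},
            "pooled_decay_fits": {
                k: f.to_dict() for k, f in self.pooled_decay_fits.items()
            },
            "phasing": [p.to_dict() for p in self.phasing] if self.phasing else None,
            "enrichment_normalized": self.enrichment_normalized,
            "long_short": self.long_short.to_dict() if self.long_short else None,
            "params": self.params.__dict__ if self.params else None,
            "provenance": self.provenance,
            "notes": self.notes,
        }


def classify_signature(
    enrichment_raw: EnrichmentResult,
    transitivity: TransitivityResult,
    decay_fits: dict[str, DecayFit],
    pooled_decay_fits: dict[str, DecayFit],
    params: AnalysisParams,
    phasing: list[PhasingResult] | None = None,
    **extras,
) -> SignatureReport:
    """Combine sub-results into a verdict.

    DCL_PROCESSED iff a silencing size (21/22/24 nt) is significantly
    *enriched* in the reporter line over the wild type, or transitivity
    is detected, or a phasing register is significant (Bonferroni over
    the registers tested). Otherwise DEGRADATION_ONLY requires a clean
    exponential decay (pooled |r| above threshold) in every dsRNA-
    sprayed condition; the per-sample fits are reported but the gate
    pools replicates within condition, where the fixture-scale length
    window (a handful of points per sample) makes single-replicate
    correlations noisy. Anything else is INCONCLUSIVE.
    """
    missing = [
        name
        for name, value in (
            ("enrichment_raw", enrichment_raw),
            ("transitivity", transitivity),
            ("pooled_decay_fits", pooled_decay_fits),
        )
        if value is None or (name == "pooled_decay_fits" and not value)
    ]
    if missing:
        raise SrnaSignatureError(f"missing sub-results: {missing}")
    if not enrichment_raw.records:
        raise SrnaSignatureError("enrichment result holds no length records")

    notes = []
    enriched = enrichment_raw.significant_enriched(params.silencing_sizes)
    phasing_hit = False
    if phasing:
        tested = [p for p in phasing if p.p_value is not None]
        phase_alpha = params.alpha / max(len(tested), 1)
        phasing_hit = any(p.p_value < phase_alpha for p in tested)
    else:
        notes.append("phasing not assessed (no positional data)")

    if enriched or transitivity.verdict or phasing_hit:
        classification = DCL_PROCESSED
        if enriched:
            notes.append(f"silencing-size enrichment at {enriched} nt")
        if transitivity.verdict:
            notes.append("antisense flank (transitive) signal detected")
        if phasing_hit:
            notes.append("phased register occupancy significant")
    else:
        clean_decay = all(
            abs(fit.pearson_r) >= params.decay_r_threshold
            for fit in pooled_decay_fits.values()
        )
        if clean_decay:
            classification = DEGRADATION_ONLY
            notes.append(
                "no silencing fingerprint; pooled decay fits "
                f"|r| >= {params.decay_r_threshold} in all dsRNA conditions"
            )
        else:
            classification = INCONCLUSIVE
            notes.append(
                "no silencing fingerprint, but decay fits below the "
                "degradation threshold"
            )
    return SignatureReport(
        classification=classification,
        enrichment_raw=enrichment_raw,
        transitivity=transitivity,
        decay_fits=decay_fits,
        pooled_decay_fits=pooled_decay_fits,
        phasing=phasing,
        params=params,
        notes=notes,
        **extras,
    )
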