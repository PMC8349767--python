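"""Statistical comparison of periodicity strength between mutation cohorts.

Aggregate cohorts are compared with a count-preserving label permutation
test: mutation records are pooled, labels reshuffled keeping each
pseudo-cohort at its original size, and the full pipeline (count ->
optional normalization -> periodogram -> SNR) is recomputed per replicate.
Per-tumor SNR distributions are compared with a Wilcoxon rank-sum test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import counting, normalization
from .errors import NucperiodError
from .genomic_io import DyadPosition, GenomeSequence, MutationRecord
from .normalization import ContextFrequencyMatrix
from .periodicity import AnalysisConfig, run_periodicity_analysis
from .stratification import Cohort, subsample_to_match

logger = logging.getLogger(__name__)

NORMALIZATION_MODES = ("none", "trinuc")


def aggregate_snr(
    mutations: Sequence[MutationRecord],
    dyads: Sequence[DyadPosition],
    config: AnalysisConfig,
    genome: GenomeSequence | None = None,
    normalization_mode: str = "none",
    context_freqs: ContextFrequencyMatrix | None = None,
    background: counting.DyadRelativeCounts | None = None,
) -> float:
    """SNR of one mutation set: count, optionally normalize, fit, score.

    ``mutations`` must be coordinate-sorted.  The trinucleotide context
    frequency matrix depends only on the dyads and genome, so callers
    running many replicates over the same map should build it once and pass
    it in.
    """
    counts = counting.map_mutations_to_dyads(mutations, dyads, config.radius, genome)
    if normalization_mode == "trinuc":
        if genome is None:
            raise ValueError("trinucleotide normalization requires a genome")
        if context_freqs is None:
            context_freqs = normalization.build_context_frequencies(
                genome, dyads, config.radius
            )
        mapped = counting.filter_mapped(mutations, dyads, config.radius, genome)
        rates = normalization.estimate_context_rates(mapped, context_freqs, genome)
        data: counting.DyadRelativeCounts | normalization.NormalizedCounts = (
            normalization.normalize_counts(counts, context_freqs, rates)
        )
    elif normalization_mode == "background":
        if background is None:
            raise ValueError("background normalization requires background counts")
        data = normalization.normalize_counts(counts, background=background)
    elif normalization_mode == "none":
        data = counts
    else:
        raise ValueError(f"unknown normalization mode {normalization_mode!r}")
    pg = run_periodicity_analysis(data, config)
    assert pg.snr is not None
    return pg.snr


@dataclass
class CohortComparison:
    """Observed SNR difference between two cohorts and its permutation null."""

    label_a: str
    label_b: str
    snr_a: float
    snr_b: float
    observed_diff: float
    null_diffs: np.ndarray
    n_permutations: int
    p_value: float
    seed: int


def permutation_test_aggregate(
    cohort_a: Cohort,
    cohort_b: Cohort,
    dyads: Sequence[DyadPosition],
    config: AnalysisConfig,
    n_perm: int = 100,
    seed: int = 0,
    genome: GenomeSequence | None = None,
    normalization_mode: str = "none",
) -> CohortComparison:
    """Count-preserving label-permutation test of the SNR difference.

    Pools both cohorts' mutations and, per replicate, assigns |A| records to
    pseudo-A and the rest to pseudo-B uniformly at random, recomputing the
    full pipeline for each pseudo-cohort.  The one-sided p-value uses the
    add-one convention p = (1 + #{null >= observed}) / (1 + n_perm), so 100
    permutations with zero exceedances give p = 1/101 < 0.01.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not cohort_a.mutations or not cohort_b.mutations:
        raise ValueError("both cohorts must contain mutations")
    context_freqs = None
    if normalization_mode == "trinuc":
        if genome is None:
            raise ValueError("trinucleotide normalization requires a genome")
        context_freqs = normalization.build_context_frequencies(genome, dyads, config.radius)

    def snr_of(records: list[MutationRecord]) -> float:
        return aggregate_snr(
            records, dyads, config, genome, normalization_mode, context_freqs
        )

    sort_key = lambda m: (m.chrom, m.pos)
    snr_a = snr_of(sorted(cohort_a.mutations, key=sort_key))
    snr_b = snr_of(sorted(cohort_b.mutations, key=sort_key))
    observed = snr_a - snr_b

    pooled = sorted(cohort_a.mutations + cohort_b.mutations, key=sort_key)
    n_a, n_total = len(cohort_a), len(pooled)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_total)
        a_idx = np.sort(perm[:n_a])
        b_idx = np.sort(perm[n_a:])
        # subsets of a sorted pool stay sorted
        pseudo_a = [pooled[int(j)] for j in a_idx]
        pseudo_b = [pooled[int(j)] for j in b_idx]
        null[i] = snr_of(pseudo_a) - snr_of(pseudo_b)
    p = (1 + int(np.sum(null >= observed))) / (1 + n_perm)
    return CohortComparison(
        cohort_a.label, cohort_b.label, snr_a, snr_b, observed, null, n_perm, p, seed
    )


def rank_sum_test(
    snrs_a: Sequence[float],
    snrs_b: Sequence[float],
    alternative: str = "two-sided",
) -> float:
    """Wilcoxon rank-sum (Mann-Whitney) p-value for per-tumor SNR samples.

    Exact enumeration for small tie-free samples (both n <= 20); otherwise
    the normal approximation with tie correction.  Samples that are entirely
    tied across both groups return p = 1 with a warning.
    """
    a = np.asarray(snrs_a, dtype=float)
    b = np.asarray(snrs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        warnings.warn("all values tied across both groups; rank-sum test is uninformative")
        return 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


@dataclass
class PeakPeriodSummary:
    """Location and spread of per-unit peak periods."""

    peak_periods: np.ndarray
    median: float
    sd: float
    iqr: float


def summarize_peak_periods(peak_periods: Sequence[float]) -> PeakPeriodSummary:
    """Median, sample SD (n-1 denominator) and IQR (linear-interpolation quartiles)."""
    values = np.asarray(peak_periods, dtype=float)
    if len(values) == 0:
        raise ValueError("at least one peak period is required")
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    q1, q3 = np.percentile(values, [25, 75])
    return PeakPeriodSummary(values, float(np.median(values)), sd, float(q3 - q1))


@dataclass
class MatchedSubsampleResult:
    """SNRs of count-matched subsamples of the larger cohort vs. the smaller's SNR."""

    replicate_snrs: np.ndarray
    reference_snr: float
    n_matched: int
    seed: int


def matched_subsample_comparison(
    larger_cohort: Cohort,
    smaller_cohort: Cohort,
    n_reps: int,
    dyads: Sequence[DyadPosition],
    config: AnalysisConfig,
    seed: int = 0,
    genome: GenomeSequence | None = None,
    normalization_mode: str = "none",
) -> MatchedSubsampleResult:
    """Re-run the pipeline on count-matched subsamples of the larger cohort.

    Controls for the SNR's dependence on mutation count when cohorts differ
    in size: each replicate subsamples the larger cohort down to the smaller
    cohort's count and recomputes the SNR.
    """
    if len(larger_cohort) <= len(smaller_cohort):
        raise ValueError("first cohort must be strictly larger than the second")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    context_freqs = None
    if normalization_mode == "trinuc":
        if genome is None:
            raise ValueError("trinucleotide normalization requires a genome")
        context_freqs = normalization.build_context_frequencies(genome, dyads, config.radius)
    sort_key = lambda m: (m.chrom, m.pos)
    n_match = len(smaller_cohort)
    reference = aggregate_snr(
        sorted(smaller_cohort.mutations, key=sort_key), dyads, config, genome,
        normalization_mode, context_freqs,
    )
    rng = np.random.default_rng(seed)
    snrs = np.empty(n_reps)
    for i in range(n_reps):
        sub = subsample_to_match(larger_cohort, n_match, int(rng.integers(0, 2**31 - 1)))
        snrs[i] = aggregate_snr(
            sorted(sub.mutations, key=sort_key), dyads, config, genome,
            normalization_mode, context_freqs,
        )
    return MatchedSubsampleResult(snrs, reference, n_match, seed)
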