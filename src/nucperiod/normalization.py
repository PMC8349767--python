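"""Trinucleotide-context and background normalization of dyad-relative counts.

Raw counts confound nucleosome biology with sequence composition: if a
mutable trinucleotide is itself periodically placed around dyads, raw counts
oscillate with no repair/damage signal at all.  Context normalization divides
observed counts by the expectation under position-independent per-context
mutation rates, leaving a rate ratio that is flat when composition alone
explains the counts.

Contexts are strand-collapsed to the 32 pyrimidine-centered trinucleotides
(standard in mutation-signature work); dyad maps carry no strand, so the two
strands are indistinguishable anyway.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .counting import DyadRelativeCounts
from .errors import NucperiodError
from .genomic_io import DyadPosition, GenomeSequence, MutationRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 32 pyrimidine-centered trinucleotide classes (C-centered block then
#: T-centered block, flanks in A<C<G<T order — matches the array layout).
PYRIMIDINE_CONTEXTS: tuple[str, ...] = tuple(
    l + c + r for c in "CT" for l in "ACGT" for r in "ACGT"
)
_CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(PYRIMIDINE_CONTEXTS)}

INVALID_CONTEXT = "invalid"

# base codes for vectorized context classification
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_trinucleotide(tri: str) -> str:
    """Collapse a raw 3-mer to its pyrimidine-centered class ("invalid" if not ACGT)."""
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        return INVALID_CONTEXT
    return tri if tri[1] in "CT" else reverse_complement(tri)


def trinucleotide_context(genome: GenomeSequence, chrom: str, pos: int) -> str:
    """Pyrimidine-collapsed trinucleotide centered on `pos` (0-based).

    Positions lacking a flank on either side are a boundary error; any N (or
    other ambiguity code) in the triplet yields the "invalid" sentinel.
    """
    if pos < 1 or pos > genome.chrom_length(chrom) - 2:
        raise ValueError(
            f"position {chrom}:{pos} lacks a flanking base; context undefined at chromosome edges"
        )
    return collapse_trinucleotide(genome.fetch(chrom, pos - 1, pos + 2))


@dataclass
class ContextFrequencyMatrix:
    """Counts of each collapsed context at each dyad offset, over all dyads.

    freq[c, p+radius] = number of dyad windows whose offset-p base sits in
    collapsed context c; columns sum to n_dyads minus the windows whose
    triplet at that offset contains an ambiguous base.
    """

    radius: int
    freq: np.ndarray  # shape (32, 2*radius+1)
    n_dyads: int
    n_invalid: np.ndarray  # per-offset tally of ambiguous-triplet windows

    @property
    def context_totals(self) -> np.ndarray:
        """Total occurrences of each context across all offsets and dyads."""
        return self.freq.sum(axis=1)


def _classify_window(codes: np.ndarray) -> np.ndarray:
    """Collapsed context index per center position of a code array (-1 invalid)."""
    left, center, right = codes[:-2], codes[1:-1], codes[2:]
    valid = (left >= 0) & (center >= 0) & (right >= 0)
    l = left.copy()
    c = center.copy()
    r = right.copy()
    # purine center (A=0, G=2) -> reverse complement the triplet
    pur = valid & ((c == 0) | (c == 2))
    l[pur], r[pur] = _COMP_CODE[r[pur] % 4], _COMP_CODE[l[pur] % 4]
    c[pur] = _COMP_CODE[c[pur] % 4]
    # collapsed index: center C->0, T->1; idx = center*16 + left*4 + right
    idx = np.where(valid, (c == 3).astype(np.int64) * 16 + l * 4 + r, -1)
    return idx


def build_context_frequencies(
    genome: GenomeSequence, dyads: Sequence[DyadPosition], radius: int
) -> ContextFrequencyMatrix:
    """Tally collapsed trinucleotide contexts at every offset of every dyad window.

    Dyads whose window plus 1-bp flanks leaves the chromosome are skipped
    (matching the counting stage's in-bounds rule).
    """
    size = 2 * radius + 1
    freq = np.zeros((32, size), dtype=np.int64)
    n_invalid = np.zeros(size, dtype=np.int64)
    n_used = 0
    cols = np.arange(size)
    for d in dyads:
        length = genome.chrom_length(d.chrom)
        if d.pos - radius - 1 < 0 or d.pos + radius + 2 > length:
            continue
        window = genome.fetch(d.chrom, d.pos - radius - 1, d.pos + radius + 2)
        codes = _BASE_CODE[np.frombuffer(window.encode("ascii"), dtype=np.uint8)]
        idx = _classify_window(codes)
        valid = idx >= 0
        np.add.at(freq, (idx[valid], cols[valid]), 1)
        n_invalid += ~valid
        n_used += 1
    return ContextFrequencyMatrix(radius, freq, n_used, n_invalid)


def fill_contexts(
    mutations: Sequence[MutationRecord], genome: GenomeSequence
) -> None:
    """Annotate each record's collapsed trinucleotide context in place."""
    for m in mutations:
        if m.context is None:
            if 1 <= m.pos <= genome.chrom_length(m.chrom) - 2:
                m.context = trinucleotide_context(genome, m.chrom, m.pos)
            else:
                m.context = INVALID_CONTEXT


def estimate_context_rates(
    mutations: Sequence[MutationRecord],
    context_freqs: ContextFrequencyMatrix,
    genome: GenomeSequence | None = None,
) -> dict[str, float]:
    """Per-context mutation rates from mutations inside the counted windows.

    rate[c] = (# mutations in context c) / (total occurrences of c over all
    dyad windows).  Callers must pass only mutations that lie within counted
    windows; mutations with an invalid context are excluded.  Contexts never
    seen in any window get rate 0 with a warning.
    """
    if genome is not None:
        fill_contexts(mutations, genome)
    mut_counts = np.zeros(32, dtype=np.int64)
    n_valid = 0
    for m in mutations:
        if m.context is None:
            raise NucperiodError(
                "mutation context not filled; pass a genome or call fill_contexts first"
            )
        i = _CONTEXT_INDEX.get(m.context)
        if i is not None:
            mut_counts[i] += 1
            n_valid += 1
    if n_valid == 0:
        raise NucperiodError("no mutations with a valid trinucleotide context")
    totals = context_freqs.context_totals
    rates = np.zeros(32, dtype=float)
    seen = totals > 0
    rates[seen] = mut_counts[seen] / totals[seen]
    if (~seen & (mut_counts > 0)).any():
        missing = [PYRIMIDINE_CONTEXTS[i] for i in np.nonzero(~seen & (mut_counts > 0))[0]]
        logger.warning("contexts with mutations but zero window occurrences: %s", missing)
    elif (~seen).any():
        logger.warning(
            "%d contexts never occur in dyad windows; their rates are 0", int((~seen).sum())
        )
    return {ctx: float(rates[i]) for i, ctx in enumerate(PYRIMIDINE_CONTEXTS)}


@dataclass
class NormalizedCounts:
    """Observed counts, composition-based expectation, and their ratio.

    expected is rescaled so that sum(expected) == sum(observed); normalized
    is NaN (and excluded downstream) where expected == 0.
    """

    radius: int
    observed: np.ndarray
    expected: np.ndarray
    normalized: np.ndarray
    n_mutations_mapped: int = 0

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.radius, self.radius + 1)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.normalized)


def normalize_counts(
    observed: DyadRelativeCounts,
    context_freqs: ContextFrequencyMatrix | None = None,
    rates: Mapping[str, float] | None = None,
    background: DyadRelativeCounts | None = None,
) -> NormalizedCounts:
    """Divide observed counts by a composition- or background-based expectation.

    Context mode (context_freqs + rates): expected[p] = sum_c rate[c] *
    freq[c, p].  Background mode: expected proportional to another dataset's
    counts at the same radius.  Either way expected is rescaled to conserve
    the observed total, so normalized values are dimensionless rate ratios
    around 1.
    """
    if (context_freqs is None) == (background is None):
        raise ValueError("provide exactly one of (context_freqs & rates) or background")
    obs = observed.counts.astype(float)
    if context_freqs is not None:
        if rates is None:
            raise ValueError("context mode requires per-context rates")
        if context_freqs.radius != observed.radius:
            raise ValueError("context frequency radius does not match counts radius")
        rate_vec = np.array([rates[c] for c in PYRIMIDINE_CONTEXTS])
        expected = rate_vec @ context_freqs.freq
    else:
        assert background is not None
        if background.radius != observed.radius:
            raise ValueError("background radius does not match counts radius")
        expected = background.counts.astype(float)
    total_exp = expected.sum()
    if total_exp <= 0:
        raise NucperiodError("expected counts are zero everywhere; cannot normalize")
    expected = expected * (obs.sum() / total_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(expected > 0, obs / expected, np.nan)
    n_undef = int((expected == 0).sum())
    if n_undef:
        logger.warning(
            "%d offsets have zero expected counts; normalized values undefined there", n_undef
        )
    return NormalizedCounts(
        observed.radius, observed.counts.copy(), expected, normalized,
        n_mutations_mapped=observed.n_mutations_mapped,
    )
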