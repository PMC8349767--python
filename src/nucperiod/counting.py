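"""Dyad-relative mutation counting.

Maps each mutation to signed offsets from every dyad center within a window
radius (73 bp for single-nucleosome rotational analysis, 1000 bp for
multi-nucleosome translational analysis) and accumulates per-offset counts.
Both inputs must be coordinate-sorted; a single coordinated sweep moves two
window pointers monotonically over the dyad list, so each dyad enters and
leaves a mutation's window exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InsufficientMutationsError, UnsortedInputError
from .genomic_io import DyadPosition, GenomeSequence, MutationRecord

DEFAULT_MIN_MUTATIONS = 5000
ROTATIONAL_RADIUS = 73
TRANSLATIONAL_RADIUS = 1000


@dataclass
class DyadRelativeCounts:
    """Mutation counts indexed by signed offset from the dyad center.

    counts[offset + radius] is the number of (mutation, dyad) pairings at
    that offset; a mutation within the radius of k dyads contributes k
    pairings, so sum(counts) == n_mapped while n_mutations_mapped counts
    distinct mutations with at least one pairing.
    """

    radius: int
    counts: np.ndarray
    n_dyads: int
    n_mapped: int
    n_mutations_mapped: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.radius, self.radius + 1)

    def __add__(self, other: "DyadRelativeCounts") -> "DyadRelativeCounts":
        if self.radius != other.radius:
            raise ValueError("cannot add counts with different radii")
        return DyadRelativeCounts(
            self.radius,
            self.counts + other.counts,
            self.n_dyads,
            self.n_mapped + other.n_mapped,
            self.n_mutations_mapped + other.n_mutations_mapped,
        )


@dataclass
class GateResult:
    """Outcome of the minimum-mapped-mutations check."""

    passed: bool
    n_mutations_mapped: int
    minimum: int
    message: str = field(default="")


def _check_sorted(positions: np.ndarray, chroms: Sequence[str], what: str) -> None:
    for i in range(1, len(chroms)):
        if chroms[i] < chroms[i - 1] or (
            chroms[i] == chroms[i - 1] and positions[i] < positions[i - 1]
        ):
            raise UnsortedInputError(
                f"{what} not sorted by (chrom, pos): {chroms[i - 1]}:{positions[i - 1]} "
                f"precedes {chroms[i]}:{positions[i]}"
            )


def _by_chrom(chroms: Sequence[str], positions: np.ndarray) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out[chroms[start]] = positions[start:i]
            start = i
    return out


def _window_bounds(dyad_pos: np.ndarray, mut_pos: np.ndarray, radius: int):
    """Two-pointer sweep: for each mutation the dyad index range inside its window."""
    n = len(mut_pos)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    l = h = 0
    nd = len(dyad_pos)
    for i in range(n):
        m = mut_pos[i]
        while l < nd and dyad_pos[l] < m - radius:
            l += 1
        if h < l:
            h = l
        while h < nd and dyad_pos[h] <= m + radius:
            h += 1
        lo[i] = l
        hi[i] = h
    return lo, hi


def map_mutations_to_dyads(
    mutations: Sequence[MutationRecord],
    dyads: Sequence[DyadPosition],
    radius: int,
    genome: GenomeSequence | None = None,
) -> DyadRelativeCounts:
    """Count mutations at signed offsets from dyad centers.

    Both inputs must be sorted by (chrom, pos).  When a genome is supplied,
    dyads whose full window [pos-radius, pos+radius] leaves the chromosome
    are dropped so edge offsets are not biased by partial windows.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    mut_chroms = [m.chrom for m in mutations]
    mut_pos = np.fromiter((m.pos for m in mutations), dtype=np.int64, count=len(mutations))
    dy_chroms = [d.chrom for d in dyads]
    dy_pos = np.fromiter((d.pos for d in dyads), dtype=np.int64, count=len(dyads))
    _check_sorted(mut_pos, mut_chroms, "mutations")
    _check_sorted(dy_pos, dy_chroms, "dyads")

    dyads_by_chrom = _by_chrom(dy_chroms, dy_pos)
    n_dyads = 0
    if genome is not None:
        trimmed = {}
        for chrom, pos in dyads_by_chrom.items():
            length = genome.chrom_length(chrom)
            keep = (pos - radius >= 0) & (pos + radius < length)
            trimmed[chrom] = pos[keep]
        dyads_by_chrom = trimmed
    n_dyads = sum(len(v) for v in dyads_by_chrom.values())

    size = 2 * radius + 1
    counts = np.zeros(size, dtype=np.int64)
    n_mapped = 0
    n_mut_mapped = 0
    for chrom, mpos in _by_chrom(mut_chroms, mut_pos).items():
        dpos = dyads_by_chrom.get(chrom)
        if dpos is None or len(dpos) == 0:
            continue
        lo, hi = _window_bounds(dpos, mpos, radius)
        lengths = hi - lo
        total = int(lengths.sum())
        if total == 0:
            continue
        starts = np.cumsum(lengths) - lengths
        didx = np.repeat(lo, lengths) + (np.arange(total) - np.repeat(starts, lengths))
        offs = np.repeat(mpos, lengths) - dpos[didx]
        counts += np.bincount(offs + radius, minlength=size)
        n_mapped += total
        n_mut_mapped += int((lengths > 0).sum())
    return DyadRelativeCounts(radius, counts, n_dyads, n_mapped, n_mut_mapped)


def filter_mapped(
    mutations: Sequence[MutationRecord],
    dyads: Sequence[DyadPosition],
    radius: int,
    genome: GenomeSequence | None = None,
) -> list[MutationRecord]:
    """Subset of mutations lying within `radius` of at least one (in-bounds) dyad."""
    mut_chroms = [m.chrom for m in mutations]
    mut_pos = np.fromiter((m.pos for m in mutations), dtype=np.int64, count=len(mutations))
    dy_chroms = [d.chrom for d in dyads]
    dy_pos = np.fromiter((d.pos for d in dyads), dtype=np.int64, count=len(dyads))
    _check_sorted(mut_pos, mut_chroms, "mutations")
    _check_sorted(dy_pos, dy_chroms, "dyads")
    dyads_by_chrom = _by_chrom(dy_chroms, dy_pos)
    if genome is not None:
        for chrom in list(dyads_by_chrom):
            pos = dyads_by_chrom[chrom]
            length = genome.chrom_length(chrom)
            dyads_by_chrom[chrom] = pos[(pos - radius >= 0) & (pos + radius < length)]
    kept: list[MutationRecord] = []
    offset = 0
    for chrom, mpos in _by_chrom(mut_chroms, mut_pos).items():
        dpos = dyads_by_chrom.get(chrom)
        if dpos is not None and len(dpos):
            lo, hi = _window_bounds(dpos, mpos, radius)
            for j in np.nonzero(hi > lo)[0]:
                kept.append(mutations[offset + int(j)])
        offset += len(mpos)
    return kept


def check_minimum_mapped(
    counts: DyadRelativeCounts, minimum: int = DEFAULT_MIN_MUTATIONS
) -> GateResult:
    """Gate periodogram analysis on having enough dyad-mapped mutations."""
    ok = counts.n_mutations_mapped >= minimum
    msg = "" if ok else (
        f"{counts.n_mutations_mapped} mutations map within dyad windows; "
        f"minimum is {minimum}"
    )
    return GateResult(ok, counts.n_mutations_mapped, minimum, msg)


def require_minimum_mapped(
    counts: DyadRelativeCounts, minimum: int = DEFAULT_MIN_MUTATIONS
) -> None:
    result = check_minimum_mapped(counts, minimum)
    if not result.passed:
        raise InsufficientMutationsError(result.n_mutations_mapped, minimum)
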