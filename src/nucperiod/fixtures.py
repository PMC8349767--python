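"""Synthetic genomes, dyad maps, domains and mutation sets with known periodicity.

The mutation generator draws signed dyad offsets from a cosine intensity

    intensity(p) = baseline * (1 + amplitude * cos(2*pi*p/period + phase))

so an injected rotational (~10.2 bp helical repeat) or translational
(~190 bp nucleosome repeat length) signal can be recovered downstream and
compared against the known truth.  Everything is deterministic given a seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NucperiodError
from .genomic_io import DomainAnnotation, DyadPosition, GenomeSequence, MutationRecord

BASES = np.array(list("ACGT"))


@dataclass
class PeriodicIntensityModel:
    """Cosine mutation-intensity profile over dyad offsets [-R, +R].

    amplitude in [0, 1] guarantees a non-negative intensity everywhere;
    baseline is the expected mutation count per position (arbitrary scale —
    offsets are drawn from the normalized profile).
    """

    period: float
    amplitude: float
    window_radius: int
    phase: float = 0.0
    baseline: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.amplitude <= 1.0:
            raise ValueError("amplitude must lie in [0, 1]")
        if self.period <= 0 or self.window_radius < 1 or self.baseline < 0:
            raise ValueError("period and window_radius must be positive, baseline >= 0")

    def intensity(self, offsets: np.ndarray) -> np.ndarray:
        offsets = np.asarray(offsets, dtype=float)
        return self.baseline * (
            1.0 + self.amplitude * np.cos(2.0 * np.pi * offsets / self.period + self.phase)
        )


def generate_toy_genome(
    n_chrom: int, length_bp: int, gc_fraction: float = 0.4, seed: int = 0
) -> GenomeSequence:
    """Random genome with i.i.d. bases at the requested GC fraction."""
    if n_chrom < 1 or length_bp < 1:
        raise ValueError("n_chrom and length_bp must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    seqs = {}
    for i in range(n_chrom):
        draws = rng.choice(4, size=length_bp, p=probs)
        seqs[f"chr{i + 1}"] = "".join(BASES[draws])
    return GenomeSequence(seqs)


def generate_dyad_map(
    genome: GenomeSequence,
    spacing_bp: int,
    margin_bp: int,
    seed: int = 0,
    jitter_bp: int = 0,
) -> list[DyadPosition]:
    """Regularly spaced dyads (optional +/- jitter) with all windows in-bounds.

    Dyads run from ``margin_bp`` to ``length - margin_bp`` inclusive; choose a
    margin of at least the counting radius plus flank slack so that every
    window and its trinucleotide flanks fit in the chromosome.
    """
    if spacing_bp < 1:
        raise ValueError("spacing_bp must be >= 1")
    if jitter_bp < 0 or 2 * jitter_bp >= spacing_bp:
        raise ValueError("jitter must satisfy 0 <= 2*jitter < spacing")
    rng = np.random.default_rng(seed)
    dyads: list[DyadPosition] = []
    for chrom in genome.chrom_names:
        length = genome.chrom_length(chrom)
        if length < 2 * margin_bp:
            raise NucperiodError(
                f"chromosome {chrom} ({length} bp) is shorter than twice the margin "
                f"({margin_bp} bp); no dyad window fits"
            )
        positions = np.arange(margin_bp, length - margin_bp + 1, spacing_bp)
        if jitter_bp:
            positions = positions + rng.integers(-jitter_bp, jitter_bp + 1, size=len(positions))
            positions = np.clip(positions, margin_bp, length - margin_bp)
        dyads.extend(DyadPosition(chrom, int(p)) for p in positions)
    return sorted(dyads)


def generate_periodic_mutations(
    genome: GenomeSequence,
    dyads: list[DyadPosition],
    model: PeriodicIntensityModel,
    n_mutations: int,
    seed: int = 0,
    n_donors: int = 1,
    cohort_label: str = "",
) -> list[MutationRecord]:
    """Draw exactly ``n_mutations`` records around randomly chosen dyads.

    Each mutation picks a dyad uniformly, then a signed offset in
    [-R, +R] from the model's normalized intensity; ref is read from the
    genome and alt drawn uniformly from the three other bases.  Donors are
    assigned uniformly among ``n_donors`` ids.
    """
    if n_mutations < 1:
        raise ValueError("n_mutations must be >= 1")
    if not dyads:
        raise ValueError("dyad list is empty")
    radius = model.window_radius
    offsets_grid = np.arange(-radius, radius + 1)
    intensity = model.intensity(offsets_grid)
    total = intensity.sum()
    if total <= 0:
        raise NucperiodError("intensity is zero everywhere; cannot draw offsets")
    probs = intensity / total

    rng = np.random.default_rng(seed)
    dyad_idx = rng.integers(0, len(dyads), size=n_mutations)
    offs = rng.choice(offsets_grid, size=n_mutations, p=probs)
    donor_idx = (
        rng.integers(0, n_donors, size=n_mutations) if n_donors > 1 else np.zeros(n_mutations, int)
    )
    alt_pick = rng.integers(0, 3, size=n_mutations)

    records = []
    for i in range(n_mutations):
        d = dyads[dyad_idx[i]]
        pos = d.pos + int(offs[i])
        ref = genome.fetch(d.chrom, pos, pos + 1)
        if ref in "ACGT":
            alt = [b for b in "ACGT" if b != ref][alt_pick[i]]
        else:
            ref, alt = ".", "."
        records.append(
            MutationRecord(
                d.chrom, pos, ref, alt,
                donor_id=f"donor{donor_idx[i] + 1}", cohort=cohort_label,
            )
        )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def generate_domain_annotation(
    genome: GenomeSequence,
    labels: list[str],
    n_intervals_per_label: int,
    interval_length_bp: int,
    seed: int = 0,
) -> DomainAnnotation:
    """Random non-degenerate labelled intervals (may overlap across labels)."""
    rng = np.random.default_rng(seed)
    intervals = []
    for label in labels:
        for _ in range(n_intervals_per_label):
            chrom = genome.chrom_names[rng.integers(0, len(genome.chrom_names))]
            length = genome.chrom_length(chrom)
            span = min(interval_length_bp, length - 1)
            start = int(rng.integers(0, length - span))
            intervals.append((chrom, start, start + span, label))
    return DomainAnnotation(intervals)
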