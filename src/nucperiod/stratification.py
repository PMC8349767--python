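"""Cohort splitting, nucleosome-map stratification, and count matching."""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import NucperiodError, ValidationError
from .genomic_io import DomainAnnotation, DyadPosition, MutationRecord

logger = logging.getLogger(__name__)


@dataclass
class Cohort:
    """A labelled mutation subset (e.g. MSS or MSI tumors)."""

    label: str
    mutations: list[MutationRecord] = field(default_factory=list)

    @property
    def donor_ids(self) -> set[str]:
        return {m.donor_id for m in self.mutations}

    def __len__(self) -> int:
        return len(self.mutations)


def split_by_label(
    mutations: Sequence[MutationRecord],
    label_table: Mapping[str, str] | None = None,
) -> dict[str, Cohort]:
    """Partition mutations into cohorts by label.

    Labels come from each record's cohort field, or from a donor->label
    table when given.  A donor whose records carry a cohort label that
    conflicts with the table is an error.  Unlabeled records are excluded
    with a logged count; the cohorts partition the labeled records.
    """
    cohorts: dict[str, Cohort] = {}
    n_unlabeled = 0
    for m in mutations:
        if label_table is not None:
            label = label_table.get(m.donor_id, "")
            if label and m.cohort and m.cohort != label:
                raise ValidationError(
                    f"donor {m.donor_id!r} has conflicting labels: record says "
                    f"{m.cohort!r}, table says {label!r}"
                )
        else:
            label = m.cohort
        if not label:
            n_unlabeled += 1
            continue
        cohorts.setdefault(label, Cohort(label)).mutations.append(m)
    if n_unlabeled:
        logger.info("excluded %d unlabeled mutations from cohort split", n_unlabeled)
    return cohorts


def stratify_dyads_by_domains(
    dyads: Sequence[DyadPosition], domains: DomainAnnotation, label: str
) -> list[DyadPosition]:
    """Dyads whose center base lies in a half-open interval carrying `label`.

    Only the single dyad-center base is tested (not the 147-bp footprint),
    so the rule is unambiguous for dyads near domain edges.
    """
    if label not in domains.labels:
        raise NucperiodError(
            f"label {label!r} absent from annotation; available: {sorted(domains.labels)}"
        )
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, lab in domains.intervals:
        if lab == label:
            merged.setdefault(chrom, []).append((start, end))
    # merge overlapping intervals so a bisect on starts suffices
    index: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in merged.items():
        ivs.sort()
        starts: list[int] = []
        ends: list[int] = []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        index[chrom] = (starts, ends)
    kept = []
    for d in dyads:
        if d.chrom not in index:
            continue
        starts, ends = index[d.chrom]
        i = bisect_right(starts, d.pos) - 1
        if i >= 0 and d.pos < ends[i]:
            kept.append(d)
    return kept


def subsample_to_match(cohort: Cohort, n_target: int, seed: int) -> Cohort:
    """Uniform subsample without replacement to a target mutation count.

    Used to compare cohorts of unequal size at a matched count, since the
    periodicity SNR scales with sample size.  Record order (coordinate sort)
    is preserved.
    """
    if n_target > len(cohort):
        raise ValueError(
            f"cannot subsample {n_target} from a cohort of {len(cohort)} mutations"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(cohort), size=n_target, replace=False)
    idx.sort()
    return Cohort(cohort.label, [cohort.mutations[int(i)] for i in idx])
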