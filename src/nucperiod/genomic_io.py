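"""Readers and writers for the pipeline's file formats.

All internal coordinates are 0-based half-open.  BED inputs are taken as-is;
the ICGC simple-somatic-mutation TSV dialect uses 1-based inclusive
coordinates and is shifted by -1 on load.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

IUPAC_CHARS = set("ACGTNRYSWKMBDHVU")
_SEQ_RE = re.compile(r"^[ACGTNRYSWKMBDHVUacgtnryswkmbdhvu]*$")

MUTATION_DIALECTS = ("icgc_tsv", "extended_bed")

ICGC_COLUMNS = (
    "chromosome",
    "chromosome_start",
    "chromosome_end",
    "reference_genome_allele",
    "mutated_to_allele",
    "icgc_donor_id",
)


class GenomeSequence:
    """An in-memory genome with 0-based half-open `fetch` access.

    Sequences are stored uppercase; chromosome names are unique and keep
    their input order.
    """

    def __init__(self, sequences: dict[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise FormatError(
                    f"chromosome {name!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            self._seqs[name] = seq

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def chrom_length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self._seqs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the sequence of [start, end) on `chrom` (exactly end-start bases)."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self._seqs[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"fetch({chrom!r}, {start}, {end}) outside chromosome bounds [0, {len(seq)})"
            )
        return seq[start:end]


@dataclass(frozen=True, order=True)
class DyadPosition:
    """A single-base nucleosome dyad-center coordinate (0-based)."""

    chrom: str
    pos: int


@dataclass(order=True)
class MutationRecord:
    """One somatic single-base substitution.

    ``ref``/``alt`` are single bases or "." when unknown; ``context`` is the
    pyrimidine-collapsed trinucleotide, filled lazily by the normalization
    stage.
    """

    chrom: str
    pos: int
    ref: str = "."
    alt: str = "."
    donor_id: str = ""
    cohort: str = ""
    context: str | None = field(default=None, compare=False)


@dataclass
class DomainAnnotation:
    """Labelled genomic intervals (0-based half-open), e.g. chromatin domains."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self):
        for chrom, start, end, _label in self.intervals:
            if start >= end:
                raise FormatError(f"domain interval {chrom}:{start}-{end} has start >= end")
        self.intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2], iv[3]))

    @property
    def labels(self) -> set[str]:
        return {label for *_coords, label in self.intervals}


def _validate_fasta_text(path: str | Path) -> None:
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                saw_header = True
                if len(line) == 1:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
            else:
                if not saw_header:
                    raise FormatError(f"{path}: sequence before any FASTA header at line {lineno}")
                if not _SEQ_RE.match(line):
                    raise FormatError(f"{path}: non-IUPAC characters at line {lineno}")


def read_fasta_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA genome into memory, case-normalized to uppercase."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_fasta_text(path)
    try:
        fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, build_index=True)
    except Exception as exc:  # pragma: no cover - malformed files caught above
        raise FormatError(f"{path}: {exc}") from exc
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    return GenomeSequence(seqs)


def write_fasta_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, genome.chrom_length(chrom))
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_dyad_map(path: str | Path, genome: GenomeSequence | None = None) -> list[DyadPosition]:
    """Read a BED file of nucleosome dyads.

    Multi-base records resolve to their midpoint floor((start+end-1)/2 + ...)
    — precisely ``(start + end) // 2`` rounded down into the record, which for
    a single-base record is the base itself.  The result is sorted with
    duplicates removed (a warning reports how many).
    """
    rows = _read_bed_rows(path, min_cols=3)
    dyads: list[DyadPosition] = []
    for lineno, cols in rows:
        chrom, start, end = cols[0], _int(cols[1], path, lineno), _int(cols[2], path, lineno)
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        dyads.append(DyadPosition(chrom, (start + end) // 2))
    if genome is not None:
        missing = sorted({d.chrom for d in dyads if d.chrom not in genome})
        if missing:
            raise ValidationError(f"{path}: chromosomes absent from genome: {missing}")
        for d in dyads:
            if not 0 <= d.pos < genome.chrom_length(d.chrom):
                raise ValidationError(f"{path}: dyad {d.chrom}:{d.pos} outside chromosome")
    unique = sorted(set(dyads))
    n_dup = len(dyads) - len(unique)
    if n_dup:
        logger.warning("%s: removed %d duplicate dyad positions", path, n_dup)
    return unique


def write_dyad_map(dyads: Iterable[DyadPosition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in dyads:
            fh.write(f"{d.chrom}\t{d.pos}\t{d.pos + 1}\n")


def read_domains(path: str | Path) -> DomainAnnotation:
    """Read a BED4+ file of labelled intervals (4th column = label)."""
    rows = _read_bed_rows(path, min_cols=4)
    intervals = []
    for lineno, cols in rows:
        intervals.append(
            (cols[0], _int(cols[1], path, lineno), _int(cols[2], path, lineno), cols[3])
        )
    return DomainAnnotation(intervals)


def write_domains(domains: DomainAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in domains.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_label_table(path: str | Path) -> dict[str, str]:
    """Read a two-column donor_id -> label TSV; conflicting duplicates error."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated columns")
            donor, label = cols[0], cols[1]
            if donor in table and table[donor] != label:
                raise ValidationError(
                    f"{path}: donor {donor!r} assigned conflicting labels "
                    f"{table[donor]!r} and {label!r}"
                )
            table[donor] = label
    return table


def read_mutations(
    path: str | Path,
    dialect: str,
    genome: GenomeSequence | None = None,
    max_ref_mismatch_fraction: float = 0.001,
) -> list[MutationRecord]:
    """Read mutation data in the ICGC TSV or extended-BED dialect.

    Records are returned sorted by (chrom, pos).  When a genome is supplied,
    each non-"." ref allele is checked against the genome base; mismatching
    records are dropped with a reported count, and a mismatch fraction above
    ``max_ref_mismatch_fraction`` raises (a wrong genome build, most likely).
    """
    if dialect not in MUTATION_DIALECTS:
        raise ValueError(f"unknown mutation dialect {dialect!r}; choose from {MUTATION_DIALECTS}")
    if dialect == "extended_bed":
        records = _read_extended_bed(path)
    else:
        records = _read_icgc_tsv(path)
    if genome is not None:
        records = _validate_refs(records, genome, max_ref_mismatch_fraction, path)
    records.sort(key=lambda r: (r.chrom, r.pos))
    _log_tallies(records, path)
    return records


def write_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write mutations in the extended-BED dialect (the package's native format)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.ref}>{r.alt}\t.\t+\t"
                f"{r.donor_id}\t{r.cohort}\n"
            )


def write_icgc_mutations(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write mutations in the ICGC simple-somatic-mutation TSV dialect (1-based)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ICGC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t{r.pos + 1}\t{r.ref}\t{r.alt}\t{r.donor_id}\n"
            )


def write_counts_table(counts, path: str | Path) -> None:
    """Write a dyad-relative counts table as TSV.

    One row per signed offset -R..+R; raw counts get (offset, observed)
    columns, normalized counts add expected and normalized columns.
    """
    df = counts_to_frame(counts)
    # %.17g guarantees float64 round-trips bit-exactly through the TSV
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def counts_to_frame(counts) -> pd.DataFrame:
    radius = counts.radius
    offsets = np.arange(-radius, radius + 1)
    data: dict[str, np.ndarray] = {"offset": offsets}
    if hasattr(counts, "normalized"):
        data["observed"] = counts.observed
        data["expected"] = counts.expected
        data["normalized"] = counts.normalized
    else:
        data["observed"] = counts.counts
    return pd.DataFrame(data)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "offset" not in df.columns or "observed" not in df.columns:
        raise FormatError(f"{path}: counts table must have offset and observed columns")
    return df


# -- helpers -----------------------------------------------------------------


def _int(token: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: expected integer, got {token!r}") from None


def _read_bed_rows(path: str | Path, min_cols: int) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                raise FormatError(f"{path}:{lineno}: expected >= {min_cols} columns, got {len(cols)}")
            rows.append((lineno, cols))
    return rows


def _read_extended_bed(path: str | Path) -> list[MutationRecord]:
    records = []
    for lineno, cols in _read_bed_rows(path, min_cols=4):
        chrom = cols[0]
        start = _int(cols[1], path, lineno)
        change = cols[3]
        if ">" not in change:
            raise FormatError(f"{path}:{lineno}: expected ref>alt in column 4, got {change!r}")
        ref, alt = change.split(">", 1)
        donor = cols[6] if len(cols) > 6 else ""
        cohort = cols[7] if len(cols) > 7 else ""
        records.append(MutationRecord(chrom, start, ref.upper(), alt.upper(), donor, cohort))
    return records


def _read_icgc_tsv(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ICGC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required ICGC columns: {missing}")
    records = []
    n_skipped = 0
    for row in df.itertuples(index=False):
        ref = str(row.reference_genome_allele).upper()
        alt = str(row.mutated_to_allele).upper()
        if not (_is_allele(ref) and _is_allele(alt)):
            n_skipped += 1  # indels / MNVs are outside the single-base model
            continue
        pos = int(row.chromosome_start) - 1  # 1-based inclusive -> 0-based
        records.append(
            MutationRecord(str(row.chromosome), pos, ref, alt, str(row.icgc_donor_id), "")
        )
    if n_skipped:
        logger.info("%s: skipped %d non-single-base-substitution rows", path, n_skipped)
    return records


def _is_allele(a: str) -> bool:
    return a == "." or (len(a) == 1 and a in "ACGT")


def _validate_refs(
    records: Sequence[MutationRecord],
    genome: GenomeSequence,
    max_fraction: float,
    path,
) -> list[MutationRecord]:
    kept, n_mismatch = [], 0
    for r in records:
        if r.chrom not in genome or not 0 <= r.pos < genome.chrom_length(r.chrom):
            raise ValidationError(f"{path}: mutation {r.chrom}:{r.pos} outside genome bounds")
        if r.ref != "." and genome.fetch(r.chrom, r.pos, r.pos + 1) != r.ref:
            n_mismatch += 1
            continue
        kept.append(r)
    if records and n_mismatch / len(records) > max_fraction:
        raise ValidationError(
            f"{path}: {n_mismatch}/{len(records)} ref alleles mismatch the genome "
            f"(> {max_fraction:.2%}); wrong genome build?"
        )
    if n_mismatch:
        logger.warning("%s: dropped %d ref-mismatching records", path, n_mismatch)
    return kept


def _log_tallies(records: Sequence[MutationRecord], path) -> None:
    donors = {r.donor_id for r in records}
    cohorts: dict[str, int] = {}
    for r in records:
        cohorts[r.cohort] = cohorts.get(r.cohort, 0) + 1
    logger.info(
        "%s: %d mutations from %d donors; per-cohort counts: %s",
        path, len(records), len(donors), cohorts,
    )
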