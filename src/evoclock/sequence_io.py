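"""Reading, validating and joining FASTA sequences with dated TSV metadata.

The input contract mirrors common genomic-surveillance exports: a multi-FASTA
whose *first* record is the reference genome, and a tab-separated metadata
table carrying, at minimum, a sample identifier and a collection date.
Samples and metadata are joined on exact identifier match; rows whose dates
are not complete ISO-8601 days (``YYYY-MM-DD``) are dropped and counted, never
imputed, because downstream time-binning requires day resolution.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import ConfigurationError, EmptyDatasetError, FormatError, ValidationError

__all__ = [
    "SequenceRecord",
    "SampleMetadata",
    "Dataset",
    "MetadataReport",
    "JoinReport",
    "read_fasta",
    "read_metadata",
    "join",
    "write_fasta",
    "write_metadata",
]

_DATE_FORMAT = "%Y-%m-%d"


@dataclass(frozen=True)
class SequenceRecord:
    """A single nucleotide sequence, normalized to uppercase with U mapped to T."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.sequence:
            raise ValidationError(f"sequence {self.id!r} is empty")
        normalized = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", normalized)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SampleMetadata:
    """Collection date and arbitrary extra columns for one sample."""

    id: str
    collection_date: _dt.date
    extra: Mapping[str, str] = field(default_factory=dict)


@dataclass
class Dataset:
    """Reference sequence plus joined (sequence, metadata) sample pairs.

    The reference participates only as the alignment target: its mutation
    count against itself is identically zero and would bias the first time
    bin, so it is never part of ``samples``.
    """

    reference: SequenceRecord
    samples: list[tuple[SequenceRecord, SampleMetadata]]

    def __post_init__(self) -> None:
        ids = [seq.id for seq, _ in self.samples]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sample ids in dataset")
        if self.reference.id in set(ids):
            raise ValidationError("reference sequence must not appear among samples")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class MetadataReport:
    """Accounting of metadata parsing: total rows seen, rows dropped for bad dates."""

    n_rows: int = 0
    n_dropped_dates: int = 0

    def to_dict(self) -> dict:
        return {"rows": self.n_rows, "dropped_invalid_dates": self.n_dropped_dates}


@dataclass
class JoinReport:
    """Accounting of the sequence/metadata inner join."""

    n_joined: int = 0
    n_sequences_without_metadata: int = 0
    n_metadata_without_sequence: int = 0

    def to_dict(self) -> dict:
        return {
            "joined": self.n_joined,
            "sequences_without_metadata": self.n_sequences_without_metadata,
            "metadata_without_sequence": self.n_metadata_without_sequence,
        }


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`, preserving order.

    Raises :class:`FormatError` for an empty file or one that does not start
    with a header line, and :class:`ValidationError` for duplicate ids.
    """
    path = Path(path)
    with open(path) as handle:
        first = ""
        for line in handle:
            if line.strip():
                first = line
                break
        if not first:
            raise FormatError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FormatError(f"{path}: first non-blank line is not a FASTA header")
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
    return records


def read_metadata(
    path: str | Path,
    date_column: str = "date",
    id_column: str = "id",
) -> tuple[list[SampleMetadata], MetadataReport]:
    """Read TSV metadata, parsing ``date_column`` as full ISO-8601 dates.

    Rows whose date is missing, partial (e.g. ``2021-01``) or unparseable are
    dropped and counted in the returned :class:`MetadataReport`.
    """
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in (id_column, date_column):
        if col not in table.columns:
            raise ConfigurationError(
                f"{path}: required column {col!r} not found "
                f"(available: {', '.join(table.columns)})"
            )
    report = MetadataReport(n_rows=len(table))
    parsed = pd.to_datetime(table[date_column], format=_DATE_FORMAT, errors="coerce")
    valid = parsed.notna()
    report.n_dropped_dates = int((~valid).sum())
    extra_cols = [c for c in table.columns if c not in (id_column, date_column)]
    records = [
        SampleMetadata(
            id=row[id_column],
            collection_date=date.date(),
            extra={c: row[c] for c in extra_cols},
        )
        for (_, row), date in zip(table[valid].iterrows(), parsed[valid])
    ]
    return records, report


def join(
    sequences: Iterable[SequenceRecord],
    metadata: Iterable[SampleMetadata],
) -> tuple[Dataset, JoinReport]:
    """Build a :class:`Dataset`: first sequence is the reference, the rest are
    inner-joined with metadata on exact id match."""
    sequences = list(sequences)
    if not sequences:
        raise EmptyDatasetError("no sequences to join")
    reference, rest = sequences[0], sequences[1:]
    by_id = {m.id: m for m in metadata}
    report = JoinReport()
    samples: list[tuple[SequenceRecord, SampleMetadata]] = []
    for seq in rest:
        meta = by_id.pop(seq.id, None)
        if meta is None:
            report.n_sequences_without_metadata += 1
        else:
            samples.append((seq, meta))
    report.n_metadata_without_sequence = len(by_id)
    report.n_joined = len(samples)
    if not samples:
        raise EmptyDatasetError(
            "no samples after joining sequences with metadata "
            f"({report.n_sequences_without_metadata} sequences unmatched, "
            f"{report.n_metadata_without_sequence} metadata rows unmatched)"
        )
    return Dataset(reference=reference, samples=samples), report


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")


def write_metadata(
    samples: Iterable[SampleMetadata],
    path: str | Path,
    date_column: str = "date",
    id_column: str = "id",
) -> None:
    samples = list(samples)
    extra_cols: list[str] = []
    for m in samples:
        for c in m.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    with open(path, "w") as handle:
        handle.write("\t".join([id_column, date_column, *extra_cols]) + "\n")
        for m in samples:
            row = [m.id, m.collection_date.isoformat()]
            row += [str(m.extra.get(c, "")) for c in extra_cols]
            handle.write("\t".join(row) + "\n")
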