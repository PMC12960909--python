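"""Pairwise alignment against the reference and mutation-event extraction.

Each sample is aligned globally to the reference, either with the external
MAFFT binary or with a builtin affine-gap aligner. Mutation events are read
off the aligned columns:

* a column with differing A/C/G/T bases on both rows is one substitution;
* a maximal run of gaps in the reference row is ONE insertion event (anchored
  to the reference base immediately to its left; position 0 for an insertion
  before base 1);
* a maximal run of gaps in the query row is ONE deletion event — unless the
  run touches the start or end of the alignment, in which case it is treated
  as incomplete sequencing (terminal missing data) rather than a deletion;
* columns where the sample carries N or any other non-ACGT code yield no
  event (missing data, not a substitution).

Counting a k-base indel as a single event matches standard variant semantics
and keeps the per-sample mutation count an event count rather than an
affected-base count.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

from Bio import Align

from .errors import AlignerError, ConfigurationError, ValidationError
from .sequence_io import SequenceRecord, write_fasta

__all__ = [
    "PairwiseAlignment",
    "MutationEvent",
    "MutationProfile",
    "align_pair",
    "call_mutations",
    "profile",
    "CATEGORIES",
    "MUTATION_TYPES",
]

_ACGT = frozenset("ACGT")

CATEGORIES = ("total", "substitutions", "indels")
MUTATION_TYPES = CATEGORIES + ("all",)

# Fixed builtin scoring: match +2, mismatch -1, gap open -5, gap extend -1.
# The contract is alignment validity, not parity with MAFFT.
_BUILTIN = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-1,
    open_gap_score=-5,
    extend_gap_score=-1,
)
_BUILTIN.wildcard = "N"


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two equal-length gapped strings; de-gapping row i reproduces sequence i."""

    ref_aligned: str
    qry_aligned: str

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.qry_aligned):
            raise ValidationError("aligned rows have unequal lengths")
        if any(r == "-" == q for r, q in zip(self.ref_aligned, self.qry_aligned)):
            raise ValidationError("alignment column gapped in both rows")
        if not self.ref_aligned.replace("-", ""):
            raise ValidationError("reference row is all gaps")


@dataclass(frozen=True)
class MutationEvent:
    kind: str  # substitution | insertion | deletion
    ref_position: int  # 1-based; insertions anchored to the base on their left
    ref_allele: str  # empty for insertions
    alt_allele: str  # empty for deletions


@dataclass
class MutationProfile:
    """Classified differences of one sample vs. the reference, with category counts."""

    sample_id: str
    events: list[MutationEvent]
    counts: dict[str, int] = field(default_factory=dict)


def align_pair(
    reference: SequenceRecord,
    sample: SequenceRecord,
    backend: str = "builtin",
) -> PairwiseAlignment:
    """Globally align ``sample`` to ``reference``.

    backend "builtin" uses the internal affine-gap aligner; "external" shells
    out to the MAFFT binary and raises :class:`AlignerError` with a hint to
    fall back to builtin when the binary is absent.
    """
    if not reference.sequence or not sample.sequence:
        raise ValidationError("cannot align empty sequences")
    if backend == "builtin":
        aln = _BUILTIN.align(reference.sequence, sample.sequence)[0]
        return PairwiseAlignment(ref_aligned=str(aln[0]), qry_aligned=str(aln[1]))
    if backend == "external":
        return _align_mafft(reference, sample)
    raise ConfigurationError(f"unknown aligner backend {backend!r}")


def _align_mafft(reference: SequenceRecord, sample: SequenceRecord) -> PairwiseAlignment:
    if shutil.which("mafft") is None:
        raise AlignerError(
            "mafft binary not found on PATH; install MAFFT or use --aligner builtin"
        )
    with tempfile.TemporaryDirectory() as tmp:
        ref_fa = Path(tmp) / "ref.fasta"
        qry_fa = Path(tmp) / "qry.fasta"
        write_fasta([reference], ref_fa)
        write_fasta([sample], qry_fa)
        proc = subprocess.run(
            ["mafft", "--quiet", "--auto", "--add", str(qry_fa), str(ref_fa)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0:
            raise AlignerError(f"mafft failed (exit {proc.returncode}): {proc.stderr.strip()}")
        rows = _parse_fasta_text(proc.stdout)
    if len(rows) != 2:
        raise AlignerError(f"mafft returned {len(rows)} records, expected 2")
    ref_row, qry_row = rows[0].upper(), rows[1].upper()
    if ref_row.replace("-", "") != reference.sequence:
        raise AlignerError("mafft output does not de-gap to the reference")
    if qry_row.replace("-", "") != sample.sequence:
        raise AlignerError("mafft output does not de-gap to the sample")
    return PairwiseAlignment(ref_aligned=ref_row, qry_aligned=qry_row)


def _parse_fasta_text(text: str) -> list[str]:
    rows: list[str] = []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if current:
                rows.append("".join(current))
            current = []
        else:
            current.append(line.strip())
    if current:
        rows.append("".join(current))
    return rows


def call_mutations(aln: PairwiseAlignment) -> list[MutationEvent]:
    """Extract substitution / insertion / deletion events from an alignment."""
    ref, qry = aln.ref_aligned, aln.qry_aligned
    n = len(ref)

    # Terminal query-gap runs are missing data, not deletions.
    lead = 0
    while lead < n and qry[lead] == "-":
        lead += 1
    trail = n
    while trail > lead and qry[trail - 1] == "-":
        trail -= 1

    events: list[MutationEvent] = []
    ref_pos = 0  # 1-based position of the last reference base seen
    i = 0
    while i < n:
        r, q = ref[i], qry[i]
        if r == "-":
            j = i
            while j < n and ref[j] == "-":
                j += 1
            # Insertion columns carry query bases, so they can never fall in a
            # terminal query-gap run; always called.
            events.append(MutationEvent("insertion", ref_pos, "", qry[i:j]))
            i = j
            continue
        if q == "-":
            j = i
            run_len = 0
            while j < n and ref[j] != "-" and qry[j] == "-":
                run_len += 1
                j += 1
            if i >= lead and j <= trail:
                events.append(
                    MutationEvent(
                        "deletion", ref_pos + 1, ref[i:j], ""
                    )
                )
            ref_pos += run_len
            i = j
            continue
        ref_pos += 1
        if r != q and r in _ACGT and q in _ACGT:
            events.append(MutationEvent("substitution", ref_pos, r, q))
        i += 1
    return events


def profile(
    sample_id: str,
    events: list[MutationEvent],
    mutation_type: str = "all",
    position_range: tuple[int, int] | None = None,
) -> MutationProfile:
    """Restrict events to a reference-coordinate window and count categories.

    An indel is in range when its reference anchor position is in range.
    Counts are computed for all three categories regardless of
    ``mutation_type``; the latter only selects which categories downstream
    analyses consume.
    """
    if mutation_type not in MUTATION_TYPES:
        raise ConfigurationError(
            f"unknown mutation type {mutation_type!r}; expected one of {MUTATION_TYPES}"
        )
    if position_range is not None:
        lo, hi = position_range
        events = [e for e in events if lo <= e.ref_position <= hi]
    n_sub = sum(1 for e in events if e.kind == "substitution")
    n_indel = len(events) - n_sub
    counts = {"total": len(events), "substitutions": n_sub, "indels": n_indel}
    return MutationProfile(sample_id=sample_id, events=list(events), counts=counts)
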