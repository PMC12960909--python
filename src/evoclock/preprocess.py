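"""Quality and scope filters applied to a dataset before alignment.

Filters are per-sample and independent, so their order cannot change the
surviving set; the report attributes each removal to the first failing filter
in the fixed order length -> N-fraction -> date range -> metadata predicates.
The genome position range is *recorded* here but applied later, at
mutation-profiling time, because it restricts which mutation events are
counted rather than which samples survive.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from .errors import EmptyDatasetError, ValidationError
from .sequence_io import Dataset, SampleMetadata, SequenceRecord

__all__ = ["FilterConfig", "FilterReport", "apply_filters"]

FILTER_ORDER = ("length", "n_fraction", "date_range", "metadata")


@dataclass
class FilterConfig:
    """Sample-level filters.

    max_n_fraction follows the convention that up to the threshold is
    allowed (strictly more N's than the fraction removes the sample); the
    default 0.01 corresponds to tolerating at most 1% unresolved bases.
    Ambiguity codes other than N do not count toward the fraction.
    """

    min_length: int | None = None
    max_n_fraction: float = 0.01
    date_range: tuple[_dt.date, _dt.date] | None = None
    position_range: tuple[int, int] | None = None
    metadata_predicates: list[tuple[str, frozenset[str]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_n_fraction <= 1.0):
            raise ValidationError("max_n_fraction must lie in [0, 1]")
        if self.date_range is not None and self.date_range[0] > self.date_range[1]:
            raise ValidationError("date_range start must be <= end")
        if self.position_range is not None and self.position_range[0] > self.position_range[1]:
            raise ValidationError("position_range start must be <= end")
        self.metadata_predicates = [
            (col, frozenset(vals)) for col, vals in self.metadata_predicates
        ]


@dataclass
class FilterReport:
    """Per-filter removal counts (first-failing-filter attribution)."""

    n_input: int = 0
    n_surviving: int = 0
    removed: dict[str, int] = field(default_factory=lambda: {f: 0 for f in FILTER_ORDER})

    def to_dict(self) -> dict:
        return {
            "input": self.n_input,
            "surviving": self.n_surviving,
            "removed": dict(self.removed),
        }


def _first_failing(
    seq: SequenceRecord, meta: SampleMetadata, cfg: FilterConfig
) -> str | None:
    if cfg.min_length is not None and seq.length < cfg.min_length:
        return "length"
    if seq.sequence.count("N") / seq.length > cfg.max_n_fraction:
        return "n_fraction"
    if cfg.date_range is not None:
        start, end = cfg.date_range
        if not (start <= meta.collection_date <= end):
            return "date_range"
    for column, allowed in cfg.metadata_predicates:
        if meta.extra.get(column) not in allowed:
            return "metadata"
    return None


def apply_filters(dataset: Dataset, cfg: FilterConfig) -> tuple[Dataset, FilterReport]:
    """Remove samples failing any enabled filter; raise if none survive."""
    report = FilterReport(n_input=len(dataset))
    surviving = []
    for seq, meta in dataset.samples:
        failing = _first_failing(seq, meta, cfg)
        if failing is None:
            surviving.append((seq, meta))
        else:
            report.removed[failing] += 1
    report.n_surviving = len(surviving)
    if not surviving:
        raise EmptyDatasetError(
            "all samples removed by filters; removals per filter: "
            + ", ".join(f"{k}={v}" for k, v in report.removed.items())
        )
    return Dataset(reference=dataset.reference, samples=surviving), report
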