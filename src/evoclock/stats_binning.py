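"""Temporal discretization and per-interval mutation statistics.

Samples are grouped into half-open intervals of ``interval_days`` anchored at
the earliest surviving collection date (bin k covers days
``[k*interval, (k+1)*interval)`` after the origin). For bin k with N_k
samples and counts m_{k,i}:

    mu_k      = (1/N_k) * sum_i m_{k,i}
    sigma2_k  = (1/(N_k-1)) * sum_i (m_{k,i} - mu_k)^2      (N_k >= 2)
    w_k       = tanh(N_k / 15)

The weight saturates towards 1 as bins accumulate sequences, discounting
intervals estimated from few genomes. Time is measured in units of the
interval length (t_k = k), matching rate estimates reported per interval
(e.g. per week for 7-day bins). Bins with a single sample keep their mean
but carry no variance; empty bins are simply absent, never zero-filled or
interpolated.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .align_mutations import MutationProfile
from .errors import InsufficientDataError, ValidationError

__all__ = ["TimeBinStats", "BinnedSeries", "assign_bins", "bin_stats", "bin_weight"]

logger = logging.getLogger(__name__)

RECOMMENDED_MIN_SAMPLES = 30  # statistical-power guidance, warned about, not enforced


def bin_weight(n: int) -> float:
    """Reliability weight of a bin with n samples: tanh(n/15)."""
    return math.tanh(n / 15.0)


@dataclass(frozen=True)
class TimeBinStats:
    k: int
    t: float  # bin time in interval units (== k, first bin at t=0)
    n: int
    mu: float
    sigma2: float | None  # None when n < 2 (variance undefined)
    w: float


@dataclass
class BinnedSeries:
    category: str
    origin_date: _dt.date
    interval_days: int
    bins: list[TimeBinStats]

    def variance_bins(self) -> list[TimeBinStats]:
        return [b for b in self.bins if b.sigma2 is not None]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "k": b.k,
                "date_start": (
                    self.origin_date + _dt.timedelta(days=b.k * self.interval_days)
                ).isoformat(),
                "N_k": b.n,
                "mu_k": b.mu,
                "sigma2_k": float("nan") if b.sigma2 is None else b.sigma2,
                "w_k": b.w,
            }
            for b in self.bins
        ]
        return pd.DataFrame(rows)


def assign_bins(
    profiles: Iterable[MutationProfile],
    dates: Mapping[str, _dt.date],
    interval_days: int = 7,
    category: str = "total",
) -> tuple[dict[int, list[int]], _dt.date]:
    """Map each sample's mutation count to its time bin.

    Returns (counts per bin index, origin date). The origin is the earliest
    collection date among the given profiles; a sample collected on day d
    lands in bin floor((d - origin) / interval_days).
    """
    if interval_days < 1:
        raise ValidationError("interval_days must be >= 1")
    profiles = list(profiles)
    if not profiles:
        raise InsufficientDataError("no mutation profiles to bin")
    missing = [p.sample_id for p in profiles if p.sample_id not in dates]
    if missing:
        raise ValidationError(f"no collection date for samples: {missing[:5]}")
    origin = min(dates[p.sample_id] for p in profiles)
    counts: dict[int, list[int]] = {}
    for p in profiles:
        k = (dates[p.sample_id] - origin).days // interval_days
        counts.setdefault(k, []).append(p.counts[category])
    return counts, origin


def bin_stats(
    counts_by_bin: Mapping[int, list[int]],
    origin_date: _dt.date,
    interval_days: int = 7,
    category: str = "total",
) -> BinnedSeries:
    """Compute per-bin mean, unbiased variance and weight.

    Requires at least two bins with N_k >= 2, otherwise no variance model can
    be fitted downstream.
    """
    bins: list[TimeBinStats] = []
    for k in sorted(counts_by_bin):
        m = np.asarray(counts_by_bin[k], dtype=float)
        n = m.size
        if n < 1:
            continue
        sigma2 = float(m.var(ddof=1)) if n >= 2 else None
        bins.append(
            TimeBinStats(
                k=k, t=float(k), n=n, mu=float(m.mean()), sigma2=sigma2, w=bin_weight(n)
            )
        )
    series = BinnedSeries(
        category=category, origin_date=origin_date, interval_days=interval_days, bins=bins
    )
    n_variance = len(series.variance_bins())
    if n_variance < 2:
        raise InsufficientDataError(
            f"only {n_variance} bins with >= 2 samples; variance fitting needs >= 2"
        )
    small = [b.k for b in bins if b.n < RECOMMENDED_MIN_SAMPLES]
    if small:
        logger.warning(
            "%d/%d bins hold fewer than %d sequences (k=%s...); estimates there "
            "carry reduced statistical power",
            len(small),
            len(bins),
            RECOMMENDED_MIN_SAMPLES,
            small[:8],
        )
    return series
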