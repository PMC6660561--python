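"""Shock Index and its population-baseline CDF normalization.

The Shock Index (SI) is heart rate divided by systolic blood pressure.
It is mapped onto a 0-1 scale (SI_norm) through the normal CDF
parameterized by the pooled baseline mean and standard deviation of the
event records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import norm

from .core import RecordSeries, RecordType, ValidationError


@dataclass(frozen=True)
class BaselineStats:
    """Pooled baseline mean/SD of the shock index across event records."""

    mean: float
    sd: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValidationError(f"baseline sd must be > 0, got {self.sd}")
        if self.n_samples < 2:
            raise ValidationError(f"baseline needs >= 2 samples, got {self.n_samples}")


def shock_index(hr: np.ndarray, sbp: np.ndarray) -> np.ndarray:
    """Elementwise heart rate over systolic pressure.

    Raises a domain error identifying the first offending sample if any
    systolic value is nonpositive.
    """
    hr = np.asarray(hr, dtype=float)
    sbp = np.asarray(sbp, dtype=float)
    if hr.shape != sbp.shape:
        raise ValidationError(
            f"hr and sbp must have the same shape, got {hr.shape} and {sbp.shape}"
        )
    bad = np.flatnonzero(sbp <= 0)
    if bad.size:
        raise ValidationError(
            f"sbp must be positive; first violation at sample index {bad[0]}"
        )
    return hr / sbp


def fit_baseline_stats(records: Iterable[RecordSeries]) -> BaselineStats:
    """Pool shock-index samples from event-record baseline windows.

    Non-event records in the input are ignored. The standard deviation is
    the sample (n-1 denominator) SD of the pooled samples.
    """
    pooled: list[np.ndarray] = []
    for rec in records:
        if rec.record_type is not RecordType.EVENT:
            continue
        mask = rec.baseline_mask()
        if mask.any():
            pooled.append(shock_index(rec.hr[mask], rec.sbp[mask]))
    if not pooled:
        raise ValidationError("no baseline samples found in any event record")
    si = np.concatenate(pooled)
    if si.size < 2:
        raise ValidationError(f"baseline needs >= 2 pooled samples, got {si.size}")
    sd = float(np.std(si, ddof=1))
    if sd == 0:
        raise ValidationError("degenerate baseline: pooled shock index is constant")
    return BaselineStats(mean=float(np.mean(si)), sd=sd, n_samples=int(si.size))


def normalize_si(si: np.ndarray, stats: BaselineStats) -> np.ndarray:
    """Map shock-index values through the baseline normal CDF onto (0, 1)."""
    si = np.asarray(si, dtype=float)
    p = norm.cdf((si - stats.mean) / stats.sd)
    # cdf saturates to exactly 0/1 in the far tails; keep the open interval
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
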