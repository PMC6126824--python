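"""Equilibration detection, decorrelation and bootstrap machinery.

Time series from molecular simulations are autocorrelated and usually
start from an unequilibrated state.  Every statistical check in this
package therefore expects its input to be (a) truncated to the
equilibrated part and (b) subsampled to approximately independent frames.
This module provides the shared tooling:

* :func:`statistical_inefficiency` — the factor ``g`` by which
  autocorrelation reduces the effective number of independent samples,
  ``g = 1 + 2 * sum_t (1 - t/n) * rho(t)``, with the sum truncated at the
  first non-positive autocorrelation estimate.
* :func:`detect_equilibration` — picks the production start index that
  maximizes the effective number of samples of the retained tail.
* :func:`subsample_decorrelated` — keeps every ``ceil(g)``-th frame.
* :func:`bootstrap_statistic` — simple iid bootstrap on (decorrelated)
  frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


@dataclass(frozen=True)
class DecorrelationInfo:
    """Equilibration start, statistical inefficiency and effective samples."""

    start: int
    g: float
    n_eff: float

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start index must be non-negative")
        if self.g < 1:
            raise ValueError("statistical inefficiency must be >= 1")


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation estimate rho(t) for t = 0..n-1, via FFT."""
    n = len(x)
    dx = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n] / n
    if acov[0] <= 0:
        raise ValueError("zero-variance series")
    return acov / acov[0]


def statistical_inefficiency(series: np.ndarray) -> float:
    """Statistical inefficiency g >= 1 of a scalar time series.

    Uses the initial-positive-sequence style truncation: the weighted sum
    over the autocorrelation function stops at the first non-positive
    estimate, which keeps the noisy large-lag tail out of the sum.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if len(x) < 10:
        raise ValueError("series too short (need >= 10 frames)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    rho = _autocorrelation(x)
    n = len(x)
    t = np.arange(1, n)
    tail = rho[1:]
    nonpos = np.nonzero(tail <= 0)[0]
    t_max = nonpos[0] if len(nonpos) else n - 1
    g = 1.0 + 2.0 * np.sum((1.0 - t[:t_max] / n) * tail[:t_max])
    return float(max(g, 1.0))


def detect_equilibration(series: np.ndarray, n_candidates: int = 100) -> int:
    """Start index of the equilibrated part of a series.

    Scans candidate truncation points over the first 90% of the series
    and returns the one maximizing ``n_eff = (n - start) / g`` of the
    retained tail, recomputing ``g`` for each candidate.  A degenerate
    (zero-variance) series yields 0.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("series too short (need >= 10 frames)")
    n = len(x)
    candidates = np.unique(
        np.linspace(0, int(0.9 * n), min(n_candidates, n), dtype=int)
    )
    best_start, best_neff = 0, -np.inf
    for start in candidates:
        tail = x[start:]
        if len(tail) < 10:
            break
        try:
            g = statistical_inefficiency(tail)
        except ValueError:
            continue
        n_eff = len(tail) / g
        if n_eff > best_neff:
            best_start, best_neff = int(start), n_eff
    return best_start


def subsample_decorrelated(series: np.ndarray, info: DecorrelationInfo) -> np.ndarray:
    """Frames start, start + ceil(g), ... of the series, order preserved."""
    x = np.asarray(series)
    stride = int(np.ceil(info.g))
    return x[info.start :: stride]


def decorrelate(series: np.ndarray) -> tuple[np.ndarray, DecorrelationInfo]:
    """Equilibration-detect, compute g, and subsample in one step."""
    x = np.asarray(series, dtype=float)
    start = detect_equilibration(x)
    g = statistical_inefficiency(x[start:])
    info = DecorrelationInfo(start=start, g=g, n_eff=(len(x) - start) / g)
    return subsample_decorrelated(x, info), info


def bootstrap_statistic(
    series: np.ndarray,
    statistic: Callable[[np.ndarray], float],
    n_resamples: int = 200,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Point estimate and bootstrap standard error of a statistic.

    Resamples frames with replacement; the caller is responsible for
    passing decorrelated data.  Reproducible under a fixed seed.
    """
    x = np.asarray(series, dtype=float)
    if len(x) == 0:
        raise ValueError("empty series")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    estimate = float(statistic(x))
    idx = rng.integers(0, len(x), size=(n_resamples, len(x)))
    stats = np.array([statistic(x[i]) for i in idx])
    return estimate, float(stats.std(ddof=1))
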