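"""Kinetic-energy ensemble validation.

In any constant-temperature ensemble the kinetic energy of a system (or
of any subset of its degrees of freedom) follows a gamma distribution:
for N degrees of freedom at temperature T, the momentum components are
independent normals with variance m kB T, so

    K ~ Gamma(shape = N/2, scale = kB T),

with mean N kB T / 2 and standard deviation sqrt(N/2) kB T.  Two checks
follow:

* a *strict* test: one-sample Kolmogorov–Smirnov of the sampled kinetic
  energies against the analytic gamma law, with shape and scale taken
  from the system and the thermostat target — never fitted to the data
  (fitting would invalidate the K-S p-value);
* a *non-strict* test: the sample mean and standard deviation are mapped
  to equivalent temperatures

      T_mu    = 2 <K> / (N kB),
      T_sigma = sqrt(2/N) std(K) / kB,

  with bootstrap standard errors; estimates more than a few standard
  errors from the target temperature are flagged.  T_sigma reads as "the
  distribution has the width of a correct ensemble at T_sigma" — a
  weak-coupling (Berendsen) thermostat, for example, keeps T_mu on target
  while T_sigma comes out far too low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import KB
from .prep import bootstrap_statistic


@dataclass(frozen=True)
class KineticReference:
    """Analytic kinetic-energy distribution for N dof at temperature T."""

    ndof: float
    temperature: float

    def __post_init__(self) -> None:
        if self.ndof < 1:
            raise ValueError("need at least one degree of freedom")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def shape(self) -> float:
        return self.ndof / 2.0

    @property
    def scale(self) -> float:
        """Scale parameter theta = kB T in kJ/mol."""
        return KB * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.scale

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def std(self) -> float:
        return np.sqrt(self.shape) * self.scale

    @property
    def distribution(self) -> stats.rv_continuous:
        """Frozen scipy gamma distribution."""
        return stats.gamma(a=self.shape, scale=self.scale)


def kinetic_reference(ndof: float, temperature: float) -> KineticReference:
    """Build the analytic gamma reference for a system.

    ``ndof`` should already account for globally removed degrees of
    freedom (e.g. centre-of-mass motion removal); see
    :attr:`simval.data.SystemInfo.ndof_effective`.
    """
    return KineticReference(ndof=ndof, temperature=temperature)


def _check_series(K: np.ndarray, min_len: int = 20) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 1:
        raise ValueError("kinetic-energy series must be one-dimensional")
    if len(K) < min_len:
        raise ValueError(f"series too short (need >= {min_len} frames)")
    if np.any(K < 0):
        raise ValueError("negative kinetic energies in series")
    return K


def ks_test_kinetic(K_series: np.ndarray, ref: KineticReference) -> float:
    """Strict test: one-sample K-S p-value against the analytic gamma law.

    The reference parameters come from the system and target temperature,
    never from the series itself, so the standard K-S null distribution
    applies.  The caller must pass decorrelated frames.  A p-value of
    0.02 means: were the null true, a sample at least this extreme would
    occur with probability 2%.
    """
    K = _check_series(K_series)
    result = stats.kstest(K, ref.distribution.cdf)
    return float(result.pvalue)


@dataclass(frozen=True)
class KineticTestResult:
    """Result of the moment-level (non-strict) kinetic-energy test."""

    t_mean: float
    t_mean_se: float
    t_std: float
    t_std_se: float
    target: float
    dev_mean: float  #: |T_mu - T| in units of its SE
    dev_std: float  #: |T_sigma - T| in units of its SE
    tolerance: float
    passed: bool
    p_value: float | None = None  #: strict K-S p-value, when computed

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"T(mean)  = {self.t_mean:9.3f} +- {self.t_mean_se:.3f} K "
            f"({self.dev_mean:.1f} SE from target {self.target:g} K)",
            f"T(sigma) = {self.t_std:9.3f} +- {self.t_std_se:.3f} K "
            f"({self.dev_std:.1f} SE from target)",
            f"verdict: {'pass' if self.passed else 'FAIL'} "
            f"(tolerance {self.tolerance:g} SE)",
        ]
        if self.p_value is not None:
            lines.insert(0, f"K-S p-value = {self.p_value:.3g}")
        return "\n".join(lines)


def mean_std_test(
    K_series: np.ndarray,
    ref: KineticReference,
    n_resamples: int = 200,
    seed: int | np.random.Generator | None = None,
    tolerance: float = 3.0,
    include_strict: bool = False,
) -> KineticTestResult:
    """Non-strict test: temperature equivalents of mean and width.

    Bootstrap standard errors use ``n_resamples`` resamples of the
    (decorrelated) series.  The verdict fails when either temperature
    equivalent deviates from the target by more than ``tolerance``
    standard errors; 2–3 SE is the usual flagging range.
    """
    K = _check_series(K_series)
    N, T = ref.ndof, ref.temperature
    rng = np.random.default_rng(seed)

    def t_mu(x: np.ndarray) -> float:
        return 2.0 * x.mean() / (N * KB)

    def t_sigma(x: np.ndarray) -> float:
        return np.sqrt(2.0 / N) * x.std(ddof=1) / KB

    t_mean, t_mean_se = bootstrap_statistic(K, t_mu, n_resamples, rng)
    t_std, t_std_se = bootstrap_statistic(K, t_sigma, n_resamples, rng)
    dev_mean = abs(t_mean - T) / t_mean_se if t_mean_se > 0 else np.inf
    dev_std = abs(t_std - T) / t_std_se if t_std_se > 0 else np.inf
    p = ks_test_kinetic(K, ref) if include_strict else None
    return KineticTestResult(
        t_mean=t_mean,
        t_mean_se=t_mean_se,
        t_std=t_std,
        t_std_se=t_std_se,
        target=T,
        dev_mean=float(dev_mean),
        dev_std=float(dev_std),
        tolerance=tolerance,
        passed=bool(dev_mean <= tolerance and dev_std <= tolerance),
        p_value=p,
    )


def sensitivity_scan(
    ndof: float,
    t_ref: float,
    sample_sizes: np.ndarray,
    temperatures: np.ndarray,
    repeats: int = 10,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Mean K-S p-value grid over (sample size, generating temperature).

    For each cell, draws ``repeats`` gamma samples of the given size at
    the given temperature and tests each against the reference at
    ``t_ref`` with the same number of degrees of freedom.  The grid maps
    out the sensitivity of the strict test: larger samples, larger
    temperature offsets and more degrees of freedom all drive the mean
    p-value down.

    Returns an array of shape ``(len(temperatures), len(sample_sizes))``.
    """
    if repeats < 10:
        raise ValueError("need at least 10 repeats per cell")
    rng = np.random.default_rng(seed)
    ref = kinetic_reference(ndof, t_ref)
    out = np.empty((len(temperatures), len(sample_sizes)))
    for i, T in enumerate(temperatures):
        gen = stats.gamma(a=ndof / 2.0, scale=KB * T)
        for j, n in enumerate(sample_sizes):
            ps = [
                ks_test_kinetic(gen.rvs(size=int(n), random_state=rng), ref)
                for _ in range(repeats)
            ]
            out[i, j] = np.mean(ps)
    return out
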