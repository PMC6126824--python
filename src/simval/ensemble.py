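"""Configurational-ensemble validation via maximum-likelihood slope fits.

The distributions of configurational observables (potential energy U,
volume V, particle number N) are not known analytically, but the *ratio*
of their distributions between two state points is: the density of states
cancels, leaving a log-ratio linear in the observables.  For two
simulations of the same system,

    NVT:   log P(E|b2)/P(E|b1)       = const - (b2 - b1) E
    NPT:   log P(E,V|b2,P2)/P(E,V|b1,P1)
                                     = const - (b2 - b1) E - (b2 P2 - b1 P1) V
    muVT:  log P(E,N|b2,mu2)/P(E,N|b1,mu1)
                                     = const - (b2 - b1) E + (b2 mu2 - b1 mu1) N

with b = 1/(kB T).  A trajectory pair sampling the correct ensembles must
reproduce these slopes.  The slopes are estimated by a pooled logistic
maximum-likelihood fit (the standard unbinned realization of the linear
log-ratio: which of the two state points a sample came from is logistic
in the observables, with a free intercept absorbing the unknown
free-energy offset).  The estimate is converted to intuitive interval
estimates

    dT' = a_E kB T1 T2        (~ T1 - T2)
    dP' = a_V kB T            (single-T pressure fit)
    dP' = a_V kB (T1 + T2)/2  (two-parameter T,P fit)

and judged by its deviation from the true interval in units of the fit's
standard error (analytic from the inverse Hessian, or bootstrap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import BAR_NM3_TO_KJ_PER_MOL, KB
from .data import EnsembleSpec

MODES = ("T", "P", "TP", "mu", "Tmu")

#: slope names per fit mode, in design-matrix order
MODE_SLOPES = {
    "T": ("a_E",),
    "P": ("a_V",),
    "TP": ("a_E", "a_V"),
    "mu": ("a_N",),
    "Tmu": ("a_E", "a_N"),
}

#: sign with which each observable enters the logistic design so that the
#: fitted coefficient equals the slope as written in the log-ratio above
_SLOPE_SIGN = {"a_E": -1.0, "a_V": -1.0, "a_N": +1.0}

#: observable feeding each slope
_SLOPE_OBS = {"a_E": "energy", "a_V": "volume", "a_N": "n_species"}


class OverlapError(RuntimeError):
    """The two samples barely overlap; the method breaks down.

    Choose state points closer together (see :func:`suggest_intervals`).
    """


@dataclass
class StatePointPair:
    """Two state points of the same system with their observable samples.

    The energy samples should be decorrelated before fitting (see
    :mod:`simval.prep`); ``energy`` may hold potential energy, total
    energy, or enthalpy series depending on the check being run.
    Potential energy is generally preferable: the kinetic part is
    independent of the configurational observables and is checked more
    rigorously by the kinetic-energy tests.
    """

    ensemble1: EnsembleSpec
    ensemble2: EnsembleSpec
    energy: tuple[np.ndarray, np.ndarray] | None = None
    volume: tuple[np.ndarray, np.ndarray] | None = None
    n_species: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.ensemble1.kind != self.ensemble2.kind:
            raise ValueError("state points must share the ensemble kind")
        for name in ("energy", "volume", "n_species"):
            v = getattr(self, name)
            if v is not None:
                setattr(
                    self,
                    name,
                    (np.asarray(v[0], float), np.asarray(v[1], float)),
                )

    def swapped(self) -> "StatePointPair":
        """The same pair with the two state points exchanged."""

        def flip(v):
            return None if v is None else (v[1], v[0])

        return StatePointPair(
            ensemble1=self.ensemble2,
            ensemble2=self.ensemble1,
            energy=flip(self.energy),
            volume=flip(self.volume),
            n_species=flip(self.n_species),
        )


@dataclass
class EnsembleFitResult:
    """Maximum-likelihood slopes and their uncertainty."""

    mode: str
    slopes: dict[str, float]
    covariance: np.ndarray  #: analytic covariance (inverse Hessian), slopes only
    n_samples: tuple[int, int]
    n_iterations: int
    bootstrap_covariance: np.ndarray | None = None

    def slope_se(self, name: str, source: str = "analytic") -> float:
        names = MODE_SLOPES[self.mode]
        i = names.index(name)
        cov = (
            self.bootstrap_covariance
            if source == "bootstrap"
            else self.covariance
        )
        if cov is None:
            raise ValueError(f"no {source} covariance available")
        return float(np.sqrt(cov[i, i]))


def _features(pair: StatePointPair, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Stacked signed feature matrix and labels for the logistic fit."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    cols1, cols2 = [], []
    for name in MODE_SLOPES[mode]:
        obs = getattr(pair, _SLOPE_OBS[name])
        if obs is None:
            raise ValueError(f"mode {mode!r} needs the {_SLOPE_OBS[name]} samples")
        x1, x2 = obs
        _check_overlap(x1, x2, _SLOPE_OBS[name])
        sign = _SLOPE_SIGN[name]
        cols1.append(sign * x1)
        cols2.append(sign * x2)
    F = np.column_stack(
        [np.concatenate([c1, c2]) for c1, c2 in zip(cols1, cols2)]
    )
    y = np.concatenate([np.zeros(len(cols1[0])), np.ones(len(cols2[0]))])
    return F, y


def _check_overlap(x1: np.ndarray, x2: np.ndarray, name: str) -> None:
    f12 = np.mean((x1 >= x2.min()) & (x1 <= x2.max()))
    f21 = np.mean((x2 >= x1.min()) & (x2 <= x1.max()))
    if min(f12, f21) < 0.01:
        raise OverlapError(
            f"{name} samples overlap by less than 1% "
            f"({f12:.2%} / {f21:.2%}); the state points are too far apart"
        )


def _logistic_newton(
    F: np.ndarray,
    y: np.ndarray,
    grad_tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Newton fit of logit P(y=1|f) = b + f . theta with step halving.

    Features are centred and scaled internally for conditioning; the
    returned coefficients and covariance are on the original scale.
    Returns (coefficients incl. intercept, covariance, iterations).
    """
    n, k = F.shape
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (F - mu) / sd
    X = np.column_stack([np.ones(n), Z])

    n1 = np.sum(y == 0)
    n2 = n - n1
    theta = np.zeros(k + 1)
    theta[0] = np.log(n2 / n1)

    def nll(th: np.ndarray) -> float:
        eta = X @ th
        # log(1 + e^eta) - y*eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    current = nll(theta)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ theta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (p - y)
        if np.linalg.norm(grad) < grad_tol:
            break
        w = p * (1.0 - p)
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("singular Hessian in logistic fit") from exc
        # step halving on the negative log-likelihood
        lam = 1.0
        for _ in range(50):
            trial = theta - lam * step
            new = nll(trial)
            if new <= current + 1e-12:
                theta, current = trial, new
                break
            lam *= 0.5
        else:
            break
    else:
        raise RuntimeError(f"logistic fit did not converge in {max_iter} iterations")

    eta = X @ theta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    H = X.T @ (X * w[:, None])
    cov_scaled = np.linalg.inv(H)

    # undo the feature scaling: slope_j = theta_j / sd_j
    scale = np.concatenate([[1.0], 1.0 / sd])
    coeffs = theta * scale
    coeffs[0] -= np.sum(coeffs[1:] * mu)
    cov = cov_scaled * np.outer(scale, scale)
    return coeffs, cov, it


def ml_slope_fit(pair: StatePointPair, mode: str = "T") -> EnsembleFitResult:
    """Maximum-likelihood estimate of the log-ratio slope(s).

    ``mode`` selects which relation is fitted:

    * ``"T"``  — temperature difference via energy/enthalpy (slope a_E);
    * ``"P"``  — pressure difference via volume (slope a_V);
    * ``"TP"`` — simultaneous two-parameter fit (a_E, a_V);
    * ``"mu"`` — chemical-potential difference via particle number (a_N);
    * ``"Tmu"``— simultaneous (a_E, a_N) fit, single species.

    The analytic covariance is the inverse Hessian of the log-likelihood
    at the optimum, restricted to the slope parameters.
    """
    F, y = _features(pair, mode)
    coeffs, cov, n_iter = _logistic_newton(F, y)
    names = MODE_SLOPES[mode]
    slopes = {name: float(coeffs[1 + i]) for i, name in enumerate(names)}
    return EnsembleFitResult(
        mode=mode,
        slopes=slopes,
        covariance=cov[1:, 1:],
        n_samples=(int(np.sum(y == 0)), int(np.sum(y == 1))),
        n_iterations=n_iter,
    )


def bootstrap_slope_errors(
    pair: StatePointPair,
    mode: str = "T",
    n_resamples: int = 200,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Bootstrap covariance of the slope estimates.

    Each side's (decorrelated) samples are resampled with replacement
    independently and the fit repeated; returns the empirical covariance
    of the slope vector over resamples.  Fewer than ~50 resamples give a
    noisy covariance; the default follows common practice (200).
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    rng = np.random.default_rng(seed)
    names = MODE_SLOPES[mode]
    draws = np.empty((n_resamples, len(names)))
    for r in range(n_resamples):
        # one index draw per observable keeps per-frame pairing intact
        idx1 = idx2 = None
        resampled: dict[str, tuple[np.ndarray, np.ndarray] | None] = {}
        for attr in ("energy", "volume", "n_species"):
            v = getattr(pair, attr)
            if v is None:
                resampled[attr] = None
                continue
            if idx1 is None:
                idx1 = rng.integers(0, len(v[0]), len(v[0]))
                idx2 = rng.integers(0, len(v[1]), len(v[1]))
            resampled[attr] = (v[0][idx1], v[1][idx2])
        boot_pair = StatePointPair(
            ensemble1=pair.ensemble1, ensemble2=pair.ensemble2, **resampled
        )
        fit = ml_slope_fit(boot_pair, mode)
        draws[r] = [fit.slopes[n] for n in names]
    return np.atleast_2d(np.cov(draws, rowvar=False))


# ---------------------------------------------------------------------------
# interval estimates and verdicts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalEstimates:
    """Intuitive temperature/pressure interval estimates from the slopes."""

    delta_T: float | None = None  #: K, ~ T1 - T2
    delta_T_se: float | None = None
    delta_P: float | None = None  #: bar, ~ P2 - P1
    delta_P_se: float | None = None


def true_slopes(
    ensemble1: EnsembleSpec, ensemble2: EnsembleSpec, mode: str
) -> dict[str, float]:
    """Analytic slope values implied by the declared state points.

    a_E = b2 - b1 in (kJ/mol)^-1; a_V = b2 P2 - b1 P1 in nm^-3 (pressures
    converted from bar); a_N = b2 mu2 - b1 mu1 (dimensionless).
    """
    out: dict[str, float] = {}
    b1, b2 = ensemble1.beta, ensemble2.beta
    for name in MODE_SLOPES[mode]:
        if name == "a_E":
            out[name] = b2 - b1
        elif name == "a_V":
            p1, p2 = ensemble1.pressure, ensemble2.pressure
            if p1 is None or p2 is None:
                raise ValueError("both state points need a pressure")
            out[name] = (b2 * p2 - b1 * p1) * BAR_NM3_TO_KJ_PER_MOL
        elif name == "a_N":
            m1, m2 = ensemble1.chemical_potential, ensemble2.chemical_potential
            if m1 is None or m2 is None:
                raise ValueError("both state points need a chemical potential")
            out[name] = b2 * float(np.atleast_1d(m2)[0]) - b1 * float(
                np.atleast_1d(m1)[0]
            )
    return out


def interval_estimates(
    slopes: dict[str, float],
    T1: float,
    T2: float | None = None,
    slope_ses: dict[str, float] | None = None,
    mode: str = "T",
) -> IntervalEstimates:
    """Convert slope estimates into temperature/pressure intervals.

    * ``dT' = a_E kB T1 T2`` (modes with a_E and two temperatures);
    * ``dP' = a_V kB T`` for the single-temperature pressure fit;
    * ``dP' = a_V kB (T1 + T2)/2`` for the two-parameter fit.

    Standard errors propagate linearly from the slope SEs.  Volumes are
    fitted in nm^3, so a_V kB T (kJ/mol/nm^3) is converted to bar.
    """
    slope_ses = slope_ses or {}
    dT = dT_se = dP = dP_se = None
    if "a_E" in slopes:
        t2 = T2 if T2 is not None else T1
        factor = KB * T1 * t2
        dT = slopes["a_E"] * factor
        if "a_E" in slope_ses:
            dT_se = slope_ses["a_E"] * factor
    if "a_V" in slopes:
        if mode == "TP":
            if T2 is None:
                raise ValueError("two-parameter fit needs both temperatures")
            t_eff = 0.5 * (T1 + T2)
        else:
            t_eff = T1
        factor = KB * t_eff / BAR_NM3_TO_KJ_PER_MOL
        dP = slopes["a_V"] * factor
        if "a_V" in slope_ses:
            dP_se = slope_ses["a_V"] * factor
    return IntervalEstimates(dT, dT_se, dP, dP_se)


@dataclass(frozen=True)
class DeviationReport:
    deviations: dict[str, float]  #: |estimate - true| / SE per quantity
    tolerance: float
    passed: bool


def deviation_verdict(
    estimates: dict[str, tuple[float, float]],
    true_values: dict[str, float],
    tolerance: float = 3.0,
) -> DeviationReport:
    """Deviations in standard-error units and an overall verdict.

    ``estimates`` maps quantity names to ``(value, se)``;  a deviation
    beyond ``tolerance`` standard errors on any quantity fails the check
    (about 3 sigma is a clear sign of a systematic error; statistical
    noise alone reaches it rarely).
    """
    devs: dict[str, float] = {}
    for name, (value, se) in estimates.items():
        if name not in true_values:
            raise ValueError(f"no true value for {name!r}")
        if se <= 0:
            raise ValueError(f"non-positive standard error for {name!r}")
        devs[name] = abs(value - true_values[name]) / se
    return DeviationReport(
        deviations=devs,
        tolerance=tolerance,
        passed=all(d <= tolerance for d in devs.values()),
    )


# ---------------------------------------------------------------------------
# interval suggestion (rule of thumb)
# ---------------------------------------------------------------------------


def suggest_intervals(
    T: float,
    sigma_E: float | None = None,
    sigma_V: float | None = None,
    heat_capacity: float | None = None,
    compressibility: float | None = None,
    volume: float | None = None,
    factor_two: bool = True,
) -> tuple[float | None, float | None]:
    """Suggested state-point spacings (dT in K, dP in bar) for the check.

    The fit is most efficient when the two distributions are separated by
    roughly the sum of their standard deviations, giving

        dT = 2 kB T^2 / sigma_E,      dP = 2 kB T / sigma_V,

    with sigma_E (kJ/mol) the width of the energy observable used and
    sigma_V (nm^3) the width of the volume distribution.  The widths can
    be measured from a single trajectory or estimated from material
    properties:

        sigma_E^2 = 2 kB T^2 C        (C = C_V for NVT, C_P for NPT,
                                       in kJ/mol/K)
        sigma_V^2 = 2 kB T V kappa_T  (kappa_T in 1/bar, V in nm^3)

    ``factor_two=False`` switches the material-property route to the
    textbook fluctuation relations without the leading factor of two
    (sigma_E^2 = kB T^2 C, sigma_V^2 = kB T V kappa_T); both conventions
    are found in the literature and the spacing formula is a heuristic
    either way.
    """
    c = 2.0 if factor_two else 1.0
    if sigma_E is None and heat_capacity is not None:
        sigma_E = float(np.sqrt(c * KB * T**2 * heat_capacity))
    if sigma_V is None and compressibility is not None:
        if volume is None:
            raise ValueError("volume needed to use the compressibility route")
        kbt_bar_nm3 = KB * T / BAR_NM3_TO_KJ_PER_MOL  # kB T in bar nm^3
        sigma_V = float(np.sqrt(c * kbt_bar_nm3 * volume * compressibility))
    dT = dP = None
    if sigma_E is not None:
        if sigma_E <= 0:
            raise ValueError("sigma_E must be positive")
        dT = 2.0 * KB * T**2 / sigma_E
    if sigma_V is not None:
        if sigma_V <= 0:
            raise ValueError("sigma_V must be positive")
        dP = 2.0 * KB * T / sigma_V / BAR_NM3_TO_KJ_PER_MOL
    return dT, dP
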