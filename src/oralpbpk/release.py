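"""Release-kinetics model library.

Seven families of cumulative-release functions F(t) = M_t/M_∞, their
release-rate derivative R_release(t) = M_∞ · dF/dt, bounded nonlinear
least-squares fitting to time–fraction data, and AIC/BIC model selection.

Families
--------
``higuchi``                    F = k_H·√t               (matrix diffusion)
``korsmeyer_peppas``           F = k·tⁿ                 (power law; n classifies
                               Fickian vs anomalous vs relaxational transport)
``peppas_sahlin``              F = k₁·tᵐ + k₂·t²ᵐ       (diffusion + relaxation)
``hixson_crowell``             W₀^⅓ − W_t^⅓ = k_HC·t    (surface erosion of a
                               shrinking particle, expressed as a fraction)
``baker_lonsdale``             (3/2)[1 − (1−F)^⅔] − F = k_BL·t  (spherical matrix,
                               implicit; solved by bracketed root-finding)
``weibull``                    F = 1 − exp(−a·t^b)      (flexible empirical)
``biphasic_burst_zero_order``  burst fraction released first-order at
                               ``burst_rate``, remainder at a constant rate
                               until ``t_end`` (chip-style biphasic profiles)

Power-law families are early-time approximations, so every F is clamped to 1
and the release rate is zero after exhaustion: the coupled transport model
needs a globally defined, mass-conserving source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "FAMILIES",
    "ReleaseModel",
    "ReleaseData",
    "FitResult",
    "FitFailure",
    "cumulative_fraction",
    "release_rate",
    "time_to_fraction",
    "biphasic_model",
    "fit_release",
    "select_model",
]

#: floor applied to t for families with an unbounded initial rate [min]
EPS_T = 1e-6

# coefficient names, default initial guesses and (lower, upper) bounds
_FAMILY_COEFFS: dict[str, dict[str, tuple[float, float, float]]] = {
    "higuchi": {"k_H": (0.05, 1e-12, np.inf)},
    "korsmeyer_peppas": {"k": (0.05, 1e-12, np.inf), "n": (0.5, 1e-6, 1.5)},
    "peppas_sahlin": {
        "k1": (0.05, 1e-12, np.inf),
        "k2": (1e-4, 0.0, np.inf),
        "m": (0.45, 1e-6, 1.5),
    },
    "hixson_crowell": {"k_HC": (0.01, 1e-12, np.inf), "W0": (1.0, 1e-12, np.inf)},
    "baker_lonsdale": {"k_BL": (1e-3, 1e-15, np.inf)},
    "weibull": {"a": (0.05, 1e-12, np.inf), "b": (1.0, 1e-6, 5.0)},
    "biphasic_burst_zero_order": {
        "burst_fraction": (0.3, 0.0, 1.0),
        "burst_rate": (0.01, 1e-12, np.inf),
        "zero_order_rate": (1e-4, 0.0, np.inf),
        "t_end": (1e4, 1.0, np.inf),
    },
}

FAMILIES: tuple[str, ...] = tuple(_FAMILY_COEFFS)

# Baker–Lonsdale g(F) = (3/2)[1 − (1−F)^{2/3}] − F, increasing from 0 to 1/2
def _bl_g(F: float) -> float:
    return 1.5 * (1.0 - (1.0 - F) ** (2.0 / 3.0)) - F


def _bl_gprime(F: float) -> float:
    return (1.0 - F) ** (-1.0 / 3.0) - 1.0


@dataclass(frozen=True)
class ReleaseModel:
    """A parameterized cumulative-release profile with total dose ``m_inf``."""

    family: str
    coefficients: dict[str, float]
    m_inf: float = 1.0  # total releasable dose M_∞ [µg]

    def __post_init__(self) -> None:
        if self.family not in _FAMILY_COEFFS:
            raise ValueError(
                f"unknown release family {self.family!r}; choose from {FAMILIES}"
            )
        expected = set(_FAMILY_COEFFS[self.family])
        got = set(self.coefficients)
        if got != expected:
            raise ValueError(
                f"{self.family} expects coefficients {sorted(expected)}, got {sorted(got)}"
            )
        if self.m_inf <= 0:
            raise ValueError("m_inf must be positive")

    def fraction(self, t):
        return cumulative_fraction(self, t)

    def rate(self, t):
        return release_rate(self, t)


@dataclass(frozen=True)
class ReleaseData:
    """Observed cumulative-release curve: times [min] and fractions [–]."""

    times: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fractions", f)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fractions must be 1-D arrays of equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be non-negative")
        # small experimental overshoot above 1 is tolerated
        if np.any(f < 0) or np.any(f > 1.05):
            raise ValueError("fractions must lie in [0, 1.05]")

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a nonlinear least-squares release fit."""

    family: str
    coefficients: dict[str, float]
    rss: float
    n_obs: int
    converged: bool = True
    message: str = ""

    @property
    def n_params(self) -> int:
        return len(self.coefficients)

    @property
    def aic(self) -> float:
        # Gaussian log-likelihood profile: n·ln(RSS/n) + 2p
        return self.n_obs * math.log(max(self.rss, 1e-300) / self.n_obs) + 2 * self.n_params

    @property
    def bic(self) -> float:
        return (
            self.n_obs * math.log(max(self.rss, 1e-300) / self.n_obs)
            + self.n_params * math.log(self.n_obs)
        )

    def model(self, m_inf: float = 1.0) -> ReleaseModel:
        return ReleaseModel(self.family, dict(self.coefficients), m_inf)


@dataclass(frozen=True)
class FitFailure:
    """A family skipped during model selection, with the reason."""

    family: str
    reason: str


def _raw_fraction(family: str, c: dict[str, float], t: np.ndarray) -> np.ndarray:
    """Unclamped F(t) for vectorized t ≥ 0."""
    if family == "higuchi":
        return c["k_H"] * np.sqrt(t)
    if family == "korsmeyer_peppas":
        return c["k"] * np.power(t, c["n"])
    if family == "peppas_sahlin":
        m = c["m"]
        return c["k1"] * np.power(t, m) + c["k2"] * np.power(t, 2 * m)
    if family == "hixson_crowell":
        w0_13 = c["W0"] ** (1.0 / 3.0)
        wt = np.maximum(w0_13 - c["k_HC"] * t, 0.0) ** 3
        return 1.0 - wt / c["W0"]
    if family == "weibull":
        return 1.0 - np.exp(-c["a"] * np.power(t, c["b"]))
    if family == "biphasic_burst_zero_order":
        bf = c["burst_fraction"]
        burst = bf * (1.0 - np.exp(-c["burst_rate"] * t))
        # zero_order_rate is in total-fraction per minute; (1 − bf)/t_end
        # releases the remainder exactly over the zero-order window
        zero = c["zero_order_rate"] * np.minimum(t, c["t_end"])
        return burst + zero
    if family == "baker_lonsdale":
        k = c["k_BL"]

        def solve_one(ti: float) -> float:
            rhs = k * ti
            if rhs <= 0.0:
                return 0.0
            if rhs >= 0.5:  # g(1) = 1/2: matrix exhausted
                return 1.0
            # g is continuous and increasing on [0, 1], so the bracket holds
            return brentq(lambda F: _bl_g(F) - rhs, 0.0, 1.0, xtol=1e-14)

        return np.vectorize(solve_one, otypes=[float])(t)
    raise ValueError(f"unknown release family {family!r}")


def cumulative_fraction(model: ReleaseModel, t):
    """Cumulative released fraction F(t) ∈ [0, 1] at time(s) t [min]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.clip(_raw_fraction(model.family, model.coefficients, t_arr), 0.0, 1.0)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _raw_rate(family: str, c: dict[str, float], t: np.ndarray) -> np.ndarray:
    """dF/dt, before the exhaustion clamp; t already floored away from 0."""
    if family == "higuchi":
        return c["k_H"] / (2.0 * np.sqrt(t))
    if family == "korsmeyer_peppas":
        return c["k"] * c["n"] * np.power(t, c["n"] - 1.0)
    if family == "peppas_sahlin":
        m = c["m"]
        return c["k1"] * m * np.power(t, m - 1.0) + 2 * m * c["k2"] * np.power(
            t, 2 * m - 1.0
        )
    if family == "hixson_crowell":
        w0_13 = c["W0"] ** (1.0 / 3.0)
        rem = np.maximum(w0_13 - c["k_HC"] * t, 0.0)
        return 3.0 * c["k_HC"] * rem**2 / c["W0"]
    if family == "weibull":
        a, b = c["a"], c["b"]
        return a * b * np.power(t, b - 1.0) * np.exp(-a * np.power(t, b))
    if family == "biphasic_burst_zero_order":
        bf = c["burst_fraction"]
        burst = bf * c["burst_rate"] * np.exp(-c["burst_rate"] * t)
        zero = np.where(t < c["t_end"], c["zero_order_rate"], 0.0)
        return burst + zero
    if family == "baker_lonsdale":
        # implicit-function derivative: dF/dt = k / g'(F)
        F = _raw_fraction(family, c, t)
        F = np.minimum(F, 1.0 - 1e-12)
        gp = np.maximum(_bl_gprime(F), 1e-12)
        return c["k_BL"] / gp
    raise ValueError(f"unknown release family {family!r}")


def release_rate(model: ReleaseModel, t):
    """Instantaneous release rate R_release(t) = M_∞·dF/dt [µg/min].

    Families with an unbounded initial rate (Higuchi, power-law with exponent
    < 1, Weibull with b < 1, Baker–Lonsdale) are evaluated at
    ``max(t, EPS_T)``; the mass this floor forfeits is below 1e-4 of the dose.
    The rate is zero once F has reached 1.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    t_safe = np.maximum(t_arr, EPS_T)
    rate = _raw_rate(model.family, model.coefficients, t_safe)
    exhausted = _raw_fraction(model.family, model.coefficients, t_arr) >= 1.0
    rate = np.where(exhausted, 0.0, rate) * model.m_inf
    return float(rate) if np.isscalar(t) or t_arr.ndim == 0 else rate


def time_to_fraction(model: ReleaseModel, frac: float, t_max: float = 1e9) -> float:
    """Smallest t with F(t) ≥ frac, by bisection on the clamped profile."""
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    f = lambda t: cumulative_fraction(model, t) - frac
    if f(t_max) < 0:
        raise ValueError(f"profile never reaches F = {frac} before t = {t_max}")
    return brentq(f, 0.0, t_max, xtol=1e-10, rtol=1e-12)


def biphasic_model(
    burst_fraction: float,
    burst_rate: float,
    t_end: float,
    m_inf: float = 1.0,
) -> ReleaseModel:
    """Mass-complete biphasic profile: the zero-order rate is chosen so the
    non-burst remainder is released exactly over ``[0, t_end]``."""
    return ReleaseModel(
        "biphasic_burst_zero_order",
        {
            "burst_fraction": burst_fraction,
            "burst_rate": burst_rate,
            "zero_order_rate": (1.0 - burst_fraction) / t_end,
            "t_end": t_end,
        },
        m_inf,
    )


def _check_dof(family: str, n_obs: int) -> None:
    p = len(_FAMILY_COEFFS[family])
    if n_obs < p + 1:
        raise ValueError(
            f"under-determined fit: {family} has {p} coefficient(s) "
            f"but only {n_obs} observation(s); need at least {p + 1}"
        )


def fit_release(
    data: ReleaseData,
    family: str,
    x0: dict[str, float] | None = None,
) -> FitResult:
    """Bounded nonlinear least squares of one family to a release curve.

    Coefficients are constrained positive, with the power-law exponents in
    (0, 1.5) and the Weibull shape in (0, 5).  AIC/BIC follow from the
    profiled Gaussian likelihood (additive i.i.d. error), so ΔAIC compares
    families on the same data only.
    """
    if family not in _FAMILY_COEFFS:
        raise ValueError(f"unknown release family {family!r}")
    _check_dof(family, data.n_obs)
    spec = _FAMILY_COEFFS[family]
    names = list(spec)
    p0 = np.array([x0.get(n, spec[n][0]) if x0 else spec[n][0] for n in names])
    lb = np.array([spec[n][1] for n in names])
    ub = np.array([spec[n][2] for n in names])
    p0 = np.clip(p0, lb + 1e-15, np.where(np.isfinite(ub), ub - 1e-15, p0))

    # data-driven starting point for scale coefficients: anchor to last point
    t_last, f_last = float(data.times[-1]), float(np.clip(data.fractions[-1], 1e-6, 1.0))
    start = dict(zip(names, p0))
    if family == "higuchi":
        start["k_H"] = f_last / math.sqrt(t_last)
    elif family == "korsmeyer_peppas":
        start["k"] = f_last / t_last ** start["n"]
    elif family == "peppas_sahlin":
        start["k1"] = 0.8 * f_last / t_last ** start["m"]
        start["k2"] = 0.2 * f_last / t_last ** (2 * start["m"])
    elif family == "weibull":
        start["a"] = -math.log(max(1.0 - min(f_last, 0.99), 1e-6)) / t_last
    elif family == "baker_lonsdale":
        start["k_BL"] = _bl_g(min(f_last, 0.999)) / t_last
    elif family == "hixson_crowell":
        start["k_HC"] = (1.0 - (1.0 - min(f_last, 0.99)) ** (1.0 / 3.0)) / t_last
    elif family == "biphasic_burst_zero_order":
        start["t_end"] = t_last
    if x0:
        start.update(x0)
    p0 = np.clip(
        np.array([start[n] for n in names]), lb + 1e-15,
        np.where(np.isfinite(ub), ub - 1e-15, 1e300),
    )

    def resid(theta: np.ndarray) -> np.ndarray:
        c = dict(zip(names, theta))
        return _raw_fraction(family, c, data.times) - data.fractions

    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf", xtol=1e-14,
                        ftol=1e-14, gtol=1e-14, max_nfev=2000)
    rss = float(2.0 * sol.cost)
    coeffs = dict(zip(names, (float(v) for v in sol.x)))
    if not sol.success:
        return FitResult(family, coeffs, rss, data.n_obs, converged=False,
                         message=f"convergence failure (final RSS = {rss:.4g}): {sol.message}")
    return FitResult(family, coeffs, rss, data.n_obs)


def select_model(
    data: ReleaseData,
    families: Sequence[str],
) -> tuple[list[FitResult], list[FitFailure]]:
    """Fit each family and rank successful fits by AIC (ascending).

    Ties are broken by fewer parameters, then family name.  Families that
    cannot be fitted (too few points, non-convergence) are returned separately
    with the reason rather than aborting the comparison.
    """
    if len(families) < 1:
        raise ValueError("model selection needs at least one candidate family")
    results: list[FitResult] = []
    skipped: list[FitFailure] = []
    for fam in families:
        try:
            fit = fit_release(data, fam)
        except ValueError as exc:
            skipped.append(FitFailure(fam, str(exc)))
            continue
        if not fit.converged:
            skipped.append(FitFailure(fam, fit.message))
            continue
        results.append(fit)
    results.sort(key=lambda r: (r.aic, r.n_params, r.family))
    return results, skipped
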