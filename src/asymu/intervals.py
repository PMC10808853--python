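"""Measurement-uncertainty intervals: classical symmetric y±U and prediction-range inversion.

The classical interval is ``y ± k·u(y)`` with standard uncertainty ``u`` equal
to the in-house reproducibility SD.  Under heteroscedasticity that rule is
inconsistent (a value can lie inside the interval of a result without the
result lying inside the interval of the value).  The consistent alternative
inverts the prediction range: with prediction curves

    f_L(y) = alpha + beta*y - k*sigma(y),   f_U(y) = alpha + beta*y + k*sigma(y)

the uncertainty interval for a measurement result ``ym`` is the set of
measurand values whose prediction interval contains ``ym``; its limits solve
``f_U(yL) = ym`` and ``f_L(yU) = ym``, and the best estimate of the measurand
is the inverse mean curve ``ycorr = (ym - alpha)/beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .profiles import MeanCurve, PrecisionProfile

__all__ = [
    "K_95_EXACT",
    "PredictionRange",
    "UncertaintyInterval",
    "standard_uncertainty",
    "expanded_uncertainty",
    "symmetric_interval",
    "consistency_check",
    "invert_prediction_range",
    "closed_form_interval",
    "best_estimate",
    "lognormal_interval",
    "k_from_probability",
]

#: Exact two-sided 95% standard-normal quantile (vs the conventional k = 2).
K_95_EXACT = float(stats.norm.ppf(0.975))


def k_from_probability(p_pred: float) -> float:
    """Coverage factor for a two-sided prediction probability (0 < p_pred < 1)."""
    if not 0.0 < p_pred < 1.0:
        raise ValueError("prediction probability must lie in (0, 1)")
    return float(stats.norm.ppf(0.5 + p_pred / 2.0))


def probability_from_k(k: float) -> float:
    return float(2.0 * stats.norm.cdf(k) - 1.0)


def standard_uncertainty(profile: PrecisionProfile, x) -> float:
    """Standard uncertainty u(x): the reproducibility SD at concentration x."""
    return profile.sd(x)


def expanded_uncertainty(profile: PrecisionProfile, x, k: float = 2.0) -> float:
    """Expanded uncertainty U(x) = k * u(x); k is the coverage factor (>= 0)."""
    if k < 0:
        raise ValueError("coverage factor k must be non-negative")
    return k * profile.sd(x)


def symmetric_interval(ym: float, profile: PrecisionProfile | None = None,
                       k: float = 2.0, rsd: float | None = None) -> tuple[float, float]:
    """Classical y ± U interval, with U = k·u evaluated *at the measurement result*.

    Either a precision profile or a constant relative standard deviation
    (``rsd``, as a fraction, e.g. 0.35) must be supplied.
    """
    ym = float(ym)
    if ym < 0:
        raise ValueError("measurement result must be non-negative")
    if (profile is None) == (rsd is None):
        raise ValueError("supply exactly one of profile / rsd")
    u = ym * rsd if rsd is not None else float(profile.sd(ym))
    U = k * u
    return (ym - U, ym + U)


def consistency_check(ym1: float, ym2: float, interval_fn,
                      band_fn=None) -> dict[str, bool]:
    """Containment check of an interval rule for two measurement results.

    ``interval_fn(ym) -> (lo, hi)`` maps a measurement result to its set of
    attributable measurand values.  The basic report flags ``mutual`` (each
    value lies in the other's interval) and ``one_way`` (containment holds in
    exactly one direction — the inconsistency signature of y±U under
    heteroscedasticity: with a constant 35% RSD, 3 lies in the interval of 10
    but 10 does not lie in the interval of 3).

    With ``band_fn(y) -> (lo, hi)`` (the prediction interval at measurand y)
    the flags instead report agreement between interval membership and
    prediction-band membership under both role assignments — the duality
    ``y in interval(ym)  <=>  ym in band(y)`` that inverted prediction ranges
    satisfy by construction and y±U violates.
    """
    if not ym1 <= ym2:
        raise ValueError("expect ym1 <= ym2")
    lo1, hi1 = interval_fn(ym1)
    lo2, hi2 = interval_fn(ym2)
    in_1 = bool(lo1 <= ym2 <= hi1)  # ym2 attributable given result ym1
    in_2 = bool(lo2 <= ym1 <= hi2)  # ym1 attributable given result ym2
    if band_fn is None:
        return {"mutual": in_1 and in_2, "one_way": in_1 != in_2}
    blo1, bhi1 = band_fn(ym1)
    blo2, bhi2 = band_fn(ym2)
    agree_1 = in_1 == bool(blo2 <= ym1 <= bhi2)  # roles: result ym1, measurand ym2
    agree_2 = in_2 == bool(blo1 <= ym2 <= bhi1)
    return {"mutual": agree_1 and agree_2, "one_way": agree_1 != agree_2}


@dataclass(frozen=True)
class UncertaintyInterval:
    """Asymmetric uncertainty interval for one routine measurement result.

    Attributes
    ----------
    ym : measurement result.
    lower, upper : uncertainty limits (``upper`` may be ``inf``).
    best_estimate : bias-corrected best estimate of the measurand, (ym-alpha)/beta.
    truncated_low : lower limit clipped at 0 (f_U(0) already exceeds ym).
    unbounded_high : no finite upper limit (prediction band swallows ym for all y).
    """

    ym: float
    lower: float
    upper: float
    best_estimate: float
    truncated_low: bool = False
    unbounded_high: bool = False

    def __iter__(self):
        return iter((self.lower, self.upper))


@dataclass(frozen=True)
class PredictionRange:
    """Concentration-indexed prediction band: mean curve ± k·sigma.

    ``k`` is the coverage factor; the equivalent two-sided prediction
    probability is available as :attr:`p_pred`.
    """

    curve: MeanCurve
    profile: PrecisionProfile
    k: float = 2.0

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("coverage factor k must be positive")

    @classmethod
    def from_probability(cls, curve: MeanCurve, profile: PrecisionProfile,
                         p_pred: float) -> "PredictionRange":
        return cls(curve=curve, profile=profile, k=k_from_probability(p_pred))

    @property
    def p_pred(self) -> float:
        return probability_from_k(self.k)

    def f_upper(self, y):
        """Upper prediction curve f_U(y) = alpha + beta y + k sigma(y)."""
        return self.curve.predict(y) + self.k * self.profile.sd(y)

    def f_lower(self, y):
        """Lower prediction curve f_L(y) = alpha + beta y - k sigma(y)."""
        return self.curve.predict(y) - self.k * self.profile.sd(y)

    def invert(self, ym: float, tol: float = 1e-9) -> UncertaintyInterval:
        return invert_prediction_range(ym, self, tol=tol)

    def contains(self, y, ym) -> bool:
        """Is the measurement ym inside the prediction interval at measurand y?"""
        return bool(self.f_lower(y) <= ym <= self.f_upper(y))


def best_estimate(ym: float, curve: MeanCurve) -> float:
    """Best estimate of the measurand: inverse mean curve (ym - alpha)/beta, floored at 0."""
    return float(curve.invert(float(ym)))


def _solve_increasing(f, target: float, lo: float, hi0: float, tol: float):
    """Root of increasing f(y) = target on [lo, inf), growing the bracket geometrically."""
    hi = max(hi0, lo + 1.0)
    flo = f(lo) - target
    for _ in range(200):
        if f(hi) - target >= 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError(
            f"could not bracket root: f({hi:g})={f(hi):g} still below target {target:g}"
        )
    root = optimize.brentq(lambda y: f(y) - target, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(f(root) - target) > tol * max(1.0, abs(target)):
        raise RuntimeError("root did not meet the requested f-tolerance")
    return float(root)


def invert_prediction_range(ym: float, rng: PredictionRange,
                            tol: float = 1e-9) -> UncertaintyInterval:
    """Invert the prediction range at a measurement result ``ym``.

    Solves ``f_U(yL) = ym`` and ``f_L(yU) = ym`` by bracketed root finding.
    ``f_U`` is strictly increasing for y >= 0 (beta > 0, sigma non-decreasing);
    if ``f_U(0) >= ym`` the lower limit is truncated at 0.  ``f_L`` has
    asymptotic slope ``beta - k*sqrt(P)``; when that is not positive the band
    eventually contains every large measurand and the upper limit is unbounded.
    """
    ym = float(ym)
    if ym < 0:
        raise ValueError("measurement result must be non-negative")
    curve, prof, k = rng.curve, rng.profile, rng.k
    ycorr = best_estimate(ym, curve)

    if rng.f_upper(0.0) >= ym:
        yL, truncated = 0.0, True
    else:
        yL = _solve_increasing(rng.f_upper, ym, 0.0, max(2.0 * ycorr, 1.0), tol)
        truncated = False

    slope_inf = curve.beta - k * math.sqrt(prof.P)
    if slope_inf <= 0:
        yU, unbounded = math.inf, True
    else:
        # f_L is strictly increasing when beta - k sqrt(P) > 0 (its derivative
        # beta - k P y / sigma(y) decreases monotonically to that limit)
        if rng.f_lower(0.0) >= ym:
            yU, unbounded = 0.0, False
        else:
            yU = _solve_increasing(rng.f_lower, ym, 0.0, max(2.0 * ycorr, 1.0), tol)
            unbounded = False

    return UncertaintyInterval(
        ym=ym, lower=yL, upper=yU, best_estimate=ycorr,
        truncated_low=truncated, unbounded_high=unbounded,
    )


def closed_form_interval(ym: float, sigma_rel: float, k: float = 2.0) -> UncertaintyInterval:
    """Closed-form asymmetric interval for constant relative SD and no bias.

    With sigma(y) = sigma_rel * y and identity mean curve the inversion has the
    explicit solution ``[ym / (1 + k*sigma_rel), ym / (1 - k*sigma_rel)]``; the
    upper limit exists only while ``k*sigma_rel < 1`` (otherwise unbounded).
    """
    ym = float(ym)
    if ym < 0:
        raise ValueError("measurement result must be non-negative")
    if sigma_rel < 0 or k <= 0:
        raise ValueError("need sigma_rel >= 0 and k > 0")
    lower = ym / (1.0 + k * sigma_rel)
    if k * sigma_rel >= 1.0:
        upper, unbounded = math.inf, True
    else:
        upper, unbounded = ym / (1.0 - k * sigma_rel), False
    return UncertaintyInterval(
        ym=ym, lower=lower, upper=upper, best_estimate=ym,
        truncated_low=False, unbounded_high=unbounded,
    )


def lognormal_interval(ym: float, sigma_log: float, k: float = 2.0) -> UncertaintyInterval:
    """Multiplicative interval ``[ym/exp(k·sigma), ym·exp(k·sigma)]``.

    Appropriate when a log transform stabilises the variance: log results are
    normal with constant SD ``sigma_log`` so the back-transformed interval is
    asymmetric by the factor exp(k·sigma_log).
    """
    ym = float(ym)
    if ym < 0 or sigma_log < 0 or k <= 0:
        raise ValueError("need ym >= 0, sigma_log >= 0, k > 0")
    f = math.exp(k * sigma_log)
    return UncertaintyInterval(ym=ym, lower=ym / f, upper=ym * f, best_estimate=ym)
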