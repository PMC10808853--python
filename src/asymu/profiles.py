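"""Mean curve, variance components and the concentration-dependent precision profile.

The in-house reproducibility of an analytical method is modelled as a variance
function of the (true) concentration ``x``,

    sigma^2(x) = C + P * x**2,

where ``C`` collects the *constant* (absolute, units^2) variance components of all
random terms and ``P`` the *proportional* (relative, dimensionless) ones.  The
expected measured concentration is the *mean curve* ``alpha + beta * x``; its
deviation from the identity expresses the method bias (absolute component
``alpha``, relative component ``beta - 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "REPEATABILITY",
    "BLOCK",
    "MeanCurve",
    "TermVariance",
    "VarianceComponents",
    "PrecisionProfile",
    "mean_response",
    "reproducibility_sd",
    "precision_breakdown",
]

#: Reserved term names. Every other term is treated as a design factor.
REPEATABILITY = "repeatability"
BLOCK = "block"


@dataclass(frozen=True)
class MeanCurve:
    """Expected measured concentration ``alpha + beta * x``.

    Parameters
    ----------
    alpha : float
        Intercept (study units); absolute bias component.
    beta : float
        Slope (dimensionless); ``beta - 1`` is the relative bias. Must be > 0.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"mean-curve slope beta must be positive, got {self.beta}")

    def predict(self, x):
        """Expected measured concentration at true concentration ``x``."""
        return self.alpha + self.beta * np.asarray(x, dtype=float)

    def invert(self, ym):
        """Inverse of the mean curve, floored at zero (bias/recovery correction)."""
        return np.maximum((np.asarray(ym, dtype=float) - self.alpha) / self.beta, 0.0)

    @classmethod
    def identity(cls) -> "MeanCurve":
        return cls(alpha=0.0, beta=1.0)


@dataclass(frozen=True)
class TermVariance:
    """Constant (units^2) and proportional (dimensionless) variance of one random term."""

    const: float = 0.0
    prop: float = 0.0

    def __post_init__(self) -> None:
        if self.const < 0 or self.prop < 0:
            raise ValueError(
                f"variance components must be non-negative, got ({self.const}, {self.prop})"
            )

    def var(self, x):
        return self.const + self.prop * np.square(np.asarray(x, dtype=float))


class VarianceComponents(Mapping[str, TermVariance]):
    """Per-term constant/proportional variance estimates.

    Reserved names: ``"repeatability"`` (residual within-run error) and ``"block"``
    (factor-level-combination effect, e.g. week).  Every other entry is a design
    factor (operator, batch, storage, ...).  Boundary zeros are legitimate
    estimates and are kept as exact zeros.
    """

    def __init__(self, terms: Mapping[str, TermVariance | tuple]):
        self._terms: dict[str, TermVariance] = {}
        for name, tv in terms.items():
            if not isinstance(tv, TermVariance):
                tv = TermVariance(*tv)
            self._terms[str(name)] = tv

    def __getitem__(self, name: str) -> TermVariance:
        return self._terms[name]

    def __iter__(self):
        return iter(self._terms)

    def __len__(self) -> int:
        return len(self._terms)

    def __repr__(self) -> str:
        rows = ", ".join(f"{k}=({v.const:g}, {v.prop:g})" for k, v in self._terms.items())
        return f"VarianceComponents({rows})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, VarianceComponents):
            return NotImplemented
        return self._terms == other._terms

    @property
    def factor_names(self) -> list[str]:
        return [n for n in self._terms if n not in (REPEATABILITY, BLOCK)]

    @property
    def const_total(self) -> float:
        """Aggregate constant part C = sum of all constant components."""
        return float(sum(tv.const for tv in self._terms.values()))

    @property
    def prop_total(self) -> float:
        """Aggregate proportional part P = sum of all proportional components."""
        return float(sum(tv.prop for tv in self._terms.values()))

    def group_totals(self) -> dict[str, tuple[float, float]]:
        """(C, P) pooled into the three report groups: repeatability, block, factors."""
        rep = self._terms.get(REPEATABILITY, TermVariance())
        blk = self._terms.get(BLOCK, TermVariance())
        fc = sum(self._terms[n].const for n in self.factor_names)
        fp = sum(self._terms[n].prop for n in self.factor_names)
        return {
            "repeatability": (rep.const, rep.prop),
            "block": (blk.const, blk.prop),
            "factors": (float(fc), float(fp)),
        }


@dataclass(frozen=True)
class PrecisionProfile:
    """The variance function sigma(x) = sqrt(C + P x^2) assembled from components."""

    components: VarianceComponents

    @property
    def C(self) -> float:
        return self.components.const_total

    @property
    def P(self) -> float:
        return self.components.prop_total

    def sd(self, x):
        """In-house reproducibility standard deviation at concentration ``x >= 0``."""
        x = np.asarray(x, dtype=float)
        if np.any(x < 0):
            raise ValueError("concentration must be non-negative")
        return np.sqrt(self.C + self.P * np.square(x))

    def rsd(self, x):
        """Relative standard deviation sigma(x)/x in percent; requires ``x > 0``."""
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0):
            raise ValueError("relative standard deviation is undefined at x <= 0")
        return self.sd(x) / x * 100.0

    @classmethod
    def from_totals(cls, C: float, P: float) -> "PrecisionProfile":
        """Build a profile directly from aggregate (C, P), as a single 'total' term."""
        return cls(VarianceComponents({"total": TermVariance(C, P)}))


def mean_response(curve: MeanCurve, x):
    """Expected measured concentration ``alpha + beta * x`` at true concentration x."""
    return curve.predict(x)


def reproducibility_sd(profile: PrecisionProfile, x):
    """In-house reproducibility SD sqrt(C + P x^2) in study units (x >= 0)."""
    return profile.sd(x)


def precision_breakdown(profile: PrecisionProfile, x: float) -> dict[str, float]:
    """Decompose the precision at ``x > 0`` into repeatability / block / factors RSDs.

    Returns a dict with percent RSDs for the three groups and for the total
    in-house reproducibility, plus the reproducibility SD in study units.  The
    squared group RSDs sum exactly to the squared reproducibility RSD.
    """
    x = float(x)
    if x <= 0:
        raise ValueError("precision breakdown requires x > 0 (RSD undefined at 0)")
    groups = profile.components.group_totals()
    out: dict[str, float] = {}
    for name, (c, p) in groups.items():
        out[f"{name}_rsd"] = math.sqrt(c + p * x * x) / x * 100.0
    sd = profile.sd(x)
    out["reproducibility_rsd"] = float(sd / x * 100.0)
    out["reproducibility_sd"] = float(sd)
    return out
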