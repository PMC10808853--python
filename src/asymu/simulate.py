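"""Monte-Carlo engine: simulate validation studies, check coverage and parameter recovery.

Simulation follows the same generative model the estimator fits: each design
factor contributes a pair of random effects per level (constant + proportional),
each block a pair per block, and repeatability a pair per observation, so a
simulated response is

    Y = alpha + beta*x + sum_f (A_f + B_f x) + A_blk + B_blk x + a + b x.

A lognormal mode draws log-responses around log(alpha + beta*x) using the
proportional components as log-scale variances (constant components must then
be zero), emulating data whose variance a log transform stabilises.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datasets import ValidationStudy, load_fixture
from .intervals import (
    PredictionRange,
    UncertaintyInterval,
    invert_prediction_range,
    symmetric_interval,
)
from .model import UncertaintyModel
from .profiles import (
    BLOCK,
    REPEATABILITY,
    MeanCurve,
    PrecisionProfile,
    TermVariance,
    VarianceComponents,
)

__all__ = [
    "SimulationSpec",
    "two_level_design",
    "fixture_design",
    "simulate_study",
    "coverage_experiment",
    "recovery_experiment",
]

#: Standard 8-run two-level factorial layout for up to 7 factors (levels 1/2).
_EIGHT_RUN_PLAN = np.array([
    [1, 1, 1, 2, 2, 2, 1],
    [1, 1, 2, 2, 1, 1, 2],
    [1, 2, 1, 1, 2, 1, 2],
    [1, 2, 2, 1, 1, 2, 1],
    [2, 1, 1, 1, 1, 2, 2],
    [2, 1, 2, 1, 2, 1, 1],
    [2, 2, 1, 2, 1, 1, 1],
    [2, 2, 2, 2, 2, 2, 2],
])


def two_level_design(factors: Sequence[str]) -> pd.DataFrame:
    """Eight-block crossed design assigning each factor two levels ("1"/"2")."""
    if not 1 <= len(factors) <= 7:
        raise ValueError("the 8-run plan supports 1-7 two-level factors")
    cols = {"block": [f"{j + 1:02d}" for j in range(8)]}
    for i, f in enumerate(factors):
        cols[f] = [str(v) for v in _EIGHT_RUN_PLAN[:, i]]
    return pd.DataFrame(cols)


def fixture_design(name: str) -> pd.DataFrame:
    """Block/factor-level table of a packaged example study."""
    study = load_fixture(name)
    return (
        study.data[["block", *study.factors]]
        .drop_duplicates()
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Generative description of a validation study.

    Parameters
    ----------
    design : DataFrame with a ``block`` column plus one column per factor.
    known_x : known concentrations (> 0).
    p : replicates per (block, level).
    curve, components : the generative truth.
    distribution : ``"normal"`` or ``"lognormal"``.
    seed : base seed; replicate r of an experiment uses substream seed+r.
    """

    design: pd.DataFrame
    known_x: tuple[float, ...]
    curve: MeanCurve
    components: VarianceComponents
    p: int = 1
    distribution: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if "block" not in self.design.columns:
            raise ValueError("design needs a 'block' column")
        if any(x <= 0 for x in self.known_x):
            raise ValueError("known concentrations must be strictly positive")
        if self.p < 1:
            raise ValueError("replicates p must be >= 1")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError(f"unknown distribution {self.distribution!r}")
        if self.distribution == "lognormal":
            const = [n for n, tv in self.components.items() if tv.const > 0]
            if const:
                raise ValueError(
                    "lognormal mode uses proportional components as log-scale "
                    f"variances; constant components must be zero (got {const})"
                )
        object.__setattr__(self, "known_x", tuple(float(x) for x in self.known_x))

    @property
    def factors(self) -> list[str]:
        return [c for c in self.design.columns if c != "block"]


def _draw_effects(rng: np.random.Generator, labels: pd.Series, var: float) -> np.ndarray:
    """One N(0, var) effect per distinct label, broadcast to observations."""
    codes, uniques = pd.factorize(labels, sort=True)
    draws = rng.normal(0.0, np.sqrt(var), size=len(uniques)) if var > 0 else np.zeros(len(uniques))
    return draws[codes]


def simulate_study(spec: SimulationSpec) -> ValidationStudy:
    """Draw one validation study from the generative model (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    design = spec.design.reset_index(drop=True)
    rows = []
    for _, blk in design.iterrows():
        for x in spec.known_x:
            for r in range(1, spec.p + 1):
                row = {"block": str(blk["block"]), "known_x": x, "replicate": r}
                row.update({f: blk[f] for f in spec.factors})
                rows.append(row)
    df = pd.DataFrame(rows)
    x = df["known_x"].to_numpy(float)
    comps = spec.components

    def term_effect(name: str, labels) -> np.ndarray:
        tv = comps[name] if name in comps else TermVariance()
        if spec.distribution == "lognormal":
            return _draw_effects(rng, labels, tv.prop)
        return _draw_effects(rng, labels, tv.const) + _draw_effects(rng, labels, tv.prop) * x

    noise = np.zeros(len(df))
    for f in spec.factors:
        noise += term_effect(f, df[f])
    noise += term_effect(BLOCK, df["block"])
    obs_labels = pd.Series(np.arange(len(df)))
    noise += term_effect(REPEATABILITY, obs_labels)

    mean = spec.curve.predict(x)
    if spec.distribution == "lognormal":
        if np.any(mean <= 0):
            raise ValueError("lognormal mode requires a positive mean curve")
        df["y"] = np.exp(np.log(mean) + noise)
    else:
        df["y"] = mean + noise
    return ValidationStudy(df, factors=spec.factors, units="sim")


# ---------------------------------------------------------------------------
def _interval_rule(rule: str, curve: MeanCurve, profile: PrecisionProfile, k: float):
    if rule == "asymmetric":
        rng = PredictionRange(curve=curve, profile=profile, k=k)

        def fn(ym: float) -> tuple[float, float]:
            iv = rng.invert(ym)
            return iv.lower, iv.upper

    elif rule == "y_plus_minus_U":

        def fn(ym: float) -> tuple[float, float]:
            return symmetric_interval(ym, profile=profile, k=k)

    else:
        raise ValueError(f"unknown interval rule {rule!r}")
    return fn


def coverage_experiment(
    truth_curve: MeanCurve,
    truth_profile: PrecisionProfile,
    true_values: Sequence[float],
    interval_rule: str = "asymmetric",
    k: float = 2.0,
    R: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical coverage of an interval rule under a known precision profile.

    For each replicate and each true measurand value ``y``, a routine
    measurement ``ym ~ N(alpha + beta*y, sigma(y))`` is drawn, the uncertainty
    interval is computed from ``ym`` alone, and coverage of ``y`` is recorded.
    With the asymmetric rule, the exact 95% quantile and the generative
    profile, coverage is exact by construction.

    Returns one row per true value: coverage, binomial SE, replicate count.
    """
    if R < 100:
        raise ValueError("need at least 100 replicates")
    rule = _interval_rule(interval_rule, truth_curve, truth_profile, k)
    rng = np.random.default_rng(seed)
    rows = []
    for y in true_values:
        y = float(y)
        mu = float(truth_curve.predict(y))
        sd = float(truth_profile.sd(y))
        ym = np.maximum(mu + sd * rng.standard_normal(R), 0.0)
        hits = np.fromiter(
            ((lambda lo_hi: lo_hi[0] <= y <= lo_hi[1])(rule(v)) for v in ym),
            dtype=bool, count=R,
        )
        cov = hits.mean()
        rows.append({
            "true_value": y,
            "coverage": cov,
            "binomial_se": float(np.sqrt(cov * (1 - cov) / R)),
            "replicates": R,
        })
    return pd.DataFrame(rows)


def recovery_experiment(spec: SimulationSpec, R: int = 200) -> pd.DataFrame:
    """Fit R studies simulated from ``spec``; tabulate estimate quality per parameter.

    Returns one row per parameter (alpha, beta, each component) with truth,
    mean/median estimate, bias, RMSE, and the number of non-converged fits
    (reported once in the ``n_failed`` column).
    """
    if R < 50:
        raise ValueError("need at least 50 replicates")
    records: list[dict] = []
    n_failed = 0
    for r in range(R):
        study = simulate_study(replace(spec, seed=spec.seed + r))
        try:
            res = UncertaintyModel(study).fit()
        except Exception:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        rec = {"alpha": res.curve.alpha, "beta": res.curve.beta}
        for name, tv in res.components.items():
            rec[f"{name}:const"] = tv.const
            rec[f"{name}:prop"] = tv.prop
        records.append(rec)
    est = pd.DataFrame(records)
    truth = {"alpha": spec.curve.alpha, "beta": spec.curve.beta}
    for name, tv in spec.components.items():
        truth[f"{name}:const"] = tv.const
        truth[f"{name}:prop"] = tv.prop
    rows = []
    for param, tv in truth.items():
        col = est[param] if param in est else pd.Series(dtype=float)
        rows.append({
            "parameter": param,
            "truth": tv,
            "mean_estimate": float(col.mean()) if len(col) else np.nan,
            "median_estimate": float(col.median()) if len(col) else np.nan,
            "bias": float(col.mean() - tv) if len(col) else np.nan,
            "rmse": float(np.sqrt(np.mean((col - tv) ** 2))) if len(col) else np.nan,
            "n_fits": len(col),
            "n_failed": n_failed,
        })
    return pd.DataFrame(rows)
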