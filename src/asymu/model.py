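"""REML estimation of the heteroscedastic mixed model behind a validation study.

The measurement result for concentration level ``i``, block ``j``, replicate
``k`` is modelled as

    Y_ijk = alpha + beta * x_ij
            + sum_f (A_f[level_f(j)] + B_f[level_f(j)] * x_ij)    (factors)
            + A_block[j] + B_block[j] * x_ij                      (block)
            + a_ijk + b_ijk * x_ij                                (repeatability)

where every random term contributes a *constant* variance (the A / a parts,
units^2) and a *proportional* one (the B / b parts, dimensionless, scaling
with x^2).  The marginal covariance of the response vector is therefore

    V = sum_t [ s2A_t * Z_t Z_t' + s2B_t * (x .* Z_t)(x .* Z_t)' ]
        + diag(s2a + s2b * x^2)

with Z_t the indicator matrix of term t's grouping.  Variances are estimated
by numerically maximising the restricted likelihood under non-negativity
constraints (boundary zeros are reported as exact zeros); the fixed effects
(alpha, beta) follow by generalised least squares at the estimated covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .datasets import ValidationStudy
from .profiles import (
    BLOCK,
    REPEATABILITY,
    MeanCurve,
    PrecisionProfile,
    TermVariance,
    VarianceComponents,
)

__all__ = ["UncertaintyModel", "UncertaintyResults", "fit_mixed_model", "profile_from_fit"]


class ConvergenceWarning(UserWarning):
    pass


def _group_codes(values) -> np.ndarray:
    codes, _ = pd.factorize(values, sort=True)
    return codes


@dataclass
class _Term:
    name: str
    codes: np.ndarray  # grouping index per observation (residual term: arange(N))


class UncertaintyModel:
    """Mixed linear model for a factorial in-house validation study.

    Parameters
    ----------
    study : ValidationStudy
        Long-format validation data (blocks x known concentrations x replicates).

    Examples
    --------
    >>> from asymu import load_fixture, UncertaintyModel
    >>> res = UncertaintyModel(load_fixture("clopidol_egg")).fit()
    >>> rng = res.prediction_range(k=2.0)
    >>> rng.invert(2.0).lower  # doctest: +SKIP
    1.45
    """

    def __init__(self, study: ValidationStudy):
        self.study = study
        df = study.data
        self.endog = df["y"].to_numpy(float)
        self.x = df["known_x"].to_numpy(float)
        self.exog = np.column_stack([np.ones_like(self.x), self.x])
        self.nobs = len(df)
        if study.m < 2:
            raise ValueError("need at least 2 distinct known concentration levels")
        for f in study.factors:
            if df[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has fewer than 2 levels represented")
        self.term_names = [REPEATABILITY, BLOCK, *study.factors]
        self._terms = [_Term(BLOCK, _group_codes(df["block"]))]
        self._terms += [_Term(f, _group_codes(df[f])) for f in study.factors]
        self._check_confounding()
        # same-group indicator matrices for each non-residual term
        self._S = {t.name: (t.codes[:, None] == t.codes[None, :]).astype(float)
                   for t in self._terms}
        self._xx = np.outer(self.x, self.x)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors=(), units: str = "",
                       **col_names) -> "UncertaintyModel":
        return cls(ValidationStudy.from_long(df, factors=factors, units=units, **col_names))

    def _check_confounding(self) -> None:
        # two terms inducing the same partition of observations are inseparable
        seen: dict[tuple, str] = {}
        for t in self._terms:
            # canonical partition signature (label-invariant)
            first = {}
            sig = tuple(first.setdefault(c, len(first)) for c in t.codes)
            if sig in seen:
                raise ValueError(
                    f"terms {seen[sig]!r} and {t.name!r} are completely confounded "
                    "(identical grouping); drop or merge one of them"
                )
            seen[sig] = t.name

    # ------------------------------------------------------------------
    @property
    def n_variances(self) -> int:
        return 2 * len(self.term_names)

    def _covariance(self, variances: np.ndarray) -> np.ndarray:
        """Marginal covariance V for the variance vector (pairs per term)."""
        v = dict(zip(self.term_names, variances.reshape(-1, 2)))
        s2a, s2b = v[REPEATABILITY]
        V = np.diag(s2a + s2b * self.x**2)
        for t in self._terms:
            cA, cB = v[t.name]
            S = self._S[t.name]
            if cA:
                V += cA * S
            if cB:
                V += cB * (self._xx * S)
        return V

    def loglike_reml(self, variances) -> float:
        """Restricted log-likelihood at the given variance vector."""
        variances = np.asarray(variances, float)
        V = self._covariance(variances)
        n, k = self.exog.shape
        ridge, floor = 0.0, self._ridge_floor(V)
        for _ in range(6):
            try:
                cf = linalg.cho_factor(V + ridge * np.eye(n), lower=True)
                break
            except linalg.LinAlgError:
                ridge = max(ridge * 100.0, floor)
        else:
            return -np.inf
        logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_X = linalg.cho_solve(cf, self.exog)
        Vi_y = linalg.cho_solve(cf, self.endog)
        XtViX = self.exog.T @ Vi_X
        sign, logdetXtViX = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return -np.inf
        beta = np.linalg.solve(XtViX, self.exog.T @ Vi_y)
        resid = self.endog - self.exog @ beta
        quad = resid @ linalg.cho_solve(cf, resid)
        return -0.5 * ((n - k) * np.log(2 * np.pi) + logdetV + logdetXtViX + quad)

    def _ridge_floor(self, V: np.ndarray) -> float:
        """Smallest diagonal jitter that keeps a (near-)singular V factorisable."""
        scale = np.trace(V) / self.nobs
        data_scale = 1e-12 * (1.0 + float(np.mean(self.endog**2)))
        return 1e-10 * scale + data_scale

    def _gls(self, variances: np.ndarray):
        V = self._covariance(variances)
        n = self.nobs
        try:
            cf = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            cf = linalg.cho_factor(V + self._ridge_floor(V) * np.eye(n), lower=True)
        Vi_X = linalg.cho_solve(cf, self.exog)
        XtViX = self.exog.T @ Vi_X
        cov_fe = np.linalg.inv(XtViX)
        beta = cov_fe @ (self.exog.T @ linalg.cho_solve(cf, self.endog))
        return beta, cov_fe

    def _scales(self) -> np.ndarray:
        """Per-parameter scale so the optimiser works on O(1) quantities."""
        beta_ols, *_ = np.linalg.lstsq(self.exog, self.endog, rcond=None)
        resid = self.endog - self.exog @ beta_ols
        s2 = float(resid @ resid) / max(self.nobs - 2, 1)
        s2 = max(s2, 1e-12 * float(np.mean(self.endog**2)) + 1e-300)
        mx2 = float(np.mean(self.x**2))
        out = np.empty(self.n_variances)
        out[0::2] = s2          # constant components, units^2
        out[1::2] = s2 / mx2    # proportional components, dimensionless
        return out

    def _starting_points(self) -> list[np.ndarray]:
        """Deterministic multi-start grid on the scaled-variance axis."""
        nt = len(self.term_names)
        starts = []
        for wc, wp in [(1.0, 0.05), (0.05, 1.0), (0.5, 0.5)]:
            z = np.empty(self.n_variances)
            z[0::2] = wc / nt
            z[1::2] = wp / nt
            starts.append(z)
        # residual-dominant start (classical OLS picture)
        z = np.full(self.n_variances, 0.01)
        z[0] = 1.0
        starts.append(z)
        return starts

    def fit(self, non_negative: bool = True, max_iter: int = 500,
            tol: float = 1e-8) -> "UncertaintyResults":
        """Estimate variance components (REML) and fixed effects (GLS).

        Variances are optimised on a per-parameter relative scale under
        ``v >= 0`` bounds from several deterministic starting points; the best
        restricted likelihood wins.  Components pinned at the boundary are
        reported as exact zeros.
        """
        scales = self._scales()
        lower = 0.0 if non_negative else -np.inf
        bounds = [(lower, 1e8)] * self.n_variances

        def neg(z):
            return -self.loglike_reml(z * scales)

        best = None
        for z0 in self._starting_points():
            res = optimize.minimize(
                neg, z0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": tol * 1e-4, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        z = np.clip(best.x, lower, None)
        # snap numerically-zero components to exact zeros
        z[np.abs(z) < 1e-10] = 0.0
        variances = z * scales
        loglik = self.loglike_reml(variances)
        converged = bool(best.success) and np.isfinite(loglik)
        if not converged:
            warnings.warn(
                f"REML optimisation did not converge: {best.message}", ConvergenceWarning
            )
        beta, cov_fe = self._gls(variances)
        comps = VarianceComponents({
            name: TermVariance(*pair)
            for name, pair in zip(self.term_names, variances.reshape(-1, 2))
        })
        return UncertaintyResults(
            model=self,
            curve=MeanCurve(alpha=float(beta[0]), beta=float(beta[1])),
            components=comps,
            converged=converged,
            n_obs=self.nobs,
            loglik=float(loglik),
            se_alpha=float(np.sqrt(cov_fe[0, 0])),
            se_beta=float(np.sqrt(cov_fe[1, 1])),
            optimizer_message=str(best.message),
        )


@dataclass
class UncertaintyResults:
    """Fitted mean curve, variance components and derived uncertainty machinery."""

    model: UncertaintyModel
    curve: MeanCurve
    components: VarianceComponents
    converged: bool
    n_obs: int
    loglik: float
    se_alpha: float
    se_beta: float
    optimizer_message: str = ""

    @property
    def profile(self) -> PrecisionProfile:
        """Precision profile sigma(x) = sqrt(C + P x^2) pooled over all terms."""
        return PrecisionProfile(self.components)

    def prediction_range(self, k: float | None = 2.0, p_pred: float | None = None,
                         bias_corrected: bool = True):
        """Prediction range (mean curve ± k·sigma) for uncertainty-interval inversion.

        ``bias_corrected=False`` replaces the fitted mean curve by the identity,
        i.e. ignores method bias when projecting intervals.
        """
        from .intervals import PredictionRange

        curve = self.curve if bias_corrected else MeanCurve.identity()
        if p_pred is not None:
            return PredictionRange.from_probability(curve, self.profile, p_pred)
        return PredictionRange(curve=curve, profile=self.profile, k=float(k))

    # ---- report tables ----------------------------------------------------
    def variance_table(self) -> pd.DataFrame:
        """Per-term constant/proportional variance estimates."""
        rows = [
            {"term": name, "constant": tv.const, "proportional": tv.prop}
            for name, tv in self.components.items()
        ]
        return pd.DataFrame(rows)

    def precision_table(self, concentrations, ndigits: int = 1,
                        sd_digits: int = 2) -> pd.DataFrame:
        """Precision estimates by concentration: group RSDs (%) and total SD."""
        from .profiles import precision_breakdown

        prof = self.profile
        rows = []
        for x in concentrations:
            b = precision_breakdown(prof, float(x))
            rows.append({
                "concentration": float(x),
                "repeatability_pct": round(b["repeatability_rsd"], ndigits),
                "block_pct": round(b["block_rsd"], ndigits),
                "factors_pct": round(b["factors_rsd"], ndigits),
                "reproducibility_pct": round(b["reproducibility_rsd"], ndigits),
                "reproducibility_sd": round(b["reproducibility_sd"], sd_digits),
            })
        return pd.DataFrame(rows)

    def expanded_uncertainty_table(self, concentrations, k: float = 2.0,
                                   ndigits: int = 1, u_digits: int = 2) -> pd.DataFrame:
        """Expanded uncertainty U(x) = k·sigma(x) by concentration."""
        prof = self.profile
        rows = []
        for x in concentrations:
            x = float(x)
            U = k * float(prof.sd(x))
            rows.append({
                "concentration": x,
                "expanded_uncertainty_pct": round(U / x * 100.0, ndigits),
                "expanded_uncertainty": round(U, u_digits),
            })
        return pd.DataFrame(rows)

    def uncertainty_table(self, measured, k: float = 2.0, bias_corrected: bool = True,
                          ndigits: int = 2) -> pd.DataFrame:
        """Asymmetric uncertainty intervals for routine measurement results."""
        rng = self.prediction_range(k=k, bias_corrected=bias_corrected)
        prof = self.profile
        rows = []
        for ym in measured:
            ym = float(ym)
            iv = rng.invert(ym)
            rows.append({
                "measured": ym,
                "lower": round(iv.lower, ndigits),
                "upper": round(iv.upper, ndigits) if np.isfinite(iv.upper) else np.inf,
                "best_estimate": round(iv.best_estimate, ndigits),
                "best_minus_lower": round(iv.best_estimate - iv.lower, ndigits),
                "upper_minus_best": (round(iv.upper - iv.best_estimate, ndigits)
                                     if np.isfinite(iv.upper) else np.inf),
                "expanded_uncertainty": round(k * float(prof.sd(ym)), ndigits),
                "truncated_low": iv.truncated_low,
                "unbounded_high": iv.unbounded_high,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary of the fit."""
        u = self.units
        lines = [
            "Heteroscedastic mixed-model precision fit (REML)",
            "=" * 52,
            f"observations: {self.n_obs}   levels: {self.model.study.m}   "
            f"blocks: {self.model.study.n}   replicates: {self.model.study.p}",
            f"converged: {self.converged}   restricted log-likelihood: {self.loglik:.4f}",
            "",
            "Mean curve  E[Y] = alpha + beta * x",
            f"  alpha = {self.curve.alpha:10.5f}  (se {self.se_alpha:.5f}) {u}",
            f"  beta  = {self.curve.beta:10.5f}  (se {self.se_beta:.5f})",
            "",
            f"Variance components          constant [{u}^2]   proportional [-]",
        ]
        for name, tv in self.components.items():
            lines.append(f"  {name:<24} {tv.const:16.5f} {tv.prop:18.5f}")
        prof = self.profile
        lines += [
            "  " + "-" * 58,
            f"  {'total (C, P)':<24} {prof.C:16.5f} {prof.P:18.5f}",
            "",
            f"sigma(x) = sqrt(C + P x^2); e.g. sigma at top level = "
            f"{float(prof.sd(self.model.x.max())):.4f} {u}",
        ]
        return "\n".join(lines)

    @property
    def units(self) -> str:
        return self.model.study.units or "units"


def fit_mixed_model(data: ValidationStudy, non_negative: bool = True,
                    max_iter: int = 500, tol: float = 1e-8) -> UncertaintyResults:
    """Functional wrapper: fit the mixed model to a validation study."""
    return UncertaintyModel(data).fit(non_negative=non_negative, max_iter=max_iter, tol=tol)


def profile_from_fit(fit: UncertaintyResults) -> PrecisionProfile:
    """Pool a fit's components into the aggregate precision profile (C, P)."""
    return fit.profile
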