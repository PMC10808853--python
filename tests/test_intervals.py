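"""Uncertainty intervals: y±U, prediction-range inversion, closed forms, lognormal."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import asymu
from asymu import (
    MeanCurve,
    PrecisionProfile,
    PredictionRange,
    best_estimate,
    closed_form_interval,
    consistency_check,
    expanded_uncertainty,
    invert_prediction_range,
    k_from_probability,
    lognormal_interval,
    standard_uncertainty,
    symmetric_interval,
)


def test_standard_uncertainty_is_reproducibility_sd(ex2_reference_profile):
    assert round(float(standard_uncertainty(ex2_reference_profile, 4.0)), 2) == 0.59
    zero = PrecisionProfile.from_totals(0.0, 0.0)
    assert standard_uncertainty(zero, 3.0) == 0.0


@settings(max_examples=100, derandomize=True)
@given(C=st.floats(0, 100), P=st.floats(0, 1), x=st.floats(0, 1e3))
def test_standard_uncertainty_identity(C, P, x):
    prof = PrecisionProfile.from_totals(C, P)
    u = float(standard_uncertainty(prof, x))
    assert u * u - C == pytest.approx(P * x * x, rel=1e-9, abs=1e-9)


def test_expanded_uncertainty_published_values(ex2_reference_profile):
    assert round(float(expanded_uncertainty(ex2_reference_profile, 4.0, k=2)), 2) == 1.19
    assert round(float(expanded_uncertainty(ex2_reference_profile, 5.5, k=2)), 2) == 1.62
    assert expanded_uncertainty(ex2_reference_profile, 5.5, k=0) == 0.0


def test_symmetric_interval_constant_rsd():
    assert symmetric_interval(10, rsd=0.35, k=2) == pytest.approx((3.0, 17.0))
    assert symmetric_interval(3, rsd=0.35, k=2) == pytest.approx((0.9, 5.1))
    assert symmetric_interval(5, rsd=0.0, k=2) == (5.0, 5.0)
    with pytest.raises(ValueError):
        symmetric_interval(5)  # neither profile nor rsd


def test_symmetric_rule_is_one_way_inconsistent():
    rule = lambda ym: symmetric_interval(ym, rsd=0.35, k=2)
    rep = consistency_check(3, 10, rule)
    assert rep["one_way"] and not rep["mutual"]
    assert consistency_check(4, 4, rule)["mutual"]


def test_asymmetric_rule_consistent_with_prediction_band():
    """Inverted intervals satisfy the duality y in interval(ym) <=> ym in band(y);
    the y±U rule violates it under a constant relative SD."""
    band = lambda y: (y * (1 - 2 * 0.4), y * (1 + 2 * 0.4))
    asym = lambda ym: tuple(closed_form_interval(ym, 0.4, k=2))
    symm = lambda ym: symmetric_interval(ym, rsd=0.4, k=2)
    saw_violation = False
    for ym1 in np.linspace(0.5, 20, 8):
        for ym2 in np.linspace(ym1, 25, 8):
            assert consistency_check(ym1, ym2, asym, band_fn=band)["mutual"]
            rep = consistency_check(ym1, ym2, symm, band_fn=band)
            saw_violation |= not rep["mutual"]
    assert saw_violation


# ---- closed forms ----------------------------------------------------------
def test_closed_form_worked_example():
    iv = closed_form_interval(100, 0.4, k=2)
    assert iv.lower == pytest.approx(100 / 1.8)
    assert round(iv.lower) == 56
    assert iv.upper == pytest.approx(500.0)


def test_closed_form_degenerate_cases():
    iv = closed_form_interval(7, 1e-12, k=2)
    assert iv.lower == pytest.approx(7) and iv.upper == pytest.approx(7)
    assert tuple(closed_form_interval(0, 0.4, k=2)) == (0.0, 0.0)


def test_closed_form_unbounded_flag_not_exception():
    iv = closed_form_interval(10, 0.6, k=2)  # k*sigma_rel = 1.2 >= 1
    assert iv.unbounded_high and math.isinf(iv.upper)


def test_lognormal_interval_factor():
    iv = lognormal_interval(1.0, 0.25, k=2)
    assert iv.upper == pytest.approx(math.exp(0.5))
    assert round(iv.upper, 2) == 1.65
    assert iv.lower == pytest.approx(1 / math.exp(0.5))
    iv0 = lognormal_interval(3.0, 0.0, k=2)
    assert (iv0.lower, iv0.upper) == (3.0, 3.0)


def test_lognormal_agrees_with_normal_closed_form_to_first_order():
    s, k, ym = 0.01, 2.0, 10.0
    ln = lognormal_interval(ym, s, k)
    cf = closed_form_interval(ym, s, k)
    assert ln.lower == pytest.approx(cf.lower, abs=ym * (k * s) ** 2)
    assert ln.upper == pytest.approx(cf.upper, abs=2 * ym * (k * s) ** 2)


# ---- best estimate ---------------------------------------------------------
def test_best_estimate_identity_and_floor():
    assert best_estimate(4.0, MeanCurve.identity()) == 4.0
    assert best_estimate(0.1, MeanCurve(0.5, 1.0)) == 0.0  # floored at zero


# ---- inversion --------------------------------------------------------------
def _range(alpha=0.0, beta=1.0, C=0.0, P=0.0, k=2.0):
    return PredictionRange(curve=MeanCurve(alpha, beta),
                           profile=PrecisionProfile.from_totals(C, P), k=k)


def test_inversion_identities_hold(ex2_reference_profile):
    rng = PredictionRange(curve=MeanCurve(0.0554, 1.00756),
                          profile=ex2_reference_profile, k=2.0)
    for ym in (0.5, 1.0, 2.0, 4.0, 6.0):
        iv = rng.invert(ym)
        assert rng.f_upper(iv.lower) == pytest.approx(ym, rel=1e-9)
        assert rng.f_lower(iv.upper) == pytest.approx(ym, rel=1e-9)
        assert 0 <= iv.lower <= iv.best_estimate <= iv.upper


def test_inversion_truncates_at_zero(ex2_reference_profile):
    rng = PredictionRange(curve=MeanCurve(0.0554, 1.00756),
                          profile=ex2_reference_profile, k=2.0)
    iv = rng.invert(0.2)
    assert iv.truncated_low and iv.lower == 0.0
    assert round(iv.upper, 2) == pytest.approx(0.39, abs=0.01)


def test_constant_absolute_sd_reproduces_y_plus_minus_U():
    """P = 0, no bias: the asymmetric interval equals y ± k*sigma exactly."""
    rng = _range(C=0.25, P=0.0, k=2.0)
    iv = rng.invert(10.0)
    assert iv.lower == pytest.approx(10 - 2 * 0.5, abs=1e-9)
    assert iv.upper == pytest.approx(10 + 2 * 0.5, abs=1e-9)
    assert iv.upper - iv.best_estimate == pytest.approx(iv.best_estimate - iv.lower, abs=1e-9)


@pytest.mark.parametrize("sigma_rel", [0.05, 0.2, 0.4])
@pytest.mark.parametrize("k", [1.0, 2.0])
def test_inversion_matches_closed_form_oracle(sigma_rel, k):
    """Iterative inversion equals the constant-RSD closed form when C = 0, no bias."""
    if k * sigma_rel >= 1:
        pytest.skip("upper limit unbounded")
    rng = _range(C=0.0, P=sigma_rel**2, k=k)
    for ym in (0.5, 1.0, 10.0, 100.0):
        iv = rng.invert(ym)
        oracle = closed_form_interval(ym, sigma_rel, k=k)
        assert iv.lower == pytest.approx(oracle.lower, rel=1e-9)
        assert iv.upper == pytest.approx(oracle.upper, rel=1e-9)


def test_unbounded_upper_when_band_slope_dominates():
    rng = _range(C=0.01, P=0.36, k=2.0)  # beta - k*sqrt(P) = 1 - 1.2 < 0
    iv = rng.invert(5.0)
    assert iv.unbounded_high and math.isinf(iv.upper)
    assert iv.lower > 0


def test_limits_monotone_in_measurement():
    rng = _range(alpha=0.1, beta=1.05, C=0.2, P=0.04, k=2.0)
    prev = None
    for ym in np.linspace(0.0, 20.0, 41):
        iv = rng.invert(float(ym))
        if prev is not None:
            assert iv.lower >= prev.lower - 1e-12
            assert iv.upper >= prev.upper - 1e-12
            assert iv.best_estimate >= prev.best_estimate - 1e-12
        prev = iv


def test_interval_is_the_band_membership_set():
    """[yL, yU] = {y >= 0 : f_L(y) <= ym <= f_U(y)}, by brute-force grid."""
    rng = _range(alpha=0.2, beta=0.95, C=0.3, P=0.02, k=2.0)
    ym = 4.0
    iv = rng.invert(ym)
    for y in np.linspace(0, 12, 601):
        inside = rng.f_lower(y) <= ym <= rng.f_upper(y)
        assert inside == (iv.lower - 1e-9 <= y <= iv.upper + 1e-9)


def test_asymmetry_grows_with_proportional_variance():
    """At fixed C, increasing P inflates (yU-ycorr)/(ycorr-yL) above 1."""
    ratios = []
    for P in (0.0, 0.01, 0.04, 0.09):
        iv = _range(C=0.25, P=P, k=2.0).invert(5.0)
        ratios.append((iv.upper - iv.best_estimate) / (iv.best_estimate - iv.lower))
    assert ratios[0] == pytest.approx(1.0, abs=1e-9)
    assert all(b > a for a, b in zip(ratios, ratios[1:]))


@settings(max_examples=150, derandomize=True, deadline=None)
@given(
    alpha=st.floats(0, 2), beta=st.floats(0.5, 2), C=st.floats(0, 4),
    P=st.floats(0, 0.04), ym=st.floats(0, 50), k=st.floats(0.5, 3),
)
def test_inversion_identity_property(alpha, beta, C, P, ym, k):
    rng = _range(alpha=alpha, beta=beta, C=C, P=P, k=k)
    iv = rng.invert(ym)
    if not iv.truncated_low:
        assert rng.f_upper(iv.lower) == pytest.approx(ym, rel=1e-9, abs=1e-9)
    if not iv.unbounded_high and iv.upper > 0:
        assert rng.f_lower(iv.upper) == pytest.approx(ym, rel=1e-9, abs=1e-9)
    if math.isfinite(iv.upper):
        assert 0 <= iv.lower <= iv.upper + 1e-12


def test_negative_measurement_rejected():
    with pytest.raises(ValueError):
        invert_prediction_range(-1.0, _range(C=1.0))


def test_coverage_factor_probability_interconversion():
    assert k_from_probability(0.95) == pytest.approx(1.959964, abs=1e-6)
    assert asymu.K_95_EXACT == pytest.approx(1.959964, abs=1e-6)
    rng = PredictionRange.from_probability(
        MeanCurve.identity(), PrecisionProfile.from_totals(1.0, 0.0), 0.95)
    assert rng.p_pred == pytest.approx(0.95, abs=1e-12)
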