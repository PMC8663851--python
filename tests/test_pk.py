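"""One-compartment simulation: closed forms vs ODE oracles, sampling, percentiles."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from tdmassay import (
    DoseRegimen,
    PKParameters,
    conc_iv_multidose,
    conc_po_multidose,
    concentration_percentiles,
    derive_calibration_range,
    range_from_summaries,
    sample_parameters,
    simulate_population,
)
from tdmassay.errors import (
    DegenerateSimulationError,
    InsufficientSampleError,
    InvalidInputError,
    InvalidParameterError,
)

IV = DoseRegimen(dose=200.0, interval=24.0, n_doses=7, route="iv", infusion_duration=1.0)
PO = DoseRegimen(dose=200.0, interval=24.0, n_doses=7, route="po")


def ode_iv_single(t_eval, dose, tinf, cl, v):
    """Runge-Kutta oracle: dA/dt = R0*1{t<Tinf} - k*A, C = A/V."""
    k, r0 = cl / v, dose / tinf
    sol1 = solve_ivp(
        lambda t, a: [r0 - k * a[0]], (0.0, tinf), [0.0], rtol=1e-12, atol=1e-14,
        dense_output=True,
    )
    a_tinf = sol1.y[0, -1]
    sol2 = solve_ivp(
        lambda t, a: [-k * a[0]], (tinf, max(t_eval) + 1.0), [a_tinf], rtol=1e-12,
        atol=1e-14, dense_output=True,
    )
    out = np.where(
        np.asarray(t_eval) <= tinf,
        sol1.sol(np.clip(t_eval, 0, tinf))[0],
        sol2.sol(np.clip(t_eval, tinf, None))[0],
    )
    return out / v


def ode_po_single(t_eval, dose, cl, v, ka, f):
    """Oracle: dAgut/dt = -ka*Agut, dA/dt = ka*Agut - k*A, C = A/V."""
    k = cl / v
    sol = solve_ivp(
        lambda t, y: [-ka * y[0], ka * y[0] - k * y[1]],
        (0.0, max(t_eval) + 1.0),
        [f * dose, 0.0],
        rtol=1e-12,
        atol=1e-14,
        dense_output=True,
    )
    return sol.sol(t_eval)[1] / v


@pytest.mark.parametrize("cl,v", [(8.0, 60.0), (3.0, 40.0), (15.0, 120.0)])
def test_iv_closed_form_matches_ode_oracle(cl, v):
    single = DoseRegimen(200.0, 24.0, 1, "iv", 1.0)
    t = np.array([0.25, 0.5, 1.0, 1.5, 4.0, 12.0, 23.0])
    closed = conc_iv_multidose(t, single, cl, v)
    oracle = ode_iv_single(t, 200.0, 1.0, cl, v)
    np.testing.assert_allclose(closed, oracle, rtol=1e-6)


@pytest.mark.parametrize("cl,v,ka,f", [(8.0, 60.0, 1.2, 0.86), (5.0, 90.0, 0.4, 1.0)])
def test_po_closed_form_matches_ode_oracle(cl, v, ka, f):
    single = DoseRegimen(200.0, 24.0, 1, "po")
    t = np.array([0.25, 1.0, 2.0, 6.0, 12.0, 23.0])
    closed = conc_po_multidose(t, single, cl, v, ka, f)
    oracle = ode_po_single(t, 200.0, cl, v, ka, f)
    np.testing.assert_allclose(closed, oracle, rtol=1e-6)


def test_iv_single_dose_end_of_infusion_value():
    single = DoseRegimen(200.0, 24.0, 1, "iv", 1.0)
    expected = (200.0 / 1.0) / 8.0 * (1.0 - np.exp(-(8.0 / 60.0) * 1.0))
    assert conc_iv_multidose(1.0, single, 8.0, 60.0) == pytest.approx(expected, rel=1e-12)


def test_no_drug_before_first_dose():
    assert conc_iv_multidose(0.0, IV, 8.0, 60.0) == 0.0
    assert conc_po_multidose(0.0, PO, 8.0, 60.0, 1.2, 0.9) == 0.0


def test_multidose_is_sum_of_shifted_single_doses():
    single = DoseRegimen(200.0, 24.0, 1, "iv", 1.0)
    t = 168.0
    expected = sum(
        conc_iv_multidose(t - 24.0 * i, single, 8.0, 60.0) for i in range(7) if t - 24.0 * i >= 0
    )
    assert conc_iv_multidose(t, IV, 8.0, 60.0) == pytest.approx(expected, rel=1e-12)

    singlep = DoseRegimen(200.0, 24.0, 1, "po")
    expected = sum(conc_po_multidose(t - 24.0 * i, singlep, 8.0, 60.0, 1.2, 0.86) for i in range(7))
    assert conc_po_multidose(t, PO, 8.0, 60.0, 1.2, 0.86) == pytest.approx(expected, rel=1e-12)


def test_iv_profile_continuous_at_end_of_infusion():
    eps = 1e-9
    below = conc_iv_multidose(1.0 - eps, IV, 8.0, 60.0)
    above = conc_iv_multidose(1.0 + eps, IV, 8.0, 60.0)
    assert below == pytest.approx(above, rel=1e-6)


def test_po_fast_absorption_approaches_iv_bolus():
    k = 8.0 / 60.0
    single = DoseRegimen(200.0, 24.0, 1, "po")
    t = np.array([2.0, 6.0, 12.0])
    fast = conc_po_multidose(t, single, 8.0, 60.0, 1e4 * k, 1.0)
    bolus = 200.0 / 60.0 * np.exp(-k * t)
    np.testing.assert_allclose(fast, bolus, rtol=1e-3)


def test_po_ka_equals_k_uses_stable_limit():
    k = 8.0 / 60.0
    single = DoseRegimen(200.0, 24.0, 1, "po")
    exact_limit = conc_po_multidose(5.0, single, 8.0, 60.0, k, 1.0)
    near = conc_po_multidose(5.0, single, 8.0, 60.0, k * (1 + 1e-7), 1.0)
    assert exact_limit == pytest.approx(200.0 * k * 5.0 * np.exp(-k * 5.0) / 60.0, rel=1e-12)
    assert near == pytest.approx(exact_limit, rel=1e-5)


@pytest.mark.parametrize(
    "kwargs",
    [dict(cl=0.0, v=60.0), dict(cl=8.0, v=-1.0)],
)
def test_invalid_disposition_parameters_raise(kwargs):
    with pytest.raises(InvalidParameterError):
        conc_iv_multidose(1.0, IV, **kwargs)


def test_negative_time_raises():
    with pytest.raises(InvalidInputError):
        conc_iv_multidose(-1.0, IV, 8.0, 60.0)


def test_invalid_oral_parameters_raise():
    with pytest.raises(InvalidParameterError):
        conc_po_multidose(1.0, PO, 8.0, 60.0, -1.0, 0.9)
    with pytest.raises(InvalidParameterError):
        conc_po_multidose(1.0, PO, 8.0, 60.0, 1.2, 1.5)


PARAMS = PKParameters(cl_mean=6.9, cl_sd=1.5, v_mean=80.0, v_sd=16.0,
                      ka_mean=1.2, ka_sd=0.5, f_mean=0.86, f_sd=0.08)


def test_sample_parameters_degenerate_sd_returns_means():
    params = PKParameters(cl_mean=8.0, cl_sd=0.0, v_mean=60.0, v_sd=0.0,
                          ka_mean=1.2, ka_sd=0.0, f_mean=0.9, f_sd=0.0)
    frame = sample_parameters(params, "po", 5, seed=0)
    assert (frame["cl"] == 8.0).all() and (frame["v"] == 60.0).all()
    assert (frame["ka"] == 1.2).all() and (frame["f"] == 0.9).all()


def test_sample_parameters_moment_matching():
    frame = sample_parameters(
        PKParameters(cl_mean=8.0, cl_sd=2.0, v_mean=60.0, v_sd=10.0), "iv", 100_000, seed=5
    )
    assert frame["cl"].mean() == pytest.approx(8.0, rel=0.02)
    assert frame["cl"].std(ddof=1) == pytest.approx(2.0, rel=0.05)


def test_sample_parameters_reproducible():
    a = sample_parameters(PARAMS, "po", 100, seed=42)
    b = sample_parameters(PARAMS, "po", 100, seed=42)
    assert a.equals(b)


def test_sampled_bioavailability_never_exceeds_one():
    frame = sample_parameters(PARAMS, "po", 10_000, seed=3)
    assert (frame["f"] <= 1.0).all()


def test_negative_sd_raises():
    with pytest.raises(InvalidParameterError):
        PKParameters(cl_mean=8.0, cl_sd=-1.0, v_mean=60.0, v_sd=0.0)


def test_population_deterministic_limit_matches_closed_form():
    params = PKParameters(cl_mean=8.0, cl_sd=0.0, v_mean=60.0, v_sd=0.0)
    times = np.linspace(0.0, 168.0, 200)
    profiles = simulate_population(params, IV, times, 1, seed=0)
    np.testing.assert_allclose(profiles[0], conc_iv_multidose(times, IV, 8.0, 60.0), rtol=1e-12)


def test_population_percentiles_ordered_and_nonnegative():
    times = np.arange(0.0, 168.1, 0.5)
    profiles = simulate_population(PARAMS, IV, times, 300, seed=1)
    assert (profiles >= 0).all()
    summary = concentration_percentiles(times, profiles)
    assert (summary.lower <= summary.median).all()
    assert (summary.median <= summary.upper).all()
    assert (summary.lower >= 0).all()


def test_troughs_accumulate_toward_steady_state():
    """Pre-dose troughs are non-decreasing across intervals for every subject."""
    trough_times = np.array([24.0 * j for j in range(1, 8)])
    profiles = simulate_population(PARAMS, IV, trough_times, 50, seed=2)
    diffs = np.diff(profiles, axis=1)
    assert (diffs >= -1e-12).all()


def test_empty_time_grid_raises():
    with pytest.raises(InvalidInputError):
        simulate_population(PARAMS, IV, [], 10, seed=0)


def test_times_beyond_regimen_raise():
    with pytest.raises(InvalidInputError):
        simulate_population(PARAMS, IV, [169.0], 10, seed=0)


def quantile_oracle(values, p):
    """Sort-and-interpolate between closest order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * p
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def test_percentiles_match_sort_interpolate_oracle():
    rng = np.random.default_rng(7)
    profiles = rng.lognormal(0.0, 1.0, size=(1000, 4))
    times = np.arange(4.0)
    summary = concentration_percentiles(times, profiles, (0.025, 0.975))
    for j in range(4):
        assert summary.lower[j] == pytest.approx(quantile_oracle(profiles[:, j], 0.025), rel=1e-12)
        assert summary.upper[j] == pytest.approx(quantile_oracle(profiles[:, j], 0.975), rel=1e-12)


def test_percentiles_of_constant_ramp_profiles():
    profiles = np.arange(1.0, 1001.0)[:, None] * np.ones((1, 3))
    summary = concentration_percentiles(np.arange(3.0), profiles, (0.025, 0.975))
    assert summary.lower[0] == pytest.approx(quantile_oracle(np.arange(1.0, 1001.0), 0.025))
    assert summary.upper[0] == pytest.approx(quantile_oracle(np.arange(1.0, 1001.0), 0.975))


def test_median_of_three_values():
    profiles = np.array([[1.0], [3.0], [2.0]])
    summary = concentration_percentiles([0.0], profiles, (0.5, 0.5))
    assert summary.lower[0] == 2.0


def test_identical_profiles_collapse_the_band():
    profiles = np.tile(np.array([1.0, 2.0, 3.0]), (10, 1))
    summary = concentration_percentiles(np.arange(3.0), profiles)
    np.testing.assert_array_equal(summary.lower, summary.upper)
    np.testing.assert_array_equal(summary.lower, [1.0, 2.0, 3.0])


def test_too_few_profiles_raise():
    with pytest.raises(InsufficientSampleError):
        concentration_percentiles([0.0], np.array([[1.0]]))


def test_range_rule_on_reported_percentiles():
    crange = derive_calibration_range([0.09, 0.11, 0.10, 0.16], [3.79, 2.09, 4.32, 3.10])
    assert crange.lloq_upper_bound == pytest.approx(0.045)
    assert crange.top_lower_bound == pytest.approx(8.64)
    assert crange.admits(0.025, 10.0)


def test_range_rule_single_summary_brackets():
    crange = derive_calibration_range([2.0], [2.0])
    assert crange.lloq_upper_bound == 1.0
    assert crange.top_lower_bound == 4.0


def test_range_rule_always_brackets_percentiles():
    rng = np.random.default_rng(0)
    lowers = rng.uniform(0.05, 0.5, 6)
    uppers = rng.uniform(1.0, 9.0, 6)
    crange = derive_calibration_range(lowers, uppers)
    assert crange.lloq_upper_bound < lowers.min()
    assert crange.top_lower_bound > uppers.max()


def test_range_rule_rejects_nonpositive_percentiles():
    with pytest.raises(DegenerateSimulationError):
        derive_calibration_range([0.0, 0.1], [1.0])


def test_sd_zero_band_collapse_and_range_from_summaries():
    params = PKParameters(cl_mean=8.0, cl_sd=0.0, v_mean=60.0, v_sd=0.0)
    times = np.arange(0.0, 168.1, 1.0)
    profiles = simulate_population(params, IV, times, 10, seed=0)
    summary = concentration_percentiles(times, profiles)
    np.testing.assert_allclose(summary.lower, summary.upper, rtol=1e-12)
    crange = range_from_summaries([summary], (24.0, 168.0))
    lo24, _ = summary.at(24.0)
    lo168, _ = summary.at(168.0)
    assert crange.lloq_upper_bound == pytest.approx(0.5 * min(lo24, lo168))
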