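"""Accuracy/precision statistics, aggregation, recovery, selectivity, gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdmassay import (
    AcceptanceLimits,
    AssayGeometry,
    QCResult,
    ResponseModel,
    RetentionWindow,
    SamplePlan,
    accuracy,
    aggregate_runs,
    evaluate_acceptance,
    precision,
    recovery,
    render_chromatogram,
    rsd_from_stats,
    selectivity_check,
)
from tdmassay.errors import DesignError, InsufficientSampleError, InvalidInputError
from tdmassay.synth import Chromatogram


def test_accuracy_worked_examples():
    assert accuracy(9.92, 10.00) == pytest.approx(99.2)
    assert accuracy(0.107, 0.100) == pytest.approx(107.0)
    assert accuracy(5.0, 5.0) == 100.0


def test_accuracy_rejects_nonpositive_theoretical():
    with pytest.raises(InvalidInputError):
        accuracy(1.0, 0.0)


def test_precision_of_equal_values_is_zero():
    assert precision([2.0, 2.0, 2.0]) == 0.0


def test_precision_needs_two_values():
    with pytest.raises(InsufficientSampleError):
        precision([1.0])


def two_pass_sd(values):
    values = list(values)
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    return mean, var**0.5


@given(
    st.lists(st.floats(min_value=0.5, max_value=100.0, allow_nan=False), min_size=2, max_size=12)
)
@settings(max_examples=100, deadline=None)
def test_precision_matches_two_pass_oracle(values):
    mean, sd = two_pass_sd(values)
    assert precision(values) == pytest.approx(sd / mean * 100.0, rel=1e-12, abs=1e-12)


def test_rsd_from_reported_stats():
    assert rsd_from_stats(0.05, 9.92) == pytest.approx(0.504, abs=5e-4)
    assert round(rsd_from_stats(0.05, 9.92), 1) == 0.5
    assert round(rsd_from_stats(0.03, 9.92), 1) == 0.3


def make_obs(values_by_day, level=1.0):
    rows = []
    for day, values in values_by_day.items():
        for rep, value in enumerate(values, start=1):
            rows.append(
                {"nominal_conc_ug_ml": level, "day": day, "replicate": rep,
                 "back_calc_ug_ml": value}
            )
    return pd.DataFrame(rows)


def test_aggregate_identical_values_gives_perfect_stats():
    obs = make_obs({1: [1.0] * 3, 2: [1.0] * 3, 3: [1.0] * 3})
    results = aggregate_runs(obs)
    for res in results:
        assert res.accuracy_pct == pytest.approx(100.0)
        assert res.precision_pct == pytest.approx(0.0)
    assert {r.scope for r in results} == {"intra", "inter"}


def test_inter_statistics_are_over_day_means():
    obs = make_obs({1: [1.0, 1.0], 2: [1.1, 1.1], 3: [1.2, 1.2]})
    inter = [r for r in aggregate_runs(obs) if r.scope == "inter"][0]
    mean, sd = two_pass_sd([1.0, 1.1, 1.2])
    assert inter.observed_mean == pytest.approx(mean, rel=1e-12)
    assert inter.observed_sd == pytest.approx(sd, rel=1e-12)
    assert inter.n == 3


def test_aggregate_requires_replicates():
    obs = make_obs({1: [1.0], 2: [1.0, 1.1]})
    with pytest.raises(DesignError):
        aggregate_runs(obs)


def test_aggregate_missing_columns_raise():
    with pytest.raises(DesignError):
        aggregate_runs(pd.DataFrame({"a": [1.0]}))


def test_inter_precision_recovers_configured_cv():
    """Configured 1% CV yields mean inter RSD inside [0.2, 2.5]% over 200 seeds."""
    master = np.random.default_rng(41)
    rsds = []
    for _ in range(200):
        rng = np.random.default_rng(master.integers(2**31))
        obs = make_obs({d: 1.0 + rng.normal(0.0, 0.01, 3) for d in (1, 2, 3)})
        inter = [r for r in aggregate_runs(obs) if r.scope == "inter"][0]
        rsds.append(inter.precision_pct)
    assert 0.2 <= np.mean(rsds) <= 2.5


def test_recovery_definition():
    assert recovery(100.0, 100.0) == 100.0
    assert recovery(111.9, 100.0) == pytest.approx(111.9)
    with pytest.raises(InvalidInputError):
        recovery(1.0, 0.0)


def test_recovery_unbiased_at_unit_efficiency():
    """Mean recovery over 100 seeded triplicate pairs lies within 2 SE of 100%."""
    master = np.random.default_rng(51)
    values = []
    for _ in range(100):
        rng = np.random.default_rng(master.integers(2**31))
        ext = 100.0 * np.exp(rng.normal(0.0, 0.02, 3))
        ref = 100.0 * np.exp(rng.normal(0.0, 0.02, 3))
        values.append(recovery(ext.mean(), ref.mean()))
    se = np.std(values, ddof=1) / np.sqrt(len(values))
    assert abs(np.mean(values) - 100.0) < 2.0 * se + 0.2


def qc(level_type, acc, prec):
    return QCResult(
        level_type=level_type, theoretical_conc=1.0, observed_mean=1.0, observed_sd=0.0,
        accuracy_pct=acc, precision_pct=prec, scope="intra", n=3,
    )


def test_acceptance_gates_printed_qc_rows():
    limits = AcceptanceLimits()
    assert evaluate_acceptance(qc("high", 99.2, 0.5), limits)
    assert evaluate_acceptance(qc("lloq", 105.7, 17.0), limits)  # relaxed limits
    assert not evaluate_acceptance(qc("lloq", 105.7, 20.0), limits)


def test_acceptance_boundaries_are_strict_for_precision_closed_for_accuracy():
    limits = AcceptanceLimits()
    assert not evaluate_acceptance(qc("low", 100.0, 15.0), limits)  # strict <15
    assert evaluate_acceptance(qc("low", 85.0, 1.0), limits)  # closed interval
    assert not evaluate_acceptance(qc("low", 84.9, 1.0), limits)


@given(
    st.floats(min_value=50.0, max_value=150.0),
    st.floats(min_value=0.0, max_value=30.0),
    st.floats(min_value=0.0, max_value=10.0),
)
@settings(max_examples=100, deadline=None)
def test_worsening_precision_never_flips_fail_to_pass(acc, prec, extra):
    limits = AcceptanceLimits()
    before = evaluate_acceptance(qc("low", acc, prec), limits)
    after = evaluate_acceptance(qc("low", acc, prec + extra), limits)
    assert not (after and not before)


def _blank(with_interferent=False, height=0.0):
    t = np.linspace(0.0, 15.0, 1801)
    y = np.full(t.size, 10.0)
    if with_interferent:
        y += height * np.exp(-((t - 12.9) ** 2) / (2 * 0.05**2))
    rng = np.random.default_rng(0)
    y = y + rng.normal(0.0, 0.05, t.size)
    return Chromatogram(times=t, intensities=y, sample_id="blank1")


WINDOWS = (RetentionWindow(12.9, 0.2), RetentionWindow(8.8, 0.2))


def test_selectivity_passes_on_clean_blanks():
    report = selectivity_check([_blank()], *WINDOWS, lloq_analyte_height=2.5, is_height=1000.0)
    assert report.passed
    assert report.interferences == ()


def test_selectivity_fails_on_injected_interferent():
    report = selectivity_check(
        [_blank(True, height=2.0)], *WINDOWS, lloq_analyte_height=2.5, is_height=1000.0
    )
    assert not report.passed
    assert any("blank1" in entry for entry in report.interferences)


def test_selectivity_threshold_is_strict():
    """A peak exactly at the interference threshold fails (pass needs strict <)."""
    t = np.linspace(0.0, 15.0, 1801)
    y = np.zeros(t.size)
    y += 0.5 * np.exp(-((t - 12.9) ** 2) / (2 * 0.05**2))  # exactly 20% of 2.5
    chrom = Chromatogram(times=t, intensities=y, sample_id="edge")
    report = selectivity_check([chrom], *WINDOWS, lloq_analyte_height=2.5, is_height=1000.0)
    assert not report.passed


def test_selectivity_requires_blanks():
    with pytest.raises(InvalidInputError):
        selectivity_check([], *WINDOWS, lloq_analyte_height=2.5, is_height=1000.0)


def test_generator_blanks_pass_selectivity_by_default():
    geometry = AssayGeometry()
    blanks = [
        render_chromatogram(
            SamplePlan(f"b{i}", "blank", 0.0, with_is=False), geometry, ResponseModel(), seed=i
        )
        for i in range(5)
    ]
    report = selectivity_check(blanks, *WINDOWS, lloq_analyte_height=2.5, is_height=1000.0)
    assert report.passed
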