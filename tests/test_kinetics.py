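"""Stopped-flow trace fitting, the pseudo-first-order rate law, and group stats."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from membind import (KineticSeries, KineticTrace, compare_conditions,
                     fit_monoexponential, fit_rate_law, vesicle_concentration)
from membind.composition import LipidComposition, NoiseModel
from membind.errors import DegenerateDataError
from membind.synthetic import simulate_stopped_flow


# ---------------------------------------------------------------------------
# vesicle concentration conversion

@pytest.mark.parametrize("lipid_M, expected_vesicle_M", [
    (90e-6, 1.0e-9),     # 90 uM lipid at 90,000 lipids/vesicle -> 1 nM vesicles
    (0.0, 0.0),
    (270e-6, 3.0e-9),    # top of the 0.3-3 nM working range
    (27e-6, 0.3e-9),
])
def test_vesicle_concentration(lipid_M, expected_vesicle_M):
    assert vesicle_concentration(lipid_M) == pytest.approx(expected_vesicle_M, rel=1e-12)


def test_vesicle_concentration_honours_composition():
    comp = LipidComposition.from_dict({"PtdChol": 1.0}, lipids_per_vesicle=45_000)
    assert vesicle_concentration(90e-6, comp) == pytest.approx(2.0e-9)


# ---------------------------------------------------------------------------
# monoexponential fitting

def test_noiseless_trace_recovers_exact_parameters():
    t = np.linspace(0, 2, 200)
    trace = KineticTrace(t=t, F=2.0 + 3.0 * np.exp(-5.0 * t))
    fit = fit_monoexponential(trace)
    assert fit.F0 == pytest.approx(2.0, abs=1e-9)
    assert fit.A_obs == pytest.approx(3.0, abs=1e-9)
    assert fit.k_obs == pytest.approx(5.0, abs=1e-9)
    assert fit.rss == pytest.approx(0.0, abs=1e-16)


def test_noisy_trace_recovers_k_obs_within_3se():
    [trace] = simulate_stopped_flow(1e11, 5.0, [1e-9],
                                    noise=NoiseModel(sigma=0.01, seed=7))
    truth = trace.meta.ground_truth["k_obs"]
    fit = fit_monoexponential(trace)
    assert abs(fit.k_obs - truth) < 3 * fit.k_obs_se


def test_fit_beats_log_rate_grid_oracle():
    """Brute-force grid over log k (with linear LSQ for F0, A at each k)
    never finds a lower RSS than the nonlinear fit."""
    [trace] = simulate_stopped_flow(1e11, 5.0, [1e-9],
                                    noise=NoiseModel(sigma=0.02, seed=3))
    fit = fit_monoexponential(trace)
    t, F = trace.t, trace.F
    best = np.inf
    for k in np.logspace(-3, 4, 2000):
        X = np.column_stack([np.ones_like(t), np.exp(-k * t)])
        beta, *_ = np.linalg.lstsq(X, F, rcond=None)
        rss = float(np.sum((F - X @ beta) ** 2))
        best = min(best, rss)
    assert fit.rss <= best + 1e-12


def test_affine_rescaling_leaves_k_obs_unchanged():
    t = np.linspace(0, 1.5, 150)
    F = 1.0 + 0.5 * np.exp(-4.0 * t) + 0.005 * np.random.default_rng(0).standard_normal(150)
    base = fit_monoexponential(KineticTrace(t=t, F=F))
    scaled = fit_monoexponential(KineticTrace(t=t, F=3.0 * F + 10.0))
    assert scaled.k_obs == pytest.approx(base.k_obs, rel=1e-6)
    assert scaled.F0 == pytest.approx(3.0 * base.F0 + 10.0, rel=1e-6)
    assert scaled.A_obs == pytest.approx(3.0 * base.A_obs, rel=1e-6)


def test_constant_trace_rejected():
    t = np.linspace(0, 1, 10)
    with pytest.raises(DegenerateDataError):
        fit_monoexponential(KineticTrace(t=t, F=np.ones_like(t)))


def test_trace_validation():
    with pytest.raises(ValueError):
        KineticTrace(t=np.array([0.0, 1.0, 0.5, 2.0]), F=np.zeros(4))
    with pytest.raises(ValueError):
        KineticTrace(t=np.array([0.0, 1.0, 2.0]), F=np.zeros(3))


# ---------------------------------------------------------------------------
# rate law

def test_exact_line_recovers_rates_and_kd():
    v = np.array([0.5, 1.0, 2.0, 3.0]) * 1e-9
    series = KineticSeries(vesicle_M=v, k_obs=1e11 * v + 20.0)
    rc = fit_rate_law(series)
    assert rc.k_on == pytest.approx(1e11, rel=1e-9)
    assert rc.k_off == pytest.approx(20.0, rel=1e-9)
    assert rc.K_d == pytest.approx(2e-10, rel=1e-9)


def test_two_points_interpolate_exactly():
    v = np.array([1e-9, 2e-9])
    series = KineticSeries(vesicle_M=v, k_obs=np.array([120.0, 220.0]))
    rc = fit_rate_law(series)
    assert rc.k_on == pytest.approx(1e11)
    assert rc.k_off == pytest.approx(20.0)


def test_kd_identity_and_3se_recovery_on_noisy_series(rng):
    v = np.linspace(0.3, 3.0, 8) * 1e-9
    k_true = 1e11 * v + 20.0
    series = KineticSeries(vesicle_M=v, k_obs=k_true + rng.normal(0, 5.0, 8))
    rc = fit_rate_law(series)
    assert rc.K_d == rc.k_off / rc.k_on
    assert abs(rc.K_d - 2e-10) < 3 * rc.K_d_se


def test_negative_intercept_warned_not_clamped(rng):
    v = np.linspace(1, 3, 6) * 1e-9
    y = 1e11 * v - 30.0 + rng.normal(0, 1.0, 6)
    with pytest.warns(UserWarning):
        rc = fit_rate_law(KineticSeries(vesicle_M=v, k_obs=y))
    assert rc.k_off < 0
    assert rc.negative_koff_warning


def test_zero_koff_interval_covers_zero_mostly():
    """With data generated at k_off = 0, the 95% CI on the intercept should
    cover 0 in at least 90% of replicates."""
    from scipy import stats
    v = np.linspace(0.3, 3.0, 8) * 1e-9
    covered = 0
    for seed in range(100):
        g = np.random.default_rng(seed)
        y = np.clip(1e11 * v + g.normal(0, 8.0, 8), 1e-3, None)
        rc = fit_rate_law(KineticSeries(vesicle_M=v, k_obs=y))
        tcrit = stats.t.ppf(0.975, len(v) - 2)
        if abs(rc.k_off) <= tcrit * rc.k_off_se:
            covered += 1
    assert covered >= 90


# ---------------------------------------------------------------------------
# ANOVA + Fisher LSD

def test_two_group_f_equals_t_squared(rng):
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.5, 1, 10)
    from scipy import stats
    res = compare_conditions({"a": a, "b": b})
    t, p = stats.ttest_ind(a, b)
    assert res.F == pytest.approx(t ** 2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_identical_groups_give_f_zero_p_one():
    res = compare_conditions({"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0], "c": [1.0, 1.0]})
    assert res.F == 0.0
    assert res.p == 1.0
    assert not any(v["significant"] for v in res.pairwise.values())


def test_three_group_anova_matches_sum_of_squares_oracle(rng):
    groups = {k: rng.normal(mu, 1.0, n)
              for k, mu, n in [("x", 0.0, 6), ("y", 1.0, 7), ("z", 2.5, 5)]}
    res = compare_conditions(groups)
    # independent textbook decomposition
    allv = np.concatenate(list(groups.values()))
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups.values())
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    F = (ssb / 2) / (ssw / (len(allv) - 3))
    from scipy import stats
    assert res.F == pytest.approx(F, rel=1e-12)
    assert res.p == pytest.approx(stats.f.sf(F, 2, len(allv) - 3), rel=1e-12)


def test_single_observation_group_rejected():
    with pytest.raises(ValueError):
        compare_conditions({"a": [1.0], "b": [1.0, 2.0]})


# ---------------------------------------------------------------------------
# properties

@given(st.floats(0.5, 50.0), st.floats(0.1, 200.0))
@settings(max_examples=20, deadline=None)
def test_generator_fitter_roundtrip_is_exact(k_scaled, k_off):
    """Zero-noise generator/fitter round trip at machine precision."""
    k_on = k_scaled * 1e10
    [trace] = simulate_stopped_flow(k_on, k_off, [1e-9])
    fit = fit_monoexponential(trace)
    assert fit.k_obs == pytest.approx(k_on * 1e-9 + k_off, rel=1e-7)
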