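"""Single-site ITC isotherm: heat prediction, fitting, thermodynamics."""

import numpy as np
import pytest
from scipy import optimize

from membind import (TitrationProtocol, derive_thermo, fit_isotherm,
                     predict_heats, simulate_itc)
from membind.composition import NoiseModel
from membind.errors import InvalidProtocolError
from membind.itc import _concentration_schedule, bound_concentration


def test_zero_enthalpy_gives_zero_heats(protocol):
    heats = predict_heats(1.0, 1e-5, 0.0, protocol)
    assert np.allclose(heats.q_kJ, 0.0)


def test_stoichiometric_limit_heats_step(protocol):
    """At K_d -> 0 each pre-equivalence injection releases dH times the
    injected moles; post-equivalence heats vanish."""
    heats = predict_heats(1.0, 1e-12, -30.0, protocol)
    mol_inj = 1e-3 * 10e-6  # syringe conc x injection volume
    pre = heats.q_kJ[heats.molar_ratio < 0.8]
    post = heats.q_kJ[heats.molar_ratio > 1.3]
    assert np.allclose(pre, -30.0 * mol_inj, rtol=2e-2)
    assert np.all(np.abs(post) < 1e-2 * np.abs(pre[0]))


def test_total_heat_conservation_when_saturating():
    """Integrated heat far past saturation equals n dH (cell protein moles)
    within 1%, and exactly equals dH times the complex ever formed in the
    overflow cell (including complex later displaced by injections)."""
    protocol = TitrationProtocol.uniform(
        20, 5e-6, cell_volume_L=1.4e-3, cell_conc_M=50e-6, syringe_conc_M=1e-2)
    n, dH, K_d = 1.0, -30.0, 1e-8
    heats = predict_heats(n, K_d, dH, protocol)
    P_t, L_t, dil = _concentration_schedule(protocol)
    formed = 0.0
    B_prev = 0.0
    for i in range(len(P_t)):
        B = bound_concentration(n, K_d, P_t[i], L_t[i])
        formed += B - B_prev * dil[i]
        B_prev = B
    assert heats.q_kJ.sum() == pytest.approx(dH * formed * protocol.cell_volume_L,
                                             rel=1e-12)
    expected = n * dH * protocol.cell_conc_M * protocol.cell_volume_L
    assert heats.q_kJ.sum() == pytest.approx(expected, rel=1e-2)


def test_bound_concentration_matches_bisection_oracle(protocol):
    n, K_d = 0.8, 2e-5
    P_t, L_t, _ = _concentration_schedule(protocol)
    for P, L in zip(P_t, L_t):
        B = bound_concentration(n, K_d, P, L)
        f = lambda b: (n * P - b) * (L - b) - K_d * b
        oracle = optimize.bisect(f, 0.0, min(n * P, L), xtol=1e-18)
        assert B == pytest.approx(oracle, rel=1e-10, abs=1e-18)


def test_invalid_protocols_rejected():
    with pytest.raises(InvalidProtocolError):
        TitrationProtocol.uniform(25, 10e-6, cell_volume_L=1.4e-3,
                                  cell_conc_M=50e-6, syringe_conc_M=0.0)
    with pytest.raises(InvalidProtocolError):
        TitrationProtocol.uniform(2, 10e-6, cell_volume_L=1.4e-3,
                                  cell_conc_M=50e-6, syringe_conc_M=1e-3)


# ---------------------------------------------------------------------------
# fitting

def test_noiseless_fit_recovers_parameters_to_01_percent(protocol):
    heats = predict_heats(1.2, 14e-6, -30.0, protocol)
    fit = fit_isotherm(heats)
    assert fit.n == pytest.approx(1.2, rel=1e-3)
    assert fit.K_d == pytest.approx(14e-6, rel=1e-3)
    assert fit.dH == pytest.approx(-30.0, rel=1e-3)


def test_fix_n_mode(protocol):
    heats = predict_heats(1.0, 14e-6, -30.0, protocol)
    fit = fit_isotherm(heats, fix_n=1.0)
    assert fit.n == 1.0
    assert fit.n_se == 0.0
    assert fit.K_d == pytest.approx(14e-6, rel=1e-6)


def test_rss_minimum_coincides_with_profile_scan(protocol):
    """1-D profile over K_d (refitting dH, n at each node) brackets the
    least-squares estimate at its RSS minimum."""
    heats = simulate_itc(1.0, 14e-6, -30.0, protocol,
                         noise=NoiseModel(sigma=2e-6, seed=11))
    fit = fit_isotherm(heats, fit_offset=False)

    def profile_rss(K_d):
        def resid(theta):
            n, dH = theta
            if n <= 0:
                return np.full(len(heats.q_kJ), 1e6)
            return predict_heats(n, K_d, dH, heats.protocol).q_kJ - heats.q_kJ
        sol = optimize.least_squares(resid, [1.0, -30.0])
        return 2 * sol.cost

    grid = fit.K_d * np.geomspace(0.5, 2.0, 21)
    rss_grid = [profile_rss(k) for k in grid]
    assert min(rss_grid) >= fit.rss - 1e-12 * max(1.0, fit.rss)
    # the scan's own minimum sits at the node closest to the fitted K_d
    assert grid[int(np.argmin(rss_grid))] == pytest.approx(fit.K_d, rel=0.08)


def test_thermodynamic_identities(protocol):
    heats = predict_heats(1.0, 14e-6, -30.0, protocol)
    fit = fit_isotherm(heats)
    assert fit.dG == pytest.approx(8.314e-3 * 298.15 * np.log(fit.K_d), rel=1e-12)
    assert fit.dG == pytest.approx(fit.dH + fit.minus_TdS, rel=1e-12)


def test_derive_thermo_values():
    dG, mTdS = derive_thermo(1.0, -10.0, 298.15)
    assert dG == 0.0                       # K_d = 1 M reference state
    assert mTdS == pytest.approx(10.0)
    dG, _ = derive_thermo(14e-6, -30.0, 298.15)
    assert dG == pytest.approx(-27.7, abs=0.05)   # hand: RT ln(1.4e-5)
    dG, mTdS = derive_thermo(1e-6, dH=8.314e-3 * 298.15 * np.log(1e-6), T=298.15)
    assert mTdS == pytest.approx(0.0, abs=1e-12)  # dH = dG -> -TdS = 0


def test_heat_magnitude_monotone_after_equivalence_on_c_ladder():
    for c in (15.0, 50.0, 200.0):
        K_d = 1.0 * 50e-6 / c
        protocol = TitrationProtocol.uniform(
            30, 10e-6, cell_volume_L=1.4e-3, cell_conc_M=50e-6, syringe_conc_M=1.2e-3)
        heats = predict_heats(1.0, K_d, -30.0, protocol)
        post = np.abs(heats.q_kJ[heats.molar_ratio > 1.0])
        assert np.all(np.diff(post) <= 1e-15)


def test_fit_invariant_to_volume_conc_rescaling(protocol):
    """Halving injection volumes with doubled syringe concentration keeps the
    mole schedule and hence the fitted parameters (dilution differs slightly,
    so the generator uses the rescaled protocol for its own heats)."""
    scaled = TitrationProtocol(
        cell_volume_L=protocol.cell_volume_L, cell_conc_M=protocol.cell_conc_M,
        syringe_conc_M=2 * protocol.syringe_conc_M,
        injection_volumes_L=tuple(v / 2 for v in protocol.injection_volumes_L))
    f1 = fit_isotherm(predict_heats(1.0, 14e-6, -30.0, protocol))
    f2 = fit_isotherm(predict_heats(1.0, 14e-6, -30.0, scaled))
    assert f1.K_d == pytest.approx(f2.K_d, rel=1e-6)
    assert f1.n == pytest.approx(f2.n, rel=1e-6)
    assert f1.dH == pytest.approx(f2.dH, rel=1e-6)


def test_median_kd_recovery_under_2pct_noise(protocol):
    """Median |K_d error| over 50 seeded replicates at 2% noise stays below 15%."""
    ref = predict_heats(1.0, 14e-6, -30.0, protocol)
    sigma = 0.02 * np.max(np.abs(ref.q_kJ))
    errs = []
    for seed in range(50):
        heats = simulate_itc(1.0, 14e-6, -30.0, protocol,
                             noise=NoiseModel(sigma=sigma, seed=seed))
        fit = fit_isotherm(heats)
        errs.append(abs(fit.K_d - 14e-6) / 14e-6)
    assert np.median(errs) < 0.15


def test_c_value_warning(protocol):
    heats = predict_heats(1.0, 14e-6, -30.0, protocol)
    assert not fit_isotherm(heats).c_warning
    weak = TitrationProtocol.uniform(
        30, 10e-6, cell_volume_L=1.4e-3, cell_conc_M=5e-6, syringe_conc_M=2e-2)
    fit = fit_isotherm(predict_heats(1.0, 2e-2, -30.0, weak), fix_n=1.0)
    assert fit.c_warning
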