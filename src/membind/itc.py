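"""Isothermal titration calorimetry: the single-site binding isotherm.

A ligand at syringe concentration L_syr is injected stepwise into a fixed
cell of macromolecule. The cell overflows, so each injection of volume dV
dilutes both species by (1 - dV/V0) while adding L_syr * dV/V0 of fresh
ligand. After each injection the bound ligand concentration follows from
the single-site mass-action closure:

    B = 1/2 [ (n P_t + L_t + K_d) - sqrt((n P_t + L_t + K_d)^2 - 4 n P_t L_t) ]

and the heat evolved by injection i is the enthalpy times the newly formed
complex in the cell:

    q_i = dH * V0 * (B_i - B_{i-1} * (1 - dV_i/V0))

Fitting the q_i series against the molar ratio recovers the stoichiometry
n, dissociation constant K_d and molar enthalpy dH; dG = RT ln K_d and
-TdS = dG - dH complete the thermodynamic decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import R_KJ
from .errors import FitFailureError, InvalidProtocolError

_C_WINDOW = (1.0, 1000.0)


@dataclass(frozen=True)
class TitrationProtocol:
    """Injection schedule for a fixed-volume (overflow) calorimeter cell.

    All volumes in litres, concentrations molar, temperature in kelvin.
    """

    cell_volume_L: float
    cell_conc_M: float
    syringe_conc_M: float
    injection_volumes_L: tuple[float, ...]
    temperature_K: float = 298.15

    def __post_init__(self):
        if self.cell_volume_L <= 0 or self.cell_conc_M <= 0:
            raise InvalidProtocolError("cell volume and concentration must be positive")
        if self.syringe_conc_M <= 0:
            raise InvalidProtocolError("syringe concentration must be positive")
        if len(self.injection_volumes_L) < 3:
            raise InvalidProtocolError("need at least 3 injections")
        if any(v <= 0 for v in self.injection_volumes_L):
            raise InvalidProtocolError("injection volumes must be positive")
        if self.temperature_K <= 0:
            raise InvalidProtocolError("temperature must be positive")
        object.__setattr__(self, "injection_volumes_L",
                           tuple(float(v) for v in self.injection_volumes_L))

    @classmethod
    def uniform(cls, n_injections: int, injection_volume_L: float, **kwargs) -> "TitrationProtocol":
        return cls(injection_volumes_L=(injection_volume_L,) * n_injections, **kwargs)


@dataclass
class InjectionHeats:
    """Per-injection heats (kJ) and the ligand:protein molar ratio after each."""

    q_kJ: np.ndarray
    molar_ratio: np.ndarray
    protocol: TitrationProtocol
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q_kJ = np.asarray(self.q_kJ, dtype=float)
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        if len(self.q_kJ) != len(self.protocol.injection_volumes_L):
            raise InvalidProtocolError("heat list does not match injection schedule")


@dataclass
class IsothermFit:
    """Fitted single-site parameters and the derived thermodynamic terms.

    dG = RT ln K_d (association convention, negative for K_d < 1 M) and
    -TdS = dG - dH hold exactly on every instance.
    """

    n: float
    K_d: float
    dH: float
    dG: float
    minus_TdS: float
    n_se: float
    K_d_se: float
    dH_se: float
    T: float
    rss: float
    q_offset: float = 0.0
    c_value: float = np.nan
    c_warning: bool = False

    def __post_init__(self):
        dG, mTdS = derive_thermo(self.K_d, self.dH, self.T)
        if not (np.isclose(self.dG, dG, rtol=1e-9) and np.isclose(self.minus_TdS, mTdS, rtol=1e-9, atol=1e-12)):
            raise ValueError("dG/-TdS inconsistent with K_d, dH, T")


# ---------------------------------------------------------------------------

def bound_concentration(n: float, K_d: float, P_t: float, L_t: float) -> float:
    """Bound-ligand concentration from the single-site quadratic closure."""
    s = n * P_t + L_t + K_d
    disc = s * s - 4.0 * n * P_t * L_t
    if disc < 0:
        raise ArithmeticError("negative discriminant in mass-action closure")
    return 0.5 * (s - np.sqrt(disc))


def _concentration_schedule(protocol: TitrationProtocol):
    """Total cell concentrations of protein and ligand after each injection."""
    V0 = protocol.cell_volume_L
    P = protocol.cell_conc_M
    L = 0.0
    P_t, L_t, dil = [], [], []
    for dV in protocol.injection_volumes_L:
        d = 1.0 - dV / V0
        if d <= 0:
            raise InvalidProtocolError("injection volume exceeds cell volume")
        P = P * d
        L = L * d + protocol.syringe_conc_M * (dV / V0)
        P_t.append(P)
        L_t.append(L)
        dil.append(d)
    return np.array(P_t), np.array(L_t), np.array(dil)


def predict_heats(n: float, K_d: float, dH: float, protocol: TitrationProtocol,
                  q_offset: float = 0.0) -> InjectionHeats:
    """Exact finite-concentration heats for a single-site titration.

    Parameters
    ----------
    n, K_d, dH : stoichiometry (sites), dissociation constant (M), molar
        binding enthalpy (kJ/mol).
    q_offset : constant per-injection heat of dilution (kJ), default 0.

    Returns per-injection heats in kJ together with the cumulative
    ligand:protein molar ratio.
    """
    if n <= 0 or K_d <= 0:
        raise ValueError("n and K_d must be positive")
    P_t, L_t, dil = _concentration_schedule(protocol)
    V0 = protocol.cell_volume_L
    q = np.empty(len(P_t))
    B_prev = 0.0
    for i in range(len(P_t)):
        B = bound_concentration(n, K_d, P_t[i], L_t[i])
        q[i] = dH * V0 * (B - B_prev * dil[i]) + q_offset
        B_prev = B
    return InjectionHeats(q_kJ=q, molar_ratio=L_t / P_t, protocol=protocol,
                         ground_truth={"n": n, "K_d": K_d, "dH": dH})


def derive_thermo(K_d: float, dH: float, T: float) -> tuple[float, float]:
    """(dG, -TdS) in kJ/mol from K_d (M) and dH (kJ/mol) at temperature T (K)."""
    if K_d <= 0 or T <= 0:
        raise ValueError("K_d and T must be positive")
    dG = R_KJ * T * np.log(K_d)
    return float(dG), float(dG - dH)


def fit_isotherm(heats: InjectionHeats, fix_n: float | None = None,
                 skip_first: bool = False, fit_offset: bool = True) -> IsothermFit:
    """Least-squares fit of the single-site isotherm to integrated heats.

    Parameters
    ----------
    fix_n : float, optional
        Fix the stoichiometry (common when cell concentration is too low to
        determine it); only (K_d, dH) are then free.
    skip_first : bool
        Drop the first injection from the residuals (syringe-tip diffusion
        artefact in real data). Default off.
    fit_offset : bool
        Include a constant per-injection heat-of-dilution offset. Default on.

    Notes
    -----
    K_d and n are optimised on log scale to keep them positive. The c-value
    n * P_cell / K_d is reported; a warning flag is set outside [1, 1000]
    where the isotherm shape constrains the parameters poorly.
    """
    protocol = heats.protocol
    q_obs = heats.q_kJ
    mask = np.ones(len(q_obs), dtype=bool)
    if skip_first:
        mask[0] = False
    n_free = int(np.sum(mask))
    n_params = (2 if fix_n is not None else 3) + (1 if fit_offset else 0)
    if n_free < max(5, n_params + 1):
        raise InvalidProtocolError("too few informative injections to fit")

    scale = np.max(np.abs(q_obs)) or 1.0
    # crude starting values: dH from early heats, K_d from cell concentration
    moles_inj0 = protocol.syringe_conc_M * protocol.injection_volumes_L[0]
    dH0 = q_obs[0] / moles_inj0 if moles_inj0 > 0 else -10.0
    if dH0 == 0:
        dH0 = -10.0
    K0 = protocol.cell_conc_M / 5.0
    n0 = 1.0 if fix_n is None else float(fix_n)

    def unpack(theta):
        i = 0
        if fix_n is None:
            n = np.exp(theta[i]); i += 1
        else:
            n = fix_n
        K_d = np.exp(theta[i]); i += 1
        dH = theta[i]; i += 1
        off = theta[i] if fit_offset else 0.0
        return n, K_d, dH, off

    def residuals(theta):
        with np.errstate(over="ignore", invalid="ignore"):
            n, K_d, dH, off = unpack(theta)
            if not np.all(np.isfinite([n, K_d, dH, off])):
                return np.full(n_free, 1e6)
            try:
                q_mod = predict_heats(n, K_d, dH, protocol, q_offset=off).q_kJ
            except (ArithmeticError, ValueError):
                return np.full(n_free, 1e6)
        if not np.all(np.isfinite(q_mod)):
            return np.full(n_free, 1e6)
        return (q_mod[mask] - q_obs[mask]) / scale

    theta0 = []
    if fix_n is None:
        theta0.append(np.log(n0))
    theta0 += [np.log(K0), dH0]
    if fit_offset:
        theta0.append(0.0)

    best = None
    for kfac in (1.0, 0.1, 10.0, 0.01, 100.0):
        t0 = list(theta0)
        t0[1 if fix_n is None else 0] = np.log(K0 * kfac)
        try:
            sol = optimize.least_squares(residuals, t0, method="lm", max_nfev=20000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("isotherm fit did not converge",
                              diagnostics={"theta0": theta0})
    sol = best
    n_hat, Kd_hat, dH_hat, off_hat = unpack(sol.x)

    # covariance of theta from the Jacobian, then delta method to (n, K_d, dH)
    dof = n_free - len(sol.x)
    J = sol.jac
    rss = float(2 * sol.cost * scale ** 2)
    se = {"n": np.nan, "K": np.nan, "dH": np.nan}
    if dof > 0:
        s2 = 2 * sol.cost / dof
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            diag = np.sqrt(np.clip(np.diag(cov), 0, None))
            i = 0
            if fix_n is None:
                se["n"] = diag[i] * n_hat; i += 1  # delta method, n = e^theta
            else:
                se["n"] = 0.0
            se["K"] = diag[i] * Kd_hat; i += 1  # delta method, K_d = e^theta
            se["dH"] = diag[i]
        except np.linalg.LinAlgError:
            pass
    else:
        se = {"n": 0.0, "K": 0.0, "dH": 0.0}

    T = protocol.temperature_K
    dG, mTdS = derive_thermo(Kd_hat, dH_hat, T)
    c_val = n_hat * protocol.cell_conc_M / Kd_hat
    return IsothermFit(
        n=float(n_hat), K_d=float(Kd_hat), dH=float(dH_hat),
        dG=dG, minus_TdS=mTdS,
        n_se=float(se["n"]), K_d_se=float(se["K"]), dH_se=float(se["dH"]),
        T=T, rss=rss, q_offset=float(off_hat),
        c_value=float(c_val),
        c_warning=not (_C_WINDOW[0] <= c_val <= _C_WINDOW[1]),
    )
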