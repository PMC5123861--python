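"""Stopped-flow kinetics: monoexponential trace fitting and the pseudo-first-order rate law.

A protein mixed rapidly with vesicles under pseudo-first-order conditions
(vesicles in excess over protein binding sites) relaxes to equilibrium as

    F(t) = F0 + A_obs * exp(-k_obs * t)

with the observed rate a linear function of vesicle concentration [v]:

    k_obs = k_on * [v] + k_off

The slope of k_obs versus [v] is the bimolecular association rate constant
k_on (1/M/s), the intercept the unimolecular dissociation rate constant
k_off (1/s), and K_d = k_off / k_on is the apparent vesicle dissociation
constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import optimize, stats

from .composition import LipidComposition
from .errors import DegenerateDataError, FitFailureError
from .constants import LIPIDS_PER_VESICLE


# ---------------------------------------------------------------------------
# domain types

@dataclass
class TraceMeta:
    """Experimental context for one stopped-flow trace (all concentrations molar)."""

    protein_M: float = np.nan
    lipid_M: float = np.nan
    composition: LipidComposition | None = None
    temperature_K: float = 298.15
    ca_free_M: float = np.nan
    ground_truth: dict = field(default_factory=dict)


@dataclass
class KineticTrace:
    """One time-resolved fluorescence trace."""

    t: np.ndarray
    F: np.ndarray
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.F.shape:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if len(self.t) < 4:
            raise ValueError("a trace needs at least 4 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")


@dataclass
class ExponentialFit:
    """Least-squares estimates for F(t) = F0 + A_obs exp(-k_obs t)."""

    F0: float
    A_obs: float
    k_obs: float
    F0_se: float
    A_obs_se: float
    k_obs_se: float
    rss: float

    def __post_init__(self):
        if self.k_obs <= 0:
            raise ValueError("k_obs must be positive")


@dataclass
class KineticSeries:
    """(vesicle concentration, k_obs) points feeding the rate-law regression."""

    vesicle_M: np.ndarray
    k_obs: np.ndarray
    k_obs_se: np.ndarray | None = None

    def __post_init__(self):
        self.vesicle_M = np.asarray(self.vesicle_M, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.k_obs_se is not None:
            self.k_obs_se = np.asarray(self.k_obs_se, dtype=float)
        if len(np.unique(self.vesicle_M)) < 2:
            raise ValueError("need at least 2 distinct vesicle concentrations")


@dataclass
class RateConstants:
    """(k_on, k_off, K_d) triple with propagated uncertainties.

    K_d is k_off/k_on by construction. A negative fitted intercept is kept
    as-is (with ``negative_koff_warning``) so that error propagation to K_d
    stays honest.
    """

    k_on: float
    k_off: float
    K_d: float
    k_on_se: float
    k_off_se: float
    K_d_se: float
    cov_on_off: float
    negative_koff_warning: bool = False

    def __post_init__(self):
        if self.k_on <= 0:
            raise ValueError("k_on must be positive")
        if not np.isclose(self.K_d, self.k_off / self.k_on, rtol=1e-12, atol=0.0, equal_nan=True):
            raise ValueError("K_d must equal k_off/k_on")


# ---------------------------------------------------------------------------
# operations

def vesicle_concentration(total_lipid_M: float, composition: LipidComposition | None = None) -> float:
    """Convert bulk lipid concentration (M) to vesicle particle concentration (M).

    Uses the composition's lipids-per-vesicle count (default 90,000 for a
    ~100 nm LUV).
    """
    if total_lipid_M < 0:
        raise ValueError("total lipid concentration must be non-negative")
    n = composition.lipids_per_vesicle if composition is not None else LIPIDS_PER_VESICLE
    return total_lipid_M / n


def _monoexp(t, F0, A, k):
    return F0 + A * np.exp(-k * t)


def _initial_guess(t: np.ndarray, F: np.ndarray) -> tuple[float, float, float]:
    """F0 from the last decile, A from the first point, k from a log-linear fit."""
    n_tail = max(1, len(F) // 10)
    F0 = float(np.mean(F[-n_tail:]))
    A = float(F[0] - F0)
    resid = np.abs(F - F0)
    mask = resid > 1e-12 * max(1.0, np.max(resid))
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(resid[mask]), 1)[0]
        k = max(-slope, 1e-6)
    else:
        k = 1.0 / max(t[-1] - t[0], 1e-12)
    return F0, A, k


def fit_monoexponential(trace: KineticTrace) -> ExponentialFit:
    """Fit F(t) = F0 + A_obs exp(-k_obs t) by nonlinear least squares.

    Standard errors come from the parameter covariance at the optimum.
    Retries with multiplicatively perturbed initial rates before giving up.

    Raises
    ------
    DegenerateDataError
        If the trace is constant (no amplitude to fit).
    FitFailureError
        If the optimiser fails after all restarts.
    """
    t, F = trace.t, trace.F
    if np.ptp(F) == 0.0:
        raise DegenerateDataError("trace is constant; no exponential signal")
    F0_0, A_0, k_0 = _initial_guess(t, F)
    last_err = None
    for factor in (1.0, 0.2, 5.0, 0.04, 25.0):
        try:
            popt, pcov = optimize.curve_fit(
                _monoexp, t, F, p0=[F0_0, A_0, k_0 * factor],
                bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
            se = np.sqrt(np.diag(pcov))
            rss = float(np.sum((F - _monoexp(t, *popt)) ** 2))
            return ExponentialFit(
                F0=float(popt[0]), A_obs=float(popt[1]), k_obs=float(popt[2]),
                F0_se=float(se[0]), A_obs_se=float(se[1]), k_obs_se=float(se[2]),
                rss=rss,
            )
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare paths
            last_err = err
    raise FitFailureError(
        "monoexponential fit did not converge",
        diagnostics={"restarts": 5, "initial": (F0_0, A_0, k_0), "error": str(last_err)},
    )


def fit_rate_law(series: KineticSeries, weighted: bool | None = None) -> RateConstants:
    """Linear regression of k_obs on vesicle concentration.

    k_obs = k_on [v] + k_off. When ``weighted`` is True (or left None with
    standard errors present on the series... default is unweighted even
    then, matching common practice) points are weighted by 1/SE^2.

    The K_d standard error is propagated from the full (slope, intercept)
    covariance:

        var(K_d) = (koff/kon)^2 * [var(koff)/koff^2 + var(kon)/kon^2
                                   - 2 cov(kon, koff)/(kon koff)]
    """
    v, y = series.vesicle_M, series.k_obs
    use_weights = bool(weighted) and series.k_obs_se is not None
    if use_weights:
        w = 1.0 / np.asarray(series.k_obs_se, dtype=float) ** 2
    else:
        w = np.ones_like(y)

    X = np.column_stack([v, np.ones_like(v)])
    WX = X * w[:, None]
    xtx = X.T @ WX
    beta = np.linalg.solve(xtx, WX.T @ y)
    resid = y - X @ beta
    dof = len(y) - 2
    if dof > 0:
        s2 = float(resid @ (w * resid)) / dof
    else:
        s2 = 0.0  # two points: interpolating line, zero residual variance
    cov = s2 * np.linalg.inv(xtx)

    k_on, k_off = float(beta[0]), float(beta[1])
    if k_on <= 0:
        raise DegenerateDataError("fitted k_on is non-positive; series carries no association signal")
    var_on, var_off = cov[0, 0], cov[1, 1]
    cov_on_off = cov[0, 1]
    K_d = k_off / k_on
    if k_off != 0:
        var_Kd = K_d ** 2 * (
            var_off / k_off ** 2 + var_on / k_on ** 2 - 2 * cov_on_off / (k_on * k_off)
        )
    else:
        var_Kd = var_off / k_on ** 2
    neg = k_off < 0
    if neg:
        warnings.warn("fitted k_off is negative; reported unclamped", stacklevel=2)
    return RateConstants(
        k_on=k_on, k_off=k_off, K_d=K_d,
        k_on_se=float(np.sqrt(var_on)), k_off_se=float(np.sqrt(var_off)),
        K_d_se=float(np.sqrt(max(var_Kd, 0.0))),
        cov_on_off=float(cov_on_off), negative_koff_warning=neg,
    )


# ---------------------------------------------------------------------------
# group comparison (one-way ANOVA with Fisher LSD post hoc)

@dataclass
class AnovaResult:
    """One-way ANOVA table plus pairwise Fisher least-significant-difference tests.

    ``pairwise`` maps (label_a, label_b) to (mean difference, t, p, significant).
    Pairwise significance is protected: flagged only when the omnibus F test
    itself is significant at alpha.
    """

    F: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    group_means: dict
    pairwise: dict
    alpha: float = 0.05

    @property
    def omnibus_significant(self) -> bool:
        return self.p < self.alpha


def compare_conditions(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA across labelled groups with Fisher-LSD pairwise follow-up.

    Each pairwise comparison uses the pooled within-group variance (the
    ANOVA mean square error) and its degrees of freedom, which is what
    distinguishes the LSD test from independent two-sample t tests.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if len(a) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")

    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    k_groups = len(arrays)
    N = len(all_vals)
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k_groups - 1, N - k_groups
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        F = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        F = ms_b / ms_w
        p = float(stats.f.sf(F, df_b, df_w))

    omnibus_sig = p < alpha
    pairwise = {}
    for (la, a), (lb, b) in combinations(arrays.items(), 2):
        diff = a.mean() - b.mean()
        se = np.sqrt(ms_w * (1 / len(a) + 1 / len(b)))
        if se == 0.0:
            tstat = np.inf if diff != 0 else 0.0
            pp = 0.0 if diff != 0 else 1.0
        else:
            tstat = diff / se
            pp = float(2 * stats.t.sf(abs(tstat), df_w))
        pairwise[(la, lb)] = {
            "diff": float(diff), "t": float(tstat), "p": pp,
            "significant": bool(omnibus_sig and pp < alpha),
        }
    return AnovaResult(
        F=float(F), p=float(p), df_between=df_b, df_within=df_w,
        ms_within=float(ms_w),
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        pairwise=pairwise, alpha=alpha,
    )
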