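"""EPR power-saturation depth analysis for spin-labeled membrane proteins.

The peak-to-peak amplitude of a nitroxide EPR line saturates with incident
microwave power P as

    A(P) = I * sqrt(P) * [1 + (2^(1/eps) - 1) * P / P_half]^(-eps)

where P_half is the power at half saturation and eps the resonator-line
homogeneity exponent. Collisions with a paramagnetic relaxant shift P_half;
the shifts produced by a lipophilic relaxant (O2) and a polar one (NiEDDA),
each referenced to the nitrogen-purged baseline, define the depth parameter

    Phi = ln[ dP_half(O2) / dP_half(NiEDDA) ]

which increases monotonically with the label's immersion into the bilayer.
An empirical calibration - here a tanh curve fitted to reference
(Phi, distance) pairs from spin labels of known position - converts Phi into
a signed distance from the lipid phosphate plane (positive = hydrocarbon
side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import interpolate, optimize

from .errors import CalibrationError, InvalidAccessibilityError

CONDITIONS = ("N2", "O2", "NiEDDA")


@dataclass
class SaturationCurve:
    """Amplitude versus incident microwave power for one relaxant condition."""

    P_mW: np.ndarray
    A: np.ndarray
    condition: str = "N2"

    def __post_init__(self):
        self.P_mW = np.asarray(self.P_mW, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if self.P_mW.shape != self.A.shape or len(self.P_mW) < 5:
            raise ValueError("need >= 5 matched (P, A) points")
        if np.any(self.P_mW <= 0) or np.any(np.diff(self.P_mW) <= 0):
            raise ValueError("powers must be positive and strictly increasing")


@dataclass
class SaturationFit:
    """Fitted saturation parameters for one curve."""

    P_half: float
    eps: float
    I: float
    P_half_se: float
    eps_se: float
    I_se: float
    rss: float
    unbounded_warning: bool = False

    def __post_init__(self):
        if self.P_half <= 0:
            raise ValueError("P_half must be positive")
        if not 0.5 <= self.eps <= 1.5:
            raise ValueError("eps outside physical range [0.5, 1.5]")


@dataclass
class DepthRecord:
    """Depth parameter and derived immersion depth for one labeled site.

    Sign convention: positive distance = hydrocarbon side of the phosphate
    plane, negative = aqueous side.
    """

    site: str
    dP_O2: float
    dP_NiEDDA: float
    phi: float
    phi_err: float = np.nan
    distance_A: float = np.nan
    distance_err: float = np.nan


def saturation_amplitude(P, I, P_half, eps):
    """The homogeneity-corrected saturation rollover curve."""
    P = np.asarray(P, dtype=float)
    return I * np.sqrt(P) * (1.0 + (2.0 ** (1.0 / eps) - 1.0) * P / P_half) ** (-eps)


def fit_saturation(curve: SaturationCurve, fix_eps: float | None = None) -> SaturationFit:
    """Least-squares fit of (I, P_half, eps) to a saturation curve.

    ``fix_eps`` pins the homogeneity exponent (1.5 for a perfectly
    inhomogeneous line) leaving (I, P_half) free. When the curve shows no
    rollover inside the scanned power range the fit is flagged
    ``unbounded_warning`` and P_half is effectively a lower bound.
    """
    P, A = curve.P_mW, curve.A
    I0 = float(A[0] / np.sqrt(P[0]))
    # P_half guess: power where A/sqrt(P) has dropped to half its low-power value
    ratio = A / np.sqrt(P)
    below = np.nonzero(ratio < 0.5 * ratio[0])[0]
    P0 = float(P[below[0]]) if len(below) else float(P[-1])

    if fix_eps is not None:
        def model(P, I, P_half):
            return saturation_amplitude(P, I, P_half, fix_eps)
        p0, bounds = [I0, P0], ([0, 1e-6], [np.inf, np.inf])
    else:
        def model(P, I, P_half, eps):
            return saturation_amplitude(P, I, P_half, eps)
        p0, bounds = [I0, P0, 1.2], ([0, 1e-6, 0.5], [np.inf, np.inf, 1.5])

    popt, pcov = optimize.curve_fit(model, P, A, p0=p0, bounds=bounds, maxfev=20000)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    if fix_eps is not None:
        I, P_half, eps = popt[0], popt[1], fix_eps
        I_se, P_se, e_se = se[0], se[1], 0.0
    else:
        I, P_half, eps = popt
        I_se, P_se, e_se = se
    rss = float(np.sum((A - saturation_amplitude(P, I, P_half, eps)) ** 2))
    return SaturationFit(
        P_half=float(P_half), eps=float(np.clip(eps, 0.5, 1.5)), I=float(I),
        P_half_se=float(P_se), eps_se=float(e_se), I_se=float(I_se), rss=rss,
        unbounded_warning=bool(P_half > 2 * P[-1]),
    )


def depth_parameter(P_half_O2: float, P_half_NiEDDA: float, P_half_N2: float,
                    se_O2: float = 0.0, se_NiEDDA: float = 0.0, se_N2: float = 0.0,
                    ) -> tuple[float, float]:
    """Depth parameter Phi = ln(dP_half_O2 / dP_half_NiEDDA) and its error.

    Both accessibility shifts are referenced to the nitrogen-purged
    (relaxant-free) P_half. The error is first-order propagation from the
    three P_half standard errors.
    """
    if min(P_half_O2, P_half_NiEDDA, P_half_N2) <= 0:
        raise ValueError("P_half values must be positive")
    dO2 = P_half_O2 - P_half_N2
    dNi = P_half_NiEDDA - P_half_N2
    if dO2 <= 0 or dNi <= 0:
        raise InvalidAccessibilityError(
            "non-positive accessibility shift; label not resolvable")
    phi = float(np.log(dO2 / dNi))
    # d(phi)/dP_O2 = 1/dO2 ; d/dP_Ni = -1/dNi ; d/dP_N2 = 1/dNi - 1/dO2
    var = (se_O2 / dO2) ** 2 + (se_NiEDDA / dNi) ** 2 + ((1.0 / dNi - 1.0 / dO2) * se_N2) ** 2
    return phi, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# calibration

def _tanh_model(x, A, B, C, D):
    return A * np.tanh(B * (x - C)) + D


@dataclass
class CalibrationCurve:
    """Monotone mapping between immersion depth x (A) and depth parameter Phi.

    Fitted form Phi(x) = A tanh(B (x - C)) + D with A, B > 0 so the curve is
    strictly increasing and invertible. ``spline`` holds a monotone
    piecewise-cubic fallback when the tanh form misfits the supplied pairs.
    """

    A: float
    B: float
    C: float
    D: float
    x_min: float
    x_max: float
    residuals_phi: np.ndarray = field(default_factory=lambda: np.empty(0))
    spline: object | None = None
    spline_inv: object | None = None

    def phi_at(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = (self.spline(x) if self.spline is not None
               else _tanh_model(x, self.A, self.B, self.C, self.D))
        return float(out) if out.ndim == 0 else out

    #: fraction of the tanh asymptote range treated as invertible
    _SATURATION = 0.9999

    @property
    def phi_min(self) -> float:
        """Lower end of the invertible Phi range.

        For the tanh form this is near the lower asymptote D - A (the curve
        extrapolates beyond the training data); the spline fallback is only
        defined on the data range.
        """
        if self.spline is not None:
            return float(self.phi_at(self.x_min))
        return float(self.D - self._SATURATION * self.A)

    @property
    def phi_max(self) -> float:
        if self.spline is not None:
            return float(self.phi_at(self.x_max))
        return float(self.D + self._SATURATION * self.A)

    def slope_at(self, x: float) -> float:
        if self.spline is not None:
            return float(self.spline.derivative()(x))
        u = self.B * (x - self.C)
        return float(self.A * self.B / np.cosh(u) ** 2)


def fit_calibration(pairs, spline_threshold_phi: float = 0.15) -> CalibrationCurve:
    """Fit the empirical depth calibration from (phi, distance) reference pairs.

    Parameters
    ----------
    pairs : iterable of (phi, x)
        Depth parameters with known label distances (A, signed) spanning
        both sides of the phosphate plane; at least 6 pairs required.
    spline_threshold_phi : float
        If the tanh fit leaves any |residual| above this, fall back to a
        monotone piecewise-cubic (PCHIP) interpolant through the
        x-sorted pairs.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 6:
        raise CalibrationError("need at least 6 (phi, x) pairs")
    phi, x = arr[:, 0], arr[:, 1]
    if x.min() >= 0 or x.max() <= 0:
        raise CalibrationError("pairs must span both sides of the phosphate plane")
    order = np.argsort(x)
    xs, ps = x[order], phi[order]
    # aggregate duplicate x so interpolants stay well-defined
    xu, idx = np.unique(xs, return_index=True)
    pu = np.array([ps[xs == v].mean() for v in xu])
    if np.any(np.diff(pu) < -0.5):
        raise CalibrationError("pairs are non-monotone beyond noise tolerance")

    p0 = [max((phi.max() - phi.min()) / 2, 0.1), 0.2, float(np.median(x)), float(phi.mean())]
    curve = None
    try:
        popt, _ = optimize.curve_fit(
            _tanh_model, x, phi, p0=p0,
            bounds=([1e-6, 1e-6, -np.inf, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=50000)
        resid = phi - _tanh_model(x, *popt)
        if np.max(np.abs(resid)) <= spline_threshold_phi:
            curve = CalibrationCurve(*map(float, popt), x_min=float(x.min()),
                                     x_max=float(x.max()), residuals_phi=resid)
    except RuntimeError:
        pass
    if curve is None:
        # monotone fallback through the aggregated pairs
        if np.any(np.diff(pu) <= 0):
            raise CalibrationError("non-monotone pairs; cannot build fallback interpolant")
        sp = interpolate.PchipInterpolator(xu, pu)
        sp_inv = interpolate.PchipInterpolator(pu, xu)
        curve = CalibrationCurve(np.nan, np.nan, np.nan, np.nan,
                                 x_min=float(x.min()), x_max=float(x.max()),
                                 residuals_phi=phi - sp(x), spline=sp, spline_inv=sp_inv)
    return curve


def depth_from_phi(phi: float, curve: CalibrationCurve,
                   phi_err: float = 0.0) -> tuple[float, float, bool]:
    """Invert the calibration: distance x (A) from a measured Phi.

    Returns (x, x_err, clamped). Phi outside the curve's invertible range is
    clamped to the nearest end (flagged). The error is phi_err divided by
    the local slope dPhi/dx.
    """
    lo, hi = curve.phi_min, curve.phi_max
    clamped = False
    p = float(phi)
    if p <= lo or p >= hi:
        p = float(np.clip(p, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo)))
        clamped = True
    if curve.spline_inv is not None:
        x = float(curve.spline_inv(p))
    else:
        u = (p - curve.D) / curve.A
        u = float(np.clip(u, -1 + 1e-15, 1 - 1e-15))
        x = float(curve.C + np.arctanh(u) / curve.B)
    slope = curve.slope_at(x)
    x_err = float(phi_err / slope) if slope > 0 else np.inf
    return x, x_err, clamped


def reference_depth_table() -> pd.DataFrame:
    """Published reference (site, composition, Phi, distance) table for
    spin-labeled C2-domain sites bound to PtdSer/PtdIns(4,5)P2 membranes.

    Used both as the default calibration dataset and as docking restraint
    input.
    """
    with resources.files("membind.data").joinpath("depth_reference.csv").open() as fh:
        return pd.read_csv(fh)


def reference_calibration() -> CalibrationCurve:
    """Calibration curve fitted to the packaged reference depth table."""
    tab = reference_depth_table()
    return fit_calibration(list(zip(tab["phi"], tab["distance_A"])))
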