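"""Equilibrium membrane partitioning from vesicle sedimentation assays.

The fraction of protein co-sedimenting with sucrose-loaded vesicles follows
a simple partition equilibrium in accessible lipid concentration [L]:

    f_b = K [L] / (1 + K [L])

K is a reciprocal molar partition coefficient (1/M); its reciprocal is the
accessible lipid concentration at which half the protein is membrane-bound.
Ratios of K between conditions translate into binding free-energy
differences, ddG = RT ln(K_a/K_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .composition import LipidComposition
from .constants import AREA_PER_LIPID_NM2, N_AVOGADRO, R_KJ, ROOM_TEMPERATURE_K
from .errors import DegenerateDataError


@dataclass
class PartitionDataset:
    """Accessible lipid concentrations (M) and measured fractions bound."""

    L: np.ndarray
    f_b: np.ndarray
    condition: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.L = np.asarray(self.L, dtype=float)
        self.f_b = np.asarray(self.f_b, dtype=float)
        if self.L.shape != self.f_b.shape:
            raise ValueError("L and f_b must have equal length")
        if np.any(self.L < 0):
            raise ValueError("lipid concentrations must be non-negative")
        if np.any((self.f_b < 0) | (self.f_b > 1)):
            raise ValueError("fractions bound must lie in [0, 1]")


@dataclass
class PartitionFit:
    """Fitted reciprocal molar partition coefficient (1/M)."""

    K: float
    K_se: float
    rss: float

    def __post_init__(self):
        if self.K <= 0:
            raise ValueError("K must be positive")

    @property
    def half_binding_L(self) -> float:
        """Accessible lipid concentration (M) at 50% binding: 1/K."""
        return 1.0 / self.K


def fraction_bound(K: float, L) -> np.ndarray | float:
    """Partition isotherm f_b = K L / (1 + K L)."""
    if K <= 0:
        raise ValueError("K must be positive")
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("L must be non-negative")
    out = K * L / (1.0 + K * L)
    return float(out) if out.ndim == 0 else out


def accessible_lipid(total_lipid_M: float, composition: LipidComposition) -> float:
    """Lipid concentration available to protein: total times the outer-leaflet fraction."""
    if total_lipid_M < 0:
        raise ValueError("total lipid must be non-negative")
    return total_lipid_M * composition.accessible_fraction


def fraction_bound_from_depletion(protein_sup_M, protein_total_M) -> np.ndarray:
    """f_b from supernatant depletion: 1 - [P]_supernatant / [P]_total."""
    sup = np.asarray(protein_sup_M, dtype=float)
    tot = np.asarray(protein_total_M, dtype=float)
    if np.any(tot <= 0):
        raise ValueError("total protein must be positive")
    return np.clip(1.0 - sup / tot, 0.0, 1.0)


def fit_partition(data: PartitionDataset) -> PartitionFit:
    """Nonlinear least-squares estimate of K from (L, f_b) points.

    Requires at least 4 points and refuses datasets that are saturated or
    empty everywhere (no information about K).
    """
    L, fb = data.L, data.f_b
    if len(L) < 4:
        raise DegenerateDataError("need at least 4 points to fit K")
    if np.all(fb < 0.02) or np.all(fb > 0.98):
        raise DegenerateDataError("fractions bound are uninformative (all ~0 or all ~1)")

    # initial K from the point nearest half-saturation
    i = int(np.argmin(np.abs(fb - 0.5)))
    K0 = 1.0 / L[i] if L[i] > 0 else 1.0 / np.mean(L[L > 0])

    def model(L, logK):
        return fraction_bound(np.exp(logK), L)

    popt, pcov = optimize.curve_fit(model, L, fb, p0=[np.log(K0)], maxfev=10000)
    K = float(np.exp(popt[0]))
    K_se = float(np.sqrt(pcov[0, 0]) * K)  # delta method from log scale
    rss = float(np.sum((fb - fraction_bound(K, L)) ** 2))
    return PartitionFit(K=K, K_se=K_se, rss=rss)


def delta_delta_G(K_a: float, K_b: float, T: float = ROOM_TEMPERATURE_K) -> float:
    """Binding free-energy difference RT ln(K_a/K_b) in kJ/mol.

    Positive when condition ``a`` binds tighter than ``b``. Antisymmetric
    under swapping the arguments.
    """
    if K_a <= 0 or K_b <= 0 or T <= 0:
        raise ValueError("partition coefficients and temperature must be positive")
    return float(R_KJ * T * np.log(K_a / K_b))


def effective_local_concentration(tether_range_nm: float = 4.0,
                                  area_per_lipid_nm2: float = AREA_PER_LIPID_NM2) -> float:
    """Accessible-lipid concentration (M) felt by a membrane-tethered domain.

    Order-of-magnitude slab model: a domain confined within ``tether_range_nm``
    of the bilayer sees the outer-leaflet lipids (surface density
    1/area_per_lipid) spread through the slab volume. The molar
    concentration is

        c = 1 / (N_A * t * a)

    with t the slab thickness and a the area per lipid (SI units inside).
    Doubling the tether range halves the result.
    """
    if tether_range_nm <= 0 or area_per_lipid_nm2 <= 0:
        raise ValueError("geometry parameters must be positive")
    t_m = tether_range_nm * 1e-9
    a_m2 = area_per_lipid_nm2 * 1e-18
    per_m3 = 1.0 / (t_m * a_m2)     # lipids per cubic metre in the slab
    molar = per_m3 / N_AVOGADRO / 1000.0  # mol per litre
    return float(molar)
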