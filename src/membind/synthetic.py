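"""Synthetic-data generators for every stage of the pipeline.

Each generator is the exact inverse of its analysis model: at zero noise a
refit recovers the generating parameters to machine precision, which is the
backbone of the package's round-trip tests. Noise is additive Gaussian on
the measured quantity (fluorescence, heat, amplitude, fraction bound, ppm);
identical parameters and seed always reproduce identical data.
"""

from __future__ import annotations

import numpy as np

from .composition import LipidComposition, NoiseModel
from .epr import CONDITIONS, SaturationCurve, saturation_amplitude
from .errors import InvalidProtocolError
from .itc import InjectionHeats, TitrationProtocol, predict_heats
from .kinetics import KineticTrace, TraceMeta
from .partitioning import PartitionDataset, fraction_bound
from .structure import StructureModel


# ---------------------------------------------------------------------------
# stopped-flow

def simulate_stopped_flow(k_on: float, k_off: float, vesicle_concs_M,
                          F0: float = 1.0, amplitude: float = 1.0,
                          duration_s: float | None = None, n_points: int = 400,
                          noise: NoiseModel | None = None) -> list[KineticTrace]:
    """Monoexponential association traces at a series of vesicle concentrations.

    Each trace follows F(t) = F0 + A exp(-(k_on [v] + k_off) t); the trace
    duration defaults to 5 relaxation times of the slowest trace so every
    curve decays essentially to baseline. Ground-truth rates are recorded
    in the trace metadata.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rate constants must be positive")
    vesicle_concs_M = np.asarray(vesicle_concs_M, dtype=float)
    if np.any(vesicle_concs_M <= 0):
        raise ValueError("vesicle concentrations must be positive")
    if n_points < 4:
        raise InvalidProtocolError("need at least 4 points per trace")
    if duration_s is not None and duration_s <= 0:
        raise InvalidProtocolError("duration must be positive")
    noise = noise or NoiseModel()
    noise.reset()
    traces = []
    for v in vesicle_concs_M:
        k_obs = k_on * v + k_off
        dur = duration_s if duration_s is not None else 5.0 / k_obs
        t = np.linspace(0.0, dur, n_points)
        F = F0 + amplitude * np.exp(-k_obs * t)
        traces.append(KineticTrace(
            t=t, F=noise.perturb(F),
            meta=TraceMeta(lipid_M=np.nan, ground_truth={
                "k_on": k_on, "k_off": k_off, "k_obs": k_obs, "vesicle_M": float(v),
                "F0": F0, "amplitude": amplitude, "sigma": noise.sigma})))
    return traces


# ---------------------------------------------------------------------------
# ITC

def simulate_itc(n: float, K_d: float, dH: float, protocol: TitrationProtocol,
                 noise: NoiseModel | None = None) -> InjectionHeats:
    """Single-site titration heats with per-injection dilution bookkeeping."""
    if K_d <= 0:
        raise ValueError("K_d must be positive")
    noise = noise or NoiseModel()
    noise.reset()
    exact = predict_heats(n, K_d, dH, protocol)
    return InjectionHeats(q_kJ=noise.perturb(exact.q_kJ),
                          molar_ratio=exact.molar_ratio, protocol=protocol,
                          ground_truth={"n": n, "K_d": K_d, "dH": dH,
                                        "sigma": noise.sigma})


# ---------------------------------------------------------------------------
# sedimentation

def simulate_sedimentation(K: float, lipid_concs_M, noise: NoiseModel | None = None,
                           condition: dict | None = None) -> PartitionDataset:
    """Fraction-bound points from the partition isotherm; noise clipped to [0, 1]."""
    if K <= 0:
        raise ValueError("K must be positive")
    L = np.asarray(lipid_concs_M, dtype=float)
    noise = noise or NoiseModel()
    noise.reset()
    fb = np.clip(noise.perturb(fraction_bound(K, L)), 0.0, 1.0)
    return PartitionDataset(L=L, f_b=fb, condition=condition or {},
                            ground_truth={"K": K, "sigma": noise.sigma})


# ---------------------------------------------------------------------------
# EPR power saturation

def simulate_power_saturation(P_half_mW: dict[str, float], eps: float = 1.2,
                              scale: float = 1.0, powers_mW=None,
                              noise: NoiseModel | None = None) -> dict[str, SaturationCurve]:
    """Saturation curves per relaxant condition (N2, O2, NiEDDA).

    The default power ladder is 12 log-spaced steps from 0.6 to 36 mW,
    matching a typical X-band progressive-saturation protocol.
    """
    if powers_mW is None:
        powers_mW = np.geomspace(0.6, 36.0, 12)
    powers_mW = np.asarray(powers_mW, dtype=float)
    noise = noise or NoiseModel()
    noise.reset()
    out = {}
    for cond in CONDITIONS:
        if cond not in P_half_mW:
            continue
        A = saturation_amplitude(powers_mW, scale, P_half_mW[cond], eps)
        out[cond] = SaturationCurve(P_mW=powers_mW, A=noise.perturb(A), condition=cond)
    return out


# ---------------------------------------------------------------------------
# HSQC peak lists

def simulate_hsqc_shifts(base_peaks: dict[int, tuple[float, float]],
                         perturbed_residues: dict[int, tuple[float, float]],
                         noise: NoiseModel | None = None,
                         ) -> tuple[dict, dict]:
    """Reference and titrated peak lists with planted per-residue shifts.

    ``perturbed_residues`` maps residue -> (ddH, ddN) in ppm. Noise is
    applied to both dimensions of the titrated list only, so the zero-noise
    reference list is reproduced exactly.
    """
    noise = noise or NoiseModel()
    noise.reset()
    reference = {r: (float(h), float(n)) for r, (h, n) in base_peaks.items()}
    titrated = {}
    for r, (h, n) in reference.items():
        dh, dn = perturbed_residues.get(r, (0.0, 0.0))
        hh, nn = noise.perturb(np.array([h + dh, n + dn]))
        titrated[r] = (float(hh), float(nn))
    return reference, titrated


# ---------------------------------------------------------------------------
# toy structure

def make_toy_domain(n_residues: int = 20, geometry_seed: int = 0,
                    radius: float = 10.0) -> StructureModel:
    """Compact fold-like rigid point set with Ca and Cb per residue.

    Ca atoms are placed on a deterministic spherical spiral of the given
    radius with small seeded jitter; each Cb sits 1.53 A radially outward
    from its Ca so label vectors point away from the core, as side chains
    do on a globular domain. Identical seed and parameters reproduce the
    same coordinates bitwise.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(geometry_seed)
    atoms = []
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for i in range(n_residues):
        zfrac = 1.0 - 2.0 * (i + 0.5) / n_residues
        r_xy = np.sqrt(max(0.0, 1.0 - zfrac ** 2))
        ang = golden * i
        unit = np.array([r_xy * np.cos(ang), r_xy * np.sin(ang), zfrac])
        ca = radius * unit + rng.normal(0.0, 0.3, 3)
        u = ca / np.linalg.norm(ca)
        cb = ca + 1.53 * u
        atoms.append((i + 1, "CA", ca))
        atoms.append((i + 1, "CB", cb))
    return StructureModel.from_atoms(atoms)
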