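"""Rigid-body docking of a domain against a membrane plane from depth restraints.

The membrane is the fixed plane z = 0 with +z pointing into the hydrocarbon
interior (same sign convention as the EPR depth analysis). EPR-derived
immersion depths of spin-labeled sites become point-to-plane restraints:
the pseudo-label point of each restrained residue should sit at its target
signed z within a flat-bottom window equal to the experimental depth
uncertainty.

Only three pose degrees of freedom are observable - tilt theta, azimuth psi
of the body frame, and the vertical offset z - because rotation about the
membrane normal and in-plane translation leave every depth unchanged. The
optimiser therefore scans a coarse (theta, psi, z) grid and polishes the
best nodes with a local minimiser, reporting all poses whose objective ties
the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import MissingAtomError
from .structure import StructureModel

#: default nitroxide label reach beyond the Cb atom, angstroms
DEFAULT_LABEL_OFFSET = 7.0


@dataclass(frozen=True)
class PlaneRestraint:
    """Target signed distance (A) of a site's label point to the phosphate plane."""

    site: int
    target_x: float
    range: float

    def __post_init__(self):
        if self.range <= 0:
            raise ValueError("restraint range must be positive")


@dataclass
class DockingResult:
    """Optimal rigid pose and its restraint residuals.

    The pose maps body coordinates x to membrane-frame coordinates
    R x + (0, 0, z_offset). ``residuals`` are signed label-depth errors
    (achieved minus target) per restraint; ``degenerate_poses`` lists
    (theta, psi, z, objective) tuples that tie the optimum within
    tolerance, sorted by tilt.
    """

    rotation: np.ndarray
    z_offset: float
    tilt_deg: float
    azimuth_deg: float
    residuals: np.ndarray
    objective: float
    degenerate_poses: list = field(default_factory=list)
    converged: bool = True

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper orthonormal")
        self.rotation = R


def label_site_position(structure: StructureModel, residue: int,
                        offset_len: float = DEFAULT_LABEL_OFFSET) -> np.ndarray:
    """Pseudo-nitroxide position: Cb extended along the Ca->Cb direction.

    A fixed-length surrogate for the spin-label side chain; offset_len = 0
    returns Cb itself. Glycine (no Cb) raises MissingAtomError.
    """
    ca = structure.atom(residue, "CA")
    if not structure.has_atom(residue, "CB"):
        raise MissingAtomError(
            f"residue {residue} has no CB (glycine?); supply mutated coordinates")
    cb = structure.atom(residue, "CB")
    direction = cb - ca
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError(f"degenerate Ca/Cb geometry at residue {residue}")
    return cb + offset_len * direction / norm


def rotation_from_angles(theta_deg: float, psi_deg: float) -> np.ndarray:
    """Body rotation R = Ry(theta) Rz(psi): azimuthal spin then tilt."""
    th, ps = np.deg2rad(theta_deg), np.deg2rad(psi_deg)
    Rz = np.array([[np.cos(ps), -np.sin(ps), 0], [np.sin(ps), np.cos(ps), 0], [0, 0, 1]])
    Ry = np.array([[np.cos(th), 0, np.sin(th)], [0, 1, 0], [-np.sin(th), 0, np.cos(th)]])
    return Ry @ Rz


def _label_z(points: np.ndarray, theta_deg, psi_deg):
    """z-coordinates of body points under R(theta, psi); broadcasts over angles.

    Row 3 of Ry(th) Rz(ps) is (-sin th cos ps, sin th sin ps, cos th).
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    ps = np.deg2rad(np.asarray(psi_deg, dtype=float))
    st, ct = np.sin(th), np.cos(th)
    cp, sp = np.cos(ps), np.sin(ps)
    # shapes: angles (...,), points (m, 3) -> (..., m)
    return (-(st * cp)[..., None] * points[:, 0]
            + (st * sp)[..., None] * points[:, 1]
            + ct[..., None] * points[:, 2])


def flat_bottom_penalty(residual: np.ndarray, half_width: np.ndarray) -> np.ndarray:
    """Zero inside +/- half_width, quadratic in the excess outside."""
    excess = np.abs(residual) - half_width
    return np.where(excess > 0, excess ** 2, 0.0)


def dock_to_plane(structure: StructureModel, restraints: list[PlaneRestraint],
                  label_offset: float = DEFAULT_LABEL_OFFSET,
                  grid_deg: float = 5.0, grid_z: float = 0.5,
                  degeneracy_tol: float = 1e-3) -> DockingResult:
    """Dock a rigid domain to the membrane plane by restraint satisfaction.

    Minimises the summed flat-bottom penalty of all label depths over
    (tilt, azimuth, z-offset). A single restraint degenerates to a
    translation-only problem (solved with the orientation left at
    identity). The returned objective never exceeds the best coarse-grid
    node; refinement failures fall back to that node with
    ``converged=False``.
    """
    if not restraints:
        raise ValueError("need at least one restraint")
    pts = np.array([label_site_position(structure, r.site, label_offset) for r in restraints])
    pts = pts - structure.coords.mean(axis=0)  # body frame centred on the domain
    targets = np.array([r.target_x for r in restraints])
    widths = np.array([r.range for r in restraints])

    if len(restraints) == 1:
        z = float(targets[0] - pts[0, 2])
        return DockingResult(rotation=np.eye(3), z_offset=z, tilt_deg=0.0,
                             azimuth_deg=0.0, residuals=np.zeros(1), objective=0.0,
                             degenerate_poses=[(0.0, 0.0, z, 0.0)])

    thetas = np.arange(0.0, 180.0 + 1e-9, grid_deg)
    psis = np.arange(0.0, 360.0, grid_deg)
    TH, PS = np.meshgrid(thetas, psis, indexing="ij")
    z_lab = _label_z(pts, TH, PS)                      # (nth, nps, m)
    span = np.abs(pts).sum() + np.abs(targets).max() + 5.0
    zs = np.arange(-span, span + 1e-9, grid_z)
    # residual: z_lab + z0 - target  -> objective over (nth, nps, nz)
    resid = z_lab[..., None, :] + zs[None, None, :, None] - targets
    obj = flat_bottom_penalty(resid, widths).sum(axis=-1)
    grid_best = float(obj.min())

    def objective(x):
        th, ps, z0 = x
        r = _label_z(pts, th, ps) + z0 - targets
        return float(flat_bottom_penalty(r, widths).sum())

    # refine the best grid nodes (all nodes tied near the minimum, capped)
    flat = np.argsort(obj, axis=None)
    cand_idx = flat[: min(40, obj.size)]
    cand_idx = [i for i in cand_idx if obj.flat[i] <= grid_best + max(10 * degeneracy_tol, 0.5)]
    poses = []
    for i in cand_idx:
        it, ip, iz = np.unravel_index(i, obj.shape)
        x0 = np.array([thetas[it], psis[ip], zs[iz]])
        sol = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
        x = sol.x if sol.fun <= objective(x0) else x0
        poses.append((float(x[0]) % 360.0, float(x[1]) % 360.0, float(x[2]), objective(x)))

    best = min(poses, key=lambda p: p[3])
    converged = best[3] <= grid_best + 1e-12
    if not converged:  # pragma: no cover - refinement can only improve
        best = min(poses + [(0.0, 0.0, 0.0, grid_best)], key=lambda p: p[3])
    degenerate = sorted({(round(p[0], 4), round(p[1], 4), round(p[2], 4), p[3])
                         for p in poses if p[3] <= best[3] + degeneracy_tol},
                        key=lambda p: p[0])

    th, ps, z0, fval = best
    R = rotation_from_angles(th, ps)
    resid_best = _label_z(pts, th, ps) + z0 - targets
    # tilt of the body z-axis against the membrane normal
    tilt = float(np.degrees(np.arccos(np.clip(R[2, 2], -1.0, 1.0))))
    return DockingResult(rotation=R, z_offset=z0, tilt_deg=tilt, azimuth_deg=ps,
                         residuals=np.asarray(resid_best, dtype=float).ravel(),
                         objective=fval, degenerate_poses=list(degenerate),
                         converged=converged)


def report_depths(structure: StructureModel, result: DockingResult) -> dict[int, float]:
    """Signed z (A) of every Ca under the docked pose, keyed by residue."""
    centre = structure.coords.mean(axis=0)
    out = {}
    for res in structure.residues:
        if structure.has_atom(res, "CA"):
            p = structure.atom(res, "CA") - centre
            out[res] = float((result.rotation @ p)[2] + result.z_offset)
    return out


def apply_pose(structure: StructureModel, result: DockingResult) -> StructureModel:
    """Return the structure transformed into the membrane frame of the pose."""
    centre = structure.coords.mean(axis=0)
    shifted = StructureModel(coords=structure.coords - centre, index=dict(structure.index),
                             residue_names=dict(structure.residue_names), chain=structure.chain)
    return shifted.transformed(result.rotation, np.array([0.0, 0.0, result.z_offset]))
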