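"""Rigid-body membrane docking from depth restraints."""

import numpy as np
import pytest

from membind import (PlaneRestraint, StructureModel, dock_to_plane,
                     label_site_position, make_toy_domain, report_depths)
from membind.docking import (_label_z, apply_pose, flat_bottom_penalty,
                             rotation_from_angles)
from membind.errors import MissingAtomError


def planted_restraints(domain, sites, theta, psi, z0, width=0.1, offset=7.0):
    centre = domain.coords.mean(axis=0)
    R = rotation_from_angles(theta, psi)
    out = []
    for s in sites:
        p = label_site_position(domain, s, offset) - centre
        out.append(PlaneRestraint(site=s, target_x=float((R @ p)[2] + z0), range=width))
    return out


# ---------------------------------------------------------------------------
# label placement

def test_label_geometry():
    dom = make_toy_domain(10, geometry_seed=0)
    ca, cb = dom.atom(4, "CA"), dom.atom(4, "CB")
    p0 = label_site_position(dom, 4, offset_len=0.0)
    assert np.allclose(p0, cb)
    p = label_site_position(dom, 4, offset_len=7.0)
    assert np.linalg.norm(p - cb) == pytest.approx(7.0, abs=1e-12)
    # collinearity of Ca, Cb, label point
    cross = np.cross(cb - ca, p - cb)
    assert np.linalg.norm(cross) < 1e-9


def test_label_requires_cb():
    dom = StructureModel.from_atoms([(1, "CA", (0, 0, 0)), (2, "CA", (3, 0, 0)),
                                     (2, "CB", (4, 0, 0))])
    with pytest.raises(MissingAtomError):
        label_site_position(dom, 1)


# ---------------------------------------------------------------------------
# docking

def test_single_restraint_translation_only():
    dom = StructureModel.from_atoms([(1, "CA", (0, 0, 0)), (1, "CB", (1.5, 0, 0))])
    res = dock_to_plane(dom, [PlaneRestraint(site=1, target_x=4.0, range=0.5)])
    assert res.objective == 0.0
    assert np.allclose(res.rotation, np.eye(3))
    assert res.residuals == pytest.approx(0.0)


@pytest.mark.parametrize("theta,psi,z0", [(35.0, 120.0, -3.0), (150.0, 40.0, -8.0),
                                          (75.0, 300.0, 6.0)])
def test_planted_pose_recovery(theta, psi, z0):
    """Noiseless restraints from a known pose are recovered within 2 degrees
    of tilt and 0.2 A of offset, with zero objective."""
    dom = make_toy_domain(20, geometry_seed=3)
    restraints = planted_restraints(dom, [2, 7, 11, 16], theta, psi, z0)
    result = dock_to_plane(dom, restraints)
    assert result.objective == pytest.approx(0.0, abs=1e-12)
    true_tilt = theta if theta <= 180 else 360 - theta
    assert abs(result.tilt_deg - true_tilt) < 2.0
    assert abs(result.z_offset - z0) < 0.2
    assert np.all(np.abs(result.residuals) <= 0.1 + 1e-9)


def test_objective_dominates_coarse_grid():
    """The returned pose never scores worse than any node of the coarse grid."""
    dom = make_toy_domain(16, geometry_seed=5)
    restraints = planted_restraints(dom, [3, 8, 13], 60.0, 200.0, 2.0, width=0.3)
    result = dock_to_plane(dom, restraints)
    centre = dom.coords.mean(axis=0)
    pts = np.array([label_site_position(dom, r.site) for r in restraints]) - centre
    targets = np.array([r.target_x for r in restraints])
    widths = np.array([r.range for r in restraints])
    best = np.inf
    for th in np.arange(0.0, 181.0, 5.0):
        for ps in np.arange(0.0, 360.0, 5.0):
            z_lab = _label_z(pts, th, ps)
            for z in np.arange(-20.0, 20.0, 0.5):
                best = min(best, flat_bottom_penalty(z_lab + z - targets, widths).sum())
    assert result.objective <= best + 1e-12


def test_equivariance_to_prerotation():
    """Docking a pre-rotated copy recovers the same membrane-frame label depths."""
    dom = make_toy_domain(18, geometry_seed=7)
    restraints = planted_restraints(dom, [4, 9, 14], 40.0, 80.0, -2.0, width=0.05)
    res1 = dock_to_plane(dom, restraints)
    R_pre = rotation_from_angles(25.0, 140.0)
    centre = dom.coords.mean(axis=0)
    rotated = dom.transformed(R_pre, centre - R_pre @ centre)
    res2 = dock_to_plane(rotated, restraints)
    assert res2.objective == pytest.approx(0.0, abs=1e-12)
    # same physical pose: restrained label depths agree in the membrane frame
    for r, d1, d2 in zip(restraints, res1.residuals, res2.residuals):
        assert abs(d1 - d2) < 0.15


def test_report_depths_identity_and_flip():
    dom = make_toy_domain(8, geometry_seed=1)
    restraints = planted_restraints(dom, [2, 5], 0.0, 0.0, 0.0, width=0.05)
    res = dock_to_plane(dom, restraints)
    depths = report_depths(dom, res)
    centre = dom.coords.mean(axis=0)
    posed = apply_pose(dom, res)
    for r, z in depths.items():
        assert z == pytest.approx(posed.atom(r, "CA")[2], abs=1e-9)
    # a 180 degree flip about an in-plane axis negates all depths
    flipped = rotation_from_angles(180.0, 0.0)
    for r in dom.residues:
        p = dom.atom(r, "CA") - centre
        assert (flipped @ p)[2] == pytest.approx(-p[2], abs=1e-9)


def test_restrained_site_depths_match_geometry():
    """The label z under the docked pose equals target within the window, and
    the Ca depth differs from it by the projected label offset."""
    dom = make_toy_domain(20, geometry_seed=9)
    restraints = planted_restraints(dom, [2, 8, 15], 55.0, 10.0, 1.0, width=0.05)
    res = dock_to_plane(dom, restraints)
    centre = dom.coords.mean(axis=0)
    for r in restraints:
        lab = label_site_position(dom, r.site) - centre
        z_lab = (res.rotation @ lab)[2] + res.z_offset
        assert abs(z_lab - r.target_x) <= r.range + 1e-9
        ca = dom.atom(r.site, "CA") - centre
        z_ca = (res.rotation @ ca)[2] + res.z_offset
        proj = z_lab - z_ca   # projection of the Ca->label vector on the normal
        direct = (res.rotation @ (lab - ca))[2]
        assert proj == pytest.approx(direct, abs=1e-9)


def test_degenerate_poses_sorted_by_tilt():
    dom = make_toy_domain(12, geometry_seed=2)
    restraints = planted_restraints(dom, [3, 9], 20.0, 0.0, 0.0, width=2.0)
    res = dock_to_plane(dom, restraints)
    tilts = [p[0] for p in res.degenerate_poses]
    assert tilts == sorted(tilts)
    assert all(p[3] <= res.objective + 1e-3 for p in res.degenerate_poses)
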