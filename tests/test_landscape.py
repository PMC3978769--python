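"""Exponential-map coordinates, contact condition, balancing and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from encounterdock import Pose, make_toy_complex
from encounterdock.landscape import (BALL_RADIUS_DEFAULT, ExpCoord,
                                     LandscapeFrame, balance_coords,
                                     build_frame, contact_distance,
                                     expcoord_to_pose, filter_near_native,
                                     motion_fraction, pose_to_expcoord,
                                     rotation_exp, rotation_log, run_pca,
                                     sample_ball, select_low_energy,
                                     sigma_to_sphere, sphere_to_sigma,
                                     subsample_uniform)
from encounterdock.structures import Structure

from conftest import random_rotation


@pytest.fixture(scope="module")
def frame():
    return build_frame(make_toy_complex(seed=7))


# ---------------------------------------------------------------------------
# Frame construction
# ---------------------------------------------------------------------------

def test_frame_axes_orthonormal_and_z_toward_interface(toy, frame):
    A = frame.axes
    assert np.allclose(A.T @ A, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(A), 1.0)
    z_expect = toy.ligand_interface_center - toy.receptor_center
    z_expect /= np.linalg.norm(z_expect)
    assert np.allclose(A[:, 2], z_expect, atol=1e-12)


def test_native_pose_maps_to_origin(frame):
    c = pose_to_expcoord(Pose.identity(), frame)
    assert np.allclose(c.as_vector(), 0.0, atol=1e-12)
    assert np.isclose(c.r, frame.native_r)


def test_degenerate_frame_errors(toy):
    import dataclasses
    broken = dataclasses.replace(
        toy, ligand_interface_center=toy.receptor_center.copy())
    with pytest.raises(ValueError):
        build_frame(broken)


# ---------------------------------------------------------------------------
# Sphere tangent map
# ---------------------------------------------------------------------------

def test_sigma_map_special_points():
    assert sphere_to_sigma(1.23, 0.0) == (0.0, 0.0)
    s1, s2 = sphere_to_sigma(0.0, 0.5)
    assert np.isclose(s1, 0.0) and np.isclose(s2, 0.5)
    assert sigma_to_sphere(0.0, 0.0) == (0.0, 0.0)
    with pytest.raises(ValueError):
        sphere_to_sigma(0.0, np.pi)


@settings(max_examples=200, derandomize=True)
@given(theta=st.floats(0.0, 2 * np.pi, exclude_max=True),
       phi=st.floats(1e-6, np.pi, exclude_max=True))
def test_sigma_round_trip(theta, phi):
    s1, s2 = sphere_to_sigma(theta, phi)
    theta2, phi2 = sigma_to_sphere(s1, s2)
    assert np.isclose(phi2, phi, atol=1e-12)
    dtheta = (theta2 - theta + np.pi) % (2 * np.pi) - np.pi
    assert abs(dtheta) < 1e-9


# ---------------------------------------------------------------------------
# Rotation exponential map
# ---------------------------------------------------------------------------

def test_rotation_exp_log_special_cases():
    assert np.allclose(rotation_exp([0.0, 0.0, 0.0]), np.eye(3))
    assert np.allclose(rotation_log(np.eye(3)), 0.0)
    R = rotation_exp([0.0, 0.0, 0.3])
    assert np.allclose(R, Rotation.from_euler("z", 0.3).as_matrix(), atol=1e-12)
    assert np.allclose(rotation_log(R), [0.0, 0.0, 0.3], atol=1e-12)
    with pytest.raises(ValueError):
        rotation_log(Rotation.from_euler("x", np.pi).as_matrix())


def test_rotation_round_trip_against_independent_oracle(rng):
    worst = 0.0
    for _ in range(1000):
        w = rng.standard_normal(3)
        w *= rng.uniform(0, 3.0) / np.linalg.norm(w)
        R = rotation_exp(w)
        # independent oracle
        assert np.allclose(R, Rotation.from_rotvec(w).as_matrix(), atol=1e-12)
        worst = max(worst, np.abs(rotation_log(R) - w).max())
    assert worst < 1e-10


# ---------------------------------------------------------------------------
# Pose <-> coordinates
# ---------------------------------------------------------------------------

def test_pure_z_rotation_maps_to_omega3(toy, frame):
    alpha = np.deg2rad(10.0)
    R = frame.axes @ rotation_exp([0, 0, alpha]) @ frame.axes.T
    c_int = frame.ligand_interface_center
    pose = Pose(R, c_int - R @ c_int)  # rotate about the interface center
    c = pose_to_expcoord(pose, frame)
    assert np.allclose([c.sigma1, c.sigma2], 0.0, atol=1e-9)
    assert np.allclose([c.omega1, c.omega2], 0.0, atol=1e-9)
    assert np.isclose(abs(c.omega3), alpha, atol=1e-12)


def test_pose_coord_round_trip(frame, rng):
    worst = 0.0
    for _ in range(1000):
        v = sample_ball(1, radius=BALL_RADIUS_DEFAULT, seed=rng)[0]
        r = frame.native_r + rng.uniform(-1.0, 1.0)
        pose = expcoord_to_pose(ExpCoord.from_vector(v, r=r), frame)
        c2 = pose_to_expcoord(pose, frame)
        err = max(np.abs(c2.as_vector() - v).max(), abs(c2.r - r))
        worst = max(worst, err)
    assert worst < 1e-8


def test_frame_equivariance(toy, rng):
    """Rigidly moving the whole system leaves all coordinates unchanged."""
    import dataclasses
    frame = build_frame(toy)
    G = random_rotation(rng)
    shift = rng.normal(size=3) * 7
    moved = dataclasses.replace(
        toy,
        receptor=toy.receptor.transformed(G, shift),
        ligand=toy.ligand.transformed(G, shift),
        receptor_interface_center=G @ toy.receptor_interface_center + shift,
        ligand_interface_center=G @ toy.ligand_interface_center + shift,
        receptor_center=G @ toy.receptor_center + shift,
    )
    frame2 = build_frame(moved)
    for _ in range(20):
        v = sample_ball(1, seed=rng)[0]
        pose = expcoord_to_pose(ExpCoord.from_vector(v, r=frame.native_r), frame)
        # the same physical pose expressed in the moved system
        R2 = G @ pose.rotation @ G.T
        t2 = G @ pose.translation + shift - R2 @ shift
        c2 = pose_to_expcoord(Pose(R2, t2), frame2)
        assert np.allclose(c2.as_vector(), v, atol=1e-8)


# ---------------------------------------------------------------------------
# Contact distance
# ---------------------------------------------------------------------------

def _single_atom(chain, pos, radius=1.7):
    return Structure(
        chain=np.array([chain]), resid=np.array([1]), icode=np.array([""]),
        resname=np.array(["ALA"]), atname=np.array(["CA"]),
        element=np.array(["C"]), xyz=np.array([pos], float),
        radius=np.array([radius]),
    )


def test_contact_two_atoms_line_of_centers():
    a = _single_atom("A", [0.0, 0.0, 0.0])
    b = _single_atom("B", [0.0, 0.0, 5.0])
    fr = LandscapeFrame(np.zeros(3), np.eye(3), np.array([0.0, 0.0, 5.0]), 5.0)
    assert np.isclose(contact_distance([0, 0, 1.0], np.eye(3), a, b, fr,
                                       overlap_factor=1.0), 3.4)
    assert np.isclose(contact_distance([0, 0, 1.0], np.eye(3), a, b, fr,
                                       overlap_factor=0.9), 3.06)


def test_contact_matches_bisection_oracle(toy, rng):
    frame = build_frame(toy)
    d = frame.axes[:, 2] + 0.1 * rng.standard_normal(3)
    d /= np.linalg.norm(d)
    R = random_rotation(rng, 0.3)
    r = contact_distance(d, R, toy.receptor, toy.ligand, frame)

    def min_gap(rr):
        base = (toy.ligand.xyz[toy.ligand.heavy_mask]
                - frame.ligand_interface_center) @ R.T \
            + frame.origin + rr * d
        rec = toy.receptor.xyz[toy.receptor.heavy_mask]
        dist = np.linalg.norm(rec[:, None] - base[None, :], axis=2)
        s = 0.9 * (toy.receptor.radius[toy.receptor.heavy_mask][:, None]
                   + toy.ligand.radius[toy.ligand.heavy_mask][None, :])
        return (dist - s).min()

    lo, hi = 0.0, 60.0
    for _ in range(40):   # independent bracketing bisection
        mid = 0.5 * (lo + hi)
        if min_gap(mid) >= 0:
            hi = mid
        else:
            lo = mid
    assert np.isclose(r, hi, atol=0.01)
    assert abs(min_gap(r)) < 1e-6  # touching contact


def test_contact_native_direction_near_native_separation(toy):
    frame = build_frame(toy)
    r = contact_distance(frame.axes[:, 2], np.eye(3), toy.receptor,
                         toy.ligand, frame, overlap_factor=1.0)
    assert abs(r - frame.native_r) < 1.5


def test_contact_unreachable_errors():
    # receptor far off the approach ray: the ligand never touches it
    a = _single_atom("A", [100.0, 0.0, 0.0])
    b = _single_atom("B", [0.0, 0.0, 5.0])
    fr = LandscapeFrame(np.zeros(3), np.eye(3), np.array([0.0, 0.0, 5.0]), 5.0)
    with pytest.raises(ValueError):
        contact_distance([0.0, 0.0, 1.0], np.eye(3), a, b, fr)


# ---------------------------------------------------------------------------
# Ball sampling, filtering, balancing
# ---------------------------------------------------------------------------

def test_sample_ball_properties():
    pts = sample_ball(20000, seed=5)
    norms = np.linalg.norm(pts, axis=1)
    assert norms.max() <= BALL_RADIUS_DEFAULT + 1e-12
    # mean within 3 standard errors of zero per coordinate
    se = BALL_RADIUS_DEFAULT / np.sqrt(7.0) / np.sqrt(len(pts))
    assert np.all(np.abs(pts.mean(axis=0)) < 3 * se)
    assert np.array_equal(pts, sample_ball(20000, seed=5))
    with pytest.raises(ValueError):
        sample_ball(0)
    with pytest.raises(ValueError):
        sample_ball(5, radius=-1.0)


def test_filter_near_native(toy):
    near = Pose.identity()
    far = Pose(np.eye(3), np.array([50.0, 0.0, 0.0]))
    kept = filter_near_native([near, far], toy, irmsd_cutoff=10.0)
    assert kept == [near]
    assert near.irmsd == 0.0


def test_filter_matches_brute_force(toy, rng):
    from encounterdock import compute_irmsd
    poses = [Pose(random_rotation(rng, 0.8), rng.normal(size=3) * 6)
             for _ in range(30)]
    kept = filter_near_native(list(poses), toy, irmsd_cutoff=6.0)
    expect = [p for p in poses if compute_irmsd(p, toy) <= 6.0]
    assert kept == expect


def test_balance_coords(rng):
    stds = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    X = rng.standard_normal((4000, 5)) * stds
    balanced, scales = balance_coords(X)
    assert np.allclose(scales, X.std(axis=0, ddof=1))
    assert np.allclose(balanced.std(axis=0, ddof=1), 1.0, atol=1e-9)
    again, scales2 = balance_coords(balanced)
    assert np.allclose(scales2, 1.0, atol=1e-12)
    X[:, 3] = 7.0
    with pytest.raises(ValueError, match="omega2"):
        balance_coords(X)


# ---------------------------------------------------------------------------
# PCA and selection
# ---------------------------------------------------------------------------

def test_pca_planar_data_has_zero_minor_eigenvalues(rng):
    basis = np.linalg.qr(rng.standard_normal((5, 5)))[0][:, :2]
    X = rng.standard_normal((200, 2)) @ basis.T
    pca = run_pca(X)
    assert np.allclose(pca.eigenvalues[2:], 0.0, atol=1e-9)
    assert np.isclose(pca.eigenvalues.sum(), 100.0, atol=1e-9)


def test_pca_isotropic_cloud(rng):
    pca = run_pca(rng.standard_normal((100000, 5)))
    assert np.all(np.abs(pca.eigenvalues - 20.0) < 0.5)
    V = pca.eigenvectors
    assert np.allclose(V.T @ V, np.eye(5), atol=1e-9)
    assert np.all(np.diff(pca.eigenvalues) <= 1e-12)


def test_pca_minimum_rows():
    with pytest.raises(ValueError):
        run_pca(np.zeros((5, 5)))


def test_select_low_energy():
    poses = [Pose(np.eye(3), np.zeros(3), energy=float(e))
             for e in [5, 1, 3, 2, 4] * 20]
    assert len(select_low_energy(poses, 1.0)) == 100
    low = select_low_energy(poses, 0.05)
    assert len(low) == 5
    assert all(p.energy == 1.0 for p in low)
    with pytest.raises(ValueError):
        select_low_energy(poses, 0.0)


def test_motion_fraction_table_row():
    from encounterdock.landscape import PCAResult
    pca = PCAResult(np.zeros(5), np.array([55.0, 26.8, 15.3, 2.7, 0.2]),
                    np.eye(5))
    assert np.isclose(motion_fraction(pca, [1, 2]), 81.8)
    assert np.isclose(motion_fraction(pca, range(1, 6)), 100.0)
    assert motion_fraction(pca, []) == 0.0
    with pytest.raises(ValueError):
        motion_fraction(pca, [1, 1])


def test_subsample_uniform_deterministic(rng):
    X = rng.standard_normal((500, 5))
    idx = subsample_uniform(X, 50)
    assert len(idx) == 50 and len(set(idx.tolist())) == 50
    assert np.array_equal(idx, subsample_uniform(X, 50))
    assert np.array_equal(subsample_uniform(X, 600), np.arange(500))
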