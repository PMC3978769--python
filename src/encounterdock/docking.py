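"""Systematic rigid-body sampling by FFT correlation.

The docking energy is a "smooth" physics-based score evaluated exhaustively
over a discretized 6-D space: a deterministic quasi-uniform set of ligand
rotations, and for each rotation every translation on a cubic grid (default
1.0 Angstrom spacing). The score is

    E = E_attr + w1 * E_rep + w2 * E_elec + w3 * E_pair

where E_attr/E_rep are attractive and repulsive van der Waals terms, E_elec a
screened Coulomb term with kernel

    q_i q_j / sqrt(r^2 + D^2 exp(-r^2 / 4 D^2))

(D an atom-type-independent Born-radius scale, finite at r = 0), and E_pair a
statistical pairwise contact potential eps_ij representing desolvation. Each
term is a sum of grid correlation functions, so the full translational scan
for one rotation costs a handful of forward FFTs and a single inverse FFT.
The pair potential enters through the eigendecomposition of eps: each retained
eigencomponent contributes one correlation channel.

The repulsive core height is finite, so moderate steric overlap is tolerated;
this keeps the landscape smooth enough for a rigid-body search. Default
weights are w1 = 4, w2 = 600, w3 = 5.

A brute-force scan over the same discretization (`brute_force_scan`) serves
as the independent oracle for the FFT path: both must agree to near machine
precision on any input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .structures import NativeComplex, Pose, Structure

__all__ = [
    "EnergyWeights",
    "ChannelParams",
    "PairPotential",
    "Grid",
    "RotationSet",
    "PoseCluster",
    "decompose_pair_potential",
    "default_pair_potential",
    "elec_pair_energy",
    "build_receptor_grids",
    "fft_scan",
    "brute_force_scan",
    "pose_energy",
    "dock",
    "cluster_poses",
    "generate_rotations",
    "rotation_dispersion",
]


@dataclass
class EnergyWeights:
    """Weights of the docking score contributions.

    w1 scales steric repulsion, w2 the screened electrostatics, w3 the
    pairwise contact potential. ``born_radius`` is the atom-type-independent
    generalized-Born scale D (Angstrom) of the electrostatic kernel.
    """

    w1: float = 4.0
    w2: float = 600.0
    w3: float = 5.0
    born_radius: float = 2.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("weights must be nonnegative")
        if self.born_radius <= 0:
            raise ValueError("born_radius must be positive")


@dataclass
class ChannelParams:
    """Functional-form knobs of the grid channels.

    The attractive van der Waals channel is a square well of depth
    ``attr_depth`` on grid nodes whose distance to an atom lies in
    ``[core, core + attr_width]``; the repulsive channel is a constant
    penalty ``rep_height`` inside the core. The core radius of an atom is
    ``overlap_factor * (r_atom + probe_radius)``, i.e. a contact distance
    against a typical heavy partner atom, shrunk to tolerate modest overlap.
    The pair-potential channels count contacts within ``contact_radius``.
    """

    overlap_factor: float = 0.9
    probe_radius: float = 1.7
    attr_width: float = 2.0
    attr_depth: float = 0.5
    rep_height: float = 1.0
    contact_radius: float = 4.5
    elec_cutoff: float = 12.0

    def core_radius(self, atom_radius: float) -> float:
        return self.overlap_factor * (atom_radius + self.probe_radius)


@dataclass
class PairPotential:
    """Symmetric atom-type contact matrix and its truncated eigenexpansion."""

    matrix: np.ndarray
    eigenvalues: np.ndarray   # sorted by |value| descending, full set
    eigenvectors: np.ndarray  # columns matching eigenvalues
    rank: int

    @property
    def n_types(self) -> int:
        return self.matrix.shape[0]

    def truncated(self) -> np.ndarray:
        """Reconstruction of the matrix from the retained components."""
        lam = self.eigenvalues[: self.rank]
        vec = self.eigenvectors[:, : self.rank]
        return (vec * lam) @ vec.T


def decompose_pair_potential(matrix: np.ndarray,
                             mass_fraction: float = 0.99,
                             rank: int | None = None) -> PairPotential:
    """Eigendecompose a symmetric pair-potential matrix.

    The retained rank is the smallest number of eigencomponents whose
    absolute-eigenvalue mass reaches ``mass_fraction``, unless an explicit
    ``rank`` is given.
    """
    eps = np.asarray(matrix, dtype=float)
    if eps.ndim != 2 or eps.shape[0] != eps.shape[1]:
        raise ValueError("pair potential must be a square matrix")
    if not np.allclose(eps, eps.T, atol=1e-9):
        raise ValueError("pair potential must be symmetric")
    lam, vec = np.linalg.eigh(eps)
    order = np.argsort(-np.abs(lam), kind="stable")
    lam, vec = lam[order], vec[:, order]
    if rank is None:
        total = np.abs(lam).sum()
        if total == 0:
            rank = 1
        else:
            cum = np.cumsum(np.abs(lam)) / total
            rank = int(np.searchsorted(cum, mass_fraction - 1e-12) + 1)
    rank = min(rank, len(lam))
    if rank < 1:
        raise ValueError("rank must be >= 1")
    return PairPotential(eps, lam, vec, rank)


def default_pair_potential(rank: int | None = None) -> PairPotential:
    """A documented simple hydrophobic-contact default over two atom types.

    Type 1 (apolar carbon/sulfur) pairs gain a favorable contact energy;
    polar-apolar contacts are mildly favorable; polar-polar neutral. Any
    user-supplied symmetric matrix (e.g. from a TSV) is a drop-in replacement.
    """
    eps = np.array([[0.0, -0.1],
                    [-0.1, -0.5]])
    return decompose_pair_potential(eps, rank=rank)


def elec_pair_energy(r, q_i, q_j, born_radius: float):
    """Screened two-charge interaction, finite at contact.

    Equals ``q_i q_j / sqrt(r^2 + D^2 exp(-r^2/4D^2))``; at r = 0 this is
    ``q_i q_j / D``, and for r >> D it goes over to the bare Coulomb 1/r.
    """
    if born_radius <= 0:
        raise ValueError("born_radius must be positive")
    r = np.asarray(r, dtype=float)
    D = born_radius
    denom = np.sqrt(r * r + D * D * np.exp(-(r * r) / (4.0 * D * D)))
    return q_i * q_j / denom


@dataclass
class Grid:
    """Receptor-side correlation grids.

    ``channels`` holds the unweighted scalar fields: ``attr``, ``rep``,
    ``elec`` and one ``pair{p}`` field per retained eigencomponent. Weights
    are applied at scan time so the energy responds linearly to each weight
    with channels held fixed. Receptor-channel FFTs are cached lazily.
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    channels: dict[str, np.ndarray]
    params: ChannelParams
    pair_potential: PairPotential
    _ffts: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def channel_fft(self, name: str) -> np.ndarray:
        if name not in self._ffts:
            self._ffts[name] = scipy.fft.fftn(self.channels[name])
        return self._ffts[name]


def build_receptor_grids(receptor: Structure, weights: EnergyWeights,
                         pair_potential: PairPotential | None = None,
                         padding: float = 15.0, spacing: float = 1.0,
                         params: ChannelParams | None = None) -> Grid:
    """Accumulate the receptor's correlation channels on a cubic grid.

    The grid covers the receptor bounding box plus ``padding`` on every side;
    the padding must be at least the ligand diameter for all contacting
    placements to fit without wrap-around.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if padding <= 0:
        raise ValueError("padding must be positive and at least the ligand diameter")
    params = params or ChannelParams()
    pair_potential = pair_potential or default_pair_potential()

    heavy = receptor.heavy_mask
    xyz = receptor.xyz[heavy]
    radii = receptor.radius[heavy]
    charges = receptor.charge[heavy]
    types = receptor.pair_type[heavy]

    lo = xyz.min(axis=0) - padding
    hi = xyz.max(axis=0) + padding
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / spacing)) + 1 for a in range(3))
    origin = lo

    shape = dims
    attr = np.zeros(shape)
    rep = np.zeros(shape)
    elec = np.zeros(shape)
    pair = [np.zeros(shape) for _ in range(pair_potential.rank)]

    axes = [origin[a] + spacing * np.arange(dims[a]) for a in range(3)]

    for pos, rad, q, t in zip(xyz, radii, charges, types):
        core = params.core_radius(rad)
        reach = max(core + params.attr_width, params.contact_radius,
                    params.elec_cutoff if q != 0.0 else 0.0)
        sl, offsets = _local_block(axes, pos, reach, spacing)
        d = np.sqrt(offsets)
        rep[sl] += np.where(d < core, params.rep_height, 0.0)
        attr[sl] += np.where((d >= core) & (d < core + params.attr_width),
                             -params.attr_depth, 0.0)
        if q != 0.0:
            D = weights.born_radius
            kern = 1.0 / np.sqrt(d * d + D * D * np.exp(-(d * d) / (4 * D * D)))
            elec[sl] += np.where(d < params.elec_cutoff, q * kern, 0.0)
        contact = d < params.contact_radius
        for p in range(pair_potential.rank):
            u = pair_potential.eigenvectors[t, p]
            if u != 0.0:
                pair[p][sl] += np.where(contact, u, 0.0)

    channels = {"attr": attr, "rep": rep, "elec": elec}
    for p in range(pair_potential.rank):
        channels[f"pair{p}"] = pair[p]
    return Grid(np.asarray(origin, float), float(spacing), dims, channels,
                params, pair_potential)


def _local_block(axes, pos, reach, spacing):
    """Slice of the grid within ``reach`` of ``pos`` and squared distances."""
    sl = []
    coords = []
    for a in range(3):
        i0 = int(np.searchsorted(axes[a], pos[a] - reach))
        i1 = int(np.searchsorted(axes[a], pos[a] + reach, side="right"))
        sl.append(slice(i0, i1))
        coords.append(axes[a][i0:i1] - pos[a])
    dx, dy, dz = np.meshgrid(*coords, indexing="ij")
    return tuple(sl), dx * dx + dy * dy + dz * dz


# ---------------------------------------------------------------------------
# Translational scans
# ---------------------------------------------------------------------------

def _ligand_node_values(grid: Grid, ligand: Structure, rotation: np.ndarray):
    """Snap the rotated ligand's heavy atoms to grid nodes.

    The ligand is rotated about its heavy-atom geometric center; atoms map to
    the nearest grid node (the same assignment the brute-force oracle uses).
    Returns node indices (m, 3) and per-atom charge / pair-eigenvector values.
    """
    heavy = ligand.heavy_mask
    xyz = ligand.xyz[heavy]
    center = xyz.mean(axis=0)
    dims = np.array(grid.dims)
    # place the rotated ligand about the central grid node; the scan over
    # shifts makes the absolute input position irrelevant
    g0 = dims // 2
    idx = np.rint((xyz - center) @ np.asarray(rotation).T / grid.spacing
                  ).astype(int) + g0
    if np.any(idx < 0) or np.any(idx >= dims):
        raise ValueError("rotated ligand is larger than the grid; "
                         "increase padding or grid size")
    charges = ligand.charge[heavy]
    pp = grid.pair_potential
    types = ligand.pair_type[heavy]
    pair_vals = [pp.eigenvalues[p] * pp.eigenvectors[types, p]
                 for p in range(pp.rank)]
    return idx, charges, pair_vals, center


def _scatter(idx: np.ndarray, values: np.ndarray, dims) -> np.ndarray:
    arr = np.zeros(dims)
    np.add.at(arr, (idx[:, 0], idx[:, 1], idx[:, 2]), values)
    return arr


def fft_scan(grid: Grid, ligand: Structure, rotation: np.ndarray,
             weights: EnergyWeights) -> np.ndarray:
    """Total docking energy for every grid translation of one rotation.

    Element ``E[s]`` is the energy of the ligand displaced by ``s`` grid steps
    (circularly); correlations are evaluated with P + 2 forward FFTs and one
    inverse FFT. Identical, to numerical precision, to
    :func:`brute_force_scan` on the same discretization.
    """
    idx, charges, pair_vals, _ = _ligand_node_values(grid, ligand, rotation)
    occ = _scatter(idx, np.ones(len(idx)), grid.dims)
    F_occ = scipy.fft.fftn(occ)
    S = np.conj(F_occ) * (grid.channel_fft("attr")
                          + weights.w1 * grid.channel_fft("rep"))
    if np.any(charges != 0.0):
        F_q = scipy.fft.fftn(_scatter(idx, charges, grid.dims))
        S += weights.w2 * np.conj(F_q) * grid.channel_fft("elec")
    for p, vals in enumerate(pair_vals):
        if np.any(vals != 0.0):
            F_p = scipy.fft.fftn(_scatter(idx, vals, grid.dims))
            S += weights.w3 * np.conj(F_p) * grid.channel_fft(f"pair{p}")
    return scipy.fft.ifftn(S).real


def brute_force_scan(grid: Grid, ligand: Structure, rotation: np.ndarray,
                     weights: EnergyWeights) -> np.ndarray:
    """Direct double-sum evaluation of the same discretized energy.

    For every circular shift, sums receptor channel values at the shifted
    ligand nodes. Independent of the FFT path (no Fourier transforms); used
    as the module's central oracle.
    """
    idx, charges, pair_vals, _ = _ligand_node_values(grid, ligand, rotation)
    combined = (grid.channels["attr"] + weights.w1 * grid.channels["rep"])
    energy = np.zeros(grid.dims)
    for j in range(len(idx)):
        energy += np.roll(combined, shift=tuple(-idx[j]), axis=(0, 1, 2))
    if np.any(charges != 0.0):
        ch = grid.channels["elec"]
        for j in range(len(idx)):
            if charges[j] != 0.0:
                energy += weights.w2 * charges[j] * np.roll(
                    ch, shift=tuple(-idx[j]), axis=(0, 1, 2))
    for p, vals in enumerate(pair_vals):
        ch = grid.channels[f"pair{p}"]
        for j in range(len(idx)):
            if vals[j] != 0.0:
                energy += weights.w3 * vals[j] * np.roll(
                    ch, shift=tuple(-idx[j]), axis=(0, 1, 2))
    return energy


def pose_energy(receptor: Structure, ligand: Structure, pose: Pose,
                weights: EnergyWeights | None = None,
                pair_potential: PairPotential | None = None,
                params: ChannelParams | None = None) -> float:
    """Continuous-space evaluation of the docking energy for one pose.

    Sums the same functional forms the grid channels discretize (square-well
    van der Waals terms, screened-charge kernel, truncated-rank contact
    potential) directly over atom pairs, with no grid. Useful for scoring
    poses generated off-grid, e.g. along the contact manifold.
    """
    weights = weights or EnergyWeights()
    pair_potential = pair_potential or default_pair_potential()
    params = params or ChannelParams()
    rmask, lmask = receptor.heavy_mask, ligand.heavy_mask
    rx = receptor.xyz[rmask]
    lx = pose.apply(ligand.xyz[lmask])
    d = np.linalg.norm(rx[:, None, :] - lx[None, :, :], axis=2)
    core = params.core_radius(receptor.radius[rmask])[:, None]
    energy = float(np.sum(np.where(d < core, weights.w1 * params.rep_height, 0.0)))
    energy += float(np.sum(np.where(
        (d >= core) & (d < core + params.attr_width), -params.attr_depth, 0.0)))
    q = receptor.charge[rmask][:, None] * ligand.charge[lmask][None, :]
    active = (q != 0.0) & (d < params.elec_cutoff)
    if np.any(active):
        D = weights.born_radius
        dd = d[active]
        kern = 1.0 / np.sqrt(dd * dd + D * D * np.exp(-(dd * dd) / (4 * D * D)))
        energy += weights.w2 * float(np.sum(q[active] * kern))
    eps = pair_potential.truncated()
    pairs_eps = eps[np.ix_(receptor.pair_type[rmask], ligand.pair_type[lmask])]
    energy += weights.w3 * float(np.sum(np.where(d < params.contact_radius,
                                                 pairs_eps, 0.0)))
    return energy


def _valid_shift_mask(idx: np.ndarray, dims) -> np.ndarray:
    """Mask of circular shifts for which no ligand node wraps around."""
    mask = np.ones(dims, dtype=bool)
    for a, d in enumerate(dims):
        lo, hi = idx[:, a].min(), idx[:, a].max()
        s = np.arange(d)
        # displacement s keeps nodes in range, or s - d does
        ok = (hi + s < d) | (lo + s - d >= 0)
        shape = [1, 1, 1]
        shape[a] = d
        mask &= ok.reshape(shape)
    return mask


# ---------------------------------------------------------------------------
# Rotations
# ---------------------------------------------------------------------------

@dataclass
class RotationSet:
    """A deterministic ordered set of proper rotations."""

    matrices: np.ndarray      # (n, 3, 3)
    generator: str
    quaternions: np.ndarray = None  # (n, 4), scalar-last

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, float).reshape(-1, 3, 3)

    def __len__(self) -> int:
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)


def generate_rotations(count: int, generator: str = "super_fibonacci"
                       ) -> RotationSet:
    """Deterministic quasi-uniform cover of SO(3).

    Uses the super-Fibonacci spiral on the quaternion 3-sphere, a layered
    deterministic low-dispersion sequence; the first element is the identity
    rotation by convention. Nearest-neighbor dispersion decreases as the
    count grows.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if generator != "super_fibonacci":
        raise ValueError(f"unknown rotation generator {generator!r}")
    quats = np.empty((count, 4))
    quats[0] = (0.0, 0.0, 0.0, 1.0)  # identity, scalar-last
    if count > 1:
        n = count - 1
        i = np.arange(n, dtype=float)
        s = i + 0.5
        phi = np.sqrt(2.0)
        psi = 1.533751168755204288118041
        t = s / n
        d = 2.0 * np.pi * s
        r = np.sqrt(t)
        R = np.sqrt(1.0 - t)
        alpha = d / phi
        beta = d / psi
        quats[1:, 0] = r * np.sin(alpha)
        quats[1:, 1] = r * np.cos(alpha)
        quats[1:, 2] = R * np.sin(beta)
        quats[1:, 3] = R * np.cos(beta)
    mats = _quat_to_matrix(quats)
    return RotationSet(mats, generator, quats)


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    x, y, z, w = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
    m = np.empty((len(q), 3, 3))
    m[:, 0, 0] = 1 - 2 * (y * y + z * z)
    m[:, 0, 1] = 2 * (x * y - z * w)
    m[:, 0, 2] = 2 * (x * z + y * w)
    m[:, 1, 0] = 2 * (x * y + z * w)
    m[:, 1, 1] = 1 - 2 * (x * x + z * z)
    m[:, 1, 2] = 2 * (y * z - x * w)
    m[:, 2, 0] = 2 * (x * z - y * w)
    m[:, 2, 1] = 2 * (y * z + x * w)
    m[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def rotation_dispersion(rotations: RotationSet) -> float:
    """Mean nearest-neighbor rotation angle (radians) of the set."""
    q = rotations.quaternions
    if q is None:
        raise ValueError("rotation set lacks quaternions")
    dots = np.abs(q @ q.T)
    np.fill_diagonal(dots, -1.0)
    nn = np.clip(dots.max(axis=1), -1.0, 1.0)
    return float(np.mean(2.0 * np.arccos(nn)))


# ---------------------------------------------------------------------------
# Docking driver and clustering
# ---------------------------------------------------------------------------

def dock(receptor: Structure, ligand: Structure, rotations: RotationSet,
         weights: EnergyWeights | None = None,
         pair_potential: PairPotential | None = None,
         retain: int = 1, spacing: float = 1.0,
         padding: float | None = None,
         grid: Grid | None = None,
         params: ChannelParams | None = None) -> list[Pose]:
    """Exhaustive rigid-body scan: FFT translational sweep per rotation.

    For each rotation the ``retain`` lowest-energy non-wrapping translations
    are kept (ties broken by lowest flat grid index). Returns poses ordered
    by rotation then energy; fully deterministic for fixed inputs.
    """
    if len(rotations) == 0:
        raise ValueError("empty rotation set")
    weights = weights or EnergyWeights()
    if grid is None:
        if padding is None:
            heavy = ligand.xyz[ligand.heavy_mask]
            diameter = float(np.linalg.norm(heavy.max(0) - heavy.min(0)))
            padding = 0.5 * diameter + 4.0 * spacing
        grid = build_receptor_grids(receptor, weights, pair_potential,
                                    padding=padding, spacing=spacing,
                                    params=params)
    dims = np.array(grid.dims)
    poses: list[Pose] = []
    heavy = ligand.heavy_mask
    center = ligand.xyz[heavy].mean(axis=0)
    for R in rotations:
        energy = fft_scan(grid, ligand, R, weights)
        idx, _, _, _ = _ligand_node_values(grid, ligand, R)
        valid = _valid_shift_mask(idx, grid.dims)
        flat = np.where(valid.ravel(), energy.ravel(), np.inf)
        order = np.argsort(flat, kind="stable")[:retain]
        for f in order:
            if not np.isfinite(flat[f]):
                break
            s = np.array(np.unravel_index(f, grid.dims))
            # interpret each circular shift as the in-range displacement
            disp = np.where(idx.max(axis=0) + s < dims, s, s - dims)
            # continuous pose: ligand center lands on the displaced central node
            g0 = dims // 2
            t = grid.origin + grid.spacing * (g0 + disp) - R @ center
            poses.append(Pose(R, t, energy=float(flat[f])))
    return poses


@dataclass
class PoseCluster:
    center: int                 # index into the input pose list
    members: list[int]          # includes the center

    def __len__(self) -> int:
        return len(self.members)


def cluster_poses(poses: list[Pose], native: NativeComplex,
                  radius: float = 10.0) -> list[PoseCluster]:
    """Greedy energy-ordered clustering with a pairwise-IRMSD radius.

    Repeatedly takes the lowest-energy unassigned pose as a cluster center and
    absorbs every unassigned pose whose ligand-interface C-alpha RMSD to the
    center (receptors already share a frame) is within ``radius``. Clusters
    come back ordered by center energy.
    """
    if not poses:
        return []
    ca = native.ligand_interface_ca()
    coords = np.stack([p.apply(ca) for p in poses])   # (n, m, 3)
    energies = np.array([p.energy if p.energy is not None else np.inf
                         for p in poses])
    order = np.argsort(energies, kind="stable")
    unassigned = np.ones(len(poses), dtype=bool)
    clusters: list[PoseCluster] = []
    for i in order:
        if not unassigned[i]:
            continue
        diff = coords[unassigned] - coords[i]
        rms = np.sqrt(np.mean(np.sum(diff * diff, axis=2), axis=1))
        cand = np.flatnonzero(unassigned)
        members = cand[rms <= radius]
        unassigned[members] = False
        clusters.append(PoseCluster(int(i), members.tolist()))
    return clusters
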