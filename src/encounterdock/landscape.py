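"""Exponential-map coordinates and PCA of the near-native energy landscape.

Poses of a ligand touching a fixed receptor live on a five-dimensional
manifold: two angles for the direction from the receptor center to the ligand
interface center, and three for the ligand orientation, with the contact
distance r along that direction fixed by the no-overlap/contact condition.
Euler-angle-style charts of this space suffer gimbal lock, so both factors
are parameterized by exponential maps, which are locally one-to-one and yield
independent Euclidean coordinates suitable for PCA:

* the approach direction (theta: longitude, phi: colatitude from the native
  direction) maps to the tangent-plane coordinates
  (sigma1, sigma2) = (-phi sin(theta), phi cos(theta));
* the orientation relative to the native one maps to the rotation-group
  exponential coordinates omega = (w1, w2, w3) (axis-angle vector, the
  elements of the generating skew-symmetric matrix).

The native pose is the origin (0, 0, 0, 0, 0). A near-native sample is drawn
or selected inside a 5-D ball of angular radius 22.5 degrees (roughly a 10 A
IRMSD neighborhood for small proteins), filtered at 10 A IRMSD, balanced so
every coordinate has unit sample variance, and the lowest-energy fraction
(default 5%) is analyzed by PCA of the mean-centered covariance. Eigenvalues
are reported in percent of their sum; the eigenvectors of the two largest
eigenvalues span the "permissive" subspace along which low-energy poses vary
freely, those of the two smallest the "restrictive" subspace.

All five coordinates are stored in radians; reports print degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import NativeComplex, Pose, Structure, compute_irmsd

__all__ = [
    "LandscapeFrame",
    "ExpCoord",
    "PCAResult",
    "BALL_RADIUS_DEFAULT",
    "build_frame",
    "sphere_to_sigma",
    "sigma_to_sphere",
    "rotation_exp",
    "rotation_log",
    "pose_to_expcoord",
    "expcoord_to_pose",
    "contact_distance",
    "sample_ball",
    "filter_near_native",
    "balance_coords",
    "run_pca",
    "select_low_energy",
    "motion_fraction",
    "subsample_uniform",
]

#: 22.5 degrees, the default angular radius of the near-native ball (radians)
BALL_RADIUS_DEFAULT = float(np.deg2rad(22.5))

_COORD_NAMES = ("sigma1", "sigma2", "omega1", "omega2", "omega3")


@dataclass
class LandscapeFrame:
    """Reference frame of the landscape coordinates.

    Origin at the receptor center; the z axis points toward the native
    interface center. x and y complete a right-handed orthonormal triad by a
    fixed convention (see :func:`build_frame`) so that eigenvectors are
    reproducible run to run.
    """

    origin: np.ndarray                 # (3,)
    axes: np.ndarray                   # (3, 3), columns x, y, z
    ligand_interface_center: np.ndarray  # native ligand frame, (3,)
    native_r: float

    def __post_init__(self) -> None:
        A = np.asarray(self.axes, float).reshape(3, 3)
        if not np.allclose(A.T @ A, np.eye(3), atol=1e-9):
            raise ValueError("frame axes must be orthonormal")
        if np.linalg.det(A) < 0:
            raise ValueError("frame must be right-handed")
        self.axes = A


@dataclass
class ExpCoord:
    """Exponential-map coordinates of one pose plus its contact distance."""

    sigma1: float
    sigma2: float
    omega1: float
    omega2: float
    omega3: float
    r: float | None = None

    def as_vector(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2,
                         self.omega1, self.omega2, self.omega3])

    @classmethod
    def from_vector(cls, v: np.ndarray, r: float | None = None) -> "ExpCoord":
        v = np.asarray(v, float).reshape(5)
        return cls(*v, r=r)


@dataclass
class PCAResult:
    """PCA of the balanced 5-D coordinates of a low-energy ensemble."""

    mean: np.ndarray          # (5,) balanced-coordinate sample mean
    eigenvalues: np.ndarray   # (5,) percent, descending, summing to 100
    eigenvectors: np.ndarray  # (5, 5), columns v1..v5
    scales: np.ndarray | None = None  # per-coordinate balancing scales
    n_samples: int = 0

    def permissive(self, k: int = 2) -> np.ndarray:
        return self.eigenvectors[:, :k]

    def restrictive(self, k: int = 2) -> np.ndarray:
        return self.eigenvectors[:, -k:]


def build_frame(native: NativeComplex) -> LandscapeFrame:
    """Deterministic landscape frame of a native complex.

    z points from the receptor center to the native ligand interface center.
    The in-plane x axis is fixed by a structure-intrinsic reference (the
    first receptor atom whose direction from the origin is not parallel to
    z, orthogonalized against z), so the frame co-rotates with the complex:
    rigidly moving the whole system leaves every pose's coordinates
    unchanged, and eigenvectors are reproducible run to run.
    """
    origin = np.asarray(native.receptor_center, float)
    y_vec = np.asarray(native.ligand_interface_center, float) - origin
    r = float(np.linalg.norm(y_vec))
    if r < 1e-9:
        raise ValueError("interface center coincides with receptor center")
    z = y_vec / r
    x = None
    for pos in native.receptor.xyz:
        ref = pos - origin
        perp = ref - np.dot(ref, z) * z
        norm = np.linalg.norm(perp)
        if norm > 1e-6:
            x = perp / norm
            break
    if x is None:
        raise ValueError("all receptor atoms lie on the z axis; "
                         "frame is underdetermined")
    y = np.cross(z, x)
    axes = np.column_stack([x, y, z])
    return LandscapeFrame(origin, axes, np.asarray(
        native.ligand_interface_center, float), r)


# ---------------------------------------------------------------------------
# The two exponential maps
# ---------------------------------------------------------------------------

def sphere_to_sigma(theta: float, phi: float) -> tuple[float, float]:
    """Tangent-plane coordinates of a direction on the sphere.

    theta is the longitude in [0, 2 pi), phi the colatitude from the native
    (+z) direction in [0, pi). The map is (-phi sin(theta), phi cos(theta));
    the native direction phi = 0 maps to the origin.
    """
    if not (0.0 <= phi < np.pi):
        raise ValueError("phi must lie in [0, pi)")
    return (-phi * np.sin(theta), phi * np.cos(theta))


def sigma_to_sphere(sigma1: float, sigma2: float) -> tuple[float, float]:
    """Inverse of :func:`sphere_to_sigma`; (0, 0) maps to theta = 0, phi = 0."""
    phi = float(np.hypot(sigma1, sigma2))
    if phi >= np.pi:
        raise ValueError("|sigma| must be < pi")
    if phi == 0.0:
        return 0.0, 0.0
    theta = float(np.arctan2(-sigma1, sigma2)) % (2.0 * np.pi)
    return theta, phi


def rotation_exp(omega: np.ndarray) -> np.ndarray:
    """Rotation matrix of an axis-angle vector (Rodrigues formula).

    Small angles use the quadratic series of the coefficients, so the map is
    smooth through the identity.
    """
    w = np.asarray(omega, float).reshape(3)
    angle = np.linalg.norm(w)
    K = np.array([[0.0, -w[2], w[1]],
                  [w[2], 0.0, -w[0]],
                  [-w[1], w[0], 0.0]])
    if angle < 1e-8:
        return np.eye(3) + K + 0.5 * (K @ K)
    a = np.sin(angle) / angle
    b = (1.0 - np.cos(angle)) / (angle * angle)
    return np.eye(3) + a * K + b * (K @ K)


def rotation_log(R: np.ndarray) -> np.ndarray:
    """Principal-branch axis-angle vector of a proper rotation.

    Rotations by exactly pi sit on the branch cut and raise; the sampled
    near-native region (radius 22.5 degrees) never approaches it.
    """
    R = np.asarray(R, float).reshape(3, 3)
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-7):
        raise ValueError("not an orthogonal matrix")
    cos_angle = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_angle))
    if np.pi - angle < 1e-6:
        raise ValueError("rotation angle at the branch cut (pi)")
    axis_raw = np.array([R[2, 1] - R[1, 2],
                         R[0, 2] - R[2, 0],
                         R[1, 0] - R[0, 1]])
    if angle < 1e-8:
        return 0.5 * axis_raw  # sin(x) ~ x
    return axis_raw * angle / (2.0 * np.sin(angle))


# ---------------------------------------------------------------------------
# Pose <-> coordinate maps
# ---------------------------------------------------------------------------

def pose_to_expcoord(pose: Pose, frame: LandscapeFrame) -> ExpCoord:
    """Exponential-map coordinates of a pose.

    The translation is measured by the vector from the receptor center to the
    posed ligand interface center; the rotation is the pose rotation relative
    to the native one, expressed in frame axes.
    """
    y = pose.apply(frame.ligand_interface_center) - frame.origin
    r = float(np.linalg.norm(y))
    if r < 1e-9:
        raise ValueError("ligand interface center at the receptor center")
    yf = frame.axes.T @ y
    phi = float(np.arccos(np.clip(yf[2] / r, -1.0, 1.0)))
    theta = float(np.arctan2(yf[1], yf[0])) % (2.0 * np.pi)
    s1, s2 = sphere_to_sigma(theta, phi)
    R_f = frame.axes.T @ pose.rotation @ frame.axes
    w = rotation_log(R_f)
    return ExpCoord(s1, s2, w[0], w[1], w[2], r=r)


def expcoord_to_pose(coord: ExpCoord, frame: LandscapeFrame,
                     receptor: Structure | None = None,
                     ligand: Structure | None = None,
                     overlap_factor: float = 0.9) -> Pose:
    """Pose of a coordinate vector; r resolved by the contact condition.

    The rotation acts about the ligand interface center. When ``coord.r`` is
    unset, the receptor and ligand structures are required and the distance is
    set so the proteins touch without overlapping (:func:`contact_distance`).
    """
    theta, phi = sigma_to_sphere(coord.sigma1, coord.sigma2)
    d_f = np.array([np.sin(phi) * np.cos(theta),
                    np.sin(phi) * np.sin(theta),
                    np.cos(phi)])
    d = frame.axes @ d_f
    R = frame.axes @ rotation_exp(
        [coord.omega1, coord.omega2, coord.omega3]) @ frame.axes.T
    if coord.r is not None:
        r = float(coord.r)
    else:
        if receptor is None or ligand is None:
            raise ValueError("structures required to resolve contact distance")
        r = contact_distance(d, R, receptor, ligand, frame,
                             overlap_factor=overlap_factor)
    target = frame.origin + r * d
    t = target - R @ frame.ligand_interface_center
    return Pose(R, t)


def contact_distance(direction: np.ndarray, rotation: np.ndarray,
                     receptor: Structure, ligand: Structure,
                     frame: LandscapeFrame,
                     overlap_factor: float = 0.9) -> float:
    """Contact distance r along an approach direction.

    The smallest r >= 0 placing the rotated ligand (interface center at
    ``origin + r * direction``) so that no heavy-atom pair is closer than
    ``overlap_factor`` times the sum of radii, while the critical pair touches
    exactly. Solved in closed form: the largest positive root over all
    atom-pair quadratics along the ray.
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    rmask, lmask = receptor.heavy_mask, ligand.heavy_mask
    a = receptor.xyz[rmask]
    ar = receptor.radius[rmask]
    lx = ligand.xyz[lmask]
    lr = ligand.radius[lmask]
    base = (lx - frame.ligand_interface_center) @ np.asarray(rotation).T \
        + frame.origin
    # pair geometry: |u - r d| >= s, u = a_i - base_j
    u = a[:, None, :] - base[None, :, :]
    s = overlap_factor * (ar[:, None] + lr[None, :])
    ud = u @ d
    disc = ud * ud - np.sum(u * u, axis=2) + s * s
    touching = disc > 0
    if not np.any(touching):
        raise ValueError("no contact achievable along this direction")
    roots = ud[touching] + np.sqrt(disc[touching])
    r = float(roots.max())
    if r <= 0:
        raise ValueError("contact point lies behind the receptor center")
    return r


# ---------------------------------------------------------------------------
# Sampling, filtering, balancing, PCA
# ---------------------------------------------------------------------------

def sample_ball(n: int, radius: float = BALL_RADIUS_DEFAULT,
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """n points uniform in the 5-D ball of the given angular radius (radians)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    v = rng.standard_normal((n, 5))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    u = rng.random(n) ** (1.0 / 5.0)
    return radius * v * u[:, None]


def filter_near_native(poses: list[Pose], native: NativeComplex,
                       irmsd_cutoff: float = 10.0) -> list[Pose]:
    """Keep poses within the IRMSD cutoff of the native; order preserved.

    Each retained pose gets its ``irmsd`` annotation filled in.
    """
    kept = []
    for p in poses:
        v = compute_irmsd(p, native)
        if v <= irmsd_cutoff:
            p.irmsd = v
            kept.append(p)
    return kept


def balance_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each coordinate column by its sample standard deviation.

    Equalizing the per-axis variances removes the arbitrary relative scaling
    of the sphere-tangent and rotation coordinates and reduces dependence on
    the sizes of the two proteins. Returns the balanced matrix and the scales.
    """
    X = np.asarray(coords, float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a matrix with at least 2 rows")
    scales = X.std(axis=0, ddof=1)
    for j, s in enumerate(scales):
        if s < 1e-15:
            name = _COORD_NAMES[j] if j < len(_COORD_NAMES) else f"col{j}"
            raise ValueError(f"zero variance in coordinate {name}")
    return X / scales, scales


def run_pca(balanced: np.ndarray, scales: np.ndarray | None = None,
            min_rows: int = 10) -> PCAResult:
    """PCA of the mean-centered covariance of balanced coordinates.

    Eigenvalues are sorted descending and normalized to sum to 100 (percent);
    eigenvectors are orthonormal columns. Rank deficiency shows up as zero
    eigenvalues, not as an error.
    """
    X = np.asarray(balanced, float)
    if len(X) < min_rows:
        raise ValueError(f"need at least {min_rows} rows for PCA")
    mu = X.mean(axis=0)
    C = (X - mu).T @ (X - mu)
    lam, vec = np.linalg.eigh(C)
    lam, vec = lam[::-1], vec[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("degenerate sample: zero total variance")
    return PCAResult(mu, 100.0 * lam / total, vec, scales=scales,
                     n_samples=len(X))


def select_low_energy(poses: list[Pose], fraction: float = 0.05) -> list[Pose]:
    """The ceil(fraction * n) lowest-energy poses, input order breaking ties."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.ceil(fraction * len(poses)))
    energies = np.array([p.energy for p in poses], dtype=float)
    order = np.argsort(energies, kind="stable")[:k]
    return [poses[i] for i in sorted(order)]


def motion_fraction(pca: PCAResult, indices) -> float:
    """Percent of the total variance in the selected eigendirections.

    Indices are 1-based (v1 is the most permissive direction).
    """
    idx = list(indices)
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate eigenvector indices")
    if any(i < 1 or i > len(pca.eigenvalues) for i in idx):
        raise ValueError("eigenvector index out of range")
    return float(sum(pca.eigenvalues[i - 1] for i in idx))


def subsample_uniform(coords: np.ndarray, count: int) -> np.ndarray:
    """Greedy farthest-point subsampling toward spatial uniformity.

    Deterministic: starts from the point nearest the origin (the native pose)
    and repeatedly adds the point farthest from the current selection.
    Returns indices into ``coords``.
    """
    X = np.asarray(coords, float)
    n = len(X)
    if count >= n:
        return np.arange(n)
    start = int(np.argmin(np.linalg.norm(X, axis=1)))
    chosen = [start]
    dist = np.linalg.norm(X - X[start], axis=1)
    for _ in range(count - 1):
        nxt = int(np.argmax(dist))
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(X - X[nxt], axis=1))
    return np.array(sorted(chosen))
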