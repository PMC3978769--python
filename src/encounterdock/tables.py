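"""Flat-file artifacts: pose tables and landscape coordinate tables (TSV)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .landscape import ExpCoord
from .structures import Pose

__all__ = [
    "write_pose_table",
    "read_pose_table",
    "write_coord_table",
]


def write_pose_table(poses: Sequence[Pose], path: str | Path,
                     cluster_ids: Sequence[int] | None = None,
                     dialect: str = "matrix") -> None:
    """Write poses as TSV.

    ``dialect="matrix"`` stores the rotation as 9 floats row-major
    (r00..r22); ``"quaternion"`` as a scalar-last unit quaternion (qx..qw).
    """
    rows = []
    for i, p in enumerate(poses):
        row = {"pose_id": i, "dialect": dialect}
        if dialect == "matrix":
            for a in range(3):
                for b in range(3):
                    row[f"r{a}{b}"] = p.rotation[a, b]
        elif dialect == "quaternion":
            q = _matrix_to_quat(p.rotation)
            for name, val in zip(("qx", "qy", "qz", "qw"), q):
                row[name] = val
        else:
            raise ValueError(f"unknown dialect {dialect!r}")
        row["translation_x"], row["translation_y"], row["translation_z"] = p.translation
        row["energy"] = p.energy if p.energy is not None else np.nan
        row["irmsd"] = p.irmsd if p.irmsd is not None else np.nan
        row["cluster_id"] = cluster_ids[i] if cluster_ids is not None else -1
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pose_table(path: str | Path) -> list[Pose]:
    df = pd.read_csv(path, sep="\t")
    poses = []
    for _, row in df.iterrows():
        if row["dialect"] == "matrix":
            R = np.array([[row[f"r{a}{b}"] for b in range(3)] for a in range(3)])
        else:
            R = _quat_to_matrix_single(np.array(
                [row["qx"], row["qy"], row["qz"], row["qw"]]))
        t = np.array([row["translation_x"], row["translation_y"],
                      row["translation_z"]])
        energy = None if pd.isna(row["energy"]) else float(row["energy"])
        irmsd = None if pd.isna(row["irmsd"]) else float(row["irmsd"])
        poses.append(Pose(R, t, energy=energy, irmsd=irmsd))
    return poses


def write_coord_table(coords: Sequence[ExpCoord], poses: Sequence[Pose],
                      path: str | Path) -> None:
    rows = []
    for i, (c, p) in enumerate(zip(coords, poses)):
        rows.append({
            "pose_id": i, "sigma1": c.sigma1, "sigma2": c.sigma2,
            "omega1": c.omega1, "omega2": c.omega2, "omega3": c.omega3,
            "r": c.r,
            "energy": p.energy if p.energy is not None else np.nan,
            "irmsd": p.irmsd if p.irmsd is not None else np.nan,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.10g")


def _matrix_to_quat(R: np.ndarray) -> np.ndarray:
    # scalar-last convention, w >= 0
    w = 0.5 * np.sqrt(max(0.0, 1.0 + np.trace(R)))
    if w > 1e-8:
        x = (R[2, 1] - R[1, 2]) / (4 * w)
        y = (R[0, 2] - R[2, 0]) / (4 * w)
        z = (R[1, 0] - R[0, 1]) / (4 * w)
    else:  # near 180-degree rotation
        d = np.diag(R)
        i = int(np.argmax(d))
        j, k = (i + 1) % 3, (i + 2) % 3
        x_i = 0.5 * np.sqrt(max(0.0, 1.0 + d[i] - d[j] - d[k]))
        q = np.zeros(3)
        q[i] = x_i
        q[j] = (R[j, i] + R[i, j]) / (4 * x_i)
        q[k] = (R[k, i] + R[i, k]) / (4 * x_i)
        x, y, z = q
        w = (R[k, j] - R[j, k]) / (4 * x_i)
    q = np.array([x, y, z, w])
    return q / np.linalg.norm(q)


def _quat_to_matrix_single(q: np.ndarray) -> np.ndarray:
    q = q / np.linalg.norm(q)
    x, y, z, w = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
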