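"""Back-calculation of transverse paramagnetic relaxation enhancement rates.

A paramagnetic metal ion (here Mn2+ on an EDTA label) enhances the transverse
relaxation of nearby nuclei; the enhancement rate Gamma2 of a backbone amide
proton falls off as the inverse sixth power of its distance r to the unpaired
electron:

    Gamma_ji = C * sum_k r_ikj^-6

summed over the K rotameric states of the label, with C = 1.2e10 A^6/s. Rates
are capped at 90 s^-1, where both measured and back-calculated values become
unreliable because tiny distance changes dominate. Because the encounter
ensemble is in fast exchange, the observed profile is the population-weighted
mean over structures:

    <Gamma2(i)> = (sum_j Gamma_ji) / N_st

for a uniform ensemble of N_st docked structures. Profiles are compared after
normalizing each to its own maximum; observed values too large to quantify
(> 60 s^-1) sit at the saturation level 1.0 of the normalized scale.

Note on units: the prefactor C corresponds to one particular electron-proton
correlation time. Worked two-state examples quoted with a different reference
rate (e.g. 2 s^-1 at 30 A for a ~30 kDa complex) assume a different
correlation time; :func:`two_state_average` therefore takes rates as inputs
and never invokes C.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .structures import ParamagneticLabel, Pose, ResidueId, Structure

__all__ = [
    "PREConstants",
    "PREProfile",
    "gamma2_single",
    "rate_at_distance",
    "amide_proton_positions",
    "gamma2_structure",
    "ensemble_profile",
    "two_state_average",
    "normalize_profile",
    "profile_correlation",
    "read_experimental_profile",
]


@dataclass
class PREConstants:
    """Physical constants of the PRE back-calculation.

    C : A^6/s prefactor of the r^-6 law.
    cap : ceiling (s^-1) applied to every per-structure rate.
    saturation : display/comparison threshold (s^-1) above which observed
        rates cannot be quantified and are treated as saturated.
    """

    C: float = 1.2e10
    cap: float = 90.0
    saturation: float = 60.0

    def __post_init__(self) -> None:
        if min(self.C, self.cap, self.saturation) <= 0:
            raise ValueError("PRE constants must be positive")
        if self.cap < self.saturation:
            raise ValueError("cap must be at least the saturation threshold")


@dataclass
class PREProfile:
    """Per-residue transverse PRE rates, optionally normalized."""

    residues: list[ResidueId]
    gamma2: np.ndarray
    normalized: np.ndarray | None = None
    saturated: np.ndarray = None

    def __post_init__(self) -> None:
        self.gamma2 = np.asarray(self.gamma2, dtype=float)
        if np.any(self.gamma2 < 0):
            raise ValueError("gamma2 rates must be nonnegative")
        if self.saturated is None:
            self.saturated = np.zeros(len(self.gamma2), dtype=bool)
        self.saturated = np.asarray(self.saturated, dtype=bool)

    def __len__(self) -> int:
        return len(self.gamma2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": [f"{c}:{n}{i}" for c, n, i in self.residues],
            "gamma2": self.gamma2,
            "normalized": (self.normalized if self.normalized is not None
                           else np.full(len(self), np.nan)),
            "saturated": self.saturated.astype(int),
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def gamma2_single(r: float, constants: PREConstants | None = None,
                  apply_cap: bool = True) -> float:
    """Rate from a single metal-proton distance: C * r^-6, optionally capped."""
    constants = constants or PREConstants()
    if r <= 0:
        raise ValueError("distance must be positive")
    g = constants.C / float(r) ** 6
    return min(g, constants.cap) if apply_cap else g


def rate_at_distance(gamma_ref: float, r_ref: float, r: float) -> float:
    """Scale a reference rate to another distance by the r^-6 law.

    Useful for worked examples quoted against a reference rate measured at a
    known distance (sidestepping the absolute prefactor C).
    """
    if r_ref <= 0 or r <= 0:
        raise ValueError("distances must be positive")
    return gamma_ref * (r_ref / r) ** 6


def amide_proton_positions(structure: Structure) -> dict[ResidueId, np.ndarray]:
    """Backbone amide proton position per residue.

    An explicit ``H`` atom is used when present. Otherwise H is built at
    1.01 A from N along the external bisector of the C(prev)-N-CA angle, in
    that plane (standard trigonal amide geometry). The first residue of each
    chain and prolines have no amide proton and are skipped; residues with
    missing backbone atoms are skipped with a warning.
    """
    positions: dict[ResidueId, np.ndarray] = {}
    skipped = 0
    residues = structure.residue_ids()
    prev_by_chain: dict[str, ResidueId] = {}
    for rid in residues:
        h_idx = structure.atom_index(rid, "H")
        if h_idx is not None:
            positions[rid] = structure.xyz[h_idx].copy()
            prev_by_chain[rid[0]] = rid
            continue
        prev = prev_by_chain.get(rid[0])
        prev_by_chain[rid[0]] = rid
        if prev is None:
            continue  # chain start: no preceding carbonyl
        resname_idx = structure.atom_index(rid, "CA")
        if resname_idx is not None and structure.resname[resname_idx] == "PRO":
            continue
        n_idx = structure.atom_index(rid, "N")
        ca_idx = structure.atom_index(rid, "CA")
        c_idx = structure.atom_index(prev, "C")
        if n_idx is None or ca_idx is None or c_idx is None:
            skipped += 1
            continue
        N = structure.xyz[n_idx]
        u = N - structure.xyz[c_idx]
        v = N - structure.xyz[ca_idx]
        u = u / np.linalg.norm(u)
        v = v / np.linalg.norm(v)
        bisector = u + v
        norm = np.linalg.norm(bisector)
        if norm < 1e-8:
            skipped += 1
            continue
        positions[rid] = N + 1.01 * bisector / norm
    if skipped:
        warnings.warn(f"{skipped} residues lack backbone atoms for amide "
                      "proton construction; omitted from PRE profile",
                      stacklevel=2)
    return positions


def gamma2_structure(pose: Pose, receptor: Structure, label: ParamagneticLabel,
                     constants: PREConstants | None = None,
                     apply_cap: bool = True) -> PREProfile:
    """PRE profile of the receptor for a single posed ligand.

    The label's rotamer metal positions (ligand frame) are moved by the pose;
    each residue's rate is C * sum_k r_ik^-6 over the K rotamers, capped.
    """
    constants = constants or PREConstants()
    if label.n_rotamers < 1:
        raise ValueError("label has no rotamer positions")
    protons = amide_proton_positions(receptor)
    metals = label.posed_positions(pose)
    residues = list(protons)
    hpos = np.array([protons[r] for r in residues]).reshape(-1, 3)
    d = np.linalg.norm(hpos[:, None, :] - metals[None, :, :], axis=2)
    g = constants.C * np.sum(d ** -6.0, axis=1)
    if apply_cap:
        g = np.minimum(g, constants.cap)
    return PREProfile(residues, g, saturated=g >= constants.saturation)


def ensemble_profile(poses: Sequence[Pose], receptor: Structure,
                     label: ParamagneticLabel,
                     constants: PREConstants | None = None,
                     weights: np.ndarray | None = None,
                     chunk: int = 2048) -> PREProfile:
    """Fast-exchange ensemble PRE profile over a pose list.

    Per residue, the weighted mean of the per-structure capped rates; uniform
    weights (1/N_st) by default.
    """
    constants = constants or PREConstants()
    if len(poses) < 1:
        raise ValueError("need at least one pose")
    if weights is None:
        w = np.full(len(poses), 1.0 / len(poses))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights sum to zero")
        w = w / total
    protons = amide_proton_positions(receptor)
    residues = list(protons)
    hpos = np.array([protons[r] for r in residues]).reshape(-1, 3)
    base = label.positions                     # (K, 3)
    acc = np.zeros(len(residues))
    for start in range(0, len(poses), chunk):
        block = poses[start:start + chunk]
        R = np.stack([p.rotation for p in block])      # (b, 3, 3)
        t = np.stack([p.translation for p in block])   # (b, 3)
        metals = np.einsum("bij,kj->bki", R, base) + t[:, None, :]
        diff = hpos[None, :, None, :] - metals[:, None, :, :]
        d = np.linalg.norm(diff, axis=3)               # (b, m, K)
        g = constants.C * np.sum(d ** -6.0, axis=2)    # (b, m)
        g = np.minimum(g, constants.cap)
        acc += w[start:start + chunk] @ g
    return PREProfile(residues, acc, saturated=acc >= constants.saturation)


def two_state_average(p_a: float, gamma_a: float,
                      p_b: float, gamma_b: float) -> float:
    """Fast-exchange two-state PRE: population-weighted average of rates.

    Populations must be nonnegative and sum to one. Rates are taken as given
    (no distance prefactor is applied here).
    """
    if p_a < 0 or p_b < 0 or not np.isclose(p_a + p_b, 1.0):
        raise ValueError("populations must be nonnegative and sum to 1")
    return p_a * gamma_a + p_b * gamma_b


def normalize_profile(profile: PREProfile) -> PREProfile:
    """Divide every rate by the profile maximum (which becomes exactly 1)."""
    peak = profile.gamma2.max() if len(profile) else 0.0
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return PREProfile(list(profile.residues), profile.gamma2.copy(),
                      normalized=profile.gamma2 / peak,
                      saturated=profile.saturated.copy())


def profile_correlation(calculated: PREProfile, experimental: PREProfile,
                        saturation_policy: str = "clip") -> float:
    """Pearson correlation between two profiles over their shared residues.

    Both profiles are normalized to their maxima first. Under the default
    ``"clip"`` policy, entries flagged saturated on either side are set to the
    saturation level 1.0 of the normalized scale and kept; the ``"exclude"``
    policy drops them instead.
    """
    if saturation_policy not in ("clip", "exclude"):
        raise ValueError("saturation_policy must be 'clip' or 'exclude'")
    calc = normalize_profile(calculated)
    expv = normalize_profile(experimental)
    cmap = dict(zip(map(tuple, calc.residues), range(len(calc))))
    emap = dict(zip(map(tuple, expv.residues), range(len(expv))))
    shared = [r for r in cmap if tuple(r) in emap]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared residues")
    ci = np.array([cmap[r] for r in shared])
    ei = np.array([emap[tuple(r)] for r in shared])
    x = calc.normalized[ci].copy()
    y = expv.normalized[ei].copy()
    sat = calc.saturated[ci] | expv.saturated[ei]
    if saturation_policy == "clip":
        x[calc.saturated[ci]] = 1.0
        y[expv.saturated[ei]] = 1.0
    else:
        x, y = x[~sat], y[~sat]
        if len(x) < 3:
            raise ValueError("fewer than 3 shared residues after exclusion")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one side")
    return float(pearsonr(x, y).statistic)


def read_experimental_profile(path: str | Path) -> PREProfile:
    """Read an experimental PRE table: TSV residue, gamma2, error, saturated."""
    df = pd.read_csv(path, sep="\t")
    required = {"residue", "gamma2", "saturated"}
    if not required <= set(df.columns):
        raise ValueError(f"experimental table needs columns {sorted(required)}")
    residues = []
    for token in df["residue"].astype(str):
        if ":" in token:
            chain, _, num = token.partition(":")
        else:
            chain, num = "A", token
        icode = num[-1] if num and num[-1].isalpha() else ""
        residues.append((chain, int(num.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")), icode))
    return PREProfile(residues, df["gamma2"].to_numpy(float),
                      saturated=df["saturated"].to_numpy(bool))
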