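"""Geometric primitives: distances, angles, rigid superposition, RMSF.

All lengths in angstroms, all angles in degrees.  Superposition is
solved with the SVD (Kabsch) method with a determinant guard so a proper
rotation (no reflection) is always returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, InsufficientPointsError
from .structio import Trajectory


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid superposition of a mobile onto a reference point set.

    ``transform(x)`` maps mobile-frame coordinates into the reference
    frame: ``x @ rotation.T + translation``.
    """

    rotation: np.ndarray  # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,)
    rmsd: float
    n_atoms: int

    def transform(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class MobilityProfile:
    """Per-atom root-mean-square fluctuation about the trajectory mean."""

    rmsf: dict[int, float]  # roster index -> RMSF in angstroms
    fit_reference: str


def distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two points."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.linalg.norm(a - b))


def angle(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle a-vertex-c in degrees, in [0, 180]."""
    u = np.asarray(a, dtype=float) - np.asarray(vertex, dtype=float)
    v = np.asarray(c, dtype=float) - np.asarray(vertex, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("angle arm of zero length")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosine)))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Both arrays are (n, 3) with paired rows, n >= 3.  Minimises the RMSD
    over proper rotations and translations; reflections are excluded by
    flipping the sign of the smallest singular vector when the raw SVD
    solution has negative determinant.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InsufficientPointsError(f"superposition needs >= 3 points, got {n}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    p = mobile - cm
    q = reference - cr
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    moved = p @ rotation.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )


def rmsf(
    trajectory: Trajectory,
    target_atoms: np.ndarray,
    fit_atoms: np.ndarray | None = None,
) -> MobilityProfile:
    """Per-atom RMSF over a trajectory, optionally after frame alignment.

    When ``fit_atoms`` is given, every frame is first superposed onto the
    first frame over those atoms; fluctuations are then measured about
    each atom's mean position across the (aligned) frames:

        RMSF_i = sqrt( mean_f |r_i(f) - <r_i>|^2 )
    """
    target_atoms = np.asarray(target_atoms, dtype=int)
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    coords = trajectory.coords
    if fit_atoms is not None:
        fit_atoms = np.asarray(fit_atoms, dtype=int)
        if len(fit_atoms) < 3:
            raise InsufficientPointsError("fitting needs >= 3 atoms")
        ref = coords[0, fit_atoms]
        aligned = np.empty_like(coords)
        aligned[0] = coords[0]
        for f in range(1, trajectory.n_frames):
            sup = kabsch(coords[f, fit_atoms], ref)
            aligned[f] = sup.transform(coords[f])
        coords = aligned
        fit_reference = f"superposed onto frame 0 over {len(fit_atoms)} atoms"
    else:
        fit_reference = "no fitting"
    sub = coords[:, target_atoms, :]
    mean = sub.mean(axis=0, keepdims=True)
    values = np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))
    return MobilityProfile(
        rmsf={int(i): float(v) for i, v in zip(target_atoms, values)},
        fit_reference=fit_reference,
    )


def mobility_profile_frame(
    profile: MobilityProfile, trajectory: Trajectory
):
    """Export a mobility profile as a DataFrame (index, atom name, rmsf_A)."""
    import pandas as pd

    rows = [
        (i, trajectory.roster[i].name, v) for i, v in sorted(profile.rmsf.items())
    ]
    return pd.DataFrame(rows, columns=["index", "atom_name", "rmsf_A"])
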