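"""Near-attack-conformation (NAC) scoring and active-site water analysis.

A frame counts as a NAC for a hydroxylation site when ANY of the site's
chemically equivalent hydrogens lies within van-der-Waals contact of the
compound I ferryl oxygen (d(H...O) < d_max) with the C-H...O angle within
a tolerance of the transition-state reference angle.  The per-site NAC
percentage over a trajectory is the core regioselectivity statistic.

Defaults: d_max = 2.72 A (Bondi radii, r_O 1.52 + r_H 1.20); reference
angle 180 deg (near-linear hydrogen abstraction) with a 20 deg tolerance.
Both are configurable because the appropriate transition-state geometry
depends on the quantum-chemical model used to derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .structio import Trajectory

#: Bondi van-der-Waals radii (angstrom) used for the default H...O contact
VDW_RADII = {"H": 1.20, "O": 1.52, "C": 1.70, "N": 1.55}

DEFAULT_D_MAX = VDW_RADII["O"] + VDW_RADII["H"]  # 2.72 A
DEFAULT_THETA_REF = 180.0
DEFAULT_THETA_TOL = 20.0
DEFAULT_HBOND_D_MAX = 3.5  # O...O, A
DEFAULT_HBOND_ANGLE_MIN = 120.0  # O-H...O, deg


@dataclass(frozen=True)
class SiteDefinition:
    """A candidate hydroxylation site: equivalent hydrogens + their carbon."""

    site_label: str
    hydrogen_indices: tuple[int, ...]
    carbon_index: int

    def __post_init__(self) -> None:
        if len(self.hydrogen_indices) < 1:
            raise ConfigurationError(f"site {self.site_label}: no hydrogens")
        if self.carbon_index in self.hydrogen_indices:
            raise ConfigurationError(
                f"site {self.site_label}: carbon coincides with a hydrogen"
            )


@dataclass(frozen=True)
class NACCriterion:
    """Geometric NAC definition relative to the compound I oxygen."""

    acceptor_oxygen_index: int
    sites: tuple[SiteDefinition, ...]
    d_max: float = DEFAULT_D_MAX
    theta_ref: float = DEFAULT_THETA_REF
    theta_tol: float = DEFAULT_THETA_TOL

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ConfigurationError("d_max must be positive")
        if not (0 < self.theta_ref <= 180):
            raise ConfigurationError("theta_ref must be in (0, 180]")
        if self.theta_tol <= 0:
            raise ConfigurationError("theta_tol must be positive")
        labels = [s.site_label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate site labels")
        for s in self.sites:
            if self.acceptor_oxygen_index in s.hydrogen_indices:
                raise ConfigurationError(
                    f"site {s.site_label}: acceptor coincides with a hydrogen"
                )


@dataclass(frozen=True)
class FrameSiteResult:
    """Classification of one site in one frame."""

    is_nac: bool
    best_hydrogen: int  # roster index of closest hydrogen
    d: float  # H...O distance of that hydrogen, A
    theta: float  # C-H...O angle of that hydrogen, deg


@dataclass(frozen=True)
class NACResult:
    """Per-site NAC counts and percentages over a trajectory."""

    nac_frames: dict[str, int]
    total_frames: int
    d_max: float
    theta_ref: float
    theta_tol: float

    @property
    def nac_percent(self) -> dict[str, float]:
        return {
            k: 100.0 * v / self.total_frames for k, v in self.nac_frames.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (label, n, self.total_frames, 100.0 * n / self.total_frames)
            for label, n in self.nac_frames.items()
        ]
        return pd.DataFrame(
            rows, columns=["site", "nac_frames", "total_frames", "nac_percent"]
        )


@dataclass(frozen=True)
class WaterTrace:
    """Per-frame nearest water to the ferryl oxygen with H-bond flags."""

    distances: np.ndarray  # (n_frames,), A
    hbond: np.ndarray  # (n_frames,), bool
    water_index_per_frame: np.ndarray  # (n_frames,), roster index of arg-min O
    hbond_d_max: float
    hbond_angle_min: float

    def to_frame(self, frame_times: np.ndarray | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "frame": np.arange(len(self.distances)),
                "nearest_water_distance_A": self.distances,
                "hbond": self.hbond,
                "water_index": self.water_index_per_frame,
            }
        )
        if frame_times is not None:
            out.insert(1, "time_ps", frame_times)
        return out


def _site_geometry(
    coords: np.ndarray, site: SiteDefinition, acceptor: int
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and C-H...O angles for every hydrogen of a site.

    ``coords`` is (n_frames, n_atoms, 3); returns two (n_frames, n_H)
    arrays.  The angle vertex is the hydrogen.
    """
    h_idx = np.asarray(site.hydrogen_indices, dtype=int)
    h = coords[:, h_idx, :]  # (F, H, 3)
    o = coords[:, acceptor, :][:, None, :]  # (F, 1, 3)
    c = coords[:, site.carbon_index, :][:, None, :]
    to_o = o - h
    to_c = c - h
    d = np.linalg.norm(to_o, axis=2)
    nc = np.linalg.norm(to_c, axis=2)
    cosine = np.einsum("fhk,fhk->fh", to_o, to_c) / np.clip(d * nc, 1e-12, None)
    theta = np.degrees(np.arccos(np.clip(cosine, -1.0, 1.0)))
    return d, theta


def _validate_indices(trajectory: Trajectory, criterion: NACCriterion) -> None:
    n = trajectory.n_atoms
    idx = [criterion.acceptor_oxygen_index]
    for s in criterion.sites:
        idx.extend(s.hydrogen_indices)
        idx.append(s.carbon_index)
    for i in idx:
        if not (0 <= i < n):
            raise IndexError(f"roster index {i} out of range (n_atoms={n})")


def classify_frame(
    frame_coords: np.ndarray, criterion: NACCriterion
) -> dict[str, FrameSiteResult]:
    """Classify every site of a criterion in a single frame.

    A site is NAC iff any equivalent hydrogen satisfies both the distance
    and the angle test; the reported (d, theta) belong to the hydrogen
    closest to the acceptor (ties broken by lowest roster index).
    """
    coords = np.asarray(frame_coords, dtype=float)[None, :, :]
    out: dict[str, FrameSiteResult] = {}
    for site in criterion.sites:
        d, theta = _site_geometry(coords, site, criterion.acceptor_oxygen_index)
        d, theta = d[0], theta[0]
        ok = (d < criterion.d_max) & (
            np.abs(theta - criterion.theta_ref) <= criterion.theta_tol
        )
        order = np.lexsort((site.hydrogen_indices, d))
        best = order[0]
        out[site.site_label] = FrameSiteResult(
            is_nac=bool(ok.any()),
            best_hydrogen=int(site.hydrogen_indices[best]),
            d=float(d[best]),
            theta=float(theta[best]),
        )
    return out


def nac_percentages(
    trajectory: Trajectory, criterion: NACCriterion
) -> NACResult:
    """Per-site NAC percentages over all frames of a trajectory."""
    if not criterion.sites:
        raise ConfigurationError("criterion has no sites")
    _validate_indices(trajectory, criterion)
    counts: dict[str, int] = {}
    for site in criterion.sites:
        d, theta = _site_geometry(
            trajectory.coords, site, criterion.acceptor_oxygen_index
        )
        ok = (d < criterion.d_max) & (
            np.abs(theta - criterion.theta_ref) <= criterion.theta_tol
        )
        counts[site.site_label] = int(ok.any(axis=1).sum())
    return NACResult(
        nac_frames=counts,
        total_frames=trajectory.n_frames,
        d_max=criterion.d_max,
        theta_ref=criterion.theta_ref,
        theta_tol=criterion.theta_tol,
    )


def classify_trajectory(
    trajectory: Trajectory, criterion: NACCriterion
) -> dict[str, np.ndarray]:
    """Per-frame boolean NAC labels per site (streaming-equals-batch check)."""
    _validate_indices(trajectory, criterion)
    out = {}
    for site in criterion.sites:
        d, theta = _site_geometry(
            trajectory.coords, site, criterion.acceptor_oxygen_index
        )
        ok = (d < criterion.d_max) & (
            np.abs(theta - criterion.theta_ref) <= criterion.theta_tol
        )
        out[site.site_label] = ok.any(axis=1)
    return out


def min_distance_trace(
    trajectory: Trajectory, site: SiteDefinition, acceptor_index: int
) -> np.ndarray:
    """Per-frame minimum H...O distance over a site's equivalent hydrogens.

    For sites with several identical hydrogens (e.g. the three C21
    hydrogens of a pregnane side chain) only the shortest distance is
    meaningful at each time point.
    """
    h_idx = np.asarray(site.hydrogen_indices, dtype=int)
    if not (0 <= acceptor_index < trajectory.n_atoms):
        raise IndexError(f"acceptor index {acceptor_index} out of range")
    h = trajectory.coords[:, h_idx, :]
    o = trajectory.coords[:, acceptor_index, :][:, None, :]
    return np.linalg.norm(h - o, axis=2).min(axis=1)


def nearest_water_trace(
    trajectory: Trajectory,
    acceptor_index: int,
    water_oxygen_indices: np.ndarray,
    hbond_d_max: float = DEFAULT_HBOND_D_MAX,
    hbond_angle_min: float = DEFAULT_HBOND_ANGLE_MIN,
    water_hydrogens: dict[int, tuple[int, ...]] | None = None,
) -> WaterTrace:
    """Nearest-water distance trace to the ferryl oxygen, with H-bond flags.

    The H-bond flag is set when the nearest water oxygen is within
    ``hbond_d_max`` of the acceptor and, if that water's hydrogens are in
    the roster, at least one O-H...O angle (vertex at the water hydrogen)
    is >= ``hbond_angle_min``.  Waters without explicit hydrogens are
    judged on distance alone.

    ``water_hydrogens`` maps a water-oxygen roster index to its hydrogen
    indices; by default hydrogens are found by shared residue number and
    chain.
    """
    water_oxygen_indices = np.asarray(water_oxygen_indices, dtype=int)
    if len(water_oxygen_indices) == 0:
        raise ConfigurationError("empty water-oxygen index set")
    if water_hydrogens is None:
        water_hydrogens = {}
        for oi in water_oxygen_indices:
            oa = trajectory.roster[oi]
            hs = tuple(
                i
                for i, a in enumerate(trajectory.roster)
                if a.element == "H"
                and a.residue_number == oa.residue_number
                and a.chain == oa.chain
                and a.residue_name == oa.residue_name
            )
            water_hydrogens[int(oi)] = hs
    o = trajectory.coords[:, acceptor_index, :][:, None, :]
    w = trajectory.coords[:, water_oxygen_indices, :]
    d = np.linalg.norm(w - o, axis=2)  # (F, W)
    nearest = d.argmin(axis=1)
    n_frames = trajectory.n_frames
    distances = d[np.arange(n_frames), nearest]
    water_idx = water_oxygen_indices[nearest]
    hbond = np.zeros(n_frames, dtype=bool)
    acc = trajectory.coords[:, acceptor_index, :]
    for f in range(n_frames):
        if distances[f] > hbond_d_max:
            continue
        hs = water_hydrogens.get(int(water_idx[f]), ())
        if not hs:
            hbond[f] = True
            continue
        wo = trajectory.coords[f, water_idx[f]]
        for hi in hs:
            h = trajectory.coords[f, hi]
            u = wo - h
            v = acc[f] - h
            nu = np.linalg.norm(u)
            nv = np.linalg.norm(v)
            if nu == 0 or nv == 0:
                continue
            ang = np.degrees(
                np.arccos(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))
            )
            if ang >= hbond_angle_min:
                hbond[f] = True
                break
    return WaterTrace(
        distances=distances,
        hbond=hbond,
        water_index_per_frame=water_idx,
        hbond_d_max=hbond_d_max,
        hbond_angle_min=hbond_angle_min,
    )
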