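"""Seeded synthetic-data generators with recorded ground truth.

Every generator is a pure function of its spec (seed included), so
repeat calls are bitwise identical.  The generators emulate the study
designs the analyses expect — MD-style trajectories with site-labelled
abstractable hydrogens around a compound I oxygen, scheduled water
approaches, quadratic tight-binding titrations, conversion time courses
with a planted maximal rate and coupling ratio, and perturbed structure
pairs with a calibrated C-alpha RMSD — while recording the planted
labels, so downstream classification can be checked exactly rather than
in expectation.

Geometry planting keeps every hydrogen strictly outside a margin band
around the NAC thresholds: planted-NAC hydrogens satisfy both criteria
with room to spare and all other hydrogens violate both, so frame
classification is robust to floating-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binding import TitrationSeries, tight_binding_model
from .kinetics import EPSILON_NADH_340_mM, TimeCourse
from .posecompare import ComplexStructure
from .reactivity import (
    DEFAULT_D_MAX,
    DEFAULT_THETA_REF,
    DEFAULT_THETA_TOL,
    NACCriterion,
    SiteDefinition,
)
from .structio import AtomRecord, Trajectory

#: default 12-point ligand grid (uM), 0 to 150 as in a standard titration
DEFAULT_LIGAND_GRID = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 35.0, 50.0, 75.0,
                       100.0, 125.0, 150.0)


@dataclass(frozen=True)
class SiteSpec:
    """One candidate hydroxylation site to plant in a trajectory."""

    site_label: str
    n_equivalent_h: int
    target_nac_fraction: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_nac_fraction <= 1.0):
            raise ValueError("target_nac_fraction must be in [0, 1]")
        if self.n_equivalent_h < 1:
            raise ValueError("need at least one equivalent hydrogen")


@dataclass(frozen=True)
class ReactiveTrajectorySpec:
    """Spec for a synthetic reactive trajectory.

    ``margin`` is the keep-away band around the NAC thresholds as a
    fraction (0.1 means planted geometries stay 10 % inside/outside both
    the distance and angle limits).  ``water_schedule`` entries are
    (first_frame, last_frame, approach_distance_A), inclusive; outside
    scheduled windows waters are parked beyond 7 A.
    """

    n_frames: int
    sites: tuple[SiteSpec, ...]
    seed: int
    jitter_sigma: float = 0.05
    margin: float = 0.10
    n_waters: int = 1
    water_schedule: tuple[tuple[int, int, float], ...] = ()
    d_max: float = DEFAULT_D_MAX
    theta_ref: float = DEFAULT_THETA_REF
    theta_tol: float = DEFAULT_THETA_TOL
    frame_dt_ps: float = 50.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 < self.margin < 1.0):
            raise ValueError("margin must be in (0, 1)")
        if self.d_max * (1.0 - self.margin) <= 1.8:
            raise ValueError(
                "infeasible geometry: d_max*(1-margin) must exceed 1.8 A"
            )
        labels = [s.site_label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate site labels")


@dataclass(frozen=True)
class TrajectoryTruth:
    """Planted per-frame labels of a generated trajectory."""

    nac_labels: dict[str, np.ndarray]  # site label -> (n_frames,) bool
    water_min_distance: np.ndarray  # (n_frames,) planted nearest-water O...O, A

    @property
    def nac_counts(self) -> dict[str, int]:
        return {k: int(v.sum()) for k, v in self.nac_labels.items()}


@dataclass(frozen=True)
class GeneratedTrajectory:
    trajectory: Trajectory
    criterion: NACCriterion
    truth: TrajectoryTruth


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    while True:
        p = np.cross(u, _random_unit(rng))
        n = np.linalg.norm(p)
        if n > 1e-6:
            return p / n


def _plant_nac_hydrogen(
    rng: np.random.Generator, spec: ReactiveTrajectorySpec
) -> tuple[np.ndarray, np.ndarray]:
    """Place one hydrogen satisfying the criterion (inside the margin)
    and its bonded carbon; acceptor is at the origin."""
    d = rng.uniform(1.8, spec.d_max * (1.0 - spec.margin))
    lo = max(spec.theta_ref - spec.theta_tol * (1.0 - spec.margin), 1.0)
    hi = min(spec.theta_ref + spec.theta_tol * (1.0 - spec.margin), 180.0)
    theta = np.radians(rng.uniform(lo, hi))
    u = _random_unit(rng)  # acceptor -> hydrogen direction
    h = d * u
    to_o = -u  # hydrogen -> acceptor
    p = _perpendicular(u, rng)
    v = np.cos(theta) * to_o + np.sin(theta) * p
    c = h + 1.09 * v
    return h, c


def _plant_violating_hydrogen(
    rng: np.random.Generator, spec: ReactiveTrajectorySpec, carbon: np.ndarray
) -> np.ndarray:
    """Place a hydrogen violating BOTH the distance and the angle test by
    at least the margin, relative to the given carbon (acceptor at origin)."""
    d_lo = spec.d_max * (1.0 + spec.margin)
    theta_band = spec.theta_tol * (1.0 + spec.margin)
    for _ in range(1000):
        h = rng.uniform(d_lo, d_lo + 3.0) * _random_unit(rng)
        to_o = -h / np.linalg.norm(h)
        to_c = carbon - h
        n = np.linalg.norm(to_c)
        if n < 0.5:
            continue
        theta = np.degrees(np.arccos(np.clip(np.dot(to_o, to_c / n), -1, 1)))
        if abs(theta - spec.theta_ref) >= theta_band:
            return h
    raise RuntimeError("could not place a margin-violating hydrogen")


def gen_reactive_trajectory(spec: ReactiveTrajectorySpec) -> GeneratedTrajectory:
    """Generate a trajectory with NAC geometry planted at known frames.

    Each frame and site independently is a NAC with probability
    ``target_nac_fraction``; the drawn outcome is recorded as the ground
    truth label, so classification can be compared against exact counts.
    Waters follow the schedule and are otherwise parked beyond 7 A from
    the acceptor.
    """
    rng = np.random.default_rng(spec.seed)
    roster: list[AtomRecord] = []
    serial = 1
    roster.append(AtomRecord(serial, "OFE", "O", "CPI", 500, "X", (0.0, 0.0, 0.0)))
    acceptor_index = 0
    serial += 1
    site_defs: list[SiteDefinition] = []
    site_atom_idx: list[tuple[int, list[int]]] = []  # (carbon, hydrogens)
    for k, site in enumerate(spec.sites):
        c_index = len(roster)
        roster.append(
            AtomRecord(serial, f"C{k + 1}", "C", "STR", 600, "S", (0.0, 0.0, 4.0))
        )
        serial += 1
        h_indices = []
        for j in range(site.n_equivalent_h):
            h_indices.append(len(roster))
            roster.append(
                AtomRecord(serial, f"H{k + 1}{j + 1}", "H", "STR", 600, "S",
                           (0.0, 0.0, 5.0))
            )
            serial += 1
        site_defs.append(
            SiteDefinition(
                site_label=site.site_label,
                hydrogen_indices=tuple(h_indices),
                carbon_index=c_index,
            )
        )
        site_atom_idx.append((c_index, h_indices))
    water_atoms: list[tuple[int, int, int]] = []  # (O, H1, H2) roster indices
    for k in range(spec.n_waters):
        oi = len(roster)
        roster.append(
            AtomRecord(serial, "O", "O", "HOH", 700 + k, "W", (9.0, 0.0, 0.0))
        )
        serial += 1
        h1 = len(roster)
        roster.append(
            AtomRecord(serial, "H1", "H", "HOH", 700 + k, "W", (9.9, 0.0, 0.0))
        )
        serial += 1
        h2 = len(roster)
        roster.append(
            AtomRecord(serial, "H2", "H", "HOH", 700 + k, "W", (9.0, 0.9, 0.0))
        )
        serial += 1
        water_atoms.append((oi, h1, h2))

    n_atoms = len(roster)
    coords = np.zeros((spec.n_frames, n_atoms, 3))
    labels = {s.site_label: np.zeros(spec.n_frames, dtype=bool) for s in spec.sites}
    water_min = np.zeros(spec.n_frames)

    # parked positions: fixed direction per water, distance comfortably > 7 A
    park_dir = [_random_unit(rng) for _ in water_atoms]
    park_dist = [rng.uniform(7.5 + 6.0 * spec.jitter_sigma, 12.0)
                 for _ in water_atoms]
    approach_dir = {
        i: _random_unit(rng) for i in range(len(spec.water_schedule))
    }

    for f in range(spec.n_frames):
        for site, (c_index, h_indices) in zip(spec.sites, site_atom_idx):
            is_nac = bool(rng.random() < site.target_nac_fraction)
            labels[site.site_label][f] = is_nac
            if is_nac:
                which = int(rng.integers(len(h_indices)))
                h, c = _plant_nac_hydrogen(rng, spec)
                coords[f, h_indices[which]] = h
                coords[f, c_index] = c
                for j, hi in enumerate(h_indices):
                    if j != which:
                        coords[f, hi] = _plant_violating_hydrogen(rng, spec, c)
            else:
                c = rng.uniform(4.0, 8.0) * _random_unit(rng)
                coords[f, c_index] = c
                for hi in h_indices:
                    coords[f, hi] = _plant_violating_hydrogen(rng, spec, c)
        # waters
        dists = []
        for k, (oi, h1, h2) in enumerate(water_atoms):
            pos = None
            for si, (f0, f1, appr) in enumerate(spec.water_schedule):
                if si % len(water_atoms) == k and f0 <= f <= f1:
                    pos = appr * approach_dir[si]
                    break
            if pos is None:
                jitter = rng.normal(scale=spec.jitter_sigma, size=3)
                pos = park_dist[k] * park_dir[k] + jitter
            coords[f, oi] = pos
            # one O-H bond pointed at the acceptor (origin): near-linear
            # O-H...O geometry, so close approaches register as H-bonds
            to_acc = -pos / np.linalg.norm(pos)
            coords[f, h1] = pos + 0.96 * to_acc
            perp = _perpendicular(to_acc, rng)
            v = np.cos(np.radians(104.5)) * to_acc + np.sin(np.radians(104.5)) * perp
            coords[f, h2] = pos + 0.96 * v
            dists.append(np.linalg.norm(pos))
        water_min[f] = min(dists) if dists else np.nan

    criterion = NACCriterion(
        acceptor_oxygen_index=acceptor_index,
        sites=tuple(site_defs),
        d_max=spec.d_max,
        theta_ref=spec.theta_ref,
        theta_tol=spec.theta_tol,
    )
    trajectory = Trajectory(
        roster=roster,
        coords=coords,
        frame_times=spec.frame_dt_ps * (1.0 + np.arange(spec.n_frames)),
    )
    return GeneratedTrajectory(
        trajectory=trajectory,
        criterion=criterion,
        truth=TrajectoryTruth(nac_labels=labels, water_min_distance=water_min),
    )


@dataclass(frozen=True)
class TitrationSpec:
    """Spec for a synthetic type-I titration series."""

    kd_nM: float
    delta_A_max: float
    seed: int
    enzyme_total_uM: float = 3.0
    ligand_grid_uM: tuple[float, ...] = DEFAULT_LIGAND_GRID
    noise_sigma: float = 0.01  # relative, multiplicative
    replicates: int = 2

    def __post_init__(self) -> None:
        if 0.0 not in self.ligand_grid_uM:
            raise ValueError("ligand grid must include the 0 point")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def gen_titration(spec: TitrationSpec) -> tuple[TitrationSeries, dict]:
    """Titration series from the tight-binding model with multiplicative
    Gaussian noise; replicate points share the ligand grid."""
    rng = np.random.default_rng(spec.seed)
    L = np.repeat(np.asarray(spec.ligand_grid_uM, float), spec.replicates)
    clean = tight_binding_model(
        L, spec.enzyme_total_uM, spec.kd_nM * 1e-3, spec.delta_A_max
    )
    noisy = clean * (1.0 + rng.normal(scale=spec.noise_sigma, size=len(L)))
    series = TitrationSeries(
        ligand_total=L, delta_A=noisy, enzyme_total=spec.enzyme_total_uM
    )
    truth = {
        "kd_nM": spec.kd_nM,
        "delta_A_max": spec.delta_A_max,
        "enzyme_total_uM": spec.enzyme_total_uM,
    }
    return series, truth


def gen_timecourse(
    ton_true: float,
    p450_total_uM: float,
    s0_uM: float,
    window: tuple[float, float],
    seed: int,
    coupling_true_percent: float = 68.0,
    nadh0_uM: float | None = None,
    noise_uM: float = 1.0,
    t_end_min: float | None = None,
    dt_min: float = 5.0,
) -> tuple[TimeCourse, dict]:
    """Conversion time course with a planted steepest phase.

    Substrate is flat outside ``window`` and declines at
    ``ton_true * p450_total`` uM/min inside it.  The NADH trace consumes
    ``100 / coupling_true_percent`` uM NADH per uM substrate converted;
    when ``nadh0_uM`` is given the course is truncated where NADH runs
    out (the endpoint-extraction design of a coupling assay), otherwise
    the initial NADH amount is set to what the full course consumes.
    """
    t_a, t_b = window
    if t_b <= t_a:
        raise ValueError("window end must be after window start")
    if t_end_min is None:
        t_end_min = t_b + max(2.0 * dt_min, 0.25 * (t_b - t_a))
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end_min + 0.5 * dt_min, dt_min)
    rate = ton_true * p450_total_uM  # uM/min during the steep phase
    elapsed = np.clip(t, t_a, t_b) - t_a
    converted = rate * elapsed
    substrate = np.clip(s0_uM - converted, 0.0, None)
    converted = s0_uM - substrate
    consumed = converted * 100.0 / coupling_true_percent
    if nadh0_uM is None:
        nadh0 = float(consumed[-1]) if consumed[-1] > 0 else 200.0
    else:
        nadh0 = nadh0_uM
        keep = consumed <= nadh0 + 1e-9
        if keep.sum() >= 3:
            t, substrate, consumed = t[keep], substrate[keep], consumed[keep]
    nadh = np.clip(nadh0 - consumed, 0.0, None)
    a340 = nadh * EPSILON_NADH_340_mM * 1e-3
    noisy_substrate = np.clip(
        substrate + rng.normal(scale=noise_uM, size=len(t)), 0.0, None
    )
    tc = TimeCourse(
        time=t,
        substrate=noisy_substrate,
        p450_total=p450_total_uM,
        nadh_abs=a340,
    )
    truth = {
        "ton_true": ton_true,
        "coupling_true_percent": coupling_true_percent,
        "window": (t_a, t_b),
        "nadh0_uM": nadh0,
        "converted_uM": float(converted[-1]),
    }
    return tc, truth


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_complex_pair(
    rmsd_target: float,
    n_residues: int = 100,
    seed: int = 0,
    ligand_offsets: dict[tuple[str, str], float] | None = None,
) -> tuple[ComplexStructure, ComplexStructure, dict]:
    """A pair of complexes whose minimised C-alpha RMSD equals the target.

    The first structure is a self-avoiding-ish C-alpha random walk; the
    second is the first plus Gaussian perturbations rescaled iteratively
    until the superposed RMSD matches ``rmsd_target`` within 0.1 %, then
    moved by a random rigid motion.  ``ligand_offsets`` maps
    (atom_name_in_a, atom_name_in_b) to a planted post-alignment
    distance between the two ligand atoms.
    """
    from .geometry import kabsch  # local import to avoid cycle at module load

    rng = np.random.default_rng(seed)
    ca = [np.zeros(3)]
    for _ in range(n_residues - 1):
        d = _random_unit(rng)
        ca.append(ca[-1] + 3.8 * (0.7 * d + 0.3 * _random_unit(rng)))
    ca_a = np.array(ca)
    center = ca_a.mean(axis=0)

    if rmsd_target > 0:
        delta = rng.normal(size=ca_a.shape)
        for _ in range(30):
            trial = ca_a + delta
            r = kabsch(trial, ca_a).rmsd
            if abs(r - rmsd_target) <= 1e-3 * rmsd_target:
                break
            delta *= rmsd_target / r
        ca_b = ca_a + delta
    else:
        ca_b = ca_a.copy()

    lig_a: list[AtomRecord] = []
    lig_b_pre: list[tuple[str, np.ndarray]] = []
    planted: dict[tuple[str, str], float] = {}
    if ligand_offsets:
        # superposing the perturbed backbone onto the original is not
        # exactly the identity, so plant ligand positions through the
        # inverse of the actual optimal alignment: the offset is then
        # exact after superposition
        sup0 = kabsch(ca_b, ca_a)
        for (name_a, name_b), offset in ligand_offsets.items():
            pos_a = center + rng.uniform(-2, 2, size=3)
            lig_a.append(
                AtomRecord(9000 + len(lig_a), name_a, "C", "STR", 601, "S",
                           tuple(pos_a))
            )
            target = pos_a + offset * _random_unit(rng)
            pos_b = sup0.rotation.T @ (target - sup0.translation)
            lig_b_pre.append((name_b, pos_b))
            planted[(name_a, name_b)] = offset

    rot = _random_rotation(rng)
    shift = rng.uniform(-20, 20, size=3)

    def protein_atoms(coords: np.ndarray, transform: bool) -> list[AtomRecord]:
        out = []
        for i, p in enumerate(coords):
            if transform:
                p = rot @ p + shift
            out.append(
                AtomRecord(i + 1, "CA", "C", "ALA", i + 1, "A", tuple(p))
            )
        return out

    a = ComplexStructure(
        identifier="SYNTH-A", protein_atoms=protein_atoms(ca_a, False),
        ligand_atoms=lig_a,
    )
    lig_b = [
        AtomRecord(9500 + i, name, "C", "STR", 601, "S", tuple(rot @ p + shift))
        for i, (name, p) in enumerate(lig_b_pre)
    ]
    b = ComplexStructure(
        identifier="SYNTH-B", protein_atoms=protein_atoms(ca_b, True),
        ligand_atoms=lig_b,
    )
    truth = {"rmsd_target": rmsd_target, "ligand_offsets": planted}
    return a, b, truth
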