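import numpy as np
import pytest

from p450kit.errors import ConfigurationError
from p450kit.geometry import angle, distance
from p450kit.reactivity import (
    NACCriterion,
    SiteDefinition,
    classify_frame,
    classify_trajectory,
    min_distance_trace,
    nac_percentages,
    nearest_water_trace,
)
from p450kit.synthgen import ReactiveTrajectorySpec, SiteSpec, gen_reactive_trajectory

from conftest import make_trajectory


def brute_force_site_nac(coords, site, acceptor, d_max, theta_ref, theta_tol):
    """Independent per-hydrogen oracle using the scalar geometry ops."""
    o = coords[acceptor]
    c = coords[site.carbon_index]
    for hi in site.hydrogen_indices:
        h = coords[hi]
        d = distance(h, o)
        th = angle(c, h, o)
        if d < d_max and abs(th - theta_ref) <= theta_tol:
            return True
    return False


def random_criterion_trajectory(rng, n_frames=100, n_sites=3):
    """Frames with fully random geometry around an acceptor at the origin."""
    sites = []
    n_atoms = 1
    for k in range(n_sites):
        n_h = int(rng.integers(1, 4))
        sites.append(
            SiteDefinition(
                site_label=f"s{k}",
                hydrogen_indices=tuple(range(n_atoms + 1, n_atoms + 1 + n_h)),
                carbon_index=n_atoms,
            )
        )
        n_atoms += 1 + n_h
    coords = rng.uniform(-4.0, 4.0, size=(n_frames, n_atoms, 3))
    coords[:, 0] = 0.0
    traj = make_trajectory(coords, elements=["O"] + ["C"] * (n_atoms - 1))
    criterion = NACCriterion(
        acceptor_oxygen_index=0, sites=tuple(sites),
        d_max=2.72, theta_ref=180.0, theta_tol=20.0,
    )
    return traj, criterion


class TestClassifyFrame:
    def test_constructed_nac_is_true(self):
        # hydrogen at 2.0 A from the acceptor, C-H...O angle exactly 180
        coords = np.array([[0, 0, 0], [0, 0, 3.09], [0, 0, 2.0]], float)
        crit = NACCriterion(
            acceptor_oxygen_index=0,
            sites=(SiteDefinition("s", (2,), 1),),
        )
        res = classify_frame(coords, crit)["s"]
        assert res.is_nac
        assert res.d == pytest.approx(2.0)
        assert res.theta == pytest.approx(180.0)

    def test_far_hydrogens_never_nac(self, rng):
        # all hydrogens at >= 6 A: abstraction impossible at any angle
        for _ in range(20):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            h = (6.0 + rng.uniform(0, 3)) * u
            c = h + rng.normal(size=3)
            coords = np.stack([np.zeros(3), c, h])
            crit = NACCriterion(0, (SiteDefinition("s", (2,), 1),))
            assert not classify_frame(coords, crit)["s"].is_nac

    def test_reported_hydrogen_is_closest(self):
        coords = np.array(
            [[0, 0, 0], [0, 0, 6], [0, 0, 4], [0, 0, 3], [0, 0, 5]], float
        )
        crit = NACCriterion(0, (SiteDefinition("s", (2, 3, 4), 1),))
        res = classify_frame(coords, crit)["s"]
        assert res.best_hydrogen == 3
        assert res.d == pytest.approx(3.0)

    def test_acceptor_in_site_rejected(self):
        with pytest.raises(ConfigurationError):
            NACCriterion(2, (SiteDefinition("s", (2,), 1),))

    def test_matches_brute_force_oracle(self, rng):
        traj, crit = random_criterion_trajectory(rng, n_frames=500)
        labels = classify_trajectory(traj, crit)
        for f in range(traj.n_frames):
            per_frame = classify_frame(traj.coords[f], crit)
            for site in crit.sites:
                expected = brute_force_site_nac(
                    traj.coords[f], site, crit.acceptor_oxygen_index,
                    crit.d_max, crit.theta_ref, crit.theta_tol,
                )
                assert per_frame[site.site_label].is_nac == expected
                assert labels[site.site_label][f] == expected


class TestNacPercentages:
    def test_planted_counts_recovered_exactly(self):
        spec = ReactiveTrajectorySpec(
            n_frames=1000,
            sites=(SiteSpec("16a", 1, 0.22), SiteSpec("21", 3, 0.07)),
            seed=7,
        )
        gen = gen_reactive_trajectory(spec)
        result = nac_percentages(gen.trajectory, gen.criterion)
        assert result.nac_frames == gen.truth.nac_counts
        assert result.total_frames == 1000

    def test_single_nac_frame_is_100_percent(self):
        coords = np.array([[[0, 0, 0], [0, 0, 3.09], [0, 0, 2.0]]], float)
        traj = make_trajectory(coords, elements=["O", "C", "H"])
        crit = NACCriterion(0, (SiteDefinition("s", (2,), 1),))
        assert nac_percentages(traj, crit).nac_percent["s"] == 100.0

    def test_deterministic(self, rng):
        traj, crit = random_criterion_trajectory(rng, n_frames=50)
        r1 = nac_percentages(traj, crit)
        r2 = nac_percentages(traj, crit)
        assert r1.nac_frames == r2.nac_frames

    def test_empty_site_list_rejected(self, rng):
        traj, crit = random_criterion_trajectory(rng, n_frames=5)
        empty = NACCriterion(0, ())
        with pytest.raises(ConfigurationError):
            nac_percentages(traj, empty)

    def test_streaming_equals_batch(self, rng):
        traj, crit = random_criterion_trajectory(rng, n_frames=200)
        labels = classify_trajectory(traj, crit)
        batch = nac_percentages(traj, crit)
        for site, arr in labels.items():
            assert int(arr.sum()) == batch.nac_frames[site]

    def test_invariant_under_rigid_motion(self, rng):
        traj, crit = random_criterion_trajectory(rng, n_frames=100)
        theta = np.radians(49.0)
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = make_trajectory(traj.coords @ rot.T + np.array([3.0, -7.0, 1.0]))
        assert (
            nac_percentages(traj, crit).nac_frames
            == nac_percentages(moved, crit).nac_frames
        )

    def test_monotone_in_thresholds(self, rng):
        traj, crit = random_criterion_trajectory(rng, n_frames=200)
        loose_d = NACCriterion(0, crit.sites, d_max=3.0, theta_ref=180.0,
                               theta_tol=crit.theta_tol)
        tight_d = NACCriterion(0, crit.sites, d_max=2.5, theta_ref=180.0,
                               theta_tol=crit.theta_tol)
        loose_t = NACCriterion(0, crit.sites, d_max=crit.d_max,
                               theta_ref=180.0, theta_tol=30.0)
        tight_t = NACCriterion(0, crit.sites, d_max=crit.d_max,
                               theta_ref=180.0, theta_tol=10.0)
        for label in [s.site_label for s in crit.sites]:
            assert (nac_percentages(traj, loose_d).nac_frames[label]
                    >= nac_percentages(traj, tight_d).nac_frames[label])
            assert (nac_percentages(traj, loose_t).nac_frames[label]
                    >= nac_percentages(traj, tight_t).nac_frames[label])


class TestTraces:
    def test_single_hydrogen_trace_is_plain_distance(self, rng):
        coords = rng.uniform(-5, 5, size=(30, 3, 3))
        traj = make_trajectory(coords)
        site = SiteDefinition("s", (2,), 1)
        trace = min_distance_trace(traj, site, 0)
        expected = np.linalg.norm(coords[:, 2] - coords[:, 0], axis=1)
        assert np.allclose(trace, expected)

    def test_three_hydrogens_min(self):
        coords = np.zeros((1, 5, 3))
        coords[0, 2] = [2, 0, 0]
        coords[0, 3] = [0, 3, 0]
        coords[0, 4] = [0, 0, 4]
        traj = make_trajectory(coords)
        trace = min_distance_trace(traj, SiteDefinition("s", (2, 3, 4), 1), 0)
        assert trace[0] == pytest.approx(2.0)

    def test_trace_matches_brute_force(self, rng):
        coords = rng.uniform(-6, 6, size=(100, 6, 3))
        traj = make_trajectory(coords)
        site = SiteDefinition("s", (2, 3, 4, 5), 1)
        trace = min_distance_trace(traj, site, 0)
        for f in range(100):
            expected = min(
                distance(coords[f, h], coords[f, 0]) for h in (2, 3, 4, 5)
            )
            assert trace[f] == pytest.approx(expected, abs=1e-12)


class TestWaterTrace:
    def test_parked_water_constant_seven_no_hbond(self):
        coords = np.zeros((20, 2, 3))
        coords[:, 1] = [7.0, 0, 0]
        traj = make_trajectory(
            coords, elements=["O", "O"], resnames=["CPI", "HOH"],
            resnums=[1, 101],
        )
        wt = nearest_water_trace(traj, 0, np.array([1]))
        assert np.allclose(wt.distances, 7.0)
        assert not wt.hbond.any()

    def test_scheduled_approach_detected_in_exact_frames(self):
        spec = ReactiveTrajectorySpec(
            n_frames=100,
            sites=(SiteSpec("s", 1, 0.0),),
            seed=11,
            water_schedule=((50, 60, 1.9),),
        )
        gen = gen_reactive_trajectory(spec)
        from p450kit.structio import water_oxygen_indices

        waters = water_oxygen_indices(gen.trajectory)
        wt = nearest_water_trace(
            gen.trajectory, gen.criterion.acceptor_oxygen_index, waters
        )
        close = wt.distances < 2.0
        assert set(np.nonzero(close)[0]) == set(range(50, 61))
        # a sub-2 A water with an O-H bond pointed at the acceptor H-bonds
        assert wt.hbond[50:61].all()
        assert not wt.hbond[:50].any() and not wt.hbond[61:].any()

    def test_matches_exhaustive_nearest_neighbour(self, rng):
        n_w = 200
        coords = rng.uniform(-20, 20, size=(30, n_w + 1, 3))
        coords[:, 0] = 0.0
        traj = make_trajectory(
            coords,
            elements=["O"] * (n_w + 1),
            resnames=["CPI"] + ["HOH"] * n_w,
            resnums=[1] + list(range(100, 100 + n_w)),
        )
        waters = np.arange(1, n_w + 1)
        wt = nearest_water_trace(traj, 0, waters)
        for f in range(30):
            d = np.array([distance(coords[f, w], coords[f, 0]) for w in waters])
            assert wt.distances[f] == pytest.approx(d.min(), abs=1e-12)
            assert wt.water_index_per_frame[f] == waters[int(np.argmin(d))]

    def test_empty_water_set_rejected(self, tiny_water_trajectory):
        with pytest.raises(ConfigurationError):
            nearest_water_trace(tiny_water_trajectory, 0, np.array([], dtype=int))

    def test_hbond_requires_distance(self, tiny_water_trajectory):
        wt = nearest_water_trace(tiny_water_trajectory, 0, np.array([1, 2, 3, 4]))
        assert (~wt.hbond | (wt.distances <= wt.hbond_d_max)).all()
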