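"""Observables: RDF normalization, radial profiles, MSD, clustering."""

import numpy as np
import pytest

from mesocapsule.analysis import (
    clusters,
    contact_fraction,
    diffusion_coefficient,
    largest_cluster_fraction,
    msd,
    periodic_center_of_mass,
    radial_profile,
    rdf,
    rdf_window,
    shell_order,
    shell_order_trajectory,
)
from mesocapsule.engine import Trajectory


def make_traj(wrapped, species, L, unwrapped=None, dt=1.0):
    """Single- or multi-frame trajectory from raw arrays."""
    wrapped = np.asarray(wrapped, dtype=float)
    if wrapped.ndim == 2:
        wrapped = wrapped[None]
    return Trajectory(
        steps=np.arange(len(wrapped), dtype=np.int64),
        wrapped=wrapped % L,
        unwrapped=wrapped.copy() if unwrapped is None else np.asarray(unwrapped, float),
        species=np.asarray(species),
        bonds=np.empty((0, 2), dtype=np.int64),
        box_length=L,
        seed=0,
        dt=dt,
    )


class TestRDF:
    def test_ideal_gas_limit(self):
        """Uniform random beads give g(r) = 1 away from zero."""
        rng = np.random.default_rng(42)
        L, n = 10.0, 5000
        traj = make_traj(rng.uniform(0, L, (n, 3)), ["W"] * n, L)
        res = rdf(traj, "W", "W", n_bins=50, r_max=5.0, window=[0])
        sel = (res.bin_centers > 1.0) & (res.bin_centers < 3.0)
        assert 0.95 <= res.g[sel].mean() <= 1.05

    def test_two_isolated_beads_single_bin(self):
        L = 10.0
        d = 2.05
        traj = make_traj([[1.0, 5.0, 5.0], [1.0 + d, 5.0, 5.0]], ["C1", "N1"], L)
        res = rdf(traj, "C1", "N1", n_bins=50, r_max=5.0, window=[0])
        occupied = np.nonzero(res.g)[0]
        assert len(occupied) == 1
        assert abs(res.bin_centers[occupied[0]] - d) <= 0.05  # bin width

    def test_default_window_is_500_frames(self):
        steps = rdf_window(250_000)
        assert len(steps) == 500
        assert steps[-1] == 250_000
        assert steps[0] == 200_100  # last 50,000 steps sampled every 100

    def test_absent_species_rejected(self):
        traj = make_traj([[1.0, 1.0, 1.0]], ["W"], 10.0)
        with pytest.raises(ValueError, match="not present"):
            rdf(traj, "C1", "W", window=[0])

    def test_nonnegative(self):
        rng = np.random.default_rng(3)
        traj = make_traj(rng.uniform(0, 8, (200, 3)), ["W"] * 200, 8.0)
        res = rdf(traj, "W", "W", window=[0])
        assert np.all(res.g >= 0)


class TestRadialProfile:
    def test_point_mass_in_bin_zero(self):
        pos = np.full((20, 3), 5.0)
        prof = radial_profile(pos, np.array(["C1"] * 20), 10.0, ["C1"], center=np.full(3, 5.0))
        assert prof.counts["C1"][0] == 20
        assert prof.counts["C1"][1:].sum() == 0

    def test_uniform_shell_peaks_at_radius(self):
        rng = np.random.default_rng(1)
        R, L = 2.0, 12.0
        v = rng.normal(size=(500, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        pos = 6.0 + R * v
        prof = radial_profile(pos, np.array(["O4"] * 500), L, ["O4"], center=np.full(3, 6.0))
        centers = 0.5 * (prof.bin_edges[:-1] + prof.bin_edges[1:])
        peak = centers[np.argmax(prof.counts["O4"])]
        assert abs(peak - R) < 0.15

    def test_counts_conserve_species_totals(self):
        """Binned counts sum exactly to each species' bead count."""
        rng = np.random.default_rng(5)
        L = 9.0
        n = 400
        species = np.array(["C1"] * 100 + ["N1"] * 150 + ["W"] * 150)
        pos = rng.uniform(0, L, (n, 3))
        prof = radial_profile(pos, species, L, ["C1", "N1", "W"])
        assert prof.counts["C1"].sum() == 100
        assert prof.counts["N1"].sum() == 150
        assert prof.counts["W"].sum() == 150

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty species"):
            radial_profile(np.zeros((1, 3)), np.array(["W"]), 5.0, [])

    def test_water_only_needs_explicit_center(self):
        with pytest.raises(ValueError, match="center"):
            radial_profile(np.zeros((5, 3)), np.array(["W"] * 5), 5.0, ["W"])


def test_periodic_com_spans_boundary():
    """A blob straddling the wrap point has its center inside the blob."""
    pts = np.array([[0.2, 5.0, 5.0], [9.8, 5.0, 5.0]])
    com = periodic_center_of_mass(pts, 10.0)
    assert min(abs(com[0] - 0.0), abs(com[0] - 10.0)) < 1e-9


class TestMSD:
    def test_static_beads(self):
        pos = np.tile(np.random.default_rng(0).uniform(0, 5, (10, 3)), (4, 1, 1))
        traj = make_traj(pos[0], ["W"] * 10, 5.0)
        traj = Trajectory(
            steps=np.arange(4, dtype=np.int64),
            wrapped=pos % 5.0,
            unwrapped=pos,
            species=np.array(["W"] * 10),
            bonds=np.empty((0, 2), dtype=np.int64),
            box_length=5.0,
            seed=0,
            dt=1.0,
        )
        res = msd(traj)
        assert np.allclose(res.msd, 0)
        assert res.diffusion_coefficient == 0

    def test_ballistic_quadratic(self):
        v = 0.7
        t = np.arange(10, dtype=float)
        un = np.zeros((10, 1, 3))
        un[:, 0, 0] = v * t
        traj = Trajectory(
            steps=np.arange(10, dtype=np.int64),
            wrapped=un % 20.0,
            unwrapped=un,
            species=np.array(["C1"]),
            bonds=np.empty((0, 2), dtype=np.int64),
            box_length=20.0,
            seed=0,
            dt=1.0,
        )
        res = msd(traj, "C1")
        assert np.allclose(res.msd, (v * t) ** 2)

    def test_random_walk_diffusion_recovered(self):
        """Gaussian walk with per-step variance s2 per axis: D = s2/(2 dt)."""
        rng = np.random.default_rng(99)
        n_beads, n_frames, s = 1000, 2000, 0.1
        steps = rng.normal(scale=s, size=(n_frames, n_beads, 3))
        steps[0] = 0.0
        un = np.cumsum(steps, axis=0)
        traj = Trajectory(
            steps=np.arange(n_frames, dtype=np.int64),
            wrapped=un % 50.0,
            unwrapped=un,
            species=np.array(["W"] * n_beads),
            bonds=np.empty((0, 2), dtype=np.int64),
            box_length=50.0,
            seed=0,
            dt=1.0,
        )
        res = msd(traj)
        expected = s**2 / 2.0
        assert res.diffusion_coefficient == pytest.approx(expected, rel=0.10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_multi_origin_estimator_tighter(self, seed):
        """Origin-averaged D stays within 10% across seeds (lower variance)."""
        rng = np.random.default_rng(seed)
        n_beads, n_frames, s = 500, 1000, 0.2
        incr = rng.normal(scale=s, size=(n_frames, n_beads, 3))
        incr[0] = 0.0
        un = np.cumsum(incr, axis=0)
        traj = Trajectory(
            steps=np.arange(n_frames, dtype=np.int64),
            wrapped=un % 100.0,
            unwrapped=un,
            species=np.array(["W"] * n_beads),
            bonds=np.empty((0, 2), dtype=np.int64),
            box_length=100.0,
            seed=seed,
            dt=1.0,
        )
        assert diffusion_coefficient(traj) == pytest.approx(s**2 / 2.0, rel=0.10)


class TestClusters:
    def test_all_singletons(self):
        pos = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 3, 0]]) + 1.0
        labels = clusters(pos, 8.0, cutoff=1.0)
        assert len(set(labels)) == 3

    def test_two_blobs(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 0.5, (20, 3)) + 1.0
        b = rng.uniform(0, 0.5, (20, 3)) + 6.0
        labels = clusters(np.vstack([a, b]), 10.0)
        assert len(set(labels)) == 2
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            clusters(np.zeros((2, 3)), 5.0, cutoff=0.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_union_find_oracle(self, seed):
        """Component structure equals a brute-force union-find on all pairs."""
        rng = np.random.default_rng(seed)
        L = rng.uniform(4.0, 7.0)
        n = 60 if seed < 49 else 300
        pos = rng.uniform(0, L, (n, 3))
        labels = clusters(pos, L, cutoff=1.0)

        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.rint(d / L)
        r2 = (d**2).sum(axis=-1)
        for i, j in zip(*np.where(np.triu(r2 < 1.0, k=1))):
            parent[find(i)] = find(j)
        oracle = np.array([find(i) for i in range(n)])
        # same partition: labels agree iff oracle roots agree
        for i in range(n):
            for j in range(i + 1, n):
                assert (labels[i] == labels[j]) == (oracle[i] == oracle[j])


class TestShellOrder:
    def test_concentric_shells_ranked(self):
        rng = np.random.default_rng(4)
        L = 14.0
        center = np.full(3, 7.0)
        pos, species = [], []
        for r, sp in [(1.0, "C1"), (2.0, "N1"), (3.0, "O4")]:
            v = rng.normal(size=(100, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            pos.append(center + r * v)
            species += [sp] * 100
        order = shell_order(np.vstack(pos), np.array(species), L, ["C1", "N1", "O4"],
                            center=center)
        assert order["C1"] < order["N1"] < order["O4"]

    def test_single_species_single_value(self):
        pos = np.random.default_rng(0).uniform(0, 5, (30, 3))
        order = shell_order(pos, np.array(["C1"] * 30), 5.0, ["C1"])
        assert set(order) == {"C1"}

    def test_missing_species_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            shell_order(np.zeros((2, 3)), np.array(["C1", "C1"]), 5.0, ["N1"])

    def test_trajectory_average_matches_static_frames(self):
        """Frame-averaged ordering equals the single-frame one when frames repeat."""
        rng = np.random.default_rng(6)
        L = 10.0
        pos = rng.uniform(3.0, 7.0, (40, 3))
        species = np.array(["C1"] * 20 + ["N1"] * 20)
        traj = make_traj(np.tile(pos, (5, 1, 1)), species, L)
        avg = shell_order_trajectory(traj, ["C1", "N1"], n_frames=3)
        single = shell_order(pos, species, L, ["C1", "N1"])
        assert avg["C1"] == pytest.approx(single["C1"])
        assert avg["N1"] == pytest.approx(single["N1"])


class TestContactFraction:
    def test_fully_mixed_lattice_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        pos = rng.uniform(0, 8.0, (n, 3))
        species = np.array(["C1", "W"] * (n // 2))  # random labels on random points
        phi = contact_fraction(pos, species, 8.0, "C1", "W")
        assert abs(phi - 0.5) < 0.03

    def test_separated_blobs_near_zero(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1.5, (100, 3)) + 1.0
        b = rng.uniform(0, 1.5, (100, 3)) + 6.0
        pos = np.vstack([a, b])
        species = np.array(["C1"] * 100 + ["W"] * 100)
        assert contact_fraction(pos, species, 10.0, "C1", "W") < 0.05


def test_largest_cluster_fraction_bounds():
    rng = np.random.default_rng(10)
    pos = rng.uniform(0, 6.0, (50, 3))
    f = largest_cluster_fraction(pos, 6.0)
    assert 0 < f <= 1
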