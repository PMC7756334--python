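"""Trajectory observables: RDF, dipole correlation, structural quantities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cutoffmd as md
from cutoffmd.dynamics import TrajectoryFrame


def frames_from_positions(list_of_positions, box):
    return [
        TrajectoryFrame(
            time=float(k), positions=np.asarray(p, dtype=float),
            velocities=np.zeros_like(np.asarray(p, dtype=float)), box=np.asarray(box, dtype=float),
        )
        for k, p in enumerate(list_of_positions)
    ]


class TestRDF:
    def test_fixed_pair_occupies_single_bin(self):
        box = [5.0, 5.0, 5.0]
        pos = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.73]])
        frames = frames_from_positions([pos], box)
        curve = md.rdf(frames, np.array([0]), np.array([1]), 0.02, 2.0)
        occupied = np.flatnonzero(curve.counts)
        assert len(occupied) == 1
        assert abs(curve.bin_centers[occupied[0]] - 0.73) <= 0.02

    def test_invariant_under_global_translation(self):
        rng = np.random.default_rng(1)
        box = np.array([4.0, 4.0, 4.0])
        pos = rng.uniform(0, 4, (50, 3))
        sel = np.arange(50)
        a = md.rdf(frames_from_positions([pos], box), sel, sel, 0.05, 1.9)
        b = md.rdf(frames_from_positions([pos + 1.234], box), sel, sel, 0.05, 1.9)
        assert np.array_equal(a.counts, b.counts)

    def test_ideal_gas_is_flat(self):
        rng = np.random.default_rng(2)
        box = np.array([6.0, 6.0, 6.0])
        n, n_frames, bw, r_max = 500, 100, 0.1, 2.0
        frames = frames_from_positions(
            [rng.uniform(0, 6, (n, 3)) for _ in range(n_frames)], box
        )
        sel = np.arange(n)
        curve = md.rdf(frames, sel, sel, bw, r_max)
        # the 4 pi r^2 dr normalization carries a known small-r bias against
        # the exact shell volume; the oracle expectation includes it
        r_lo = curve.bin_centers - bw / 2
        r_hi = curve.bin_centers + bw / 2
        exact_shell = 4 * np.pi / 3 * (r_hi**3 - r_lo**3)
        approx_shell = 4 * np.pi * curve.bin_centers**2 * bw
        mu = exact_shell / approx_shell
        expected_counts = exact_shell * n * (n - 1) / box.prod() * n_frames
        beyond = curve.bin_centers > 2 * bw
        se = mu[beyond] / np.sqrt(expected_counts[beyond])
        assert np.all(np.abs(curve.values[beyond] - mu[beyond]) <= 3 * se + 0.01)

    def test_bin_mass_conservation_matches_brute_force(self):
        rng = np.random.default_rng(3)
        box = np.array([4.0, 4.0, 4.0])
        pos = rng.uniform(0, 4, (40, 3))
        r_max = 1.9
        curve = md.rdf(frames_from_positions([pos], box), np.arange(40), np.arange(40), 0.05, r_max)
        delta = pos[:, None, :] - pos[None, :, :]
        delta -= box * np.rint(delta / box)
        d = np.linalg.norm(delta, axis=-1)
        iu = np.triu_indices(40, k=1)
        expected = 2 * int((d[iu] < r_max).sum())  # ordered pairs
        assert curve.counts.sum() == expected

    def test_oversized_rmax_rejected(self):
        frames = frames_from_positions([np.zeros((2, 3))], [3.0, 3.0, 3.0])
        with pytest.raises(ValueError, match="half"):
            md.rdf(frames, np.array([0]), np.array([1]), 0.05, 2.0)


class TestDipoleCorrelation:
    def test_aligned_dipoles_give_unity(self, water8):
        # rotate every water identically so all dipoles are parallel
        base = water8.positions[:3] - water8.positions[0]
        pos = water8.positions.copy()
        for m in range(8):
            pos[3 * m: 3 * m + 3] = water8.positions[3 * m] + base
        frames = frames_from_positions([pos], water8.box)
        curve = md.dipole_correlation(frames, water8, 0.05, 0.6)
        occupied = curve.counts > 0
        assert np.allclose(curve.values[occupied], 1.0, atol=1e-10)

    def test_antiparallel_pair_gives_minus_one(self):
        # a 2-water system with the second flipped relative to the first
        from test_pairlist import two_waters_at

        system = two_waters_at(0.5)
        pos = system.positions.copy()
        mol0 = pos[:3] - pos[0]
        pos[3:6] = pos[3] - mol0  # mirrored geometry: dipole reversed
        frames = frames_from_positions([pos], system.box)
        curve = md.dipole_correlation(frames, system, 0.05, 1.4)
        occupied = np.flatnonzero(curve.counts)
        assert len(occupied) == 1
        assert curve.values[occupied[0]] == pytest.approx(-1.0, abs=1e-10)

    def test_random_orientations_decorrelate(self):
        rng = np.random.default_rng(5)
        n, n_frames = 125, 40
        box = np.full(3, 2.8)
        system = md.build_water_box(n, 2.8, seed=6)
        frame_pos = []
        for _ in range(n_frames):
            pos = system.positions.reshape(n, 3, 3).copy()
            base = pos[:, :, :] - pos[:, :1, :]
            q = rng.normal(size=(n, 4))
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            w, x, y, z = q.T
            rot = np.stack([
                np.stack([1 - 2 * (y*y + z*z), 2 * (x*y - w*z), 2 * (x*z + w*y)], -1),
                np.stack([2 * (x*y + w*z), 1 - 2 * (x*x + z*z), 2 * (y*z - w*x)], -1),
                np.stack([2 * (x*z - w*y), 2 * (y*z + w*x), 1 - 2 * (x*x + y*y)], -1),
            ], 1)
            rotated = np.einsum("nij,naj->nai", rot, base) + pos[:, :1, :]
            frame_pos.append(rotated.reshape(-1, 3))
        frames = frames_from_positions(frame_pos, box)
        curve = md.dipole_correlation(frames, system, 0.1, 1.3)
        occupied = curve.counts > 20
        se = 1.0 / np.sqrt(3 * curve.counts[occupied])
        assert np.all(np.abs(curve.values[occupied]) <= 3 * se + 0.02)
        assert np.nanmax(np.abs(curve.values)) <= 1.0

    def test_apolar_molecule_rejected(self):
        from test_dynamics import free_particles

        system = free_particles(4, 3.0)
        frames = frames_from_positions([system.positions], system.box)
        with pytest.raises(ValueError, match="apolar"):
            md.dipole_correlation(frames, system, 0.1, 1.0)


class TestStructuralObservables:
    def test_radius_of_gyration_basics(self):
        assert md.radius_of_gyration(np.zeros((1, 3)), np.array([12.0])) == 0.0
        two = np.array([[0.0, 0, 0], [0.2, 0, 0]])
        assert md.radius_of_gyration(two, np.array([5.0, 5.0])) == pytest.approx(0.1)

    def test_radius_of_gyration_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 16, 20)
        base = md.radius_of_gyration(pos, masses)
        theta = 0.7
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        moved = pos @ rot.T + np.array([1.0, -2.0, 0.5])
        assert md.radius_of_gyration(moved, masses) == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize(
        "rmsd,n,expected",
        [(0.3, 100, 0.3), (0.0, 250, 0.0), (0.2, 400, 0.2 / (1 + np.log(2)))],
    )
    def test_rmsd100_normalization(self, rmsd, n, expected):
        assert md.rmsd100(rmsd, n) == pytest.approx(expected, rel=1e-12)

    def test_rmsd100_flags_below_validity_range(self):
        assert np.isnan(md.rmsd100(0.2, 10))

    def test_noe_average_hand_values(self):
        assert md.noe_average([0.3, 0.3, 0.3]) == pytest.approx(0.3, rel=1e-12)
        expected = (0.5 * (0.2**-3 + 0.4**-3)) ** (-1.0 / 3.0)
        assert md.noe_average([0.2, 0.4]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2423, abs=5e-4)

    @given(st.lists(st.floats(min_value=0.05, max_value=2.0), min_size=1, max_size=30))
    def test_noe_average_biased_toward_short_distances(self, series):
        assert md.noe_average(series) <= np.mean(series) + 1e-12


class TestHydrogenBonds:
    def geometry(self, dist, angle_deg):
        """Donor-H along x; acceptor placed at ``dist`` from the donor such
        that the acceptor-hydrogen-donor angle is ``angle_deg``."""
        from scipy.optimize import brentq

        donor = np.array([0.0, 0.0, 0.0])
        hydrogen = np.array([0.1, 0.0, 0.0])
        theta = np.radians(angle_deg)
        # H->D points along -x; H->A makes the requested angle with it
        u = np.array([-np.cos(theta), np.sin(theta), 0.0])
        length = brentq(
            lambda L: np.linalg.norm(hydrogen + L * u - donor) - dist, 1e-4, 1.0
        )
        acceptor = hydrogen + length * u
        return donor, hydrogen, acceptor

    @pytest.mark.parametrize(
        "dist,angle,expected",
        [(0.24, 150.0, 1), (0.26, 150.0, 0), (0.24, 119.0, 0)],
    )
    def test_geometric_criterion(self, dist, angle, expected):
        donor, hydrogen, acceptor = self.geometry(dist, angle)
        pos = np.stack([donor, hydrogen, acceptor])
        box = np.full(3, 10.0)
        n = md.count_hbonds(pos, box, np.array([0]), np.array([1]), np.array([2]))
        assert n == expected

    def test_hydrogen_acceptor_switch(self):
        donor, hydrogen, acceptor = self.geometry(0.29, 160.0)
        pos = np.stack([donor, hydrogen, acceptor])
        box = np.full(3, 10.0)
        assert md.count_hbonds(pos, box, [0], [1], [2]) == 0
        ha = np.linalg.norm(acceptor - hydrogen)
        assert ha < 0.25
        assert (
            md.count_hbonds(pos, box, [0], [1], [2], distance_between="hydrogen-acceptor")
            == 1
        )


class TestBathTemperatureSeries:
    def make_log(self):
        return pd.DataFrame(
            {
                "time": [0.0, 1.0, 2.0, 3.0],
                "T_solute": [300.0, 300.0, 300.0, 300.0],
                "T_solvent": [290.0, 300.0, 310.0, 320.0],
            }
        )

    def test_constant_series_has_zero_sd(self):
        _, summary = md.bath_temperature_series(self.make_log())
        solute = summary[summary["bath"] == "solute"].iloc[0]
        assert solute["sd"] == 0.0
        assert solute["mean"] == 300.0

    def test_mean_matches_hand_arithmetic(self):
        _, summary = md.bath_temperature_series(self.make_log())
        solvent = summary[summary["bath"] == "solvent"].iloc[0]
        assert solvent["mean"] == pytest.approx((290 + 300 + 310 + 320) / 4)

    def test_window_drops_excluded_rows(self):
        series, summary = md.bath_temperature_series(self.make_log(), window=(1.0, 2.0))
        assert len(series) == 2
        solvent = summary[summary["bath"] == "solvent"].iloc[0]
        assert solvent["mean"] == pytest.approx(305.0)
        assert solvent["n"] == 2

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="temperature"):
            md.bath_temperature_series(pd.DataFrame({"time": [0.0]}))
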