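"""Trajectory observables: contacts, persistence, distances, Rg, globularity."""

import math
from dataclasses import replace

import numpy as np
import pytest

from ionsyn.md_metrics import (
    RegionPartition,
    globularity,
    ion_proximity_frequency,
    radius_of_gyration,
    region_com_distance,
    water_persistence,
)
from ionsyn.presets import CONDITION_PRESETS, IonSpec
from ionsyn.synthetic_data import make_toy_trajectory
from ionsyn.trajectory import ION, PROTEIN, WATER, Trajectory


def _manual_trajectory(coords, kind, species, residue, masses, dt=5.0):
    return Trajectory(
        coords=np.asarray(coords, float),
        kind=np.array(kind),
        species=np.array(species),
        residue=np.array(residue, int),
        masses=np.array(masses, float),
        frame_dt_ps=dt,
    )


class TestRegionPartition:
    def test_default_scheme_nac_ends_at_95(self):
        part = RegionPartition.default()
        assert part.ranges["nac"] == (61, 95)
        assert part.ranges["n_term"] == (1, 60)
        assert part.ranges["c_term"] == (96, 140)

    def test_fine_scheme_early_late_splits(self):
        part = RegionPartition.fine()
        assert part.ranges["n_term_early"] == (1, 30)
        assert part.ranges["nac_late"] == (79, 95)

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            RegionPartition({"a": (1, 10), "b": (10, 20)})


class TestRadiusOfGyration:
    def test_single_atom_is_zero(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_unit_cube_corners_closed_form(self):
        corners = np.array(
            [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
        )
        assert radius_of_gyration(corners) == pytest.approx(math.sqrt(3) / 2)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 12, 20)
        a = radius_of_gyration(pts, masses)
        b = radius_of_gyration(pts + np.array([10.0, -40.0, 3.0]), masses)
        assert a == pytest.approx(b)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        assert radius_of_gyration(pts) == pytest.approx(radius_of_gyration(pts @ rot.T))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((0, 3)))


class TestRegionComDistance:
    def test_two_rigid_point_groups(self):
        coords = np.zeros((3, 2, 3))
        coords[:, 1, 0] = 10.0
        traj = _manual_trajectory(
            coords, [PROTEIN, PROTEIN], ["", ""], [1, 2], [1.0, 1.0]
        )
        part = RegionPartition({"a": (1, 1), "b": (2, 2)})
        series, _, _ = region_com_distance(traj, part, ("a", "b"))
        np.testing.assert_allclose(series, 10.0)

    def test_mass_weighted_com(self):
        """Masses (1, 3) at x = 0 and 4 put the COM at x = 3."""
        coords = np.zeros((2, 3, 3))
        coords[:, 1, 0] = 4.0
        coords[:, 2, 0] = -5.0
        traj = _manual_trajectory(
            coords, [PROTEIN] * 3, [""] * 3, [1, 1, 2], [1.0, 3.0, 1.0]
        )
        part = RegionPartition({"a": (1, 1), "b": (2, 2)})
        series, _, _ = region_com_distance(traj, part, ("a", "b"))
        np.testing.assert_allclose(series, 8.0)  # |3 - (-5)|

    def test_unknown_region_rejected(self, na_ca_trajectory):
        traj, _ = na_ca_trajectory
        with pytest.raises(KeyError):
            region_com_distance(traj, RegionPartition.default(), ("n_term", "tail"))

    def test_global_translation_invariance(self, na_ca_trajectory):
        traj, _ = na_ca_trajectory
        part = RegionPartition.default()
        base, _, _ = region_com_distance(traj, part, ("n_term", "c_term"))
        shifted = Trajectory(
            traj.coords + np.array([5.0, -2.0, 9.0]), traj.kind, traj.species,
            traj.residue, traj.masses, traj.frame_dt_ps,
        )
        moved, _, _ = region_com_distance(shifted, part, ("n_term", "c_term"))
        np.testing.assert_allclose(base, moved, rtol=1e-12)


class TestIonProximity:
    def test_fixed_adjacent_ion_gives_unit_frequency(self):
        n_frames = 5
        coords = np.zeros((n_frames, 3, 3))
        coords[:, 1, 0] = 50.0  # residue 2 far away
        coords[:, 2, :] = [2.0, 0.0, 0.0]  # ion next to residue 1
        traj = _manual_trajectory(
            coords, [PROTEIN, PROTEIN, ION], ["", "", "NA"], [1, 2, -1], [110.0, 110.0, 23.0]
        )
        freq, residence = ion_proximity_frequency(traj, "NA", cutoff=3.5)
        assert freq[1] == 1.0 and freq[2] == 0.0
        assert residence["mean_residence_ps"].iloc[0] == pytest.approx(5 * 5.0)

    def test_zero_cutoff_gives_zero_frequencies(self):
        coords = np.zeros((3, 2, 3))
        traj = _manual_trajectory(
            coords, [PROTEIN, ION], ["", "CA"], [1, -1], [110.0, 40.0]
        )
        freq, _ = ion_proximity_frequency(traj, "CA", cutoff=0.0)
        assert (freq == 0).all()

    def test_missing_species_rejected(self, na_ca_trajectory):
        traj, _ = na_ca_trajectory
        with pytest.raises(ValueError):
            ion_proximity_frequency(traj, "MG")

    def test_sticky_divalent_outlives_monovalent(self, na_ca_trajectory):
        """Divalent residence at acidic C-terminal sites exceeds monovalent."""
        traj, _ = na_ca_trajectory
        _, res_ca = ion_proximity_frequency(traj, "CA")
        _, res_na = ion_proximity_frequency(traj, "NA")
        assert res_ca["mean_residence_ps"].mean() > 5 * res_na["mean_residence_ps"].mean()

    def test_divalent_contacts_concentrate_at_acidic_cterm(self, na_ca_trajectory):
        traj, truth = na_ca_trajectory
        freq, _ = ion_proximity_frequency(traj, "CA")
        acidic = truth["acidic_cterm_sites"]
        assert freq[acidic].mean() > 10 * freq[[r for r in freq.index if r < 60]].mean()

    def test_null_stickiness_removes_species_asymmetry(self):
        """Equal stickiness and targets -> statistically equal contact rates."""
        spec = IonSpec(
            n_divalent=40, n_monovalent=40, divalent_stickiness=0.0,
            monovalent_stickiness=0.0, divalent_targets="any", monovalent_targets="any",
        )
        preset = replace(CONDITION_PRESETS["na_ca"], ion_spec=spec)
        traj, _ = make_toy_trajectory(preset, n_residues=60, n_frames=200, n_waters=10, seed=9)
        _, res_ca = ion_proximity_frequency(traj, "CA")
        _, res_na = ion_proximity_frequency(traj, "NA")
        f_ca = res_ca["contact_fraction"].mean()
        f_na = res_na["contact_fraction"].mean()
        assert abs(f_ca - f_na) < 0.05

    def test_brute_force_contact_oracle(self, na_ca_trajectory):
        """All-pairs distance loop reproduces the tree-based frequencies."""
        traj, _ = na_ca_trajectory
        sub = Trajectory(
            traj.coords[:20], traj.kind, traj.species, traj.residue,
            traj.masses, traj.frame_dt_ps,
        )
        freq, _ = ion_proximity_frequency(sub, "CA", cutoff=3.5)
        ions = sub.select(ION, "CA")
        prot = sub.protein_index
        residues = np.unique(sub.residue[prot])
        brute = {int(r): 0 for r in residues}
        for f in range(sub.n_frames):
            for r in residues:
                atoms = prot[sub.residue[prot] == r]
                d = np.linalg.norm(
                    sub.coords[f, atoms][:, None, :] - sub.coords[f, ions][None, :, :], axis=2
                )
                if (d <= 3.5).any():
                    brute[int(r)] += 1
        for r in residues:
            assert freq[r] == pytest.approx(brute[int(r)] / sub.n_frames)


class TestWaterPersistence:
    def test_immobile_water_spans_full_window(self):
        """A water that never leaves a 601-frame window persists 3000 ps."""
        preset = replace(CONDITION_PRESETS["no_salt"], water_exchange_rate=0.0)
        traj, _ = make_toy_trajectory(preset, n_residues=20, n_frames=601, n_waters=5, seed=1)
        wp = water_persistence(traj)
        assert wp.mean_persistence_ps == pytest.approx(3000.0)

    def test_water_always_outside_shell_excluded(self):
        coords = np.zeros((4, 2, 3))
        coords[:, 1, :] = 100.0
        traj = _manual_trajectory(
            coords, [PROTEIN, WATER], ["", ""], [1, -1], [110.0, 18.0]
        )
        wp = water_persistence(traj)
        assert wp.durations_ps.size == 0

    def test_single_frame_rejected(self):
        coords = np.zeros((1, 2, 3))
        traj = _manual_trajectory(
            coords, [PROTEIN, WATER], ["", ""], [1, -1], [110.0, 18.0]
        )
        with pytest.raises(ValueError):
            water_persistence(traj)

    def test_escape_rate_recovered_within_10_percent(self):
        """Geometric shell-residence: 1/mean(run) estimates the escape rate."""
        preset = replace(CONDITION_PRESETS["no_salt"], water_exchange_rate=0.05)
        traj, _ = make_toy_trajectory(preset, n_residues=30, n_frames=601, n_waters=200, seed=3)
        wp = water_persistence(traj)
        assert wp.escape_rate_per_frame == pytest.approx(0.05, rel=0.10)

    def test_escape_rate_ratio_recovered(self):
        """Presets at rates 0.01 vs 0.05 give a fitted-rate ratio near 5."""
        rates = {}
        for rate in (0.01, 0.05):
            preset = replace(CONDITION_PRESETS["no_salt"], water_exchange_rate=rate)
            traj, _ = make_toy_trajectory(
                preset, n_residues=30, n_frames=601, n_waters=200, seed=13
            )
            rates[rate] = water_persistence(traj).escape_rate_per_frame
        assert rates[0.05] / rates[0.01] == pytest.approx(5.0, rel=0.10)


class TestGlobularity:
    def _isotropic_traj(self, n_frames=400, sigma=np.ones(3), seed=0, n_atoms=8):
        rng = np.random.default_rng(seed)
        base = np.arange(n_atoms)[:, None] * np.array([3.8, 0.0, 0.0])
        coords = base[None, :, :] + rng.normal(0, sigma, size=(n_frames, n_atoms, 3))
        return _manual_trajectory(
            coords, [PROTEIN] * n_atoms, [""] * n_atoms,
            np.arange(1, n_atoms + 1), [110.0] * n_atoms,
        )

    def test_isotropic_fluctuations_approach_unity(self):
        traj = self._isotropic_traj(n_frames=2000)
        shapes = globularity(traj, window=6, align=False, full_chain=False)
        assert shapes[0].globularity > 0.85

    def test_uniaxial_fluctuations_give_small_g(self):
        traj = self._isotropic_traj(n_frames=500, sigma=np.array([1.0, 1e-3, 1e-3]))
        shapes = globularity(traj, window=6, align=False, full_chain=False)
        assert shapes[0].globularity < 0.01

    def test_known_diagonal_covariance(self):
        """diag(4, 1, 1) fluctuations -> g = 0.25 and eig ratio = 4."""
        traj = self._isotropic_traj(n_frames=4000, sigma=np.array([2.0, 1.0, 1.0]), seed=5)
        shapes = globularity(traj, window=6, align=False, full_chain=False)
        assert shapes[0].globularity == pytest.approx(0.25, rel=0.1)
        assert shapes[0].eig_ratio == pytest.approx(4.0, rel=0.1)

    def test_window_below_three_residues_rejected(self, na_ca_trajectory):
        traj, _ = na_ca_trajectory
        with pytest.raises(ValueError):
            globularity(traj, window=2)

    def test_windowed_output_covers_chain(self, na_ca_trajectory):
        traj, _ = na_ca_trajectory
        shapes = globularity(traj, window=6, stride=1)
        assert len(shapes) == 135 + 1  # sliding windows + full chain
        assert all(0 < s.globularity <= 1 for s in shapes if s.valid)
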