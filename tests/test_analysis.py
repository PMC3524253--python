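"""Barrier extraction, convergence/drift reports, superposition, toy system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from barriermap import (
    BackendConfig,
    EnergyChannel,
    EnergyRecord,
    Frame,
    EnergyProfile,
    convergence_report,
    drift_report,
    extract_barrier,
    kabsch_rmsd,
    make_toy_system,
    write_pdb,
)
from conftest import make_dimer, point_cloud_model

CH = EnergyChannel.CONVENTIONAL_SP


def profile_from_energies(energies, channel=CH, scf_cycles=None, label=""):
    """Wrap a list of energies (None = failed frame) into an EnergyProfile."""
    template = make_dimer(1.0)
    frames = []
    for i, e in enumerate(energies):
        f = Frame(index=i, structure=template.copy(), constrained=0 < i < len(energies) - 1,
                  rc_atoms=(1, 2))
        if e is not None:
            f.energies.append(EnergyRecord(channel=channel, heat_of_formation=float(e)))
            if scf_cycles is not None:
                f.energies[-1].scf_cycles = scf_cycles[i]
            f.status = f.status.OPTIMIZED
        else:
            f.status = f.status.FAILED
        frames.append(f)
    return EnergyProfile(frames=frames, reference_channel=channel, label=label)


def barrier_oracle(energies):
    """Independent enumeration of the rule: scan for the highest point (first
    on ties), then scan everything before it for the lowest point."""
    i_max = 0
    for i, e in enumerate(energies):
        if e > energies[i_max]:
            i_max = i
    if i_max == 0:
        return 0.0
    lowest = energies[0]
    for e in energies[1:i_max]:
        if e < lowest:
            lowest = e
    return energies[i_max] - lowest


class TestExtractBarrier:
    def test_simple_rise_and_fall(self):
        est = extract_barrier(profile_from_energies([0, 2, 5, 3, 1]))
        assert (est.barrier, est.max_frame, est.reference_frame) == (5, 2, 0)

    def test_dip_below_start_is_the_reference(self):
        est = extract_barrier(profile_from_energies([0, -1, 4, 2]))
        assert est.barrier == 5
        assert est.reference_frame == 1

    def test_translation_invariance_exact(self):
        # quarter-step energies and a power-of-two shift: float-exact arithmetic
        rng = np.random.default_rng(3)
        e = rng.integers(-400, 400, 12) / 4.0
        a = extract_barrier(profile_from_energies(e))
        b = extract_barrier(profile_from_energies(e + 1024.0))
        assert a.barrier == b.barrier
        assert (a.max_frame, a.reference_frame) == (b.max_frame, b.reference_frame)

    def test_ties_break_toward_lowest_index(self):
        est = extract_barrier(profile_from_energies([0, 3, 1, 3, 0]))
        assert est.max_frame == 1

    def test_maximum_at_first_frame_means_flat(self):
        est = extract_barrier(profile_from_energies([5, 1, 0]))
        assert est.barrier == 0.0
        assert est.reference_frame == est.max_frame

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=2,
            max_size=20,
        )
    )
    def test_matches_exhaustive_oracle(self, energies):
        est = extract_barrier(profile_from_energies(energies))
        assert est.barrier == pytest.approx(barrier_oracle(energies), abs=1e-12)

    def test_all_failed_frames_rejected(self):
        with pytest.raises(ValueError):
            extract_barrier(profile_from_energies([None, None, None]))


class TestConvergenceReport:
    def test_single_profile_one_row(self):
        table = convergence_report([profile_from_energies([0, 4, 1], label="PM6//M(C15, G0.5)")])
        assert len(table) == 1
        assert table.barrier.iloc[0] == 4

    def test_identical_profiles_zero_deltas(self):
        p = [0.0, 3.0, 1.0, 0.5]
        table = convergence_report(
            [profile_from_energies(p, label="PM6//M(C15, G0.5)"),
             profile_from_energies(p, label="PM6//M(C12, G1.0)")]
        )
        np.testing.assert_array_equal(table.attrs["frame_deltas"].to_numpy(), 0.0)

    def test_injected_offsets_recovered_in_deltas(self):
        base = np.array([0.0, 3.0, 5.0, 1.0])
        offsets = np.array([0.5, -0.25, 1.0, 0.0])
        table = convergence_report(
            [profile_from_energies(base, label="PM6//M(C9, G5.0)"),
             profile_from_energies(base + offsets, label="PM6//M(C15, G0.5)")]
        )
        deltas = table.attrs["frame_deltas"].iloc[:, 0].to_numpy()
        np.testing.assert_allclose(deltas, -offsets, atol=1e-12)

    def test_monotone_flag_tracks_strictness_ordering(self):
        # stricter config (larger cutoff, smaller GCC) -> lower barrier
        profiles = [
            profile_from_energies([0, 13.0, 1], label="PM6//M(C9, G5.0)"),
            profile_from_energies([0, 7.8, 1], label="PM6//M(C12, G1.0)"),
            profile_from_energies([0, 6.0, 1], label="PM6//M(C15, G0.5)"),
        ]
        assert convergence_report(profiles).attrs["monotone_with_strictness"]
        profiles[0], profiles[2] = profiles[2], profiles[0]
        # labels still encode strictness, so the flag is order-independent
        assert convergence_report(profiles).attrs["monotone_with_strictness"]

    def test_mismatched_frame_counts_rejected(self):
        with pytest.raises(ValueError):
            convergence_report(
                [profile_from_energies([0, 1, 2]), profile_from_energies([0, 1])]
            )


class TestDriftReport:
    def _two_channel_profile(self, mozyme, conventional, scf=None):
        template = make_dimer(1.0)
        frames = []
        for i, (em, ec) in enumerate(zip(mozyme, conventional)):
            f = Frame(index=i, structure=template.copy(), constrained=False, rc_atoms=(1, 2))
            if em is not None:
                f.energies.append(
                    EnergyRecord(EnergyChannel.MOZYME, em, scf_cycles=scf[i] if scf else None)
                )
            if ec is not None:
                f.energies.append(EnergyRecord(CH, ec))
            f.status = f.status.OPTIMIZED
            frames.append(f)
        return EnergyProfile(frames=frames, reference_channel=CH)

    def test_identical_channels_zero_differences(self):
        e = [1.0, 2.0, 3.0]
        report = drift_report(self._two_channel_profile(e, e))
        col = f"{EnergyChannel.CONVENTIONAL_SP.value} - {EnergyChannel.MOZYME.value}"
        np.testing.assert_array_equal(report.table[col].to_numpy(), 0.0)

    def test_endpoint_drift_pattern_flagged(self):
        # orthogonality loss concentrated in the unconstrained endpoint frames
        conventional = [0.0] * 12
        mozyme = [0.0] * 12
        mozyme[0], mozyme[11] = 2.5, 4.0
        report = drift_report(self._two_channel_profile(mozyme, conventional))
        col = f"{EnergyChannel.CONVENTIONAL_SP.value} - {EnergyChannel.MOZYME.value}"
        nonzero = report.table.loc[report.table[col] != 0, "frame"].tolist()
        assert nonzero == [0, 11]

    def test_rows_are_frames_with_both_channels(self):
        report = drift_report(
            self._two_channel_profile([1.0, None, 3.0], [1.0, 2.0, 3.0])
        )
        assert report.table.frame.tolist() == [0, 2]

    def test_drift_correlates_with_scf_cycles(self):
        conventional = [0.0] * 5
        scf = [494, 25, 100, 437, 1896]
        mozyme = [0.005 * c for c in scf]  # drift grows with SCF history
        report = drift_report(self._two_channel_profile(mozyme, conventional, scf))
        assert report.cycle_correlation == pytest.approx(1.0, abs=1e-9)


def rmsd_bruteforce(pa, pb):
    """Oracle: minimize RMSD over rotation vectors directly (multi-start)."""
    pa = pa - pa.mean(axis=0)
    pb = pb - pb.mean(axis=0)

    def cost(rv):
        diff = pa - Rotation.from_rotvec(rv).apply(pb)
        return np.sqrt((diff**2).sum() / len(pa))

    best = np.inf
    for start in (
        [0, 0, 0], [np.pi / 2, 0, 0], [0, np.pi / 2, 0], [0, 0, np.pi / 2],
        [np.pi, 0.5, -0.5], [-1.2, 2.0, 0.3],
    ):
        res = minimize(cost, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestKabschRmsd:
    def test_identical_structures_zero(self, toy):
        full, _, _ = toy
        assert kabsch_rmsd(full, full) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self, toy):
        full, _, _ = toy
        moved = full.copy()
        rot = Rotation.from_rotvec([0.4, -0.2, 1.1])
        xyz = rot.apply(moved.coords()) + np.array([5.0, -3.0, 2.0])
        moved.set_coords(xyz)
        assert kabsch_rmsd(full, moved) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, toy):
        full, _, _ = toy
        moved = full.copy()
        rng = np.random.default_rng(2)
        moved.set_coords(moved.coords() + rng.normal(0, 0.3, moved.coords().shape))
        assert kabsch_rmsd(full, moved) == pytest.approx(kabsch_rmsd(moved, full), abs=1e-12)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_bruteforce_rotation_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        pa = rng.normal(0, 2, (5, 3))
        pb = pa + rng.normal(0, 0.4, (5, 3))
        a, b = point_cloud_model(pa), point_cloud_model(pb)
        assert kabsch_rmsd(a, b) == pytest.approx(rmsd_bruteforce(pa, pb), abs=1e-6)

    def test_hydrogens_excluded_by_default(self, toy):
        full, _, _ = toy
        moved = full.copy()
        idx = {a.serial: i for i, a in enumerate(moved.atoms)}
        for a in moved.atoms:
            if a.element == "H":
                a.position = a.position + 5.0  # garbage H positions
        assert kabsch_rmsd(full, moved) == pytest.approx(0.0, abs=1e-9)
        assert kabsch_rmsd(full, moved, include_hydrogens=True) > 0.5

    def test_collinear_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        a, b = point_cloud_model(pts), point_cloud_model(pts)
        with pytest.raises(ValueError, match="collinear"):
            kabsch_rmsd(a, b)

    def test_too_few_atoms_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], float)
        with pytest.raises(ValueError, match=">= 3"):
            kabsch_rmsd(point_cloud_model(pts), point_cloud_model(pts))


class TestMakeToySystem:
    def test_same_seed_byte_identical_pdb(self):
        a = make_toy_system(seed=7)[0]
        b = make_toy_system(seed=7)[0]
        assert write_pdb(a) == write_pdb(b)

    def test_different_seeds_differ(self):
        a = make_toy_system(seed=1)[0]
        b = make_toy_system(seed=2)[0]
        assert write_pdb(a) != write_pdb(b)

    def test_es_reaction_coordinate_distance(self, toy):
        _, pair, _ = toy
        idx = pair.es.serial_index()
        d = np.linalg.norm(
            pair.es.atoms[idx[pair.rc.nucleophile_atom]].position
            - pair.es.atoms[idx[pair.rc.electrophile_atom]].position
        )
        assert d == pytest.approx(3.5, abs=1e-9)

    def test_ti_reaction_coordinate_distance(self, toy):
        _, pair, _ = toy
        idx = pair.ti.serial_index()
        d = np.linalg.norm(
            pair.ti.atoms[idx[pair.rc.nucleophile_atom]].position
            - pair.ti.atoms[idx[pair.rc.electrophile_atom]].position
        )
        assert d == pytest.approx(1.5, abs=1e-9)

    def test_es_is_a_stationary_point_of_the_surrogate(self, toy, toy_backend):
        _, pair, _ = toy
        e, g = toy_backend(pair.es)
        assert e == pytest.approx(0.0, abs=1e-9)
        assert np.abs(g).max() < 1e-9

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            make_toy_system(seed=1, n_residues=2)
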