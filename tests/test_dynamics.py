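"""Trajectory statistics, covariance modes and the gated correlation matrix."""

import numpy as np
import pytest

import groovescan as gs
from groovescan.dynamics import (
    CorrelationMatrix,
    Trajectory,
    covariance_modes,
    domain_block_summary,
    write_trajectory,
)
from groovescan.structure import DomainMap


def _random_structure(n, seed=0, spread=5.0):
    return np.random.default_rng(seed).normal(0, spread, (n, 3))


class TestTrajectoryIO:
    @pytest.mark.parametrize("fmt", ["xyz", "csv"])
    def test_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(1)
        traj = Trajectory(rng.normal(0, 3, (10, 5, 3)))
        path = tmp_path / f"t.{fmt}"
        write_trajectory(traj, path, format=fmt)
        back = gs.read_trajectory(path, format=fmt)
        assert back.coords.shape == (10, 5, 3)
        assert np.allclose(back.coords, traj.coords, atol=1e-5)
        assert back.labels == traj.labels

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            Trajectory(np.zeros((1, 5, 3)))

    def test_ragged_frames_rejected(self, tmp_path):
        path = tmp_path / "ragged.xyz"
        path.write_text(
            "2\nframe 0\nR1 0 0 0\nR2 1 0 0\n"
            "3\nframe 1\nR1 0 0 0\nR2 1 0 0\nR3 2 0 0\n"
        )
        with pytest.raises(ValueError):
            gs.read_trajectory(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "bad.xyz"
        path.write_text("1\nframe 0\nR1 0 zero 0\n1\nframe 1\nR1 0 0 0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            gs.read_trajectory(path)


class TestDiscardConcatenate:
    def test_three_replicas_of_48_minus_8_gives_120(self):
        reps = [
            Trajectory(_random_structure(4, s)[None] + np.zeros((48, 4, 3))
                       + np.random.default_rng(s).normal(0, 0.1, (48, 4, 3)))
            for s in range(3)
        ]
        macro = gs.discard_and_concatenate(reps, discard=8)
        assert macro.n_frames == 120

    def test_zero_discard_is_plain_concatenation(self):
        reps = [Trajectory(np.random.default_rng(s).normal(size=(5, 3, 3))) for s in range(2)]
        macro = gs.discard_and_concatenate(reps, discard=0)
        assert macro.n_frames == 10
        assert np.allclose(macro.coords[:5], reps[0].coords)

    def test_discard_at_least_replica_length_rejected(self):
        reps = [Trajectory(np.random.default_rng(0).normal(size=(5, 3, 3)))]
        with pytest.raises(ValueError):
            gs.discard_and_concatenate(reps, discard=5)

    def test_residue_count_mismatch_rejected(self):
        reps = [
            Trajectory(np.random.default_rng(0).normal(size=(5, 3, 3))),
            Trajectory(np.random.default_rng(1).normal(size=(5, 4, 3))),
        ]
        with pytest.raises(ValueError, match="mismatch"):
            gs.discard_and_concatenate(reps, discard=0)


class TestRmsdRmsf:
    def test_static_trajectory_is_flat_zero(self):
        base = _random_structure(6)
        traj = Trajectory(np.tile(base, (8, 1, 1)))
        assert np.allclose(gs.rmsd_series(traj), 0.0, atol=1e-12)
        assert np.allclose(gs.rmsf_profile(traj), 0.0, atol=1e-12)

    def test_rigid_rotation_removed_by_superposition(self):
        base = _random_structure(7, seed=2)
        rng = np.random.default_rng(3)
        frames = []
        for _ in range(6):
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(Q) < 0:
                Q[:, 0] *= -1
            frames.append(base @ Q.T + rng.normal(0, 10, 3))
        traj = Trajectory(np.stack(frames))
        assert np.allclose(gs.rmsd_series(traj), 0.0, atol=1e-9)

    def test_two_frame_hand_case(self):
        # symmetric 1-D stretch: optimal fit leaves +-0.5 A per atom
        f0 = np.array([[-0.5, 0, 0], [0.5, 0, 0]])
        f1 = np.array([[-1.0, 0, 0], [1.0, 0, 0]])
        traj = Trajectory(np.stack([f0, f1]))
        rmsd = gs.rmsd_series(traj, reference_frame=0)
        assert np.isclose(rmsd[0], 0.0, atol=1e-12)
        assert np.isclose(rmsd[1], 0.5, atol=1e-9)

    def test_invariance_under_global_transform_of_every_frame(self):
        rng = np.random.default_rng(4)
        coords = _random_structure(5)[None] + rng.normal(0, 0.3, (12, 5, 3))
        traj = Trajectory(coords)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = Trajectory(coords @ Q.T + np.array([4.0, -2.0, 9.0]))
        assert np.allclose(gs.rmsd_series(traj), gs.rmsd_series(moved), atol=1e-9)
        assert np.allclose(gs.rmsf_profile(traj), gs.rmsf_profile(moved), atol=1e-9)


class TestCovarianceModes:
    def test_known_1d_oscillation(self):
        base = _random_structure(4, seed=5)
        sig = np.random.default_rng(6).normal(0, 1.5, 200)
        frames = base[None] + np.einsum("f,x->fx", sig, np.array([1.0, 0, 0]))[:, None, :]
        modes = covariance_modes(Trajectory(frames), 2)
        # one coherent x-mode carrying all the variance: eigenvalue N * var(s)
        assert np.isclose(modes[0].eigenvalue, 4 * sig.var(), rtol=1e-9)
        assert np.abs(modes[0].vectors[:, 1:]).max() < 1e-9
        assert modes[1].eigenvalue < 1e-9 * modes[0].eigenvalue

    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(7)
        traj = Trajectory(rng.normal(0, 1.0, (4000, 4, 3)))
        modes = covariance_modes(traj, 12)
        evals = np.array([m.eigenvalue for m in modes])
        assert evals.max() / evals.min() < 1.5

    def test_eigenvalues_descending_nonnegative_and_k_guard(self):
        traj = Trajectory(np.random.default_rng(8).normal(size=(20, 3, 3)))
        modes = covariance_modes(traj, 9)
        evals = [m.eigenvalue for m in modes]
        assert all(e >= 0 for e in evals)
        assert evals == sorted(evals, reverse=True)
        with pytest.raises(ValueError):
            covariance_modes(traj, 10)

    def test_sign_convention(self):
        base = _random_structure(4, seed=9)
        sig = np.random.default_rng(10).normal(0, 1, 100)
        frames = base[None] + np.einsum("f,x->fx", sig, np.array([1.0, 0, 0]))[:, None, :]
        v = covariance_modes(Trajectory(frames), 1)[0].vectors
        assert v.ravel()[np.argmax(np.abs(v))] > 0


class TestICRM:
    def test_coherent_rigid_translation_all_ones(self):
        base = _random_structure(5, seed=11)
        shifts = np.random.default_rng(12).normal(0, 1, 40)
        frames = base[None] + np.einsum("f,x->fx", shifts, np.array([1.0, 1.0, 0]))[:, None, :]
        m = gs.icrm(Trajectory(frames), distance_threshold=np.inf)
        assert np.allclose(m.values, 1.0, atol=1e-9)

    def test_independent_noise_decorrelates(self):
        rng = np.random.default_rng(13)
        traj = Trajectory(_random_structure(10, 14, 3.0)[None] + rng.normal(0, 0.5, (5000, 10, 3)))
        m = gs.icrm(traj, distance_threshold=np.inf)
        off = m.values[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_distance_gate_zeroes_far_pairs_exactly(self):
        coords = np.zeros((30, 2, 3))
        coords[:, 1, 0] = 40.0
        coords += np.random.default_rng(15).normal(0, 0.2, coords.shape)
        m = gs.icrm(Trajectory(coords), distance_threshold=30.0)
        assert m.values[0, 1] == 0.0 and m.values[1, 0] == 0.0
        assert m.gated[0, 1]

    def test_symmetric_unit_diagonal_bounded(self):
        traj = gs.make_coupled_trajectory(coupling=0.7, F=200, seed=16)
        m = gs.icrm(traj, 30.0)
        assert np.array_equal(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)
        assert (m.values >= 0).all() and (m.values <= 1).all()

    def test_zero_variance_residue_flagged_and_zeroed(self):
        coords = np.random.default_rng(17).normal(0, 1, (50, 3, 3))
        coords[:, 2, :] = 7.0  # frozen residue
        with pytest.warns(UserWarning, match="zero-variance"):
            m = gs.icrm(Trajectory(coords), np.inf)
        assert np.all(m.values[2, :] == 0.0)


class TestCoordinationScore:
    def test_identity_matrix_scores_one(self):
        m = CorrelationMatrix(np.eye(6), 30.0, np.zeros((6, 6), dtype=bool))
        assert np.isclose(gs.coordination_score(m).first_eigenvalue, 1.0)

    def test_all_ones_scores_N(self):
        m = CorrelationMatrix(np.ones((7, 7)), 30.0, np.zeros((7, 7), dtype=bool))
        assert np.isclose(gs.coordination_score(m).first_eigenvalue, 7.0)

    def test_bounded_by_N(self):
        traj = gs.make_coupled_trajectory(coupling=1.0, F=150, seed=18)
        score = gs.coordination_score(gs.icrm(traj, 30.0)).first_eigenvalue
        assert 1.0 <= score <= traj.n_residues + 1e-9

    def test_mean_score_strictly_increasing_in_coupling(self):
        """The synthetic analogue of consensus > intermediate > unbound."""
        means = []
        for c in (0.0, 0.5, 1.0):
            scores = [
                gs.coordination_score(
                    gs.icrm(gs.superpose(
                        gs.make_coupled_trajectory(coupling=c, F=400, seed=s)), 30.0)
                ).first_eigenvalue
                for s in range(20)
            ]
            means.append(np.mean(scores))
        assert means[0] < means[1] < means[2]


class TestDomainBlocks:
    def test_block_diagonal_matrix(self):
        vals = np.eye(6)
        vals[0:3, 0:3] = 0.8
        vals[3:6, 3:6] = 0.6
        np.fill_diagonal(vals, 1.0)
        m = CorrelationMatrix(vals, 30.0, np.zeros((6, 6), dtype=bool))
        dm = DomainMap({"A": (1, 3), "B": (4, 6)})
        summary = domain_block_summary(m, dm)
        get = lambda a, b: summary[
            (summary.domain_a == a) & (summary.domain_b == b)
        ].mean_abs_correlation.iloc[0]
        assert get("A", "B") == 0.0
        assert get("A", "A") > 0 and get("B", "B") > 0

    def test_all_ones_every_block_mean_one(self):
        m = CorrelationMatrix(np.ones((6, 6)), 30.0, np.zeros((6, 6), dtype=bool))
        dm = DomainMap({"A": (1, 2), "B": (3, 4), "C": (5, 6)})
        summary = domain_block_summary(m, dm)
        assert np.allclose(summary.mean_abs_correlation, 1.0)

    def test_matches_bruteforce_pair_loop(self):
        rng = np.random.default_rng(19)
        raw = rng.random((12, 12))
        vals = np.clip(0.5 * (raw + raw.T), 0, 1)
        np.fill_diagonal(vals, 1.0)
        m = CorrelationMatrix(vals, 30.0, np.zeros((12, 12), dtype=bool))
        dm = DomainMap({"NTD": (1, 4), "BTD": (5, 8), "CTD": (9, 12)})
        summary = domain_block_summary(m, dm)
        for _, row in summary.iterrows():
            lo_a, hi_a = dm.ranges[row.domain_a]
            lo_b, hi_b = dm.ranges[row.domain_b]
            acc = [
                vals[i - 1, j - 1]
                for i in range(lo_a, hi_a + 1)
                for j in range(lo_b, hi_b + 1)
                if not (row.domain_a == row.domain_b and i == j)
            ]
            assert np.isclose(row.mean_abs_correlation, np.mean(np.abs(acc)))

    def test_out_of_range_domain_rejected(self):
        m = CorrelationMatrix(np.eye(4), 30.0, np.zeros((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="outside"):
            domain_block_summary(m, DomainMap({"A": (1, 9)}))
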