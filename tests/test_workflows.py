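import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from locohd.core import ComparisonSettings
from locohd.errors import DomainError
from locohd.fixtures import make_ensemble, make_structure, make_trajectory
from locohd.structure_io import Structure
from locohd.workflows import (
    BIMODALITY_REFERENCE,
    AnchorSeries,
    ScoreMatrix,
    bimodality,
    complete_linkage,
    ensemble_matrices,
    kabsch_rmsd,
    rank_bimodal,
    rmsd_matrix,
    score_model_pair,
    spearman,
    trajectory_series,
)
from oracles import grid_search_rmsd

SEQ = "AVGLSDKR"


@pytest.fixture(scope="module")
def base():
    return make_structure(SEQ, geometry="helix-like")


class TestScoreMatrix:
    def test_rejects_asymmetric(self):
        with pytest.raises(DomainError):
            ScoreMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]), ["a", "b"], "locohd")

    def test_rejects_nonzero_diagonal(self):
        with pytest.raises(DomainError):
            ScoreMatrix(np.array([[1.0, 0.5], [0.5, 0.0]]), ["a", "b"], "locohd")

    def test_upper_triangle(self):
        m = ScoreMatrix(np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], float), list("abc"), "rmsd")
        np.testing.assert_allclose(m.upper_triangle(), [1, 2, 3])


class TestEnsembleMatrices:
    def test_identical_copies_all_zero(self, base):
        members = [Structure(model_id=i, residues=base.residues) for i in range(3)]
        settings = ComparisonSettings(scheme_name="FA")
        per_anchor, mean_matrix, anchor_means = ensemble_matrices(members, settings)
        assert np.allclose(mean_matrix.values, 0.0)
        assert np.allclose(anchor_means, 0.0)

    def test_comparison_count(self, base):
        # M anchors, N structures -> M per-anchor matrices of N(N-1)/2 pairs
        members, _ = make_ensemble(base, n_structures=3, noise_sigma=0.2, seed=1)
        settings = ComparisonSettings(scheme_name="CG")
        per_anchor, mean_matrix, anchor_means = ensemble_matrices(members, settings)
        assert len(per_anchor) == len(anchor_means)
        n = mean_matrix.values.shape[0]
        assert n == 3
        for m in per_anchor:
            assert np.allclose(m.values, m.values.T)
            assert np.allclose(np.diag(m.values), 0.0)
            assert np.all((m.values >= 0) & (m.values <= 1))

    def test_planted_blocks_recovered(self, base):
        members, labels = make_ensemble(
            base, n_structures=6, noise_sigma=0.05, n_clusters=2, cluster_shift=8.0, seed=3
        )
        settings = ComparisonSettings(scheme_name="CG")
        _, mean_matrix, _ = ensemble_matrices(members, settings)
        found = complete_linkage(mean_matrix, k=2)
        # same partition up to label swap
        assert len(set(zip(labels.tolist(), found.tolist()))) == 2

    def test_too_few_structures(self, base):
        with pytest.raises(DomainError):
            ensemble_matrices([base], ComparisonSettings(scheme_name="FA"))


class TestKabschRmsd:
    def test_self_zero(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(X, X) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        R = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        Y = X @ R.T + np.array([5.0, -2.0, 7.0])
        assert kabsch_rmsd(X, Y) == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        X = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        Y = X.copy()
        Y[2] += np.array([0.7, -0.4, 0.9])
        assert kabsch_rmsd(X, Y) == pytest.approx(grid_search_rmsd(X, Y), abs=1e-4)

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    def test_reflection_disallowed(self):
        # a mirrored tetrahedron cannot be superposed by a proper rotation
        X = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        Y = X * np.array([1.0, 1.0, -1.0])
        assert kabsch_rmsd(X, Y) > 0.1


class TestRmsdMatrix:
    def test_identical_copies_zero(self, base):
        members = [Structure(model_id=i, residues=base.residues) for i in range(3)]
        m = rmsd_matrix(members, "FA")
        assert np.allclose(m.values, 0.0)

    def test_rigid_body_moves_zero(self, base):
        import dataclasses

        members = [base]
        for i, shift in enumerate([(4.0, 0, 0), (0, 9.0, 0)], start=1):
            moved = {
                k: [dataclasses.replace(a, coords=tuple(np.add(a.coords, shift))) for a in v]
                for k, v in base.residues.items()
            }
            members.append(Structure(model_id=i, residues=moved))
        m = rmsd_matrix(members, "FA")
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_gaussian_noise_expectation(self, base):
        # X, Y = base + iid N(0, sigma^2) per coordinate: the difference has
        # variance 2*sigma^2 in each of 3 coordinates, so E[RMSD^2] ~ 6*sigma^2
        # shrunk by the ~6 rigid-body DOF absorbed by the superposition:
        # RMSD ~ sigma*sqrt(6)*sqrt(1 - 2/n); checked within 10%.
        sigma = 0.4
        members, _ = make_ensemble(base, n_structures=12, noise_sigma=sigma, seed=7)
        m = rmsd_matrix(members, "FA")
        n_atoms = sum(len(v) for v in base.residues.values())
        expected = sigma * np.sqrt(6.0) * np.sqrt(1.0 - 2.0 / n_atoms)
        mean_off = m.upper_triangle().mean()
        assert mean_off == pytest.approx(expected, rel=0.10)


class TestCompleteLinkage:
    def _two_block_matrix(self):
        v = np.full((6, 6), 5.0)
        v[:3, :3] = 0.5
        v[3:, 3:] = 0.5
        np.fill_diagonal(v, 0.0)
        return ScoreMatrix(v, [str(i) for i in range(6)], "locohd")

    def test_k2_recovers_blocks(self):
        labels = complete_linkage(self._two_block_matrix(), k=2)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_threshold_below_min_gives_singletons(self):
        labels = complete_linkage(self._two_block_matrix(), threshold=0.1)
        assert len(set(labels.tolist())) == 6

    def test_threshold_above_max_gives_one_cluster(self):
        labels = complete_linkage(self._two_block_matrix(), threshold=100.0)
        assert set(labels.tolist()) == {0}

    def test_k_larger_than_n(self):
        with pytest.raises(DomainError):
            complete_linkage(self._two_block_matrix(), k=7)

    def test_exactly_one_criterion(self):
        with pytest.raises(DomainError):
            complete_linkage(self._two_block_matrix(), threshold=1.0, k=2)


class TestSpearman:
    def test_monotone_increasing(self):
        assert spearman(np.arange(5.0), np.arange(5.0) ** 3) == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman(np.arange(5.0), -np.arange(5.0)) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert spearman(np.array([1, 2, 3, 4.0]), np.array([2, 1, 4, 3.0])) == pytest.approx(0.6)

    def test_constant_is_undefined(self):
        assert spearman(np.ones(5), np.arange(5.0)) is None

    def test_too_short(self):
        with pytest.raises(DomainError):
            spearman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestScoreModelPair:
    def test_self_comparison_zero(self, base):
        settings = ComparisonSettings(scheme_name="FA+Cent")
        result = score_model_pair(base, base, settings)
        assert result.prm_locohd == pytest.approx(0.0, abs=1e-12)
        assert all(r.locohd == pytest.approx(0.0, abs=1e-12) for r in result.rows)

    def test_planted_flip_dominates(self, base):
        import dataclasses

        keys = list(base.residues)
        target = keys[3]
        moved = {
            k: (
                [
                    dataclasses.replace(a, coords=(a.coords[0] + 5.0, a.coords[1], a.coords[2]))
                    if a.atom_name not in ("N", "CA", "C", "O")
                    else a
                    for a in v
                ]
                if k == target
                else list(v)
            )
            for k, v in base.residues.items()
        }
        model = Structure(model_id=1, residues=moved)
        settings = ComparisonSettings(scheme_name="FA+Cent")
        result = score_model_pair(base, model, settings)
        ranked = sorted(result.rows, key=lambda r: -r.locohd)
        top_keys = {r.key for r in ranked[:3]}
        assert target in top_keys

    def test_external_scores_joined(self, base):
        settings = ComparisonSettings(scheme_name="FA+Cent")
        ext = {k: float(i) for i, k in enumerate(base.residues)}
        result = score_model_pair(base, base, settings, external_scores=ext)
        assert result.prm_external is not None
        assert result.unjoined == 0
        assert all(r.external is not None for r in result.rows)

    def test_partial_join_logged_not_fatal(self, base):
        settings = ComparisonSettings(scheme_name="FA+Cent")
        keys = list(base.residues)
        ext = {k: 1.0 * i for i, k in enumerate(keys[:4])}
        result = score_model_pair(base, base, settings, external_scores=ext)
        assert result.unjoined == len(keys) - 4


class TestTrajectorySeries:
    def test_identical_frames_flat_zero(self, base):
        frames = [Structure(model_id=i, residues=base.residues) for i in range(5)]
        settings = ComparisonSettings(scheme_name="CG+Cent")
        series = trajectory_series(frames, 0, settings)
        for s in series:
            assert np.allclose(s.scores, 0.0)

    def test_stride(self, base):
        frames = [Structure(model_id=i, residues=base.residues) for i in range(10)]
        settings = ComparisonSettings(scheme_name="CG+Cent")
        series = trajectory_series(frames, 0, settings, stride=2)
        assert len(series[0].scores) == 5

    def test_two_state_fixture_two_level(self, base):
        switch = list(base.residues)[4]
        frames = make_trajectory(
            base, n_frames=16, switch_frame=8, switch_residue=switch,
            displacement=5.0, noise_sigma=0.02, seed=5,
        )
        settings = ComparisonSettings(scheme_name="CG+Cent")
        series = trajectory_series(frames, 0, settings)
        target = next(s for s in series if s.anchor_id == str(switch))
        before, after = target.scores[:8], target.scores[8:]
        assert after.mean() > before.mean() + 0.05

    def test_reference_out_of_range(self, base):
        frames = [Structure(model_id=i, residues=base.residues) for i in range(4)]
        with pytest.raises(DomainError):
            trajectory_series(frames, 99, ComparisonSettings(scheme_name="CG+Cent"))


class TestBimodality:
    def test_uniform_reference(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(size=100_000)
        assert bimodality(x).beta == pytest.approx(5.0 / 9.0, abs=0.01)

    def test_gaussian_third(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100_000)
        assert bimodality(x).beta == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_two_point_is_one(self):
        x = np.array([-1.0, 1.0] * 500)
        r = bimodality(x)
        assert r.beta == pytest.approx(1.0)
        assert r.skewness == pytest.approx(0.0)
        assert r.kurtosis == pytest.approx(1.0)

    def test_bernoulli_half(self):
        rng = np.random.default_rng(2)
        x = (rng.uniform(size=100_000) < 0.5).astype(float)
        assert bimodality(x).beta == pytest.approx(1.0, abs=0.01)

    def test_nonexcess_kurtosis_convention(self):
        # excess kurtosis would make the uniform reference negative-denominator
        rng = np.random.default_rng(3)
        r = bimodality(rng.uniform(size=50_000))
        assert r.kurtosis == pytest.approx(1.8, abs=0.02)  # 9/5, not -6/5

    def test_constant_sample_undefined(self):
        with pytest.raises(DomainError):
            bimodality(np.ones(10))

    def test_too_few(self):
        with pytest.raises(DomainError):
            bimodality(np.array([0.0, 1.0, 2.0]))


class TestRankBimodal:
    def test_planted_two_state_ranks_first(self):
        rng = np.random.default_rng(4)
        flat = [
            AnchorSeries(f"flat{i}", np.arange(200.0), rng.normal(0.2, 0.01, 200))
            for i in range(5)
        ]
        two_state = AnchorSeries(
            "switch", np.arange(200.0),
            np.concatenate([rng.normal(0.1, 0.01, 100), rng.normal(0.3, 0.01, 100)]),
        )
        ranked = rank_bimodal(flat + [two_state])
        assert ranked[0][0] == "switch"
        assert ranked[0][1] > BIMODALITY_REFERENCE

    def test_gaussian_series_below_reference(self):
        rng = np.random.default_rng(5)
        series = [
            AnchorSeries(f"g{i}", np.arange(5000.0), rng.normal(0.2, 0.02, 5000))
            for i in range(4)
        ]
        ranked = rank_bimodal(series)
        assert all(abs(b - 1 / 3) < 0.05 for _, b in ranked)
        assert all(b < BIMODALITY_REFERENCE for _, b in ranked)

    def test_empty_list(self):
        assert rank_bimodal([]) == []
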