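"""Bernoulli-HMM: forward/posterior/Viterbi oracles, EM behavior, labeling."""

import numpy as np
import pytest

import chromdyn as cd
from chromdyn.chromhmm_core import HmmError

from conftest import enumerate_paths, random_hmm


def single_state_model(emission):
    emission = np.atleast_2d(emission)
    return cd.HmmModel(
        K=1,
        M=emission.shape[1],
        mark_names=tuple(f"m{i}" for i in range(emission.shape[1])),
        initial=np.ones(1),
        transition=np.ones((1, 1)),
        emission=emission,
    )


class TestLogLikelihood:
    def test_single_state_fair_coins(self):
        # K=1 with p=0.5 everywhere: every observation has probability 0.5
        model = single_state_model([[0.5, 0.5, 0.5]])
        obs = np.array([[0, 1, 0], [1, 1, 1], [0, 0, 0], [1, 0, 1]])
        assert cd.log_likelihood(model, obs) == pytest.approx(12 * np.log(0.5))

    def test_single_step_marginal(self):
        rng = np.random.default_rng(0)
        model = random_hmm(rng, K=3, M=2)
        obs = np.array([[1, 0]])
        emit = np.prod(
            np.where(obs[0], model.emission, 1 - model.emission), axis=1
        )
        expected = np.log(np.dot(model.initial, emit))
        assert cd.log_likelihood(model, obs) == pytest.approx(expected, abs=1e-12)

    def test_matches_path_enumeration(self):
        rng = np.random.default_rng(1)
        model = random_hmm(rng, K=3, M=2)
        obs = rng.integers(0, 2, size=(6, 2))
        ll_oracle, _, _ = enumerate_paths(model, obs)
        assert cd.log_likelihood(model, obs) == pytest.approx(ll_oracle, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        model = single_state_model([[0.5, 0.5]])
        with pytest.raises(HmmError):
            cd.log_likelihood(model, np.zeros((4, 3), dtype=int))


class TestPosteriorDecode:
    def test_symmetric_model_uniform_posterior_tie_to_state_one(self):
        model = cd.HmmModel(
            K=4,
            M=2,
            mark_names=("a", "b"),
            initial=np.full(4, 0.25),
            transition=np.full((4, 4), 0.25),
            emission=np.full((4, 2), 0.5),
        )
        obs = np.array([[0, 1], [1, 1], [0, 0]])
        seg = cd.posterior_decode(model, obs, keep_posterior=True)
        assert np.allclose(seg.posterior, 0.25)
        assert np.all(seg.states == 1)

    def test_uniform_transitions_factorize(self):
        # with uniform rows the chain carries no information; posteriors
        # reduce to the per-bin initial x emission product
        rng = np.random.default_rng(2)
        K, M = 3, 2
        emission = rng.uniform(0.1, 0.9, size=(K, M))
        initial = rng.dirichlet(np.ones(K))
        model = cd.HmmModel(
            K=K,
            M=M,
            mark_names=("a", "b"),
            initial=initial,
            transition=np.full((K, K), 1.0 / K),
            emission=emission,
        )
        obs = rng.integers(0, 2, size=(5, M))
        seg = cd.posterior_decode(model, obs, keep_posterior=True)
        for t in range(5):
            emit = np.prod(np.where(obs[t], emission, 1 - emission), axis=1)
            # interior bins see the uniform row, not the initial distribution
            w = (initial if t == 0 else np.ones(K) / K) * emit
            assert np.allclose(seg.posterior[t], w / w.sum(), atol=1e-12)

    def test_matches_enumeration(self):
        rng = np.random.default_rng(3)
        model = random_hmm(rng, K=3, M=2)
        obs = rng.integers(0, 2, size=(6, 2))
        _, post_oracle, _ = enumerate_paths(model, obs)
        seg = cd.posterior_decode(model, obs, keep_posterior=True)
        assert np.allclose(seg.posterior, post_oracle, atol=1e-9)


class TestViterbi:
    def test_single_state_path(self):
        model = single_state_model([[0.5, 0.5]])
        assert np.all(cd.viterbi(model, np.zeros((5, 2), dtype=int)) == 1)

    def test_uniform_transitions_per_bin_argmax(self):
        rng = np.random.default_rng(4)
        K, M = 3, 2
        emission = rng.uniform(0.1, 0.9, size=(K, M))
        model = cd.HmmModel(
            K=K,
            M=M,
            mark_names=("a", "b"),
            initial=np.full(K, 1.0 / K),
            transition=np.full((K, K), 1.0 / K),
            emission=emission,
        )
        obs = rng.integers(0, 2, size=(6, M))
        path = cd.viterbi(model, obs)
        for t in range(6):
            emit = np.prod(np.where(obs[t], emission, 1 - emission), axis=1)
            assert path[t] == np.argmax(emit) + 1

    def test_joint_probability_is_enumeration_maximum(self):
        rng = np.random.default_rng(5)
        model = random_hmm(rng, K=3, M=2)
        obs = rng.integers(0, 2, size=(8, 2))
        _, _, best = enumerate_paths(model, obs)
        path = cd.viterbi(model, obs) - 1
        p = model.initial[path[0]]
        for t in range(8):
            for m in range(2):
                e = model.emission[path[t], m]
                p *= e if obs[t, m] else 1 - e
            if t:
                p *= model.transition[path[t - 1], path[t]]
        assert p == pytest.approx(best, abs=1e-12)


class TestBaumWelch:
    def test_single_state_closed_form(self):
        # K=1: the EM fixed point is the empirical mark frequency
        rng = np.random.default_rng(6)
        seqs = [rng.integers(0, 2, size=(50, 3)) for _ in range(3)]
        model = cd.baum_welch(seqs, K=1, max_iter=10, seed=0)
        freq = np.concatenate(seqs).mean(axis=0)
        assert np.allclose(model.emission[0], freq, atol=1e-9)

    def test_train_log_non_decreasing(self):
        rng = np.random.default_rng(7)
        seqs = [rng.integers(0, 2, size=(100, 2)) for _ in range(2)]
        model = cd.baum_welch(seqs, K=3, max_iter=50, tol=0.0, seed=1, restarts=2)
        diffs = np.diff(model.train_log)
        assert np.all(diffs >= -1e-8)

    def test_identical_observations_warn(self):
        seqs = [np.ones((30, 2), dtype=int)]
        with pytest.warns(UserWarning, match="identical"):
            cd.baum_welch(seqs, K=2, max_iter=5, seed=0)

    def test_invalid_k_rejected(self):
        with pytest.raises(HmmError):
            cd.baum_welch([np.zeros((5, 2), dtype=int)], K=0)

    def test_permuted_initialization_same_segmentation(self, default_sim):
        """Training from a permuted starting point yields the same
        semantic segmentation once states are relabeled."""
        rng = np.random.default_rng(8)
        cfg = cd.SimConfig(
            n_chroms=1, chrom_length=500_000, delayed_fraction=0.0, seed=9
        )
        bins, counts, _ = cd.simulate_chromatin(cfg)
        calls = cd.binarize(counts[cfg.conditions[0]], bins).calls
        emission0 = rng.uniform(0.1, 0.9, size=(4, 3))
        transition0 = np.full((4, 4), 0.125) + 0.5 * np.eye(4)
        init = (np.full(4, 0.25), transition0, emission0)
        perm = np.array([2, 0, 3, 1])
        init_perm = (
            np.full(4, 0.25),
            transition0[np.ix_(perm, perm)],
            emission0[perm],
        )
        segs = []
        for ini in (init, init_perm):
            model = cd.baum_welch(
                [calls], K=4, mark_names=cfg.mark_names, max_iter=100, init=ini
            )
            model.labeling = cd.label_states(model)
            segs.append(cd.posterior_decode(model, calls).states)
        assert np.array_equal(segs[0], segs[1])


class TestLabelStates:
    def make_model(self, emission):
        emission = np.asarray(emission)
        return cd.HmmModel(
            K=4,
            M=3,
            mark_names=("H2AK119ub", "H3K27me3", "H3K27ac"),
            initial=np.full(4, 0.25),
            transition=np.full((4, 4), 0.25),
            emission=emission,
        )

    def test_pattern_rule(self):
        model = self.make_model(
            [
                [0.05, 0.05, 0.90],  # active
                [0.05, 0.05, 0.05],  # unmarked
                [0.08, 0.80, 0.10],  # one repressive
                [0.90, 0.85, 0.10],  # both repressive
            ]
        )
        labeling = cd.label_states(model)
        assert labeling.raw_to_semantic.tolist() == [1, 2, 3, 4]
        assert labeling.from_pattern_rule

    def test_permutation_invariance(self):
        emission = np.array(
            [
                [0.05, 0.05, 0.90],
                [0.05, 0.05, 0.05],
                [0.08, 0.80, 0.10],
                [0.90, 0.85, 0.10],
            ]
        )
        perm = np.array([3, 1, 0, 2])
        lab = cd.label_states(self.make_model(emission))
        lab_p = cd.label_states(self.make_model(emission[perm]))
        # the same raw state must map to the same semantic state
        assert np.array_equal(lab.raw_to_semantic[perm], lab_p.raw_to_semantic)

    def test_ambiguous_patterns_fall_back_with_warning(self):
        model = self.make_model(
            [
                [0.05, 0.05, 0.90],
                [0.06, 0.05, 0.85],  # duplicate active pattern
                [0.08, 0.80, 0.10],
                [0.90, 0.85, 0.10],
            ]
        )
        with pytest.warns(UserWarning, match="ambiguous"):
            labeling = cd.label_states(model)
        assert sorted(labeling.raw_to_semantic.tolist()) == [1, 2, 3, 4]
        assert not labeling.from_pattern_rule

    def test_wrong_k_rejected(self):
        model = cd.HmmModel(
            K=2,
            M=3,
            mark_names=("a", "b", "c"),
            initial=np.full(2, 0.5),
            transition=np.full((2, 2), 0.5),
            emission=np.full((2, 3), 0.5),
        )
        with pytest.raises(HmmError):
            cd.label_states(model)

    def test_simulated_model_labels_match_planted(self, trained_model, default_sim):
        """Semantic labeling recovers the simulator's state identities."""
        err = np.abs(
            trained_model.labeling.emission_by_semantic
            - default_sim["cfg"].emission_truth
        ).max()
        assert err < 0.05


class TestProbabilityConservation:
    def test_model_and_posterior_normalization(self, trained_model):
        trained_model.validate()
        rng = np.random.default_rng(10)
        calls = rng.integers(0, 2, size=(50, 3))
        seg = cd.posterior_decode(trained_model, calls, keep_posterior=True)
        assert np.allclose(seg.posterior.sum(axis=1), 1.0, atol=1e-8)
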