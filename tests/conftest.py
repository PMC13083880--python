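"""Shared fixtures: one default simulation and one trained model per session."""

import numpy as np
import pytest

import chromdyn as cd


@pytest.fixture(scope="session")
def default_sim():
    """Default simulated study: bins, per-condition counts, full truth."""
    cfg = cd.SimConfig(seed=7)
    bins, counts, truth = cd.simulate_chromatin(cfg)
    genes, expression, degs, truth = cd.simulate_expression(cfg, truth, bins)
    return {
        "cfg": cfg,
        "bins": bins,
        "counts": counts,
        "truth": truth,
        "genes": genes,
        "expression": expression,
        "degs": degs,
    }


@pytest.fixture(scope="session")
def default_binarized(default_sim):
    """Per-condition presence calls on the default simulation."""
    bins = default_sim["bins"]
    return {
        cond: cd.binarize(cm, bins)
        for cond, cm in default_sim["counts"].items()
    }


@pytest.fixture(scope="session")
def trained_model(default_sim, default_binarized):
    """One Bernoulli-HMM trained jointly on all conditions, semantically labeled."""
    cfg, bins = default_sim["cfg"], default_sim["bins"]
    sequences = [
        default_binarized[cond].calls[bins.chrom_index(chrom)]
        for cond in cfg.conditions
        for chrom in bins.chrom_sizes
    ]
    model = cd.baum_welch(
        sequences, K=4, mark_names=cfg.mark_names, seed=11
    )
    model.labeling = cd.label_states(model)
    return model


@pytest.fixture(scope="session")
def inferred_segmentations(default_sim, default_binarized, trained_model):
    """Per-condition semantic segmentations decoded from the trained model."""
    cfg, bins = default_sim["cfg"], default_sim["bins"]
    segs = {}
    for cond in cfg.conditions:
        states = np.concatenate(
            [
                cd.posterior_decode(
                    trained_model,
                    default_binarized[cond].calls[bins.chrom_index(chrom)],
                ).states
                for chrom in bins.chrom_sizes
            ]
        )
        segs[cond] = cd.Segmentation(condition=cond, states=states)
    return segs


@pytest.fixture(scope="session")
def truth_segmentations(default_sim):
    """Segmentations taken directly from the planted state paths."""
    return {
        cond: cd.Segmentation(cond, states=path.copy())
        for cond, path in default_sim["truth"].state_paths.items()
    }


def random_hmm(rng, K, M):
    """A random valid Bernoulli-HMM for oracle comparisons."""
    initial = rng.dirichlet(np.ones(K))
    transition = rng.dirichlet(np.ones(K), size=K)
    emission = rng.uniform(0.05, 0.95, size=(K, M))
    return cd.HmmModel(
        K=K,
        M=M,
        mark_names=tuple(f"m{i}" for i in range(M)),
        initial=initial,
        transition=transition,
        emission=emission,
    )


def enumerate_paths(model, obs):
    """Brute-force path enumeration oracle.

    Returns (log-likelihood, posteriors, best joint probability) by
    summing the joint probability of every K^T state path directly.
    """
    import itertools

    obs = np.asarray(obs, dtype=float)
    T, M = obs.shape
    K = model.K
    e = model.emission
    emit = np.ones((T, K))
    for t in range(T):
        for k in range(K):
            for m in range(M):
                emit[t, k] *= e[k, m] if obs[t, m] else 1 - e[k, m]
    total = 0.0
    post = np.zeros((T, K))
    best = 0.0
    for path in itertools.product(range(K), repeat=T):
        p = model.initial[path[0]] * emit[0, path[0]]
        for t in range(1, T):
            p *= model.transition[path[t - 1], path[t]] * emit[t, path[t]]
        total += p
        best = max(best, p)
        for t, k in enumerate(path):
            post[t, k] += p
    return np.log(total), post / total, best
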