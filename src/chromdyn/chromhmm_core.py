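"""K-state hidden Markov model with independent Bernoulli emissions per mark.

Chromatin states are latent labels per genomic bin; each state *k* emits
mark *m* independently with probability ``emission[k, m]``, so the
emission probability of a binary observation ``o`` is
``prod_m e_km**o_m * (1 - e_km)**(1 - o_m)``.  One model is trained
jointly on all conditions' binarized tracks (chromosomes are independent
sequences; no transition crosses a chromosome boundary), then each
condition is segmented separately so state identities are comparable
across conditions.

Training is Baum-Welch EM with random restarts; segmentation assigns
each bin its maximal-posterior state (forward-backward), with Viterbi
available as a testing aid.  For the three-mark panel
(H2AK119ub, H3K27me3, H3K27ac) a four-state model is relabeled into the
semantic order: state 1 active (H3K27ac alone), state 2 unmarked,
state 3 one repressive mark, state 4 both repressive marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HmmModel",
    "Segmentation",
    "StateLabeling",
    "log_likelihood",
    "baum_welch",
    "posterior_decode",
    "viterbi",
    "label_states",
]

EMISSION_FLOOR = 1e-6
TRANSITION_FLOOR = 1e-12


class HmmError(ValueError):
    """Raised for dimension mismatches or invalid model requests."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class StateLabeling:
    """Bijective mapping from raw EM state order to semantic states 1..K."""

    raw_to_semantic: np.ndarray  # raw index i -> semantic state (1-based)
    emission_by_semantic: np.ndarray  # (K, M), rows in semantic order
    from_pattern_rule: bool = True  # False when the ordering fallback was used

    @property
    def semantic_to_raw(self) -> np.ndarray:
        """Raw index of each semantic state (0-based array over semantic-1)."""
        inv = np.empty_like(self.raw_to_semantic)
        inv[self.raw_to_semantic - 1] = np.arange(len(self.raw_to_semantic))
        return inv


@dataclass
class HmmModel:
    K: int
    M: int
    mark_names: tuple[str, ...]
    initial: np.ndarray  # (K,)
    transition: np.ndarray  # (K, K) row-stochastic
    emission: np.ndarray  # (K, M) in (EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    train_log: list[float] = field(default_factory=list)
    max_iter: int = 300
    tol: float = 1e-4
    labeling: StateLabeling | None = None

    def validate(self) -> None:
        if abs(self.initial.sum() - 1.0) > 1e-10:
            raise HmmError("initial distribution does not sum to 1")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-10):
            raise HmmError("transition rows do not sum to 1")
        if np.any(self.emission < EMISSION_FLOOR) or np.any(
            self.emission > 1 - EMISSION_FLOOR
        ):
            raise HmmError("emissions outside floor bounds")

    def final_log_likelihood(self) -> float:
        return self.train_log[-1] if self.train_log else float("nan")


@dataclass
class Segmentation:
    """Per-bin state assignment for one condition (semantic order if labeled)."""

    condition: str
    states: np.ndarray  # (T,) labels in 1..K
    posterior: np.ndarray | None = None  # (T, K), columns in the label order


# ---------------------------------------------------------------------------
# emission and forward-backward machinery
# ---------------------------------------------------------------------------

def _check_obs(model: HmmModel, obs: np.ndarray) -> np.ndarray:
    obs = np.asarray(obs)
    if obs.ndim != 2 or obs.shape[1] != model.M:
        raise HmmError(f"observations must be T x {model.M}, got {obs.shape}")
    if not np.isin(obs, (0, 1)).all():
        raise HmmError("observations must be binary")
    return obs.astype(np.float64)


def _emission_probs(emission: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """(T, K) matrix of P(o_t | state k) for independent Bernoulli marks."""
    e = np.clip(emission, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    logB = obs @ np.log(e).T + (1.0 - obs) @ np.log1p(-e).T
    return np.exp(logB)


def _forward(initial, transition, B):
    """Scaled forward pass.  Returns (alpha, scale, log-likelihood)."""
    T, K = B.shape
    alpha = np.empty((T, K))
    scale = np.empty(T)
    a = initial * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transition) * B[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]
    return alpha, scale, float(np.log(scale).sum())


def _backward(transition, B, scale):
    T, K = B.shape
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transition @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    return beta


def log_likelihood(model: HmmModel, observations: np.ndarray) -> float:
    """Forward-recursion log P(observations | model), scaled per step."""
    obs = _check_obs(model, observations)
    B = _emission_probs(model.emission, obs)
    _, _, ll = _forward(model.initial, model.transition, B)
    return ll


def _posteriors(model: HmmModel, obs: np.ndarray):
    B = _emission_probs(model.emission, obs)
    alpha, scale, ll = _forward(model.initial, model.transition, B)
    beta = _backward(model.transition, B, scale)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, ll


def posterior_decode(
    model: HmmModel,
    observations: np.ndarray,
    condition: str = "",
    keep_posterior: bool = False,
) -> Segmentation:
    """Assign each bin its maximal-posterior state.

    When the model carries a :class:`StateLabeling`, posteriors are
    reordered into semantic state order before the argmax, so ties break
    toward the lowest semantic state index.
    """
    obs = _check_obs(model, observations)
    gamma, _ = _posteriors(model, obs)
    if model.labeling is not None:
        gamma = gamma[:, model.labeling.semantic_to_raw]
    states = np.argmax(gamma, axis=1) + 1
    return Segmentation(
        condition=condition,
        states=states,
        posterior=gamma if keep_posterior else None,
    )


def viterbi(model: HmmModel, observations: np.ndarray) -> np.ndarray:
    """Maximum-probability raw state path (1-based labels)."""
    obs = _check_obs(model, observations)
    e = np.clip(model.emission, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    logB = obs @ np.log(e).T + (1.0 - obs) @ np.log1p(-e).T
    logA = np.log(np.clip(model.transition, TRANSITION_FLOOR, None))
    T, K = logB.shape
    delta = np.log(np.clip(model.initial, TRANSITION_FLOOR, None)) + logB[0]
    psi = np.zeros((T, K), dtype=np.int64)
    for t in range(1, T):
        cand = delta[:, None] + logA
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.int64)
    path[-1] = np.argmax(delta)
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path + 1


# ---------------------------------------------------------------------------
# Baum-Welch training
# ---------------------------------------------------------------------------

def _batched_em_pass(initial, transition, emission, groups):
    """One E-step + sufficient statistics over sequences batched by length.

    ``groups`` maps length T -> observation array (S, T, M).  Returns
    (loglik, init_stat, xi_stat, emit_num, emit_den).
    """
    K = len(initial)
    M = emission.shape[1]
    e = np.clip(emission, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
    loge, log1me = np.log(e).T, np.log1p(-e).T
    ll = 0.0
    init_stat = np.zeros(K)
    xi_stat = np.zeros((K, K))
    emit_num = np.zeros((K, M))
    emit_den = np.zeros(K)
    for T, obs in groups.items():
        S = obs.shape[0]
        B = np.exp(obs @ loge + (1.0 - obs) @ log1me)  # (S, T, K)
        alpha = np.empty((S, T, K))
        scale = np.empty((S, T))
        a = initial[None, :] * B[:, 0, :]
        scale[:, 0] = a.sum(axis=1)
        alpha[:, 0, :] = a / scale[:, 0, None]
        for t in range(1, T):
            a = (alpha[:, t - 1, :] @ transition) * B[:, t, :]
            scale[:, t] = a.sum(axis=1)
            alpha[:, t, :] = a / scale[:, t, None]
        ll += float(np.log(scale).sum())
        beta = np.ones((S, K))
        gamma = alpha[:, T - 1, :] * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        emit_num += np.einsum("sk,sm->km", gamma, obs[:, T - 1, :])
        emit_den += gamma.sum(axis=0)
        for t in range(T - 2, -1, -1):
            bb = B[:, t + 1, :] * beta  # (S, K)
            xi_stat += transition * np.einsum(
                "sk,sj->kj", alpha[:, t, :], bb / scale[:, t + 1, None]
            )
            beta = (bb @ transition.T) / scale[:, t + 1, None]
            gamma = alpha[:, t, :] * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            emit_num += np.einsum("sk,sm->km", gamma, obs[:, t, :])
            emit_den += gamma.sum(axis=0)
        init_stat += gamma.sum(axis=0)  # gamma at t = 0 after the loop
    return ll, init_stat, xi_stat, emit_num, emit_den


def _group_by_length(sequences):
    groups: dict[int, list[np.ndarray]] = {}
    for s in sequences:
        groups.setdefault(s.shape[0], []).append(s.astype(np.float64))
    return {T: np.stack(v) for T, v in groups.items()}


def _default_init(K, M, rng):
    """Random emissions in (0.1, 0.9); uniform transitions with 0.5 self weight."""
    emission = rng.uniform(0.1, 0.9, size=(K, M))
    transition = np.full((K, K), 0.5 / K) + 0.5 * np.eye(K)
    initial = np.full(K, 1.0 / K)
    return initial, transition, emission


def baum_welch(
    sequences: list[np.ndarray],
    K: int,
    M: int | None = None,
    mark_names: tuple[str, ...] | None = None,
    max_iter: int = 300,
    tol: float = 1e-4,
    seed: int = 0,
    restarts: int = 5,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> HmmModel:
    """Fit the Bernoulli-emission HMM by EM over pooled sequences.

    Each sequence (one chromosome of one condition) is an independent
    realization of the chain.  Among ``restarts`` random initializations
    the fit with the highest final log-likelihood is returned; pass
    ``init=(initial, transition, emission)`` to fix the starting point
    (a single run).  Stops at ``max_iter`` or when the log-likelihood
    gain drops below ``tol``.
    """
    if K < 1:
        raise HmmError(f"K must be >= 1, got {K}")
    if not sequences:
        raise HmmError("at least one sequence is required")
    seqs = [np.asarray(s) for s in sequences]
    Ms = {s.shape[1] for s in seqs}
    if len(Ms) != 1:
        raise HmmError(f"sequences disagree on mark count: {sorted(Ms)}")
    M_obs = Ms.pop()
    if M is not None and M != M_obs:
        raise HmmError(f"M={M} but sequences have {M_obs} marks")
    M = M_obs
    for s in seqs:
        if not np.isin(s, (0, 1)).all():
            raise HmmError("observations must be binary")
    stacked = np.concatenate([s.reshape(-1, M) for s in seqs], axis=0)
    if len(np.unique(stacked, axis=0)) == 1:
        warnings.warn(
            "all observations identical; the fitted model has one effective state",
            stacklevel=2,
        )
    groups = _group_by_length(seqs)

    rng = np.random.default_rng(seed)
    n_runs = 1 if init is not None else max(1, restarts)
    best: HmmModel | None = None
    for _ in range(n_runs):
        if init is not None:
            initial, transition, emission = (np.array(x, dtype=float) for x in init)
        else:
            initial, transition, emission = _default_init(K, M, rng)
        train_log: list[float] = []
        for _it in range(max_iter):
            ll, init_stat, xi_stat, emit_num, emit_den = _batched_em_pass(
                initial, transition, emission, groups
            )
            train_log.append(ll)
            if len(train_log) > 1 and ll - train_log[-2] < tol:
                break
            initial = init_stat / init_stat.sum()
            rows = xi_stat.sum(axis=1, keepdims=True)
            # a state never left (or never visited) keeps its current row
            transition = np.where(rows > 0, xi_stat / np.where(rows > 0, rows, 1.0),
                                  transition)
            transition = np.clip(transition, TRANSITION_FLOOR, None)
            transition /= transition.sum(axis=1, keepdims=True)
            emission = emit_num / np.where(emit_den > 0, emit_den, 1.0)[:, None]
            emission = np.clip(emission, EMISSION_FLOOR, 1 - EMISSION_FLOOR)
        model = HmmModel(
            K=K,
            M=M,
            mark_names=tuple(mark_names) if mark_names else tuple(
                f"mark{i + 1}" for i in range(M)
            ),
            initial=initial,
            transition=transition,
            emission=emission,
            train_log=train_log,
            max_iter=max_iter,
            tol=tol,
        )
        if best is None or model.final_log_likelihood() > best.final_log_likelihood():
            best = model
    assert best is not None
    best.validate()
    return best


# ---------------------------------------------------------------------------
# semantic state labeling
# ---------------------------------------------------------------------------

def label_states(model: HmmModel, threshold: float = 0.5) -> StateLabeling:
    """Map raw states to the semantic four-state scheme.

    With marks ordered (H2AK119ub, H3K27me3, H3K27ac) and emissions
    thresholded at ``threshold``: state 4 has both repressive marks
    high, state 3 exactly one repressive mark high, state 1 H3K27ac high
    with repressive marks low, state 2 the remaining (unmarked) state.
    When two raw states share a pattern class the deterministic fallback
    orders states by repressive emission sum ascending (H3K27ac
    descending on ties) and warns.
    """
    if model.K != 4:
        raise HmmError(f"semantic labeling requires K=4, got K={model.K}")
    if model.M != 3:
        raise HmmError(f"semantic labeling requires M=3 marks, got M={model.M}")
    e = model.emission
    high = e >= threshold
    classes = np.empty(4, dtype=np.int64)
    for k in range(4):
        ub, me3, ac = high[k]
        n_rep = int(ub) + int(me3)
        if n_rep == 2:
            classes[k] = 4
        elif n_rep == 1:
            classes[k] = 3
        elif ac:
            classes[k] = 1
        else:
            classes[k] = 2
    if sorted(classes.tolist()) == [1, 2, 3, 4]:
        raw_to_semantic = classes
        from_pattern = True
    else:
        warnings.warn(
            "ambiguous emission patterns; using repressive-sum ordering fallback",
            stacklevel=2,
        )
        rep_sum = e[:, 0] + e[:, 1]
        order = np.lexsort((-e[:, 2], rep_sum))  # ascending rep sum, ac desc on ties
        raw_to_semantic = np.empty(4, dtype=np.int64)
        raw_to_semantic[order] = np.arange(1, 5)
        from_pattern = False
    labeling = StateLabeling(
        raw_to_semantic=raw_to_semantic,
        emission_by_semantic=e[np.argsort(raw_to_semantic)],
        from_pattern_rule=from_pattern,
    )
    return labeling
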