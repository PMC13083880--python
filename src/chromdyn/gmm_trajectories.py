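"""Trajectory clustering with diagonal-covariance Gaussian mixtures.

Per-gene expression trajectories (condition means, z-scored per gene)
are clustered with a G-component Gaussian mixture whose covariances are
diagonal with free per-component, per-dimension variances — the "VVI"
parameterization (component-specific volume and shape, axis-aligned
orientation).  The number of components is scanned over a grid and
selected by BIC, here on the convention

    BIC = 2 * log-likelihood - df * log(n),  df = (G - 1) + G*D + G*D,

so larger is better.  Two selection rules are reported: "max" (argmax
BIC over the grid, the default) and "first-drop" (the largest G before
BIC first decreases along the grid).

EM is initialized from seeded k-means++ centers with hard nearest-center
responsibilities, with random restarts; an emptied component is reseeded
from the point with the lowest maximum responsibility.  A variance floor
(1e-6) regularizes degenerate components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

__all__ = [
    "TrajectoryMatrix",
    "GmmFit",
    "BicScan",
    "zscore_rows",
    "fit_gmm",
    "bic",
    "bic_scan",
    "select_g",
    "assign_clusters",
]

VARIANCE_FLOOR = 1e-6


class GmmError(ValueError):
    """Raised for invalid grids, dimensions or failed scans."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryMatrix:
    """Z-scored per-gene trajectories over D conditions."""

    values: np.ndarray  # (n, D), each row mean 0, sd 1
    genes: list[str]
    conditions: list[str]
    dropped: list[str] = field(default_factory=list)  # zero-variance genes


@dataclass
class GmmFit:
    G: int
    weights: np.ndarray  # (G,)
    means: np.ndarray  # (G, D)
    variances: np.ndarray  # (G, D), >= VARIANCE_FLOOR
    log_likelihood: float
    responsibilities: np.ndarray  # (n, G)
    train_log: list[float]
    seed: int
    restarts: int

    @property
    def D(self) -> int:
        return self.means.shape[1]

    @property
    def n(self) -> int:
        return self.responsibilities.shape[0]

    @property
    def df(self) -> int:
        return (self.G - 1) + self.G * self.D + self.G * self.D

    @property
    def bic(self) -> float:
        return bic(self, self.n)


@dataclass
class BicScan:
    grid: list[int]
    bic_values: list[float]  # NaN where a fit failed
    chosen_max: int
    chosen_first_drop: int
    rule: str  # "max" or "first-drop"
    fits: dict[int, GmmFit]

    @property
    def chosen(self) -> int:
        return self.chosen_max if self.rule == "max" else self.chosen_first_drop


# ---------------------------------------------------------------------------
# z-scoring
# ---------------------------------------------------------------------------

def zscore_rows(condition_means: pd.DataFrame) -> TrajectoryMatrix:
    """Standardize each gene's trajectory to mean 0, sd 1 (sample sd, n-1).

    Rows with zero variance cannot be standardized; they are dropped and
    listed in :attr:`TrajectoryMatrix.dropped`.
    """
    if condition_means.shape[1] < 2:
        raise GmmError("z-scoring needs at least two conditions")
    x = condition_means.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = condition_means.index[~keep].tolist()
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant trajectories", stacklevel=2)
    xk = x[keep]
    z = (xk - xk.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return TrajectoryMatrix(
        values=z,
        genes=condition_means.index[keep].tolist(),
        conditions=list(condition_means.columns),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# EM for the diagonal (VVI) mixture
# ---------------------------------------------------------------------------

def _log_density(X, weights, means, variances):
    """(n, G) log of weight_g * N(x | mu_g, diag(var_g)).

    The quadratic form expands into three matrix products, avoiding the
    (n, G, D) intermediate.
    """
    D = X.shape[1]
    inv = 1.0 / variances  # (G, D)
    log_norm = -0.5 * (D * np.log(2 * np.pi) + np.log(variances).sum(axis=1))
    quad = -0.5 * (
        (X**2) @ inv.T - 2.0 * X @ (means * inv).T + (means**2 * inv).sum(axis=1)
    )
    return np.log(weights)[None, :] + log_norm[None, :] + quad


def _m_step(X, resp):
    nk = resp.sum(axis=0)
    weights = nk / nk.sum()
    means = (resp.T @ X) / nk[:, None]
    # E[x^2] - mean^2 under the responsibilities
    variances = (resp.T @ (X**2)) / nk[:, None] - means**2
    variances = np.maximum(variances, VARIANCE_FLOOR)
    return weights, means, variances


def fit_gmm(
    X: TrajectoryMatrix | np.ndarray,
    G: int,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> GmmFit:
    """Fit a G-component VVI mixture by EM, best of ``restarts`` by likelihood.

    Initialization draws k-means++ centers from the data (seeded) and
    assigns one-hot responsibilities by the nearest center.  The
    per-iteration log-likelihood is non-decreasing; an emptied component
    is reseeded from the point with the lowest maximum responsibility.
    """
    data = X.values if isinstance(X, TrajectoryMatrix) else np.asarray(X, dtype=float)
    n, D = data.shape
    if G < 1:
        raise GmmError(f"G must be >= 1, got {G}")
    if n <= G:
        raise GmmError(f"need more points ({n}) than components ({G})")
    rng = np.random.default_rng(seed)
    best: GmmFit | None = None
    for _r in range(max(1, restarts)):
        if G == 1:
            resp = np.ones((n, 1))
        else:
            rs = int(rng.integers(0, 2**31 - 1))
            centers, _ = kmeans_plusplus(data, n_clusters=G, random_state=rs)
            d2 = ((data[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            resp = np.zeros((n, G))
            resp[np.arange(n), np.argmin(d2, axis=1)] = 1.0
        weights, means, variances = _m_step(data, resp)
        train_log: list[float] = []
        for _it in range(max_iter):
            logdens = _log_density(data, weights, means, variances)
            lse = logsumexp(logdens, axis=1)
            ll = float(lse.sum())
            resp = np.exp(logdens - lse[:, None])
            empty = resp.sum(axis=0) < 1e-10
            if empty.any():
                warnings.warn(
                    f"reseeding {int(empty.sum())} empty component(s)", stacklevel=2
                )
                worst = np.argsort(resp.max(axis=1))
                for j, comp in enumerate(np.flatnonzero(empty)):
                    resp[worst[j]] = 0.0
                    resp[worst[j], comp] = 1.0
            train_log.append(ll)
            if len(train_log) > 1 and ll - train_log[-2] < tol:
                break
            weights, means, variances = _m_step(data, resp)
        fit = GmmFit(
            G=G,
            weights=weights,
            means=means,
            variances=variances,
            log_likelihood=train_log[-1],
            responsibilities=resp,
            train_log=train_log,
            seed=seed,
            restarts=restarts,
        )
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def bic(fit: GmmFit, n: int) -> float:
    """BIC = 2*loglik - df*log(n); df = (G-1) + G*D + G*D.  Larger is better."""
    if n <= 0:
        raise GmmError(f"n must be positive, got {n}")
    return 2.0 * fit.log_likelihood - fit.df * np.log(n)


def select_g(grid: list[int], bic_values: list[float]) -> tuple[int, int]:
    """Apply both selection rules to a BIC profile; failed fits (NaN) skipped.

    Returns ``(argmax BIC, largest G before the first BIC decrease)``;
    the first-drop choice is the last valid G when BIC never decreases.
    """
    valid = [(g, b) for g, b in zip(grid, bic_values) if np.isfinite(b)]
    if not valid:
        raise GmmError("every fit in the scan failed")
    chosen_max = max(valid, key=lambda gb: gb[1])[0]
    chosen_fd = valid[-1][0]
    for (g_prev, b_prev), (_g, b) in zip(valid[:-1], valid[1:]):
        if b < b_prev:
            chosen_fd = g_prev
            break
    return chosen_max, chosen_fd


def bic_scan(
    X: TrajectoryMatrix | np.ndarray,
    grid: list[int] | None = None,
    seed: int = 0,
    rule: str = "max",
    restarts: int = 10,
    max_iter: int = 200,
) -> BicScan:
    """Fit each G on the grid and select by BIC.

    "max" picks the argmax of BIC over the grid; "first-drop" picks the
    largest G before the first decrease of BIC along the grid (the last
    grid value when BIC never decreases).  Both choices are recorded;
    ``rule`` names which one :attr:`BicScan.chosen` reports.
    """
    if grid is None:
        grid = list(range(2, 31, 2))
    grid = list(grid)
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise GmmError("grid must be non-empty and strictly increasing")
    if rule not in ("max", "first-drop"):
        raise GmmError(f"unknown selection rule {rule!r}")
    data = X.values if isinstance(X, TrajectoryMatrix) else np.asarray(X, dtype=float)
    n = data.shape[0]
    fits: dict[int, GmmFit] = {}
    bics: list[float] = []
    for i, G in enumerate(grid):
        try:
            fit = fit_gmm(data, G, seed=seed + i, restarts=restarts, max_iter=max_iter)
            fits[G] = fit
            bics.append(bic(fit, n))
        except GmmError as exc:  # pragma: no cover - scan continues past failures
            warnings.warn(f"fit failed for G={G}: {exc}", stacklevel=2)
            bics.append(float("nan"))
    chosen_max, chosen_fd = select_g(grid, bics)
    return BicScan(
        grid=grid,
        bic_values=bics,
        chosen_max=chosen_max,
        chosen_first_drop=chosen_fd,
        rule=rule,
        fits=fits,
    )


def assign_clusters(fit: GmmFit) -> np.ndarray:
    """Hard labels (1-based): argmax responsibility, ties to the lowest index."""
    return np.argmax(fit.responsibilities, axis=1) + 1
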