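"""Synthetic chromatin and expression data with planted ground truth.

Emulates the statistical structure of the study inputs so the whole
pipeline can be exercised without sequencing data:

* per condition, a Markov chain over 5 kb bins gives each bin a
  chromatin state (1 active, 2 unmarked, 3 singly repressed, 4 doubly
  repressed);
* "delayed remodeling" is planted as short windows of doubly-repressed
  bins that leave state 4 at the late time point in the wild type but
  stay state 4 in the knockout (transition codes #41_44/#42_44/#43_44);
* per bin and mark, presence is drawn from the state's emission
  probability and the read count from a two-component Poisson law
  (background rate, or fold_on times it when the mark is on), scaled by
  the terminal bin's length fraction;
* gene expression trajectories follow planted Gaussian cluster
  templates in log2 space; genes anchored to delayed windows carry a
  wild-type induction whose knockout response is attenuated, and
  matching differential-expression tables are emitted.

All randomness flows from one seed through named substreams, so every
stage is reproducible in isolation and identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .binarize import CountMatrix, GenomeBins
from .expression_integration import ExpressionTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_chromatin",
    "simulate_expression",
    "simulate_trajectories",
    "stationary_distribution",
]

DEFAULT_EMISSION = np.array(
    [
        [0.05, 0.05, 0.90],  # state 1: active, H3K27ac alone
        [0.05, 0.05, 0.05],  # state 2: unmarked
        [0.05, 0.90, 0.10],  # state 3: one repressive mark
        [0.90, 0.90, 0.10],  # state 4: both repressive marks
    ]
)
# sticky chain whose stationary distribution leaves most of the genome
# unmarked (state 2), as in real chromatin: pi = (0.15, 0.60, 0.125, 0.125)
_PI = np.array([0.15, 0.60, 0.125, 0.125])
DEFAULT_TRANSITION = 0.80 * np.eye(4) + 0.20 * np.tile(_PI, (4, 1))

DELAYED_WINDOW_BINS = 3  # planted remodeling domains span 3 consecutive bins
ANCHOR_MARGIN_BINS = 2  # non-delayed gene anchors keep this distance from windows


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    bin_size: int = 5000
    n_states: int = 4
    n_marks: int = 3
    mark_names: tuple[str, ...] = ("H2AK119ub", "H3K27me3", "H3K27ac")
    emission_truth: np.ndarray = field(default_factory=lambda: DEFAULT_EMISSION.copy())
    transition_truth: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION.copy()
    )
    lambda_bg: float = 20.0
    fold_on: float = 6.0
    conditions: tuple[str, ...] = ("WT_0h", "WT_16h", "KO_0h", "KO_16h")
    delayed_fraction: float = 0.1
    delayed_targets: tuple[int, ...] = (1, 2, 3)
    n_genes: int = 1200
    n_clusters_truth: int = 6
    cluster_separation: float = 3.0
    seed: int = 0
    # expression noise model (log2 scale)
    sigma_within: float = 0.5  # within-cluster per-condition sd of a gene
    sigma_rep: float = 0.4  # replicate noise sd
    delayed_sigma: float = 0.25  # per-condition sd of the delayed cohort
    delayed_log2fc: float = 3.0  # planted wild-type induction of delayed genes
    delayed_attenuation: float = 0.2  # knockout induction as a fraction of wild type
    silent_fraction: float = 0.05  # genes kept below the TPM filter
    n_replicates: int = 3
    gene_length: int = 2000

    def validate(self) -> None:
        e = np.asarray(self.emission_truth, dtype=float)
        A = np.asarray(self.transition_truth, dtype=float)
        if e.shape != (self.n_states, self.n_marks):
            raise ConfigurationError("emission_truth must be n_states x n_marks")
        if np.any(e <= 0) or np.any(e >= 1):
            raise ConfigurationError("emission probabilities must lie in (0, 1)")
        if A.shape != (self.n_states, self.n_states):
            raise ConfigurationError("transition_truth must be n_states x n_states")
        if np.any(A < 0) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigurationError("transition_truth rows must sum to 1")
        if self.lambda_bg <= 0:
            raise ConfigurationError("lambda_bg must be positive")
        if self.chrom_length // self.bin_size < 10:
            raise ConfigurationError("each chromosome must hold at least 10 bins")
        if not 0.0 <= self.delayed_fraction <= 1.0:
            raise ConfigurationError("delayed_fraction must lie in [0, 1]")
        if self.delayed_fraction > 0 and len(self.conditions) != 4:
            raise ConfigurationError("delayed planting requires four conditions")
        if any(t not in range(1, self.n_states) for t in self.delayed_targets):
            raise ConfigurationError(
                f"delayed_targets must lie in 1..{self.n_states - 1}"
            )
        if len(self.mark_names) != self.n_marks:
            raise ConfigurationError("mark_names length must equal n_marks")


@dataclass
class SimTruth:
    """Everything the simulator planted, for recovery checks downstream."""

    state_paths: dict[str, np.ndarray]  # condition -> (n_bins,) states 1..K
    mark_on: dict[str, np.ndarray]  # condition -> (n_bins, M) bool on/off draws
    delayed_bins: dict[int, str]  # bin index -> planted transition code
    delayed_windows: list[tuple[int, int, int]]  # (start_bin, n_bins, target_state)
    gene_anchor: dict[str, int] = field(default_factory=dict)
    delayed_genes: list[str] = field(default_factory=list)
    deg_truth: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    cluster_labels_truth: dict[str, int] = field(default_factory=dict)
    cluster_templates: np.ndarray | None = None
    silent_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "state_paths": {c: p.tolist() for c, p in self.state_paths.items()},
            "mark_on": {c: m.astype(int).tolist() for c, m in self.mark_on.items()},
            "delayed_bins": {str(k): v for k, v in self.delayed_bins.items()},
            "delayed_windows": [list(w) for w in self.delayed_windows],
            "gene_anchor": self.gene_anchor,
            "delayed_genes": self.delayed_genes,
            "deg_truth": self.deg_truth,
            "cluster_labels_truth": self.cluster_labels_truth,
            "cluster_templates": None
            if self.cluster_templates is None
            else self.cluster_templates.tolist(),
            "silent_genes": self.silent_genes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            state_paths={c: np.asarray(p) for c, p in d["state_paths"].items()},
            mark_on={c: np.asarray(m, dtype=bool) for c, m in d["mark_on"].items()},
            delayed_bins={int(k): v for k, v in d["delayed_bins"].items()},
            delayed_windows=[tuple(w) for w in d["delayed_windows"]],
            gene_anchor=d.get("gene_anchor", {}),
            delayed_genes=d.get("delayed_genes", []),
            deg_truth=d.get("deg_truth", {}),
            cluster_labels_truth=d.get("cluster_labels_truth", {}),
            cluster_templates=None
            if d.get("cluster_templates") is None
            else np.asarray(d["cluster_templates"]),
            silent_genes=d.get("silent_genes", []),
        )


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream: one master seed, independent generator per stage."""
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1, normalized."""
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# chromatin simulation
# ---------------------------------------------------------------------------

def _sample_chain(rng, transition, initial, T):
    cum_init = np.cumsum(initial)
    cum_trans = np.cumsum(transition, axis=1)
    u = rng.random(T)
    path = np.empty(T, dtype=np.int64)
    path[0] = np.searchsorted(cum_init, u[0])
    for t in range(1, T):
        path[t] = np.searchsorted(cum_trans[path[t - 1]], u[t])
    return path + 1  # states 1-based


def _plant_delayed(config: SimConfig, bins: GenomeBins, paths: dict):
    """Carve delayed-remodeling windows out of wild-type state-4 runs.

    Windows of ``DELAYED_WINDOW_BINS`` consecutive state-4 bins (at the
    early wild-type time point, within one chromosome) are forced to a
    target state at the late wild-type time point and held at state 4 in
    both knockout conditions, approximating a fraction
    ``delayed_fraction`` of state-4 bins.  Afterwards any *unplanted*
    bin whose four-condition pattern would read as a delayed code is
    reset to #44_44, so the planted set is exactly the coded set.
    """
    wt0, wt1, ko0, ko1 = (paths[c] for c in config.conditions)
    rng = _rng(config.seed, "plant")
    w = DELAYED_WINDOW_BINS
    is4 = wt0 == config.n_states
    n4 = int(is4.sum())
    n_windows = int(round(config.delayed_fraction * n4 / w))
    delayed_bins: dict[int, str] = {}
    windows: list[tuple[int, int, int]] = []
    if n_windows > 0:
        same_chrom = np.ones(bins.n_bins, dtype=bool)
        chroms = bins.chroms
        run_ok = is4.copy()
        for off in range(1, w):
            run_ok[: bins.n_bins - off] &= is4[off:] & (
                chroms[: bins.n_bins - off] == chroms[off:]
            )
        run_ok[bins.n_bins - w + 1 :] = False
        candidates = np.flatnonzero(run_ok)
        rng.shuffle(candidates)
        taken = np.zeros(bins.n_bins, dtype=bool)
        for start in candidates:
            lo = max(0, start - (w + ANCHOR_MARGIN_BINS))
            hi = min(bins.n_bins, start + w + w + ANCHOR_MARGIN_BINS)
            if taken[lo:hi].any():
                continue
            target = int(rng.choice(config.delayed_targets))
            sl = slice(start, start + w)
            wt1[sl] = target
            ko0[sl] = config.n_states
            ko1[sl] = config.n_states
            taken[sl] = True
            code = f"#{config.n_states}{target}_{config.n_states}{config.n_states}"
            for b in range(start, start + w):
                delayed_bins[b] = code
            windows.append((int(start), w, target))
            if len(windows) >= n_windows:
                break
        del same_chrom
    # reset accidental delayed-code bins so the planted set is exact
    if len(config.conditions) == 4:
        planted = np.zeros(bins.n_bins, dtype=bool)
        planted[list(delayed_bins)] = True
        accidental = (
            ~planted
            & (wt0 == config.n_states)
            & (ko0 == config.n_states)
            & (ko1 == config.n_states)
            & np.isin(wt1, config.delayed_targets)
        )
        wt1[accidental] = config.n_states
    windows.sort()
    return delayed_bins, windows


def simulate_chromatin(
    config: SimConfig,
) -> tuple[GenomeBins, dict[str, CountMatrix], SimTruth]:
    """Sample per-condition state paths, mark on/off draws and Poisson counts."""
    config.validate()
    bins = GenomeBins.tile(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)},
        config.bin_size,
    )
    A = np.asarray(config.transition_truth, dtype=float)
    pi = stationary_distribution(A)
    paths: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        rng = _rng(config.seed, f"path:{cond}")
        per_chrom = []
        for chrom in bins.chrom_sizes:
            T = int(bins.chrom_index(chrom).sum())
            per_chrom.append(_sample_chain(rng, A, pi, T))
        paths[cond] = np.concatenate(per_chrom)

    if config.delayed_fraction > 0:
        delayed_bins, windows = _plant_delayed(config, bins, paths)
    else:
        delayed_bins, windows = {}, []

    e = np.asarray(config.emission_truth, dtype=float)
    length_frac = bins.lengths / config.bin_size
    counts: dict[str, CountMatrix] = {}
    mark_on: dict[str, np.ndarray] = {}
    for cond in config.conditions:
        rng = _rng(config.seed, f"counts:{cond}")
        p_on = e[paths[cond] - 1]  # (n_bins, M)
        on = rng.random(p_on.shape) < p_on
        lam = (
            config.lambda_bg
            * np.where(on, config.fold_on, 1.0)
            * length_frac[:, None]
        )
        counts[cond] = CountMatrix(
            condition=cond,
            marks=tuple(config.mark_names),
            counts=rng.poisson(lam).astype(np.int64),
        )
        mark_on[cond] = on
    truth = SimTruth(
        state_paths=paths,
        mark_on=mark_on,
        delayed_bins=delayed_bins,
        delayed_windows=windows,
    )
    return bins, counts, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def _scaled_templates(rng, G, D, separation, sigma):
    """Cluster templates with min pairwise distance separation*sigma*sqrt(D).

    Template 1 is the flat (all-zero) trajectory; the others are random
    directions rescaled so the smallest pairwise distance over all pairs
    hits the target.
    """
    templates = np.zeros((G, D))
    if G > 1:
        raw = rng.normal(0.0, 1.0, size=(G - 1, D))
        templates[1:] = raw
        dists = [
            float(np.linalg.norm(templates[i] - templates[j]))
            for i in range(G)
            for j in range(i + 1, G)
        ]
        target = separation * sigma * np.sqrt(D)
        templates[1:] *= target / min(dists)
    return templates


def simulate_expression(
    config: SimConfig, truth: SimTruth, bins: GenomeBins
) -> tuple[pd.DataFrame, ExpressionTable, dict[str, pd.DataFrame], SimTruth]:
    """Emit a gene model, a TPM table, and per-contrast DEG tables.

    Each delayed window is anchored by one gene whose TSS sits at the
    window's center bin; those genes carry a planted wild-type induction
    (``delayed_log2fc``) whose knockout response is attenuated to
    ``delayed_attenuation`` of the wild-type effect.  Remaining genes
    are spread over bins away from the windows and follow their
    cluster's template.  Returns (genes, expression, DEG tables, truth),
    with ``truth`` updated in place.
    """
    if config.n_clusters_truth < 1:
        raise ConfigurationError("n_clusters_truth must be >= 1")
    conds = list(config.conditions)
    D = len(conds)
    G = config.n_clusters_truth
    rng = _rng(config.seed, "expression")
    templates = _scaled_templates(
        rng, G, D, config.cluster_separation, config.sigma_within
    )

    # --- gene anchors ------------------------------------------------------
    window_centers = [s + w // 2 for s, w, _t in truth.delayed_windows]
    excluded = np.zeros(bins.n_bins, dtype=bool)
    for s, w, _t in truth.delayed_windows:
        lo = max(0, s - ANCHOR_MARGIN_BINS)
        hi = min(bins.n_bins, s + w + ANCHOR_MARGIN_BINS)
        excluded[lo:hi] = True
    free_bins = np.flatnonzero(~excluded)
    n_delayed = len(window_centers)
    n_other = config.n_genes - n_delayed
    if n_other < 0:
        raise ConfigurationError("n_genes smaller than the number of delayed windows")
    if n_other > len(free_bins):
        raise ConfigurationError("not enough bins to anchor all genes")
    other_anchors = free_bins[
        np.linspace(0, len(free_bins) - 1, n_other).round().astype(int)
    ]
    width = len(str(config.n_genes))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(config.n_genes)]
    anchors = np.concatenate([np.asarray(window_centers, dtype=int), other_anchors])
    order = np.argsort(anchors, kind="stable")
    anchors = anchors[order]
    is_delayed = np.concatenate(
        [np.ones(n_delayed, dtype=bool), np.zeros(n_other, dtype=bool)]
    )[order]

    labels = np.empty(config.n_genes, dtype=np.int64)
    labels[is_delayed] = 1  # delayed cohort rides on the flat template
    labels[~is_delayed] = rng.integers(1, G + 1, size=int((~is_delayed).sum()))
    silent = np.zeros(config.n_genes, dtype=bool)
    silent[~is_delayed] = rng.random(int((~is_delayed).sum())) < config.silent_fraction

    rows = []
    for i, (gid, b) in enumerate(zip(gene_ids, anchors)):
        chrom = bins.chroms[b]
        tss = int(round(float(bins.midpoints[b])))
        strand = "+" if i % 2 == 0 else "-"
        clen = bins.chrom_sizes[chrom]
        if strand == "+":
            start, end = tss, min(clen, tss + config.gene_length)
        else:
            start, end = max(0, tss - config.gene_length), tss
        rows.append((chrom, start, end, gid, 0, strand))
    genes = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )

    # --- log2 expression surface ------------------------------------------
    baseline = rng.normal(4.0, 1.0, size=config.n_genes)
    baseline[silent] = -6.0
    sigma_g = np.where(is_delayed, config.delayed_sigma, config.sigma_within)
    offsets = rng.normal(0.0, 1.0, size=(config.n_genes, D)) * sigma_g[:, None]
    mu = baseline[:, None] + templates[labels - 1] + offsets
    if n_delayed and D == 4:
        effect = np.array(
            [
                0.0,
                config.delayed_log2fc,
                0.0,
                config.delayed_attenuation * config.delayed_log2fc,
            ]
        )
        mu[is_delayed] += effect[None, :]

    R = config.n_replicates
    noise = rng.normal(0.0, config.sigma_rep, size=(config.n_genes, D, R))
    log2_tpm = mu[:, :, None] + noise
    samples = [f"{c}_rep{r + 1}" for c in conds for r in range(R)]
    tpm = pd.DataFrame(
        2.0 ** log2_tpm.reshape(config.n_genes, D * R),
        index=gene_ids,
        columns=samples,
    )
    expression = ExpressionTable(
        tpm=tpm, sample_condition={f"{c}_rep{r + 1}": c for c in conds for r in range(R)}
    )

    # --- differential-expression tables ------------------------------------
    deg_tables: dict[str, pd.DataFrame] = {}
    contrasts = []
    if D == 4:
        contrasts = [(conds[1], conds[0]), (conds[3], conds[1])]
    for c1, c0 in contrasts:
        a = log2_tpm[:, conds.index(c1), :]
        b = log2_tpm[:, conds.index(c0), :]
        lfc = a.mean(axis=1) - b.mean(axis=1)
        # moderated test: per-gene dispersions are shrunk to the
        # genome-wide pooled value, as dispersion-sharing DE tools do;
        # a per-gene t-test at n=3 cannot represent their power
        pooled = 0.5 * (a.var(axis=1, ddof=1) + b.var(axis=1, ddof=1))
        se = np.sqrt(2.0 * float(np.median(pooled)) / R)
        p = 2.0 * stats.norm.sf(np.abs(lfc) / se)
        padj = stats.false_discovery_control(p, method="bh")
        deg_tables[f"{c1}_vs_{c0}"] = pd.DataFrame(
            {"gene": gene_ids, "log2FC": lfc, "padj": padj}
        )

    gid_arr = np.asarray(gene_ids, dtype=object)
    truth.gene_anchor = {g: int(b) for g, b in zip(gene_ids, anchors)}
    truth.delayed_genes = sorted(gid_arr[is_delayed].tolist())
    truth.silent_genes = sorted(gid_arr[silent].tolist())
    truth.cluster_labels_truth = {
        g: int(l) for g, l, s in zip(gene_ids, labels, silent) if not s
    }
    truth.cluster_templates = templates
    truth.deg_truth = {
        name: {
            "up": sorted(t.loc[(t["padj"] < 0.05) & (t["log2FC"] > 0), "gene"]),
            "down": sorted(t.loc[(t["padj"] < 0.05) & (t["log2FC"] < 0), "gene"]),
        }
        for name, t in deg_tables.items()
    }
    return genes, expression, deg_tables, truth


# ---------------------------------------------------------------------------
# standalone trajectory simulation (for clustering studies)
# ---------------------------------------------------------------------------

def simulate_trajectories(
    n: int,
    n_clusters: int,
    D: int,
    separation: float,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Planted Gaussian clusters in D dimensions.

    Templates are pairwise ``separation * sigma * sqrt(D)`` apart: for
    ``n_clusters <= D`` they sit on scaled coordinate axes (exactly
    equidistant); otherwise random directions are rescaled so the
    minimum pairwise distance hits the target.  Points are the template
    plus isotropic N(0, sigma^2) noise; rows are shuffled.  Returns
    (X, labels 1-based, templates).
    """
    if n_clusters < 1 or n <= n_clusters:
        raise ConfigurationError("need n > n_clusters >= 1")
    rng = np.random.default_rng([seed, zlib.crc32(b"trajectories")])
    target = separation * sigma * np.sqrt(D)
    if n_clusters == 1:
        templates = np.zeros((1, D))
    elif n_clusters <= D:
        templates = np.eye(n_clusters, D) * (target / np.sqrt(2.0))
    else:
        raw = rng.normal(size=(n_clusters, D))
        dmin = min(
            float(np.linalg.norm(raw[i] - raw[j]))
            for i in range(n_clusters)
            for j in range(i + 1, n_clusters)
        )
        templates = raw * (target / dmin)
    labels = np.arange(n) % n_clusters
    X = templates[labels] + rng.normal(0.0, sigma, size=(n, D))
    perm = rng.permutation(n)
    return X[perm], labels[perm] + 1, templates
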