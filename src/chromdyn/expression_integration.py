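"""Link delayed-remodeling loci to expression: gene sets and intersections.

Combines three gene sets to nominate candidates whose delayed chromatin
remodeling plausibly explains their delayed induction: (1) genes nearest
to delayed-remodeling bins, (2) genes upregulated in wild type between
time points, (3) genes downregulated in the knockout relative to wild
type at the late time point.  Differential-expression tables are
consumed as input (gene, log2 fold-change, adjusted p), never
recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "genes_near_bins",
    "deg_set",
    "triple_intersection",
    "filter_expressed",
]


class IntegrationError(ValueError):
    """Raised for unmapped samples, missing columns or unannotated bins."""


@dataclass
class ExpressionTable:
    """Genes x samples TPM with a sample -> condition map."""

    tpm: pd.DataFrame  # index: gene ids; columns: sample ids
    sample_condition: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.tpm.columns if s not in self.sample_condition]
        if missing:
            raise IntegrationError(f"samples without a condition: {missing}")
        if (self.tpm.to_numpy() < 0).any():
            raise IntegrationError("TPM values must be non-negative")

    def condition_means(self) -> pd.DataFrame:
        """Mean TPM per condition over its replicates (genes x conditions)."""
        cond = pd.Series(self.sample_condition)
        groups = cond.loc[list(self.tpm.columns)]
        return self.tpm.T.groupby(groups.to_numpy()).mean().T


def genes_near_bins(bin_indices, annotation: pd.DataFrame) -> list[str]:
    """Deduplicated, sorted nearest-gene assignments over a bin set."""
    idx = np.asarray(list(bin_indices), dtype=np.int64)
    if idx.size == 0:
        return []
    if idx.min() < 0 or idx.max() >= len(annotation):
        raise IntegrationError("bin index outside the annotated grid")
    genes = annotation["nearest_gene"].to_numpy()[idx]
    if any(g is None or g == "" for g in genes):
        raise IntegrationError("bin without a nearest-gene annotation")
    return sorted(set(genes.tolist()))


def deg_set(
    table: pd.DataFrame,
    direction: str,
    alpha: float = 0.05,
    lfc_min: float = 0.0,
) -> list[str]:
    """Genes passing the differential-expression thresholds in one direction.

    up:   log2FC >  lfc_min and padj < alpha
    down: log2FC < -lfc_min and padj < alpha
    """
    required = {"gene", "log2FC", "padj"}
    if not required.issubset(table.columns):
        raise IntegrationError(
            f"DEG table missing columns: {sorted(required - set(table.columns))}"
        )
    if direction not in ("up", "down"):
        raise IntegrationError(f"direction must be 'up' or 'down', got {direction!r}")
    sig = table["padj"].to_numpy() < alpha
    lfc = table["log2FC"].to_numpy()
    keep = sig & (lfc > lfc_min) if direction == "up" else sig & (lfc < -lfc_min)
    return sorted(set(table.loc[keep, "gene"].tolist()))


def triple_intersection(near_genes, up_wt, down_ko) -> list[str]:
    """Sorted intersection of the three candidate gene sets."""
    return sorted(set(near_genes) & set(up_wt) & set(down_ko))


def filter_expressed(
    expression: ExpressionTable,
    conditions: list[str] | None = None,
    tpm_min: float = 0.1,
) -> list[str]:
    """Genes with mean TPM strictly above ``tpm_min`` in >= 1 condition.

    ``conditions`` restricts which condition means are considered
    (default: all).  The inequality is strict: a mean of exactly
    ``tpm_min`` is excluded.
    """
    means = expression.condition_means()
    if conditions is None:
        conditions = list(means.columns)
    if not conditions:
        raise IntegrationError("empty condition subset")
    unknown = [c for c in conditions if c not in means.columns]
    if unknown:
        raise IntegrationError(f"unknown conditions: {unknown}")
    keep = (means[conditions] > tpm_min).any(axis=1)
    return means.index[keep].tolist()
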