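"""Cross-condition chromatin-state dynamics.

Tracks every genomic bin's state across four conditions — two genotypes
at two time points — and summarizes the flows.  Each bin receives a
four-digit transition code ``#{a0}{a1}_{b0}{b1}``: states of genotype A
at (t0, t1), then genotype B at (t0, t1).  For example ``#41_44`` reads
"4 -> 1 in wild type vs 4 -> 4 in knockout".  Delayed-remodeling bins
are those that leave the doubly-repressed state 4 in the wild type while
remaining state 4 in the knockout (codes #41_44, #42_44, #43_44).

Bins are annotated against a gene model into promoter / genic / distal
intergenic classes, with a nearest-TSS gene assignment used downstream
to link delayed bins to genes.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binarize import GenomeBins
from .chromhmm_core import Segmentation

__all__ = [
    "TransitionTable",
    "transition_codes",
    "flow_table",
    "select_delayed_bins",
    "annotate_bins",
    "DELAYED_CODES",
]

DELAYED_CODES = frozenset({"#41_44", "#42_44", "#43_44"})
_CODE_RE = re.compile(r"^#(\d)(\d)_(\d)(\d)$")


class DynamicsError(ValueError):
    """Raised for mismatched bin grids or malformed codes."""


@dataclass
class TransitionTable:
    """Per-bin transition codes over (A_t0, A_t1, B_t0, B_t1) plus tallies."""

    bins: GenomeBins
    codes: np.ndarray  # (n_bins,) strings "#{a0}{a1}_{b0}{b1}"
    code_counts: dict[str, int]
    flows: list[np.ndarray]  # consecutive-pair K x K counts, order as given
    condition_order: tuple[str, str, str, str]


def _check_same_grid(segs: list[Segmentation], bins: GenomeBins) -> None:
    n = bins.n_bins
    for seg in segs:
        if len(seg.states) != n:
            raise DynamicsError(
                f"segmentation '{seg.condition}' has {len(seg.states)} bins, "
                f"grid has {n}"
            )


def transition_codes(
    seg_a0: Segmentation,
    seg_a1: Segmentation,
    seg_b0: Segmentation,
    seg_b1: Segmentation,
    bins: GenomeBins,
    K: int = 4,
) -> TransitionTable:
    """Assemble per-bin codes from four segmentations on one bin grid.

    Slot order is fixed: genotype A at t0 and t1, then genotype B at t0
    and t1 (for the study design: WT 0 h, WT 16 h, KO 0 h, KO 16 h).
    """
    segs = [seg_a0, seg_a1, seg_b0, seg_b1]
    _check_same_grid(segs, bins)
    if K > 9:
        raise DynamicsError("single-digit codes require K <= 9")
    s = np.stack([seg.states for seg in segs], axis=1)
    if np.any((s < 1) | (s > K)):
        raise DynamicsError(f"states outside 1..{K}")
    codes = np.array(
        [f"#{a0}{a1}_{b0}{b1}" for a0, a1, b0, b1 in s], dtype=object
    )
    return TransitionTable(
        bins=bins,
        codes=codes,
        code_counts=dict(Counter(codes.tolist())),
        flows=flow_table(segs, bins, K),
        condition_order=tuple(seg.condition for seg in segs),
    )


def flow_table(
    segmentations: list[Segmentation], bins: GenomeBins, K: int = 4
) -> list[np.ndarray]:
    """K x K bin counts for each consecutive pair of segmentations.

    Entry (i, j) of pair p counts bins in state i+1 under segmentation p
    and state j+1 under p+1 — the alluvial flow between adjacent
    conditions.
    """
    if len(segmentations) < 2:
        raise DynamicsError("need at least two segmentations")
    _check_same_grid(segmentations, bins)
    flows = []
    for a, b in zip(segmentations[:-1], segmentations[1:]):
        table = np.zeros((K, K), dtype=np.int64)
        np.add.at(table, (a.states - 1, b.states - 1), 1)
        flows.append(table)
    return flows


def select_delayed_bins(
    table: TransitionTable, codes: frozenset[str] | set[str] = DELAYED_CODES
) -> np.ndarray:
    """Indices (genomic order) of bins whose code is in ``codes``."""
    for code in codes:
        if not _CODE_RE.match(code):
            raise DynamicsError(f"malformed transition code: {code!r}")
    if not codes:
        return np.array([], dtype=np.int64)
    return np.flatnonzero(np.isin(table.codes, sorted(codes)))


# ---------------------------------------------------------------------------
# gene-model annotation
# ---------------------------------------------------------------------------

def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    ms, me = [], []
    for a, b in zip(s, e):
        if me and a <= me[-1]:
            me[-1] = max(me[-1], b)
        else:
            ms.append(a)
            me.append(b)
    return np.asarray(ms), np.asarray(me)


def _overlaps_any(bs, be, ms, me):
    """For bins [bs, be) and merged sorted intervals [ms, me): any overlap."""
    if len(ms) == 0:
        return np.zeros(len(bs), dtype=bool)
    idx = np.searchsorted(ms, be, side="left") - 1  # last interval starting < be
    valid = idx >= 0
    out = np.zeros(len(bs), dtype=bool)
    out[valid] = me[idx[valid]] > bs[valid]
    return out


def annotate_bins(
    bins: GenomeBins,
    genes: pd.DataFrame,
    promoter_window: int = 3000,
) -> pd.DataFrame:
    """Classify every bin and assign its nearest gene by TSS distance.

    ``genes`` is BED6-like (chrom, start, end, name, score, strand) with
    0-based half-open coordinates; the TSS is ``start`` on the + strand
    and ``end`` on the - strand.  A bin overlapping any promoter window
    ``[TSS - w, TSS + w)`` is "promoter"; otherwise a bin overlapping any
    gene body is "genic"; otherwise "distal intergenic".  Overlap is
    any-overlap, not midpoint.  The nearest gene minimizes
    |bin midpoint - TSS|; ties break to the lower TSS, then the
    lexicographically smaller gene name.  Distance is signed,
    midpoint - TSS.
    """
    if genes.empty:
        raise DynamicsError("gene model is empty")
    genes = genes.copy()
    for _, g in genes.iterrows():
        if g["chrom"] not in bins.chrom_sizes:
            raise DynamicsError(f"gene {g['name']} on unknown chromosome {g['chrom']}")
        if g["start"] < 0 or g["end"] > bins.chrom_sizes[g["chrom"]]:
            raise DynamicsError(f"gene {g['name']} outside genome bounds")
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"])

    n = bins.n_bins
    feature = np.full(n, "distal intergenic", dtype=object)
    nearest = np.empty(n, dtype=object)
    distance = np.zeros(n, dtype=np.int64)
    mid = bins.midpoints

    for chrom in bins.chrom_sizes:
        mask = bins.chrom_index(chrom)
        if not mask.any():
            continue
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            raise DynamicsError(f"no genes on chromosome {chrom}; cannot annotate")
        bs, be = bins.starts[mask], bins.ends[mask]

        prom_s = np.maximum(g["tss"].to_numpy() - promoter_window, 0)
        prom_e = g["tss"].to_numpy() + promoter_window
        ms, me = _merge_intervals(prom_s, prom_e)
        is_prom = _overlaps_any(bs, be, ms, me)
        ms, me = _merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
        is_genic = _overlaps_any(bs, be, ms, me) & ~is_prom
        f = feature[mask]
        f[is_prom] = "promoter"
        f[is_genic] = "genic"
        feature[mask] = f

        # nearest TSS: sort genes by (tss, name); candidates flank the midpoint
        g = g.sort_values(["tss", "name"], kind="stable")
        tss = g["tss"].to_numpy()
        names = g["name"].to_numpy()
        m = mid[mask]
        right = np.searchsorted(tss, m, side="left")
        left = right - 1
        best_idx = np.empty(len(m), dtype=np.int64)
        for i, (lo, hi) in enumerate(zip(left, right)):
            cand = [j for j in (lo, hi) if 0 <= j < len(tss)]
            # expand over equal-TSS runs so the name tie-break sees them all
            full = set()
            for j in cand:
                k = j
                while k - 1 >= 0 and tss[k - 1] == tss[j]:
                    k -= 1
                while k < len(tss) and tss[k] == tss[j]:
                    full.add(k)
                    k += 1
                full.add(j)
            best_idx[i] = min(
                full, key=lambda j: (abs(m[i] - tss[j]), tss[j], names[j])
            )
        nearest[mask] = names[best_idx]
        distance[mask] = np.rint(m - tss[best_idx]).astype(np.int64)

    return pd.DataFrame(
        {
            "chrom": bins.chroms,
            "start": bins.starts,
            "end": bins.ends,
            "feature": feature,
            "nearest_gene": nearest,
            "tss_distance": distance,
        }
    )
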