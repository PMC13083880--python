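"""Poisson-background binarization of binned ChIP-seq coverage.

Counts in fixed-width genomic bins are converted to per-bin, per-mark
presence calls by comparing each count with a uniform background
expectation.  A bin is called "present" for a mark when its count reaches
a fold-enrichment multiple of the background expectation (default 2x)
*and* the upper-tail Poisson probability of the count under the
background law falls below ``tail_alpha`` (default 1e-4; set
``tail_alpha=1`` to disable the tail test and use the fold rule alone).

The background expectation for mark *m* is the library size of *m*
spread uniformly over the genome: ``lambda_m = library_size_m * bin_size
/ genome_length``.  A shorter terminal bin uses its length fraction of
that expectation, so simulation and inference agree on partial bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "GenomeBins",
    "CountMatrix",
    "BinaryMatrix",
    "estimate_background",
    "binarize",
]


class BinarizationError(ValueError):
    """Raised for invalid counts or an unestimable background."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeBins:
    """Tiling of chromosomes into fixed-width, 0-based half-open bins.

    Bins tile each chromosome without gaps or overlaps; only the last bin
    of a chromosome may be shorter than ``bin_size``.
    """

    chrom_sizes: dict[str, int]
    bin_size: int
    chroms: np.ndarray  # per-bin chromosome name
    starts: np.ndarray  # per-bin start, 0-based inclusive
    ends: np.ndarray  # per-bin end, exclusive

    @classmethod
    def tile(cls, chrom_sizes: dict[str, int], bin_size: int) -> "GenomeBins":
        if bin_size <= 0:
            raise BinarizationError(f"bin_size must be positive, got {bin_size}")
        if not chrom_sizes or any(L <= 0 for L in chrom_sizes.values()):
            raise BinarizationError("chromosome sizes must be positive and non-empty")
        chroms, starts, ends = [], [], []
        for chrom, length in chrom_sizes.items():
            s = np.arange(0, length, bin_size, dtype=np.int64)
            e = np.minimum(s + bin_size, length)
            chroms.extend([chrom] * len(s))
            starts.append(s)
            ends.append(e)
        return cls(
            chrom_sizes=dict(chrom_sizes),
            bin_size=int(bin_size),
            chroms=np.asarray(chroms, dtype=object),
            starts=np.concatenate(starts),
            ends=np.concatenate(ends),
        )

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) / 2.0

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Boolean mask of bins belonging to ``chrom``."""
        return self.chroms == chrom

    def validate(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            mask = self.chrom_index(chrom)
            s, e = self.starts[mask], self.ends[mask]
            if s[0] != 0 or e[-1] != length:
                raise BinarizationError(f"{chrom}: bins do not span [0, {length})")
            if np.any(s[1:] != e[:-1]):
                raise BinarizationError(f"{chrom}: bins have gaps or overlaps")
            if np.any((e - s)[:-1] != self.bin_size):
                raise BinarizationError(f"{chrom}: interior bin of wrong width")

    def same_grid(self, other: "GenomeBins") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chrom_sizes == other.chrom_sizes
            and np.array_equal(self.starts, other.starts)
        )


@dataclass
class CountMatrix:
    """Per-condition binned coverage counts, bins x marks."""

    condition: str
    marks: tuple[str, ...]
    counts: np.ndarray  # (n_bins, M) non-negative integers
    library_size: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != len(self.marks):
            raise BinarizationError("counts must be bins x marks")
        if np.any(self.counts < 0):
            raise BinarizationError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if self.library_size is None:
            self.library_size = colsums.astype(np.int64)
        elif not np.array_equal(np.asarray(self.library_size), colsums):
            raise BinarizationError("library_size does not match column sums")


@dataclass
class BinaryMatrix:
    """Per-bin, per-mark presence calls with the thresholds that produced them."""

    condition: str
    marks: tuple[str, ...]
    calls: np.ndarray  # (n_bins, M) in {0, 1}
    background_rate: np.ndarray  # per mark, expected count per full bin
    fold_threshold: float = 2.0
    tail_alpha: float = 1e-4


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def estimate_background(counts: CountMatrix, bins: GenomeBins) -> np.ndarray:
    """Uniform background rate per mark: expected count in one full bin.

    ``lambda_m = library_size_m * bin_size / genome_length``.
    """
    G = bins.genome_length
    if G <= 0:
        raise BinarizationError("zero-length genome")
    if counts.counts.shape[0] != bins.n_bins:
        raise BinarizationError(
            f"count matrix has {counts.counts.shape[0]} bins, grid has {bins.n_bins}"
        )
    lib = np.asarray(counts.library_size, dtype=float)
    if np.any(lib <= 0):
        raise BinarizationError("library size must be positive for every mark")
    return lib * bins.bin_size / G


def binarize(
    counts: CountMatrix,
    bins: GenomeBins,
    fold_threshold: float = 2.0,
    tail_alpha: float = 1e-4,
    closed_boundary: bool = True,
) -> BinaryMatrix:
    """Call per-bin mark presence against the Poisson background.

    A call is 1 iff ``count >= fold_threshold * lambda_bin`` (``>`` when
    ``closed_boundary=False``) and ``P(X >= count) <= tail_alpha`` for
    ``X ~ Poisson(lambda_bin)``.  ``tail_alpha=1`` disables the tail test.
    ``lambda_bin`` is the per-mark background scaled by the bin's length
    fraction, so a short terminal bin is not over-called.
    """
    if fold_threshold < 1:
        warnings.warn(
            f"fold_threshold={fold_threshold} < 1 calls bins below background",
            stacklevel=2,
        )
    lam = estimate_background(counts, bins)
    lam_bin = lam[None, :] * (bins.lengths / bins.bin_size)[:, None]
    c = counts.counts
    if closed_boundary:
        fold_ok = c >= fold_threshold * lam_bin
    else:
        fold_ok = c > fold_threshold * lam_bin
    if tail_alpha >= 1.0:
        tail_ok = np.ones_like(fold_ok, dtype=bool)
    else:
        # P(X >= c) = sf(c - 1); sf handles c = 0 -> 1
        tail_ok = stats.poisson.sf(c - 1, lam_bin) <= tail_alpha
    calls = (fold_ok & tail_ok).astype(np.uint8)
    return BinaryMatrix(
        condition=counts.condition,
        marks=counts.marks,
        calls=calls,
        background_rate=lam,
        fold_threshold=fold_threshold,
        tail_alpha=tail_alpha,
    )
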