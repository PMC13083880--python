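"""Readers and writers for the pipeline's text formats.

Formats: bedGraph (chrom, start, end, value; 0-based half-open), BED6
gene models, ChromHMM-style binarized text (two header lines, then one
0/1 row per bin), 4-column segmentation BED with consecutive same-state
bins merged, TSV tables with headers, and JSON for models, configs and
simulation truth.  All writes are atomic (temp file, then rename) and
round-trip byte-identically for canonical inputs.
"""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from .binarize import BinaryMatrix, GenomeBins
from .chromhmm_core import HmmModel, Segmentation, StateLabeling

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_bed6",
    "write_binarized",
    "read_binarized",
    "write_segmentation_bed",
    "write_model_json",
    "read_model_json",
    "read_tsv_matrix",
    "write_tsv",
    "write_truth_json",
    "read_truth_json",
]


class FormatError(ValueError):
    """Raised on malformed input files; messages cite file and line."""


@contextmanager
def atomic_write(path: str | Path):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(path, bins: GenomeBins, values, comments: tuple[str, ...] = ()):
    values = np.asarray(values)
    with atomic_write(path) as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for chrom, s, e, v in zip(bins.chroms, bins.starts, bins.ends, values):
            fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_bedgraph(path):
    """Parse a bedGraph into interval arrays; rejects malformed records.

    Returns (chroms, starts, ends, values).  Intervals must be 0-based
    half-open with start < end and numeric values.
    """
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, s, e, v = parts
            try:
                s, e = int(s), int(e)
                v = float(v)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if s < 0 or e <= s:
                raise FormatError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            chroms.append(chrom)
            starts.append(s)
            ends.append(e)
            values.append(v)
    return (
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(values),
    )


def bins_from_bedgraph(chroms, starts, ends) -> GenomeBins:
    """Reconstruct the bin grid from one track's intervals, validating tiling."""
    chrom_sizes: dict[str, int] = {}
    for c, e in zip(chroms, ends):
        chrom_sizes[c] = max(chrom_sizes.get(c, 0), int(e))
    widths = ends - starts
    bin_size = int(np.bincount(widths.astype(int)).argmax())
    bins = GenomeBins(
        chrom_sizes=chrom_sizes,
        bin_size=bin_size,
        chroms=np.asarray(chroms, dtype=object),
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
    )
    bins.validate()
    return bins


# ---------------------------------------------------------------------------
# BED6 gene models
# ---------------------------------------------------------------------------

def read_bed6(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(parts)}")
            chrom, s, e, name, score, strand = parts[:6]
            try:
                s, e = int(s), int(e)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if s < 0 or s > e:
                raise FormatError(f"{path}:{lineno}: invalid interval [{s}, {e})")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            rows.append((chrom, s, e, name, score, strand))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed6(path, genes: pd.DataFrame):
    with atomic_write(path) as fh:
        for _, g in genes.iterrows():
            fh.write(
                f"{g['chrom']}\t{g['start']}\t{g['end']}\t{g['name']}\t"
                f"{g['score']}\t{g['strand']}\n"
            )


# ---------------------------------------------------------------------------
# ChromHMM-style binarized text
# ---------------------------------------------------------------------------

def write_binarized(outdir, binary: BinaryMatrix, bins: GenomeBins):
    """One file per (condition, chromosome): header lines, then 0/1 rows."""
    outdir = Path(outdir)
    paths = []
    for chrom in bins.chrom_sizes:
        mask = bins.chrom_index(chrom)
        path = outdir / f"{binary.condition}_{chrom}_binary.txt"
        with atomic_write(path) as fh:
            fh.write(f"{binary.condition}\t{chrom}\n")
            fh.write("\t".join(binary.marks) + "\n")
            for row in binary.calls[mask]:
                fh.write("\t".join(str(int(x)) for x in row) + "\n")
        paths.append(path)
    return paths


def read_binarized(path):
    """Returns (condition, chrom, marks, calls array)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) != 2:
            raise FormatError(f"{path}:1: expected 'condition<TAB>chrom'")
        condition, chrom = header
        marks = tuple(fh.readline().rstrip("\n").split("\t"))
        rows = []
        for lineno, line in enumerate(fh, 3):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(marks):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(marks)} columns, got {len(parts)}"
                )
            try:
                row = [int(x) for x in parts]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer call") from None
            if any(x not in (0, 1) for x in row):
                raise FormatError(f"{path}:{lineno}: calls must be 0 or 1")
            rows.append(row)
    return condition, chrom, marks, np.asarray(rows, dtype=np.uint8)


# ---------------------------------------------------------------------------
# segmentation BED and model JSON
# ---------------------------------------------------------------------------

def write_segmentation_bed(path, seg: Segmentation, bins: GenomeBins):
    """4-column BED with consecutive same-state bins merged per chromosome."""
    with atomic_write(path) as fh:
        for chrom in bins.chrom_sizes:
            mask = bins.chrom_index(chrom)
            states = seg.states[mask]
            starts = bins.starts[mask]
            ends = bins.ends[mask]
            run_start = 0
            for i in range(1, len(states) + 1):
                if i == len(states) or states[i] != states[run_start]:
                    fh.write(
                        f"{chrom}\t{starts[run_start]}\t{ends[i - 1]}\t"
                        f"E{states[run_start]}\n"
                    )
                    run_start = i


def write_model_json(path, model: HmmModel):
    doc = {
        "K": model.K,
        "M": model.M,
        "mark_names": list(model.mark_names),
        "initial": model.initial.tolist(),
        "transition": model.transition.tolist(),
        "emission": model.emission.tolist(),
        "train_log": model.train_log,
        "max_iter": model.max_iter,
        "tol": model.tol,
        "labeling": None
        if model.labeling is None
        else {
            "raw_to_semantic": model.labeling.raw_to_semantic.tolist(),
            "emission_by_semantic": model.labeling.emission_by_semantic.tolist(),
            "from_pattern_rule": model.labeling.from_pattern_rule,
        },
    }
    with atomic_write(path) as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path) -> HmmModel:
    with open(path) as fh:
        doc = json.load(fh)
    labeling = None
    if doc.get("labeling"):
        lab = doc["labeling"]
        labeling = StateLabeling(
            raw_to_semantic=np.asarray(lab["raw_to_semantic"], dtype=np.int64),
            emission_by_semantic=np.asarray(lab["emission_by_semantic"]),
            from_pattern_rule=lab["from_pattern_rule"],
        )
    model = HmmModel(
        K=doc["K"],
        M=doc["M"],
        mark_names=tuple(doc["mark_names"]),
        initial=np.asarray(doc["initial"]),
        transition=np.asarray(doc["transition"]),
        emission=np.asarray(doc["emission"]),
        train_log=doc["train_log"],
        max_iter=doc["max_iter"],
        tol=doc["tol"],
        labeling=labeling,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# tables and truth
# ---------------------------------------------------------------------------

def read_tsv_matrix(path, index_col: int | None = 0) -> pd.DataFrame:
    # no comment stripping: transition codes legitimately start with '#'
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv(path, frame: pd.DataFrame, index: bool = True):
    with atomic_write(path) as fh:
        frame.to_csv(fh, sep="\t", index=index)


def write_truth_json(path, truth):
    with atomic_write(path) as fh:
        json.dump(truth.to_dict(), fh, sort_keys=True)
        fh.write("\n")


def read_truth_json(path):
    from .synthetic_data import SimTruth

    with open(path) as fh:
        return SimTruth.from_dict(json.load(fh))
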