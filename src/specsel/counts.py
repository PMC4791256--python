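"""Spectral-count matrices and sample annotations.

A label-free shotgun proteomics experiment yields, per LC-MS/MS run, the
number of MS/MS spectra assigned to each protein (the *spectral count*), a
semi-quantitative proxy of protein abundance.  This module holds the two
core containers — the protein-by-run count matrix and the run annotation
mapping each run to a biological class and replicate — plus the standard
preprocessing applied before any feature selection: low-count filtering,
per-protein z-scoring, per-run relative abundances and signed fold changes.

File dialect: tab-separated UTF-8; row 1 holds run identifiers, column 1
protein identifiers; absence is encoded as 0, never as a missing cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SpectralCountMatrix",
    "SampleAnnotation",
    "CountsFormatError",
    "AnnotationError",
    "read_counts",
    "read_annotation",
    "filter_low_counts",
    "zscore_rows",
    "relative_abundance",
    "fold_change",
]


class CountsFormatError(ValueError):
    """Raised when a counts table violates the format contract."""


class AnnotationError(ValueError):
    """Raised when a sample annotation is inconsistent with the counts."""


@dataclass(frozen=True)
class SpectralCountMatrix:
    """Non-negative integer counts, proteins (rows) by runs (columns).

    ``run_totals[j]`` is the total number of spectra observed in run *j*
    (the column sum), which later serves as the number of trials in the
    beta-binomial abundance model and as the denominator of per-run
    relative abundances.
    """

    protein_ids: tuple[str, ...]
    run_ids: tuple[str, ...]
    counts: np.ndarray  # (n_proteins, n_runs) int64

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.protein_ids), len(self.run_ids)):
            raise CountsFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.run_ids)} runs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise CountsFormatError(
                    f"non-integer count at protein {self.protein_ids[bad[0]]!r}, "
                    f"run {self.run_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise CountsFormatError(
                f"negative count at protein {self.protein_ids[bad[0]]!r}, "
                f"run {self.run_ids[bad[1]]!r}"
            )
        _check_unique(self.protein_ids, "protein id")
        _check_unique(self.run_ids, "run id")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def run_totals(self) -> np.ndarray:
        """Per-run total spectra T_j (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.protein_ids),
                            columns=list(self.run_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectralCountMatrix":
        return cls(tuple(str(i) for i in df.index),
                   tuple(str(c) for c in df.columns),
                   df.to_numpy())

    def subset_proteins(self, ids: list[str] | np.ndarray) -> "SpectralCountMatrix":
        index = {p: i for i, p in enumerate(self.protein_ids)}
        rows = [index[p] for p in ids]
        return SpectralCountMatrix(tuple(ids), self.run_ids, self.counts[rows])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="protein_id")


@dataclass(frozen=True)
class SampleAnnotation:
    """Run-level metadata: biological class and replicate index per run."""

    run_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    replicate_index: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.class_labels) != len(self.run_ids):
            raise AnnotationError("one class label required per run")
        _check_unique(self.run_ids, "run id")
        if not self.replicate_index:
            object.__setattr__(self, "replicate_index", tuple([1] * len(self.run_ids)))
        if len(self.replicate_index) != len(self.run_ids):
            raise AnnotationError("one replicate index required per run")
        if any(r < 1 for r in self.replicate_index):
            raise AnnotationError("replicate indices must be positive integers")
        counts = pd.Series(self.class_labels).value_counts()
        if len(counts) < 2:
            raise AnnotationError("at least 2 distinct classes required")
        small = counts[counts < 2]
        if len(small):
            raise AnnotationError(
                f"every class needs >=2 runs; underpopulated: {sorted(small.index)}"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        """Distinct class labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.class_labels:
            seen.setdefault(c, None)
        return tuple(seen)

    def labels_for(self, run_ids: tuple[str, ...]) -> np.ndarray:
        lookup = dict(zip(self.run_ids, self.class_labels))
        missing = [r for r in run_ids if r not in lookup]
        if missing:
            raise AnnotationError(f"annotation missing runs: {missing}")
        return np.array([lookup[r] for r in run_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "run_id": list(self.run_ids),
            "class": list(self.class_labels),
            "replicate": list(self.replicate_index),
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise CountsFormatError(f"duplicated {what}: {x!r}")
        seen.add(x)


def read_counts(path: str | Path,
                annotation_path: str | Path) -> tuple[SpectralCountMatrix, SampleAnnotation]:
    """Read a counts TSV and its run annotation, validated and cross-checked.

    Row/column order is preserved from the files.  Every run in the counts
    header must appear in the annotation (extra annotated runs are an
    error too, so the two files always describe the same experiment).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise CountsFormatError(f"{path}: no run columns found")
    try:
        values = df.apply(pd.to_numeric).to_numpy()
    except (ValueError, TypeError) as exc:
        raise CountsFormatError(f"{path}: non-numeric cell ({exc})") from exc
    m = SpectralCountMatrix(tuple(str(i) for i in df.index),
                            tuple(str(c) for c in df.columns), values)
    ann = read_annotation(annotation_path)
    if set(ann.run_ids) != set(m.run_ids):
        missing = sorted(set(m.run_ids) - set(ann.run_ids))
        extra = sorted(set(ann.run_ids) - set(m.run_ids))
        raise AnnotationError(
            f"annotation/counts run mismatch; missing from annotation: {missing}; "
            f"unknown runs annotated: {extra}"
        )
    return m, ann


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a run annotation TSV with columns run_id, class[, replicate]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"run_id", "class"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"{path}: annotation needs columns {sorted(required)}")
    reps = (tuple(int(r) for r in df["replicate"])
            if "replicate" in df.columns else ())
    return SampleAnnotation(tuple(df["run_id"]), tuple(df["class"]), reps)


def filter_low_counts(m: SpectralCountMatrix, threshold: int = 2,
                      aggregator: Literal["total", "max"] = "total",
                      ) -> SpectralCountMatrix:
    """Discard proteins whose aggregated spectral count is <= ``threshold``.

    Shotgun runs undersample low-abundance proteins; proteins observed only
    a handful of times across the whole experiment carry no usable
    quantitative signal and are dropped before testing.  The default
    aggregates by the total over all runs (a protein is kept iff its total
    exceeds the threshold); ``aggregator="max"`` keys on the single highest
    per-run count instead.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if aggregator == "total":
        agg = m.counts.sum(axis=1)
    elif aggregator == "max":
        agg = m.counts.max(axis=1) if m.n_proteins else np.array([])
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    keep = np.flatnonzero(agg > threshold)
    kept_ids = [m.protein_ids[i] for i in keep]
    if not kept_ids:
        import warnings
        warnings.warn("low-count filter removed every protein", stacklevel=2)
    return SpectralCountMatrix(tuple(kept_ids), m.run_ids, m.counts[keep])


def zscore_rows(m: SpectralCountMatrix | np.ndarray) -> np.ndarray:
    """Z-score each protein across runs (sample sd, ddof=1).

    Rows with zero spread map to all zeros, a neutral value under both the
    Pearson and Euclidean distances used downstream.
    """
    x = m.counts if isinstance(m, SpectralCountMatrix) else np.asarray(m)
    x = x.astype(float)
    if x.shape[1] < 2:
        raise ValueError("z-scoring requires >=2 runs")
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def relative_abundance(m: SpectralCountMatrix) -> np.ndarray:
    """Per-run protein proportions y_ij / T_j; each column sums to 1."""
    totals = m.run_totals
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(f"runs with zero total spectra: "
                         f"{[m.run_ids[j] for j in zero]}")
    return m.counts / totals[np.newaxis, :]


def fold_change(m: SpectralCountMatrix, ann: SampleAnnotation,
                target_class: str, reference_class: str,
                threshold: float = 1.3) -> pd.DataFrame:
    """Signed per-protein fold change between two classes of runs.

    Class mean spectral counts ``a`` (target) and ``b`` (reference) are
    compared after replacing a zero mean by one (so never-seen proteins do
    not divide by zero).  The signed convention returns ``a/b`` when the
    protein is at least as abundant in the target and ``-b/a`` otherwise,
    so |FC| >= 1 always and negative means lower in the target class.  The
    ``regulated`` flag marks |FC| >= ``threshold`` (default 1.3, the usual
    two-sided cut -1.3 >= FC >= 1.3).
    """
    labels = ann.labels_for(m.run_ids)
    for cls in (target_class, reference_class):
        if cls not in labels:
            raise ValueError(f"class {cls!r} has no runs in the matrix")
    a = m.counts[:, labels == target_class].mean(axis=1)
    b = m.counts[:, labels == reference_class].mean(axis=1)
    a = np.where(a == 0, 1.0, a)
    b = np.where(b == 0, 1.0, b)
    fc = np.where(a >= b, a / b, -b / a)
    return pd.DataFrame({
        "protein_id": list(m.protein_ids),
        "fold_change": fc,
        "regulated": np.abs(fc) >= threshold,
    })
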