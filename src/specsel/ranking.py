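"""Ranked candidate-biomarker lists shared by all selection methods."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RankedFeatureList"]


@dataclass(frozen=True)
class RankedFeatureList:
    """An ordered protein list (best first) with scores and a cut-off N.

    ``n_selected`` is the method's optimal feature-subset size: the first
    ``n_selected`` proteins form the selected subset.  ``scores`` holds the
    method-specific ranking score (a p-value for univariate tests, a
    centroid-deviation or margin-weight criterion for the classifiers).
    """

    method_name: str
    protein_ids: tuple[str, ...]
    scores: tuple[float, ...]
    n_selected: int

    def __post_init__(self) -> None:
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("ranked list contains duplicate protein ids")
        if len(self.scores) != len(self.protein_ids):
            raise ValueError("one score required per protein")
        if not 0 <= self.n_selected <= len(self.protein_ids):
            raise ValueError("n_selected outside [0, list length]")

    def __len__(self) -> int:
        return len(self.protein_ids)

    @property
    def selected(self) -> tuple[str, ...]:
        """The optimal subset: the top ``n_selected`` proteins."""
        return self.protein_ids[: self.n_selected]

    def top(self, k: int) -> tuple[str, ...]:
        return self.protein_ids[:k]

    def to_frame(self) -> pd.DataFrame:
        n = len(self.protein_ids)
        return pd.DataFrame({
            "rank": np.arange(1, n + 1),
            "protein_id": list(self.protein_ids),
            "score": list(self.scores),
            "selected": [i < self.n_selected for i in range(n)],
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
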