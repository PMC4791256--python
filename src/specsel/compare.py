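"""Concordance of ranked candidate-biomarker lists.

Methods as different as a univariate count test, a shrunken-centroid
classifier and margin-based elimination rarely return identical lists;
Jaccard prefix curves and a three-way Venn partition quantify how much of
the candidate panel is method-invariant.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

from .ranking import RankedFeatureList

__all__ = ["jaccard", "jaccard_curve", "venn_partition"]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; two empty sets count as identical (1.0)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def jaccard_curve(lists: list[RankedFeatureList], k_max: int,
                  three_way: bool = False) -> pd.DataFrame:
    """Mean pairwise Jaccard of top-k prefixes for k = 1..k_max.

    With ``three_way=True`` an extra column holds |∩ all|/|∪ all| of the
    prefixes instead of the pairwise mean.
    """
    if len(lists) < 2:
        raise ValueError("need >=2 ranked lists")
    if k_max > min(len(l) for l in lists):
        raise ValueError("k_max exceeds the shortest list")
    rows = []
    for k in range(1, k_max + 1):
        prefixes = [set(l.top(k)) for l in lists]
        pair = float(np.mean([jaccard(a, b) for a, b in combinations(prefixes, 2)]))
        row = {"k": k, "mean_jaccard": pair}
        if three_way:
            inter = set.intersection(*prefixes)
            union = set.union(*prefixes)
            row["joint_jaccard"] = len(inter) / len(union) if union else 1.0
        rows.append(row)
    return pd.DataFrame(rows)


def venn_partition(lists: list[RankedFeatureList],
                   use_selected: bool = True) -> tuple[dict[str, int], pd.DataFrame]:
    """Partition three feature sets into the 7 exclusive Venn regions.

    By default each list contributes its optimal subset (top-N); with
    ``use_selected=False`` the full lists are used.  Region keys are
    binary membership strings ordered as the input lists, e.g. "110" =
    in lists 1 and 2 only.  Returns (region sizes, per-protein membership
    table).
    """
    if len(lists) != 3:
        raise ValueError("venn_partition expects exactly 3 lists")
    sets = [set(l.selected if use_selected else l.protein_ids) for l in lists]
    names = [l.method_name for l in lists]
    union = sorted(set.union(*sets))
    membership = pd.DataFrame({
        "protein_id": union,
        **{f"in_{name}": [p in s for p in union] for name, s in zip(names, sets)},
    })
    regions = {a + b + c: 0 for a in "01" for b in "01" for c in "01"
               if a + b + c != "000"}
    for p in union:
        key = "".join("1" if p in s else "0" for s in sets)
        regions[key] += 1
    return regions, membership
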