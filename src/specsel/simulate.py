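"""Synthetic spectral-count experiments with planted differential proteins.

The generator emulates a multi-class label-free secretome study: a few
thousand proteins observed over a handful of runs per class, with per-run
totals in the thousands.  Baseline relative abundances follow a
log-normal law (shotgun spectral counts are strongly heavy-tailed: a few
proteins soak up most spectra while most proteins yield a handful), a
chosen subset of proteins carries a multiplicative fold effect in one
class, and counts are drawn either multinomially (pure sampling noise) or
per-protein from a beta-binomial to add the between-replicate
overdispersion real MS runs show.

The default design mirrors an 18-run, 3-class experiment: 6 runs per
class, ~1,700 proteins (the post-filter scale of a ~2,500-protein
identification list), totals uniform in [7,500, 9,500] spectra per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import SampleAnnotation, SpectralCountMatrix

__all__ = ["SyntheticSpec", "PlantedEffect", "generate_counts", "null_spec",
           "DEFAULT_CLASSES"]

DEFAULT_CLASSES = ("carcinoma", "melanoma", "noncancerous")


@dataclass(frozen=True)
class PlantedEffect:
    """A protein index carrying ``fold``-times baseline abundance in one class."""

    protein_index: int
    affected_class: str
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold effects must be > 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic experiment."""

    n_proteins: int = 1700
    classes: tuple[str, ...] = DEFAULT_CLASSES
    runs_per_class: int = 6
    total_range: tuple[int, int] = (7500, 9500)
    sigma: float = 2.0            # log-normal spread of baseline abundances
    theta: float = 0.001          # beta-binomial overdispersion; 0 = multinomial
    planted: tuple[PlantedEffect, ...] = field(default=())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("need >=1 protein")
        if self.total_range[0] <= 0 or self.total_range[1] < self.total_range[0]:
            raise ValueError("invalid total-spectra range")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        for e in self.planted:
            if not 0 <= e.protein_index < self.n_proteins:
                raise ValueError(f"planted index {e.protein_index} out of range")
            if e.affected_class not in self.classes:
                raise ValueError(f"planted class {e.affected_class!r} unknown")


def null_spec(n_proteins: int = 1700,
              classes: tuple[str, ...] = DEFAULT_CLASSES,
              runs_per_class: int = 6, seed: int = 0,
              **kwargs) -> SyntheticSpec:
    """A global-null spec: no planted effects, all classes exchangeable."""
    return SyntheticSpec(n_proteins=n_proteins, classes=classes,
                         runs_per_class=runs_per_class, planted=(),
                         seed=seed, **kwargs)


def planted_spec(n_planted: int, fold: float,
                 affected_class: str | tuple[str, ...] = DEFAULT_CLASSES[0],
                 n_proteins: int = 1700, seed: int = 0,
                 min_mean_count: float = 1.0,
                 **kwargs) -> SyntheticSpec:
    """Spec with ``n_planted`` proteins at ``fold`` x baseline abundance.

    ``affected_class`` may be a single class or a tuple of classes, in
    which case the planted proteins are assigned round-robin (emulating a
    study where each tumor class carries its own marker panel).

    Effects are planted on proteins *quantifiable at baseline*: those
    whose expected spectral count is at least ``min_mean_count`` per run
    given the baseline abundance law and the mid-range run total.  A
    candidate biomarker must be observable to begin with; planting fold
    effects on proteins the instrument essentially never samples measures
    the sampling process, not the selection method.  Eligibility is
    computed from the same baseline draw ``generate_counts`` will use for
    this seed, so the spec stays fully deterministic.
    """
    probe = SyntheticSpec(n_proteins=n_proteins, seed=seed, **kwargs)
    rng = np.random.default_rng(seed)
    weights = rng.lognormal(mean=0.0, sigma=probe.sigma, size=n_proteins)
    baseline = weights / weights.sum()
    t_mid = 0.5 * (probe.total_range[0] + probe.total_range[1])
    eligible = np.flatnonzero(baseline * t_mid >= min_mean_count)
    if len(eligible) < n_planted:
        raise ValueError(
            f"only {len(eligible)} proteins are quantifiable at baseline; "
            f"cannot plant {n_planted} effects")
    pick_rng = np.random.default_rng([seed, n_planted])
    idx = pick_rng.choice(eligible, size=n_planted, replace=False)
    targets = (affected_class,) if isinstance(affected_class, str) else tuple(affected_class)
    planted = tuple(PlantedEffect(int(i), targets[k % len(targets)], fold)
                    for k, i in enumerate(sorted(idx)))
    return SyntheticSpec(n_proteins=n_proteins, planted=planted, seed=seed, **kwargs)


def generate_counts(spec: SyntheticSpec,
                    ) -> tuple[SpectralCountMatrix, SampleAnnotation, pd.DataFrame]:
    """Draw one experiment; deterministic given ``spec.seed``.

    Returns the count matrix, its run annotation and the planted truth
    table (protein_id, class, fold).  With ``theta == 0`` each run is a
    multinomial draw, so column sums equal the requested totals exactly;
    with ``theta > 0`` counts are drawn protein-wise from a beta-binomial
    with mean equal to the run's expected proportion, so totals vary
    around the requested value.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    protein_ids = tuple(f"P{i:05d}" for i in range(n))

    weights = rng.lognormal(mean=0.0, sigma=spec.sigma, size=n)
    baseline = weights / weights.sum()

    run_ids, labels, reps = [], [], []
    for c in spec.classes:
        for r in range(spec.runs_per_class):
            run_ids.append(f"{c}_r{r + 1}")
            labels.append(c)
            reps.append(r + 1)
    totals = rng.integers(spec.total_range[0], spec.total_range[1] + 1,
                          size=len(run_ids))

    effect = np.ones((n, len(spec.classes)))
    for e in spec.planted:
        g = spec.classes.index(e.affected_class)
        effect[e.protein_index, g] *= e.fold

    counts = np.zeros((n, len(run_ids)), dtype=np.int64)
    for j, c in enumerate(labels):
        g = spec.classes.index(c)
        q = baseline * effect[:, g]
        q = q / q.sum()
        if spec.theta == 0:
            counts[:, j] = rng.multinomial(totals[j], q)
        else:
            a = q / spec.theta
            b = (1.0 - q) / spec.theta
            lam = rng.beta(a, b)
            counts[:, j] = rng.binomial(int(totals[j]), lam)

    m = SpectralCountMatrix(protein_ids, tuple(run_ids), counts)
    ann = SampleAnnotation(tuple(run_ids), tuple(labels), tuple(reps))
    truth = pd.DataFrame(
        [{"protein_id": protein_ids[e.protein_index],
          "class": e.affected_class, "fold": e.fold} for e in spec.planted],
        columns=["protein_id", "class", "fold"],
    )
    return m, ann, truth
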