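"""End-to-end orchestration: filter, select, compare, cluster, report.

One call runs the whole candidate-biomarker workflow on a count matrix:
low-count filtering, the three selectors (beta-binomial at p < alpha; NSC
and SVM-RFE tuned under double CV), per-protein class association, list
concordance (Venn partition and Jaccard prefix curve) and clustering
diagnostics before/after selection.  Every artifact lands in the run
directory under a stable filename, and all randomness flows from the
single configured seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import compare as _compare
from . import simulate as _simulate
from . import univariate as _uni
from .counts import (SampleAnnotation, SpectralCountMatrix, filter_low_counts,
                     read_counts)
from .dcv import DCVConfig, DCVReport, assign_protein_class, run_dcv
from .ranking import RankedFeatureList

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("specsel")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; YAML-friendly flat keys."""

    counts_path: str | None = None
    annotation_path: str | None = None
    simulate: _simulate.SyntheticSpec | None = None
    out_dir: str = "specsel_run"
    seed: int = 0
    filter_threshold: int = 2
    filter_aggregator: str = "total"
    bb_alpha: float = 0.05
    anova_alpha: float = 0.05
    jaccard_kmax: int = 200
    dcv: DCVConfig = field(default_factory=lambda: DCVConfig(method="nsc"))

    def __post_init__(self) -> None:
        if (self.counts_path is None) == (self.simulate is None):
            raise ValueError("provide exactly one of counts_path or simulate")
        if self.counts_path is not None and self.annotation_path is None:
            raise ValueError("annotation_path required with counts_path")


@dataclass(frozen=True)
class PipelineResult:
    matrix: SpectralCountMatrix
    filtered: SpectralCountMatrix
    annotation: SampleAnnotation
    bb_list: RankedFeatureList
    anova_list: RankedFeatureList
    nsc_report: DCVReport
    svm_report: DCVReport
    venn_regions: dict[str, int]
    jaccard: pd.DataFrame
    sc_pre: float
    sc_pre_tree: float
    sc_post: float
    sc_post_tree: float
    summary: pd.DataFrame


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %-12s %7.1fs", name, time.time() - t0)

    try:
        if cfg.simulate is not None:
            m, ann, truth = _simulate.generate_counts(cfg.simulate)
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
            m.write(out / "counts.tsv")
            ann.write(out / "annotation.tsv")
        else:
            m, ann = read_counts(cfg.counts_path, cfg.annotation_path)
        stage("load")

        filtered = filter_low_counts(m, cfg.filter_threshold,
                                     cfg.filter_aggregator)
        filtered.write(out / "counts_filtered.tsv")
        stage("filter")

        bb_results = _uni.betabinom_test_all(filtered, ann)
        bb_list = _uni.betabinom_rank(bb_results, alpha=cfg.bb_alpha)
        _uni.results_to_frame(bb_results).to_csv(out / "bb_results.tsv",
                                                 sep="\t", index=False)
        bb_assign = assign_protein_class(filtered, ann, bb_list)
        bb_assign.to_csv(out / "bb_class_assignment.tsv", sep="\t", index=False)
        stage("betabinomial")

        anova_list = _uni.anova_per_protein(filtered, ann, alpha=cfg.anova_alpha)
        anova_list.write(out / "anova_results.tsv")
        stage("anova")

        nsc_report = run_dcv(filtered, ann,
                             replace(cfg.dcv, method="nsc", seed=cfg.seed))
        (out / "nsc_report.txt").write_text(nsc_report.to_text())
        stage("nsc-dcv")

        svm_report = run_dcv(filtered, ann,
                             replace(cfg.dcv, method="svm_rfe", seed=cfg.seed))
        (out / "svmrfe_report.txt").write_text(svm_report.to_text())
        stage("svmrfe-dcv")

        lists = [bb_list, nsc_report.selected_features,
                 svm_report.selected_features]
        regions, membership = _compare.venn_partition(lists)
        membership.to_csv(out / "venn.tsv", sep="\t", index=False)
        kmax = min(cfg.jaccard_kmax, min(len(l) for l in lists))
        curve = _compare.jaccard_curve(lists, kmax, three_way=True)
        curve.to_csv(out / "jaccard_curve.tsv", sep="\t", index=False)
        stage("compare")

        labels = ann.labels_for(filtered.run_ids)
        d_pre = _cluster.sample_distances(filtered)
        tree_pre = _cluster.nj_tree(d_pre)
        tree_pre.write(str(out / "nj_pre.nwk"))
        _, sc_pre = _cluster.silhouette_from_data(d_pre, labels)
        sc_pre_tree = _cluster.silhouette_from_tree(tree_pre, labels)

        union = sorted(set().union(*(l.selected for l in lists)))
        if len(union) >= 2:
            post = filtered.subset_proteins(union)
            d_post = _cluster.sample_distances(post)
            tree_post = _cluster.nj_tree(d_post)
            tree_post.write(str(out / "nj_post.nwk"))
            _, sc_post = _cluster.silhouette_from_data(d_post, labels)
            sc_post_tree = _cluster.silhouette_from_tree(tree_post, labels)
        else:
            sc_post = sc_post_tree = float("nan")
        stage("cluster")

        summary = _summary_table(cfg, m, filtered, bb_list, anova_list,
                                 nsc_report, svm_report, regions,
                                 sc_pre, sc_pre_tree, sc_post, sc_post_tree)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        stage("summary")
    except Exception:
        log.exception("pipeline stage failed; partial outputs kept in %s", out)
        raise

    return PipelineResult(
        matrix=m, filtered=filtered, annotation=ann,
        bb_list=bb_list, anova_list=anova_list,
        nsc_report=nsc_report, svm_report=svm_report,
        venn_regions=regions, jaccard=curve,
        sc_pre=sc_pre, sc_pre_tree=sc_pre_tree,
        sc_post=sc_post, sc_post_tree=sc_post_tree,
        summary=summary,
    )


def _summary_table(cfg, m, filtered, bb_list, anova_list, nsc_report,
                   svm_report, regions, sc_pre, sc_pre_tree, sc_post,
                   sc_post_tree) -> pd.DataFrame:
    rows = [
        ("seed", cfg.seed),
        ("n_proteins_input", m.n_proteins),
        ("n_proteins_filtered", filtered.n_proteins),
        ("n_discarded", m.n_proteins - filtered.n_proteins),
        ("n_selected_betabinomial", bb_list.n_selected),
        ("n_selected_anova", anova_list.n_selected),
        ("n_selected_nsc", nsc_report.optimal_n),
        ("n_selected_svm_rfe", svm_report.optimal_n),
        ("dcv_error_nsc", _fmt(nsc_report.outer_error)),
        ("dcv_error_svm_rfe", _fmt(svm_report.outer_error)),
        ("accuracy_nsc", _fmt(nsc_report.accuracy)),
        ("accuracy_svm_rfe", _fmt(svm_report.accuracy)),
        ("sc_data_pre", _fmt(sc_pre)),
        ("sc_tree_pre", _fmt(sc_pre_tree)),
        ("sc_data_post", _fmt(sc_post)),
        ("sc_tree_post", _fmt(sc_post_tree)),
    ]
    rows += [(f"venn_{k}", v) for k, v in sorted(regions.items())]
    return pd.DataFrame(rows, columns=["quantity", "value"])


def _fmt(x: float) -> str:
    return f"{x:.6g}"
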