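"""Per-protein differential-abundance tests for spectral counts.

The workhorse is a beta-binomial likelihood-ratio test.  Each protein's
count in run *j* is modelled as the number of successes in T_j trials,
where T_j is the run's total spectral count, with success proportion pi
and overdispersion theta >= 0.  Writing alpha = pi/theta and
beta = (1-pi)/theta, the count follows a beta-binomial distribution whose
variance exceeds the binomial by a factor growing with theta; theta -> 0
recovers plain binomial sampling.  The null model shares one pi across
classes, the alternative gives each class its own pi_g (theta shared), and
the likelihood ratio Lambda = 2(l_alt - l_null) is referred to a
chi-square with G-1 degrees of freedom.  Overdispersion matters because
replicate MS runs show more count variation than binomial sampling alone
explains; ignoring it inflates false positives.

A one-way ANOVA on raw counts is provided as the classical univariate
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .counts import SampleAnnotation, SpectralCountMatrix
from .ranking import RankedFeatureList

__all__ = [
    "BetaBinomialResult",
    "betabinom_loglik",
    "betabinom_lrt",
    "betabinom_test_all",
    "betabinom_rank",
    "anova_table",
    "anova_per_protein",
]

_LOGIT_CLIP = 1e-10
_LOG_THETA_BOUNDS = (-16.0, 6.0)


@dataclass(frozen=True)
class BetaBinomialResult:
    """Fitted beta-binomial LRT for one protein."""

    protein_id: str
    pi_hat_by_group: dict[str, float]
    theta_hat: float
    lrt_stat: float
    df: int
    p_value: float
    converged: bool = True
    message: str = ""


def betabinom_loglik(y: np.ndarray, T: np.ndarray, pi: float,
                     theta: float) -> float:
    """Log-likelihood of counts ``y`` out of totals ``T``.

    ``theta == 0`` gives the binomial log-likelihood; ``theta > 0`` the
    beta-binomial with alpha = pi/theta, beta = (1-pi)/theta.  ``pi`` at
    the 0/1 boundary is permitted only when the data are degenerate in the
    matching direction (all y == 0, resp. all y == T); otherwise the mass
    is zero and -inf is returned.
    """
    y = np.asarray(y, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(y > T):
        raise ValueError("count exceeds its run total (y_j > T_j)")
    if np.any(y < 0) or np.any(T < 0):
        raise ValueError("negative counts or totals")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    if pi == 0.0:
        return 0.0 if np.all(y == 0) else -np.inf
    if pi == 1.0:
        return 0.0 if np.all(y == T) else -np.inf
    choose = special.gammaln(T + 1) - special.gammaln(y + 1) - special.gammaln(T - y + 1)
    if theta == 0.0:
        return float(np.sum(choose + y * np.log(pi) + (T - y) * np.log1p(-pi)))
    a = pi / theta
    b = (1.0 - pi) / theta
    return float(np.sum(choose + special.betaln(y + a, T - y + b) - special.betaln(a, b)))


def _neg_loglik_groups(params: np.ndarray, y: np.ndarray, T: np.ndarray,
                       group_idx: np.ndarray, n_groups: int,
                       ) -> tuple[float, np.ndarray]:
    """Negative kernel log-likelihood and its gradient.

    params = (logit pi_1..G, log theta), theta shared across groups.  The
    binomial coefficient term is constant in the parameters and omitted;
    it cancels in every likelihood-ratio comparison (the boundary
    evaluation drops it too, see ``_boundary_loglik``).
    """
    pis = np.clip(special.expit(params[:n_groups]), 1e-14, 1 - 1e-14)
    theta = np.exp(params[n_groups])
    p_run = pis[group_idx]
    a = p_run / theta
    b = (1.0 - p_run) / theta
    ll = np.sum(special.betaln(y + a, T - y + b) - special.betaln(a, b))
    psi = special.digamma
    common = psi(a + b) - psi(T + a + b)
    dl_da = psi(y + a) - psi(a) + common
    dl_db = psi(T - y + b) - psi(b) + common
    grad = np.zeros_like(params)
    per_run_pi = (dl_da - dl_db) * p_run * (1.0 - p_run) / theta
    np.add.at(grad, group_idx, per_run_pi)
    grad[n_groups] = -np.sum(a * dl_da + b * dl_db)
    return -float(ll), -grad


def _boundary_loglik(y: np.ndarray, T: np.ndarray, group_idx: np.ndarray,
                     n_groups: int) -> tuple[float, np.ndarray]:
    """theta = 0 boundary: binomial with each group's pooled-ratio MLE.

    Returns the kernel log-likelihood (no binomial coefficient), matching
    ``_neg_loglik_groups``.
    """
    pis = np.empty(n_groups)
    total = 0.0
    for g in range(n_groups):
        mask = group_idx == g
        pis[g] = y[mask].sum() / max(T[mask].sum(), 1.0)
        p = pis[g]
        yk, Tk = y[mask], T[mask]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(yk > 0, yk * np.log(p), 0.0) + \
                np.where(Tk - yk > 0, (Tk - yk) * np.log1p(-p), 0.0)
        total += float(term.sum())
    return total, pis


def _fit(y: np.ndarray, T: np.ndarray, group_idx: np.ndarray, n_groups: int,
         starts: list[np.ndarray]) -> tuple[float, np.ndarray, float, bool, str]:
    """Maximize the (beta-)binomial likelihood; returns the best of the
    interior optimum over the given starts and the theta=0 boundary."""
    best_ll, best_pis = _boundary_loglik(y, T, group_idx, n_groups)
    best_theta = 0.0
    ok, msg = True, ""
    bounds = [(-30.0, 30.0)] * n_groups + [_LOG_THETA_BOUNDS]
    for x0 in starts:
        res = optimize.minimize(
            _neg_loglik_groups, x0, args=(y, T, group_idx, n_groups),
            method="L-BFGS-B", jac=True, bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
        )
        if not res.success and not np.isfinite(res.fun):
            ok, msg = False, str(res.message)
            continue
        if -res.fun > best_ll:
            best_ll = -res.fun
            best_pis = special.expit(res.x[:n_groups])
            best_theta = float(np.exp(res.x[n_groups]))
    return best_ll, best_pis, best_theta, ok, msg


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    return special.logit(p)


def _lrt_core(protein_id: str, y: np.ndarray, T: np.ndarray,
              group_idx: np.ndarray, classes: tuple[str, ...],
              ) -> BetaBinomialResult:
    G = len(classes)
    pooled = y.sum() / T.sum()
    theta0 = np.log(0.01)
    null_starts = [np.concatenate([_logit(np.array([pooled])), [theta0]])]
    ll_null, pi_null, theta_null, ok_n, msg_n = _fit(y, T, group_idx[:] * 0, 1, null_starts)

    per_class = np.array([
        y[group_idx == g].sum() / max(T[group_idx == g].sum(), 1.0) for g in range(G)
    ])
    alt_starts = [
        np.concatenate([_logit(per_class), [theta0]]),
        # start the alternative at the null optimum so l_alt >= l_null
        np.concatenate([_logit(np.full(G, pi_null[0])),
                        [np.log(max(theta_null, 1e-7))]]),
    ]
    ll_alt, pi_alt, theta_alt, ok_a, msg_a = _fit(y, T, group_idx, G, alt_starts)

    lam = max(2.0 * (ll_alt - ll_null), 0.0)
    df = G - 1
    p = float(stats.chi2.sf(lam, df)) if lam > 0 else 1.0
    return BetaBinomialResult(
        protein_id=protein_id,
        pi_hat_by_group={c: float(pi_alt[g]) for g, c in enumerate(classes)},
        theta_hat=float(theta_alt),
        lrt_stat=float(lam),
        df=df,
        p_value=p,
        converged=ok_n and ok_a,
        message="; ".join(s for s in (msg_n, msg_a) if s),
    )


def betabinom_lrt(m: SpectralCountMatrix, ann: SampleAnnotation,
                  protein_id: str,
                  run_totals: np.ndarray | None = None) -> BetaBinomialResult:
    """Beta-binomial likelihood-ratio test of class effect for one protein.

    Trials default to the matrix's per-run totals (column sums after
    filtering); pass ``run_totals`` to test against pre-filter totals.
    """
    try:
        row = m.protein_ids.index(protein_id)
    except ValueError as exc:
        raise KeyError(f"unknown protein {protein_id!r}") from exc
    y = m.counts[row].astype(float)
    T = (m.run_totals if run_totals is None else np.asarray(run_totals)).astype(float)
    classes = ann.classes
    labels = ann.labels_for(m.run_ids)
    group_idx = np.array([classes.index(c) for c in labels])
    return _lrt_core(protein_id, y, T, group_idx, classes)


def betabinom_test_all(m: SpectralCountMatrix, ann: SampleAnnotation,
                       run_totals: np.ndarray | None = None,
                       ) -> list[BetaBinomialResult]:
    """Run the beta-binomial LRT on every protein of the matrix."""
    T = (m.run_totals if run_totals is None else np.asarray(run_totals)).astype(float)
    classes = ann.classes
    labels = ann.labels_for(m.run_ids)
    group_idx = np.array([classes.index(c) for c in labels])
    return [_lrt_core(pid, m.counts[i].astype(float), T, group_idx, classes)
            for i, pid in enumerate(m.protein_ids)]


def betabinom_rank(results: list[BetaBinomialResult],
                   alpha: float = 0.05) -> RankedFeatureList:
    """Rank by ascending p-value (ties: descending Lambda, then id).

    The selected subset N is every protein with p < ``alpha``.
    """
    order = sorted(results, key=lambda r: (r.p_value, -r.lrt_stat, r.protein_id))
    n_sel = sum(r.p_value < alpha for r in results)
    return RankedFeatureList(
        method_name="betabinomial",
        protein_ids=tuple(r.protein_id for r in order),
        scores=tuple(r.p_value for r in order),
        n_selected=n_sel,
    )


def results_to_frame(results: list[BetaBinomialResult]) -> pd.DataFrame:
    rows = []
    for r in sorted(results, key=lambda r: (r.p_value, -r.lrt_stat, r.protein_id)):
        row = {"protein_id": r.protein_id}
        row.update({f"pi_{c}": v for c, v in r.pi_hat_by_group.items()})
        row.update({"theta": r.theta_hat, "lrt_stat": r.lrt_stat,
                    "df": r.df, "p_value": r.p_value, "converged": r.converged})
        rows.append(row)
    df = pd.DataFrame(rows)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def anova_table(m: SpectralCountMatrix, ann: SampleAnnotation) -> pd.DataFrame:
    """Vectorized one-way fixed-effects ANOVA on raw counts per protein.

    Degenerate proteins with zero between- and zero within-class variance
    get p = 1 by convention; zero within-class variance with distinct
    class means gives p = 0 (infinite F).
    """
    labels = ann.labels_for(m.run_ids)
    classes = ann.classes
    G = len(classes)
    n = m.n_runs
    if any(np.sum(labels == c) < 2 for c in classes):
        raise ValueError("every class needs >=2 runs for ANOVA")
    x = m.counts.astype(float)
    grand = x.mean(axis=1)
    ssb = np.zeros(m.n_proteins)
    ssw = np.zeros(m.n_proteins)
    for c in classes:
        mask = labels == c
        xc = x[:, mask]
        mc = xc.mean(axis=1)
        ssb += mask.sum() * (mc - grand) ** 2
        ssw += ((xc - mc[:, None]) ** 2).sum(axis=1)
    df_b, df_w = G - 1, n - G
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    p = np.empty(m.n_proteins)
    regular = ssw > 0
    p[regular] = stats.f.sf(F[regular], df_b, df_w)
    p[~regular & (ssb > 0)] = 0.0
    F[~regular & (ssb > 0)] = np.inf
    degenerate = ~regular & (ssb == 0)
    p[degenerate] = 1.0
    F[degenerate] = 0.0
    return pd.DataFrame({"protein_id": list(m.protein_ids),
                         "F": F, "p_value": p})


def anova_per_protein(m: SpectralCountMatrix, ann: SampleAnnotation,
                      alpha: float = 0.05) -> RankedFeatureList:
    """One-way ANOVA ranking with selection at p < ``alpha``."""
    tab = anova_table(m, ann)
    tab = tab.sort_values(["p_value", "F", "protein_id"],
                          ascending=[True, False, True], kind="mergesort")
    n_sel = int((tab["p_value"] < alpha).sum())
    return RankedFeatureList(
        method_name="anova",
        protein_ids=tuple(tab["protein_id"]),
        scores=tuple(tab["p_value"]),
        n_selected=n_sel,
    )
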