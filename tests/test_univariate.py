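"""Beta-binomial LRT and the ANOVA baseline."""

import itertools

import numpy as np
import pytest
from scipy import special, stats

import specsel as ss
from specsel.univariate import anova_table, betabinom_loglik


def bb_logpmf_oracle(y, T, pi, theta):
    """Independent log-gamma evaluation of the beta-binomial mass."""
    a, b = pi / theta, (1 - pi) / theta
    lg = special.gammaln
    return (lg(T + 1) - lg(y + 1) - lg(T - y + 1)
            + lg(y + a) + lg(T - y + b) + lg(a + b)
            - lg(T + a + b) - lg(a) - lg(b))


class TestLoglik:
    def test_binomial_limit_single_zero_count(self):
        val = betabinom_loglik(np.array([0]), np.array([10]), 0.5, 0.0)
        assert val == pytest.approx(10 * np.log(0.5), abs=1e-10)

    def test_matches_log_gamma_oracle(self):
        y, T = np.array([2.0, 3.0]), np.array([10.0, 10.0])
        expected = sum(bb_logpmf_oracle(yi, Ti, 0.25, 0.1)
                       for yi, Ti in zip(y, T))
        assert betabinom_loglik(y, T, 0.25, 0.1) == pytest.approx(expected, rel=1e-12)

    def test_count_exceeding_total_is_domain_error(self):
        with pytest.raises(ValueError):
            betabinom_loglik(np.array([11]), np.array([10]), 0.5, 0.1)

    def test_boundary_pi(self):
        assert betabinom_loglik(np.array([0, 0]), np.array([5, 5]), 0.0, 0.1) == 0.0
        assert betabinom_loglik(np.array([1]), np.array([5]), 0.0, 0.1) == -np.inf


def grid_mle(y, T, group_idx, n_groups, rounds=6):
    """Coarse-to-fine grid maximization of the beta-binomial kernel
    likelihood, independent of the package's optimizer."""
    def kernel(pis_run, theta):
        if theta == 0:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (np.where(y > 0, y * np.log(pis_run), 0.0)
                     + np.where(T - y > 0, (T - y) * np.log1p(-pis_run), 0.0))
            return float(t.sum())
        a, b = pis_run / theta, (1 - pis_run) / theta
        return float(np.sum(special.betaln(y + a, T - y + b)
                            - special.betaln(a, b)))

    lp = [np.linspace(-14, 6, 21)] * n_groups
    lt = np.linspace(-10, 3, 15)
    best, arg = -np.inf, None
    for _ in range(rounds):
        for combo in itertools.product(*lp, lt):
            pis = special.expit(np.array(combo[:n_groups]))[group_idx]
            ll = kernel(pis, float(np.exp(combo[n_groups])))
            if ll > best:
                best, arg = ll, combo
        # wide windows (+-2 grid steps) so a drifting pi/theta ridge is
        # not lost while the resolution shrinks
        spans = [g[1] - g[0] for g in lp] + [lt[1] - lt[0]]
        lp = [np.linspace(arg[i] - 2 * spans[i], arg[i] + 2 * spans[i], 13)
              for i in range(n_groups)]
        lt = np.linspace(arg[n_groups] - 2 * spans[-1],
                         arg[n_groups] + 2 * spans[-1], 13)
    # theta = 0 boundary with closed-form binomial MLEs
    pis0 = np.array([y[group_idx == g].sum() / T[group_idx == g].sum()
                     for g in range(n_groups)])
    best = max(best, kernel(pis0[group_idx], 0.0))
    return best


def grid_lrt_pvalue(y, T, group_idx, n_groups):
    ll_alt = grid_mle(y, T, group_idx, n_groups)
    ll_null = grid_mle(y, T, np.zeros_like(group_idx), 1)
    lam = max(2 * (ll_alt - ll_null), 0.0)
    return float(stats.chi2.sf(lam, n_groups - 1)) if lam > 0 else 1.0


def _matrix_from_counts(y, classes):
    runs = tuple(f"run{i}" for i in range(len(y)))
    m = ss.SpectralCountMatrix(("P1", "FILL"), runs,
                               np.array([y, [100 - v for v in y]]))
    ann = ss.SampleAnnotation(runs, tuple(classes))
    return m, ann


class TestBetabinomLRT:
    def test_identical_class_profiles_give_null(self):
        y = [5] * 6
        m, ann = _matrix_from_counts(y, ["A", "A", "B", "B", "C", "C"])
        r = ss.betabinom_lrt(m, ann, "P1")
        assert r.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert r.p_value == pytest.approx(1.0, abs=1e-6)
        assert r.df == 2

    def test_toy_table_matches_grid_search_oracle(self):
        m, ann = _matrix_from_counts([9, 8, 1, 0], ["A", "A", "B", "B"])
        r = ss.betabinom_lrt(m, ann, "P1")
        p_oracle = grid_lrt_pvalue(np.array([9, 8, 1, 0.0]),
                                   np.full(4, 100.0), np.array([0, 0, 1, 1]), 2)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-3)

    def test_lambda_invariant_under_within_class_permutation(self):
        m, ann = _matrix_from_counts([9, 8, 1, 0], ["A", "A", "B", "B"])
        m2, ann2 = _matrix_from_counts([8, 9, 0, 1], ["A", "A", "B", "B"])
        r1 = ss.betabinom_lrt(m, ann, "P1")
        r2 = ss.betabinom_lrt(m2, ann2, "P1")
        assert r1.lrt_stat == pytest.approx(r2.lrt_stat, rel=1e-6, abs=1e-9)

    def test_nesting_lambda_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = rng.integers(0, 30, 6)
            m, ann = _matrix_from_counts(list(y), ["A", "A", "B", "B", "C", "C"])
            assert ss.betabinom_lrt(m, ann, "P1").lrt_stat >= 0

    def test_power_monotone_in_effect_size(self):
        """Rejection rate grows with the planted proportion gap."""
        rates = []
        for fold in (1.5, 3.0, 8.0):
            spec = ss.simulate.planted_spec(
                30, fold, n_proteins=300, seed=13, sigma=1.0)
            m, ann, truth = ss.generate_counts(spec)
            f = ss.filter_low_counts(m)
            res = {r.protein_id: r for r in ss.betabinom_test_all(f, ann)}
            planted = [p for p in truth.protein_id if p in res]
            rates.append(np.mean([res[p].p_value < 0.05 for p in planted]))
        assert rates[0] <= rates[1] + 0.1 <= rates[2] + 0.2
        assert rates[2] > rates[0]


class TestBetabinomRank:
    def _result(self, pid, p, lam=1.0):
        return ss.BetaBinomialResult(pid, {"A": 0.1, "B": 0.2}, 0.01, lam, 1, p)

    def test_selection_at_alpha(self):
        ranked = ss.betabinom_rank(
            [self._result("P1", 0.01), self._result("P2", 0.20)])
        assert ranked.n_selected == 1
        assert ranked.protein_ids[0] == "P1"

    def test_all_null_ranked_by_id(self):
        ranked = ss.betabinom_rank(
            [self._result("Pb", 1.0, 0.0), self._result("Pa", 1.0, 0.0)])
        assert ranked.n_selected == 0
        assert ranked.protein_ids == ("Pa", "Pb")


class TestAnova:
    def _matrix(self, rows, classes):
        runs = tuple(f"r{i}" for i in range(len(classes)))
        ids = tuple(f"P{i}" for i in range(len(rows)))
        return (ss.SpectralCountMatrix(ids, runs, np.array(rows)),
                ss.SampleAnnotation(runs, tuple(classes)))

    def test_equal_class_means_give_small_f(self):
        m, ann = self._matrix([[3, 5, 4, 4, 5, 3]],
                              ["A", "A", "B", "B", "C", "C"])
        tab = anova_table(m, ann)
        assert tab["F"].iloc[0] < 1.0

    def test_strong_separation_matches_closed_form(self):
        rows = [[0, 1, 0, 1, 1000, 1001]]
        m, ann = self._matrix(rows, ["A", "A", "B", "B", "C", "C"])
        tab = anova_table(m, ann)
        f_scipy = stats.f_oneway([0, 1], [0, 1], [1000, 1001])
        assert tab["F"].iloc[0] == pytest.approx(f_scipy.statistic)
        assert tab["p_value"].iloc[0] == pytest.approx(f_scipy.pvalue)
        assert tab["p_value"].iloc[0] < 1e-6

    def test_degenerate_constant_protein_p_one(self):
        m, ann = self._matrix([[2, 2, 2, 2]], ["A", "A", "B", "B"])
        tab = anova_table(m, ann)
        assert tab["p_value"].iloc[0] == 1.0

    def test_ranking_and_selection(self):
        m, ann = self._matrix(
            [[0, 1, 0, 1, 10, 11], [3, 5, 4, 4, 5, 3]],
            ["A", "A", "B", "B", "C", "C"])
        ranked = ss.anova_per_protein(m, ann)
        assert ranked.protein_ids[0] == "P0"
        assert ranked.n_selected == 1
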