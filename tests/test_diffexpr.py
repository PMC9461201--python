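"""Moderated-t differential expression: pooled stats, prior moment matching,
shrunken t, BH adjustment and calls."""

import math

import numpy as np
import pytest
from scipy import special, stats

from fimbria import diffexpr as de


def _sim_matrix(rng, n_genes, n1, n2, delta=None, sigma=1.0):
    """Gaussian log2 expression: genes x cells, groups carrier|control."""
    X = rng.normal(0.0, sigma, size=(n_genes, n1 + n2))
    if delta is not None:
        X[: len(delta), :n1] += np.asarray(delta)[:, None]
    groups = np.array(["carrier"] * n1 + ["control"] * n2, dtype=object)
    return X, groups


class TestFitGeneStats:
    def test_identical_groups_zero_lfc(self):
        X = np.array([[1.0, 4.0, 1.0, 4.0], [2.0, 0.0, 2.0, 0.0]])
        groups = np.array(["carrier", "carrier", "control", "control"], dtype=object)
        gs = de.fit_gene_stats(X, groups)
        assert gs.log2fc == pytest.approx([0, 0])

    def test_hand_computed_pooled_variance(self):
        """{1,3} vs {0,2}: log2FC 1, pooled s2 = 2 on 2 df."""
        X = np.array([[1.0, 3.0, 0.0, 2.0]])
        groups = np.array(["carrier", "carrier", "control", "control"], dtype=object)
        gs = de.fit_gene_stats(X, groups)
        assert gs.log2fc[0] == pytest.approx(1.0)
        assert gs.s2[0] == pytest.approx(2.0)
        assert gs.df == 2

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(0)
        X, groups = _sim_matrix(rng, 30, 5, 7)
        gs = de.fit_gene_stats(X, groups)
        X1, X2 = X[:, :5], X[:, 5:]
        assert gs.log2fc == pytest.approx(X1.mean(1) - X2.mean(1))
        pooled = (X1.var(1, ddof=1) * 4 + X2.var(1, ddof=1) * 6) / 10
        assert gs.s2 == pytest.approx(pooled)

    def test_small_group_rejected(self):
        X = np.zeros((2, 3))
        groups = np.array(["carrier", "control", "control"], dtype=object)
        with pytest.raises(ValueError, match="2 cells"):
            de.fit_gene_stats(X, groups)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(1)
        X, groups = _sim_matrix(rng, 20, 6, 6)
        a = de.fit_gene_stats(X, groups)
        b = de.fit_gene_stats(X, groups, carrier="control", control="carrier")
        assert b.log2fc == pytest.approx(-a.log2fc)
        assert b.s2 == pytest.approx(a.s2)


class TestEstimatePrior:
    def test_parameter_recovery(self):
        """s2 simulated from a (d0=4, s0^2=2) prior at 5000 genes is recovered
        within 15% (d0) / 10% (s0^2)."""
        rng = np.random.default_rng(42)
        d0_true, s0_true, d = 4.0, 2.0, 4
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, size=5000)
        s2 = sigma2 * rng.chisquare(d, size=5000) / d
        prior = de.estimate_prior(s2, df=d)
        assert prior.d0 == pytest.approx(d0_true, rel=0.15)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_constant_s2_infinite_d0(self):
        prior = de.estimate_prior(np.full(100, 1.7), df=10)
        assert math.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(1.7, rel=0.2)

    def test_matches_independent_moment_solution(self):
        """Independent numeric solution of the moment equations agrees to 1e-6."""
        rng = np.random.default_rng(9)
        d = 6
        s2 = 1.5 * (rng.chisquare(d, 400) / d) / (rng.chisquare(8, 400) / 8)
        prior = de.estimate_prior(s2, df=d)
        z = np.log(s2)
        excess = z.var(ddof=1) - special.polygamma(1, d / 2)
        from scipy.optimize import brentq

        half_d0 = brentq(lambda x: special.polygamma(1, x) - excess, 1e-6, 1e8, xtol=1e-12)
        s0_sq = math.exp(
            z.mean() - special.digamma(d / 2) + math.log(d / 2)
            + special.digamma(half_d0) - math.log(half_d0)
        )
        assert prior.d0 == pytest.approx(2 * half_d0, abs=1e-6)
        assert prior.s0_sq == pytest.approx(s0_sq, abs=1e-6)

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="at least"):
            de.estimate_prior(np.ones(5), df=4)


class TestModeratedT:
    def test_tiny_d0_matches_ordinary_t(self):
        """In the no-shrinkage limit the moderated t equals the pooled t."""
        rng = np.random.default_rng(3)
        X, groups = _sim_matrix(rng, 15, 5, 5)
        gs = de.fit_gene_stats(X, groups)
        t_mod, _, _ = de.moderated_t(gs, de.EBayesPrior(d0=1e-9, s0_sq=1.0))
        t_ref = gs.log2fc / np.sqrt(gs.s2 * (1 / 5 + 1 / 5))
        assert t_mod == pytest.approx(t_ref, rel=1e-6)

    def test_null_gene(self):
        gs = de.GeneStats(
            mean_carrier=np.array([1.0]), mean_control=np.array([1.0]),
            log2fc=np.array([0.0]), s2=np.array([1.0]), df=8, n1=5, n2=5,
        )
        t, _, p = de.moderated_t(gs, de.EBayesPrior(4.0, 1.0))
        assert t[0] == 0.0 and p[0] == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        X, groups = _sim_matrix(rng, 25, 6, 8)
        gs = de.fit_gene_stats(X, groups)
        prior = de.EBayesPrior(d0=3.0, s0_sq=0.8)
        t_mod, df_total, p = de.moderated_t(gs, prior)
        s2_post = (3.0 * 0.8 + gs.df * gs.s2) / (3.0 + gs.df)
        t_ref = gs.log2fc / np.sqrt(s2_post * (1 / 6 + 1 / 8))
        assert t_mod == pytest.approx(t_ref, abs=1e-10)
        assert df_total == gs.df + 3.0
        assert p == pytest.approx(2 * stats.t.sf(np.abs(t_ref), gs.df + 3.0), abs=1e-10)

    def test_infinite_d0_normal_reference(self):
        gs = de.GeneStats(
            mean_carrier=np.array([1.0]), mean_control=np.array([0.0]),
            log2fc=np.array([1.0]), s2=np.array([5.0]), df=8, n1=5, n2=5,
        )
        t, df_total, p = de.moderated_t(gs, de.EBayesPrior(math.inf, 1.0))
        assert t[0] == pytest.approx(1.0 / math.sqrt(0.4))
        assert math.isinf(df_total)
        assert p[0] == pytest.approx(2 * stats.norm.sf(t[0]), abs=1e-12)


class TestBhAndCalls:
    def test_hand_computed_bh(self):
        q = de.bh_adjust(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert de.bh_adjust(np.array([0.2])) == pytest.approx([0.2])

    def test_all_ones(self):
        assert de.bh_adjust(np.ones(5)) == pytest.approx(np.ones(5))

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(8)
        p = rng.random(50)
        q = de.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert ((q >= p) & (q <= 1.0)).all()

    @pytest.mark.parametrize(
        "q, lfc, expected",
        [(0.01, 0.5, "up"), (0.01, -0.5, "down"), (0.2, 0.5, "ns"), (0.01, 0.1, "ns")],
    )
    def test_call_rule(self, q, lfc, expected):
        assert de.call_de(np.array([lfc]), np.array([q]))[0] == expected


class TestEstimatorAndCalibration:
    def test_null_calibration(self):
        """No group difference: p < 0.05 rate within binomial 99% CI of 5%,
        q < 0.05 calls essentially absent."""
        hits, calls = 0, 0
        n_genes, n_seeds = 2000, 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X, groups = _sim_matrix(rng, n_genes, 100, 100)
            est = de.ModeratedTTest().fit(X.T, groups)
            hits += int((est.p_ < 0.05).sum())
            calls += int((est.q_ < 0.05).sum())
        lo, hi = stats.binom.interval(0.99, n_genes * n_seeds, 0.05)
        assert lo <= hits <= hi
        assert calls <= 5

    def test_sensitivity_with_planted_effects(self):
        """log2FC = 1 planted in 5% of genes, 200 cells/group: >= 80% of the
        planted genes called at q < 0.05."""
        rng = np.random.default_rng(11)
        n_genes, n_planted = 2000, 100
        X, groups = _sim_matrix(rng, n_genes, 200, 200, delta=np.ones(n_planted))
        est = de.ModeratedTTest().fit(X.T, groups)
        sensitivity = (est.call_[:n_planted] == "up").mean()
        assert sensitivity >= 0.80

    def test_swap_symmetry(self):
        rng = np.random.default_rng(12)
        X, groups = _sim_matrix(rng, 40, 10, 10)
        a = de.ModeratedTTest().fit(X.T, groups)
        b = de.ModeratedTTest(carrier="control", control="carrier").fit(X.T, groups)
        assert b.log2fc_ == pytest.approx(-a.log2fc_)
        assert b.t_ == pytest.approx(-a.t_)

    def test_ranked_list_deterministic(self):
        rng = np.random.default_rng(13)
        X, groups = _sim_matrix(rng, 20, 5, 5)
        est = de.ModeratedTTest().fit(X.T, groups)
        tbl = de.de_table(est, [f"G{i:02d}" for i in range(20)])
        assert (tbl["log2FC"].to_numpy()[:-1] >= tbl["log2FC"].to_numpy()[1:]).all()
        ranked = de.ranked_list(tbl)
        assert list(ranked.columns) == ["gene", "log2FC"]
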