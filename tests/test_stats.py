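"""Inferential layer: Fisher-z machinery, JZS Bayes factor, paired tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pupilstyle.stats import (
    ANCHORED_PRIOR_SCALE,
    anchored_prior_scale,
    bayes_factor_r,
    fisher_z_compare,
    paired_t,
    pearson_full,
    quartile_summary,
    subscale_matrix,
)


def synth_xy(r, n, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = r * x + math.sqrt(1 - r * r) * rng.standard_normal(n)
    return x, y


class TestPearsonFull:
    @pytest.mark.parametrize(
        "r,n,expected_ci",
        [(0.70, 50, (0.52, 0.82)), (0.68, 22, (0.36, 0.86))],
    )
    def test_fisher_ci_endpoints(self, r, n, expected_ci):
        """CI endpoints follow tanh(atanh(r) ± 1.96/sqrt(n-3))."""
        z, se = math.atanh(r), 1 / math.sqrt(n - 3)
        q = sps.norm.ppf(0.975)
        lo, hi = math.tanh(z - q * se), math.tanh(z + q * se)
        assert (round(lo, 2), round(hi, 2)) == expected_ci
        # the function itself, on data engineered to the exact r
        x = np.arange(n, dtype=float)
        # construct y with exact correlation r via two orthogonal vectors
        y0 = np.arange(n, dtype=float)
        e = np.random.default_rng(1).standard_normal(n)
        e -= e.mean()
        e -= (e @ (y0 - y0.mean())) / ((y0 - y0.mean()) @ (y0 - y0.mean())) * (
            y0 - y0.mean())
        y = r * (y0 - y0.mean()) / y0.std() + math.sqrt(1 - r * r) * e / e.std()
        res = pearson_full(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == expected_ci
        assert res.ci_low <= res.r <= res.ci_high

    def test_p_value_matches_t_reference(self):
        x, y = synth_xy(0.5, 40, seed=2)
        res = pearson_full(x, y)
        _, p_ref = sps.pearsonr(x, y)
        assert res.p == pytest.approx(p_ref, rel=1e-10)

    def test_null_p_uniform(self):
        """Under independence, the p-value is uniform (KS over 2000 sims)."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(2000):
            x = rng.standard_normal(50)
            y = rng.standard_normal(50)
            r = np.corrcoef(x, y)[0, 1]
            t = r * math.sqrt(48) / math.sqrt(1 - r * r)
            ps.append(2 * sps.t.sf(abs(t), 48))
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            pearson_full([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            pearson_full([1, 1, 1, 1], [1, 2, 3, 4])


class TestBayesFactor:
    @staticmethod
    def quadrature_oracle(r, n, scale=1.0):
        """Brute-force integration of the same marginal-likelihood integrand
        on a substituted finite domain (g = u/(1-u)), dense trapezoid."""
        u = np.linspace(1e-9, 1 - 1e-9, 200001)
        g = u / (1 - u)
        logf = ((n - 2) / 2.0 * np.log1p(g)
                - (n - 1) / 2.0 * np.log1p((1 - r**2) * g)
                - 1.5 * np.log(g) - n * scale**2 / (2 * g)
                - 2 * np.log1p(-u))
        integral = np.trapezoid(np.exp(logf), u)
        return math.sqrt(n * scale**2 / 2.0) / math.gamma(0.5) * integral

    @pytest.mark.parametrize("r", [0.0, 0.2, 0.5, 0.68, 0.9])
    @pytest.mark.parametrize("n", [10, 22, 50, 100])
    def test_matches_quadrature_oracle(self, r, n):
        bf = bayes_factor_r(r, n)
        assert bf == pytest.approx(self.quadrature_oracle(r, n), rel=5e-4)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        for r, n in [(0.3, 30), (0.68, 22), (0.75, 25)]:
            ref = float(pingouin.bayesfactor_pearson(r, n, method="wetzels"))
            assert bayes_factor_r(r, n) == pytest.approx(ref, rel=1e-6)

    def test_monotone_in_r(self):
        bfs = [bayes_factor_r(r, 30) for r in np.linspace(0, 0.95, 12)]
        assert np.all(np.diff(bfs) > 0)

    def test_null_favoring_at_zero(self):
        assert bayes_factor_r(0.0, 40) < 1

    def test_anchored_scale_reproduces_published_value(self):
        s = anchored_prior_scale(0.68, 22, 62.7)
        assert s == pytest.approx(ANCHORED_PRIOR_SCALE, abs=1e-5)
        assert round(bayes_factor_r(0.68, 22, scale=s), 1) == 62.7

    def test_degenerate_r_raises(self):
        with pytest.raises(ValueError):
            bayes_factor_r(1.0, 20)


class TestFisherZCompare:
    def test_equal_correlations_null(self):
        res = fisher_z_compare(0.5, 30, 0.5, 30)
        assert res.z == 0 and res.p == 1

    def test_hand_computed_example(self):
        res = fisher_z_compare(0.75, 25, 0.64, 25)
        z = (math.atanh(0.75) - math.atanh(0.64)) / math.sqrt(2 / 22)
        assert res.z == pytest.approx(z)
        assert res.z == pytest.approx(0.71, abs=0.01)
        assert res.p == pytest.approx(0.48, abs=0.01)

    def test_antisymmetry(self):
        a = fisher_z_compare(0.7, 20, 0.4, 35)
        b = fisher_z_compare(0.4, 35, 0.7, 20)
        assert a.z == -b.z and a.p == b.p

    def test_type_I_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x1, y1 = rng.standard_normal((2, 28))
            x2, y2 = rng.standard_normal((2, 28))
            r1 = np.corrcoef(x1, y1)[0, 1]
            r2 = np.corrcoef(x2, y2)[0, 1]
            if fisher_z_compare(r1, 28, r2, 28).p < 0.05:
                rejections += 1
        assert rejections / n_sim == pytest.approx(0.05, abs=0.02)


class TestPairedT:
    def test_published_style_round_trip(self):
        """t = -2.72 with df 9 gives two-tailed p rounding to 0.024."""
        assert round(2 * sps.t.sf(2.72, 9), 3) == 0.024

    def test_identical_inputs(self):
        t, df, p = paired_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and df == 2 and p == 1

    def test_matches_exact_sign_flip_distribution(self):
        """p agrees with exhaustive sign-flip resampling of the differences."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(10) + 0.8
        y = rng.standard_normal(10)
        t_obs, df, p = paired_t(x, y)
        d = x - y
        n = d.size
        count = 0
        total = 2**n
        for signs in itertools.product([1, -1], repeat=n):
            ds = d * np.array(signs)
            t = ds.mean() / (ds.std(ddof=1) / math.sqrt(n))
            if abs(t) >= abs(t_obs) - 1e-12:
                count += 1
        p_exact = count / total
        # the t reference and the randomization distribution agree closely
        # for near-symmetric draws
        assert p == pytest.approx(p_exact, abs=0.02)

    def test_scipy_agreement(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 15))
        t, df, p = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestSubscaleMatrix:
    def test_linear_index_correlates_perfectly_with_total(self):
        rng = np.random.default_rng(5)
        sub = rng.integers(0, 11, size=(40, 5)).astype(float)
        total = sub.sum(axis=1)
        out = subscale_matrix(0.01 * total, sub)
        assert out["index_vs_total"].r == pytest.approx(1.0)
        assert out["stars"]["index_vs_total"] == "***"

    def test_independent_subscales_mostly_unstarred(self):
        rng = np.random.default_rng(6)
        sub = rng.normal(5, 2, size=(200, 5))
        idx = rng.standard_normal(200)
        out = subscale_matrix(idx, sub)
        rs = [c.r for c in out["index_vs_subscale"]]
        assert max(abs(np.array(rs))) < 0.25

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            subscale_matrix(np.zeros(10), np.zeros((9, 5)))


class TestQuartileSummary:
    def test_monotone_bins_for_identity(self):
        x = np.arange(50, dtype=float)
        out = quartile_summary(x, x)
        means = [b["mean"] for b in out]
        assert means == sorted(means)
        assert sum(b["n"] for b in out) == 50
        assert all(11 <= b["n"] <= 14 for b in out)

    def test_constant_y(self):
        rng = np.random.default_rng(8)
        out = quartile_summary(rng.standard_normal(40), np.full(40, 2.0))
        assert all(b["mean"] == pytest.approx(2.0) for b in out)
        assert all(b["sem"] == 0 for b in out)
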