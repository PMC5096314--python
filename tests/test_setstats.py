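"""Self-contained statistics: MLRT, TWT and MPDT."""

import numpy as np
import pytest
from scipy import stats

from rmtgsa.rmt import marchenko_pastur, tw_scaling
from rmtgsa.setstats import (
    eigenspectrum,
    ks_distance,
    mlrt_statistic,
    mpdt_statistic,
    twt_statistic,
)
from tests.conftest import orthogonal_centered_columns


class TestMLRT:
    def test_zero_at_identity_sample_covariance(self):
        # orthogonal columns with centered squared norm n give S_gg = I
        n, g = 12, 4
        X = orthogonal_centered_columns(n, g)
        res = mlrt_statistic(X, np.arange(g))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_univariate_closed_form(self):
        # g=1, S=[2]: statistic n(a - ln a - 1) with a=2, df=1
        n, a = 10, 2.0
        X = orthogonal_centered_columns(n, 1, scale=a)
        res = mlrt_statistic(X, [0])
        expected = n * (a - np.log(a) - 1.0)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.statistic == pytest.approx(3.0685, abs=1e-4)
        assert res.pvalue == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_degrees_of_freedom_g_ten(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 15))
        res = mlrt_statistic(X, np.arange(10))
        assert res.pvalue == pytest.approx(
            stats.chi2.sf(res.statistic, 55), rel=1e-12
        )  # df = g(g+1)/2 = 55

    def test_rotation_invariance(self, rng):
        # statistic depends on S_gg only through trace and log-determinant
        X = rng.standard_normal((40, 8))
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        rotated = X @ q
        a = mlrt_statistic(X, np.arange(8)).statistic
        b = mlrt_statistic(rotated, np.arange(8)).statistic
        assert a == pytest.approx(b, rel=1e-9)

    def test_singular_covariance_raises(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((5, 8))  # n - 1 < g: rank-deficient S_gg
        with pytest.raises(ValueError, match="singular"):
            mlrt_statistic(X, np.arange(8))


class TestTWT:
    def test_constructed_flat_spectrum(self):
        # orthogonal set columns with squared norm n: all eigenvalues equal n
        n, g = 20, 5
        X = orthogonal_centered_columns(n, g)
        res = twt_statistic(X, np.arange(g))
        sc = tw_scaling(g, n)
        assert res.statistic == pytest.approx((n - sc.mu) / sc.sigma, rel=1e-10)

    def test_duplicated_column_brute_force(self, rng):
        # two identical genes: lambda1 = 2 * centered column sum of squares
        col = rng.standard_normal(30)
        X = np.column_stack([col, col, rng.standard_normal(30)])
        spec = eigenspectrum(X, [0, 1])
        c = col - col.mean()
        assert spec[0] == pytest.approx(2 * c @ c, rel=1e-10)
        assert spec[1] == pytest.approx(0.0, abs=1e-7)
        brute = np.linalg.eigvalsh(np.cov(X[:, :2].T, bias=True) * 30)[::-1]
        assert np.allclose(spec, brute, atol=1e-7)

    def test_pvalue_is_upper_tail_tw(self, rng):
        X = rng.standard_normal((50, 12))
        res = twt_statistic(X, np.arange(10))
        from rmtgsa.rmt import tracy_widom_goe

        assert res.pvalue == pytest.approx(
            float(tracy_widom_goe().sf(res.statistic)), rel=1e-12
        )


class TestMPDT:
    def test_degenerate_spectrum_at_upper_edge(self):
        mp = marchenko_pastur(0.1)
        vals = np.full(10, mp.b_plus)
        assert ks_distance(vals, mp.cdf) == pytest.approx(1.0)

    def test_quantile_placement_minimizes_distance(self):
        g = 10
        mp = marchenko_pastur(10 / 99)
        vals = mp.ppf(np.arange(1, g + 1) / (g + 1))
        assert ks_distance(np.sort(vals), mp.cdf) <= 1.0 / (g + 1) + 1e-9

    def test_matches_brute_force_sup(self, rng):
        # exact sup over both sides of every jump vs dense-grid brute force
        mp = marchenko_pastur(10 / 99)
        vals = np.sort(mp.ppf(rng.random(10) * 0.98 + 0.01))
        d = ks_distance(vals, mp.cdf)
        grid = np.linspace(mp.b_minus - 0.01, mp.b_plus + 0.01, 200_001)
        ecdf = np.searchsorted(vals, grid, side="right") / vals.size
        brute = np.max(np.abs(ecdf - mp.cdf(grid)))
        assert d >= brute - 1e-9
        assert d == pytest.approx(brute, abs=1e-4)

    def test_rank_deficient_set_refused(self, rng):
        X = rng.standard_normal((8, 10))
        with pytest.raises(ValueError, match="g <= n - 1"):
            mpdt_statistic(X, np.arange(10))

    def test_statistic_in_unit_interval(self, rng):
        X = rng.standard_normal((100, 20))
        res = mpdt_statistic(X, np.arange(10))
        assert 0.0 <= res.statistic <= 1.0
        assert res.anticonservative


class TestSharedInvariants:
    def test_trace_conservation(self, rng):
        # trace(n S_gg) equals the sum of centered squared column norms
        X = rng.standard_normal((30, 12))
        idx = np.array([1, 4, 7, 9])
        spec = eigenspectrum(X, idx)
        c = X[:, idx] - X[:, idx].mean(axis=0)
        assert spec.sum() == pytest.approx(np.sum(c**2), rel=1e-10)

    @pytest.mark.parametrize("fn", [mlrt_statistic, twt_statistic, mpdt_statistic])
    def test_invariant_to_sample_and_gene_ordering(self, fn, rng):
        X = rng.standard_normal((40, 15))
        idx = np.array([0, 3, 5, 8, 11])
        base = fn(X, idx).statistic
        assert fn(X[rng.permutation(40)], idx).statistic == pytest.approx(
            base, rel=1e-9
        )
        assert fn(X, rng.permutation(idx)).statistic == pytest.approx(base, rel=1e-9)

    def test_zero_variance_column_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        X[:, 2] = 3.14
        with pytest.raises(ValueError, match="zero-variance"):
            twt_statistic(X, [0, 2, 4])

    def test_duplicate_indices_rejected(self, rng):
        X = rng.standard_normal((20, 5))
        with pytest.raises(ValueError, match="duplicate"):
            mlrt_statistic(X, [0, 0, 1])
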