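"""Tracy-Widom order-1 law, Marčenko-Pastur law and scaling constants."""

import numpy as np
import pytest
from scipy.integrate import quad

from rmtgsa.rmt import marchenko_pastur, tracy_widom_goe, tw_scaling

# published GOE constants for the Tracy-Widom order-1 distribution
TW1_MEAN = -1.2065335746
TW1_VAR = 1.6077810346
TW1_MEDIAN = -1.2686


class TestTWScaling:
    @pytest.mark.parametrize(
        "g, n, mu, sigma",
        [
            (4, 5, 16.0, 4.0),  # (2+2)^2 and (2+2)*1^(1/3)
            (1, 2, 4.0, 2.0 * 2.0 ** (1.0 / 3.0)),
        ],
    )
    def test_closed_form_values(self, g, n, mu, sigma):
        sc = tw_scaling(g, n)
        assert sc.mu == pytest.approx(mu, abs=1e-12)
        assert sc.sigma == pytest.approx(sigma, abs=1e-12)

    def test_closed_form_re_evaluation(self):
        g, n = 10, 100
        sc = tw_scaling(g, n)
        a, b = np.sqrt(n - 1), np.sqrt(g)
        assert sc.mu == pytest.approx((a + b) ** 2, rel=1e-14)
        assert sc.sigma == pytest.approx((a + b) * (1 / a + 1 / b) ** (1 / 3), rel=1e-14)
        assert sc.mu > 0 and sc.sigma > 0

    def test_invalid_sample_size(self):
        with pytest.raises(ValueError, match="sample size"):
            tw_scaling(4, 1)
        with pytest.raises(ValueError, match="set size"):
            tw_scaling(0, 10)


class TestTracyWidomGOE:
    def test_cdf_limits_and_monotonicity(self):
        tw = tracy_widom_goe()
        assert tw.cdf(-50.0) == 0.0
        assert tw.cdf(50.0) == 1.0
        grid = np.linspace(-12.0, 7.0, 1000)
        vals = tw.cdf(grid)
        assert np.all(np.diff(vals) >= 0)
        assert np.all((vals >= 0) & (vals <= 1))

    def test_median(self):
        assert tracy_widom_goe().cdf(TW1_MEDIAN) == pytest.approx(0.5, abs=1e-3)

    def test_mean_and_variance_match_published_constants(self):
        # independent moment check of the Painlevé II tabulation
        tw = tracy_widom_goe()
        x = np.linspace(-13.0, 8.0, 20001)
        pdf = np.gradient(tw.cdf(x), x)
        mean = np.trapezoid(x * pdf, x)
        var = np.trapezoid((x - mean) ** 2 * pdf, x)
        assert mean == pytest.approx(TW1_MEAN, abs=5e-4)
        assert var == pytest.approx(TW1_VAR, abs=5e-4)

    @pytest.mark.parametrize("q, x", [(0.90, 0.4501), (0.95, 0.9793), (0.99, 2.0234)])
    def test_published_upper_quantiles(self, q, x):
        assert tracy_widom_goe().cdf(x) == pytest.approx(q, abs=1e-3)
        assert tracy_widom_goe().ppf(q) == pytest.approx(x, abs=1e-3)


class TestMarchenkoPastur:
    def test_support_edges_closed_form(self):
        gamma = 10 / 99  # g=10, n=100
        mp = marchenko_pastur(gamma)
        assert mp.b_minus == pytest.approx((1 - np.sqrt(gamma)) ** 2, rel=1e-14)
        assert mp.b_plus == pytest.approx((1 + np.sqrt(gamma)) ** 2, rel=1e-14)
        assert mp.cdf(mp.b_minus - 1e-9) == 0.0
        assert mp.cdf(mp.b_plus + 1e-9) == 1.0

    @pytest.mark.parametrize("gamma", [0.05, 0.1, 0.5, 1.0])
    def test_density_normalization(self, gamma):
        mp = marchenko_pastur(gamma)
        total, _ = quad(mp.pdf, mp.b_minus, mp.b_plus, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("gamma", [0.05, 10 / 99, 0.8])
    def test_cdf_quantile_roundtrip(self, gamma):
        mp = marchenko_pastur(gamma)
        q = np.linspace(0.01, 0.99, 99)
        assert np.max(np.abs(mp.cdf(mp.ppf(q)) - q)) < 1e-6

    def test_monotone_cdf(self):
        mp = marchenko_pastur(0.3)
        x = np.linspace(mp.b_minus, mp.b_plus, 2000)
        assert np.all(np.diff(mp.cdf(x)) >= 0)

    def test_rank_deficient_regime_refused(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            marchenko_pastur(1.5)
        with pytest.raises(ValueError, match="positive"):
            marchenko_pastur(-0.1)


def test_audit_table_dumps(tmp_path):
    f1_path = tmp_path / "f1.tsv"
    tracy_widom_goe().dump_table(f1_path)
    x, f1 = np.loadtxt(f1_path, skiprows=1, unpack=True)
    assert np.all(np.diff(x) > 0) and 0.0 <= f1.min() and f1.max() <= 1.0

    mp_path = tmp_path / "mp.tsv"
    marchenko_pastur(0.25).dump_table(mp_path)
    x, g = np.loadtxt(mp_path, skiprows=1, unpack=True)
    assert g[0] == 0.0 and g[-1] == 1.0


def test_second_order_scaling_shifts_constants():
    plain = tw_scaling(10, 100)
    corr = tw_scaling(10, 100, corrected=True)
    assert corr.mu < plain.mu  # half-step df correction centers lower
    assert corr.sigma == pytest.approx(plain.sigma, rel=0.02)
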