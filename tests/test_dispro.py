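"""The four disproportionality estimators and their oracles."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from pvsignal.dispro import (ContingencyTable, GPSPrior, SignalMetrics,
                             SignalThresholds, bcpnn_ic, classify,
                             compute_metrics, mgps_ebgm, mgps_fit_prior,
                             mgps_posterior_weight, prr_estimate,
                             ror_estimate, _mixture_loglik, MGPS_START)
from pvsignal.errors import ValidationError

T_REF = ContingencyTable(a=10, b=90, c=100, d=9800)


class TestContingencyTable:
    def test_expected_count(self):
        assert T_REF.expected == pytest.approx(100 * 110 / 10000)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(a=-1, b=0, c=0, d=5)

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(a=0, b=0, c=0, d=0)


class TestROR:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = ror_estimate(ContingencyTable(10, 10, 10, 10))
        assert ror == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_reference_table(self):
        """ad/bc = 98000/9000; CI from the log-scale Wald formula."""
        ror, lo, hi = ror_estimate(T_REF)
        assert ror == pytest.approx(10.888888, rel=1e-6)
        se = math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9800)
        assert lo == pytest.approx(ror * math.exp(-1.959964 * se), rel=1e-6)
        assert (lo, hi) == (pytest.approx(5.50, rel=5e-3),
                            pytest.approx(21.55, rel=5e-3))

    def test_zero_cell_continuity_correction(self):
        ror, lo, hi = ror_estimate(ContingencyTable(0, 10, 10, 100))
        assert 0 < ror < math.inf and 0 < lo < hi < math.inf


class TestPRR:
    def test_reference_table(self):
        prr, chi2 = prr_estimate(T_REF)
        assert prr == pytest.approx((10 / 100) / (100 / 9900), rel=1e-9)
        assert prr == pytest.approx(9.9, rel=1e-9)
        n = 10000
        ref = n * (abs(10 * 9800 - 90 * 100) - n / 2) ** 2 / (
            100 * 9900 * 110 * 9890)
        assert chi2 == pytest.approx(ref, rel=1e-9)
        assert chi2 == pytest.approx(65.5, rel=1e-2)

    def test_homogeneous_rates(self):
        prr, chi2 = prr_estimate(ContingencyTable(10, 90, 100, 900))
        assert prr == pytest.approx(1.0)
        assert chi2 < 0.1

    def test_zero_a_reports_zero_with_raw_chi2(self):
        prr, chi2 = prr_estimate(ContingencyTable(0, 100, 50, 9850))
        assert prr == 0.0 and chi2 >= 0


class TestBCPNN:
    def test_ic_zero_when_a_equals_expectation(self):
        for k in (1, 5, 50):
            ic, *_ = bcpnn_ic(ContingencyTable(k, k, k, k))
            assert ic == pytest.approx(0.0, abs=1e-12)

    def test_reference_table(self):
        ic, ic025, ic975 = bcpnn_ic(T_REF)
        assert ic == pytest.approx(math.log2(10.5 / 1.6), rel=1e-9)
        assert ic == pytest.approx(2.714, abs=2e-3)
        assert ic025 == pytest.approx(
            ic - 3.3 * 10.5 ** -0.5 - 2.0 * 10.5 ** -1.5, rel=1e-9)
        assert ic025 == pytest.approx(1.637, abs=2e-3)
        assert ic025 < ic < ic975

    def test_credibility_interval_shrinks_with_a(self):
        widths = []
        for scale in (1, 10, 100, 1000):
            t = ContingencyTable(10 * scale, 90 * scale, 100 * scale,
                                 9800 * scale)
            ic, ic025, ic975 = bcpnn_ic(t)
            widths.append(ic975 - ic025)
        assert widths == sorted(widths, reverse=True)
        assert widths[-1] < 0.1


def collapsed_prior():
    # both components identical -> effectively a single Gamma(1, 1) prior
    return GPSPrior(1.0, 1.0, 1.0, 1.0, 0.5)


class TestMGPS:
    def test_ebgm_collapsed_prior_closed_form(self):
        """Gamma(1,1) prior, a=0, E=1 -> posterior Gamma(1,2)."""
        t = ContingencyTable(0, 100, 100, 9800)
        assert t.expected == pytest.approx(1.0)
        ebgm, eb05 = mgps_ebgm(t, collapsed_prior())
        assert ebgm == pytest.approx(math.exp(special.digamma(1) - math.log(2)),
                                     rel=1e-9)
        assert ebgm == pytest.approx(0.281, abs=1e-3)
        assert eb05 == pytest.approx(-math.log(0.95) / 2, rel=1e-6)
        assert eb05 == pytest.approx(0.0256, abs=1e-4)

    def test_shrinkage_vanishes_in_the_data_limit(self):
        prior = collapsed_prior()
        for scale in (1, 10, 1000):
            t = ContingencyTable(30 * scale, 1000 * scale, 1000 * scale,
                                 100000 * scale)
            ebgm, _ = mgps_ebgm(t, prior)
            if scale == 1000:
                assert ebgm == pytest.approx(t.a / t.expected, rel=2e-3)

    def test_ebgm_shrinks_between_prior_and_observed_ratio(self):
        """EBGM stays inside [prior geometric mean, a/E] (sorted bracket).

        The lower edge uses the prior's geometric mean exp(E[ln lambda]) —
        EBGM is itself a geometric mean, so that is the quantity it shrinks
        toward, sitting slightly below the arithmetic prior mean.
        """
        rng = np.random.default_rng(5)
        for _ in range(50):
            alpha, beta = rng.uniform(0.2, 5.0, size=2)
            prior = GPSPrior(alpha, beta, alpha, beta, 0.5)
            prior_gm = math.exp(special.digamma(alpha) - math.log(beta))
            a = int(rng.integers(1, 60))
            b = int(rng.integers(a, a + 500))
            t = ContingencyTable(a, b, 1, 1)
            ebgm, eb05 = mgps_ebgm(t, prior)
            lo, hi = sorted((prior_gm, t.a / t.expected))
            assert lo - 1e-9 <= ebgm <= hi + 1e-9
            assert eb05 <= ebgm

    def test_ebgm_monotone_in_a_at_fixed_expected(self):
        prior = GPSPrior(0.7, 0.8, 2.0, 1.5, 0.4)
        values = []
        for a in range(0, 30, 3):
            q = mgps_posterior_weight(a, 5.0, prior)
            mean_log = (q * (special.digamma(prior.alpha1 + a)
                             - math.log(prior.beta1 + 5.0))
                        + (1 - q) * (special.digamma(prior.alpha2 + a)
                                     - math.log(prior.beta2 + 5.0)))
            values.append(math.exp(mean_log))
        assert values == sorted(values)

    def test_eb05_matches_numerical_cdf_inversion(self):
        """Bracketed root eb05 vs quadrature-of-pdf bisection oracle."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            prior = GPSPrior(*rng.uniform(0.2, 4.0, size=4),
                             float(rng.uniform(0.1, 0.9)))
            t = ContingencyTable(int(rng.integers(0, 40)),
                                 int(rng.integers(0, 500)),
                                 int(rng.integers(0, 500)),
                                 int(rng.integers(100, 20000)))
            _, eb05 = mgps_ebgm(t, prior)
            a, E = t.a, t.expected
            q = mgps_posterior_weight(a, E, prior)

            def pdf(x):
                return (q * stats.gamma.pdf(x, prior.alpha1 + a,
                                            scale=1 / (prior.beta1 + E))
                        + (1 - q) * stats.gamma.pdf(x, prior.alpha2 + a,
                                                    scale=1 / (prior.beta2 + E)))
            lo, hi = 0.0, 50.0
            for _ in range(60):  # bisect integral of the pdf to 5%
                mid = (lo + hi) / 2
                mass = integrate.quad(pdf, 0, mid, limit=200)[0]
                if mass < 0.05:
                    lo = mid
                else:
                    hi = mid
            assert eb05 == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_fit_recovers_single_gamma_prior(self):
        """Cells simulated from Gamma(2, rate 4): mixture mean near 0.5."""
        rng = np.random.default_rng(23)
        n = 10_000
        E = rng.lognormal(0.5, 1.0, size=n)
        lam = rng.gamma(2.0, 1.0 / 4.0, size=n)
        a = rng.poisson(lam * E)
        prior = mgps_fit_prior(np.column_stack([a, E]))
        assert prior.mean == pytest.approx(0.5, rel=0.10)

    def test_fit_improves_likelihood_over_start(self):
        rng = np.random.default_rng(29)
        E = rng.lognormal(0, 1, size=500)
        a = rng.poisson(E)
        cells = np.column_stack([a, E])
        prior = mgps_fit_prior(cells)
        fitted = _mixture_loglik(
            (prior.alpha1, prior.beta1, prior.alpha2, prior.beta2,
             prior.p_mix), cells[:, 0], cells[:, 1])
        at_start = _mixture_loglik(MGPS_START, cells[:, 0], cells[:, 1])
        assert fitted >= at_start

    def test_degenerate_all_zero_counts(self):
        E = np.full(100, 2.0)
        a = np.zeros(100)
        prior = mgps_fit_prior(np.column_stack([a, E]))
        assert prior.mean < 0.5  # converges to a small-mean prior

    def test_few_cells_warns(self, caplog):
        with caplog.at_level("WARNING"):
            mgps_fit_prior([(1, 1.0)] * 10)
        assert "only 10 cells" in caplog.text


class TestCoherence:
    def test_sign_coherence_and_ror_dominates_prr(self):
        """(ror-1), (prr-1), ic share sign; ror >= prr when ror > 1."""
        rng = np.random.default_rng(41)
        for _ in range(200):
            t = ContingencyTable(*(int(v) for v in rng.integers(1, 300, 4)))
            ror, *_ = ror_estimate(t)
            prr, _ = prr_estimate(t)
            ic, *_ = bcpnn_ic(t)
            if abs(ror - 1) > 1e-6:
                assert (ror - 1) * (prr - 1) >= -1e-9
                assert (ror - 1) * ic >= -1e-6 or abs(ic) < 0.05
            if ror > 1:
                assert ror >= prr - 1e-9


class TestClassify:
    def base_metrics(self, **kw):
        m = SignalMetrics(a=10, expected=1.0, ror=5, ror_lo95=2, ror_hi95=10,
                          prr=5, prr_chi2=20, ic=2, ic025=1, ic975=3,
                          ebgm=4, eb05=2.5)
        for k, v in kw.items():
            setattr(m, k, v)
        return m

    def test_minimum_count_gate(self):
        flags = classify(self.base_metrics(a=2))
        assert not flags["ror"] and not flags["prr"]
        assert flags["bcpnn"] and flags["mgps"]

    def test_ic025_boundary_is_strict(self):
        assert not classify(self.base_metrics(ic025=0.0))["bcpnn"]

    def test_eb05_boundary_is_strict(self):
        assert not classify(self.base_metrics(eb05=2.0))["mgps"]

    def test_aggregates(self):
        flags = classify(self.base_metrics())
        assert flags["any"] and flags["all_four"]
        flags = classify(self.base_metrics(ic025=-1))
        assert flags["any"] and not flags["all_four"]

    def test_reference_table_flags(self):
        m = compute_metrics(T_REF, prior=collapsed_prior())
        assert m.flags["ror"] and m.flags["prr"]
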