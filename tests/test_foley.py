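"""Foley solute-micelle binding fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from chromqsar.dataset import RetentionSeries
from chromqsar.errors import (
    DataValidationError,
    DegenerateFitError,
    InsufficientDataError,
)
from chromqsar.foley import fit_foley, fit_foley_batch
from chromqsar.simulate import FoleyTruth, gen_foley_series

X4 = np.array([0.075, 0.100, 0.125, 0.150])


def mlc_series(k, x=X4, cid="c"):
    return RetentionSeries(cid, "MLC", "surfactant_molarity", x=np.asarray(x), k=np.asarray(k))


class TestFitFoley:
    def test_reproduces_published_compound_2(self):
        """The printed descriptor for a mid-lipophilicity congener."""
        fit = fit_foley(mlc_series([25.51, 21.45, 18.25, 17.34]))
        assert fit.log_km == pytest.approx(1.68, abs=0.01)
        assert fit.r_squared == pytest.approx(0.9662, abs=5e-4)
        assert fit.n_points == 4
        assert not fit.negative_intercept

    def test_constant_series_has_zero_binding(self):
        fit = fit_foley(mlc_series([10.0, 10.0, 10.0, 10.0]))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.km == pytest.approx(10.0)
        assert fit.k_am == pytest.approx(0.0, abs=1e-10)
        assert fit.log_km == pytest.approx(1.0)
        assert fit.r_squared == 1.0

    def test_noiseless_model_inverted_exactly(self):
        km, kam = 50.0, 20.0
        k = km / (1.0 + kam * X4)
        fit = fit_foley(mlc_series(k))
        assert fit.km == pytest.approx(km, rel=1e-10)
        assert fit.k_am == pytest.approx(kam, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        km=st.floats(0.5, 500.0),
        kam=st.floats(0.0, 80.0),
    )
    def test_exact_recovery_property(self, km, kam):
        """Any noiseless Foley curve over >= 3 concentrations is inverted exactly."""
        k = km / (1.0 + kam * X4)
        fit = fit_foley(mlc_series(k))
        assert abs(fit.km - km) / km < 1e-10
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_monotone_decreasing_retention_gives_positive_binding(self, bundled):
        for cid in bundled.compound_ids:
            s = bundled.get_series(cid, "MLC")
            if np.all(np.diff(s.k) < 0):
                with np.errstate(all="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        fit = fit_foley(s)
                assert fit.slope > 0
                assert fit.k_am > 0

    def test_matches_generic_least_squares_minimizer(self):
        """Closed-form OLS equals a numerically minimized SSE on 1/k vs x."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            k = rng.uniform(2.0, 60.0, size=4)
            fit = fit_foley(mlc_series(k))
            y = 1.0 / k

            def sse(p):
                return np.sum((y - (p[0] + p[1] * X4)) ** 2)

            res = minimize(sse, x0=[y.mean(), 0.0], method="Nelder-Mead",
                           options={"xatol": 1e-14, "fatol": 1e-18, "maxiter": 20000})
            assert fit.intercept == pytest.approx(res.x[0], rel=1e-6, abs=1e-10)
            assert fit.slope == pytest.approx(res.x[1], rel=1e-6, abs=1e-10)

    def test_cmc_subtraction_shifts_the_abscissa(self):
        km, kam, cmc = 40.0, 15.0, 9e-5
        k = km / (1.0 + kam * (X4 - cmc))
        fit = fit_foley(mlc_series(k), cmc=cmc)
        assert fit.km == pytest.approx(km, rel=1e-10)
        assert fit.k_am == pytest.approx(kam, rel=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_foley(mlc_series([10.0, 8.0], x=[0.1, 0.15]))

    def test_wrong_series_kind_rejected(self):
        s = RetentionSeries("c", "IAM", "modifier_volume_fraction",
                            x=[0.2, 0.3, 0.4], k=[5.0, 3.0, 2.0])
        with pytest.raises(DataValidationError):
            fit_foley(s)

    def test_negative_intercept_strict_raises_lenient_flags(self):
        # strongly bound solute measured far from [M]=0: extrapolated
        # 1/k intercept goes negative
        k = [60.81, 46.76, 34.01, 29.82]
        with pytest.raises(DegenerateFitError):
            fit_foley(mlc_series(k), strict=True)
        with pytest.warns(RuntimeWarning, match="negative"):
            fit = fit_foley(mlc_series(k))
        assert fit.negative_intercept
        assert fit.log_km == pytest.approx(2.82, abs=0.01)


class TestBatch:
    def test_bundled_spot_values(self, table):
        with pytest.warns(RuntimeWarning):
            res = fit_foley_batch(table)
        assert len(res.fits) == 19 and not res.failures
        assert res.fits["14"].log_km == pytest.approx(2.70, abs=0.01)
        assert res.fits["17"].r_squared == pytest.approx(0.8604, abs=5e-4)
        # derived descriptor written back onto the table
        assert table.derived_descriptors["log_km"]["14"] == res.fits["14"].log_km

    def test_missing_series_lands_in_failure_list(self, table):
        table.retention = [s for s in table.retention if s.compound_id != "3"]
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_foley_batch(table)
        assert "3" in res.failures
        assert len(res.fits) == 18


class TestGeneratorRecovery:
    def test_small_noise_recovery(self):
        """Monte-Carlo over 500 replicate series at 1-2% retention noise.

        log k_m is recovered nearly unbiasedly; k_m = 1/intercept itself
        carries the second-order (Jensen) bias of inverting a noisy
        intercept, which must shrink ~quadratically with the noise level.
        """
        km, kam = 50.0, 20.0

        def run(cv):
            kms, lkms = [], []
            for seed in range(500):
                s = gen_foley_series(FoleyTruth(km=km, k_am=kam, noise_cv=cv, seed=seed))
                fit = fit_foley(s)
                kms.append(fit.km)
                lkms.append(fit.log_km)
            return np.mean(kms) / km - 1.0, np.mean(lkms) - np.log10(km)

        bias_02, logbias_02 = run(0.02)
        bias_01, _ = run(0.01)
        assert abs(logbias_02) < 0.01
        assert abs(bias_02) < 0.04
        assert abs(bias_01) < 0.35 * abs(bias_02)  # ~quadratic in the noise CV
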