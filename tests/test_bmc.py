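"""Benchmark-concentration modeling: fits, BMC inversion, CIs, filters."""

import itertools

import numpy as np
import pytest

from cometddi import bmc as B
from cometddi.synthetic import hill_k_for_bmc, hill_response

CONC = np.repeat([0.0, 2.5, 5.0, 10.0, 20.0, 40.0], 4)


def _series(y, conc=CONC, kind="gene"):
    return B.DoseResponseSeries(conc, np.asarray(y, dtype=float), kind)


def _linear_series(a=10.0, b=2.0, sd=1e-9, seed=0):
    rng = np.random.default_rng(seed)
    return _series(a + b * CONC + rng.normal(0, sd, CONC.size))


class TestFitting:
    def test_exact_linear_recovery_and_aic_choice(self):
        s = _linear_series()
        fits = B.fit_model_suite(s)
        best = B.select_best_model(fits)
        assert best.model_name == "Linear"
        assert best.params[1] == pytest.approx(2.0, abs=1e-6)
        assert best.fit_p == pytest.approx(1.0)

    def test_exp5_sigmoid_recovered_by_flexible_exponentials(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            mu = 10.0 - 2.0 * np.exp(-(0.12 * CONC) ** 2.5)
            s = _series(mu + rng.normal(0, 0.1, CONC.size))
            best = B.select_best_model(B.fit_model_suite(s))
            hits += best.model_name in ("Exp4", "Exp5")
        assert hits >= 27

    def test_lack_of_fit_detected_for_nonmonotone_data(self):
        # V-shaped means cannot be described by the monotone Power curve
        means = np.array([10.0, 6.0, 4.0, 4.5, 8.0, 12.0])
        rng = np.random.default_rng(1)
        s = _series(np.repeat(means, 4) + rng.normal(0, 0.2, CONC.size))
        fits = {f.model_name: f for f in B.fit_model_suite(s)}
        assert fits["Power"].fit_p < 0.1

    def test_select_best_model_rules(self):
        s = _linear_series(sd=0.5)
        fits = B.fit_model_suite(s)
        single = [fits[0]]
        assert B.select_best_model(single) is fits[0]
        by_name = {f.model_name: f for f in fits}
        lin, poly = by_name["Linear"], by_name["Poly2"]
        poly.aic = lin.aic  # exact tie -> parsimony
        assert B.select_best_model([poly, lin]).model_name == "Linear"
        fits3 = [fits[0], fits[1], fits[2]]
        fits3[0].aic, fits3[1].aic, fits3[2].aic = 102.1, 98.4, 99.0
        assert B.select_best_model(fits3) is fits3[1]
        with pytest.raises(ValueError):
            B.select_best_model([])


class TestBmcInversion:
    def test_linear_closed_form(self):
        fit = B.ModelFit("Linear", np.array([10.0, 2.0]), 0, 1.0, 4.0, "up", 0, 2)
        assert B.bmc_from_fit(fit, _linear_series()) == pytest.approx(2.0)
        flat = B.ModelFit("Linear", np.array([10.0, 0.0]), 0, 1.0, 4.0, "up", 0, 2)
        assert np.isinf(B.bmc_from_fit(flat, _linear_series()))

    def test_exp2_closed_form_value(self):
        fit = B.ModelFit("Exp2", np.array([1.0, 0.1]), 0, 1.0, 0.2, "up", 0, 2)
        assert B.bmc_from_fit(fit, _linear_series()) == pytest.approx(
            np.log(1.2) / 0.1, rel=1e-12)

    def test_closed_forms_match_root_finder(self):
        """Linear/Exp2 (and Power/Exp4/Exp5) closed forms vs bracketed roots."""
        rng = np.random.default_rng(2)
        s = _linear_series()
        for _ in range(100):
            sd = rng.uniform(0.05, 1.0)
            cases = [
                B.ModelFit("Linear", np.array([rng.normal(10, 2),
                                               rng.uniform(0.05, 2)]),
                           0, 1.0, sd, "up", 0, 2),
                B.ModelFit("Exp2", np.array([rng.uniform(0.5, 20),
                                             rng.uniform(-0.08, 0.08) or 0.01]),
                           0, 1.0, sd, "up", 0, 2),
                B.ModelFit("Power", np.array([rng.normal(10, 2),
                                              rng.uniform(0.01, 1),
                                              rng.uniform(1, 4)]),
                           0, 1.0, sd, "up", 0, 3),
            ]
            for fit in cases:
                closed = B.bmc_from_fit(fit, s)
                root = B.bmc_root_generic(fit, s)
                if np.isfinite(closed) and closed <= 10 * s.cmax:
                    assert closed == pytest.approx(root, abs=1e-8, rel=1e-8)
                else:
                    assert np.isinf(closed) == np.isinf(root) or root > s.cmax * 9

    def test_shift_invariance_and_concentration_scaling(self):
        rng = np.random.default_rng(3)
        y = 5.0 + 0.4 * CONC + rng.normal(0, 0.5, CONC.size)
        e1 = B.estimate_bmc(_series(y), ci_method="delta")
        e2 = B.estimate_bmc(_series(y + 100.0), ci_method="delta")
        assert e1.bmc == pytest.approx(e2.bmc, rel=1e-6)
        e3 = B.estimate_bmc(B.DoseResponseSeries(CONC * 4.0, y), ci_method="delta")
        assert e3.bmc == pytest.approx(4.0 * e1.bmc, rel=1e-6)


class TestConfidenceLimits:
    def test_interval_scales_with_noise_and_stays_bounded(self):
        """The BMC (and its CI) shrink proportionally to the residual SD.

        With BMR = 1 x estimated SD the BMC is proportional to sigma-hat, so
        the *relative* CI width has a floor set by sigma-hat's own sampling
        error (~1/sqrt(2(n-k)) on the log scale); the absolute interval
        collapses linearly as the noise vanishes.
        """
        widths = {}
        for sd in (1e-2, 1e-4):
            s = _linear_series(sd=sd, seed=4)
            fit = B.select_best_model(B.fit_model_suite(s))
            bmc = B.bmc_from_fit(fit, s)
            lo, hi, flag = B.bmc_confidence_limits(fit, s, bmc, method="profile")
            assert lo <= bmc <= hi and flag == ""
            assert hi / lo < 2.2
            widths[sd] = hi - lo
        assert widths[1e-4] == pytest.approx(widths[1e-2] / 100, rel=0.05)

    def test_profile_close_to_delta_for_linear(self):
        rng = np.random.default_rng(5)
        s = _series(10 + 0.5 * CONC + rng.normal(0, 0.8, CONC.size))
        fit = [f for f in B.fit_model_suite(s) if f.model_name == "Linear"][0]
        bmc = B.bmc_from_fit(fit, s)
        plo, phi, _ = B.bmc_confidence_limits(fit, s, bmc, method="profile")
        dlo, dhi, _ = B.bmc_confidence_limits(fit, s, bmc, method="delta")
        assert plo == pytest.approx(dlo, rel=0.10)
        assert phi == pytest.approx(dhi, rel=0.10)

    def test_ordering_invariant_on_random_genes(self):
        rng = np.random.default_rng(6)
        checked = 0
        for _ in range(40):
            slope = rng.uniform(0.05, 0.6)
            y = 8 + slope * CONC + rng.normal(0, 0.4, CONC.size)
            est = B.estimate_bmc(_series(y), ci_method="delta")
            if np.isfinite(est.bmc) and np.isfinite(est.bmcl):
                assert est.bmcl <= est.bmc <= est.bmcu
                checked += 1
        assert checked > 25


class TestFilters:
    def _est(self, bmc, bmcl, bmcu, fit_p=1.0):
        fit = B.ModelFit("Linear", np.array([0.0, 1.0]), 0, fit_p, 1.0, "up", 0, 2)
        return B.BMCEstimate(bmc=bmc, bmcl=bmcl, bmcu=bmcu, fit=fit)

    def test_ratio_filters(self):
        s = _linear_series()
        est = B.apply_bmc_filters(self._est(25.0, 1.0, 30.0), s)
        assert "bmc_bmcl_ratio" in est.failure_reasons
        est = B.apply_bmc_filters(self._est(10.0, 0.5, 25.0), s)
        assert "bmcu_bmcl_ratio" in est.failure_reasons

    def test_bmc_above_top_concentration_fails(self):
        s = _linear_series()
        est = B.apply_bmc_filters(self._est(45.0, 30.0, 60.0), s)
        assert "bmc_above_max_conc" in est.failure_reasons
        est_inf = B.apply_bmc_filters(self._est(np.inf, np.nan, np.nan), s)
        assert not est_inf.passed_filters

    def test_low_extrapolation_fails(self):
        s = _linear_series()  # lowest nonzero concentration 2.5
        est = B.apply_bmc_filters(self._est(0.01, 0.005, 0.02), s)
        assert "bmc_extrapolated_low" in est.failure_reasons

    def test_poor_fit_fails(self):
        s = _linear_series()
        est = B.apply_bmc_filters(self._est(5.0, 4.0, 6.0, fit_p=0.05), s)
        assert "fit_p" in est.failure_reasons

    def test_clean_strong_signal_mostly_passes(self):
        # a ~10% fail rate is built into the p > 0.1 goodness-of-fit gate
        passed = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            k = hill_k_for_bmc(10.0, 2.0, 0.3, 2.0)
            mu = 8.0 + hill_response(CONC, 2.0, k, 2.0)
            est = B.estimate_bmc(_series(mu + rng.normal(0, 0.3, CONC.size)),
                                 ci_method="delta")
            passed += est.passed_filters
        assert passed >= 28


class TestWilliams:
    def test_monotone_shift_retained(self):
        rng = np.random.default_rng(7)
        mu = np.repeat([0.0, 0.25, 0.5, 1.0, 1.5, 1.5], 4)
        s = _series(8.0 + mu + rng.normal(0, 0.1, CONC.size))
        res = B.williams_prefilter({"g": s}, rng=np.random.default_rng(0))
        assert res["g"]["retained"] and res["g"]["p"] <= 0.02

    def test_fold_change_gate(self):
        rng = np.random.default_rng(8)
        mu = np.repeat([0.0, 0.1, 0.2, 0.3, 0.4, 0.485], 4)  # max FC ~ 1.4
        s = _series(8.0 + mu + rng.normal(0, 0.02, CONC.size))
        res = B.williams_prefilter({"g": s}, rng=np.random.default_rng(0))
        assert res["g"]["p"] < 0.05
        assert res["g"]["fc"] < 1.5 and not res["g"]["retained"]

    def test_constant_gene_excluded_not_error(self):
        s = _series(np.full(CONC.size, 3.0))
        res = B.williams_prefilter({"g": s})
        assert not res["g"]["retained"]

    def test_pava_matches_sklearn_isotonic(self):
        from sklearn.isotonic import IsotonicRegression
        rng = np.random.default_rng(9)
        for _ in range(50):
            v = rng.normal(size=(1, 6))
            w = rng.uniform(0.5, 4.0, 6)
            ours = v.copy()
            B._pava_batch(ours, w)
            ref = IsotonicRegression().fit(
                np.arange(6), v[0], sample_weight=w).predict(np.arange(6))
            np.testing.assert_allclose(ours[0], ref, atol=1e-10)

    def test_permutation_p_matches_exhaustive_oracle(self):
        """Two groups x 3 replicates: all 720 orderings = exact enumeration."""
        conc = np.repeat([0.0, 10.0], 3)
        y = np.array([1.0, 2.0, 1.5, 2.5, 3.5, 3.0])
        s = B.DoseResponseSeries(conc, y)
        perms = np.array(list(itertools.permutations(range(6))))
        obs, p = B.williams_test(s, n_perm=len(perms), perms=perms)
        # exact p over the 20 distinct assignments (each appears 36x)
        stats_all = []
        for pm in perms:
            sp = B.DoseResponseSeries(conc, y[list(pm)])
            stats_all.append(abs(B.williams_statistic(sp)))
        exact = np.mean(np.asarray(stats_all) >= abs(obs) - 1e-12)
        assert p == pytest.approx(exact, abs=2.0 / len(perms))


class TestGeneSetSummaries:
    def test_median_rules(self):
        def est(bmc, ok=True):
            e = B.BMCEstimate(bmc=bmc, bmcl=bmc / 2, bmcu=bmc * 2, fit=None)
            e.passed_filters = ok
            return e

        med, n = B.gene_set_median_bmc({"a": est(2), "b": est(4), "c": est(9)})
        assert med == 4 and n == 3
        med, n = B.gene_set_median_bmc({"a": est(7), "b": est(4, ok=False)})
        assert med == 7 and n == 1
        med, n = B.gene_set_median_bmc({"a": est(7, ok=False)})
        assert med is None and n == 0

    def test_bootstrap_single_low_noise_gene_is_tight(self):
        """One near-noiseless gene: high inclusion, narrow CI around its BMC.

        Inclusion cannot be exactly 1 in general: bootstrap datasets are
        centered on the sample group means (not on the fitted curve), so the
        goodness-of-fit gate trims an appreciable share of refits even when
        the generating model is in the suite.
        """
        rng = np.random.default_rng(10)
        s = _series(8.0 + 0.05 * CONC + rng.normal(0, 0.05, CONC.size))
        cfg = B.BmcConfig(n_boot_set=400)
        res = B.bootstrap_bmc_ci({"g": s}, cfg, np.random.default_rng(0))
        assert res.inclusion_probability["g"] >= 0.3
        lo, hi = res.ci95
        assert hi / lo < 2.5
        assert lo <= res.bootstrap_median <= hi
        assert res.bootstrap_median == pytest.approx(res.per_gene["g"].bmc,
                                                     rel=0.5)

    def test_flat_genes_not_modeled(self):
        rng = np.random.default_rng(11)
        series = {f"g{i}": _series(8.0 + rng.normal(0, 0.2, CONC.size))
                  for i in range(3)}
        cfg = B.BmcConfig(n_boot_gene=20, n_boot_set=100)
        res = B.bootstrap_bmc_ci(series, cfg, np.random.default_rng(0))
        assert res.median_bmc is None or res.n_genes_modeled == 0
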