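import numpy as np
import pandas as pd
import pytest

import hgkrige as h
from hgkrige.mixed import lmm_reml_loglik

from conftest import toy_records


class TestCategorizeEvidence:
    @pytest.mark.parametrize("p,label", [
        (0.0005, "very_strong"),
        (0.003, "strong"),
        (0.02, "evidence"),
        (0.07, "weak"),
        (0.64, "little_or_none"),
        (0.001, "strong"),       # lower boundaries are exclusive upward
        (0.01, "evidence"),
        (0.05, "weak"),          # exact 0.05 / 0.1 fall to the weaker side
        (0.1, "little_or_none"),
    ])
    def test_boundaries(self, p, label):
        assert h.categorize_evidence(p) == label

    @pytest.mark.parametrize("p", [-0.1, 1.5])
    def test_rejects_out_of_range(self, p):
        with pytest.raises(ValueError):
            h.categorize_evidence(p)


class TestWaldInference:
    def test_zero_estimate_gives_p_one(self):
        tab = h.wald_inference([0.0], [0.5])
        assert tab.loc[0, "p_value"] == pytest.approx(1.0)

    def test_estimate_at_1p96_se_gives_p_05(self):
        tab = h.wald_inference([1.96], [1.0])
        assert tab.loc[0, "p_value"] == pytest.approx(0.05, abs=1e-3)
        assert tab.loc[0, "ci_low"] == pytest.approx(0.0, abs=1e-9)

    def test_vanishing_se_drives_p_to_zero(self):
        assert h.wald_inference([1.0], [1e-12]).loc[0, "p_value"] < 1e-10
        assert h.wald_inference([1.0], [0.0]).loc[0, "p_value"] == 0.0

    def test_nonfinite_se_rejected(self):
        with pytest.raises(ValueError):
            h.wald_inference([1.0], [np.nan])


class TestFitLmm:
    def test_balanced_design_matches_anova_closed_form(self):
        """For a balanced one-way layout, REML equals the ANOVA estimator:
        s2e = MSW, s2f = (MSB - MSW) / m."""
        rng = np.random.default_rng(30)
        n_fam, m = 30, 2
        y, fam = [], []
        for f in range(n_fam):
            b = 0.6 * rng.standard_normal()
            y += list(1.0 + b + 0.4 * rng.standard_normal(m))
            fam += [f"F{f}"] * m
        rec = pd.DataFrame({"participant_id": range(len(y)), "family_id": fam,
                            "outcome": y})
        fit = h.fit_lmm(rec)
        arr = np.array(y).reshape(n_fam, m)
        msw = np.sum((arr - arr.mean(1, keepdims=True)) ** 2) / (n_fam * (m - 1))
        msb = m * np.sum((arr.mean(1) - arr.mean()) ** 2) / (n_fam - 1)
        assert fit.sigma2_resid == pytest.approx(msw, abs=1e-6)
        assert fit.sigma2_family == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_zero_family_variance_reduces_to_ols(self):
        """With no true family effect the REML family variance collapses and
        the fixed effects match OLS."""
        rec = toy_records(seed=31, n_fam=120, per_fam=2, s2f=0.0)
        fit = h.fit_lmm(rec)
        X = np.column_stack([np.ones(len(rec)), rec["exposure"], rec["z"]])
        bhat = np.linalg.lstsq(X, rec["outcome"].to_numpy(), rcond=None)[0]
        assert fit.sigma2_family < 1e-4
        np.testing.assert_allclose(fit.beta["estimate"].to_numpy(), bhat,
                                   atol=1e-6 + 50 * fit.sigma2_family)

    def test_invariant_to_family_relabeling(self):
        rec = toy_records(seed=32)
        fit1 = h.fit_lmm(rec)
        fams = sorted(rec["family_id"].unique())
        relabel = {f: f"G{i:03d}" for f, i in zip(fams, reversed(range(len(fams))))}
        rec2 = rec.assign(family_id=rec["family_id"].map(relabel))
        fit2 = h.fit_lmm(rec2)
        np.testing.assert_allclose(fit1.beta["estimate"], fit2.beta["estimate"],
                                   atol=1e-8)

    def test_reml_optimum_beats_random_variance_points(self):
        rec = toy_records(seed=33)
        fit = h.fit_lmm(rec)
        y = rec["outcome"].to_numpy()
        X = np.column_stack([np.ones(len(rec)), rec["exposure"], rec["z"]])
        g = rec["family_id"].to_numpy()
        rng = np.random.default_rng(34)
        for _ in range(20):
            ll = lmm_reml_loglik(y, X, g, rng.uniform(0, 0.5), rng.uniform(0.01, 0.5))
            assert ll <= fit.loglik + 1e-6

    def test_singular_design_rejected(self):
        rec = toy_records(seed=35)
        rec["z"] = rec["exposure"]  # collinear
        with pytest.raises(ValueError):
            h.fit_lmm(rec)

    def test_variance_cis_bracket_estimates(self):
        fit = h.fit_lmm(toy_records(seed=36))
        lo, hi = fit.sigma2_family_ci
        assert lo <= fit.sigma2_family <= hi
        lo, hi = fit.sigma2_resid_ci
        assert lo <= fit.sigma2_resid <= hi

    def test_wald_type_one_error_near_nominal(self):
        """Type-I error of the z-test for a null coefficient stays within
        the documented small-sample band at the study's size."""
        rejections = 0
        for s in range(60):
            rec = toy_records(seed=600 + s, n_fam=64, per_fam=3, beta_soil=0.0)
            fit = h.fit_lmm(rec)
            rejections += fit.beta.loc["exposure", "p_value"] < 0.05
        assert 0.025 * 60 - 2 <= rejections <= 0.08 * 60 + 2


class TestRunOutcomeModels:
    def test_measured_kind_keeps_det_limit_row_predicted_omits(self, cohort):
        part, truth, cfg, soil = cohort
        meas = h.link_measured_exposure(part, soil)
        rec_u = h.make_exposure_records(part, "urine", meas["exposure"],
                                        below_lod=meas["below_lod"],
                                        include_interaction=True)
        rec_h = h.make_exposure_records(part, "hair", meas["exposure"],
                                        below_lod=meas["below_lod"],
                                        include_interaction=True)
        out = h.run_outcome_models(rec_u, rec_h, "measured")
        assert "det_limit" in out["urine"]["table"]["variable"].values
        rec_u2 = h.make_exposure_records(part, "urine", meas["exposure"],
                                         include_det_limit=False)
        rec_h2 = h.make_exposure_records(part, "hair", meas["exposure"],
                                         include_det_limit=False)
        out2 = h.run_outcome_models(rec_u2, rec_h2, "predicted")
        assert "det_limit" not in out2["urine"]["table"]["variable"].values
        # variance components appear as rows in every report
        assert {"family_variance", "residual_variance"} <= set(
            out2["hair"]["table"]["variable"])

    def test_identical_records_identical_fits(self):
        rec = toy_records(seed=37)
        f1 = h.run_outcome_models(rec, rec, "measured")["urine"]["fit"]
        f2 = h.run_outcome_models(rec, rec, "predicted")["urine"]["fit"]
        pd.testing.assert_frame_equal(f1.beta, f2.beta)
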