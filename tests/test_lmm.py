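"""REML engine: closed-form oracles, cross-implementation checks,
inference bookkeeping and model invariances."""

import json
import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

import octlayers as ol
from octlayers.lmm import (
    ModelSpec,
    NestedMixedModel,
    estimate_group_profiles,
    fit_reml,
    wald_inference,
)


def _nested_intercept_data(seed, n_pat=40, sd_p=2.0, sd_e=1.5, sd_res=3.0,
                           group_diff=5.0):
    rng = np.random.default_rng(seed)
    rows = []
    for pid in range(n_pat):
        grp = "stgd1" if pid >= n_pat // 2 else "control"
        a = rng.normal(0, sd_p)
        eyes = ["OD", "OS"] if rng.random() < 0.6 else ["OD"]
        for eye in eyes:
            b = rng.normal(0, sd_e)
            dt = rng.uniform(1.2, 8.2)
            for t in (0.0, dt):
                y = 100 + group_diff * (grp == "stgd1") + a + b + rng.normal(0, sd_res)
                rows.append(dict(patient_id=f"P{pid}", eye=eye, group=grp,
                                 years_since_baseline=t, thickness_um=y))
    return pd.DataFrame(rows)


class TestOracles:
    def test_zero_noise_recovers_fixed_effects_exactly(self):
        """Data generated exactly from the fixed part: estimates match the
        generating coefficients to 1e-8 and variances collapse."""
        rows = []
        for pid in range(12):
            grp = "stgd1" if pid >= 6 else "control"
            for eye in ("OD", "OS"):
                for t in (0.0, 2.0 + 0.25 * pid):
                    y = 50.0 - 20.0 * (grp == "stgd1") + (-1.0 - 0.5 * (grp == "stgd1")) * t
                    rows.append(dict(patient_id=f"P{pid}", eye=eye, group=grp,
                                     years_since_baseline=t, thickness_um=y))
        df = pd.DataFrame(rows)
        fit = fit_reml(df, ModelSpec("thickness_um",
                                     ("intercept", "years", "group", "years:group"),
                                     "nested_intercepts"))
        assert np.allclose(fit.fe_params, [50.0, -1.0, -20.0, -0.5], atol=1e-8)
        assert fit.vc["var_patient_intercept"] < 1e-6
        assert fit.vc["var_eye_intercept"] < 1e-6
        assert fit.vc["var_residual"] < 1e-6

    def test_balanced_one_way_matches_anova_reml(self):
        """Balanced one-way layout: REML equals the closed-form estimators
        sigma2_a = (MSB - MSW)/m and sigma2_e = MSW."""
        rng = np.random.default_rng(8)
        k, m = 25, 6
        rows = []
        for i in range(k):
            a = rng.normal(0, 3.0)
            for j in range(m):
                rows.append(dict(patient_id=f"P{i}", eye="OD", group="control",
                                 years_since_baseline=0.0,
                                 thickness_um=10 + a + rng.normal(0, 2.0)))
        df = pd.DataFrame(rows)
        fit = fit_reml(df, ModelSpec("thickness_um", ("intercept",),
                                     "patient_intercept"))
        y = df.thickness_um.to_numpy().reshape(k, m)
        gm = y.mean()
        msb = m * ((y.mean(axis=1) - gm) ** 2).sum() / (k - 1)
        msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (k * (m - 1))
        assert fit.vc["var_residual"] == pytest.approx(msw, abs=1e-6)
        assert fit.vc["var_patient_intercept"] == pytest.approx(
            (msb - msw) / m, abs=1e-6)
        assert fit.fe_params[0] == pytest.approx(gm, abs=1e-8)

    def test_matches_statsmodels_nested_intercepts(self):
        """Same data, independent fitter: REML log-likelihood and fixed
        effects agree with statsmodels MixedLM to 1e-6 relative."""
        import statsmodels.formula.api as smf

        for seed in (1, 2, 3):
            df = _nested_intercept_data(seed)
            fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                         "nested_intercepts"))
            df = df.assign(g=(df.group == "stgd1").astype(float),
                           eyeid=df.patient_id + df.eye)
            sm_fit = smf.mixedlm("thickness_um ~ g", df, groups="patient_id",
                                 re_formula="1",
                                 vc_formula={"eye": "0 + C(eyeid)"}).fit(reml=True)
            assert fit.loglik == pytest.approx(sm_fit.llf, rel=1e-6, abs=1e-4)
            assert np.allclose(fit.fe_params, sm_fit.params[:2].to_numpy(),
                               rtol=1e-4)

    def test_matches_nlme_intercept_slope(self, tmp_path):
        """The full longitudinal structure (correlated intercept+slope at
        both nested levels) against R nlme's lme on identical data: the
        in-repo optimum is at least as good, and estimates agree."""
        datasets = []
        for seed in (11, 12, 13):
            params = ol.CohortParams(
                n_patients_control=20, n_patients_stgd=20,
                fixed_effects={("ONL", "center"): ol.LayerEffects(100, -40, -0.5, -2.0)},
                seed=seed)
            table, _ = ol.simulate_cohort(params)
            df = ol.grader_average(table).query("source == 'grader_avg'")
            path = tmp_path / f"d{seed}.csv"
            df.to_csv(path, index=False)
            datasets.append((seed, path, df))

        rscript = tmp_path / "fit.R"
        rscript.write_text("""
library(nlme)
args <- commandArgs(trailingOnly=TRUE)
out <- list()
for (f in args[-length(args)]) {
  d <- read.csv(f)
  d$group <- factor(d$group, levels=c("control", "stgd1"))
  m <- lme(thickness_um ~ years_since_baseline*group,
           random=~1+years_since_baseline|patient_id/eye, data=d,
           method="REML", control=lmeControl(opt='optim', msMaxIter=100))
  out[[f]] <- list(loglik=as.numeric(logLik(m)), fe=as.numeric(fixef(m)))
}
writeLines(jsonlite::toJSON(out, auto_unbox=TRUE), args[length(args)])
""")
        out_json = tmp_path / "nlme.json"
        cmd = ["Rscript", str(rscript)] + [str(p) for _, p, _ in datasets] + [str(out_json)]
        proc = subprocess.run(cmd, capture_output=True, text=True, timeout=300)
        assert proc.returncode == 0, proc.stderr
        ref = json.loads(out_json.read_text())

        for seed, path, df in datasets:
            fit = fit_reml(df, ModelSpec(
                "thickness_um", ("intercept", "years", "group", "years:group"),
                "nested_intercept_slope"))
            r = ref[str(path)]
            # nlme's fe order: (Intercept), years, group, years:group.
            # The in-repo optimum must never be worse; nlme's optim search
            # stops less tightly, so equality is asserted within a band.
            assert fit.loglik >= r["loglik"] - 1e-4
            assert abs(fit.loglik - r["loglik"]) < 0.5
            assert np.allclose(fit.fe_params, r["fe"], rtol=5e-3, atol=0.05)


class TestInference:
    def test_zero_estimate_gives_p_one(self):
        df = _nested_intercept_data(5)
        fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                     "nested_intercepts"))
        fit.fe_params[1] = 0.0
        w = wald_inference(fit, "group")
        assert w.p == 1.0

    def test_containment_df_bookkeeping(self):
        """group is tested between patients (n_pat - 2 df); years and the
        interaction at the observation level (N - n_eyes - 2)."""
        df = _nested_intercept_data(6)
        fit = fit_reml(df, ModelSpec(
            "thickness_um", ("intercept", "years", "group", "years:group"),
            "nested_intercepts"))
        n_pat = df.patient_id.nunique()
        n_eyes = (df.patient_id + df.eye).nunique()
        assert wald_inference(fit, "group").df == n_pat - 2
        assert wald_inference(fit, "years").df == len(df) - n_eyes - 2
        assert wald_inference(fit, "intercept").df == len(df) - n_eyes - 2

    def test_type_one_error_calibration(self):
        """Under a true null group effect, the group test rejects at
        roughly the nominal 5% rate."""
        rej = 0
        n_rep = 120
        for seed in range(n_rep):
            df = _nested_intercept_data(1000 + seed, n_pat=30, group_diff=0.0)
            fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                         "nested_intercepts"), n_restarts=0)
            if wald_inference(fit, "group").p < 0.05:
                rej += 1
        # binomial 99% band around 0.05 at 120 reps
        band = 2.58 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rej / n_rep == pytest.approx(0.05, abs=band + 1e-9)

    def test_missing_term_raises(self):
        df = _nested_intercept_data(5)
        fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                     "nested_intercepts"))
        with pytest.raises(KeyError):
            wald_inference(fit, "years")


class TestProfilesAndInvariances:
    def test_group_difference_identity(self):
        df = _nested_intercept_data(9)
        fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                     "nested_intercepts"))
        prof = estimate_group_profiles(fit)
        diff = prof["stgd1"]["baseline"]["estimate"] - prof["control"]["baseline"]["estimate"]
        assert diff == pytest.approx(fit.fe_params[1], abs=1e-12)

    def test_response_shift_moves_only_intercept(self):
        df = _nested_intercept_data(10)
        spec = ModelSpec("thickness_um",
                         ("intercept", "years", "group", "years:group"),
                         "nested_intercepts")
        f0 = fit_reml(df, spec)
        f1 = fit_reml(df.assign(thickness_um=df.thickness_um + 37.5), spec)
        assert f1.fe_params[0] == pytest.approx(f0.fe_params[0] + 37.5, abs=1e-5)
        assert np.allclose(f1.fe_params[1:], f0.fe_params[1:], atol=1e-5)

    def test_time_rescaling_rescales_slopes(self):
        df = _nested_intercept_data(10)
        spec = ModelSpec("thickness_um",
                         ("intercept", "years", "group", "years:group"),
                         "nested_intercepts")
        f0 = fit_reml(df, spec)
        f1 = fit_reml(df.assign(years_since_baseline=df.years_since_baseline * 4.0),
                      spec)
        i_years = f0.term_names.index("years")
        i_int = f0.term_names.index("years:group")
        assert f1.fe_params[i_years] == pytest.approx(f0.fe_params[i_years] / 4.0,
                                                      rel=1e-4)
        assert f1.fe_params[i_int] == pytest.approx(f0.fe_params[i_int] / 4.0,
                                                    rel=1e-4)

    def test_no_clustering_collapses_to_ols(self):
        """With zero true random effects the REML fit collapses to OLS."""
        rng = np.random.default_rng(3)
        rows = []
        for pid in range(150):
            grp = "stgd1" if pid >= 75 else "control"
            rows.append(dict(patient_id=f"P{pid}", eye="OD", group=grp,
                             years_since_baseline=0.0,
                             thickness_um=10 + 2 * (grp == "stgd1") + rng.normal(0, 1)))
            rows.append(dict(patient_id=f"P{pid}", eye="OS", group=grp,
                             years_since_baseline=0.0,
                             thickness_um=10 + 2 * (grp == "stgd1") + rng.normal(0, 1)))
        df = pd.DataFrame(rows)
        fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                     "nested_intercepts"))
        X = np.column_stack([np.ones(len(df)), (df.group == "stgd1").astype(float)])
        y = df.thickness_um.to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.fe_params, beta, atol=2e-2)

    def test_local_optimality_against_random_restarts(self):
        """The returned REML criterion beats 20 random feasible parameter
        points."""
        from octlayers.lmm import ClusterSet, _build_design, _reml_profile

        df = _nested_intercept_data(14)
        fit = fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                     "nested_intercepts"))
        y = df.thickness_um.to_numpy()
        X = _build_design(df, ["intercept", "group"], "years_since_baseline",
                          "group", "eye")
        pat = pd.factorize(df.patient_id)[0]
        eye = pd.factorize(df.patient_id + df.eye)[0]
        cs = ClusterSet(y, X, df.years_since_baseline.to_numpy(), pat, eye,
                        "nested_intercepts")
        g = cs.full_groups()
        rng = np.random.default_rng(0)
        best = fit.neg2_reml
        for _ in range(20):
            th = rng.uniform(-4, 2, size=2)
            assert _reml_profile(th, cs, g, cs.n_obs).crit >= best - 1e-6


class TestErrors:
    def test_rank_deficient_names_aliased_terms(self):
        df = _nested_intercept_data(4)
        df["group"] = "control"  # constant group column
        with pytest.raises(ValueError, match="aliased"):
            fit_reml(df, ModelSpec("thickness_um", ("intercept", "group"),
                                   "nested_intercepts"))

    def test_too_few_patients(self):
        df = _nested_intercept_data(4)
        df = df[df.patient_id == "P0"]
        with pytest.raises(ValueError, match="2 patients"):
            fit_reml(df, ModelSpec("thickness_um", ("intercept",),
                                   "nested_intercepts"))

    def test_sklearn_params_roundtrip(self):
        m = NestedMixedModel(fixed_terms=("intercept", "group"), max_iter=50)
        params = m.get_params()
        assert params["max_iter"] == 50
        m2 = NestedMixedModel().set_params(**params)
        assert m2.fixed_terms == ("intercept", "group")
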