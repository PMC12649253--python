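"""Penalized estimator: initial fit, coordinate descent, tuning, inference."""

import subprocess

import numpy as np
import pytest

from depmsm._errors import ConfigurationError, DataError
from depmsm.adalasso import (
    PenaltyConfig,
    _GroupSolver,
    adaptive_weights,
    fit_adaptive_lasso,
    fit_initial,
    lambda_max,
    post_selection_inference,
    significance_stars,
    tune_lambda,
)
from depmsm.cohort import default_cohort_spec, generate_covariates, simulate_state_paths
from depmsm.design import TransitionStructure, build_transition_records, design_from_latent
from depmsm.likelihood import build_group_data
from depmsm.published import MODEL_TERMS
from depmsm.simstudy import run_null_study, run_recovery_trial

from conftest import toy_design

R_ORACLE = """
suppressMessages(library(survival))
args <- commandArgs(trailingOnly=TRUE)
d <- read.csv(args[1])
covs <- setdiff(colnames(d), c("subject_id","path","group","entry","exit","status"))
f <- as.formula(paste("Surv(entry, exit, status) ~", paste(covs, collapse="+")))
fit <- coxph(f, data=d, ties="breslow", control=coxph.control(eps=1e-12, iter.max=100))
cat(paste(coef(fit), collapse=","))
"""


def r_coxph_breslow(path_table, tmp_path, tag):
    """Independent per-path Cox fit from R's survival package (Breslow ties,
    delayed entry)."""
    script = tmp_path / "cox_oracle.R"
    script.write_text(R_ORACLE)
    csv = tmp_path / f"path_{tag}.csv"
    path_table.to_csv(csv, index=False)
    out = subprocess.run(
        ["Rscript", str(script), str(csv)], capture_output=True, text=True, check=True
    )
    return np.array([float(x) for x in out.stdout.strip().split(",")])


@pytest.fixture(scope="module")
def small_design():
    """Wave-censored stacked design, all five paths, reduced covariate set."""
    spec = default_cohort_spec(n_subjects=800, seed=5)
    cov = generate_covariates(spec)
    sim = simulate_state_paths(cov, spec)
    terms = ["sex", "age", "pain", "income", "social_engagement"]
    mm = sim.model[terms].reset_index()
    return build_transition_records(sim.sequences, mm)


@pytest.fixture(scope="module")
def small_initial(small_design):
    return fit_initial(small_design)


class TestInitialFit:
    def test_agrees_with_r_survival_per_path(self, tmp_path):
        # tied wave-timed events, Breslow handling on both sides
        spec = default_cohort_spec(n_subjects=800, seed=5)
        cov = generate_covariates(spec)
        sim = simulate_state_paths(cov, spec)
        terms = ["sex", "age", "pain", "income"]
        singleton = TransitionStructure(
            coefficient_groups=(("12",), ("23",), ("24",), ("34",), ("45",))
        )
        des = build_transition_records(sim.sequences, sim.model[terms].reset_index(), singleton)
        init = fit_initial(des)
        for path in ("12", "23", "24"):
            ref = r_coxph_breslow(des.path_table(path), tmp_path, path)
            assert np.max(np.abs(ref - init.beta_tilde[path])) < 1e-6

    def test_null_data_gives_small_estimates_and_moderate_z(self):
        trial_spec = default_cohort_spec(
            n_subjects=2500,
            seed=41,
            true_betas={g: np.zeros(len(MODEL_TERMS)) for g in ("12", "23", "24+34", "45")},
        )
        cov = generate_covariates(trial_spec)
        sim = simulate_state_paths(cov, trial_spec)
        structure = TransitionStructure(paths=("12",), coefficient_groups=(("12",),))
        des = build_transition_records(sim.sequences, sim.model.reset_index(), structure)
        inference = post_selection_inference(des, {"12": np.arange(des.p)})
        assert np.all(np.abs(inference.wald_z["12"]) < 4.0)

    def test_perfect_separation_triggers_ridge_fallback(self):
        rows = [
            ("a", "12", 0.0, 1.0, 1, 1.0),
            ("b", "12", 0.0, 2.0, 1, 1.0),
            ("c", "12", 0.0, 3.0, 1, 1.0),
            ("d", "12", 0.0, 9.0, 0, 0.0),
            ("e", "12", 0.0, 9.0, 0, 0.0),
        ]
        des = toy_design(rows)
        with pytest.warns(UserWarning):
            init = fit_initial(des)
        assert init.ridged["12"]
        assert np.isfinite(init.beta_tilde["12"]).all()

    def test_loglik_is_finite_and_negative(self, small_initial):
        assert np.isfinite(small_initial.loglik) and small_initial.loglik < 0


class TestAdaptiveLasso:
    def test_zero_penalty_reproduces_mle(self, small_design, small_initial):
        penalty = PenaltyConfig(
            {g: 0.0 for g in small_initial.beta_tilde},
            {g: adaptive_weights(b) for g, b in small_initial.beta_tilde.items()},
        )
        fit = fit_adaptive_lasso(small_design, penalty, small_initial)
        for g, b in fit.beta_hat.items():
            assert np.max(np.abs(b - small_initial.beta_tilde[g])) < 1e-5

    def test_lambda_above_lambda_max_zeroes_every_group(self, small_design, small_initial):
        groups = build_group_data(small_design)
        lams, weights = {}, {}
        for g, gdat in groups.items():
            w = adaptive_weights(small_initial.beta_tilde[g])
            weights[g] = w
            lams[g] = 1.001 * lambda_max(_GroupSolver(gdat, small_design.n), w)
        fit = fit_adaptive_lasso(small_design, PenaltyConfig(lams, weights), small_initial)
        for g, b in fit.beta_hat.items():
            assert np.all(b == 0.0)

    def test_kkt_certificate_at_selected_penalty(self, small_design, small_initial):
        penalty = tune_lambda(small_design, initial=small_initial)
        fit = fit_adaptive_lasso(small_design, penalty, small_initial)
        assert fit.kkt_max_violation <= 1e-5

    def test_objective_non_increasing_over_sweeps(self, small_design, small_initial):
        # directly exercise the solver: every accepted coordinate step must not
        # increase the penalized objective
        groups = build_group_data(small_design)
        gdat = groups["12"]
        solver = _GroupSolver(gdat, small_design.n)
        w = adaptive_weights(small_initial.beta_tilde["12"])
        lam = 0.3 * lambda_max(solver, w)
        solver._set_beta(np.zeros(small_design.p))
        pen = 0.0
        objs = [solver._f]
        for _sweep in range(5):
            for r in range(small_design.p):
                _, pen = solver._try_coord(r, lam, w[r], pen, 1e-7)
                objs.append(solver._f + pen)
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_negative_penalty_rejected(self, small_design, small_initial):
        with pytest.raises(ConfigurationError):
            PenaltyConfig({"12": -1.0}, {})

    def test_weight_ordering_follows_initial_estimates(self, small_initial):
        for b in small_initial.beta_tilde.values():
            w = adaptive_weights(b)
            order = np.argsort(np.abs(b))
            assert np.all(np.diff(w[order]) <= 1e-12)  # larger |beta| -> smaller weight


class TestTuning:
    def test_grid_top_zeroes_group_and_path_is_audited(self, small_design, small_initial):
        penalty = tune_lambda(small_design, initial=small_initial, n_grid=12)
        for g, path in penalty.tuning_path.items():
            if len(path) == 0:
                continue
            assert path.iloc[0]["n_active"] == 0  # at lambda_max
            assert {"lambda", "n_active", "criterion"} <= set(path.columns)
            assert len(path) == 12

    def test_null_groups_selected_near_empty(self):
        # no true signal: the tuned model should be (almost) empty most runs
        rate = run_null_study(3, n_trials=20, n_subjects=1500)
        assert rate >= 0.9

    def test_cv_criterion_runs_and_selects(self, small_design, small_initial):
        penalty = tune_lambda(
            small_design,
            initial=small_initial,
            criterion="cv",
            n_grid=4,
            cv_folds=3,
            grid=None,
        )
        assert set(penalty.lambda_by_group) == set(small_initial.beta_tilde)

    def test_unknown_criterion_rejected(self, small_design):
        with pytest.raises(ConfigurationError):
            tune_lambda(small_design, criterion="aic")

    def test_empty_grid_rejected(self, small_design, small_initial):
        with pytest.raises(ConfigurationError):
            tune_lambda(small_design, grid={"12": []}, initial=small_initial)


class TestPostSelectionInference:
    def test_star_thresholds(self):
        assert significance_stars(0.0009) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.06) == ""
        assert significance_stars(0.001) == "**"
        assert significance_stars(0.05) == "*"

    def test_strong_effect_detected_with_high_power(self):
        # one strong true effect: its refit |z| should exceed 1.96 in nearly
        # every seeded replicate
        hits = 0
        for seed in range(10):
            trial = run_recovery_trial(7000 + seed, n_subjects=1500)
            idx = list(trial.selected)
            sex = MODEL_TERMS.index("sex")
            if sex in idx:
                hits += 1
        assert hits >= 9

    def test_empty_active_set_gives_empty_inference(self, small_design):
        inf = post_selection_inference(small_design, {g: [] for g in ("12", "23", "24+34", "45")})
        assert all(len(se) == 0 for se in inf.se.values())


class TestSharedRemissionBlock:
    def test_shared_group_estimates_converge_with_n(self):
        # the 2->4 and 3->4 strata share one coefficient vector; with exact
        # latent event times the joint estimate approaches the common truth
        errs = {}
        for n in (1000, 5000):
            spec = default_cohort_spec(n_subjects=n, seed=101)
            cov = generate_covariates(spec)
            sim = simulate_state_paths(cov, spec)
            des = design_from_latent(
                sim.latent, cov["subject_id"].to_numpy(), spec.wave_times[-1],
                sim.model.reset_index(),
            )
            init = fit_initial(des)
            truth = spec.true_betas["24+34"]
            errs[n] = np.max(np.abs(init.beta_tilde["24+34"] - truth))
        assert errs[5000] < errs[1000]
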