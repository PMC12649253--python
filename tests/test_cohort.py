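"""Synthetic-cohort generator: marginals, latent dynamics, emission."""

import numpy as np
import pandas as pd
import pytest

from depmsm._errors import ConfigurationError
from depmsm.cesd import SYMPTOMATIC_STATES, TRANSITION_PATHS, classify_panel
from depmsm.cohort import (
    CohortSpec,
    CovariateSpec,
    default_cohort_spec,
    emit_cesd_scores,
    generate_covariates,
    simulate_state_paths,
)
from depmsm.published import MODEL_TERMS

N_MC = 50_000


@pytest.fixture(scope="module")
def large_covariates():
    spec = default_cohort_spec(n_subjects=N_MC, seed=11)
    return spec, generate_covariates(spec)


class TestCovariates:
    def test_binary_marginals_match_published_proportions(self, large_covariates):
        spec, cov = large_covariates
        p = 0.4662  # published female proportion
        mc_se = np.sqrt(p * (1 - p) / N_MC)
        assert abs(cov["sex"].mean() - p) < 3 * mc_se

    def test_continuous_marginals_match_published_moments(self, large_covariates):
        spec, cov = large_covariates
        mc_se = 8.50 / np.sqrt(N_MC)
        assert abs(cov["age"].mean() - 57.88) < 3 * mc_se

    def test_degenerate_proportion_gives_constant_column(self):
        spec = CohortSpec(
            n_subjects=200,
            covariate_specs=(CovariateSpec("flag", "binary", proportion=0.0),),
            interactions=(),
            true_betas={"12": np.zeros(1)},
            baseline_rates={"12": 0.1},
            seed=3,
        )
        assert (generate_covariates(spec)["flag"] == 0).all()

    def test_same_seed_identical_tables(self):
        spec = default_cohort_spec(n_subjects=300, seed=9)
        pd.testing.assert_frame_equal(generate_covariates(spec), generate_covariates(spec))

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ConfigurationError):
            CovariateSpec("bad", "binary", proportion=1.5)
        with pytest.raises(ConfigurationError):
            CovariateSpec("bad", "continuous", mean=0.0, sd=-1.0)


class TestSpecValidation:
    def test_wave_times_must_increase(self):
        with pytest.raises(ConfigurationError):
            default_cohort_spec(wave_times=(0.0, 4.0, 2.0))

    def test_beta_length_must_match_expanded_terms(self):
        with pytest.raises(ConfigurationError):
            default_cohort_spec(true_betas={"12": np.zeros(3)})

    def test_negative_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            default_cohort_spec(baseline_rates={"12": -0.1})


class TestLatentDynamics:
    def test_zero_intensities_keep_everyone_symptom_free(self):
        spec = default_cohort_spec(
            n_subjects=300, seed=2, baseline_rates={p: 0.0 for p in TRANSITION_PATHS}
        )
        sim = simulate_state_paths(generate_covariates(spec), spec)
        assert (sim.observed == 1).all()

    def test_onset_fraction_matches_exponential_closed_form(self):
        # beta = 0 everywhere, only the onset intensity active: time to episode
        # is Exp(rate), so P(state >= 2 by t) = 1 - exp(-rate t)
        rate = 0.08
        spec = default_cohort_spec(
            n_subjects=N_MC,
            seed=17,
            true_betas={g: np.zeros(len(MODEL_TERMS)) for g in ("12", "23", "24+34", "45")},
            baseline_rates={"12": rate},
        )
        sim = simulate_state_paths(generate_covariates(spec), spec)
        for k, t in enumerate(spec.wave_times[1:], start=1):
            expected = 1.0 - np.exp(-rate * t)
            mc_se = np.sqrt(expected * (1 - expected) / N_MC)
            observed = (sim.observed[:, k] >= 2).mean()
            assert abs(observed - expected) < 3 * mc_se

    def test_huge_onset_rate_gives_exactly_one_latent_jump(self):
        spec = default_cohort_spec(
            n_subjects=500,
            seed=23,
            true_betas={g: np.zeros(len(MODEL_TERMS)) for g in ("12", "23", "24+34", "45")},
            baseline_rates={"12": 1000.0},
        )
        sim = simulate_state_paths(generate_covariates(spec), spec)
        for jumps in sim.latent:
            assert len(jumps) == 1 and (jumps[0][1], jumps[0][2]) == (1, 2)
        # the classifier convention keeps them symptomatic: episode then persistence
        assert (sim.observed[:, 1] == 2).all()
        assert (sim.observed[:, 2:] == 3).all()

    def test_observed_transitions_closed_under_path_set(self, demo_cohort):
        _, _, sim = demo_cohort
        for row in sim.observed:
            for a, b in zip(row, row[1:]):
                assert a == b or f"{a}{b}" in TRANSITION_PATHS

    def test_determinism_same_spec_same_output(self):
        spec = default_cohort_spec(n_subjects=200, seed=31)
        a = simulate_state_paths(generate_covariates(spec), spec)
        b = simulate_state_paths(generate_covariates(spec), spec)
        assert (a.observed == b.observed).all()
        assert a.latent == b.latent


class TestEmission:
    def test_scores_respect_state_threshold(self, demo_cohort):
        _, _, sim = demo_cohort
        panel = emit_cesd_scores(sim)
        merged = panel.merge(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(sim.covariates["subject_id"].to_numpy(), sim.observed.shape[1]),
                    "wave_index": np.tile(np.arange(1, sim.observed.shape[1] + 1), len(sim.observed)),
                    "state": sim.observed.ravel(),
                }
            ),
            on=["subject_id", "wave_index"],
        )
        symptomatic = merged["state"].isin(list(SYMPTOMATIC_STATES))
        assert (merged.loc[symptomatic, "cesd_total"] >= 12).all()
        assert (merged.loc[~symptomatic, "cesd_total"] < 12).all()
        assert merged["cesd_total"].between(0, 30).all()

    def test_item_sums_reproduce_totals_after_reversal(self, demo_cohort):
        _, _, sim = demo_cohort
        panel = emit_cesd_scores(sim)
        items = panel[[f"item_{j}" for j in range(1, 11)]].to_numpy().copy()
        items[:, [4, 7]] = 3 - items[:, [4, 7]]  # re-reverse the stored raw values
        assert (items.sum(axis=1) == panel["cesd_total"].to_numpy()).all()

    def test_round_trip_recovers_observed_states(self, demo_cohort):
        _, _, sim = demo_cohort
        panel = emit_cesd_scores(sim)
        seqs = classify_panel(panel)
        recovered = np.array([s.states for s in seqs])
        assert (recovered == sim.observed).all()

    def test_round_trip_with_injected_missingness(self):
        spec = default_cohort_spec(n_subjects=300, seed=13, missing_item_rate=0.05)
        sim = simulate_state_paths(generate_covariates(spec), spec)
        panel = emit_cesd_scores(sim)
        assert panel[[f"item_{j}" for j in range(1, 11)]].isna().to_numpy().any()
        seqs = classify_panel(panel)
        recovered = np.array([s.states for s in seqs])
        assert (recovered == sim.observed).all()

    def test_zero_missing_rate_emits_complete_items(self, demo_cohort):
        _, _, sim = demo_cohort
        panel = emit_cesd_scores(sim)
        assert not panel[[f"item_{j}" for j in range(1, 11)]].isna().to_numpy().any()
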