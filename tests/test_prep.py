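"""Covariate preparation: normalization, MAD rule, imputation, screening."""

import numpy as np
import pandas as pd
import pytest

from depmsm._errors import DataError, ExclusionError
from depmsm.cohort import default_cohort_spec, generate_covariates, simulate_state_paths
from depmsm.prep import (
    PreprocessConfig,
    build_model_matrix,
    chained_impute,
    mad_outliers,
    minmax_normalize,
    screen_interactions,
)
from depmsm.published import MODEL_TERMS


class TestMinMax:
    def test_affine_identity(self):
        assert np.allclose(minmax_normalize([0, 5, 10]), [0, 0.5, 1])

    def test_range_endpoints(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        z = minmax_normalize(x)
        assert z.min() == 0.0 and z.max() == 1.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        assert np.allclose(minmax_normalize(x), minmax_normalize(x + 17.3))

    def test_idempotent(self):
        x = np.array([0.3, 0.0, 1.0, 0.7])
        assert np.allclose(minmax_normalize(minmax_normalize(x)), minmax_normalize(x))

    def test_constant_column_rejected(self):
        with pytest.raises(DataError):
            minmax_normalize([2.0, 2.0, 2.0])


class TestMadRule:
    def test_constant_column_no_flags(self):
        flags, _ = mad_outliers([4.0] * 5)
        assert not flags.any()

    def test_flags_gross_outlier_only(self):
        flags, _ = mad_outliers([1, 2, 1, 2, 100])
        assert list(flags) == [False, False, False, False, True]

    def test_sign_flip_invariance(self):
        x = np.array([1, 2, 1, 2, 100, -3, 0.5])
        f1, _ = mad_outliers(x)
        f2, _ = mad_outliers(-x)
        assert (f1 == f2).all()

    def test_zero_mad_nonconstant_warns_and_flags_none(self):
        with pytest.warns(UserWarning, match="zero MAD"):
            flags, _ = mad_outliers([1, 1, 1, 1, 100])
        assert not flags.any()

    def test_winsorize_clips_to_boundary(self):
        cfg = PreprocessConfig(mad_action="winsorize")
        _, clipped = mad_outliers([1, 2, 1, 2, 100], cfg)
        med = 2.0
        mad = 0.0  # median(|x-2|) over [1,0,1,0,98] = 1
        bound = med + cfg.mad_k * 1.4826 * 1.0
        assert clipped.max() == pytest.approx(bound)
        assert clipped[:4].tolist() == [1, 2, 1, 2]


def _correlated_table(n=400, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=n)
    return pd.DataFrame(
        {
            "x1": z + 0.3 * rng.normal(size=n),
            "x2": 0.8 * z + 0.4 * rng.normal(size=n),
            "x3": (z + rng.logistic(size=n) > 0).astype(float),
        }
    )


class TestChainedImputation:
    def test_complete_table_returned_unchanged(self):
        tab = _correlated_table()
        pd.testing.assert_frame_equal(chained_impute(tab), tab)

    def test_missing_rate_cap_mirrors_exclusion_rule(self):
        tab = _correlated_table()
        tab.loc[: len(tab) * 0.4, "x1"] = np.nan
        with pytest.raises(ExclusionError, match="x1"):
            chained_impute(tab)

    def test_beats_mean_imputation_on_correlated_mcar_data(self):
        tab = _correlated_table(n=600, seed=3)
        truth = tab["x1"].copy()
        rng = np.random.default_rng(4)
        holes = rng.random(len(tab)) < 0.10
        masked = tab.copy()
        masked.loc[holes, "x1"] = np.nan
        completed = chained_impute(masked, PreprocessConfig(seed=7))
        rmse = np.sqrt(np.mean((completed.loc[holes, "x1"] - truth[holes]) ** 2))
        rmse_mean = np.sqrt(np.mean((masked["x1"].mean() - truth[holes]) ** 2))
        assert rmse < rmse_mean
        # binary column stays binary
        assert set(completed["x3"].unique()) <= {0.0, 1.0}

    def test_seeded_determinism(self):
        masked = _correlated_table(seed=5)
        masked.loc[::7, "x2"] = np.nan
        a = chained_impute(masked, PreprocessConfig(seed=11))
        b = chained_impute(masked, PreprocessConfig(seed=11))
        pd.testing.assert_frame_equal(a, b)


class TestModelMatrix:
    def test_interactions_built_after_normalization(self):
        cov = pd.DataFrame({"subject_id": [0, 1, 2], "age": [40.0, 60.0, 80.0], "sex": [0, 1, 1]})
        mm = build_model_matrix(cov, normalize_columns=("age",), interactions=(("sex", "age"),))
        assert np.allclose(mm["age"], [0, 0.5, 1])
        assert np.allclose(mm["sex_x_age"], [0, 0.5, 1.0])
        assert mm["sex_x_age"].between(0, 1).all()

    def test_unknown_interaction_column_rejected(self):
        cov = pd.DataFrame({"subject_id": [0, 1], "age": [40.0, 60.0]})
        with pytest.raises(DataError):
            build_model_matrix(cov, normalize_columns=(), interactions=(("age", "bmi"),))


@pytest.fixture(scope="module")
def screened():
    # strong true interaction effect on n_conditions x income, none elsewhere
    beta = np.zeros(len(MODEL_TERMS))
    beta[MODEL_TERMS.index("n_conditions_x_income")] = 2.5
    spec = default_cohort_spec(
        n_subjects=4000,
        seed=29,
        true_betas={"12": beta},
        baseline_rates={"12": 0.08},
        emit_items=False,
    )
    cov = generate_covariates(spec)
    sim = simulate_state_paths(cov, spec)
    return cov, sim.sequences


class TestInteractionScreening:

    def test_signal_interaction_ranked_first(self, screened):
        cov, seqs = screened
        ranked = screen_interactions(
            [("n_conditions", "income"), ("sex", "age"), ("education", "income")], cov, seqs
        )
        assert ranked[0] == ("n_conditions", "income")

    def test_k_equal_to_all_returns_everything(self, screened):
        cov, seqs = screened
        cands = [("n_conditions", "income"), ("sex", "age")]
        assert set(screen_interactions(cands, cov, seqs, k=2)) == set(cands)

    def test_duplicates_removed(self, screened):
        cov, seqs = screened
        ranked = screen_interactions([("sex", "age"), ("sex", "age")], cov, seqs)
        assert ranked == [("sex", "age")]

    def test_unknown_column_rejected(self, screened):
        cov, seqs = screened
        with pytest.raises(DataError):
            screen_interactions([("sex", "bmi")], cov, seqs)
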