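import numpy as np
import pandas as pd
import pytest

from offtreat import (
    ImputationModelSpec,
    InestimableModelError,
    TrialData,
    fit_ancova,
    pool_rubin,
    sequential_impute,
    simulate_trial,
)
from offtreat.impute import (
    MODEL_NAMES,
    _OlsFit,
    build_design,
    compute_residual_basis,
    fit_and_draw,
)

from conftest import scenario


def arm_arrays(trial, arm):
    sub = trial.df[trial.df["arm"] == arm]
    return sub["disc_time"].to_numpy(int), sub[trial.y_columns].to_numpy(float)


class TestModelSpecs:
    def test_all_eight_models_resolve(self):
        assert len(MODEL_NAMES) == 8
        for name in MODEL_NAMES:
            spec = ImputationModelSpec.from_name(name)
            assert spec.name == name

    def test_cli_style_aliases(self):
        assert ImputationModelSpec.from_name("oics-r").name == "OICS_R"
        assert ImputationModelSpec.from_name("pics").name == "PICS"

    def test_inconsistent_fields_rejected(self):
        with pytest.raises(ValueError, match="implies"):
            ImputationModelSpec("CICS", "onoff_current", "common", "values")

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            ImputationModelSpec.from_name("XXXX")


def expected_columns(name, j, J=3):
    # closed-form column counts when every pattern level is populated
    return {
        "CICS": 1 + j,
        "OICS": 2 + j,
        "PICS": 1 + 2 * j,
        "OIOS": 2 + 2 * j,
        "PIOS": 3 * j,  # D_0:Y_0 is structurally zero and dropped
        "PIPS": 1 + J + j + J * (j - 1),
        "OICS_R": 2 + j,
        "PICS_R": 1 + 2 * j,
    }[name]


class TestDesign:
    @pytest.fixture
    def populated_arm(self):
        # one arm with every discontinuation time represented, no missing
        trial = simulate_trial(scenario(disc_c=0.5, disc_a=0.5, withdrawal=0.0), seed=13)
        return arm_arrays(trial, "C")

    @pytest.mark.parametrize("name", MODEL_NAMES)
    @pytest.mark.parametrize("j", [1, 2, 3])
    def test_column_counts_match_model_formulas(self, populated_arm, name, j):
        disc, y = populated_arm
        spec = ImputationModelSpec.from_name(name)
        basis = (
            compute_residual_basis(spec, disc, y, 3)
            if spec.conditioning == "residuals" else None
        )
        info = build_design(spec, j, disc, y, 3, resid_basis=basis)
        assert info.p == expected_columns(name, j)

    def test_cics_j2_columns(self, populated_arm):
        disc, y = populated_arm
        info = build_design(ImputationModelSpec.from_name("CICS"), 2, disc, y, 3)
        assert info.labels == ["intercept", "Y0", "Y1"]

    def test_pics_j3_seven_columns(self, populated_arm):
        disc, y = populated_arm
        info = build_design(ImputationModelSpec.from_name("PICS"), 3, disc, y, 3)
        assert info.p == 7

    def test_oios_degenerate_level_reduces_to_cics(self, rng):
        # nobody off treatment at j=1: status terms vanish
        disc = np.zeros(40, dtype=int)
        y = rng.normal(size=(40, 4))
        info = build_design(ImputationModelSpec.from_name("OIOS"), 1, disc, y, 3)
        cics = build_design(ImputationModelSpec.from_name("CICS"), 1, disc, y, 3)
        assert info.labels == cics.labels
        assert set(info.dropped_columns) == {"D1", "D1:Y0"}

    def test_recipients_in_unrepresented_stratum_raise(self, rng):
        disc = np.zeros(40, dtype=int)
        y = rng.normal(size=(40, 4))
        info = build_design(ImputationModelSpec.from_name("OICS"), 1, disc, y, 3)
        from offtreat.impute import _raw_columns
        labels, cols = _raw_columns(
            ImputationModelSpec.from_name("OICS"), 1, 3, np.array([1]), y[:1]
        )
        with pytest.raises(InestimableModelError, match="unrepresented"):
            info.transform(labels, cols)


class TestFitAndDraw:
    def test_posterior_mean_matches_ols(self, rng):
        X = np.ones((5, 1))
        y = np.array([1.0, 2, 3, 4, 5])
        draws = np.array([fit_and_draw(X, y, rng).beta[0] for _ in range(10_000)])
        assert abs(draws.mean() - 3.0) < 3 * draws.std() / np.sqrt(draws.size)

    def test_exact_fit_hits_variance_floor(self, rng):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = 2.0 + 3.0 * np.arange(10.0)
        draw = fit_and_draw(X, y, rng)
        assert draw.sigma == pytest.approx(1e-4, rel=1e-6)  # sqrt of the floor
        assert np.allclose(draw.beta, [2.0, 3.0], atol=1e-2)

    def test_deterministic_given_rng_state(self):
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        y = np.arange(8.0) * 1.5 + np.array([0.1, -0.2, 0.3, 0, 0.2, -0.1, 0, 0.1])
        d1 = fit_and_draw(X, y, np.random.default_rng(5))
        d2 = fit_and_draw(X, y, np.random.default_rng(5))
        assert np.array_equal(d1.beta, d2.beta) and d1.sigma == d2.sigma

    def test_more_parameters_than_rows_is_inestimable(self, rng):
        X = np.ones((3, 4))
        with pytest.raises(InestimableModelError):
            _OlsFit(X, np.zeros(3))


class TestResidualBasis:
    @pytest.mark.parametrize("name", ["OICS_R", "PICS_R"])
    def test_cell_means_of_residuals_are_zero(self, masked_trial, name):
        spec = ImputationModelSpec.from_name(name)
        for arm in ("C", "A"):
            disc, y = arm_arrays(masked_trial, arm)
            basis = compute_residual_basis(spec, disc, y, 3)
            for k in range(3):
                obs = ~np.isnan(y[:, k])
                resid = basis.residuals(k, y[obs, k], disc[obs])
                codes = basis.cell_codes(k, disc[obs])
                for c in np.unique(codes):
                    assert abs(resid[codes == c].mean()) < 1e-8

    def test_all_on_treatment_residuals_are_centred_values(self, rng):
        spec = ImputationModelSpec.from_name("OICS_R")
        disc = np.zeros(30, dtype=int)
        y = rng.normal(size=(30, 4))
        basis = compute_residual_basis(spec, disc, y, 3)
        r0 = basis.residuals(0, y[:, 0], disc)
        assert np.allclose(r0, y[:, 0] - y[:, 0].mean())
        # the OICS_R design spans the same space as CICS: identical OLS fits
        oics_r = build_design(spec, 2, disc, y, 3, resid_basis=basis)
        cics = build_design(ImputationModelSpec.from_name("CICS"), 2, disc, y, 3)
        yy = y[:, 2]
        pred_r = oics_r.matrix @ _OlsFit(oics_r.matrix, yy).beta
        pred_c = cics.matrix @ _OlsFit(cics.matrix, yy).beta
        assert np.allclose(pred_r, pred_c, atol=1e-8)


class TestSequentialImpute:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_pass_through_with_no_missing_data(self, complete_trial, name):
        imp = sequential_impute(complete_trial, name, 3, 1)
        y = complete_trial.y_matrix()
        for i in range(3):
            assert np.array_equal(imp.y[i], y)

    def test_observed_cells_identical_across_copies(self, masked_trial):
        imp = sequential_impute(masked_trial, "PICS", 5, 4)
        y = masked_trial.y_matrix()
        obs = ~np.isnan(y)
        for i in range(5):
            assert np.array_equal(imp.y[i][obs], y[obs])
            assert not np.isnan(imp.y[i]).any()
        # originally missing cells differ between copies
        assert not np.array_equal(imp.y[0][~obs], imp.y[1][~obs])

    def test_deterministic_given_seed(self, masked_trial):
        a = sequential_impute(masked_trial, "OIOS", 3, 99)
        b = sequential_impute(masked_trial, "OIOS", 3, 99)
        assert np.array_equal(a.y, b.y)

    def test_m_below_two_rejected(self, masked_trial):
        with pytest.raises(ValueError, match="2 imputations"):
            sequential_impute(masked_trial, "CICS", 1, 0)

    def test_stacked_round_trip_shape(self, masked_trial):
        imp = sequential_impute(masked_trial, "CICS", 3, 0)
        stacked = imp.stacked()
        assert len(stacked) == 3 * masked_trial.n
        assert stacked["imputation"].tolist() == sorted(stacked["imputation"].tolist())

    def test_no_offtreatment_donors_is_inestimable(self):
        # every discontinuer withdraws: status-based models have no donors
        trial = simulate_trial(
            scenario(disc_c=0.2, disc_a=0.2, withdrawal=1.0), seed=21
        )
        with pytest.raises(InestimableModelError) as exc:
            sequential_impute(trial, "OICS", 3, 0)
        assert exc.value.model == "OICS"
        assert exc.value.arm in ("C", "A")
        # the common-slope common-intercept model still runs
        sequential_impute(trial, "CICS", 3, 0)

    def test_mcar_imputation_recovers_full_data_estimate(self):
        # no discontinuation, 20% of final outcomes deleted completely at
        # random: CICS pooling must agree with the full-data analysis on
        # average (its validity under MCAR)
        rng = np.random.default_rng(31)
        cfg = scenario(disc_c=0.0, disc_a=0.0, withdrawal=0.0, n=100)
        diffs = []
        for r in range(200):
            trial = simulate_trial(cfg, seed=rng.integers(2**31))
            full = fit_ancova(trial.complete).effect
            y = trial.y_matrix()
            drop = rng.random(len(y)) < 0.2
            y[drop, 3] = np.nan
            masked = trial.with_y(y)
            imp = sequential_impute(masked, "CICS", 10, rng)
            pooled = pool_rubin([fit_ancova(d) for d in imp.datasets()])
            diffs.append(pooled.qbar - full)
        diffs = np.asarray(diffs)
        assert abs(diffs.mean()) < 3 * diffs.std(ddof=1) / np.sqrt(diffs.size)


class TestModelEquivalences:
    def run_paired(self, cfg, model_a, model_b, n_trials, seed0):
        diffs = []
        for r in range(n_trials):
            trial = simulate_trial(cfg, seed=np.random.SeedSequence([seed0, r]))
            est = {}
            for k, name in enumerate((model_a, model_b)):
                rng = np.random.default_rng(np.random.SeedSequence([seed0, r, k]))
                imp = sequential_impute(trial, name, 25, rng)
                fits = [fit_ancova(d) for d in imp.datasets()]
                est[name] = pool_rubin(fits).qbar
            diffs.append(est[model_a] - est[model_b])
        return np.asarray(diffs)

    def test_oics_and_oics_r_differ(self):
        # unequal DNAR discontinuation with unbalanced withdrawal: the raw-value
        # and residual-centred on/off models are genuinely different
        cfg = scenario(
            mechanism="DNAR", disc_c=0.1, disc_a=0.2,
            withdrawal=0.5, balance="more_early",
        )
        diffs = self.run_paired(cfg, "OICS", "OICS_R", 60, 77)
        assert abs(diffs.mean()) > 3 * diffs.std(ddof=1) / np.sqrt(diffs.size)
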