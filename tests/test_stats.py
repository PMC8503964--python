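import numpy as np
import pandas as pd
import pytest

from contrastadapt.observer import ObserverParams, expected_log_match
from contrastadapt.scale import build_replication_scale, contrast_at, nearest_position
from contrastadapt.session import replication_control_config, run_headless_session
from contrastadapt.stats import (
    fit_loglog,
    load_table3,
    make_results_figure,
    pooled_points,
    replicate_table2,
    summarize,
)


class TestSummarize:
    def test_constant_matches_give_zero_sd(self):
        df = pd.DataFrame(
            {
                "observer_id": ["1"] * 10,
                "condition": ["control"] * 10,
                "upper_contrast": [0.3438] * 10,
                "matched_contrast": [0.31] * 10,
                "is_practice": [False] * 10,
            }
        )
        out = summarize(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["mean_match"] == pytest.approx(0.31)
        assert row["sd_match"] == 0.0
        assert row["n"] == 10

    def test_agrees_with_two_pass_oracle(self, rng):
        n = 400
        df = pd.DataFrame(
            {
                "observer_id": rng.choice(["a", "b"], n),
                "condition": rng.choice(["control", "adaptation"], n),
                "upper_contrast": rng.choice([0.1183, 0.7], n),
                "matched_contrast": rng.uniform(0.01, 1.0, n),
                "is_practice": np.zeros(n, dtype=bool),
            }
        )
        out = summarize(df).set_index(["observer_id", "condition", "upper_contrast"])
        for key, grp in df.groupby(["observer_id", "condition", "upper_contrast"]):
            vals = grp["matched_contrast"].to_numpy()
            mean = vals.sum() / len(vals)
            sd = np.sqrt(((vals - mean) ** 2).sum() / (len(vals) - 1)) if len(vals) > 1 else 0.0
            row = out.loc[key]
            assert row["mean_match"] == pytest.approx(mean, rel=1e-12)
            assert row["sd_match"] == pytest.approx(sd, rel=1e-12)
            assert row["n"] == len(vals)

    def test_practice_trials_excluded_and_empty_rejected(self):
        df = pd.DataFrame(
            {
                "observer_id": ["1", "1"],
                "condition": ["control"] * 2,
                "upper_contrast": [0.7, 0.7],
                "matched_contrast": [0.6, 0.9],
                "is_practice": [False, True],
            }
        )
        out = summarize(df)
        assert out.iloc[0]["n"] == 1
        with pytest.raises(ValueError):
            summarize(df[df["is_practice"]])

    def test_noise_free_session_mean_is_quantized_expectation(self):
        p = ObserverParams(sigma_eps=0.0)
        records = run_headless_session(replication_control_config(seed=6), p)
        out = summarize(records).set_index("upper_contrast")
        scale = build_replication_scale()
        for c in out.index:
            expect = np.exp(expected_log_match(p, "control", c))
            quantized = contrast_at(scale, nearest_position(scale, float(expect)))
            assert out.loc[c, "mean_match"] == pytest.approx(quantized, rel=1e-12)
            assert out.loc[c, "sd_match"] == 0.0


class TestFitLoglog:
    def test_collinear_points_fit_exactly(self):
        x = np.array([0.02, 0.05, 0.1, 0.3, 0.7])
        y = np.exp(-0.2 + 1.3 * np.log(x))
        fit = fit_loglog(x, y)
        assert fit.slope == pytest.approx(1.3, abs=1e-10)
        assert fit.intercept == pytest.approx(-0.2, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-8)

    def test_accepts_point_pairs(self):
        pts = [(0.1, 0.09), (0.3, 0.28), (0.7, 0.72)]
        fit = fit_loglog(pts)
        assert fit.n_obs == 3 and fit.error_df == 1

    def test_r2_equals_squared_correlation_of_fit(self, rng):
        x = rng.uniform(0.02, 0.7, 30)
        y = np.exp(0.1 + 0.9 * np.log(x) + rng.normal(0, 0.2, 30))
        fit = fit_loglog(x, y)
        r = np.corrcoef(np.log(fit.predict(x)), np.log(y))[0, 1]
        assert fit.r2 == pytest.approx(r**2, rel=1e-10)

    def test_ci_brackets_estimate_and_df_identity(self, rng):
        x = rng.uniform(0.02, 0.7, 25)
        y = np.exp(0.9 * np.log(x) + rng.normal(0, 0.3, 25))
        fit = fit_loglog(x, y)
        assert fit.slope_ci[0] < fit.slope < fit.slope_ci[1]
        assert fit.intercept_ci[0] < fit.intercept < fit.intercept_ci[1]
        assert fit.error_df == fit.n_obs - 2

    @pytest.mark.parametrize(
        "x,y",
        [
            ([0.1, 0.2], [0.1, 0.2]),  # too few
            ([0.1, 0.2, -0.3], [0.1, 0.2, 0.3]),  # nonpositive x
            ([0.1, 0.2, 0.3], [0.1, 0.0, 0.3]),  # nonpositive y
            ([0.2, 0.2, 0.2], [0.1, 0.2, 0.3]),  # degenerate design
        ],
    )
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(ValueError):
            fit_loglog(x, y)


class TestBundledSummaryRefit:
    def test_observation_counts_and_df(self):
        fits = replicate_table2()
        assert fits["control"].n_obs == 22 and fits["control"].error_df == 20
        assert fits["adaptation"].n_obs == 12 and fits["adaptation"].error_df == 10

    def test_adaptation_slope_exceeds_unity_control_near_unity(self):
        fits = replicate_table2()
        assert fits["control"].slope > 0 and fits["adaptation"].slope > 0
        assert fits["adaptation"].slope > fits["control"].slope
        assert fits["adaptation"].slope_ci[0] > 1.0  # significantly above +1
        assert fits["control"].slope_ci[0] < 1.0 < fits["control"].slope_ci[1]

    def test_bundled_table_shape(self):
        t = load_table3()
        assert len(t) == 34  # 2 observers x (11 control + 6 adaptation)
        assert (t["n"] == 10).all()
        assert set(t["condition"]) == {"control", "adaptation"}


class TestResultsFigure:
    def test_figure_written_and_axes_logarithmic(self, tmp_path):
        summary = load_table3()
        fits = replicate_table2()
        path = tmp_path / "results.png"
        fig = make_results_figure(summary, fits, path)
        assert path.exists() and path.stat().st_size > 0
        ax = fig.axes[0]
        assert ax.get_xscale() == "log" and ax.get_yscale() == "log"
        # one fitted line per condition plus the two scatter series + diagonal
        assert len(ax.lines) >= 5
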