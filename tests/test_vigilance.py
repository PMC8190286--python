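import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from scavcam.core_io import join_snow
from scavcam.simulate import SimConfig, simulate_study, simulate_vigilance_observations
from scavcam.vigilance import (
    ConvergenceError,
    EmptyMedianError,
    UseClass,
    build_observations,
    classify_use,
    compute_median_threshold,
    fit_vigilance_model,
    predict_vigilance,
)

MARTEN_BETA = (-0.970, -0.007, 0.094, 0.331, 0.111, 0.157)


def _t(s):
    return np.datetime64(s)


class TestClassifyUse:
    def test_no_prior_use(self):
        assert classify_use(_t("2017-02-01T12:00"), np.array([], dtype="datetime64[s]")) == UseClass.NO_USE

    def test_stale_use(self):
        het = np.array([_t("2017-01-31T00:00")], dtype="datetime64[s]")  # 36 h earlier
        assert classify_use(_t("2017-02-01T12:00"), het, median_threshold=1) == UseClass.USED_GT_24H

    def test_tie_goes_to_low(self):
        # count within 24 h equals the median: classed LOW
        het = np.array([_t("2017-02-01T06:00"), _t("2017-02-01T07:00")], dtype="datetime64[s]")
        assert classify_use(_t("2017-02-01T12:00"), het, median_threshold=2) == UseClass.LOW_LT_24H
        assert classify_use(_t("2017-02-01T12:00"), het, median_threshold=1.5) == UseClass.HIGH_LT_24H

    def test_strictly_causal(self):
        """A detection at the exact observation instant does not count."""
        het = np.array([_t("2017-02-01T12:00")], dtype="datetime64[s]")
        assert classify_use(_t("2017-02-01T12:00"), het) == UseClass.NO_USE


class TestMedianThreshold:
    def test_median_split(self):
        med = compute_median_threshold(np.array([1, 1, 2, 5]))
        assert med == 1.5
        het = np.array([_t("2017-02-01T06:00")], dtype="datetime64[s]")
        assert classify_use(_t("2017-02-01T12:00"), het, median_threshold=med) == UseClass.LOW_LT_24H

    def test_all_equal_counts_all_low(self):
        assert compute_median_threshold(np.array([3, 3, 3])) == 3.0

    def test_empty_raises(self):
        with pytest.raises(EmptyMedianError):
            compute_median_threshold(np.array([]))

    def test_matches_sort_oracle(self, small_sim):
        """Pooled median equals a brute-force per-row recount and sort."""
        det = join_snow(small_sim.detections, small_sim.snow)
        obs, med = build_observations(det, "marten", "fisher")
        assert med is not None
        het = det[det["species"] == "fisher"]
        focal = obs.merge(det[["image_id", "timestamp"]], on="image_id")
        vals = []
        for _, r in focal.iterrows():
            h = het[(het["site_id"] == r["site_id"]) & (het["year_label"] == r["year_label"])]
            tdiff = (r["timestamp"] - pd.to_datetime(h["timestamp"])).dt.total_seconds()
            c = int(((tdiff > 0) & (tdiff <= 24 * 3600)).sum())
            if c >= 1:
                vals.append(c)
        assert med == float(np.median(sorted(vals)))


class TestBuildObservations:
    def test_analysis_start_and_unclassifiable_excluded(self, small_sim):
        det = join_snow(small_sim.detections, small_sim.snow)
        obs, _ = build_observations(det, "marten", "fisher")
        merged = obs.merge(small_sim.detections[["image_id", "behavior", "timestamp"]], on="image_id")
        assert (merged["behavior"] != "unclassifiable").all()
        dates = pd.to_datetime(merged["timestamp"])
        jan22 = pd.to_datetime(dates.dt.year.astype(str) + "-01-22")
        assert (dates.dt.normalize() > jan22).all()

    def test_partition_into_classes(self, small_sim):
        det = join_snow(small_sim.detections, small_sim.snow)
        obs, _ = build_observations(det, "marten", "fisher")
        counts = obs["use_class"].value_counts()
        assert counts.sum() == len(obs)
        assert set(counts.index) <= {c.value for c in UseClass}

    def test_per_individual_expansion(self, detections_factory):
        det = detections_factory(
            [("S01", "marten", 60 * 24 * 40, "vigilant", 2), ("S01", "marten", 60 * 24 * 40 + 6, "feeding", 1)]
        )
        det["depth_cm"] = 40.0
        obs1, _ = build_observations(det, "marten", "fisher")
        obs2, _ = build_observations(det, "marten", "fisher", per_individual=True)
        assert len(obs1) == 2
        assert len(obs2) == 3


class TestFitVigilanceModel:
    def test_sigma_zero_matches_plain_logistic(self):
        """With no year effect in truth, the GLMM fixed effects match a
        plain logistic fit."""
        import statsmodels.api as sm

        obs = simulate_vigilance_observations(MARTEN_BETA, sigma_year=0.0, seed=5)
        fit = fit_vigilance_model(obs, day_ref=43, snow_ref=45)
        X = np.column_stack(
            [
                np.ones(len(obs)),
                obs["days_since_jan1"] - 43,
                obs["snow_cm"] - 45,
                (obs["use_class"] == "high_lt_24h").astype(float),
                (obs["use_class"] == "low_lt_24h").astype(float),
                (obs["use_class"] == "used_gt_24h").astype(float),
            ]
        )
        plain = sm.Logit(obs["vigilant"].to_numpy(), X).fit(disp=0)
        assert fit.sigma_year < 0.05
        np.testing.assert_allclose(fit.beta, plain.params, atol=0.02)

    def test_matches_lme4_glmer(self, tmp_path):
        """Laplace ML fit agrees with lme4::glmer on the same data."""
        obs = simulate_vigilance_observations(
            MARTEN_BETA,
            sigma_year=0.3,
            n_per_class={"no_use": 600, "high_lt_24h": 150, "low_lt_24h": 150, "used_gt_24h": 900},
            seed=17,
        )
        fit = fit_vigilance_model(obs, day_ref=43, snow_ref=45)
        csv = tmp_path / "obs.csv"
        obs.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(lme4)
                d <- read.csv("{csv}")
                d$day_c <- d$days_since_jan1 - 43
                d$snow_c <- d$snow_cm - 45
                d$high <- as.numeric(d$use_class == "high_lt_24h")
                d$low <- as.numeric(d$use_class == "low_lt_24h")
                d$used <- as.numeric(d$use_class == "used_gt_24h")
                m <- glmer(vigilant ~ day_c + snow_c + high + low + used + (1 | year_label),
                           data = d, family = binomial)
                co <- summary(m)$coefficients
                write.csv(data.frame(beta = co[, 1], se = co[, 2]), "{tmp_path}/out.csv")
                """
            )
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(tmp_path / "out.csv")
        np.testing.assert_allclose(fit.beta, ref["beta"].to_numpy(), atol=5e-3)
        np.testing.assert_allclose(fit.table["se"].to_numpy(), ref["se"].to_numpy(), rtol=0.05)

    def test_recovers_generating_coefficients(self):
        obs = simulate_vigilance_observations(MARTEN_BETA, sigma_year=0.15, seed=2)
        fit = fit_vigilance_model(obs, day_ref=43, snow_ref=45)
        inside = 0
        for b_true, (_, row) in zip(MARTEN_BETA, fit.table.iterrows()):
            half = 1.96 * row["se"]
            inside += row["beta"] - half <= b_true <= row["beta"] + half
        assert inside >= 5

    def test_constant_response_raises(self):
        obs = simulate_vigilance_observations(MARTEN_BETA, seed=3)
        obs["vigilant"] = 0
        with pytest.raises(ConvergenceError):
            fit_vigilance_model(obs)

    def test_single_year_raises(self):
        obs = simulate_vigilance_observations(MARTEN_BETA, n_years=1, seed=4)
        with pytest.raises(ConvergenceError):
            fit_vigilance_model(obs)

    def test_dropped_level_recorded(self):
        obs = simulate_vigilance_observations(
            MARTEN_BETA,
            n_per_class={"no_use": 500, "low_lt_24h": 200, "used_gt_24h": 500},
            seed=6,
        )
        fit = fit_vigilance_model(obs)
        assert fit.dropped_levels == ["high_lt_24h"]
        assert "high_lt_24h" not in fit.predictors


class TestPredictVigilance:
    def test_intercept_only_identity(self):
        obs = simulate_vigilance_observations(MARTEN_BETA, seed=8)
        fit = fit_vigilance_model(obs, day_ref=43, snow_ref=45)
        p, lo, hi = predict_vigilance(fit, 43, 45, UseClass.NO_USE)
        assert lo <= p <= hi
        assert p == pytest.approx(expit(fit.beta[0]))

    def test_high_use_contrast_arithmetic(self):
        """At a baseline of 35% vigilance, the +0.331 high-use contrast
        yields about 43% (inverse-logit arithmetic)."""
        assert expit(logit(0.35) + 0.331) == pytest.approx(0.43, abs=0.005)

    def test_positive_contrast_raises_probability(self):
        obs = simulate_vigilance_observations(MARTEN_BETA, seed=9)
        fit = fit_vigilance_model(obs, day_ref=43, snow_ref=45)
        base, *_ = predict_vigilance(fit, 43, 45, UseClass.NO_USE)
        for uc in (UseClass.HIGH_LT_24H, UseClass.LOW_LT_24H, UseClass.USED_GT_24H):
            if fit.beta[fit.predictors.index(uc.value)] > 0:
                p, *_ = predict_vigilance(fit, 43, 45, uc)
                assert p > base

    def test_unknown_level_raises(self):
        obs = simulate_vigilance_observations(
            MARTEN_BETA,
            n_per_class={"no_use": 500, "low_lt_24h": 200, "used_gt_24h": 500},
            seed=10,
        )
        fit = fit_vigilance_model(obs)
        with pytest.raises(KeyError):
            predict_vigilance(fit, 43, 45, UseClass.HIGH_LT_24H)
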