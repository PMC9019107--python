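import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import special

import windkite as wk
from windkite import gamm as G


def null_facing_frame(rng, n_birds=12, n_per=400):
    """Facing simulated i.i.d. Bernoulli(1/3): no distance effect at all."""
    n = n_birds * n_per
    return pd.DataFrame({
        "bird_id": np.repeat([f"b{i}" for i in range(n_birds)], n_per),
        "distance_to_turbine_m": rng.uniform(0.0, 1500.0, size=n),
        "height_class": rng.choice(["low", "medium", "high"], size=n),
        "facing": (rng.uniform(size=n) < 1.0 / 3.0).astype(int),
    })


class TestNullData:
    @pytest.fixture(scope="class")
    def null_fit(self):
        rng = np.random.default_rng(21)
        return G.fit_facing_gamm(null_facing_frame(rng))

    def test_flat_curves_near_one_third(self, null_fit):
        grid = np.linspace(0.0, 1500.0, 16)
        for level in null_fit.class_levels:
            pe = G.predict_partial_effect(null_fit, level, grid)
            assert np.all(np.abs(pe["probability"] - 1.0 / 3.0) < 0.05)

    def test_probabilities_and_cis_well_formed(self, null_fit):
        pe = G.predict_partial_effect(null_fit, "low",
                                      np.linspace(0, 1500, 20))
        assert pe["probability"].between(0, 1).all()
        assert (pe["lci"] <= pe["probability"]).all()
        assert (pe["probability"] <= pe["uci"]).all()

    def test_edf_at_least_one(self, null_fit):
        assert (null_fit.smooths["edf"] >= 1.0 - 1e-6).all()


class TestAvoidanceRecovery:
    def test_low_class_dip_detected(self, avoidance_gamm_fit):
        s = avoidance_gamm_fit.smooths.set_index("height_class")
        assert s.loc["low", "p_value"] < 0.05
        pe = G.predict_partial_effect(avoidance_gamm_fit, "low",
                                      [200.0, 1400.0])
        assert pe["probability"].iloc[0] < pe["probability"].iloc[1]

    def test_unaffected_classes_stay_flat(self, avoidance_gamm_fit):
        s = avoidance_gamm_fit.smooths.set_index("height_class")
        for level in ("medium", "high"):
            assert s.loc[level, "p_value"] > 0.05

    def test_random_intercept_sd_recovered(self, avoidance_gamm_fit,
                                           avoidance_scenario):
        truth_sd = avoidance_scenario["config"].bird_intercept_sd
        assert avoidance_gamm_fit.sigma_b == pytest.approx(truth_sd, abs=0.15)

    def test_low_curve_roughly_monotone(self, avoidance_gamm_fit):
        pe = G.predict_partial_effect(avoidance_gamm_fit, "low",
                                      np.linspace(100, 1400, 14))
        probs = pe["probability"].to_numpy()
        assert np.all(np.diff(probs) > -0.05)  # spline wiggle tolerance


class TestPredictPartialEffect:
    def test_extrapolation_rejected(self, avoidance_gamm_fit):
        with pytest.raises(ValueError, match="range"):
            G.predict_partial_effect(avoidance_gamm_fit, "low", [1501.0])

    def test_unknown_class_rejected(self, avoidance_gamm_fit):
        with pytest.raises(ValueError):
            G.predict_partial_effect(avoidance_gamm_fit, "underground", [100])

    def test_ci_narrows_with_four_times_the_data(self):
        rng = np.random.default_rng(31)
        small = null_facing_frame(rng, n_birds=10, n_per=150)
        big = pd.concat([null_facing_frame(rng, n_birds=10, n_per=150)
                         for _ in range(4)], ignore_index=True)
        big["bird_id"] = np.repeat(
            [f"b{i}" for i in range(10)], 4 * 150)  # same 10 birds, 4x data
        lam = G.fit_facing_gamm(small).lambdas
        f_small = G.fit_facing_gamm(small, fixed_lambdas=lam)
        f_big = G.fit_facing_gamm(big, fixed_lambdas=lam)
        w = {}
        for name, fit in (("small", f_small), ("big", f_big)):
            pe = G.predict_partial_effect(fit, "low", [1000.0])
            w[name] = float(pe["uci"].iloc[0] - pe["lci"].iloc[0])
        assert w["big"] < 0.7 * w["small"]


class TestBoundaryCases:
    def test_single_bird_variance_at_zero_boundary(self):
        rng = np.random.default_rng(41)
        df = null_facing_frame(rng, n_birds=1, n_per=600)
        fit = G.fit_facing_gamm(df)
        assert fit.sigma_b == 0.0
        assert any("single bird" in w for w in fit.warnings_)

    def test_single_class_data_fits_only_that_class(self):
        rng = np.random.default_rng(42)
        df = null_facing_frame(rng, n_birds=8, n_per=120)
        df["height_class"] = "low"
        fit = G.fit_facing_gamm(df)
        assert fit.class_levels == ["low"]
        assert len(fit.smooths) == 1

    def test_sparse_class_dropped_with_warning(self):
        rng = np.random.default_rng(43)
        df = null_facing_frame(rng, n_birds=8, n_per=120)
        df.loc[df["height_class"] == "high", "height_class"] = "medium"
        df.loc[df.index[:10], "height_class"] = "high"  # 10 < 50 records
        fit = G.fit_facing_gamm(df)
        assert "high" not in fit.class_levels
        assert any("excluded" in w for w in fit.warnings_)

    def test_non_binary_response_rejected(self):
        df = pd.DataFrame({"bird_id": ["a", "b"], "facing": [0.2, 1.0],
                           "distance_to_turbine_m": [10.0, 20.0],
                           "height_class": ["low", "low"]})
        with pytest.raises(ValueError):
            G.fit_facing_gamm(df)


class TestAgainstMgcv:
    """Independent oracle: penalized-spline logistic additive model fitted
    by the reference implementation on identical data."""

    def test_matches_mgcv_fit(self, avoidance_gamm_subset, tmp_path):
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        fit = wk.fit_facing_gamm(avoidance_gamm_subset)
        csv = tmp_path / "subset.csv"
        avoidance_gamm_subset[
            ["facing", "distance_to_turbine_m", "height_class",
             "bird_id"]].to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(mgcv))
            d <- read.csv('{csv}')
            d$height_class <- factor(d$height_class,
                                     levels = c('low', 'medium', 'high'))
            d$bird_id <- factor(d$bird_id)
            m <- gam(facing ~ height_class
                       + s(distance_to_turbine_m, by = height_class,
                           k = 10, bs = 'ps', m = c(2, 2))
                       + s(bird_id, bs = 're'),
                     data = d, family = binomial, method = 'ML')
            nd <- data.frame(
                distance_to_turbine_m = rep(c(200, 600, 1000, 1400), 3),
                height_class = factor(rep(c('low', 'medium', 'high'),
                                          each = 4),
                                      levels = levels(d$height_class)),
                bird_id = d$bird_id[1])
            p <- predict(m, nd, type = 'link', exclude = 's(bird_id)',
                         newdata.guaranteed = TRUE)
            cat(plogis(p), sep = '\\n')
        """)
        rfile = tmp_path / "fit.R"
        rfile.write_text(script)
        out = subprocess.run(["Rscript", str(rfile)], capture_output=True,
                             text=True, timeout=600)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        mine = np.concatenate([
            G.predict_partial_effect(fit, lvl,
                                     [200.0, 600.0, 1000.0, 1400.0]
                                     )["probability"].to_numpy()
            for lvl in ("low", "medium", "high")])
        # same architecture, independently implemented: curves agree to a
        # couple of percentage points of probability
        np.testing.assert_allclose(mine, ref, atol=0.025)
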