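"""Phenotype correlation maps, type enrichment, regression, LOESS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from somportrait import (correlation_map, loess_trend, spot_regression,
                         type_enrichment)
from somportrait.phenotype import CorrelationMap


class TestCorrelationMap:
    def test_feature_equal_to_unit_profile_gives_r1(self, reference_run):
        som = reference_run.som
        feature = pd.Series(som.codebook_[17], index=som.sample_ids_,
                            name="unit17")
        cm = correlation_map(som, feature)
        assert cm.grid.ravel()[17] == pytest.approx(1.0)
        assert cm.argmax_unit == tuple(divmod(np.argmax(cm.grid.ravel()),
                                              som.grid_cols))
        assert np.abs(cm.grid).max() <= 1.0

    def test_hand_computed_point_biserial(self):
        """Unit profile (1,2,3,4) against (0,0,1,1) -> r = 2/sqrt(5)."""
        from somportrait import SOMPortrait
        som = SOMPortrait(grid_rows=1, grid_cols=1)
        som.codebook_ = np.array([[1.0, 2.0, 3.0, 4.0]])
        som.sample_ids_ = ["a", "b", "c", "d"]
        som.gene_ids_ = ["g"]
        som.gene_bmu_ = pd.Series([0], index=["g"])
        feature = pd.Series([0, 0, 1, 1], index=som.sample_ids_, name="f")
        cm = correlation_map(som, feature.astype(float), kind="binary")
        assert cm.grid.ravel()[0] == pytest.approx(2 / np.sqrt(5), rel=1e-12)

    def test_point_biserial_equals_pearson_on_indicator(self, reference_run):
        """The binary map is numerically identical to the continuous map of
        the 0/1 coding (machine precision)."""
        som = reference_run.som
        sex = reference_run.phenotypes["sex"]
        binary = correlation_map(som, sex, kind="binary")
        pearson = correlation_map(som, sex.astype(float), kind="continuous")
        np.testing.assert_array_equal(binary.grid, pearson.grid)

    def test_affine_invariance_and_sign_flip(self, reference_run):
        som = reference_run.som
        age = reference_run.phenotypes["age"]
        base = correlation_map(som, age).grid
        scaled = correlation_map(som, 3.0 * age + 7.0).grid
        flipped = correlation_map(som, -2.0 * age).grid
        np.testing.assert_allclose(scaled, base, atol=1e-12)
        np.testing.assert_allclose(flipped, -base, atol=1e-12)

    def test_categorical_expands_one_vs_rest(self, reference_run):
        som = reference_run.som
        levels = pd.Series(
            pd.cut(reference_run.phenotypes["bmi"], [0, 25, 30, 100],
                   labels=["nwt", "pre", "obese"]).astype(str),
            index=reference_run.phenotypes.index)
        maps = correlation_map(som, levels, kind="categorical")
        assert set(maps) == {"nwt", "pre", "obese"}
        assert all(isinstance(m, CorrelationMap) for m in maps.values())

    def test_missing_values_dropped_pairwise(self, reference_run):
        som = reference_run.som
        age = reference_run.phenotypes["age"].copy()
        age.iloc[:10] = np.nan
        cm = correlation_map(som, age)
        assert cm.n_samples == len(age) - 10

    def test_zero_variance_feature_rejected(self, reference_run):
        flat = pd.Series(1.0, index=reference_run.som.sample_ids_)
        with pytest.raises(ValueError, match="variance"):
            correlation_map(reference_run.som, flat)

    def test_coupled_phenotype_localizes_in_its_module(self, reference_run):
        """The age map peaks inside the planted age-coupled module."""
        run = reference_run
        cm = correlation_map(run.som, run.phenotypes["age"])
        coupled = run.config.resolved_phenotype_effects()["age"]
        module = run.config.module_labels()[list(coupled)[0]]
        units = set(run.som.gene_bmu_.loc[
            sorted(run.truth.module_genes()[module])])
        argmax_flat = cm.argmax_unit[0] * run.som.grid_cols + cm.argmax_unit[1]
        assert argmax_flat in units


class TestTypeEnrichment:
    def test_exclusive_level_most_enriched(self):
        types = pd.Series(["1"] * 20 + ["2"] * 20)
        level = pd.Series(["x"] * 20 + ["y"] * 20)
        out = type_enrichment(types, level)
        best = out.sort_values("p").iloc[0]
        assert (best["type"], best["level"]) in {("1", "x"), ("2", "y")}
        assert best["p"] < 1e-9
        # 2x2 table counts conserved per level
        for lev in ("x", "y"):
            assert out.loc[out["level"] == lev, "count"].sum() == 20

    def test_independent_feature_uniform_p(self, rng):
        """Under independence the enrichment p-values are ~Uniform(0,1)."""
        ps = []
        for rep in range(60):
            types = pd.Series(rng.choice(["1", "2"], size=120))
            level = pd.Series(rng.choice(["x", "y"], size=120))
            out = type_enrichment(types, level)
            ps.append(out["p"].iloc[0])
        frac = np.mean(np.asarray(ps) < 0.25)
        # discrete p-values are conservative; a right-tailed exact test
        # never rejects too often under the null
        assert frac <= 0.35

    def test_planted_disease_enriched_in_coupled_type(self, reference_run):
        """The planted age/disease coupling drives enrichment of the
        disease flag in the recovered type that hosts the coupled module."""
        run = reference_run
        out = type_enrichment(run.assignment["type"],
                              run.phenotypes["disease"].astype(int))
        sig = out[(out["level"] == 1) & (out["fdr"] < 0.05) &
                  (out["direction"] == "enriched")]
        assert len(sig) >= 1

    def test_needs_two_levels(self):
        with pytest.raises(ValueError):
            type_enrichment(pd.Series(["1", "2"]), pd.Series(["x", "x"]))


class TestSpotRegression:
    def test_single_predictor_beta_equals_pearson(self, rng):
        x = rng.normal(size=80)
        y = 0.6 * x + rng.normal(0, 0.5, 80)
        spots = pd.DataFrame({"A": y}, index=[f"s{i}" for i in range(80)])
        phen = pd.DataFrame({"x": x}, index=spots.index)
        out = spot_regression(spots, phen)
        assert out["beta_std"].iloc[0] == pytest.approx(
            np.corrcoef(x, y)[0, 1], rel=1e-9)

    def test_true_predictor_significant_null_not(self, rng):
        n = 150
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = x1 + rng.normal(0, 0.4, n)
        spots = pd.DataFrame({"A": y}, index=[f"s{i}" for i in range(n)])
        phen = pd.DataFrame({"x1": x1, "x2": x2}, index=spots.index)
        out = spot_regression(spots, phen).set_index("phenotype")
        assert out.loc["x1", "p"] < 1e-10
        assert out.loc["x2", "p"] > 0.001
        assert abs(out.loc["x2", "beta_std"]) < 0.2

    def test_noise_free_orthonormal_design_exact(self):
        n = 64
        t = np.arange(n)
        x1 = np.cos(2 * np.pi * t / n)
        x2 = np.sin(2 * np.pi * t / n)
        y = 2 * x1 - x2
        spots = pd.DataFrame({"A": y}, index=[f"s{i}" for i in range(n)])
        phen = pd.DataFrame({"x1": x1, "x2": x2}, index=spots.index)
        out = spot_regression(spots, phen).set_index("phenotype")
        # standardized betas of a noise-free orthogonal design: exact
        sy = y.std()
        assert out.loc["x1", "beta_std"] == pytest.approx(2 * x1.std() / sy)
        assert out.loc["x2", "beta_std"] == pytest.approx(-x2.std() / sy)

    def test_collinear_column_dropped_with_warning(self, rng):
        x = rng.normal(size=50)
        spots = pd.DataFrame({"A": rng.normal(size=50)},
                             index=[f"s{i}" for i in range(50)])
        phen = pd.DataFrame({"x": x, "x2": 2 * x + 1}, index=spots.index)
        with pytest.warns(UserWarning, match="collinear"):
            out = spot_regression(spots, phen)
        assert len(out) == 1
        assert out.attrs["dropped"] == ["x2"]

    def test_planted_couplings_recovered(self, reference_run):
        """Spot regression flags the phenotypes coupled into the planted
        modules behind each matched spot."""
        from somportrait import match_modules, spot_profile_matrix
        run = reference_run
        res = match_modules(run.spots, run.truth)
        mod2spot = dict(zip(res.pairs["module"], res.pairs["spot_id"]))
        out = spot_regression(spot_profile_matrix(run.spots),
                              run.phenotypes)
        out = out.set_index(["spot_id", "phenotype"])
        labels = run.config.module_labels()
        sign_ok = 0
        sig = 0
        checks = 0
        for p, slopes in run.config.resolved_phenotype_effects().items():
            for m, beta in slopes.items():
                mod = labels[m]
                if mod not in mod2spot:
                    continue
                checks += 1
                row = out.loc[(mod2spot[mod], p)]
                sign_ok += np.sign(row["beta_std"]) == np.sign(beta)
                sig += row["p"] < 0.05
        # age and the disease flag share variance by construction (disease
        # prevalence is a logistic function of age), so one partial effect
        # may fall short of significance
        assert checks >= 3
        assert sign_ok == checks
        assert sig >= checks - 1


class TestLoess:
    def test_constant_response(self):
        out = loess_trend(np.linspace(0, 1, 30), np.full(30, 3.0))
        np.testing.assert_allclose(out["y"], 3.0, atol=1e-9)
        assert len(out) == 100

    def test_exact_line_reproduced(self):
        x = np.linspace(0, 10, 50)
        out = loess_trend(x, 2 * x + 1, span=0.4)
        np.testing.assert_allclose(out["y"], 2 * out["x"] + 1, atol=1e-6)

    def test_turning_point_located(self):
        """Piecewise-linear response: the curvature peak of the fitted
        curve falls within one grid step of the slope change."""
        x = np.linspace(0, 10, 200)
        y = np.where(x < 6, 0.2 * x, 0.2 * 6 + 2.0 * (x - 6))
        out = loess_trend(x, y, span=0.3)
        curv = np.abs(np.diff(out["y"], 2))
        x0 = out["x"].iloc[int(np.argmax(curv)) + 1]
        step = out["x"].iloc[1] - out["x"].iloc[0]
        assert abs(x0 - 6.0) <= 3 * step

    def test_groups_fit_separately(self, rng):
        x = np.concatenate([np.linspace(0, 1, 30), np.linspace(0, 1, 30)])
        y = np.concatenate([np.zeros(30), np.ones(30)])
        g = np.array(["w"] * 30 + ["m"] * 30)
        out = loess_trend(x, y, groups=g)
        assert set(out["group"]) == {"w", "m"}
        np.testing.assert_allclose(out.loc[out["group"] == "w", "y"], 0,
                                   atol=1e-9)
        np.testing.assert_allclose(out.loc[out["group"] == "m", "y"], 1,
                                   atol=1e-9)

    def test_too_few_points_rejected_and_span_widened(self, rng):
        with pytest.raises(ValueError):
            loess_trend(np.arange(5), np.arange(5))
        with pytest.warns(UserWarning, match="span widened"):
            loess_trend(np.arange(12), rng.normal(size=12), span=0.05)

    def test_spot_trend_follows_planted_age_coupling(self, reference_run):
        """Expression of the age-coupled spot rises with age along the
        LOESS curve."""
        from somportrait import match_modules
        run = reference_run
        res = match_modules(run.spots, run.truth)
        coupled = run.config.resolved_phenotype_effects()["age"]
        mod = run.config.module_labels()[list(coupled)[0]]
        row = res.pairs[res.pairs["module"] == mod]
        assert not row.empty
        spot = {s.spot_id: s for s in run.spots}[row["spot_id"].iloc[0]]
        out = loess_trend(run.phenotypes["age"].to_numpy(),
                          spot.profile.to_numpy())
        assert out["y"].iloc[-1] > out["y"].iloc[0]
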