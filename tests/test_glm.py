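"""Design-matrix construction, global-covariate strategies, dual-model runs."""

import numpy as np
import pandas as pd
import pytest

import megasite as ms
from megasite.errors import ConfigurationError, DataError


def cohort(n_per_site=20, n_sites=3, seed=0):
    spec = ms.SimulationSpec(
        n_sites=n_sites, subjects_per_site=n_per_site, seed=seed,
        covariate_specs=[ms.CovariateSpec(
            "age", "truncated_normal", {"mean": 40, "sd": 10, "low": 18,
                                        "high": 80})],
    )
    return ms.generate_cohort(spec)


class TestBuildDesign:
    def test_random_intercept_fixed_slopes_column_count(self):
        sub = cohort()
        spec = ms.DesignSpec(terms=[ms.Term("age"),
                                    ms.Term("group", role="interest")],
                             intercept="random")
        d = ms.build_design(sub, spec)
        assert d.n_columns == 5  # 3 site indicators + age + group
        assert d.contrast.tolist() == [0, 0, 0, 0, 1]

    def test_random_quadratic_age_slope_column_count(self):
        sub = cohort()
        spec = ms.DesignSpec(
            terms=[ms.Term("age", slope="random", transform="quadratic"),
                   ms.Term("group", role="interest")],
            intercept="random",
        )
        d = ms.build_design(sub, spec)
        # 3 intercepts + 3 age + 3 age^2 + 1 group
        assert d.n_columns == 10

    @pytest.mark.parametrize("weights", ["size", "equal"])
    def test_random_slope_contrast_is_weighted_mean_of_site_slopes(self, weights):
        sub = cohort(seed=1)
        rng = np.random.default_rng(1)
        y = (sub.group.to_numpy() * rng.uniform(0.5, 2.0)
             + rng.normal(size=len(sub)))
        spec = ms.DesignSpec(terms=[ms.Term("group", role="interest",
                                            slope="random")],
                             intercept="random", interest_weights=weights)
        d = ms.build_design(sub, spec)
        coef, *_ = np.linalg.lstsq(d.matrix, y, rcond=None)
        mega = float(d.contrast @ coef)
        # per-site OLS slopes
        slopes, sizes = [], []
        for site in sub.site_id.unique():
            mask = (sub.site_id == site).to_numpy()
            g = sub.group.to_numpy()[mask] - 0.5
            X = np.column_stack([np.ones(mask.sum()), g - g.mean()])
            slopes.append(np.linalg.lstsq(X, y[mask], rcond=None)[0][1])
            sizes.append(mask.sum())
        w = np.asarray(sizes, float) if weights == "size" \
            else np.ones(len(sizes))
        assert mega == pytest.approx(float(np.average(slopes, weights=w)),
                                     abs=1e-8)

    def test_rank_deficiency_names_aliased_columns(self):
        sub = cohort()
        sub["age_copy"] = sub["age"]
        spec = ms.DesignSpec(terms=[ms.Term("age"), ms.Term("age_copy"),
                                    ms.Term("group", role="interest")],
                             intercept="random")
        with pytest.raises(ConfigurationError, match="age_copy"):
            ms.build_design(sub, spec)

    def test_constant_covariate_under_random_slope_dropped_with_warning(self):
        sub = cohort()
        sub.loc[sub.site_id == "site01", "age"] = 33.0
        spec = ms.DesignSpec(terms=[ms.Term("age", slope="random"),
                                    ms.Term("group", role="interest")],
                             intercept="random")
        with pytest.warns(UserWarning, match="constant within site"):
            d = ms.build_design(sub, spec)
        assert "age[site01]" not in d.columns

    def test_blocks_default_to_scanner_and_vg_to_site(self):
        sub = cohort()
        spec = ms.DesignSpec(terms=[ms.Term("group", role="interest")],
                             intercept="random")
        d = ms.build_design(sub, spec)
        assert np.array_equal(d.exchangeability_blocks,
                              sub.scanner_id.to_numpy())
        assert np.array_equal(d.variance_groups, sub.site_id.to_numpy())

    def test_nuisance_centering_leaves_interest_statistic_unchanged(self):
        sub = cohort(seed=2)
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(len(sub), 3)) + sub.group.to_numpy()[:, None]
        base = ms.DesignSpec(terms=[ms.Term("age"),
                                    ms.Term("group", role="interest")],
                             intercept="random")
        centered = ms.DesignSpec(
            terms=[ms.Term("age", transform="center"),
                   ms.Term("group", role="interest")],
            intercept="random",
        )
        d1 = ms.build_design(sub, base)
        d2 = ms.build_design(sub, centered)
        s1 = ms.robust_statistic(Y, d1.matrix, d1.contrast, d1.variance_groups)
        s2 = ms.robust_statistic(Y, d2.matrix, d2.contrast, d2.variance_groups)
        assert np.allclose(s1, s2, atol=1e-8)


class TestGlobalStrategy:
    def test_proportion_with_unit_global_is_identity(self):
        Y = np.random.default_rng(0).normal(size=(10, 4))
        out, extra, prov = ms.apply_global_strategy(Y, np.ones(10), "proportion")
        assert np.array_equal(out, Y) and extra is None
        assert prov == "global:proportion"

    def test_proportion_zero_global_rejected(self):
        with pytest.raises(DataError):
            ms.apply_global_strategy(np.zeros((3, 2)), np.array([1.0, 0.0, 2.0]),
                                     "proportion")

    def test_residualize_orthogonalizes_every_element(self):
        rng = np.random.default_rng(1)
        g = rng.normal(size=50)
        Y = np.outer(g, rng.normal(size=6)) + rng.normal(size=(50, 6))
        out, _, _ = ms.apply_global_strategy(Y, g, "residualize")
        gc = g - g.mean()
        assert np.abs(gc @ out).max() < 1e-10 * np.abs(out).max() * len(g)

    def test_include_matches_normal_equations_oracle(self):
        # 12-subject toy set: interest estimate equals the partial regression
        # coefficient from an independent normal-equations solve
        rng = np.random.default_rng(2)
        n = 12
        x = rng.normal(size=n)
        g = rng.normal(size=n)
        y = 1.0 + 0.8 * x + 0.3 * g + rng.normal(0, 0.1, size=n)
        sub = pd.DataFrame({"site_id": ["A"] * n, "x": x, "g": g,
                            "subject_id": [f"s{i}" for i in range(n)]})
        spec = ms.DesignSpec(terms=[ms.Term("x", role="interest")],
                             intercept="fixed")
        d = ms.build_design(sub, spec)
        _, extra, _ = ms.apply_global_strategy(y[:, None], g, "include")
        from megasite.glm import add_global_column

        d2 = add_global_column(d, extra)
        est = float(d2.contrast @ np.linalg.lstsq(d2.matrix, y, rcond=None)[0])
        X = np.column_stack([np.ones(n), x, g])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)[1]
        assert est == pytest.approx(float(oracle), abs=1e-10)


class TestDualModelRun:
    def test_independent_global_gives_correlated_statistics(self):
        sub = cohort(n_per_site=40, seed=3)
        rng = np.random.default_rng(3)
        sub["icv"] = rng.normal(1400, 100, size=len(sub))
        V = 20
        Y = rng.normal(size=(len(sub), V)) + 0.6 * sub.group.to_numpy()[:, None]
        spec = ms.DesignSpec(terms=[ms.Term("age"),
                                    ms.Term("group", role="interest")],
                             intercept="random", global_strategy="include",
                             global_variable="icv")
        scheme = ms.PermutationScheme(n_perm=200, seed=0,
                                      blocks=sub.site_id.to_numpy())
        table = ms.dual_model_run(Y, sub, spec, scheme)
        assert set(table.family) == {"without_global", "global:include"}
        wide = table.pivot(index="element_id", columns="family", values="stat")
        r = np.corrcoef(wide.iloc[:, 0], wide.iloc[:, 1])[0, 1]
        assert r > 0.95
        assert (table.p_fwer >= table.p_unc - 1e-12).all()

    def test_collinear_global_warns_but_produces_results(self):
        sub = cohort(seed=4)
        rng = np.random.default_rng(4)
        g = sub.group.to_numpy() + rng.normal(0, 1e-4, size=len(sub))
        sub["icv"] = g
        Y = rng.normal(size=(len(sub), 3))
        spec = ms.DesignSpec(terms=[ms.Term("group", role="interest")],
                             intercept="random", global_strategy="include",
                             global_variable="icv")
        scheme = ms.PermutationScheme(n_perm=50, seed=0,
                                      blocks=sub.site_id.to_numpy())
        with pytest.warns(UserWarning, match="collinear"):
            table = ms.dual_model_run(Y, sub, spec, scheme)
        assert len(table) == 6
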