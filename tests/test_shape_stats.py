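"""Two-way shape MANOVA, canonical axes, allometry and PCA."""

import numpy as np
import pytest

import foxmorph as fm
from foxmorph.shape_stats import _sscp_effects


def balanced_2x2(n_per_cell, p, rng, hab_shift=None, sex_shift=None, int_shift=None):
    hab = np.repeat(["rural", "urban"], 2 * n_per_cell)
    sex = np.tile(np.repeat(["F", "M"], n_per_cell), 2)
    y = rng.standard_normal((4 * n_per_cell, p))
    if hab_shift is not None:
        y[hab == "urban"] += hab_shift
    if sex_shift is not None:
        y[sex == "M"] += sex_shift
    if int_shift is not None:
        y[(hab == "urban") & (sex == "M")] += int_shift
    return y, hab, sex


class TestManova:
    def test_single_response_matches_hand_anova(self):
        """With one response, Pillai reduces to SS_e/(SS_e+SS_err) and the
        approximate F equals the univariate two-way ANOVA F, checked against
        explicit balanced-design sums of squares on 8 observations."""
        y = np.array([3.1, 2.9, 4.2, 4.4, 5.0, 5.2, 7.9, 8.1])[:, None]
        hab = np.array(["rural"] * 4 + ["urban"] * 4)
        sex = np.array(["F", "F", "M", "M"] * 2)
        res = fm.manova_two_way(y, hab, sex)

        # balanced design: classical sums of squares by cell means
        cells = {
            (h, s): y[(hab == h) & (sex == s), 0].mean()
            for h in ("rural", "urban")
            for s in ("F", "M")
        }
        grand = y.mean()
        ss_hab = 4 * sum(
            (np.mean([cells[(h, "F")], cells[(h, "M")]]) - grand) ** 2
            for h in ("rural", "urban")
        )
        ss_sex = 4 * sum(
            (np.mean([cells[("rural", s)], cells[("urban", s)]]) - grand) ** 2
            for s in ("F", "M")
        )
        ss_int = 2 * sum(
            (cells[(h, s)]
             - np.mean([cells[(h, "F")], cells[(h, "M")]])
             - np.mean([cells[("rural", s)], cells[("urban", s)]])
             + grand) ** 2
            for h in ("rural", "urban")
            for s in ("F", "M")
        )
        ss_err = sum(
            ((y[(hab == h) & (sex == s), 0] - cells[(h, s)]) ** 2).sum()
            for h in ("rural", "urban")
            for s in ("F", "M")
        )
        for name, ss in (("habitat", ss_hab), ("sex", ss_sex), ("habitat:sex", ss_int)):
            eff = res.effects[name]
            assert eff.pillai == pytest.approx(ss / (ss + ss_err), rel=1e-10)
            assert eff.approx_f == pytest.approx((ss / 1) / (ss_err / 4), rel=1e-10)
            assert (eff.num_df, eff.den_df) == (1, 4)

    def test_zero_effects_give_zero_pillai(self):
        y, hab, sex = balanced_2x2(4, 3, np.random.default_rng(0))
        y[:] = np.arange(3)  # identical responses in every group
        res = fm.manova_two_way(y, hab, sex)
        for eff in res.effects.values():
            assert eff.pillai == pytest.approx(0.0, abs=1e-12)

    def test_matches_type_two_reference_values(self):
        """Frozen reference: car::Anova(lm(y ~ hab*sex), type=2) Pillai tests
        on this exact seeded dataset."""
        rng = np.random.default_rng(123)
        n = 24
        hab = np.array(["urban"] * 12 + ["rural"] * 12)
        sex = np.tile(["F", "M"], 12)
        y = rng.standard_normal((n, 3))
        y[hab == "urban"] += [0.8, 0, 0.2]
        y[sex == "M"] += [0, 0.6, -0.3]
        res = fm.manova_two_way(y, hab, sex)
        expected = {
            "habitat": (0.1761468343, 1.28285118, 0.31042),
            "sex": (0.4522201411, 4.953305243, 0.01113),
            "habitat:sex": (0.1868515813, 1.378726764, 0.28128),
        }
        for name, (pillai, f, p) in expected.items():
            eff = res.effects[name]
            assert eff.pillai == pytest.approx(pillai, abs=1e-9)
            assert eff.approx_f == pytest.approx(f, abs=1e-7)
            assert eff.p_value == pytest.approx(p, abs=1e-5)
            assert (eff.num_df, eff.den_df) == (3, 18)

    def test_interaction_term_matches_statsmodels(self):
        """The interaction hypothesis is adjusted for both main effects in
        every SSCP convention, so its Pillai/F must agree with statsmodels'
        MANOVA term test."""
        MANOVA = pytest.importorskip("statsmodels.multivariate.manova").MANOVA
        import pandas as pd

        rng = np.random.default_rng(77)
        y, hab, sex = balanced_2x2(6, 3, rng, hab_shift=[0.5, 0, 0], int_shift=[0, 0.8, 0])
        df = pd.DataFrame(y, columns=["y1", "y2", "y3"])
        df["hab"], df["sex"] = hab, sex
        ref = (
            MANOVA.from_formula("y1 + y2 + y3 ~ hab * sex", data=df)
            .mv_test()
            .results["hab:sex"]["stat"]
        )
        eff = fm.manova_two_way(y, hab, sex).effects["habitat:sex"]
        assert eff.pillai == pytest.approx(ref.loc["Pillai's trace", "Value"], rel=1e-8)
        assert eff.approx_f == pytest.approx(ref.loc["Pillai's trace", "F Value"], rel=1e-8)

    def test_pillai_invariant_to_other_factor_label_recoding(self):
        y, hab, sex = balanced_2x2(5, 4, np.random.default_rng(1), hab_shift=0.5)
        r1 = fm.manova_two_way(y, hab, sex)
        sex_recoded = np.where(sex == "F", "M", "F")
        r2 = fm.manova_two_way(y, hab, sex_recoded)
        assert r1.effects["habitat"].pillai == pytest.approx(
            r2.effects["habitat"].pillai, rel=1e-12
        )

    def test_empty_cell_rejected(self):
        y = np.random.default_rng(2).standard_normal((12, 2))
        hab = np.array(["urban"] * 6 + ["rural"] * 6)
        sex = np.array(["F"] * 6 + ["M"] * 6)  # no urban males
        with pytest.raises(ValueError, match="cell"):
            fm.manova_two_way(y, hab, sex)

    def test_singular_error_sscp_advises_reduction(self):
        y, hab, sex = balanced_2x2(2, 20, np.random.default_rng(3))
        with pytest.raises(ValueError, match="reduce dimensionality"):
            fm.manova_two_way(y, hab, sex)

    def test_more_than_two_levels_rejected(self):
        y = np.random.default_rng(4).standard_normal((9, 2))
        hab = np.array(["urban", "rural", "peri"] * 3)
        sex = np.tile(["F", "M", "F"], 3)
        with pytest.raises(ValueError, match="2 levels"):
            fm.manova_two_way(y, hab, sex)


class TestCanonicalAxis:
    def test_recovers_separating_coordinate(self):
        rng = np.random.default_rng(5)
        y, hab, sex = balanced_2x2(30, 4, rng, hab_shift=[2.0, 0, 0, 0])
        ax = fm.canonical_axis(y, "habitat", hab, sex)
        assert abs(ax.vector[0]) > 0.97
        assert ax.group_means["urban"] > ax.group_means["rural"]
        assert ax.scores.mean() == pytest.approx(0.0, abs=1e-10)

    def test_equivariant_under_rotation_of_score_space(self):
        rng = np.random.default_rng(6)
        y, hab, sex = balanced_2x2(10, 4, rng, hab_shift=[1.0, 0.5, 0, 0])
        q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        ax1 = fm.canonical_axis(y, "habitat", hab, sex)
        ax2 = fm.canonical_axis(y @ q, "habitat", hab, sex)
        back = ax2.vector @ q.T
        align = np.sign(back @ ax1.vector)
        np.testing.assert_allclose(back * align, ax1.vector, atol=1e-8)

    def test_adjusted_axis_beats_naive_axis_under_confounding(self):
        """When sex is unbalanced across habitats, the two-way canonical
        habitat axis recovers the true habitat direction while a naive
        one-way discriminant is pulled toward the sex direction."""
        rng = np.random.default_rng(7)
        v = np.array([1.0, 0, 0, 0, 0, 0])
        w = np.array([0, 1.0, 0, 0, 0, 0])
        hab = np.array(["urban"] * 60 + ["rural"] * 60)
        sex = np.array(["M"] * 50 + ["F"] * 10 + ["M"] * 10 + ["F"] * 50)
        a_h = np.where(hab == "urban", 0.5, -0.5)
        a_s = np.where(sex == "M", 0.5, -0.5)
        y = np.outer(a_h, 1.2 * v) + np.outer(a_s, 2.5 * w)
        y += 0.25 * rng.standard_normal(y.shape)

        ax = fm.canonical_axis(y, "habitat", hab, sex)
        angle_adj = np.degrees(np.arccos(abs(np.clip(ax.vector @ v, -1, 1))))

        # naive axis: raw difference of habitat means, which absorbs the
        # confounded sex displacement
        d = y[hab == "urban"].mean(0) - y[hab == "rural"].mean(0)
        d /= np.linalg.norm(d)
        angle_naive = np.degrees(np.arccos(abs(np.clip(d @ v, -1, 1))))

        assert angle_adj < 12.0
        assert angle_naive > 3 * angle_adj


class TestAllometry:
    def make_space(self, n=40, k=10, seed=8, slope_norm=0.0, noise=0.01):
        spec = fm.SyntheticSpec(
            k=k,
            cell_counts={(h, s): n // 4 for h in ("urban", "rural") for s in ("F", "M")},
            habitat_norm=0.0,
            sex_norm=0.0,
            allometry_norm=slope_norm,
            noise_sd=noise,
            seed=seed,
        )
        ds, truth = fm.generate_population(spec)
        return fm.gpa(ds), truth

    def test_exact_allometric_construction_gives_r2_one(self):
        space, _ = self.make_space(slope_norm=0.05, noise=1e-9)
        res = fm.allometry_regression(space, n_perm=19, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-4)

    def test_null_gives_small_r2_and_nonsignificant_p(self):
        space, _ = self.make_space(slope_norm=0.0, noise=0.01)
        res = fm.allometry_regression(space, n_perm=199, seed=0)
        assert res.r_squared < 0.15
        assert res.p_value > 0.05

    def test_residuals_uncorrelated_with_predictor(self):
        space, _ = self.make_space(slope_norm=0.05, noise=0.01)
        res = fm.allometry_regression(space, n_perm=19, seed=0)
        x = np.log(space.centroid_sizes)
        flat = res.residual_shapes.reshape(space.n, -1)
        cov = (x - x.mean()) @ (flat - flat.mean(0))
        np.testing.assert_allclose(cov, 0.0, atol=1e-10)

    def test_constant_size_rejected(self):
        space, _ = self.make_space()
        space.centroid_sizes[:] = 3.0
        with pytest.raises(ValueError, match="vary"):
            fm.allometry_regression(space)


class TestSpeciesMeans:
    def test_mean_properties(self):
        rng = np.random.default_rng(9)
        coords = rng.standard_normal((5, 6, 2))
        species = np.array(["a", "b", "b", "c", "c"])
        labels, means = fm.species_mean_shapes(coords, species)
        assert labels == ["a", "b", "c"]
        np.testing.assert_allclose(means[0], coords[0])           # singleton
        np.testing.assert_allclose(means[1], coords[1:3].mean(0))  # midpoint

    def test_duplicating_specimens_leaves_means_unchanged(self):
        rng = np.random.default_rng(10)
        coords = rng.standard_normal((4, 5, 2))
        species = np.array(["a", "a", "b", "b"])
        _, m1 = fm.species_mean_shapes(coords, species)
        _, m2 = fm.species_mean_shapes(
            np.concatenate([coords, coords]), np.concatenate([species, species])
        )
        np.testing.assert_allclose(m1, m2)


class TestPca:
    def test_collinear_data_has_one_component(self):
        t = np.linspace(-1, 1, 8)
        data = np.outer(t, [1.0, 2.0, -1.0])
        res = fm.pca(data)
        assert res.eigenvalues[0] > 0
        np.testing.assert_allclose(res.eigenvalues[1:], 0.0, atol=1e-12)

    def test_total_variance_conserved_and_score_variances(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((20, 5))
        res = fm.pca(data)
        total = np.trace(np.cov(data, rowvar=False))
        assert res.eigenvalues.sum() == pytest.approx(total, rel=1e-10)
        np.testing.assert_allclose(
            res.scores.var(axis=0, ddof=1), res.eigenvalues, rtol=1e-10
        )

    def test_two_dim_closed_form(self):
        """Four-point toy set against the closed-form 2×2 eigendecomposition."""
        data = np.array([[0.0, 0.0], [2.0, 1.0], [3.0, 3.0], [5.0, 4.0]])
        c = np.cov(data, rowvar=False)
        tr, det = c[0, 0] + c[1, 1], c[0, 0] * c[1, 1] - c[0, 1] ** 2
        disc = np.sqrt(tr**2 / 4 - det)
        expected = np.array([tr / 2 + disc, tr / 2 - disc])
        res = fm.pca(data)
        np.testing.assert_allclose(res.eigenvalues, expected, rtol=1e-12)
        v1 = np.array([c[0, 1], expected[0] - c[0, 0]])
        v1 /= np.linalg.norm(v1)
        assert abs(res.eigenvectors[:, 0] @ v1) == pytest.approx(1.0, abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(12)
        data = rng.standard_normal((15, 6))
        res = fm.pca(data)
        ref = sklearn_pca(n_components=6).fit(data)
        np.testing.assert_allclose(res.eigenvalues, ref.explained_variance_, rtol=1e-9)
        for j in range(6):
            assert abs(res.eigenvectors[:, j] @ ref.components_[j]) == pytest.approx(
                1.0, abs=1e-8
            )
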