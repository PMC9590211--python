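import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import f_oneway, pearsonr

from rhizovir.ecostats import (
    DistanceMatrix,
    bray_curtis,
    fit_random_intercept_lmm,
    mantel,
    nmds,
    permanova,
    shannon_diversity,
    two_way_anova,
)


def _dm(arr, ids=None):
    arr = np.asarray(arr, dtype=float)
    ids = ids or [f"s{i}" for i in range(arr.shape[0])]
    return DistanceMatrix(pd.DataFrame(arr, index=ids, columns=ids))


def _dm_from_points(points):
    diff = points[:, None, :] - points[None, :, :]
    return _dm(np.sqrt((diff**2).sum(axis=2)))


class TestShannon:
    def test_uniform_four_taxa(self):
        assert shannon_diversity([5, 5, 5, 5]) == pytest.approx(math.log(4))

    def test_single_taxon_zero(self):
        assert shannon_diversity([0, 42, 0]) == 0.0

    def test_formula_oracle_1234(self):
        # direct formula: -sum p ln p for p = (.1, .2, .3, .4)
        expected = -sum(p * math.log(p) for p in (0.1, 0.2, 0.3, 0.4))
        assert shannon_diversity([1, 2, 3, 4]) == pytest.approx(expected)
        assert round(shannon_diversity([1, 2, 3, 4]), 4) == 1.2799

    def test_all_zero_profile_nan_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="rhizovir"):
            assert math.isnan(shannon_diversity([0.0, 0.0]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon_diversity([1, -1])


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["s1", "s2"])
        assert bray_curtis(m).values.loc["s1", "s2"] == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["s1", "s2"])
        assert bray_curtis(m, transform=None).values.loc["s1", "s2"] == 1.0

    def test_hand_arithmetic_with_sqrt(self):
        m = pd.DataFrame([[4.0, 1.0], [1.0, 4.0]], index=["s1", "s2"])
        # sqrt -> (2,1) vs (1,2): (1+1)/(3+3) = 1/3
        assert bray_curtis(m, transform="sqrt").values.loc["s1", "s2"] == (
            pytest.approx(1.0 / 3.0)
        )

    def test_matches_scipy_on_random_data(self, rng):
        m = pd.DataFrame(rng.random((6, 20)) * 10)
        mine = bray_curtis(m, transform=None).to_numpy()
        for i in range(6):
            for j in range(6):
                want = scipy_braycurtis(m.iloc[i], m.iloc[j]) if i != j else 0.0
                assert mine[i, j] == pytest.approx(want)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(pd.DataFrame([[-1.0, 2.0]]))

    def test_metric_axioms(self, rng):
        m = pd.DataFrame(rng.integers(0, 20, size=(8, 15)).astype(float))
        d = bray_curtis(m).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert ((d >= 0) & (d <= 1 + 1e-12)).all()

    def test_all_zero_pair_warns(self, caplog):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 2.0]])
        with caplog.at_level("WARNING", logger="rhizovir"):
            d = bray_curtis(m)
        assert d.to_numpy()[0, 1] == 0.0


class TestNmds:
    def test_exact_2d_embedding_low_stress(self, rng):
        points = rng.random((10, 2)) * 5
        res = nmds(_dm_from_points(points), k=2, n_starts=4, seed=0)
        assert res.stress < 1e-3

    def test_stress_history_monotone_nonincreasing(self, rng):
        points = rng.random((9, 4))
        res = nmds(_dm_from_points(points), k=2, n_starts=3, seed=1)
        hist = np.array(res.stress_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_cross_implementation_oracle_six_points(self, rng):
        # reference: sklearn's non-metric MDS configuration, scored with the
        # standard stress-1 formula
        from scipy.optimize import isotonic_regression
        from sklearn.manifold import MDS

        points = rng.random((6, 3)) * 2
        dm = _dm_from_points(points)
        d = dm.to_numpy()

        ref = MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=8, random_state=0, normalized_stress=False, max_iter=500,
        )
        coords = ref.fit_transform(d)
        diff = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((diff**2).sum(axis=2))
        iu = np.triu_indices(6, k=1)
        order = np.argsort(d[iu], kind="stable")
        dist_flat = dist[iu]
        dhat = np.empty_like(dist_flat)
        dhat[order] = isotonic_regression(dist_flat[order]).x
        ref_stress = math.sqrt(
            ((dist_flat - dhat) ** 2).sum() / (dist_flat**2).sum()
        )

        res = nmds(dm, k=2, n_starts=10, seed=2)
        assert res.stress <= ref_stress + 0.01

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(_dm(np.zeros((2, 2))), k=2)


def _oneway_permanova_f(d, labels):
    """Independent pseudo-F from the pairwise-distance group-sum identity."""
    n = len(labels)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    ss_total = (d[np.triu_indices(n, k=1)] ** 2).sum() / n
    ss_within = 0.0
    for g in groups:
        idx = np.where(labels == g)[0]
        sub = d[np.ix_(idx, idx)]
        ss_within += (sub[np.triu_indices(len(idx), k=1)] ** 2).sum() / len(idx)
    ss_between = ss_total - ss_within
    df_b, df_w = len(groups) - 1, n - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestPermanova:
    def test_extreme_separation(self, rng):
        # groups large enough that group-preserving permutations (which tie
        # the observed F) are vanishingly rare, so p hits the add-one floor
        pts = np.vstack([rng.random((8, 2)), rng.random((8, 2)) + 100])
        dm = _dm_from_points(pts)
        res = permanova(
            dm, {"grp": ["a"] * 8 + ["b"] * 8}, n_permutations=199, seed=0
        )[0]
        assert res.effect_size > 0.95
        assert res.p_value == pytest.approx(1.0 / 200.0)

    def test_statistic_matches_independent_formula(self, rng):
        pts = rng.random((9, 4))
        dm = _dm_from_points(pts)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = permanova(dm, {"grp": labels}, n_permutations=9, seed=0)[0]
        assert res.statistic == pytest.approx(
            _oneway_permanova_f(dm.to_numpy(), labels)
        )

    def test_statistic_matches_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import permanova as sk_permanova

        pts = rng.random((10, 3))
        dm = _dm_from_points(pts)
        labels = ["a", "b"] * 5
        sk = sk_permanova(
            skbio.DistanceMatrix(dm.to_numpy(), ids=dm.sample_ids),
            grouping=labels,
            permutations=9,
        )
        res = permanova(dm, {"grp": labels}, n_permutations=9, seed=0)[0]
        assert res.statistic == pytest.approx(sk["test statistic"])

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        pts = rng.random((6, 2))
        dm = _dm_from_points(pts)
        labels = ["a", "a", "a", "b", "b", "b"]
        d = dm.to_numpy()
        f_obs = _oneway_permanova_f(d, labels)
        count = 0
        total = 0
        for perm in itertools.permutations(range(6)):
            dp = d[np.ix_(perm, perm)]
            if _oneway_permanova_f(dp, labels) >= f_obs - 1e-12:
                count += 1
            total += 1
        res = permanova(dm, {"grp": labels}, exhaustive=True)[0]
        assert res.p_value == pytest.approx(count / total)

    def test_r2_terms_plus_residual_sum_to_one(self, rng, design36):
        pts = rng.random((36, 5))
        dm = _dm_from_points(pts)
        dm.values.index = dm.values.columns = design36.sample_ids
        factors = {
            "compartment": design36.factor("compartment"),
            "rotation": design36.factor("rotation"),
            "growth_stage": design36.factor("growth_stage"),
        }
        results = permanova(dm, factors, n_permutations=9, seed=0)
        r2_sum = sum(r.effect_size for r in results)
        ss_resid = results[0].extra["ss_total"] - sum(
            r.extra["ss"] for r in results
        )
        assert r2_sum + ss_resid / results[0].extra["ss_total"] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_single_level_factor_rejected(self, rng):
        dm = _dm_from_points(rng.random((4, 2)))
        with pytest.raises(ValueError, match="single level"):
            permanova(dm, {"grp": ["a"] * 4}, n_permutations=9)

    def test_reproducible_under_seed(self, rng):
        dm = _dm_from_points(rng.random((8, 2)))
        labels = ["a", "b"] * 4
        r1 = permanova(dm, {"g": labels}, n_permutations=99, seed=5)[0]
        r2 = permanova(dm, {"g": labels}, n_permutations=99, seed=5)[0]
        assert r1.p_value == r2.p_value
        assert r1.p_value > 0


class TestMantel:
    def test_identical_matrices_r_one(self, rng):
        dm = _dm_from_points(rng.random((6, 2)))
        res = mantel(dm, dm, n_permutations=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_statistic_matches_skbio(self, rng):
        pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as sk_mantel

        d1 = _dm_from_points(rng.random((7, 2)))
        d2 = _dm_from_points(rng.random((7, 2)))
        r_sk, _, _ = sk_mantel(
            d1.to_numpy(), d2.to_numpy(), method="pearson", permutations=9
        )
        res = mantel(d1, d2, n_permutations=9, seed=0)
        assert res.statistic == pytest.approx(float(r_sk))

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        d1 = _dm_from_points(rng.random((5, 2)))
        d2 = _dm_from_points(rng.random((5, 2)))
        a, b = d1.to_numpy(), d2.to_numpy()
        iu = np.triu_indices(5, k=1)
        r_obs = pearsonr(a[iu], b[iu]).statistic
        count = total = 0
        for perm in itertools.permutations(range(5)):
            bp = b[np.ix_(perm, perm)]
            if pearsonr(a[iu], bp[iu]).statistic >= r_obs - 1e-12:
                count += 1
            total += 1
        res = mantel(d1, d2, exhaustive=True)
        assert res.p_value == pytest.approx(count / total)

    def test_constant_triangle_flagged(self):
        d_const = _dm(1 - np.eye(4))
        d_var = _dm_from_points(np.random.default_rng(0).random((4, 2)))
        res = mantel(d_const, d_var, n_permutations=9)
        assert math.isnan(res.statistic)
        assert res.extra.get("undefined")


class TestTwoWayAnova:
    def test_constant_response(self):
        res = two_way_anova(
            np.ones(8), ["a", "a", "b", "b"] * 2, ["x", "y"] * 4
        )
        assert (res.terms["f"] == 0).all()
        assert (res.terms["p"] == 1).all()

    def test_collapses_to_one_way(self, rng):
        y = rng.random(12)
        fa = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        fb = ["only"] * 12
        res = two_way_anova(y, fa, fb)
        want = f_oneway(y[:4], y[4:8], y[8:])
        row = res.terms.set_index("term").loc["A"]
        assert row["f"] == pytest.approx(want.statistic)
        assert row["p"] == pytest.approx(want.pvalue)

    def test_balanced_fixture_hand_sums_of_squares(self):
        # 2x2 balanced, 2 reps: SS computed from the textbook decomposition
        y = np.array([3.0, 5.0, 6.0, 8.0, 10.0, 12.0, 15.0, 13.0])
        fa = ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"]
        fb = ["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"]
        grand = y.mean()
        ss_a = sum(
            4 * (y[np.asarray(fa) == lv].mean() - grand) ** 2 for lv in ("a1", "a2")
        )
        ss_b = sum(
            4 * (y[np.asarray(fb) == lv].mean() - grand) ** 2 for lv in ("b1", "b2")
        )
        res = two_way_anova(y, fa, fb)
        table = res.terms.set_index("term")
        assert table.loc["A", "ss"] == pytest.approx(ss_a)
        assert table.loc["B", "ss"] == pytest.approx(ss_b)

    def test_matches_statsmodels_type1(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        n = 24
        df = pd.DataFrame(
            {
                "y": rng.random(n),
                "a": rng.choice(["a1", "a2", "a3"], size=n),
                "b": list(rng.choice(["b1", "b2"], size=n - 2)) + ["b1", "b2"],
            }
        )
        fit = smf.ols("y ~ C(a) + C(b)", data=df).fit()
        want = anova_lm(fit, typ=1)
        res = two_way_anova(df["y"], list(df["a"]), list(df["b"]))
        table = res.terms.set_index("term")
        assert table.loc["A", "f"] == pytest.approx(want.loc["C(a)", "F"])
        assert table.loc["B", "f"] == pytest.approx(want.loc["C(b)", "F"])
        assert table.loc["B", "p"] == pytest.approx(want.loc["C(b)", "PR(>F)"])

    def test_tukey_matches_scipy(self, rng):
        from scipy.stats import tukey_hsd

        y = rng.random(15)
        fa = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        fb = ["one"] * 15
        res = two_way_anova(y, fa, fb)
        want = tukey_hsd(y[:5], y[5:10], y[10:])
        got = res.tukey["A"].set_index(["level_1", "level_2"])
        assert got.loc[("a", "b"), "p_adj"] == pytest.approx(
            want.pvalue[0, 1], abs=1e-6
        )
        assert got.loc[("b", "c"), "p_adj"] == pytest.approx(
            want.pvalue[1, 2], abs=1e-6
        )

    def test_empty_cell_rejected_with_interaction(self):
        y = np.arange(6.0)
        fa = ["a1"] * 3 + ["a2"] * 3
        fb = ["b1", "b1", "b1", "b2", "b2", "b2"]
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(y, fa, fb, interaction=True)


class TestMixedModel:
    def test_zero_group_variance_collapses_to_ols(self, rng):
        n = 60
        x = rng.random(n) * 10
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, n)
        group = rng.choice(["g1", "g2", "g3"], size=n)
        res = fit_random_intercept_lmm(y, x, group)
        ols_slope, _ = np.polyfit(x, y, 1)
        se = res.slope_se
        assert abs(res.slope - ols_slope) < 2 * se
        assert res.group_variance < 0.05

    def test_balanced_closed_form_variance_components(self, rng):
        # intercept-only model, balanced groups: REML estimators equal the
        # classical ANOVA ones (sigma_e^2 = MSW, sigma_u^2 = (MSB - MSW)/m)
        n_groups, m = 6, 8
        u = rng.normal(0, 2.0, n_groups)
        y = np.concatenate(
            [5.0 + u[g] + rng.normal(0, 1.0, m) for g in range(n_groups)]
        )
        group = np.repeat(np.arange(n_groups), m)
        means = y.reshape(n_groups, m).mean(axis=1)
        msw = sum(
            ((y.reshape(n_groups, m)[g] - means[g]) ** 2).sum()
            for g in range(n_groups)
        ) / (n_groups * (m - 1))
        msb = m * ((means - y.mean()) ** 2).sum() / (n_groups - 1)
        want_su2 = max(0.0, (msb - msw) / m)
        res = fit_random_intercept_lmm(y, None, group)
        assert res.residual_variance == pytest.approx(msw, rel=1e-3)
        assert res.group_variance == pytest.approx(want_su2, rel=1e-3)

    def test_matches_statsmodels_mixedlm(self, rng):
        sm = pytest.importorskip("statsmodels.api")

        n_groups, m = 5, 10
        u = rng.normal(0, 1.0, n_groups)
        group = np.repeat(np.arange(n_groups), m)
        x = rng.random(n_groups * m) * 4
        y = 2.0 - 0.7 * x + u[group] + rng.normal(0, 0.5, n_groups * m)
        res = fit_random_intercept_lmm(y, x, group)
        md = sm.MixedLM(y, np.column_stack([np.ones_like(x), x]), groups=group)
        fit = md.fit(reml=True)
        assert res.slope == pytest.approx(fit.params[1], abs=1e-4)
        assert res.residual_variance == pytest.approx(fit.scale, rel=1e-3)
        assert res.group_variance == pytest.approx(
            float(np.asarray(fit.cov_re)[0, 0]), rel=1e-2, abs=1e-3
        )

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_random_intercept_lmm(
                np.arange(6.0), np.ones(6), ["a", "a", "a", "b", "b", "b"]
            )

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            fit_random_intercept_lmm(np.arange(4.0), np.arange(4.0), ["a"] * 4)
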