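"""Tests for the permutational multivariate statistics.

Oracles: classical one-way ANOVA F (scipy), scikit-bio's one-way
PERMANOVA/PERMDISP, full enumeration of two-group relabellings, and
brute-force nested-loop recomputations.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway, ortho_group

from reefcast.mvstats import (
    DistanceMatrix,
    axis_correlations,
    cap,
    classify_interaction,
    distance_matrix,
    effect_size,
    nmds,
    normalise,
    pairwise_permanova,
    permanova,
    permdisp,
)

from conftest import balanced_design


class TestNormalise:
    def test_z_score_of_simple_column(self):
        out = normalise(pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [4.0, 0.0, 2.0]}))
        assert list(out["x"]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(30, 4)))
        once = normalise(df)
        twice = normalise(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)

    def test_columns_standardised(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(loc=5, scale=9, size=(360, 7)))
        out = normalise(df)
        assert np.all(np.abs(out.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(out.std(axis=0, ddof=1) - 1) < 1e-10)

    def test_constant_column_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "urchin": [0.0, 0.0, 0.0]})
        with pytest.raises(ValueError, match="constant"):
            normalise(df)


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(ValueError):
            DistanceMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]))  # nonzero diag

    def test_matches_nested_loop_euclidean(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 3))
        d = distance_matrix(x).values
        for i in range(8):
            for j in range(8):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()), abs=1e-12
                )


class TestPermanova:
    def test_one_way_pseudo_f_equals_classical_anova(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=18)
        g = np.repeat(["a", "b", "c"], 6)
        res = permanova(distance_matrix(x.reshape(-1, 1)), list(g),
                        n_perm=9, seed=0)
        expected = f_oneway(x[:6], x[6:12], x[12:]).statistic
        assert res.table.loc["factor", "pseudo_F"] == pytest.approx(
            expected, abs=1e-9
        )

    def test_one_way_matches_scikit_bio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(4)
        x = rng.normal(size=(24, 5))
        g = list(np.repeat(["a", "b", "c", "d"], 6))
        d = distance_matrix(x)
        ours = permanova(d, g, n_perm=9, seed=0).table.loc["factor", "pseudo_F"]
        theirs = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d.values), g, permutations=9
        )["test statistic"]
        assert ours == pytest.approx(theirs, rel=1e-9)

    def test_sampled_p_matches_full_enumeration(self):
        """Two groups of three: the sampled permutation p converges to the
        exact p over all 20 relabellings."""
        x = np.array([0.1, 0.5, 0.3, 1.2, 1.5, 0.9])
        g = np.array(["a"] * 3 + ["b"] * 3)
        d = distance_matrix(x.reshape(-1, 1))
        f_obs = permanova(d, list(g), n_perm=9, seed=0).table.loc[
            "factor", "pseudo_F"]

        exceed = total = 0
        for idx in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(idx)] = "a"
            f_perm = f_oneway(x[lab == "a"], x[lab == "b"]).statistic
            total += 1
            exceed += f_perm >= f_obs - 1e-12
        p_exact = exceed / total

        n_perm = 9999
        p_sampled = permanova(d, list(g), n_perm=n_perm, seed=7).table.loc[
            "factor", "p_perm"]
        mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_sampled - p_exact) < 4 * mc_se + 2 / n_perm

    def test_three_factor_table_structure_and_additivity(self):
        design = balanced_design(n_rep=3)
        rng = np.random.default_rng(5)
        d = distance_matrix(rng.normal(size=(len(design), 5)))
        res = permanova(d, design, n_perm=19, seed=1)
        dfs = res.table["df"].drop(index=["Residual", "Total"])
        assert list(dfs) == [1, 2, 2, 2, 2, 4, 4]
        ss_sum = res.table.drop(index="Total")["SS"].sum()
        assert ss_sum == pytest.approx(res.table.loc["Total", "SS"], abs=1e-9)
        assert res.table.loc["Residual", "df"] == len(design) - 18

    def test_pseudo_f_invariant_under_rotation_and_translation(self):
        design = balanced_design(n_rep=2)
        rng = np.random.default_rng(6)
        x = rng.normal(size=(len(design), 5))
        rot = ortho_group.rvs(5, random_state=1)
        x2 = x @ rot + np.array([3.0, -1.0, 0.5, 2.0, 7.0])
        f1 = permanova(distance_matrix(x), design, n_perm=9, seed=0).table["pseudo_F"]
        f2 = permanova(distance_matrix(x2), design, n_perm=9, seed=0).table["pseudo_F"]
        assert np.allclose(f1.dropna(), f2.dropna(), atol=1e-9)

    def test_p_values_bounded_and_reproducible(self):
        design = balanced_design(n_rep=2)
        rng = np.random.default_rng(7)
        d = distance_matrix(rng.normal(size=(len(design), 3)))
        r1 = permanova(d, design, n_perm=99, seed=11)
        r2 = permanova(d, design, n_perm=99, seed=11)
        p = r1.table["p_perm"].dropna()
        assert np.all((p >= 1 / 100) & (p <= 1.0))
        assert r1.table["p_perm"].equals(r2.table["p_perm"])

    def test_identical_rows_reported_degenerate(self):
        x = np.ones((12, 3))
        res = permanova(distance_matrix(x), ["a"] * 6 + ["b"] * 6,
                        n_perm=9, seed=0)
        assert res.degenerate
        assert res.table.loc["Total", "SS"] == 0.0
        assert np.isnan(res.table.loc["factor", "p_perm"])

    def test_unbalanced_design_rejected(self):
        x = np.random.default_rng(8).normal(size=(5, 2))
        with pytest.raises(ValueError, match="unbalanced"):
            permanova(distance_matrix(x), ["a", "a", "a", "b", "b"],
                      n_perm=9, seed=0)


class TestPairwise:
    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_number_of_comparisons(self, k):
        rng = np.random.default_rng(k)
        x = rng.normal(size=(3 * k, 2))
        g = np.repeat([f"g{i}" for i in range(k)], 3)
        table = pairwise_permanova(distance_matrix(x), g, n_perm=19, seed=0)
        assert len(table) == k * (k - 1) // 2

    def test_pseudo_t_is_sqrt_f(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(12, 2))
        g = np.repeat(["a", "b", "c"], 4)
        table = pairwise_permanova(distance_matrix(x), g, n_perm=19, seed=0)
        assert np.allclose(table["pseudo_t"], np.sqrt(table["pseudo_F"]))

    def test_small_group_skipped_with_warning(self):
        x = np.random.default_rng(10).normal(size=(5, 2))
        g = ["a", "a", "b", "b", "c"]
        with pytest.warns(UserWarning, match="skipping"):
            table = pairwise_permanova(distance_matrix(x), g, n_perm=9, seed=0)
        assert len(table) == 1  # only (a, b) testable


class TestPermdisp:
    def test_translation_leaves_dispersion_non_significant(self):
        """Rigidly separating two equally dispersed groups must not create
        a dispersion effect (p > 0.05 in >= 95% of seeded repeats)."""
        ok = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(15, 3))
            b = rng.normal(size=(15, 3)) + 25.0
            d = distance_matrix(np.vstack([a, b]))
            res = permdisp(d, ["a"] * 15 + ["b"] * 15, n_perm=99, seed=seed)
            ok += res.p_perm > 0.05
        assert ok >= 0.95 * reps

    def test_detects_threefold_sd_difference(self):
        """sd ratio 3 with n = 20 per group: significant at 0.05 in >= 80%
        of seeded repeats."""
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(10_000 + seed)
            a = rng.normal(size=(20, 3))
            b = 3.0 * rng.normal(size=(20, 3))
            d = distance_matrix(np.vstack([a, b]))
            res = permdisp(d, ["a"] * 20 + ["b"] * 20, n_perm=99, seed=seed)
            hits += res.p_perm < 0.05
        assert hits >= 0.80 * reps

    def test_identical_points_have_zero_centroid_distances(self):
        x = np.vstack([np.tile([1.0, 2.0], (4, 1)), np.tile([5.0, 5.0], (4, 1))])
        res = permdisp(distance_matrix(x), ["a"] * 4 + ["b"] * 4,
                       n_perm=9, seed=0)
        assert np.allclose(res.distances, 0.0, atol=1e-9)

    def test_matches_scikit_bio_centroid_statistic(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(size=(10, 3)), 2 * rng.normal(size=(10, 3))])
        g = ["a"] * 10 + ["b"] * 10
        d = distance_matrix(x)
        ours = permdisp(d, g, n_perm=9, seed=0).f_statistic
        theirs = skbio_stats.permdisp(
            skbio_stats.DistanceMatrix(d.values), g,
            permutations=9, test="centroid",
        )["test statistic"]
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_single_group_rejected(self):
        x = np.random.default_rng(12).normal(size=(6, 2))
        with pytest.raises(ValueError):
            permdisp(distance_matrix(x), ["a"] * 6, n_perm=9, seed=0)


class TestCap:
    def test_separable_clusters_allocate_perfectly(self):
        rng = np.random.default_rng(13)
        centres = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0]], dtype=float)
        x = np.vstack([rng.normal(size=(10, 3)) * 0.5 + c for c in centres])
        g = np.repeat(["a", "b", "c"], 10)
        res = cap(distance_matrix(x), g)
        assert res.allocation_success == 100.0
        assert np.all((res.canonical_correlations >= 0)
                      & (res.canonical_correlations <= 1))

    def test_permuted_labels_allocate_near_chance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(30, 4))
        successes = []
        for seed in range(100):
            g = np.random.default_rng(seed).permutation(
                np.repeat(["a", "b", "c"], 10))
            res = cap(distance_matrix(x), g, m_axes=3)
            successes.append(res.allocation_success)
        # chance is 100/3; allow sampling noise around it
        assert abs(np.mean(successes) - 100 / 3) < 10.0

    def test_m_exceeding_axes_rejected(self):
        x = np.random.default_rng(15).normal(size=(8, 2))
        with pytest.raises(ValueError):
            cap(distance_matrix(x), ["a"] * 4 + ["b"] * 4, m_axes=50)


class TestNmds:
    def test_perfect_2d_embedding_has_near_zero_stress(self):
        rng = np.random.default_rng(16)
        pts = rng.normal(size=(20, 2))
        res = nmds(distance_matrix(pts), k_dims=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_stress_non_increasing_in_dimensions(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(25, 5))
        d = distance_matrix(pts)
        s2 = nmds(d, k_dims=2, n_restarts=8, seed=1).stress
        s3 = nmds(d, k_dims=3, n_restarts=8, seed=1).stress
        assert s3 <= s2 + 1e-6

    def test_excessive_dimensions_rejected(self):
        x = np.random.default_rng(18).normal(size=(6, 2))
        with pytest.raises(ValueError):
            nmds(distance_matrix(x), k_dims=5)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(19)
        d = distance_matrix(rng.normal(size=(15, 4)))
        a = nmds(d, k_dims=2, n_restarts=4, seed=3)
        b = nmds(d, k_dims=2, n_restarts=4, seed=3)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates, b.coordinates)


class TestEffectSizes:
    def test_identical_groups_have_zero_effect(self):
        x = np.tile([1.0, 2.0], (6, 1))
        d = distance_matrix(x)
        assert effect_size(d, ["a"] * 3 + ["b"] * 3, "a", "b") == 0.0

    def test_singleton_pythagorean_distance(self):
        d = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert effect_size(d, ["a", "b"], "a", "b") == pytest.approx(5.0)

    def test_matches_nested_loop_recomputation(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=(14, 3))
        g = np.array(["a"] * 6 + ["b"] * 8)
        d = distance_matrix(x)
        got = effect_size(d, g, "a", "b")
        total = 0.0
        count = 0
        for i in range(6):
            for j in range(6, 14):
                total += np.sqrt(((x[i] - x[j]) ** 2).sum())
                count += 1
        assert got == pytest.approx(total / count, abs=1e-12)

    def test_empty_group_rejected(self):
        d = distance_matrix(np.eye(3))
        with pytest.raises(ValueError):
            effect_size(d, ["a", "a", "a"], "a", "b")

    @pytest.mark.parametrize(
        "ea,eb,eab,expected",
        [
            (3.0, 4.0, 7.0, "additive"),
            (3.0, 4.0, 5.0, "antagonistic"),
            (3.0, 4.0, 9.0, "synergistic"),
        ],
    )
    def test_interaction_classification(self, ea, eb, eab, expected):
        assert classify_interaction(ea, eb, eab, tolerance=0.1) == expected

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_interaction(1.0, 1.0, 2.0, tolerance=-0.1)


class TestAxisCorrelations:
    def test_perfectly_aligned_variable_has_unit_spearman(self):
        coords = np.linspace(0, 1, 20).reshape(-1, 1)
        df = pd.DataFrame({"up": np.arange(20.0), "down": -np.arange(20.0)})
        out = axis_correlations(df, coords)
        assert out.loc["up", "axis_1"] == pytest.approx(1.0)
        assert out.loc["down", "axis_1"] == pytest.approx(-1.0)

    def test_threshold_drops_weak_vectors(self):
        rng = np.random.default_rng(21)
        coords = rng.normal(size=(50, 2))
        df = pd.DataFrame({
            "strong": coords[:, 0] + 0.1 * rng.normal(size=50),
            "noise": rng.normal(size=50),
        })
        out = axis_correlations(df, coords, threshold=0.2)
        assert "strong" in out.index
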