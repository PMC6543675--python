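"""Secretion calling: z-scoring, profile matching, ANOVA, clustering, overlap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secep.secretome import (
    anova_validate,
    call_subtype_specific,
    cell_line_means,
    handle_missing,
    make_reference_profiles,
    overlap_report,
    profile_match,
    ward_cluster_order,
    zscore_rows,
)

from conftest import line_pattern, make_lfq


class TestZscoreRows:
    def test_population_sd_convention(self):
        m = make_lfq(np.tile([1.0, 2.0, 3.0], (1, 10)))
        z = zscore_rows(m)
        row = z.values.iloc[0].to_numpy()[:3]
        np.testing.assert_allclose(row, [-1.224744871, 0.0, 1.224744871], atol=1e-8)

    def test_constant_row_dropped(self):
        m = make_lfq(np.vstack([np.full(30, 5.0), np.arange(30.0)]))
        z = zscore_rows(m)
        assert list(z.values.index) == ["prot1"]

    def test_row_mean_zero_sd_one(self, rng):
        m = make_lfq(rng.normal(25, 2, (20, 30)))
        z = zscore_rows(m)
        np.testing.assert_allclose(z.values.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_idempotent(self, rng):
        m = make_lfq(rng.normal(25, 2, (10, 30)))
        z1 = zscore_rows(m)
        z2 = zscore_rows(z1)
        np.testing.assert_allclose(z1.values.to_numpy(), z2.values.to_numpy(), atol=1e-10)

    def test_missing_entries_stay_missing(self, rng):
        vals = rng.normal(25, 2, (5, 30))
        vals[0, :4] = np.nan
        z = zscore_rows(make_lfq(vals))
        assert z.values.iloc[0, :4].isna().all()


class TestHandleMissing:
    def test_fully_missing_protein_removed(self, rng):
        vals = rng.normal(25, 2, (3, 30))
        vals[1] = np.nan
        out = handle_missing(make_lfq(vals))
        assert list(out.values.index) == ["prot0", "prot2"]

    def test_fully_observed_unchanged(self, rng):
        vals = rng.normal(25, 2, (3, 30))
        out = handle_missing(make_lfq(vals), impute=False)
        np.testing.assert_array_equal(out.values.to_numpy(), vals)

    def test_kept_if_one_cell_line_quantified(self, rng):
        vals = np.full((1, 30), np.nan)
        vals[0, :6] = rng.normal(25, 1, 6)  # observed only in BAS1
        out = handle_missing(make_lfq(vals), min_valid_per_group=3)
        assert len(out.values) == 1

    def test_imputation_deterministic_under_seed(self, rng):
        vals = rng.normal(25, 2, (10, 30))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        m = make_lfq(vals)
        a = handle_missing(m, impute=True, seed=7)
        b = handle_missing(m, impute=True, seed=7)
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())
        c = handle_missing(m, impute=True, seed=8)
        assert not np.array_equal(a.values.to_numpy(), c.values.to_numpy())

    def test_imputed_values_downshifted(self, rng):
        vals = rng.normal(25, 2, (50, 30))
        miss = rng.random(vals.shape) < 0.2
        vals[miss] = np.nan
        out = handle_missing(make_lfq(vals), impute=True, seed=1)
        imputed = out.values.to_numpy()[miss]
        observed = vals[~miss]
        assert imputed.mean() < observed.mean() - 1.0

    def test_empty_after_filter_errors(self):
        vals = np.full((2, 30), np.nan)
        with pytest.raises(ValueError, match="no quantifiable"):
            handle_missing(make_lfq(vals))


class TestProfileMatch:
    def _mean_z(self, rows):
        return pd.DataFrame(rows, columns=["BAS1", "BAS2", "LUM1", "LUM2", "CTRL"])

    def test_exact_profile_perfect_correlation(self):
        m = make_lfq(np.zeros((1, 30)))
        profiles = make_reference_profiles(m, include_single_line=False)
        mz = self._mean_z([[1.0, 1.0, 0.0, 0.0, 0.0]])
        res = profile_match(mz, profiles)
        assert res.iloc[0]["profile"] == "basal-up"
        assert res.iloc[0]["pattern_r"] == pytest.approx(1.0)

    def test_negated_profile_matches_down(self):
        m = make_lfq(np.zeros((1, 30)))
        profiles = make_reference_profiles(m, include_single_line=False)
        mz = self._mean_z([[-1.0, -1.0, 0.0, 0.0, 0.0]])
        res = profile_match(mz, profiles)
        assert res.iloc[0]["profile"] == "basal-down"
        assert res.iloc[0]["pattern_r"] == pytest.approx(1.0)

    def test_orthogonal_vector_unmatched(self):
        m = make_lfq(np.zeros((1, 30)))
        profiles = make_reference_profiles(m, include_single_line=False)
        # orthogonal to every centered profile by direct Pearson computation
        mz = self._mean_z([[1.0, -1.0, 1.0, -1.0, 0.0]])
        res = profile_match(mz, profiles, r_threshold=0.8)
        assert res.iloc[0]["profile"] == "unmatched"

    def test_zero_variance_unmatched(self):
        m = make_lfq(np.zeros((1, 30)))
        profiles = make_reference_profiles(m)
        res = profile_match(self._mean_z([[0.3, 0.3, 0.3, 0.3, 0.3]]), profiles)
        assert res.iloc[0]["profile"] == "unmatched"

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_invariance_to_affine_reference_transforms(self, shift, scale):
        m = make_lfq(np.zeros((1, 30)))
        profiles = make_reference_profiles(m, include_single_line=False)
        mz = self._mean_z([[0.9, 1.1, -0.5, -0.4, -0.6]])
        base = profile_match(mz, profiles)
        res = profile_match(mz, profiles * scale + shift)
        assert res.iloc[0]["profile"] == base.iloc[0]["profile"]
        assert res.iloc[0]["pattern_r"] == pytest.approx(base.iloc[0]["pattern_r"], abs=1e-9)


class TestAnova:
    def test_identical_group_means_f_near_zero(self):
        row = line_pattern({}, 0.0)
        row[::2] += 0.5  # same within-line spread, identical means
        res = anova_validate(make_lfq(row[None, :]), average_tech=False)
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-20)
        assert res["anova_p"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_have_larger_f(self, rng):
        flat = line_pattern({}, 0.3, rng)
        split = line_pattern({"BAS1": 4.0, "BAS2": 8.0}, 0.3, rng)
        res = anova_validate(make_lfq(np.vstack([flat, split])))
        assert res["F"].iloc[1] > res["F"].iloc[0]

    def test_matches_hand_computed_f(self):
        # 3 groups of 2: {1,2},{4,6},{9,11} -> SSB/SSW hand computation
        groups = [np.array([1.0, 2.0]), np.array([4.0, 6.0]), np.array([9.0, 11.0])]
        grand = np.mean(np.concatenate(groups))
        ssb = sum(2 * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ssb / 2) / (ssw / 3)
        vals = np.full((1, 30), np.nan)
        vals[0, 0:2] = groups[0]   # BAS1 bio reps 1-2 (tech averaged trivially)
        vals[0, 6:8] = groups[1]   # BAS2
        vals[0, 12:14] = groups[2]  # LUM1
        res = anova_validate(make_lfq(vals), average_tech=False)
        assert res["F"].iloc[0] == pytest.approx(f_hand, rel=1e-12)

    def test_insufficient_groups_p_missing(self, rng):
        vals = np.full((1, 30), np.nan)
        vals[0, :6] = rng.normal(25, 1, 6)  # only one cell line observed
        res = anova_validate(make_lfq(vals))
        assert np.isnan(res["anova_p"].iloc[0])

    def test_constant_everywhere_p_missing(self):
        res = anova_validate(make_lfq(np.full((1, 30), 7.0)))
        assert np.isnan(res["anova_p"].iloc[0])


class TestCallSubtypeSpecific:
    def _call(self, vals, **kwargs):
        rng = np.random.default_rng(0)
        m = make_lfq(np.vstack([vals, [line_pattern({}, 0.3, rng) for _ in range(3)]]))
        z = zscore_rows(m)
        mz = cell_line_means(z)
        profiles = make_reference_profiles(z)
        matches = profile_match(mz, profiles)
        anova = anova_validate(m)
        return call_subtype_specific(m, mz, matches, anova, **kwargs)

    def test_basal_up_both_lines(self, rng):
        vals = line_pattern({"BAS1": 2.0, "BAS2": 2.0}, 0.2, rng)
        calls = self._call(vals[None, :])
        row = calls[calls.protein_id == "prot0"]
        assert len(row) == 1
        assert row.iloc[0]["subtype"] == "basal"
        assert row.iloc[0]["direction"] == "increased"
        assert row.iloc[0]["support"] == "both_lines"

    def test_anova_threshold_blocks_call(self, rng):
        vals = line_pattern({"BAS1": 2.0, "BAS2": 2.0}, 0.2, rng)
        calls = self._call(vals[None, :], anova_p_threshold=1e-30)
        assert "prot0" not in set(calls.protein_id)

    def test_single_luminal_line_one_line_support(self, rng):
        vals = line_pattern({"LUM1": 2.5}, 0.2, rng)
        calls = self._call(vals[None, :])
        row = calls[calls.protein_id == "prot0"]
        assert len(row) == 1
        assert row.iloc[0]["subtype"] == "luminal"
        assert row.iloc[0]["support"] == "one_line"
        assert row.iloc[0]["supporting_cell_lines"] == "LUM1"

    def test_decreased_direction(self, rng):
        vals = line_pattern({"BAS1": -2.0, "BAS2": -2.0}, 0.2, rng)
        calls = self._call(vals[None, :])
        row = calls[calls.protein_id == "prot0"]
        assert row.iloc[0]["direction"] == "decreased"

    def test_noise_proteins_not_called(self):
        calls = self._call(np.empty((0, 30)))
        assert len(calls) == 0


class TestWardClusterOrder:
    def test_identical_rows_merge_first_at_zero_height(self):
        X = pd.DataFrame([[1.0, 2.0], [5.0, 1.0], [1.0, 2.0]], index=["a", "b", "c"])
        order, Z = ward_cluster_order(X)
        assert Z[0, 2] == pytest.approx(0.0)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 2}

    def test_collinear_points_first_merge_nearest(self):
        # brute force over the 3 possible first merges: {0,1} is cheapest
        X = pd.DataFrame([[0.0], [1.0], [10.0]], index=["p0", "p1", "p10"])
        _, Z = ward_cluster_order(X)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_row_permutation_preserves_topology(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (12, 6)),
                         index=[f"r{i}" for i in range(12)])
        order1, _ = ward_cluster_order(X)
        perm = rng.permutation(12)
        order2, _ = ward_cluster_order(X.iloc[perm])
        # same partition into the two top-level clusters regardless of input order
        def top_split(df):
            o, Z = ward_cluster_order(df)
            from scipy.cluster.hierarchy import fcluster
            labels = fcluster(Z, 2, criterion="maxclust")
            groups = {}
            for name, lab in zip(df.index, labels):
                groups.setdefault(lab, set()).add(name)
            return frozenset(frozenset(g) for g in groups.values())
        assert top_split(X) == top_split(X.iloc[perm])

    def test_missing_values_rejected(self):
        X = pd.DataFrame([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="impute"):
            ward_cluster_order(X)

    def test_column_axis(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (4, 6)), columns=[f"c{i}" for i in range(6)])
        order, _ = ward_cluster_order(X, axis="columns")
        assert sorted(order) == sorted(X.columns)


class TestOverlapReport:
    def test_identical_sets_fraction_one(self):
        rep = overlap_report({"A", "B"}, {"ref": {"A", "B"}})
        assert rep.iloc[0]["fraction_of_identified"] == 1.0

    def test_disjoint_sets_zero(self):
        rep = overlap_report({"A"}, {"ref": {"B"}})
        assert rep.iloc[0]["n_overlap"] == 0

    def test_partial_overlap_fraction(self):
        rep = overlap_report({"A", "B", "C"}, {"ref": {"B", "C", "D"}})
        assert rep.iloc[0]["n_overlap"] == 2
        assert rep.iloc[0]["fraction_of_identified"] == pytest.approx(2 / 3)

    def test_empty_reference_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            rep = overlap_report({"A"}, {"ref": set()})
        assert rep.iloc[0]["n_overlap"] == 0


class TestPlantedRecovery:
    def test_planted_basal_up_recovered(self, planted_lfq):
        """>=90% of planted basal-up proteins called, <=5% of noise proteins."""
        _, matrix, truth = planted_lfq
        filtered = handle_missing(matrix)
        z = zscore_rows(filtered)
        mz = cell_line_means(z)
        matches = profile_match(mz, make_reference_profiles(z), r_threshold=0.8)
        anova = anova_validate(filtered)
        calls = call_subtype_specific(z, mz, matches, anova, anova_p_threshold=0.05)
        planted = set(truth.protein_id[truth.planted])
        called = set(calls.protein_id)
        basal_up = set(
            calls.protein_id[(calls.subtype == "basal") & (calls.direction == "increased")]
        )
        assert len(planted & basal_up) / len(planted) >= 0.90
        noise = set(truth.protein_id) - planted
        assert len(called & noise) / len(noise) <= 0.05

    def test_planted_block_contiguous_in_leaf_order(self, planted_lfq):
        """Ward/euclidean leaf order groups >=90% of planted proteins in one block."""
        _, matrix, truth = planted_lfq
        z = zscore_rows(handle_missing(matrix, impute=True, seed=0))
        order, Z = ward_cluster_order(z.values)
        planted = set(truth.protein_id[truth.planted])
        # the top-level branch is a contiguous block in leaf order; >=90% of
        # planted proteins must sit together in one branch
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(Z, 2, criterion="maxclust")
        lab = dict(zip(z.values.index, labels))
        counts = {}
        for p in planted:
            counts[lab[p]] = counts.get(lab[p], 0) + 1
        assert max(counts.values()) >= 0.9 * len(planted)
        # and that branch really is contiguous in the exported leaf order
        top = max(counts, key=counts.get)
        pos = [i for i, pid in enumerate(order) if lab[pid] == top]
        assert pos == list(range(min(pos), max(pos) + 1))
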