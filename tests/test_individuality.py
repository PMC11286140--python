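"""Individuality chain: KMO, PCA, DFA and the nested permuted DFA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from zebrarep.individuality import (dfa, kmo, nested_pdfa, pca_reduce,
                                    permute_within_levels)
from zebrarep.synth import SynthConfig, draw_call_parameter_table

NULL_SD = {k: 0.0 for k in ("f0_hz", "am_rate_hz", "tilt_db_per_oct")}


def kmo_regression_oracle(X):
    """Independent oracle: each partial correlation by regressing out all
    other variables and correlating the residuals."""
    Xc = np.asarray(X, dtype=float)
    Xc = (Xc - Xc.mean(0)) / Xc.std(0, ddof=1)
    d = Xc.shape[1]
    r = np.corrcoef(Xc, rowvar=False)
    q = np.zeros((d, d))
    for j, k in itertools.combinations(range(d), 2):
        others = [m for m in range(d) if m not in (j, k)]
        A = np.column_stack([Xc[:, others], np.ones(len(Xc))])
        rj = Xc[:, j] - A @ np.linalg.lstsq(A, Xc[:, j], rcond=None)[0]
        rk = Xc[:, k] - A @ np.linalg.lstsq(A, Xc[:, k], rcond=None)[0]
        q[j, k] = q[k, j] = np.corrcoef(rj, rk)[0, 1]
    r2 = r**2 - np.eye(d)
    q2 = q**2
    per_var = r2.sum(1) / (r2.sum(1) + q2.sum(1))
    overall = r2.sum() / (r2.sum() + q2.sum())
    return per_var, overall


class TestKMO:
    def test_matches_regression_oracle_on_random_matrices(self, rng):
        for _ in range(5):
            X = rng.normal(size=(200, 5)) @ rng.normal(size=(5, 5))
            res = kmo(X)
            per_var, overall = kmo_regression_oracle(X)
            assert np.max(np.abs(res.per_variable_msa.values - per_var)) < 1e-6
            assert abs(res.overall_msa - overall) < 1e-6

    def test_duplicated_columns_raise_singularity(self, rng):
        x = rng.normal(size=(100, 1))
        X = pd.DataFrame(np.hstack([x, x, rng.normal(size=(100, 2))]),
                         columns=list("abcd"))
        with pytest.raises(ValueError, match="singular"):
            kmo(X)

    def test_shared_factor_block_is_retained(self, rng):
        # variables driven by one common factor: high correlations, weak
        # partials -> MSA above the 0.5 screen
        f = rng.normal(size=(300, 1))
        X = f + 0.5 * rng.normal(size=(300, 6))
        res = kmo(X)
        assert (res.per_variable_msa >= 0.5).all()
        assert res.retained == list(pd.DataFrame(X).columns)

    def test_more_variables_than_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            kmo(rng.normal(size=(4, 6)))


class TestPCA:
    def test_eigenvalues_sum_to_variable_count(self, rng):
        X = rng.normal(size=(150, 6)) @ rng.normal(size=(6, 6))
        model = pca_reduce(X)
        assert model.eigenvalues.sum() == pytest.approx(6.0)
        assert np.all(np.diff(model.eigenvalues) <= 1e-9)

    def test_two_latent_factors_retained(self, rng):
        F = rng.normal(size=(400, 2))
        load = rng.normal(size=(2, 8)) * 2
        X = F @ load + 0.3 * rng.normal(size=(400, 8))
        model = pca_reduce(X)
        assert len(model.retained_components) == 2

    def test_reconstruction_with_all_components(self, rng):
        X = rng.normal(size=(100, 4))
        model = pca_reduce(X)
        Z = (X - model.mean) / model.scale
        full_scores = Z @ model.loadings.values
        assert np.allclose(full_scores @ model.loadings.values.T, Z, atol=1e-9)

    def test_loading_sign_convention(self, rng):
        X = rng.normal(size=(100, 4))
        L = pca_reduce(X).loadings.values
        for j in range(L.shape[1]):
            assert L[np.argmax(np.abs(L[:, j])), j] > 0

    def test_single_feature_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_reduce(rng.normal(size=(50, 1)))


class TestDFA:
    def test_separation_along_pc1_correlates_df1(self, rng):
        n = 40
        pc1 = np.concatenate([rng.normal(-4, 1, n), rng.normal(4, 1, n)])
        pc2 = rng.normal(0, 1, 2 * n)
        scores = np.column_stack([pc1, pc2])
        ind = np.repeat(["A", "B"], n)
        model = dfa(scores, ind)
        assert abs(model.df_pc_correlation.loc["DF1", "PC1"]) > 0.95
        assert model.strong_correlations.loc["DF1", "PC1"]

    def test_three_groups_two_dfs_variance_sums_to_100(self, rng):
        scores = rng.normal(size=(90, 2)) + np.repeat(
            [[0, 0], [5, 0], [0, 5]], 30, axis=0)
        model = dfa(scores, np.repeat(["A", "B", "C"], 30))
        assert model.coefficients.shape[1] == 2
        assert model.percent_variance.sum() == pytest.approx(100.0)

    def test_single_call_group_rejected(self, rng):
        scores = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="single"):
            dfa(scores, np.array(["A", "A", "B", "B", "C"]))


class TestPermutation:
    def test_restriction_labels_preserved(self, rng):
        ind = np.repeat([f"i{k}" for k in range(6)], 8)
        level_of = {f"i{k}": ("F" if k < 3 else "M") for k in range(6)}
        restriction = np.array([level_of[i] for i in ind])
        for _ in range(20):
            perm = permute_within_levels(ind, restriction, rng)
            # every permuted call keeps its original restriction label
            assert all(level_of[p] == r for p, r in zip(perm, restriction))
            # per-individual call counts preserved
            assert (pd.Series(perm).value_counts().sort_index()
                    == pd.Series(ind).value_counts().sort_index()).all()


class TestNestedPDFA:
    def _signal_scores(self, rng, n_ind=8, calls=10, sd=6.0):
        ind = np.repeat([f"i{k}" for k in range(n_ind)], calls)
        sex = np.repeat(["F", "M"] * (n_ind // 2), calls)
        scores = rng.normal(size=(n_ind * calls, 3)) + np.repeat(
            rng.normal(0, sd, size=(n_ind, 3)), calls, axis=0)
        return scores, ind, sex

    def test_strong_signal_hits_p_floor(self, rng):
        scores, ind, sex = self._signal_scores(rng)
        res = nested_pdfa(scores, ind, sex, n_permutations=200,
                          n_selections=10, seed=0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.percent_correct > res.chance_percent

    def test_null_signal_not_significant(self, rng):
        scores, ind, sex = self._signal_scores(rng, sd=0.0)
        res = nested_pdfa(scores, ind, sex, n_permutations=200,
                          n_selections=10, seed=0)
        assert res.p_value > 0.05
        assert abs(res.percent_correct - res.chance_percent) < 10

    def test_perfectly_separable_toy_counts_all_withheld(self):
        # 2 individuals, 5 calls each, far apart: every selection classifies
        # every withheld call correctly, so the mean count is exact
        scores = np.concatenate([np.zeros((5, 2)), np.full((5, 2), 100.0)])
        scores += np.arange(10)[:, None] * 0.01  # break exact degeneracy
        ind = np.repeat(["a", "b"], 5)
        lev = np.repeat(["L"], 10)
        res = nested_pdfa(scores, ind, lev, n_permutations=10,
                          n_selections=7, seed=0)
        # derivation 3 of 5 per individual -> 2 withheld each, 4 total
        assert res.n_crossclassified == 4
        assert res.observed_correct == 4.0
        assert res.percent_correct == 100.0

    def test_relabeling_individuals_preserves_result(self, rng):
        scores, ind, sex = self._signal_scores(rng)
        res1 = nested_pdfa(scores, ind, sex, n_permutations=50,
                           n_selections=5, seed=9)
        # order-preserving relabeling: identical draws, identical result
        renamed = np.array([i.replace("i", "zebra_") for i in ind])
        res2 = nested_pdfa(scores, renamed, sex, n_permutations=50,
                           n_selections=5, seed=9)
        assert res1.observed_correct == res2.observed_correct
        assert res1.p_value == res2.p_value

    def test_individual_in_two_levels_rejected(self, rng):
        scores = rng.normal(size=(10, 2))
        ind = np.repeat(["a", "b"], 5)
        lev = np.array(["F"] * 3 + ["M"] * 7)
        with pytest.raises(ValueError, match="restriction levels"):
            nested_pdfa(scores, ind, lev, n_permutations=10, n_selections=2)

    def test_single_individual_level_warns(self, rng):
        scores, ind, _ = self._signal_scores(rng, n_ind=4)
        lev = np.array(["A"] * 10 + ["B"] * 30)  # level A has one individual
        with pytest.warns(UserWarning, match="single individual"):
            nested_pdfa(scores, ind, lev, n_permutations=10, n_selections=2)

    def test_power_increases_with_individual_sd(self):
        # median observed_correct non-decreasing over increasing signature
        # strength (parameter-model features, snort analysis)
        medians = []
        for factor in (0.0, 1.0, 3.0):
            obs = []
            for s in range(3):
                cfg = SynthConfig(
                    n_individuals_per_location=4, locations=("A", "B"),
                    calls_per_individual_per_type=8, type_set=("snort",),
                    individual_sd={"f0_hz": 0.0, "am_rate_hz": 4.0 * factor,
                                   "tilt_db_per_oct": 2.0 * factor},
                    seed=100 + s)
                tbl = draw_call_parameter_table(cfg)
                X = tbl[["am_rate_hz", "tilt_db_per_oct", "duration_s"]].values
                X = (X - X.mean(0)) / X.std(0)
                res = nested_pdfa(X, tbl.individual_id.values, tbl.sex.values,
                                  n_permutations=1, n_selections=20, seed=s)
                obs.append(res.observed_correct)
            medians.append(np.median(obs))
        assert medians[0] <= medians[1] <= medians[2]
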