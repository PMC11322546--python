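import itertools

import numpy as np
import pandas as pd
import pytest

from samquant.stats import (compact_letters, compare_genotypes,
                            compare_timepoints, fold_change,
                            normalize_by_reference, rank_sum_test)


def exact_rank_sum_p(x, y):
    """Enumeration oracle: exact two-sided rank-sum p by listing all
    assignments of the pooled ranks to the first group."""
    pooled = sorted(x) + sorted(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n1 = len(x)
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    mean_u = n1 * len(y) / 2
    us = []
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        us.append(sum(combo) - n1 * (n1 + 1) / 2)
    us = np.array(us)
    return float(np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12))


class TestRankSum:
    def test_extreme_separation_matches_enumeration_oracle(self):
        x, y = [1, 2, 3], [10, 11, 12]
        res = rank_sum_test(x, y)
        assert res.p_value == pytest.approx(exact_rank_sum_p(x, y))
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test

    @pytest.mark.parametrize("x,y", [
        ([1, 5, 9, 12], [2, 3, 4, 20]),
        ([0.5, 2.5, 7.0], [1.0, 6.0, 8.0, 11.0]),
    ])
    def test_agrees_with_enumeration_on_small_samples(self, x, y):
        assert rank_sum_test(x, y).p_value == pytest.approx(exact_rank_sum_p(x, y))

    def test_identical_samples_maximal_p(self):
        res = rank_sum_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=9), rng.normal(loc=0.8, size=9)
        p_raw = rank_sum_test(x, y).p_value
        p_exp = rank_sum_test(np.exp(x), np.exp(y)).p_value
        assert p_exp == pytest.approx(p_raw)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            rank_sum_test([], [1, 2])

    def test_null_type_one_error_rate(self):
        # two groups from one distribution; rejection rate near alpha
        rng = np.random.default_rng(42)
        rejections = sum(
            rank_sum_test(rng.normal(size=10), rng.normal(size=10)).p_value < 0.05
            for _ in range(2000)
        )
        assert 0.035 <= rejections / 2000 <= 0.065


class TestCompareGenotypes:
    def test_dataframe_wrapper(self):
        df = pd.DataFrame({
            "genotype": ["wt"] * 3 + ["mut"] * 3,
            "timepoint_d": [14] * 6,
            "height_um": [1, 2, 3, 10, 11, 12],
        })
        res = compare_genotypes(df, "height_um", 14, "wt", "mut")
        assert res.p_value == pytest.approx(0.1)
        assert res.n1 == res.n2 == 3

    def test_missing_group_rejected(self):
        df = pd.DataFrame({"genotype": ["wt"], "timepoint_d": [14],
                           "height_um": [1.0]})
        with pytest.raises(ValueError, match="empty group"):
            compare_genotypes(df, "height_um", 14, "wt", "mut")


class TestCompactLetters:
    def _pmat(self, groups, sig_pairs):
        m = pd.DataFrame(1.0, index=groups, columns=groups)
        for a, b in sig_pairs:
            m.loc[a, b] = m.loc[b, a] = 0.001
        return m

    def test_no_differences_single_letter(self):
        letters = compact_letters(["a", "b", "c"], self._pmat(["a", "b", "c"], []))
        assert len({letters[g] for g in "abc"}) == 1

    def test_one_outlier_gets_unique_letter(self):
        groups = ["t10", "t12", "t14"]
        letters = compact_letters(
            groups, self._pmat(groups, [("t10", "t14"), ("t12", "t14")]))
        assert set(letters["t14"]).isdisjoint(letters["t10"])
        assert set(letters["t14"]).isdisjoint(letters["t12"])
        assert set(letters["t10"]) & set(letters["t12"])

    def test_chain_structure(self):
        # a<->c differ; b overlaps both
        groups = ["a", "b", "c"]
        letters = compact_letters(groups, self._pmat(groups, [("a", "c")]))
        assert set(letters["a"]).isdisjoint(letters["c"])
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])


class TestCompareTimepoints:
    def _records(self, shifts, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for tp, shift in shifts.items():
            for v in rng.normal(loc=shift, scale=1.0, size=n):
                rows.append({"genotype": "g", "timepoint_d": tp, "height_um": v})
        return pd.DataFrame(rows)

    def test_identical_distributions_usually_share_one_letter(self):
        shared = 0
        for seed in range(20):
            df = self._records({10: 0.0, 12: 0.0, 14: 0.0}, seed=seed)
            disp = compare_timepoints(df, "height_um", "g")
            if len({disp.letters[g] for g in disp.groups}) == 1:
                shared += 1
        assert shared >= 18  # >= 90% of replicates

    def test_strongly_shifted_timepoint_gets_unique_letter(self):
        for seed in range(10):
            df = self._records({10: 0.0, 12: 0.0, 14: 10.0}, seed=seed)
            disp = compare_timepoints(df, "height_um", "g")
            assert set(disp.letters[14]).isdisjoint(disp.letters[10])
            assert set(disp.letters[14]).isdisjoint(disp.letters[12])

    def test_two_timepoints_agree_with_pairwise_test(self):
        df = self._records({10: 0.0, 14: 5.0}, seed=1)
        disp = compare_timepoints(df, "height_um", "g")
        share = bool(set(disp.letters[10]) & set(disp.letters[14]))
        assert share == (disp.p_matrix.loc[10, 14] >= 0.05)

    def test_letter_invariants_validated_on_output(self):
        df = self._records({10: 0.0, 12: 1.0, 14: 2.5, 16: 2.6}, seed=3)
        disp = compare_timepoints(df, "height_um", "g")
        disp.validate()  # raises on violation

    def test_insufficient_groups_rejected(self):
        df = self._records({10: 0.0})
        with pytest.raises(ValueError, match="at least 2 timepoints"):
            compare_timepoints(df, "height_um", "g")


class TestNormalize:
    def test_hand_computed_two_experiments(self):
        df = pd.DataFrame({
            "experiment_id": ["e1"] * 4 + ["e2"] * 4,
            "genotype": ["wt", "wt", "wt", "mut"] * 2,
            "height_um": [90, 100, 110, 75, 40, 50, 60, 25],
        })
        out = normalize_by_reference(df, "wt", "height_um")
        e1 = out[out["experiment_id"] == "e1"]
        e2 = out[out["experiment_id"] == "e2"]
        assert e1.loc[e1["genotype"] == "mut", "normalized"].iloc[0] == pytest.approx(0.75)
        assert e2.loc[e2["genotype"] == "mut", "normalized"].iloc[0] == pytest.approx(0.5)

    def test_reference_normalizes_to_unit_median(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "experiment_id": np.repeat(["e1", "e2", "e3"], 7),
            "genotype": "wt",
            "height_um": rng.uniform(30, 90, 21),
        })
        out = normalize_by_reference(df, "wt", "height_um")
        for _, grp in out.groupby("experiment_id"):
            assert grp["normalized"].median() == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        df = pd.DataFrame({"experiment_id": ["e1"], "genotype": ["mut"],
                           "height_um": [50.0]})
        with pytest.raises(ValueError, match="lacks reference"):
            normalize_by_reference(df, "wt", "height_um")


class TestFoldChange:
    def test_median_ratio(self):
        df = pd.DataFrame({
            "genotype": "g", "timepoint_d": [10] * 3 + [14] * 3,
            "height_um": [58, 60, 62, 118, 120, 122],
        })
        assert fold_change(df, "height_um", 10, 14) == pytest.approx(2.0)
        assert fold_change(df, "height_um", 10, 10) == pytest.approx(1.0)

    def test_zero_baseline_rejected(self):
        df = pd.DataFrame({"genotype": "g", "timepoint_d": [10, 14],
                           "height_um": [0.0, 5.0]})
        with pytest.raises(ValueError, match="zero median"):
            fold_change(df, "height_um", 10, 14)
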