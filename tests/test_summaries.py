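from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from qsiplab.summaries import (
    anosim,
    bray_curtis,
    chao1,
    compare_richness,
    fraction_labeled,
    group_eaf_table,
    h2_effect,
    percent_change,
    treatment_summaries,
)
from qsiplab.tables import ValidationError


class TestFractionLabeled:
    @pytest.mark.parametrize(
        "labeled,unlabeled,pct",
        [
            (81, 58, 58.3),   # bicarbonate
            (26, 61, 29.9),   # bicarbonate + H2
            (73, 79, 48.0),   # acetate
            (81, 17, 82.7),   # acetate + H2
            (59, 6, 90.8),    # formate
            (37, 129, 22.3),  # formate + H2
            (107, 203, 34.5),  # all treatments pooled
            (0, 10, 0.0),
        ],
    )
    def test_labeled_percentages(self, labeled, unlabeled, pct):
        assert round(fraction_labeled(labeled, unlabeled), 1) == pct

    def test_no_otus_errors(self):
        with pytest.raises(ValidationError):
            fraction_labeled(0, 0)


class TestPercentChange:
    def test_bicarbonate_increase(self):
        assert round(percent_change(0.13, 0.32)) == 146

    def test_no_change(self):
        assert percent_change(0.25, 0.25) == 0.0

    def test_decrease(self):
        assert round(percent_change(0.32, 0.14)) == -56

    def test_zero_baseline_errors(self):
        with pytest.raises(ValidationError):
            percent_change(0.0, 0.3)


def results_frame(rows):
    return pd.DataFrame(rows, columns=["otu_id", "treatment", "eaf", "labeled", "evaluable"])


class TestTreatmentSummaries:
    def test_percentages_consistent_with_counts(self):
        rng = np.random.default_rng(0)
        rows = [(f"o{i}", "acetate", rng.normal(0.2, 0.1), bool(rng.random() < 0.4), True)
                for i in range(50)]
        res = results_frame(rows)
        summ = treatment_summaries(res).iloc[0]
        assert summ["percent_labeled"] == round(
            100 * summ["n_labeled"] / (summ["n_labeled"] + summ["n_unlabeled"]), 1)
        assert summ["n_labeled"] == sum(r[3] for r in rows)

    def test_h2_effect_means_and_change(self):
        rows = ([(f"a{i}", "acetate", 0.27, True, True) for i in range(10)]
                + [(f"b{i}", "acetate+H2", 0.42, True, True) for i in range(10)])
        eff = h2_effect(results_frame(rows), "acetate", n_boot=100, seed=0)
        assert eff.mean_eaf_noh2 == pytest.approx(0.27)
        assert eff.mean_eaf_h2 == pytest.approx(0.42)
        assert round(eff.percent_change) == 56


class TestGroupEAF:
    def test_single_and_mean_groups(self):
        res = results_frame([
            ("o1", "acetate", 0.4, True, True),
            ("o2", "acetate", 0.2, False, True),
            ("o3", "acetate", 0.4, True, True),
        ])
        tax = {"o1": "d__B;p__X", "o2": "d__B;p__X", "o3": "d__B;p__Y"}
        out = group_eaf_table(res, tax, rank="phylum").set_index("group")
        assert out.loc["X", "mean_eaf"] == pytest.approx(0.3)
        assert out.loc["Y", "mean_eaf"] == pytest.approx(0.4)
        assert bool(out.loc["X", "any_labeled"]) is True

    def test_unknown_rank_errors(self):
        res = results_frame([("o1", "acetate", 0.4, True, True)])
        with pytest.raises(ValidationError):
            group_eaf_table(res, {}, rank="kingdomz")

    def test_missing_taxonomy_grouped_unassigned(self):
        res = results_frame([("o1", "acetate", 0.4, True, True)])
        out = group_eaf_table(res, {}, rank="genus")
        assert out["group"].tolist() == ["unassigned"]


class TestChao1:
    def test_no_singletons_equals_observed(self):
        assert chao1([5, 10, 3]) == 3

    def test_standard_formula(self):
        counts = [1, 1, 2] + [5] * 7  # S_obs=10, f1=2, f2=1
        assert chao1(counts) == 12

    def test_bias_corrected_branch_when_no_doubletons(self):
        counts = [1, 1, 1, 5, 9]  # S_obs=5, f1=3, f2=0
        assert chao1(counts) == 8

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            c = rng.integers(0, 6, 20)
            if (c > 0).sum() == 0:
                continue
            assert chao1(c) >= (c > 0).sum()

    def test_all_zero_errors(self):
        with pytest.raises(ValidationError):
            chao1([0, 0])

    def test_matches_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity.alpha import chao1 as sk_chao1

        rng = np.random.default_rng(2)
        for _ in range(20):
            c = rng.integers(0, 5, 30)
            if not c.any():
                continue
            f2 = (c == 2).sum()
            # the two conventions agree whenever doubletons are present
            if f2 > 0:
                assert chao1(c) == pytest.approx(sk_chao1(c, bias_corrected=False))
            else:
                assert chao1(c) == pytest.approx(sk_chao1(c, bias_corrected=True))


class TestCompareRichness:
    def test_identical_groups_t_zero(self):
        t, p = compare_richness([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_detects_large_shift(self):
        rng = np.random.default_rng(3)
        hits = 0
        for _ in range(50):
            a = rng.normal(100, 2, 10)
            b = rng.normal(110, 2, 10)  # 5 sigma shift
            _, p = compare_richness(a, b)
            hits += p < 0.001
        assert hits >= 49

    def test_insufficient_samples(self):
        with pytest.raises(ValidationError):
            compare_richness([1], [1, 2])


class TestAnosim:
    def block_matrix(self):
        # two groups of 3; all within < all between
        d = np.full((6, 6), 5.0)
        for i in range(3):
            for j in range(3):
                d[i, j] = d[i + 3, j + 3] = 1.0 + 0.1 * abs(i - j)
        np.fill_diagonal(d, 0.0)
        return d

    def test_perfect_separation_r_is_one(self):
        r, p = anosim(self.block_matrix(), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert 0 < p <= 1

    def test_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(0, 1, (6, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        labels = np.array(["a", "a", "a", "b", "b", "b"])

        from scipy.stats import rankdata
        iu = np.triu_indices(6, 1)
        ranks = rankdata(d[iu])

        def r_of(lab):
            within = lab[iu[0]] == lab[iu[1]]
            return (ranks[~within].mean() - ranks[within].mean()) / (6 * 5 / 4)

        r_obs, _ = anosim(d, labels, n_perm=999, seed=0)
        assert r_obs == pytest.approx(r_of(labels))
        exhaustive = [r_of(np.array(perm)) for perm in set(permutations(labels))]
        p_exact = np.mean([r >= r_obs - 1e-12 for r in exhaustive])
        r_mc, p_mc = anosim(d, labels, n_perm=999, seed=1)
        assert abs(p_mc - p_exact) < 0.1

    def test_null_r_near_zero_and_bounds(self):
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(30):
            pts = rng.normal(0, 1, (8, 2))
            d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            labels = rng.permutation(["a"] * 4 + ["b"] * 4)
            r, p = anosim(d, labels, n_perm=49, seed=0)
            assert -1 <= r <= 1 and 0 < p <= 1
            rs.append(r)
        assert abs(np.mean(rs)) < 0.15

    def test_matches_scikit_bio(self):
        pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        d = self.block_matrix()
        labels = ["a"] * 3 + ["b"] * 3
        r_ours, _ = anosim(d, labels, n_perm=99, seed=0)
        sk = sk_anosim(DistanceMatrix(d), grouping=labels, permutations=99)
        assert r_ours == pytest.approx(sk["test statistic"])

    def test_degenerate_grouping_errors(self):
        with pytest.raises(ValidationError):
            anosim(np.zeros((3, 3)), ["a", "a", "b"])


class TestBrayCurtis:
    def test_identical_samples_zero_distance(self):
        d = bray_curtis(np.array([[10, 20], [20, 40]]))  # same composition
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_distance_one(self):
        d = bray_curtis(np.array([[10, 0], [0, 7]]))
        assert d[0, 1] == pytest.approx(1.0)
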