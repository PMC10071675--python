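"""Feature-table categorization, bin assignment, concordance statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from comparthic.dynamics import A_TO_B, B_TO_A, STABLE
from comparthic.hic_io import GenomeBins
from comparthic.integration import (
    DECREASED,
    FEATURE_STABLE,
    INCREASED,
    assign_features_to_bins,
    association_fractions,
    categorize_features,
    concordance_score,
    gene_set_overlap_test,
    group_difference_test,
    rate_of_concordance,
)

RES = 40_000


def feat(fid, start, end, l2fc, p, padj=None):
    return {
        "id": fid, "chrom": "chrS", "start": start, "end": end,
        "l2fc": l2fc, "pvalue": p, "padj": p * 2 if padj is None else padj,
    }


def calls_frame(cats):
    return pd.DataFrame(
        {"category": cats, "delta": 0.0}, index=pd.Index(range(len(cats)), name="bin")
    )


class TestCategorizeFeatures:
    @pytest.mark.parametrize(
        "l2fc, p, expected",
        [
            (0.5, 0.01, INCREASED),
            (0.5, 0.2, FEATURE_STABLE),
            (-0.5, 0.01, DECREASED),
            (0.0, 0.0, FEATURE_STABLE),
            (0.32, 0.01, FEATURE_STABLE),  # cutoff is strict
        ],
    )
    def test_gene_thresholds(self, l2fc, p, expected):
        df = pd.DataFrame([feat("g1", 0, 100, l2fc, p)])
        out = categorize_features(df, 0.32, 0.05, "p")
        assert out["category"].iloc[0] == expected

    def test_fdr_field(self):
        df = pd.DataFrame([feat("g1", 0, 100, 2.0, 0.04, padj=0.2)])
        assert categorize_features(df, 1.0, 0.01, "fdr")["category"].iloc[0] == FEATURE_STABLE
        df2 = pd.DataFrame([feat("g2", 0, 100, 2.0, 1e-5, padj=1e-4)])
        assert categorize_features(df2, 1.0, 0.01, "fdr")["category"].iloc[0] == INCREASED

    def test_missing_significance_flagged_stable(self):
        df = pd.DataFrame([feat("g1", 0, 100, 5.0, np.nan)])
        out = categorize_features(df, 0.32, 0.05, "p")
        assert out["category"].iloc[0] == FEATURE_STABLE
        assert out["sig_missing"].iloc[0]


class TestAssignFeatures:
    bins = GenomeBins("chrS", RES, 4)

    def test_wholly_inside_one_bin(self):
        calls = calls_frame([STABLE, B_TO_A, STABLE, STABLE])
        df = pd.DataFrame([feat("g1", RES + 100, RES + 500, 1.0, 0.01)])
        df["category"] = INCREASED
        joined = assign_features_to_bins(df, calls, self.bins)
        assert joined["compartment_category"].iloc[0] == B_TO_A
        assert joined["bin"].iloc[0] == 1

    def test_largest_overlap_wins(self):
        calls = calls_frame([STABLE, B_TO_A, STABLE, STABLE])
        # 30% in stable bin 0, 70% in B_to_A bin 1
        start = RES - 3000
        end = RES + 7000
        df = pd.DataFrame([feat("g1", start, end, 1.0, 0.01)])
        df["category"] = INCREASED
        joined = assign_features_to_bins(df, calls, self.bins)
        assert joined["compartment_category"].iloc[0] == B_TO_A

    def test_tie_breaks_to_smaller_bin(self):
        calls = calls_frame([A_TO_B, B_TO_A, STABLE, STABLE])
        df = pd.DataFrame([feat("g1", RES - 500, RES + 500, 1.0, 0.01)])
        df["category"] = INCREASED
        joined = assign_features_to_bins(df, calls, self.bins)
        assert joined["bin"].iloc[0] == 0

    def test_zero_length_rejected(self):
        calls = calls_frame([STABLE])
        df = pd.DataFrame([feat("g1", 100, 100, 1.0, 0.01)])
        df["category"] = INCREASED
        with pytest.raises(ValueError, match="length"):
            assign_features_to_bins(df, calls, GenomeBins("chrS", RES, 1))

    def test_feature_outside_grid_dropped(self):
        calls = calls_frame([STABLE])
        df = pd.DataFrame([feat("g1", 10 * RES, 11 * RES, 1.0, 0.01)])
        df["category"] = INCREASED
        joined = assign_features_to_bins(df, calls, GenomeBins("chrS", RES, 1))
        assert len(joined) == 0


class TestAssociationFractions:
    def test_fractions_sum_to_one(self, rng):
        joined = pd.DataFrame(
            {
                "compartment_category": rng.choice([A_TO_B, B_TO_A, STABLE], 300),
                "category": rng.choice([INCREASED, DECREASED, FEATURE_STABLE], 300),
            }
        )
        fr = association_fractions(joined)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-12)

    def test_simple_counts(self):
        joined = pd.DataFrame(
            {
                "compartment_category": [B_TO_A] * 4,
                "category": [INCREASED] * 3 + [FEATURE_STABLE],
            }
        )
        fr = association_fractions(joined)
        assert fr.loc[B_TO_A, INCREASED] == pytest.approx(0.75)
        assert fr.loc[B_TO_A, DECREASED] == 0.0
        assert fr.loc[B_TO_A, FEATURE_STABLE] == pytest.approx(0.25)


class TestConcordance:
    def test_all_increased_in_b_to_a(self):
        joined = pd.DataFrame(
            {"compartment_category": [B_TO_A] * 5, "category": [INCREASED] * 5}
        )
        assert concordance_score(joined, B_TO_A) == 100.0

    def test_half_concordant(self):
        joined = pd.DataFrame(
            {
                "compartment_category": [B_TO_A] * 4,
                "category": [INCREASED, INCREASED, DECREASED, DECREASED],
            }
        )
        assert concordance_score(joined, B_TO_A) == 50.0

    def test_toward_b_counts_decreased(self):
        joined = pd.DataFrame(
            {"compartment_category": [A_TO_B] * 4, "category": [DECREASED] * 3 + [INCREASED]}
        )
        assert concordance_score(joined, A_TO_B) == 75.0

    def test_stable_category_rejected(self):
        joined = pd.DataFrame({"compartment_category": [STABLE], "category": [INCREASED]})
        with pytest.raises(ValueError, match="directional"):
            concordance_score(joined, STABLE)

    def test_order_invariance(self, rng):
        cats = [INCREASED] * 7 + [DECREASED] * 3
        joined = pd.DataFrame({"compartment_category": [B_TO_A] * 10, "category": cats})
        shuffled = joined.sample(frac=1, random_state=1)
        assert concordance_score(joined, B_TO_A) == concordance_score(shuffled, B_TO_A)


class TestRateOfConcordance:
    def _tables(self, comp_cats):
        features = pd.DataFrame(
            [feat(f"g{i}", i * 100, i * 100 + 50, 1.0, 0.01) for i in range(len(comp_cats))]
        )
        features["category"] = INCREASED
        joined = features.copy()
        joined["bin"] = range(len(comp_cats))
        joined["compartment_category"] = comp_cats
        return features, joined

    def test_no_changes_zero(self):
        features, joined = self._tables([STABLE] * 5)
        assert rate_of_concordance(features, joined, "up") == 0.0

    def test_all_in_b_to_a(self):
        features, joined = self._tables([B_TO_A] * 5)
        assert rate_of_concordance(features, joined, "up") == 100.0

    def test_switches_only_flag(self):
        features, joined = self._tables([B_TO_A, "B_to_less_B", STABLE, STABLE])
        assert rate_of_concordance(features, joined, "up", include_shifts=True) == 50.0
        assert rate_of_concordance(features, joined, "up", include_shifts=False) == 25.0


class TestGroupDifferenceTest:
    def test_identical_groups_p_one(self):
        vals = np.arange(10.0)
        res = group_difference_test({"stable": vals, "x": vals.copy()})
        assert res.loc["x", "p"] == pytest.approx(1.0)
        assert res.loc["x", "statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_separated_normals_tiny_p(self, rng):
        res = group_difference_test(
            {"stable": rng.normal(0, 1, 200), "x": rng.normal(1, 1, 200)}
        )
        assert res.loc["x", "p"] < 1e-10

    def test_singleton_group_undefined(self):
        res = group_difference_test({"stable": np.arange(5.0), "x": np.array([1.0])})
        assert np.isnan(res.loc["x", "p"])

    def test_wilcoxon_option(self, rng):
        res = group_difference_test(
            {"stable": rng.normal(0, 1, 100), "x": rng.normal(2, 1, 100)},
            method="wilcoxon",
        )
        assert res.loc["x", "p"] < 1e-8


class TestGeneSetOverlap:
    def test_identical_sets_tiny_p(self):
        uni = {f"g{i}" for i in range(1000)}
        s = {f"g{i}" for i in range(20)}
        res = gene_set_overlap_test(s, s, uni)
        assert res["overlap"] == 20
        assert res["p"] < 1e-30

    def test_closed_form_tail(self):
        """2x2 (a=10,b=10,c=10,d=70): p equals the hypergeometric tail sum."""
        uni = {f"g{i}" for i in range(100)}
        sa = {f"g{i}" for i in range(20)}          # 10 shared + 10 own
        sb = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(20, 30)}
        res = gene_set_overlap_test(sa, sb, uni)
        M, nA, nB = 100, 20, 20
        tail = sum(
            math.comb(nA, k) * math.comb(M - nA, nB - k) / math.comb(M, nB)
            for k in range(10, min(nA, nB) + 1)
        )
        assert res["overlap"] == 10
        assert res["p"] == pytest.approx(tail, rel=1e-12)
        assert res["table"] == [[10, 10], [10, 70]]

    def test_disjoint_small_sets(self):
        uni = set(range(10))
        res = gene_set_overlap_test(set(range(5)), set(range(5, 10)), uni)
        assert res["overlap"] == 0
        assert res["p"] == pytest.approx(1.0)

    def test_matches_enumeration_small_universe(self, rng):
        """Exact enumeration over all overlap values for |universe| <= 50."""
        M = 50
        uni = set(range(M))
        for _ in range(20):
            nA = int(rng.integers(1, 30))
            nB = int(rng.integers(1, 30))
            sa = set(rng.choice(M, nA, replace=False).tolist())
            sb = set(rng.choice(M, nB, replace=False).tolist())
            k = len(sa & sb)
            res = gene_set_overlap_test(sa, sb, uni)
            enum = sum(
                math.comb(nA, x) * math.comb(M - nA, nB - x)
                for x in range(k, min(nA, nB) + 1)
                if nB - x <= M - nA
            ) / math.comb(M, nB)
            assert res["p"] == pytest.approx(enum, rel=1e-10)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            gene_set_overlap_test(set(), set(), set())
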