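"""Joining differential feature tables to compartment dynamics.

Feature tables (differential expression, accessibility, or histone-mark
peaks) arrive as TSV with columns id, chrom, start, end, l2fc, pvalue, padj.
Features are categorized increased/decreased/stable by effect-size and
significance cutoffs, assigned to compartment bins by largest overlap, and
summarized with the concordance statistics: per-category feature fractions,
the concordance score of a compartment-change class, the rate of concordance
of up-/down-regulated features, group difference tests, and a hypergeometric
gene-set overlap test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import TOWARD_A, TOWARD_B

INCREASED = "increased"
DECREASED = "decreased"
FEATURE_STABLE = "stable"

FEATURE_COLUMNS = ["id", "chrom", "start", "end", "l2fc", "pvalue", "padj"]

# conventional thresholds: genes |L2FC|>0.32 & p<0.05; peaks |L2FC|>1.0 & FDR<0.01
GENE_LFC, GENE_SIG = 0.32, 0.05
PEAK_LFC, PEAK_SIG = 1.0, 0.01


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def categorize_features(
    table: pd.DataFrame,
    lfc_cutoff: float = GENE_LFC,
    sig_cutoff: float = GENE_SIG,
    sig_field: str = "p",
) -> pd.DataFrame:
    """Label each feature increased/decreased/stable by the double criterion.

    ``sig_field`` selects 'p' (raw p-value) or 'fdr' (adjusted).  Features
    with a missing significance value are stable and flagged.
    """
    col = {"p": "pvalue", "fdr": "padj"}.get(sig_field)
    if col is None:
        raise ValueError("sig_field must be 'p' or 'fdr'")
    out = table.copy()
    sig = out[col]
    missing = sig.isna() | out["l2fc"].isna()
    passed = sig < sig_cutoff
    out["category"] = FEATURE_STABLE
    out.loc[passed & (out["l2fc"] > lfc_cutoff), "category"] = INCREASED
    out.loc[passed & (out["l2fc"] < -lfc_cutoff), "category"] = DECREASED
    out.loc[missing, "category"] = FEATURE_STABLE
    out["sig_missing"] = missing
    return out


def assign_features_to_bins(features: pd.DataFrame, calls: pd.DataFrame, bins) -> pd.DataFrame:
    """Map each feature to one compartment bin and its dynamics category.

    A feature is assigned to the overlapping bin with the largest overlap;
    ties break toward the smaller bin index.  Features not overlapping any
    classified bin are dropped (returned count reported via the 'assigned'
    column being absent — they simply do not appear).
    """
    res = bins.resolution
    rows = []
    call_cat = calls["category"].astype(str)
    for row in features.itertuples(index=False):
        if row.end <= row.start:
            raise ValueError(f"feature {row.id}: zero/negative length interval")
        b0 = int(row.start // res)
        b1 = int(-(-row.end // res))
        best_bin, best_ov = None, -1
        for b in range(b0, b1):
            if b not in calls.index:
                continue
            ov = min(row.end, (b + 1) * res) - max(row.start, b * res)
            if ov > best_ov:
                best_bin, best_ov = b, ov
        if best_bin is None:
            continue
        rows.append((*row, best_bin, call_cat.loc[best_bin]))
    return pd.DataFrame(rows, columns=list(features.columns) + ["bin", "compartment_category"])


def association_fractions(joined: pd.DataFrame) -> pd.DataFrame:
    """P(feature category | compartment category): rows sum to 1.

    Compartment categories with no features get NaN rows.
    """
    if len(joined) == 0:
        raise ValueError("no joined features")
    tab = pd.crosstab(joined["compartment_category"], joined["category"])
    for c in (INCREASED, DECREASED, FEATURE_STABLE):
        if c not in tab.columns:
            tab[c] = 0
    tab = tab[[INCREASED, DECREASED, FEATURE_STABLE]]
    totals = tab.sum(axis=1)
    return tab.div(totals, axis=0)


def concordance_score(joined: pd.DataFrame, category: str) -> float:
    """Percent of features in a compartment-change class moving the same way.

    Toward-A (decompacting) classes count increased features as concordant;
    toward-B (compacting) classes count decreased features.
    """
    if category in TOWARD_A:
        want = INCREASED
    elif category in TOWARD_B:
        want = DECREASED
    else:
        raise ValueError(f"{category!r} is not a directional compartment-change class")
    sub = joined[joined["compartment_category"] == category]
    if len(sub) == 0:
        raise ValueError(f"no features in compartment category {category!r}")
    return 100.0 * float((sub["category"] == want).sum()) / len(sub)


def rate_of_concordance(
    features: pd.DataFrame,
    joined: pd.DataFrame,
    direction: str = "up",
    include_shifts: bool = True,
) -> float:
    """Percent of up- (down-)regulated features explained by toward-A (toward-B) changes.

    Denominator: all categorized increased (decreased) features.  Numerator:
    those whose assigned bin carries a toward-A (toward-B) change — switches
    only, or switches plus shifts.
    """
    if direction == "up":
        feat_cat, classes = INCREASED, TOWARD_A
        switch_only = ("B_to_A",)
    elif direction == "down":
        feat_cat, classes = DECREASED, TOWARD_B
        switch_only = ("A_to_B",)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    wanted = classes if include_shifts else switch_only
    total = int((features["category"] == feat_cat).sum())
    if total == 0:
        raise ValueError(f"no {feat_cat} features")
    sub = joined[joined["category"] == feat_cat]
    hits = int(sub["compartment_category"].isin(wanted).sum())
    return 100.0 * hits / total


def group_difference_test(groups: dict[str, np.ndarray], method: str = "t_test") -> pd.DataFrame:
    """Each non-stable group vs the 'stable' group; Welch t or rank-sum.

    Degenerate groups (n < 2 or zero variance for the t-test) yield NaN p.
    """
    if "stable" not in groups:
        raise ValueError("groups must include a 'stable' reference")
    ref = np.asarray(groups["stable"], dtype=float)
    rows = []
    for name, vals in groups.items():
        if name == "stable":
            continue
        v = np.asarray(vals, dtype=float)
        if len(v) < 2 or len(ref) < 2:
            rows.append((name, np.nan, np.nan))
            continue
        if method == "t_test":
            if np.std(v) == 0 and np.std(ref) == 0:
                rows.append((name, np.nan, 1.0 if np.mean(v) == np.mean(ref) else np.nan))
                continue
            r = stats.ttest_ind(v, ref, equal_var=False)
        elif method == "wilcoxon":
            r = stats.ranksums(v, ref)
        else:
            raise ValueError("method must be 't_test' or 'wilcoxon'")
        rows.append((name, float(r.statistic), float(r.pvalue)))
    return pd.DataFrame(rows, columns=["group", "statistic", "p"]).set_index("group")


def gene_set_overlap_test(set_a, set_b, universe):
    """One-tailed (enrichment) overlap test of two feature-id sets.

    Hypergeometric upper tail: P(overlap >= observed) drawing |set_b| items
    from a universe containing |set_a| marked items.  Also returns the 2x2
    odds ratio.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a = set(set_a) & universe
    b = set(set_b) & universe
    if not (set(set_a) <= universe and set(set_b) <= universe):
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    M, nA, nB = len(universe), len(a), len(b)
    p = float(stats.hypergeom.sf(k - 1, M, nA, nB))
    table = [[k, nA - k], [nB - k, M - nA - nB + k]]
    odds = stats.contingency.odds_ratio(table, kind="sample").statistic if min(
        table[0][1], table[1][0]
    ) >= 0 else np.nan
    return {"overlap": k, "odds_ratio": float(odds), "p": p, "table": table}
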