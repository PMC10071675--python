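"""Intra-TAD activity scoring and differential interactivity testing.

Intra-TAD activity is the mean normalized interaction score over all distinct
within-TAD bin pairs (diagonal excluded).  Differential activity between two
conditions compares the two per-pair value sets with a Wilcoxon two-sided
rank-sum test, BH-adjusts across all tested TADs, and flags TADs passing both
an |L2FC| and an FDR cutoff.  TAD intervals come from the reference (low)
condition and are consumed as inputs, not called here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from statsmodels.stats.multitest import multipletests

from .hic_io import (
    DISTANCE_NORMALIZED,
    ICED,
    ContactMatrix,
    distance_normalize,
    ice_normalize,
)

DEFAULT_LFC_CUTOFF = 0.25
DEFAULT_FDR_CUTOFF = 0.01


def normalize_pair(
    cm_low: ContactMatrix,
    cm_high: ContactMatrix,
    stage: str = DISTANCE_NORMALIZED,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> tuple[ContactMatrix, ContactMatrix]:
    """Normalize a condition pair with the reference condition's bias vector.

    Balancing each condition independently would absorb a broad within-TAD
    activity change into that condition's bin biases and cancel most of the
    signal being tested.  Instead the bias is estimated once, by ICE on the
    reference (low) matrix, and applied to both matrices after depth scaling;
    each matrix is then optionally distance-normalized by its own per-offset
    means (``stage``: 'iced' or 'distance_normalized').
    """
    if cm_low.bins != cm_high.bins:
        raise ValueError("matrices are on different bin grids")
    iced_low = ice_normalize(cm_low, max_iter=max_iter, tol=tol)
    bias = np.where(np.isfinite(iced_low.bias), iced_low.bias, 1.0)
    scale = cm_low.counts.sum() / cm_high.counts.sum()
    high_counts = cm_high.counts * scale / np.outer(bias, bias)
    mask = iced_low.mask & cm_high.mask
    high_counts[~mask, :] = 0.0
    high_counts[:, ~mask] = 0.0
    iced_high = cm_high.masked_like(
        high_counts, ICED, mask=mask, bias=iced_low.bias, converged=iced_low.converged
    )
    if stage == ICED:
        return iced_low, iced_high
    return distance_normalize(iced_low), distance_normalize(iced_high)


def read_tads_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :3]
    df.columns = ["chrom", "start", "end"]
    return df


def snap_to_bins(tads: pd.DataFrame, resolution: int, n_bins: int) -> pd.DataFrame:
    """Round TAD intervals outward to bin boundaries; return bin spans too."""
    out = tads.copy()
    out["start"] = (out["start"] // resolution) * resolution
    out["end"] = -(-out["end"] // resolution) * resolution
    out["bin_start"] = (out["start"] // resolution).astype(int)
    out["bin_end"] = np.minimum((out["end"] // resolution).astype(int), n_bins)
    if (out["bin_end"] <= out["bin_start"]).any():
        raise ValueError("TAD interval collapses to zero bins after snapping")
    return out


def _within_pairs(cm: ContactMatrix, b0: int, b1: int) -> np.ndarray:
    """Values at unmasked, finite within-TAD pairs i<j for bins [b0, b1)."""
    sub = cm.counts[b0:b1, b0:b1]
    m = cm.mask[b0:b1]
    iu, ju = np.triu_indices(b1 - b0, k=1)
    vals = sub[iu, ju]
    ok = m[iu] & m[ju] & np.isfinite(vals)
    return vals[ok]


def intra_tad_activity(cm: ContactMatrix, tads: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized score over within-TAD pairs, per TAD.

    ``cm`` must be normalized (iced or distance-normalized).  TADs with no
    valid pair get NaN activity and are excluded downstream.
    """
    if cm.state not in (ICED, DISTANCE_NORMALIZED):
        raise ValueError("intra_tad_activity expects a normalized matrix")
    t = snap_to_bins(tads, cm.bins.resolution, cm.n_bins) if "bin_start" not in tads else tads
    acts, npairs = [], []
    for b0, b1 in zip(t["bin_start"], t["bin_end"]):
        v = _within_pairs(cm, b0, b1)
        acts.append(v.mean() if len(v) else np.nan)
        npairs.append(len(v))
    out = t.copy()
    out["n_pairs"] = npairs
    out["activity"] = acts
    return out


def differential_tad_activity(
    cm_low: ContactMatrix,
    cm_high: ContactMatrix,
    tads_reference: pd.DataFrame,
    lfc_cutoff: float = DEFAULT_LFC_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
) -> pd.DataFrame:
    """Per-TAD Wilcoxon rank-sum test of within-TAD interaction values.

    Both matrices must be at the same normalization stage on the same bins.
    Returns a DataFrame with activity_low, activity_high, l2fc, p, fdr,
    significant; TADs lacking valid pairs in either condition are excluded
    (reported with NaN p).
    """
    if cm_low.bins != cm_high.bins:
        raise ValueError("matrices are on different bin grids")
    if cm_low.state != cm_high.state:
        raise ValueError("matrices are at different normalization stages")
    t = snap_to_bins(tads_reference, cm_low.bins.resolution, cm_low.n_bins)
    rows = []
    for b0, b1 in zip(t["bin_start"], t["bin_end"]):
        vl = _within_pairs(cm_low, b0, b1)
        vh = _within_pairs(cm_high, b0, b1)
        if len(vl) < 1 or len(vh) < 1 or vl.mean() <= 0 or vh.mean() <= 0:
            rows.append((np.nan, np.nan, np.nan, np.nan))
            continue
        l2fc = np.log2(vh.mean() / vl.mean())
        p = ranksums(vh, vl).pvalue
        rows.append((vl.mean(), vh.mean(), l2fc, p))
    out = t.copy()
    out[["activity_low", "activity_high", "l2fc", "p"]] = pd.DataFrame(rows, index=t.index)
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["significant"] = tested & (out["l2fc"].abs() > lfc_cutoff) & (out["fdr"] < fdr_cutoff)
    return out


def classify_tads(diff: pd.DataFrame) -> pd.Series:
    """'increased' / 'decreased' / 'stable' per TAD from the significance call."""
    cls = np.where(
        diff["significant"] & (diff["l2fc"] > 0),
        "increased",
        np.where(diff["significant"] & (diff["l2fc"] < 0), "decreased", "stable"),
    )
    return pd.Series(cls, index=diff.index, name="tad_class")
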