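"""Compartment switch/shift classification between two conditions.

X is the compartment score of a bin in the reference condition (sample 1),
Y in the comparison condition (sample 2).  The change measure is the
relative delta

    delta = (Y - X) / |Y|

Positive delta points toward A, negative toward B.  A bin whose score sign
flips and whose |delta| exceeds the switch cutoff (default 1.2) is an A->B or
B->A switch; a bin keeping its sign with |delta| above the shift cutoff
(default 0.2) is a shift (A to more/less A, B to more/less B); everything
else is stable.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

A_TO_B = "A_to_B"
B_TO_A = "B_to_A"
A_TO_MORE_A = "A_to_more_A"
A_TO_LESS_A = "A_to_less_A"
B_TO_MORE_B = "B_to_more_B"
B_TO_LESS_B = "B_to_less_B"
STABLE = "stable"

CATEGORIES = (A_TO_B, B_TO_A, A_TO_MORE_A, A_TO_LESS_A, B_TO_MORE_B, B_TO_LESS_B, STABLE)
SWITCH_CATEGORIES = (A_TO_B, B_TO_A)
SHIFT_CATEGORIES = (A_TO_MORE_A, A_TO_LESS_A, B_TO_MORE_B, B_TO_LESS_B)
# grouping used for concordance with expression/accessibility direction
TOWARD_A = (B_TO_A, B_TO_LESS_B, A_TO_MORE_A)
TOWARD_B = (A_TO_B, A_TO_LESS_A, B_TO_MORE_B)

DEFAULT_SWITCH_CUTOFF = 1.2
DEFAULT_SHIFT_CUTOFF = 0.2
DELTA_DENOM_FLOOR = 1e-3


def relative_delta(x, y, denom_floor: float = DELTA_DENOM_FLOOR):
    """(y - x) / |y|, with |y| floored at ``denom_floor`` to avoid blow-up.

    Works elementwise on arrays.  Returns (delta, floored_flag).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = np.maximum(np.abs(y), denom_floor)
    delta = (y - x) / denom
    floored = np.abs(y) < denom_floor
    if delta.ndim == 0:
        return float(delta), bool(floored)
    return delta, floored


def classify_bin(
    x,
    y,
    switch_cutoff: float = DEFAULT_SWITCH_CUTOFF,
    shift_cutoff: float = DEFAULT_SHIFT_CUTOFF,
    denom_floor: float = DELTA_DENOM_FLOOR,
):
    """Classify one (x, y) score pair — or arrays of pairs — into the 7 categories.

    Switches require a sign flip AND |delta| > switch_cutoff (sign-flip bins
    failing the cutoff are stable).  Shifts require an unchanged sign and
    |delta| > shift_cutoff, directed by the sign of delta.
    """
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    delta, _ = relative_delta(x, y, denom_floor)
    delta = np.atleast_1d(delta)
    cat = np.full(x.shape, STABLE, dtype=object)

    flip = np.sign(x) * np.sign(y) < 0
    big = np.abs(delta) > switch_cutoff
    cat[flip & big & (x > 0)] = A_TO_B
    cat[flip & big & (x < 0)] = B_TO_A

    same = np.sign(x) * np.sign(y) > 0
    shifted = same & (np.abs(delta) > shift_cutoff)
    cat[shifted & (x > 0) & (delta > 0)] = A_TO_MORE_A
    cat[shifted & (x > 0) & (delta < 0)] = A_TO_LESS_A
    cat[shifted & (x < 0) & (delta > 0)] = B_TO_LESS_B
    cat[shifted & (x < 0) & (delta < 0)] = B_TO_MORE_B

    if scalar:
        return str(cat[0])
    return cat


def classify_tracks(
    x: np.ndarray,
    y: np.ndarray,
    switch_cutoff: float = DEFAULT_SWITCH_CUTOFF,
    shift_cutoff: float = DEFAULT_SHIFT_CUTOFF,
    denom_floor: float = DELTA_DENOM_FLOOR,
) -> pd.DataFrame:
    """Per-bin calls for two aligned score tracks; bins missing either score are dropped.

    Returns a DataFrame indexed by bin with columns x, y, delta, category,
    denom_floored.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("tracks have different lengths")
    ok = np.isfinite(x) & np.isfinite(y)
    idx = np.flatnonzero(ok)
    delta, floored = relative_delta(x[idx], y[idx], denom_floor)
    cat = classify_bin(x[idx], y[idx], switch_cutoff, shift_cutoff, denom_floor)
    return pd.DataFrame(
        {
            "bin": idx,
            "x": x[idx],
            "y": y[idx],
            "delta": delta,
            "category": pd.Categorical(cat, categories=list(CATEGORIES)),
            "denom_floored": floored,
        }
    ).set_index("bin")


def percent_changed(calls: pd.DataFrame | pd.Series, include_shifts: bool = False) -> float:
    """Percentage of classified bins that changed compartment.

    Switches-only: 100 * (#A->B + #B->A) / #classified.  With shifts, the four
    shift categories join the numerator; the denominator is always all
    classified bins (switching + shifting + stable).
    """
    cat = calls["category"] if isinstance(calls, pd.DataFrame) else calls
    n = len(cat)
    if n == 0:
        raise ValueError("no classified bins")
    moved = list(SWITCH_CATEGORIES) + (list(SHIFT_CATEGORIES) if include_shifts else [])
    return 100.0 * float(np.isin(np.asarray(cat, dtype=object), moved).sum()) / n


def category_counts(calls: pd.DataFrame) -> pd.Series:
    return calls["category"].value_counts().reindex(list(CATEGORIES), fill_value=0)


def shared_changes(call_sets, direction: str, min_samples: int = 2):
    """Cross-sample sharing of switches in one direction.

    Parameters
    ----------
    call_sets : list of per-sample calls — either DataFrames from
        classify_tracks (bins with the requested direction are extracted) or
        plain sets/arrays of bin ids already filtered to that direction.
    direction : 'A_to_B' or 'B_to_A'.
    min_samples : minimum number of samples a bin must appear in to count as shared.

    Returns a dict with the shared bin set, per-membership-pattern overlap
    counts (Venn cells keyed by sample-index tuples), and the shared fraction
    100 * #shared / #bins with that direction in >= 1 sample.
    """
    if direction not in SWITCH_CATEGORIES:
        raise ValueError(f"direction must be one of {SWITCH_CATEGORIES}")
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    bin_sets = []
    for cs in call_sets:
        if isinstance(cs, pd.DataFrame):
            bin_sets.append(set(cs.index[np.asarray(cs["category"]) == direction]))
        else:
            bin_sets.append(set(cs))
    k = len(bin_sets)
    union = set().union(*bin_sets) if bin_sets else set()
    counts = {b: sum(b in s for s in bin_sets) for b in union}
    shared = {b for b, c in counts.items() if c >= min_samples}
    venn = {}
    for r in range(1, k + 1):
        for combo in combinations(range(k), r):
            inside = set.intersection(*(bin_sets[i] for i in combo)) if combo else set()
            outside = set().union(*(bin_sets[i] for i in range(k) if i not in combo), set())
            venn[combo] = len(inside - outside)
    fraction = 100.0 * len(shared) / len(union) if union else 0.0
    return {
        "shared_bins": shared,
        "n_union": len(union),
        "n_shared": len(shared),
        "venn_counts": venn,
        "shared_fraction": fraction,
    }


def write_calls_bed(calls: pd.DataFrame, bins, path) -> None:
    """BED-style output: chrom, start, end, category, delta."""
    df = pd.DataFrame(
        {
            "chrom": bins.chrom,
            "start": calls.index.to_numpy() * bins.resolution,
            "end": (calls.index.to_numpy() + 1) * bins.resolution,
            "category": calls["category"].astype(str),
            "delta": calls["delta"],
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)
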