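"""Synthetic Hi-C data with planted ground truth.

Emulates the data structure the compartment-dynamics analysis assumes: a
plaid (checkerboard) compartment pattern over a power-law distance decay,
multiplicative per-bin biases, Poisson-sampled counts, paired-condition
score tracks with planted switches and shifts that classify exactly at the
standard cutoffs, TADs with planted activity fold changes, and differential
feature tables with a planted concordance rate.

Default scale models one ~40 Mb chromosome arm at 40 kb resolution
(1000 bins) sequenced to 2e6 intra-chromosomal contacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    A_TO_B,
    A_TO_LESS_A,
    A_TO_MORE_A,
    B_TO_A,
    B_TO_LESS_B,
    B_TO_MORE_B,
    SHIFT_CATEGORIES,
    STABLE,
    SWITCH_CATEGORIES,
    TOWARD_A,
    TOWARD_B,
    classify_bin,
)
from .hic_io import RAW, ContactMatrix, GenomeBins
from .integration import DECREASED, FEATURE_STABLE, INCREASED

DEFAULT_N_BINS = 1000
DEFAULT_DEPTH = 2e6
DEFAULT_ALPHA = 1.0
DEFAULT_RESOLUTION = 40_000
DEFAULT_BIAS_SIGMA = 0.2

# noiseless (x, y) exemplars per planted category; each classifies exactly
# at the (1.2, 0.2) cutoffs with a comfortable margin
_CATEGORY_EXEMPLARS = {
    A_TO_B: (0.5, -0.4),
    B_TO_A: (-0.5, 0.4),
    A_TO_MORE_A: (0.3, 0.5),
    A_TO_LESS_A: (0.5, 0.35),
    B_TO_MORE_B: (-0.3, -0.5),
    B_TO_LESS_B: (-0.5, -0.35),
}


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated chromosome."""

    bins: GenomeBins
    c_low: np.ndarray
    c_high: np.ndarray
    bias: np.ndarray
    alpha: float
    category: np.ndarray            # planted per-bin dynamics category
    tads: pd.DataFrame | None = None
    tad_multiplier: np.ndarray | None = None
    concordance: float | None = None
    seed: int | None = None
    feature_truth: pd.DataFrame | None = None


def block_profile(n_bins: int, block_size: int = 25, amplitude: float = 0.8) -> np.ndarray:
    """Alternating-block compartment profile: +-amplitude in blocks."""
    sign = (np.arange(n_bins) // block_size) % 2
    return np.where(sign == 0, amplitude, -amplitude)


def expected_matrix(
    c: np.ndarray, bias: np.ndarray, alpha: float, depth: float
) -> np.ndarray:
    """Expected Poisson rates: B_i B_j d^-alpha (1 + C_i C_j)/2, diagonal zero,
    scaled so the total expected count (both triangles) equals ``depth``."""
    n = len(c)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
    with np.errstate(divide="ignore"):
        decay = np.where(d > 0, d**-alpha, 0.0)
    rate = np.outer(bias, bias) * decay * (1.0 + np.outer(c, c)) / 2.0
    total = rate.sum()
    if total <= 0:
        raise ValueError("degenerate expected matrix")
    return rate * (depth / total)


def simulate_contact_map(
    c: np.ndarray,
    rng: np.random.Generator,
    bias: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    depth: float = DEFAULT_DEPTH,
    resolution: int = DEFAULT_RESOLUTION,
    chrom: str = "chrS",
    bias_sigma: float = DEFAULT_BIAS_SIGMA,
) -> tuple[ContactMatrix, np.ndarray]:
    """Poisson-sample a symmetric raw contact matrix from a planted profile.

    Returns (matrix, bias).  If ``bias`` is None, biases are drawn
    LogNormal(0, bias_sigma^2).  ``depth`` is the expected total count over
    the full (symmetric) matrix.
    """
    c = np.asarray(c, dtype=float)
    n = len(c)
    if n < 20:
        raise ValueError("n_bins must be >= 20")
    if depth <= 0 or alpha <= 0:
        raise ValueError("depth and alpha must be positive")
    if bias is None:
        bias = rng.lognormal(mean=0.0, sigma=bias_sigma, size=n)
    rate = expected_matrix(c, bias, alpha, depth)
    iu, ju = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    sampled = rng.poisson(rate[iu, ju])
    counts[iu, ju] = sampled
    counts[ju, iu] = sampled
    bins = GenomeBins(chrom=chrom, resolution=resolution, n_bins=n)
    return ContactMatrix(bins=bins, counts=counts, state=RAW), bias


def plant_dynamics(
    base_c: np.ndarray,
    n_switch: int,
    n_shift: int,
    rng: np.random.Generator,
    jitter: float = 0.03,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plant switches and shifts into a baseline profile.

    Selected bins get noiseless (x, y) pairs that classify exactly as
    intended at the (1.2, 0.2) cutoffs; all other bins keep x = y (stable by
    construction).  Switch bins split evenly A->B / B->A; shift bins cycle
    the four shift categories.  Returns (c_low, c_high, category).
    """
    base_c = np.asarray(base_c, dtype=float)
    n = len(base_c)
    if n_switch + n_shift > n:
        raise ValueError(
            f"requested {n_switch + n_shift} changed bins but only {n} available"
        )
    c_low = base_c.copy()
    c_high = base_c.copy()
    category = np.full(n, STABLE, dtype=object)
    chosen = rng.choice(n, size=n_switch + n_shift, replace=False)
    plan = [SWITCH_CATEGORIES[i % 2] for i in range(n_switch)] + [
        SHIFT_CATEGORIES[i % 4] for i in range(n_shift)
    ]
    for b, cat in zip(chosen, plan):
        x0, y0 = _CATEGORY_EXEMPLARS[cat]
        for _ in range(100):
            x = x0 + rng.normal(0, jitter)
            y = y0 + rng.normal(0, jitter)
            if classify_bin(x, y) == cat:
                break
        else:  # pragma: no cover - exemplars have wide margins
            x, y = x0, y0
        c_low[b], c_high[b] = x, y
        category[b] = cat
    # planted truth must classify exactly as labeled on the noiseless pair
    assert (classify_bin(c_low, c_high) == category).all()
    return c_low, c_high, category


def random_tads(
    n_bins: int,
    rng: np.random.Generator,
    min_span: int = 10,
    max_span: int = 25,
    resolution: int = DEFAULT_RESOLUTION,
    chrom: str = "chrS",
) -> pd.DataFrame:
    """Tile the chromosome into contiguous TADs of random bin spans."""
    starts, ends = [], []
    b = 0
    while b < n_bins:
        span = int(rng.integers(min_span, max_span + 1))
        e = min(b + span, n_bins)
        if n_bins - e < min_span:
            e = n_bins
        starts.append(b * resolution)
        ends.append(e * resolution)
        b = e
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def plant_tad_changes(
    c: np.ndarray,
    tads: pd.DataFrame,
    changed: list[int],
    multiplier: float,
    rng: np.random.Generator,
    bias: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    depth: float = DEFAULT_DEPTH,
    resolution: int = DEFAULT_RESOLUTION,
) -> tuple[ContactMatrix, ContactMatrix, np.ndarray]:
    """Paired matrices in which condition 2 scales within-TAD rates for
    ``changed`` TADs (row indices into ``tads``) by ``multiplier``.

    Changed TADs must not overlap each other.  Returns (cm_low, cm_high, bias).
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    c = np.asarray(c, dtype=float)
    n = len(c)
    spans = [
        (int(tads.iloc[k]["start"] // resolution), int(-(-tads.iloc[k]["end"] // resolution)))
        for k in changed
    ]
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError("changed TADs overlap")
    if bias is None:
        bias = rng.lognormal(0.0, DEFAULT_BIAS_SIGMA, size=n)
    rate = expected_matrix(c, bias, alpha, depth)
    rate2 = rate.copy()
    for b0, b1 in spans:
        blk = rate2[b0:b1, b0:b1]
        off = blk.copy()
        np.fill_diagonal(off, 0.0)
        rate2[b0:b1, b0:b1] = off * multiplier

    def sample(r):
        iu, ju = np.triu_indices(n, k=1)
        m = np.zeros((n, n))
        s = rng.poisson(r[iu, ju])
        m[iu, ju] = s
        m[ju, iu] = s
        bins = GenomeBins(chrom=str(tads.iloc[0]["chrom"]), resolution=resolution, n_bins=n)
        return ContactMatrix(bins=bins, counts=m, state=RAW)

    return sample(rate), sample(rate2), bias


def simulate_feature_table(
    category: np.ndarray,
    n_features: int,
    rng: np.random.Generator,
    concordance: float = 0.8,
    effect_size: float = 1.0,
    resolution: int = DEFAULT_RESOLUTION,
    chrom: str = "chrS",
    stable_diff_rate: float = 0.05,
) -> pd.DataFrame:
    """Feature table with a planted concordance rate against bin categories.

    Features land uniformly over bins (interval inside the bin).  In a
    toward-A bin a feature is drawn increased with probability
    ``concordance`` and decreased otherwise; mirrored for toward-B bins.
    Features in stable bins are mostly stable (a small ``stable_diff_rate``
    goes differential, split evenly).  Effect sizes are +-effect_size plus
    noise with small p-values, guaranteed past the conventional gene
    thresholds (|L2FC| > 0.32, p < 0.05); stable features sit safely inside
    them.  The planted direction is recorded in 'truth_direction'.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    n = len(category)
    bins_drawn = rng.integers(0, n, size=n_features)
    rows = []
    for k, b in enumerate(bins_drawn):
        cat = category[b]
        if cat in TOWARD_A:
            direction = INCREASED if rng.random() < concordance else DECREASED
        elif cat in TOWARD_B:
            direction = DECREASED if rng.random() < concordance else INCREASED
        else:
            if rng.random() < stable_diff_rate:
                direction = INCREASED if rng.random() < 0.5 else DECREASED
            else:
                direction = FEATURE_STABLE
        if direction == INCREASED:
            l2fc = effect_size + rng.normal(0, 0.1 * effect_size)
            l2fc = max(l2fc, 0.4)
            p = 10 ** rng.uniform(-8, -3)
        elif direction == DECREASED:
            l2fc = -effect_size + rng.normal(0, 0.1 * effect_size)
            l2fc = min(l2fc, -0.4)
            p = 10 ** rng.uniform(-8, -3)
        else:
            l2fc = rng.normal(0, 0.1)
            l2fc = float(np.clip(l2fc, -0.3, 0.3))
            p = rng.uniform(0.06, 1.0)
        start = b * resolution + int(rng.integers(0, resolution // 2))
        end = start + int(rng.integers(200, resolution // 2))
        rows.append((f"feat{k:05d}", chrom, start, end, l2fc, p, min(1.0, p * 2), direction))
    return pd.DataFrame(
        rows,
        columns=["id", "chrom", "start", "end", "l2fc", "pvalue", "padj", "truth_direction"],
    )


def simulate_study(
    seed: int,
    n_bins: int = DEFAULT_N_BINS,
    depth: float = DEFAULT_DEPTH,
    n_switch: int = 40,
    n_shift: int = 60,
    n_features: int = 2000,
    concordance: float = 0.8,
    alpha: float = DEFAULT_ALPHA,
    resolution: int = DEFAULT_RESOLUTION,
) -> tuple[SyntheticTruth, ContactMatrix, ContactMatrix, pd.DataFrame]:
    """One full synthetic study: paired matrices, truth tracks, TADs, features.

    Returns (truth, cm_low, cm_high, feature_table).
    """
    rng = np.random.default_rng(seed)
    base = block_profile(n_bins)
    c_low, c_high, category = plant_dynamics(base, n_switch, n_shift, rng)
    bias = rng.lognormal(0.0, DEFAULT_BIAS_SIGMA, size=n_bins)
    cm_low, _ = simulate_contact_map(
        c_low, rng, bias=bias, alpha=alpha, depth=depth, resolution=resolution
    )
    cm_high, _ = simulate_contact_map(
        c_high, rng, bias=bias, alpha=alpha, depth=depth, resolution=resolution
    )
    tads = random_tads(n_bins, rng, resolution=resolution)
    features = simulate_feature_table(
        category, n_features, rng, concordance=concordance, resolution=resolution
    )
    truth = SyntheticTruth(
        bins=cm_low.bins,
        c_low=c_low,
        c_high=c_high,
        bias=bias,
        alpha=alpha,
        category=category,
        tads=tads,
        concordance=concordance,
        seed=seed,
        feature_truth=features[["id", "truth_direction"]].copy(),
    )
    return truth, cm_low, cm_high, features
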