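"""Binned intra-chromosomal Hi-C contact matrices: I/O, balancing, comparison.

A contact matrix for one chromosome at a fixed resolution is held dense and
symmetric.  Normalization proceeds raw -> iced -> distance_normalized, never
backwards; each stage is a new object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RAW = "raw"
ICED = "iced"
DISTANCE_NORMALIZED = "distance_normalized"

_STATE_ORDER = {RAW: 0, ICED: 1, DISTANCE_NORMALIZED: 2}


@dataclass(frozen=True)
class GenomeBins:
    """Uniform half-open bins [i*resolution, (i+1)*resolution) tiling one chromosome."""

    chrom: str
    resolution: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if self.n_bins <= 0:
            raise ValueError(f"n_bins must be positive, got {self.n_bins}")

    @classmethod
    def from_chrom_size(cls, chrom: str, size: int, resolution: int) -> "GenomeBins":
        return cls(chrom=chrom, resolution=resolution, n_bins=-(-size // resolution))

    def start(self, i: np.ndarray | int) -> np.ndarray | int:
        return np.asarray(i) * self.resolution if np.ndim(i) else i * self.resolution

    def end(self, i: np.ndarray | int):
        return self.start(i) + self.resolution

    def bin_of(self, pos: np.ndarray | int):
        """Bin index containing genomic position ``pos`` (0-based)."""
        return np.asarray(pos) // self.resolution if np.ndim(pos) else pos // self.resolution

    def to_frame(self) -> pd.DataFrame:
        idx = np.arange(self.n_bins)
        return pd.DataFrame(
            {"chrom": self.chrom, "start": idx * self.resolution, "end": (idx + 1) * self.resolution}
        )


@dataclass
class ContactMatrix:
    """One chromosome's symmetric binned contact matrix with a per-bin validity mask.

    ``counts`` is dense float64, symmetric; masked bins carry all-zero rows and
    columns (NaN allowed only in the distance-normalized state, on undefined
    diagonals).  ``bias`` is set by ICE so that raw_ij ~= bias_i * bias_j * iced_ij.
    """

    bins: GenomeBins
    counts: np.ndarray
    mask: np.ndarray = field(default=None)  # True = valid bin
    state: str = RAW
    bias: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.bins.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(f"counts shape {self.counts.shape} != ({n}, {n})")
        with np.errstate(invalid="ignore"):
            if not np.allclose(self.counts, self.counts.T, equal_nan=True):
                raise ValueError("contact matrix must be symmetric")
        if self.state == RAW and np.nanmin(self.counts) < 0:
            raise ValueError("raw contact counts must be non-negative")
        if self.mask is None:
            marg = np.nansum(self.counts, axis=0)
            self.mask = marg > 0
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def masked_like(self, counts: np.ndarray, state: str, **kw) -> "ContactMatrix":
        if _STATE_ORDER[state] < _STATE_ORDER[self.state]:
            raise ValueError(f"cannot move from state {self.state!r} back to {state!r}")
        return replace(self, counts=counts, state=state, **kw)


def read_contacts(path, chrom: str, resolution: int, n_bins: int | None = None) -> ContactMatrix:
    """Read a whitespace-delimited COO text file (bin_i bin_j count) as a raw matrix.

    Bin indices are 0-based.  Records for (i, j) and (j, i) are summed into the
    same symmetric entry; duplicates accumulate.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["bin1", "bin2", "count"])
    if len(df) == 0:
        raise ValueError(f"{path}: empty contact file")
    i = df["bin1"].to_numpy(dtype=np.int64)
    j = df["bin2"].to_numpy(dtype=np.int64)
    c = df["count"].to_numpy(dtype=np.float64)
    if n_bins is None:
        n_bins = int(max(i.max(), j.max())) + 1
    bad = (i < 0) | (j < 0) | (i >= n_bins) | (j >= n_bins)
    if bad.any():
        k = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: bin index out of range at record {k} ({i[k]}, {j[k]}) for {n_bins} bins"
        )
    if (c < 0).any():
        k = int(np.flatnonzero(c < 0)[0])
        raise ValueError(f"{path}: negative count at record {k} ({c[k]})")
    mat = np.zeros((n_bins, n_bins))
    np.add.at(mat, (i, j), c)
    np.add.at(mat, (j, i), c)
    # the loop above double-adds the diagonal
    mat[np.diag_indices(n_bins)] /= 2.0
    bins = GenomeBins(chrom=chrom, resolution=resolution, n_bins=n_bins)
    return ContactMatrix(bins=bins, counts=mat, state=RAW)


def write_contacts(cm: ContactMatrix, path) -> None:
    """Write the upper triangle (incl. diagonal) of non-zero entries as COO text."""
    iu, ju = np.triu_indices(cm.n_bins)
    v = cm.counts[iu, ju]
    keep = np.isfinite(v) & (v != 0)
    pd.DataFrame({"bin1": iu[keep], "bin2": ju[keep], "count": v[keep]}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_bias_bedgraph(cm: ContactMatrix, path) -> None:
    if cm.bias is None:
        raise ValueError("matrix has no bias vector (run ice_normalize first)")
    df = cm.bins.to_frame()
    df["value"] = cm.bias
    df.loc[~cm.mask, "value"] = np.nan
    df.dropna().to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def low_coverage_mask(counts: np.ndarray, min_frac: float = 0.02) -> np.ndarray:
    """Valid-bin mask: marginal at least ``min_frac`` of the median positive marginal."""
    marg = counts.sum(axis=0)
    pos = marg[marg > 0]
    if len(pos) == 0:
        return np.zeros(len(marg), dtype=bool)
    return marg >= min_frac * np.median(pos)


def ice_normalize(
    cm: ContactMatrix,
    max_iter: int = 200,
    tol: float = 1e-5,
    min_coverage_frac: float = 0.02,
) -> ContactMatrix:
    """Iterative correction (matrix balancing): equalize unmasked row sums.

    Bins whose raw marginal falls below ``min_coverage_frac`` of the median
    marginal are masked before balancing.  Convergence criterion is the
    coefficient of variation (std/mean) of unmasked row sums falling below
    ``tol``.  The returned matrix carries the multiplicative bias vector with
    raw_ij ~= bias_i * bias_j * iced_ij (bias normalized to unit geometric
    mean over unmasked bins).
    """
    if cm.state != RAW:
        raise ValueError(f"ice_normalize expects a raw matrix, got state {cm.state!r}")
    mask = cm.mask & low_coverage_mask(cm.counts, min_coverage_frac)
    if mask.sum() < 2:
        raise ValueError("fewer than 2 bins survive low-coverage masking")
    work = cm.counts.copy()
    work[~mask, :] = 0.0
    work[:, ~mask] = 0.0
    bias = np.ones(cm.n_bins)
    converged = False
    cv = np.inf
    for _ in range(max_iter):
        s = work.sum(axis=0)
        sv = s[mask]
        m = sv.mean()
        cv = sv.std() / m
        if cv <= tol:
            converged = True
            break
        d = np.ones(cm.n_bins)
        d[mask] = sv / m
        work /= np.outer(d, d)
        bias *= d
    else:
        s = work.sum(axis=0)
        sv = s[mask]
        cv = sv.std() / sv.mean()
        converged = cv <= tol
    if not converged:
        warnings.warn(
            f"ICE did not converge after {max_iter} iterations "
            f"(row-sum CV {cv:.3g} > tol {tol:g})",
            RuntimeWarning,
        )
    # unit geometric mean bias on unmasked bins; fold the scale into the matrix
    g = np.exp(np.mean(np.log(bias[mask])))
    bias /= g
    work *= g * g
    bias[~mask] = np.nan
    return cm.masked_like(work, ICED, mask=mask, bias=bias, converged=converged)


def distance_normalize(cm: ContactMatrix) -> ContactMatrix:
    """Observed/expected: divide every entry by the mean of unmasked entries at
    its diagonal offset.  Offsets whose mean is zero are left NaN."""
    if cm.state != ICED:
        raise ValueError(f"distance_normalize expects an iced matrix, got {cm.state!r}")
    if cm.mask.sum() < 2:
        raise ValueError("fewer than 2 unmasked bins")
    n = cm.n_bins
    out = np.full((n, n), np.nan)
    pair_ok = np.outer(cm.mask, cm.mask)
    for d in range(n):
        idx = (np.arange(n - d), np.arange(d, n))
        ok = pair_ok[idx]
        if not ok.any():
            continue
        vals = cm.counts[idx]
        mu = vals[ok].mean()
        if mu <= 0:
            continue
        row = np.where(ok, vals / mu, np.nan)
        out[idx] = row
        out[idx[1], idx[0]] = row
    return cm.masked_like(out, DISTANCE_NORMALIZED)


def log2_ratio_matrix(
    cm_high: ContactMatrix, cm_low: ContactMatrix, pseudocount: float = 1e-6
) -> np.ndarray:
    """log2 of the depth-scaled high/low ratio, NaN where either bin is masked.

    Each matrix is first divided by its total number of intra-chromosomal
    interactions, so sequencing depth cancels.
    """
    if cm_high.bins != cm_low.bins:
        raise ValueError("matrices are on different bin grids")
    th = np.nansum(cm_high.counts)
    tl = np.nansum(cm_low.counts)
    if th <= 0 or tl <= 0:
        raise ValueError("cannot depth-scale an all-zero matrix")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log2((cm_high.counts / th + pseudocount) / (cm_low.counts / tl + pseudocount))
    bad = ~(np.outer(cm_high.mask, cm_high.mask) & np.outer(cm_low.mask, cm_low.mask))
    ratio[bad] = np.nan
    return ratio
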