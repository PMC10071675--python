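"""Maximum-likelihood A/B compartment scoring.

Each bin i carries a probability P_i of belonging to the A compartment,
reported as the compartment score C_i = 2 P_i - 1 in [-1, 1].  Contacts are
modeled as independent Poisson counts with rate

    lambda_ij = B_i * B_j * H(d_ij) * (1 + C_i * C_j) / 2

where B_i are experimental bias factors, H(d) a distance-decay scaling
function, and (1 + C_i C_j) / 2 is the probability that bins i and j occupy
the same compartment under independent A-membership (it equals
P_i P_j + (1-P_i)(1-P_j)).  The log-likelihood is maximized by blockwise
coordinate ascent: closed-form updates for H and B, damped Newton steps for
C, each phase guarded by backtracking so the likelihood never decreases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hic_io import (
    RAW,
    ContactMatrix,
    GenomeBins,
    distance_normalize,
    ice_normalize,
    low_coverage_mask,
)

# keep |C_i C_j| away from 1 so log(1 + C_i C_j) stays finite
_C_BOUND = 0.999


@dataclass
class CscoreModel:
    """Fitted compartment model for one chromosome."""

    bins: GenomeBins
    cscore: np.ndarray          # C_i in [-1, 1]; NaN for masked bins
    bias: np.ndarray            # B_i; NaN for masked bins
    h_per_offset: np.ndarray    # H(d) evaluated at every bin offset 1..n-1 (index 0 unused)
    mask: np.ndarray
    log_likelihood: float
    ll_trace: np.ndarray
    converged: bool
    n_iter: int

    @property
    def a_probability(self) -> np.ndarray:
        """P_i = (C_i + 1) / 2."""
        return (self.cscore + 1.0) / 2.0


@dataclass
class CompartmentTrack:
    """Oriented per-bin compartment score; positive = A, negative = B."""

    bins: GenomeBins
    cscore: np.ndarray
    flipped: bool = False

    @property
    def label(self) -> np.ndarray:
        """'A' where cscore > 0, 'B' where cscore < 0, '' where missing/zero."""
        lab = np.where(self.cscore > 0, "A", np.where(self.cscore < 0, "B", ""))
        lab[~np.isfinite(self.cscore)] = ""
        return lab

    def to_frame(self):
        df = self.bins.to_frame()
        df["cscore"] = self.cscore
        df["label"] = self.label
        return df


def _offset_bands(n: int, n_bands: int) -> np.ndarray:
    """Assign each bin offset 1..n-1 to one of <= n_bands log-spaced bands."""
    offsets = np.arange(1, n)
    edges = np.unique(np.geomspace(1, n - 1, num=min(n_bands, n - 1) + 1).round().astype(int))
    band = np.searchsorted(edges, offsets, side="right") - 1
    band = np.clip(band, 0, len(edges) - 2) if len(edges) > 1 else np.zeros_like(offsets)
    full = np.zeros(n, dtype=int)
    full[1:] = band
    return full  # index by offset; offset 0 unused


def _eigenvector_init(cm: ContactMatrix, mask: np.ndarray) -> np.ndarray:
    """Leading eigenvector of the O/E correlation matrix, sign pattern at +-0.5."""
    iced = ice_normalize(cm)
    oe = distance_normalize(iced)
    idx = np.flatnonzero(mask & iced.mask)
    sub = oe.counts[np.ix_(idx, idx)]
    sub = np.where(np.isfinite(sub), sub, 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(sub)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    w, v = np.linalg.eigh(corr)
    lead = v[:, np.argmax(w)]
    c0 = np.zeros(cm.n_bins)
    c0[idx] = 0.5 * np.sign(lead)
    c0[c0 == 0] = 0.1
    c0[~mask] = 0.0
    return c0


def _log_likelihood(n_ij, lam, pair_w):
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(pair_w, n_ij * np.log(lam) - lam, 0.0)
        # n=0 contributes -lam even if log(lam) = -inf
        term = np.where(pair_w & (n_ij == 0), -lam, term)
    return 0.5 * float(term.sum())


def estimate_cscore(
    cm: ContactMatrix,
    min_dist: int | None = None,
    max_dist: int | None = None,
    max_iter: int = 100,
    tol: float = 1e-7,
    n_bands: int = 50,
    seed: int | None = None,
    min_coverage_frac: float = 0.02,
) -> CscoreModel:
    """Fit B, C, H by blockwise coordinate ascent on the Poisson likelihood.

    Parameters
    ----------
    cm : raw contact matrix.
    min_dist, max_dist : genomic-distance window (bp) of pairs entering the
        likelihood; defaults exclude the diagonal and keep everything else.
    max_iter, tol : outer-iteration cap and relative log-likelihood change
        threshold for convergence.
    n_bands : number of log-spaced distance bands sharing one H value.
    seed : reserved for tie-breaking; the algorithm is deterministic.
    """
    if cm.state != RAW:
        raise ValueError("estimate_cscore expects a raw contact matrix")
    n = cm.n_bins
    res = cm.bins.resolution
    mask = cm.mask & low_coverage_mask(cm.counts, min_coverage_frac)
    if mask.sum() < 3:
        raise ValueError("too few unmasked bins to fit a compartment model")
    lo = 1 if min_dist is None else max(1, int(np.ceil(min_dist / res)))
    hi = n - 1 if max_dist is None else min(n - 1, int(max_dist // res))
    if hi < lo:
        raise ValueError("empty distance window")

    offs = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    pair_w = (offs >= lo) & (offs <= hi) & np.outer(mask, mask)
    n_ij = cm.counts

    band_of_offset = _offset_bands(n, n_bands)
    band_mat = band_of_offset[offs]          # band id per pair
    n_band = band_of_offset.max() + 1

    # --- initialization ---------------------------------------------------
    C = np.clip(_eigenvector_init(cm, mask), -_C_BOUND, _C_BOUND)
    B = np.where(mask, 1.0, 0.0)
    # H from raw per-band means (B=1, C as initialized)
    Hb = np.ones(n_band)
    Hmat = np.ones((n, n))

    def plaid():
        return (1.0 + np.outer(C, C)) / 2.0

    def update_H():
        nonlocal Hb, Hmat
        base = np.where(pair_w, np.outer(B, B) * plaid(), 0.0)
        obs = np.where(pair_w, n_ij, 0.0)
        num = np.bincount(band_mat.ravel(), weights=obs.ravel(), minlength=n_band)
        den = np.bincount(band_mat.ravel(), weights=base.ravel(), minlength=n_band)
        with np.errstate(invalid="ignore", divide="ignore"):
            newH = np.where(den > 0, num / den, Hb)
        Hb = np.where(newH > 0, newH, Hb)
        Hmat = Hb[band_mat]

    def lam():
        return np.where(pair_w, np.outer(B, B) * Hmat * plaid(), 0.0)

    update_H()
    ll = _log_likelihood(n_ij, lam(), pair_w)
    trace = [ll]
    slack = 1e-9

    def backtrack(setter, old, new, ll_old):
        """Apply ``setter`` at full step, halving toward ``old`` until ll >= ll_old."""
        step = 1.0
        for _ in range(25):
            setter(old + step * (new - old))
            ll_new = _log_likelihood(n_ij, lam(), pair_w)
            if ll_new >= ll_old - slack * max(1.0, abs(ll_old)):
                return ll_new
            step *= 0.5
        setter(old)
        return ll_old

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # (1) closed-form H given B, C — exact conditional maximizer
        update_H()
        ll = _log_likelihood(n_ij, lam(), pair_w)

        # (2) B fixed-point (Poisson marginal matching), damped if needed
        M = np.where(pair_w, Hmat * plaid(), 0.0)
        denom = (M * B[None, :]).sum(axis=1)
        num = np.where(pair_w, n_ij, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            B_new = np.where((denom > 0) & mask, num / denom, B)
        B_new = np.where(B_new > 0, B_new, B)

        def set_B(v):
            nonlocal B
            B = np.where(mask, np.maximum(v, 1e-12), 0.0)

        ll = backtrack(set_B, B.copy(), B_new, ll)

        # (3) damped Jacobi sweeps toward each C_i's conditional optimum.
        # Per coordinate the conditional log-likelihood is concave
        # (sum of log(1 + c*C_j) terms minus a linear term), so a few
        # safeguarded 1-D Newton steps reach its maximizer; coordinates are
        # then moved together with damping and a global backtracking guard.
        obs = np.where(pair_w, n_ij, 0.0)

        def set_C(v):
            nonlocal C
            C = np.clip(np.where(mask, v, 0.0), -_C_BOUND, _C_BOUND)

        for _ in range(4):
            S = 0.5 * ((np.where(pair_w, np.outer(B, B) * Hmat, 0.0)) @ C)
            c = C.copy()
            for _ in range(5):
                D = 1.0 + c[:, None] * C[None, :]
                F = (obs * (C[None, :] / D)).sum(axis=1) - S
                Fp = -(obs * (C[None, :] ** 2 / D**2)).sum(axis=1)
                newton = np.where(Fp < -1e-12, -F / Fp, 0.0)
                c = np.clip(c + newton, -_C_BOUND, _C_BOUND)
            C_new = C + 0.6 * (c - C)
            ll_new = backtrack(set_C, C.copy(), C_new, ll)
            if ll_new - ll < 1e-10 * max(1.0, abs(ll)):
                ll = ll_new
                break
            ll = ll_new

        if ll < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise RuntimeError(
                f"log-likelihood decreased at iteration {it}: {trace[-1]:.6f} -> {ll:.6f}"
            )
        rel = abs(ll - trace[-1]) / max(1.0, abs(trace[-1]))
        trace.append(ll)
        if rel < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"cscore estimation hit max_iter={max_iter} (last rel change {rel:.3g})",
            RuntimeWarning,
        )

    h_full = np.zeros(n)
    h_full[1:] = Hb[band_of_offset[1:]]
    cscore = np.where(mask, C, np.nan)
    bias = np.where(mask, B, np.nan)
    return CscoreModel(
        bins=cm.bins,
        cscore=cscore,
        bias=bias,
        h_per_offset=h_full,
        mask=mask,
        log_likelihood=trace[-1],
        ll_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
    )


def orient_track(model: CscoreModel, reference: np.ndarray) -> CompartmentTrack:
    """Resolve the model's arbitrary global sign against an activity proxy.

    The likelihood is invariant under C -> -C, so A/B polarity must come from
    outside: gene density, expression coverage, or planted truth in tests.
    Flips the track iff its Pearson correlation with ``reference`` is negative;
    a near-zero or undefined correlation leaves the sign as-is with a warning.
    """
    reference = np.asarray(reference, dtype=float)
    c = model.cscore
    ok = np.isfinite(c) & np.isfinite(reference)
    if ok.sum() < 3 or np.std(reference[ok]) == 0 or np.std(c[ok]) == 0:
        warnings.warn("degenerate reference track; orientation left unchanged", RuntimeWarning)
        return CompartmentTrack(bins=model.bins, cscore=c.copy(), flipped=False)
    r = float(np.corrcoef(c[ok], reference[ok])[0, 1])
    if abs(r) < 0.05:
        warnings.warn(
            f"reference barely correlates with cscore (r={r:.3f}); orientation left unchanged",
            RuntimeWarning,
        )
        return CompartmentTrack(bins=model.bins, cscore=c.copy(), flipped=False)
    if r < 0:
        return CompartmentTrack(bins=model.bins, cscore=-c, flipped=True)
    return CompartmentTrack(bins=model.bins, cscore=c.copy(), flipped=False)


def write_track(track: CompartmentTrack, path, fmt: str = "bedgraph") -> None:
    df = track.to_frame()
    if fmt == "bedgraph":
        df[["chrom", "start", "end", "cscore"]].dropna().to_csv(
            path, sep="\t", header=False, index=False
        )
    else:
        df.to_csv(path, sep="\t", index=False)


def read_track(path) -> np.ndarray:
    """Read a bedGraph cscore track back as a dense per-bin array (NaN gaps)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "cscore"])
    res = int((df["end"] - df["start"]).mode().iloc[0])
    n = int(df["end"].max() // res)
    out = np.full(n, np.nan)
    out[(df["start"] // res).astype(int)] = df["cscore"].to_numpy()
    return out
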