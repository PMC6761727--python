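"""Per-sample local-likelihood smoothing of CpG methylation.

At each site a weighted quadratic is fit to beta over the smallest symmetric
window containing at least ``min_sites`` sites and spanning at least
``min_width`` bp; weights are tricube(distance / half-span) times read depth,
and the fit is evaluated at the site itself. This is the standard smoother
design for bisulfite data (wide windows for region detection); segmentation
callers use the same machinery with a 3-site window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CytosineMatrix

logger = logging.getLogger(__name__)


@dataclass
class SmoothedTrack:
    """Smoothed beta aligned to a CytosineMatrix's site table."""

    sites: pd.DataFrame
    values: np.ndarray           # (n_sites, n_samples), in [0, 1] or NaN
    samples: list[str]
    min_sites: int
    min_width: int
    degree: int


def _smooth_chrom(pos, y, cov, min_sites, min_width, degree):
    """Vectorised windowed weighted polynomial fit for one chromosome."""
    n = len(pos)
    if n == 0:
        return np.empty(0)
    m = min(min_sites, n)
    if n < min_sites:
        # too sparse to smooth: raw passthrough
        return y.copy()
    # symmetric-in-count windows, clipped at the ends (nearest m sites)
    k = (m - 1) // 2
    start = np.clip(np.arange(n) - k, 0, n - m)
    win = start[:, None] + np.arange(m)[None, :]
    d = (pos[win] - pos[:, None]).astype(float)
    h = np.maximum(np.abs(d).max(axis=1), min_width / 2.0)
    u = np.abs(d) / h[:, None]
    kern = np.clip(1 - u**3, 0, None) ** 3
    w = kern * cov[win]
    yw = y[win]
    missing = np.isnan(yw)
    w = np.where(missing, 0.0, w)
    yw = np.where(missing, 0.0, yw)

    p = degree + 1
    # normal equations: sum w d^(i+j) a_j = sum w d^i y
    powers = d[:, :, None] ** np.arange(2 * degree + 1)[None, None, :]
    S = np.einsum("nm,nmp->np", w, powers)          # moments 0..2*degree
    T = np.einsum("nm,nm,nmp->np", w, yw, powers[:, :, :p])
    A = np.empty((n, p, p))
    for i in range(p):
        for j in range(p):
            A[:, i, j] = S[:, i + j]
    # tiny ridge keeps degenerate windows (few distinct positions) solvable
    A += np.eye(p)[None] * 1e-9 * (1 + S[:, [0]][:, :, None] * np.eye(p)[None])
    out = np.full(n, np.nan)
    ok = S[:, 0] > 0
    if ok.any():
        try:
            sol = np.linalg.solve(A[ok], T[ok][:, :, None])[:, 0, 0]
        except np.linalg.LinAlgError:  # pragma: no cover - ridge should prevent
            sol = np.array([np.linalg.lstsq(A[i], T[i], rcond=None)[0][0]
                            for i in np.flatnonzero(ok)])
        out[ok] = sol
    return np.clip(out, 0.0, 1.0)


def smooth_sample(
    matrix: CytosineMatrix,
    sample: str,
    min_sites: int = 70,
    min_width: int = 1000,
    degree: int = 2,
) -> np.ndarray:
    """Smoothed beta for one sample; NaN where no covered site is in reach."""
    j = matrix.samples.index(sample)
    beta = matrix.beta()[:, j]
    cov = matrix.total[:, j].astype(float)
    out = np.empty(matrix.n_sites)
    for chrom, grp in matrix.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")  # strands interleave
        idx = idx[order]
        if len(idx) < min_sites:
            logger.warning("chrom %s has %d < %d sites: raw passthrough",
                           chrom, len(idx), min_sites)
        out[idx] = _smooth_chrom(pos[order], beta[idx], cov[idx],
                                 min_sites, min_width, degree)
    return out


def smooth_all(
    matrix: CytosineMatrix,
    min_sites: int = 70,
    min_width: int = 1000,
    degree: int = 2,
) -> SmoothedTrack:
    vals = np.column_stack([
        smooth_sample(matrix, s, min_sites, min_width, degree)
        for s in matrix.samples
    ])
    return SmoothedTrack(matrix.sites, vals, list(matrix.samples),
                         min_sites, min_width, degree)
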