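"""Per-sample methylome segmentation: PMDs, UMRs, LMRs, DMVs.

PMDs (partially methylated domains) are found by two-state decoding of a
windowed disorder statistic -- the fraction of CpGs in a sliding 101-site
window with intermediate raw methylation (0.3 < beta < 0.7) -- followed by a
100-kb length filter and removal of assembly-gap sequence (gaps labelled
heterochromatin are exempt, as PMDs are genuinely heterochromatic).

UMRs/LMRs are maximal runs of >= 4 consecutive CpGs whose (lightly) smoothed
beta falls below a calibrated cutoff; runs with >= 30 CpGs are UMRs
(promoter-scale islands), shorter runs LMRs (enhancer-scale). The cutoff is
calibrated against methylation-shuffled data at a target false discovery
percentage. DMVs (DNA methylation valleys) are the UMR subset with mean
methylation <= 0.15 and width >= 5 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CytosineMatrix
from . import intervals

logger = logging.getLogger(__name__)

PMD_WINDOW = 101
PMD_MIN_LENGTH = 100_000


@dataclass
class SegmentSet:
    """All segments called for one sample plus the calibration record."""

    sample_id: str
    regions: pd.DataFrame          # chrom,start,end,kind,pmeth,ncpg,width
    cutoff: float | None = None
    fdr_percent: float | None = None


def _runs(mask: np.ndarray):
    """(start, end) index pairs (end exclusive) of True runs."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def _viterbi_two_state(score: np.ndarray, mu0: float, mu1: float,
                       sd: float = 0.12, stay: float = 0.999) -> np.ndarray:
    """Decode disordered (1) vs ordered (0) states under Gaussian emissions.

    Fixed-parameter decode: deterministic, no EM. ``stay`` encodes that PMDs
    span hundreds of consecutive windows.
    """
    n = len(score)
    if n == 0:
        return np.zeros(0, dtype=np.int8)
    ll = np.empty((n, 2))
    for k, mu in enumerate((mu0, mu1)):
        ll[:, k] = -0.5 * ((score - mu) / sd) ** 2
    log_stay = np.log(stay)
    log_switch = np.log1p(-stay)
    dp = ll[0].copy()
    back = np.zeros((n, 2), dtype=np.int8)
    for i in range(1, n):
        for k in range(2):
            cand = dp + np.where(np.arange(2) == k, log_stay, log_switch)
            back[i, k] = int(np.argmax(cand))
            dp_k = cand[back[i, k]] + ll[i, k]
            if k == 0:
                new0 = dp_k
            else:
                new1 = dp_k
        dp = np.array([new0, new1])
    states = np.empty(n, dtype=np.int8)
    states[-1] = int(np.argmax(dp))
    for i in range(n - 2, -1, -1):
        states[i] = back[i + 1, states[i + 1]]
    return states


def call_pmds(
    matrix: CytosineMatrix,
    sample: str,
    window: int = PMD_WINDOW,
    min_length: int = PMD_MIN_LENGTH,
    gaps: pd.DataFrame | None = None,
    intermediate: tuple[float, float] = (0.3, 0.7),
) -> pd.DataFrame:
    """Partially methylated domains for one sample (0-based half-open)."""
    j = matrix.samples.index(sample)
    beta = matrix.beta()[:, j]
    rows = []
    for chrom, grp in matrix.sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy() - 1
        order = np.argsort(pos, kind="mergesort")
        pos, b = pos[order], beta[idx][order]
        if len(pos) < window:
            logger.warning("chrom %s: %d sites < %d-site PMD window", chrom,
                           len(pos), window)
            continue
        inter = pd.Series(np.where(np.isnan(b), np.nan,
                                   ((b > intermediate[0]) & (b < intermediate[1]))
                                   .astype(float)))
        score = inter.rolling(window, center=True, min_periods=window // 2) \
                     .mean().to_numpy()
        score = np.nan_to_num(score, nan=0.0)
        mu0 = float(np.quantile(score, 0.25))
        mu1 = max(float(np.quantile(score, 0.95)), mu0 + 0.25, 0.4)
        states = _viterbi_two_state(score, mu0, mu1)
        for a, z in _runs(states == 1):
            rows.append({"chrom": chrom, "start": int(pos[a]),
                         "end": int(pos[z - 1]) + 1})
    pmds = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if len(pmds):
        if gaps is not None and len(gaps):
            keep = gaps
            if "label" in gaps:
                keep = gaps[gaps["label"] != "heterochromatin"]
            pmds = intervals.subtract(pmds, keep[["chrom", "start", "end"]])
        pmds = pmds[(pmds["end"] - pmds["start"]) > min_length].reset_index(drop=True)
    pmds["kind"] = "PMD"
    return pmds


def _hypo_segments(values: np.ndarray, positions: np.ndarray, chroms: np.ndarray,
                   cutoff: float, min_cpgs: int, max_join_gap: int = 5000):
    """Maximal runs of consecutive sites below cutoff, per chromosome.

    Runs never span intersite gaps above ``max_join_gap`` (masked holes such
    as PMDs or assembly gaps would otherwise be bridged)."""
    segs = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        v = values[sel]
        p = positions[sel]
        below = np.where(np.isnan(v), False, v < cutoff)
        far = np.diff(p) > max_join_gap
        for a, z in _runs(below):
            cuts = [a] + [a + 1 + i for i in np.flatnonzero(far[a:z - 1])] + [z]
            for s, e in zip(cuts[:-1], cuts[1:]):
                if e - s >= min_cpgs:
                    segs.append((chrom, p[s] - 1, p[e - 1], e - s,
                                 float(np.nanmean(v[s:e]))))
    return segs


def calibrate_cutoff(
    values: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    m: float = 0.5,
    fdr_target: float = 10.0,
    pmd_mask: np.ndarray | None = None,
    grid: np.ndarray | None = None,
    min_cpgs: int = 4,
    n_shuffles: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Choose the least stringent hypomethylation cutoff with FDR <= target.

    FDR(c) = 100 * (#segments in methylation-shuffled data) / (#observed
    segments), evaluated on a cutoff grid below ``m``; the shuffle permutes
    the smoothed values across sites (one shuffle, seeded). PMD sites are
    masked out first. Raises if no cutoff reaches the target.
    """
    if grid is None:
        grid = np.round(np.arange(0.02, m + 1e-9, 0.02), 4)
    grid = grid[grid <= m]
    keep = ~pmd_mask if pmd_mask is not None else np.ones(len(values), bool)
    v = values[keep]
    p = positions[keep]
    c = chroms[keep]
    rng = np.random.default_rng(seed)
    nulls = [rng.permutation(v) for _ in range(n_shuffles)]
    best = None
    for cutoff in grid:
        n_obs = len(_hypo_segments(v, p, c, cutoff, min_cpgs))
        if n_obs == 0:
            continue
        n_null = np.mean([len(_hypo_segments(vn, p, c, cutoff, min_cpgs))
                          for vn in nulls])
        fdr = 100.0 * n_null / n_obs
        if fdr <= fdr_target:
            best = (float(cutoff), fdr)
    if best is None:
        raise ValueError(
            "no methylation cutoff reaches the FDR target; relax fdr_target "
            "or inspect whether hypomethylated structure exists"
        )
    return best


def call_umrs_lmrs(
    values: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    cutoff: float,
    umr_min_sites: int = 30,
    min_cpgs: int = 4,
    boundary_extension: int = 500,
) -> pd.DataFrame:
    """UMR/LMR segments from smoothed beta: runs of >= ``min_cpgs`` sites
    below ``cutoff``; >= ``umr_min_sites`` CpGs -> UMR, else LMR.

    Segment boundaries are extended to the midpoint between the terminal
    segment CpG and its (above-cutoff) neighbour, capped at
    ``boundary_extension`` bp, since hypomethylation plausibly extends into
    the unsampled gap."""
    segs = _hypo_segments(values, positions, chroms, cutoff, min_cpgs)
    rows = []
    for chrom, s, e, n, pm in segs:
        sel = chroms == chrom
        p = positions[sel]
        i = np.searchsorted(p - 1, s)          # index of first segment site
        j = np.searchsorted(p, e) - 1          # index of last segment site
        ext_l = min((p[i] - p[i - 1]) // 2, boundary_extension) if i > 0 else 0
        ext_r = min((p[j + 1] - p[j]) // 2, boundary_extension) if j + 1 < len(p) else 0
        rows.append({"chrom": chrom, "start": int(s - ext_l),
                     "end": int(e + ext_r), "ncpg": n, "pmeth": pm,
                     "kind": "UMR" if n >= umr_min_sites else "LMR"})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ncpg", "pmeth", "kind"])
    df["width"] = df["end"] - df["start"]
    return df


def call_dmvs(umrs: pd.DataFrame, max_pmeth: float = 0.15,
              min_width: int = 5000) -> pd.DataFrame:
    """DMVs: UMRs with pmeth <= 0.15 and width >= 5 kb (both inclusive)."""
    u = umrs[umrs["kind"] == "UMR"]
    dmv = u[(u["pmeth"] <= max_pmeth) & (u["width"] >= min_width)].copy()
    dmv["kind"] = "DMV"
    return dmv.reset_index(drop=True)


def segment_sample(
    matrix: CytosineMatrix,
    sample: str,
    smoothed: np.ndarray | None = None,
    gaps: pd.DataFrame | None = None,
    m: float = 0.5,
    fdr_target: float = 10.0,
    umr_min_sites: int = 30,
    seed: int = 0,
) -> SegmentSet:
    """Full per-sample segmentation: PMDs, calibrated UMR/LMR call, DMVs.

    ``smoothed`` defaults to a 3-CpG local fit of this sample's beta (the
    light smoothing conventional for segmentation callers).
    """
    from .smoothing import smooth_sample

    if smoothed is None:
        # light tricube-weighted running mean (a few CpGs), the convention
        # for segmentation callers; region detection uses far wider windows
        smoothed = smooth_sample(matrix, sample, min_sites=5, min_width=100,
                                 degree=0)
    positions = matrix.sites["pos"].to_numpy()
    chroms = matrix.sites["chrom"].to_numpy()
    pmds = call_pmds(matrix, sample, gaps=gaps)
    pmd_mask = np.zeros(matrix.n_sites, dtype=bool)
    for _, r in pmds.iterrows():
        pmd_mask |= ((chroms == r["chrom"]) & (positions - 1 >= r["start"])
                     & (positions - 1 < r["end"]))
    cutoff, fdr = calibrate_cutoff(smoothed, positions, chroms, m=m,
                                   fdr_target=fdr_target, pmd_mask=pmd_mask,
                                   seed=seed)
    keep = ~pmd_mask
    uml = call_umrs_lmrs(smoothed[keep], positions[keep], chroms[keep],
                         cutoff, umr_min_sites=umr_min_sites)
    dmvs = call_dmvs(uml)
    pmds = pmds.copy()
    pmds["width"] = pmds["end"] - pmds["start"]
    regions = pd.concat([uml, dmvs, pmds], ignore_index=True)
    return SegmentSet(sample, regions, cutoff=cutoff, fdr_percent=fdr)
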