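"""Overlap and enrichment statistics for region and gene sets.

Chromatin-state composition compares the base-pair share of each state
inside a region set to its genome-wide share (log2 enrichment). Region and
gene-set tests are Fisher exact tests against an explicit background -- for
region tests the background is the full set of CpG clusters the region scan
considered, for gene sets all expressed genes. Both the sample odds ratio
(ad/bc) and the conditional-MLE odds ratio are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import intervals


def state_composition(regions: pd.DataFrame, state_track: pd.DataFrame,
                      state_col: str = "state") -> pd.DataFrame:
    """Per-state base-pair proportion inside ``regions`` vs the genome.

    ``state_track`` must tile the annotated span; regions reaching outside
    it are clipped (with a warning via the clipped base count column).
    """
    span = state_track.groupby("chrom").agg(start=("start", "min"),
                                            end=("end", "max")).reset_index()
    clipped = intervals.intersect(regions, span)
    total_in = intervals.total_length(clipped)
    genome = int((state_track["end"] - state_track["start"]).sum())
    rows = []
    for state, grp in state_track.groupby(state_col):
        bg_bases = int((grp["end"] - grp["start"]).sum())
        in_bases = intervals.total_length(intervals.intersect(clipped, grp)) \
            if total_in else 0
        obs = in_bases / total_in if total_in else np.nan
        bg = bg_bases / genome
        with np.errstate(divide="ignore"):
            l2 = np.log2(obs / bg) if (total_in and bg > 0) else np.nan
        rows.append({"state": state, "observed_prop": obs, "background_prop": bg,
                     "log2_enrichment": l2,
                     "region_bases": in_bases, "background_bases": bg_bases})
    out = pd.DataFrame(rows)
    out.attrs["clipped_bases"] = intervals.total_length(regions) - total_in
    return out


def _fisher(table: np.ndarray) -> dict:
    a, b = table[0]
    c, d = table[1]
    if b * c == 0 or a * d == 0:
        # Haldane-Anscombe correction for zero margins, flagged
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        flagged = True
    else:
        orr = (a * d) / (b * c)
        flagged = False
    cmle, p = stats.fisher_exact(table)
    return {"odds_ratio": float(orr), "odds_ratio_cmle": float(cmle),
            "p": float(p), "zero_margin": flagged,
            "a": int(a), "b": int(b), "c": int(c), "d": int(d)}


def region_fisher(hits: pd.DataFrame, targets: pd.DataFrame,
                  background: pd.DataFrame) -> dict:
    """Fisher test of hit regions overlapping a target track, against a
    background region universe containing the hits.

    The 2x2 table counts background regions by (overlaps target) x (is hit).
    Hits are matched into the background by exact (chrom, start, end).
    """
    key = ["chrom", "start", "end"]
    bg = background[key].drop_duplicates().reset_index(drop=True)
    hit_keys = set(map(tuple, hits[key].itertuples(index=False)))
    bg_keys = set(map(tuple, bg.itertuples(index=False)))
    if not hit_keys <= bg_keys:
        raise ValueError("hits must be a subset of the background regions")
    is_hit = np.array([tuple(r) in hit_keys for r in bg.itertuples(index=False)])
    ov = intervals.overlaps_any(bg, targets)
    table = np.array([
        [np.sum(ov & is_hit), np.sum(~ov & is_hit)],
        [np.sum(ov & ~is_hit), np.sum(~ov & ~is_hit)],
    ])
    return _fisher(table)


def gene_set_fisher(hit_genes, set_genes, background_genes) -> dict:
    """Fisher test of hit genes against a gene set; both are intersected
    with the expressed-gene background first."""
    bg = set(background_genes)
    hits = set(hit_genes) & bg
    gset = set(set_genes) & bg
    if not gset:
        raise ValueError("gene set empty after intersecting with background")
    table = np.array([
        [len(hits & gset), len(hits - gset)],
        [len(gset - hits), len(bg - hits - gset)],
    ])
    return _fisher(table)


def adjust_family(results: list[dict]) -> pd.DataFrame:
    """BH adjustment across one named batch of Fisher results."""
    df = pd.DataFrame(results)
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    return df


def base_overlap_fraction(a_regions: pd.DataFrame, b_regions: pd.DataFrame) -> float:
    """Fraction of merged ``a`` bases covered by merged ``b`` bases."""
    if len(a_regions) == 0:
        raise ValueError("empty query region set")
    a_len = intervals.total_length(a_regions)
    inter = intervals.total_length(intervals.intersect(a_regions, b_regions)) \
        if len(b_regions) else 0
    return inter / a_len


def hypergeom_p(table: np.ndarray) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Independent of scipy's implementation; used as an exact cross-check on
    small tables.
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    rv = stats.hypergeom(n, row1, col1)
    support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
    probs = rv.pmf(support)
    cutoff = rv.pmf(a) * (1 + 1e-7)
    return float(probs[probs <= cutoff].sum())
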