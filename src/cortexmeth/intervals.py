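"""Interval arithmetic on 0-based half-open regions held in DataFrames.

All functions accept/return DataFrames with at least ``chrom``, ``start``,
``end`` columns. Overlapping or bookended intervals are merged before any
set operation, so results are always disjoint and sorted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def make_regions(chrom, start, end, kind: str | None = None, **attrs) -> pd.DataFrame:
    df = pd.DataFrame({"chrom": chrom, "start": np.asarray(start, dtype=np.int64),
                       "end": np.asarray(end, dtype=np.int64)})
    if (df["end"] <= df["start"]).any():
        raise ValueError("regions require end > start")
    if kind is not None:
        df["kind"] = kind
    for k, v in attrs.items():
        df[k] = v
    return df


def merge(regions: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: merge overlapping/adjacent, per chromosome."""
    if len(regions) == 0:
        return regions[["chrom", "start", "end"]].copy()
    parts = []
    for chrom, grp in regions.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        run_end = np.maximum.accumulate(e)
        new = np.concatenate([[True], s[1:] > run_end[:-1]])
        idx = np.flatnonzero(new)
        starts = s[idx]
        ends = run_end[np.append(idx[1:], len(s)) - 1]
        parts.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(parts, ignore_index=True)


def total_length(regions: pd.DataFrame) -> int:
    m = merge(regions)
    return int((m["end"] - m["start"]).sum())


def _per_chrom(a: pd.DataFrame, b: pd.DataFrame):
    chroms = sorted(set(a["chrom"]).union(b["chrom"]))
    for c in chroms:
        yield c, a[a["chrom"] == c], b[b["chrom"] == c]


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Intersection of the merged base sets of ``a`` and ``b``."""
    a, b = merge(a), merge(b)
    parts = []
    for chrom, ga, gb in _per_chrom(a, b):
        if len(ga) == 0 or len(gb) == 0:
            continue
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        i = j = 0
        rows = []
        while i < len(sa) and j < len(sb):
            lo = max(sa[i], sb[j])
            hi = min(ea[i], eb[j])
            if lo < hi:
                rows.append((lo, hi))
            if ea[i] < eb[j]:
                i += 1
            else:
                j += 1
        if rows:
            arr = np.array(rows)
            parts.append(pd.DataFrame({"chrom": chrom, "start": arr[:, 0], "end": arr[:, 1]}))
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(parts, ignore_index=True)


def subtract(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Bases of ``a`` not covered by ``b`` (both merged first)."""
    a = merge(a)
    if len(b) == 0:
        return a
    b = merge(b)
    parts = []
    for chrom, ga, gb in _per_chrom(a, b):
        if len(ga) == 0:
            continue
        sb, eb = gb["start"].to_numpy(), gb["end"].to_numpy()
        rows = []
        for s, e in zip(ga["start"], ga["end"]):
            cur = s
            for bs, be in zip(sb, eb):
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    rows.append((cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                rows.append((cur, e))
        if rows:
            arr = np.array(rows)
            parts.append(pd.DataFrame({"chrom": chrom, "start": arr[:, 0], "end": arr[:, 1]}))
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(parts, ignore_index=True)


def jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Base-level Jaccard index |a & b| / |a | b| of two region sets."""
    inter = total_length(intersect(a, b)) if len(a) and len(b) else 0
    union = total_length(a) + total_length(b) - inter
    if union == 0:
        return float("nan")
    return inter / union


def overlaps_any(query: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Boolean per query region: does it overlap any (merged) target base?"""
    t = merge(targets)
    out = np.zeros(len(query), dtype=bool)
    for chrom, grp in t.groupby("chrom"):
        qm = (query["chrom"] == chrom).to_numpy()
        if not qm.any():
            continue
        qs = query.loc[qm, "start"].to_numpy()
        qe = query.loc[qm, "end"].to_numpy()
        ts = grp["start"].to_numpy()
        te = grp["end"].to_numpy()
        # target starting before query end, with end after query start
        k = np.searchsorted(ts, qe, side="left")
        hit = (k > 0) & (te[np.maximum(k - 1, 0)] > qs)
        # the previous target may end before qs while a later one overlaps; since
        # targets are merged+disjoint, checking the last one starting before qe suffices
        out[np.flatnonzero(qm)] = hit
    return out
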