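"""Cytosine-level methylation vs expression association.

The scan mirrors a cis-QTL design: for every (cytosine, expression feature)
pair within 1 kb, expression -- log2(FPKM+1) for genes/exons, raw PSI for
splice events -- is regressed on beta across matched donors; pairs passing a
genome-wide p threshold (default 5e-4) are retained and BH-adjusted within
feature type. CpGs near significant CpH hits are rescanned at a marginal
threshold (default 0.01) to classify features as CpH-exclusive vs shared.
Post-filters drop extreme-methylation records (fewer than 11 donors with
beta > 0 or beta < 1), non-protein-coding features and infinite t, and an
age-adjusted refit flags associations explained away by age.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CytosineMatrix

GENE_MEAN_FPKM_MIN = 0.22
EXON_MEAN_FPKM_MIN = 0.26
PSI_MIN_DENOMINATOR = 10


# ---------------------------------------------------------------------------
# expression preparation

def filter_expression(
    raw: pd.DataFrame,
    feature_type: str,
    sample_cols: list[str],
    min_denominator_col: str = "min_denominator",
) -> pd.DataFrame:
    """Expression filters and transforms.

    Genes are kept iff mean FPKM > 0.22, exons iff > 0.26 (strict), both then
    transformed to log2(FPKM + 1); PSI events are kept iff their splice
    denominator reached 10 reads, values left raw in [0, 1].
    """
    df = raw.copy()
    vals = df[sample_cols].to_numpy(dtype=float)
    if feature_type in ("gene", "exon"):
        cut = GENE_MEAN_FPKM_MIN if feature_type == "gene" else EXON_MEAN_FPKM_MIN
        keep = vals.mean(axis=1) > cut
        df = df.loc[keep].copy()
        df[sample_cols] = np.log2(vals[keep] + 1.0)
    elif feature_type == "psi":
        if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
            raise ValueError("PSI values must lie in [0, 1]")
        if min_denominator_col in df:
            df = df.loc[df[min_denominator_col] >= PSI_MIN_DENOMINATOR].copy()
    else:
        raise ValueError(f"unknown feature type {feature_type!r}")
    return df.reset_index(drop=True)


def feature_windows(
    features: pd.DataFrame,
    feature_type: str,
    promoter: int = 2000,
    flank: int = 5000,
    exon_pad: int = 500,
    junction_pad: int = 50,
) -> pd.DataFrame:
    """Windows used for group-mean correlations: promoter (2 kb upstream of
    the start), gene body, exon +/- 500 bp, junction 50 bp into each intron,
    flanking +/- 5 kb beyond the span (promoter excluded)."""
    rows = []
    for _, f in features.iterrows():
        s, e = int(f["start"]), int(f["end"])
        fid = f.get("feature_id", f.get("gene_id", f.get("exon_id", f.get("event_id"))))
        if feature_type == "gene":
            rows.append((fid, "promoter", max(s - promoter, 0), s))
            rows.append((fid, "gene body", s, e))
            rows.append((fid, "flanking", max(s - flank, 0), max(s - promoter, 0)))
            rows.append((fid, "flanking", e, e + flank))
        elif feature_type == "exon":
            rows.append((fid, "exon", max(s - exon_pad, 0), e + exon_pad))
        else:
            rows.append((fid, "junction", max(s - junction_pad, 0), s))
            rows.append((fid, "junction", e, e + junction_pad))
    out = pd.DataFrame(rows, columns=["feature_id", "window", "start", "end"])
    return out[out["end"] > out["start"]].reset_index(drop=True)


def group_mean_correlation(
    matrix: CytosineMatrix,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    windows: pd.DataFrame,
    sample_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation, across features, of group-mean methylation in a
    window with group-mean expression; groups are age group x cell fraction.
    Features whose window holds no cytosine are skipped."""
    if sample_cols is None:
        sample_cols = [s for s in expr.columns if s in matrix.samples]
    sub = meta[meta["sample_id"].isin(sample_cols)]
    groups = sub.groupby(["age_group", "cell_fraction"], observed=True)
    beta = matrix.beta()
    pos0 = matrix.sites["pos"].to_numpy() - 1
    rows = []
    for (age_group, frac), g in groups:
        cols = [matrix.samples.index(s) for s in g["sample_id"]]
        ecols = [s for s in g["sample_id"]]
        for wkind, wins in windows.groupby("window"):
            mvals, evals = [], []
            for _, w in wins.iterrows():
                sel = (pos0 >= w["start"]) & (pos0 < w["end"])
                if not sel.any():
                    continue
                feat = expr[expr["feature_id"] == w["feature_id"]]
                if len(feat) == 0:
                    continue
                mvals.append(np.nanmean(beta[np.ix_(sel.nonzero()[0], cols)]))
                evals.append(float(feat[ecols].to_numpy(dtype=float).mean()))
            if len(mvals) > 2:
                rho, p = stats.spearmanr(mvals, evals)
            else:
                rho, p = np.nan, np.nan
            rows.append({"window": wkind, "age_group": age_group,
                         "cell_fraction": frac, "rho": rho, "p": p,
                         "n_features": len(mvals)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cis scan

def _regress(y: np.ndarray, x: np.ndarray):
    """Simple linear regression of y on x; returns slope, t, p, r."""
    n = len(x)
    sx = x.std(ddof=0)
    sy = y.std(ddof=0)
    if sx == 0 or sy == 0 or n < 4:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    df = n - 2
    denom = 1 - r * r
    t = np.inf * np.sign(r) if denom <= 0 else r * np.sqrt(df / denom)
    p = 0.0 if np.isinf(t) else 2 * stats.t.sf(abs(t), df)
    slope = r * sy / sx
    return slope, float(t), float(p), r


def cis_scan(
    matrix: CytosineMatrix,
    expr: pd.DataFrame,
    features: pd.DataFrame,
    donors: list[str],
    window: int = 1000,
    p_threshold: float = 5e-4,
    feature_type: str = "gene",
    id_col: str = "feature_id",
) -> pd.DataFrame:
    """Regress expression on beta for every (cytosine, feature) pair within
    ``window`` bp (closed: a cytosine exactly at the window edge is tested).
    Keeps pairs with p < ``p_threshold``; BH q within the scan."""
    cols = [matrix.samples.index(d) for d in donors]
    beta = matrix.beta()[:, cols]
    pos0 = matrix.sites["pos"].to_numpy() - 1
    sites = matrix.sites
    evals = expr.set_index(id_col)
    rows = []
    n_tested = 0
    for _, f in features.iterrows():
        fid = f[id_col] if id_col in f else f.get("feature_id")
        if fid not in evals.index:
            continue
        y = evals.loc[fid, donors].to_numpy(dtype=float)
        # closed window: a cytosine exactly ``window`` bp from the nearest
        # feature base is still tested (end is half-open, hence end - 1)
        lo, hi = int(f["start"]) - window, int(f["end"]) - 1 + window
        cand = np.flatnonzero((sites["chrom"].to_numpy() == f["chrom"])
                              & (pos0 >= lo) & (pos0 <= hi))
        n_tested += len(cand)
        for i in cand:
            x = beta[i]
            ok = ~np.isnan(x)
            if ok.sum() < 4:
                continue
            res = _regress(y[ok], x[ok])
            if res is None:
                continue
            slope, t, p, r = res
            if p >= p_threshold:
                continue
            b = x[ok]
            rows.append({
                "feature_id": fid, "feature_type": feature_type,
                "gene_id": f.get("gene_id", fid),
                "chrom": sites["chrom"].iat[i], "pos": int(sites["pos"].iat[i]),
                "context": sites["context"].iat[i],
                "trinucleotide": sites["trinucleotide"].iat[i],
                "site_index": int(i),
                "slope": slope, "t": t, "p": p,
                "n": int(ok.sum()),
                "n_nonzero_meth": int((b > 0).sum()),
                "n_nonone_meth": int((b < 1).sum()),
                "expr_change": slope * float(b.max() - b.min()),
            })
    out = pd.DataFrame(rows, columns=[
        "feature_id", "feature_type", "gene_id", "chrom", "pos", "context",
        "trinucleotide", "site_index", "slope", "t", "p", "n",
        "n_nonzero_meth", "n_nonone_meth", "expr_change"])
    if len(out):
        # BH within the scan, counting every tested pair: the kept rows are
        # exactly the smallest-p subset of n_tested tests, so ranks among the
        # kept rows equal ranks among all tests
        p = out["p"].to_numpy()
        order = np.argsort(p)
        q_sorted = p[order] * n_tested / np.arange(1, len(p) + 1)
        q_sorted = np.minimum(np.minimum.accumulate(q_sorted[::-1])[::-1], 1.0)
        q = np.empty_like(q_sorted)
        q[order] = q_sorted
        out["q"] = q
    else:
        out["q"] = pd.Series(dtype=float)
    out.attrs["n_tested"] = n_tested
    return out


def marginal_cpg_rescue(
    cph_hits: pd.DataFrame,
    matrix: CytosineMatrix,
    expr: pd.DataFrame,
    features: pd.DataFrame,
    donors: list[str],
    window: int = 1000,
    p_marginal: float = 0.01,
    id_col: str = "feature_id",
) -> pd.DataFrame:
    """Rescan CpGs within +/- ``window`` of each significant CpH hit against
    the same feature at the marginal threshold; classify each CpH-hit feature
    as 'shared' (a marginal CpG association exists) or 'CpH-exclusive'."""
    cols = [matrix.samples.index(d) for d in donors]
    beta = matrix.beta()[:, cols]
    pos0 = matrix.sites["pos"].to_numpy() - 1
    is_cpg = (matrix.sites["context"] == "CpG").to_numpy()
    evals = expr.set_index(id_col)
    feat_ix = features.set_index(id_col)
    marginal_rows = []
    classification = {}
    for (fid), hits in cph_hits.groupby("feature_id"):
        if fid not in evals.index:
            continue
        y = evals.loc[fid, donors].to_numpy(dtype=float)
        found = False
        for _, h in hits.iterrows():
            center = int(h["pos"]) - 1
            cand = np.flatnonzero(is_cpg & (np.abs(pos0 - center) <= window)
                                  & (matrix.sites["chrom"].to_numpy() == h["chrom"]))
            for i in cand:
                x = beta[i]
                ok = ~np.isnan(x)
                if ok.sum() < 4:
                    continue
                res = _regress(y[ok], x[ok])
                if res is None:
                    continue
                slope, t, p, _ = res
                if p < p_marginal:
                    found = True
                    marginal_rows.append({
                        "feature_id": fid, "cph_pos": int(h["pos"]),
                        "pos": int(matrix.sites["pos"].iat[i]),
                        "slope": slope, "t": t, "p": p, "label": "marginal",
                    })
        classification[fid] = "shared" if found else "CpH-exclusive"
    out = pd.DataFrame(marginal_rows)
    cls = pd.Series(classification, name="classification")
    cls.index.name = "feature_id"
    return out, cls


def filter_associations(
    records: pd.DataFrame,
    features: pd.DataFrame | None = None,
    min_nonzero: int = 11,
    min_nonone: int = 11,
) -> pd.DataFrame:
    """Drop extreme-methylation records (too few donors with beta > 0 or
    beta < 1), non-protein-coding features, and infinite t statistics."""
    keep = (records["n_nonzero_meth"] >= min_nonzero) \
        & (records["n_nonone_meth"] >= min_nonone) \
        & np.isfinite(records["t"])
    if features is not None and "protein_coding" in features:
        coding = set(features.loc[features["protein_coding"], "gene_id"])
        keep &= records["gene_id"].isin(coding)
    return records.loc[keep].reset_index(drop=True)


def age_confound_check(
    records: pd.DataFrame,
    matrix: CytosineMatrix,
    expr_by_type: dict[str, pd.DataFrame],
    meta: pd.DataFrame,
    donors: list[str],
    id_col: str = "feature_id",
) -> pd.DataFrame:
    """Refit expression ~ beta + age per record; a record is age-confounded
    when its methylation coefficient is no longer FDR < 5% within the
    rechecked set. Collinear beta/age (|r| > 0.999) is flagged directly."""
    cols = [matrix.samples.index(d) for d in donors]
    beta = matrix.beta()[:, cols]
    age = meta.set_index("sample_id").loc[donors, "age"].to_numpy(dtype=float)
    pvals = np.ones(len(records))
    collinear = np.zeros(len(records), dtype=bool)
    for k, (_, rec) in enumerate(records.iterrows()):
        expr = expr_by_type[rec["feature_type"]].set_index(id_col)
        y = expr.loc[rec["feature_id"], donors].to_numpy(dtype=float)
        x = beta[int(rec["site_index"])]
        ok = ~np.isnan(x)
        xs, ys, ag = x[ok], y[ok], age[ok]
        if xs.std() == 0 or ag.std() == 0:
            collinear[k] = True
            continue
        if abs(np.corrcoef(xs, ag)[0, 1]) > 0.999:
            collinear[k] = True
            continue
        X = np.column_stack([np.ones_like(xs), xs, ag])
        coef, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
        resid = ys - X @ coef
        df = len(xs) - 3
        s2 = (resid**2).sum() / df
        se = np.sqrt(s2 * np.linalg.pinv(X.T @ X)[1, 1])
        tval = coef[1] / se if se > 0 else np.inf
        pvals[k] = 2 * stats.t.sf(abs(tval), df)
    q = multipletests(pvals, method="fdr_bh")[1]
    out = records.copy()
    out["age_adjusted_p"] = pvals
    out["age_confounded"] = (q >= 0.05) | collinear
    return out


# ---------------------------------------------------------------------------
# annotation and summary

def annotate_records(records: pd.DataFrame, genes: pd.DataFrame,
                     promoter: int = 2000, flank: int = 5000) -> pd.DataFrame:
    """Locate each cytosine relative to its gene: promoter, gene body, or
    flanking (within 5 kb outside the span)."""
    gx = genes.set_index("gene_id")
    where = []
    for _, r in records.iterrows():
        g = gx.loc[r["gene_id"]]
        p = int(r["pos"]) - 1
        if g["start"] - promoter <= p < g["start"]:
            where.append("promoter")
        elif g["start"] <= p < g["end"]:
            where.append("gene body")
        else:
            where.append("flanking")
    out = records.copy()
    out["annotation"] = where
    return out


def summarize_associations(records: pd.DataFrame,
                           de_flags: pd.DataFrame | None = None) -> pd.DataFrame:
    """Table-1-style summary per (feature type, context family, direction):
    counts, unique cytosines/features, mean donors with beta > 0 and < 1,
    mean |expression change|, and annotation/context/DE proportions."""
    rec = records.copy()
    rec["meth_type"] = np.where(rec["context"] == "CpG", "CpG", "CpH")
    rec["direction"] = np.where(rec["slope"] > 0, "Up", "Down")
    if de_flags is not None:
        rec = rec.merge(de_flags, on="gene_id", how="left")
        rec["de_status"] = rec["de_status"].fillna("none")
    else:
        rec["de_status"] = "none"
    rows = []
    for (ftype, mtype, direction), g in rec.groupby(
            ["feature_type", "meth_type", "direction"]):
        row = {
            "feature_type": ftype, "meth_type": mtype, "direction": direction,
            "n": len(g),
            "n_unique_c": g[["chrom", "pos"]].drop_duplicates().shape[0],
            "n_unique_features": g["feature_id"].nunique(),
            "mean_n_meth_gt0": float(g["n_nonzero_meth"].mean()),
            "mean_n_meth_lt1": float(g["n_nonone_meth"].mean()),
            "mean_expr_change": float(g["expr_change"].abs().mean()),
            "prop_age_confounded": float(g.get("age_confounded",
                                               pd.Series(False, index=g.index)).mean()),
            "prop_promoter": float((g["annotation"] == "promoter").mean()),
            "prop_gene_body": float((g["annotation"] == "gene body").mean()),
            "prop_flanking": float((g["annotation"] == "flanking").mean()),
            "prop_chg": float((g["context"] == "CHG").mean()),
            "prop_chh": float((g["context"] == "CHH").mean()),
            "prop_de_glia": float((g["de_status"] == "glia").mean()),
            "prop_de_neuron": float((g["de_status"] == "neuron").mean()),
            "prop_no_de": float((g["de_status"] == "none").mean()),
        }
        rows.append(row)
    return pd.DataFrame(rows)
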