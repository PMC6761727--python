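"""Developmental-trajectory decomposition of interaction DMRs and
context-stratified autocorrelation of methylation levels.

Each trajectory DMR is summarised by its mean per-year methylation change in
glia and in neurons (from per-cytosine age fits within each fraction); the
(glia slope, neuron slope) plane is partitioned by k-means into archetypes
such as "increasing neuronal, static glial". Model size is chosen by the
k-means AIC heuristic AIC(k) = WSS + 2 k d on standardised features.

Autocorrelation is the standard biased ACF of the beta sequence in position
order, computed inside 1-kb clusters (genome-wide scope) or inside given
regions, then averaged across clusters and across the samples of each cell
fraction. Lags are in site index, proportional to genomic distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .core import CytosineMatrix, cluster_positions
from .dmr import DesignSpec, fit_sitewise

logger = logging.getLogger(__name__)


def _sites_in_region(sites: pd.DataFrame, region) -> np.ndarray:
    pos0 = sites["pos"].to_numpy() - 1
    return np.flatnonzero((sites["chrom"].to_numpy() == region["chrom"])
                          & (pos0 >= region["start"]) & (pos0 < region["end"]))


def compute_trajectory_features(
    regions: pd.DataFrame,
    matrix: CytosineMatrix,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region mean age coefficient by cell fraction.

    Age slopes are fitted per cytosine within each fraction's samples
    (beta ~ age) and averaged over the region's cytosines; the interaction
    coefficient from the full two-fraction model is averaged the same way.
    """
    beta = matrix.beta()
    design_age = DesignSpec("age_only", "age")
    design_int = DesignSpec("age_by_cell_interaction", "age:cell")
    frac_fits = {}
    site_means = np.nanmean(beta, axis=1)
    filled = np.where(np.isnan(beta), site_means[:, None], beta)
    for frac in ("glia", "neuron"):
        sel = (meta["cell_fraction"] == frac).to_numpy()
        frac_fits[frac] = fit_sitewise(filled[:, sel], meta[sel], design_age)["coef"].to_numpy()
    both = meta["cell_fraction"].isin(["glia", "neuron"]).to_numpy()
    inter = fit_sitewise(filled[:, both], meta[both], design_int)["coef"].to_numpy()

    rows = []
    for i, region in regions.iterrows():
        idx = _sites_in_region(matrix.sites, region)
        if len(idx) == 0:
            raise ValueError(f"region {i} contains no tested cytosine")
        rows.append({
            "region": i,
            "glia_slope": float(frac_fits["glia"][idx].mean()),
            "neuron_slope": float(frac_fits["neuron"][idx].mean()),
            "interaction": float(inter[idx].mean()),
            "ncpg": len(idx),
        })
    return pd.DataFrame(rows).set_index("region")


def standardize(features: pd.DataFrame, cols=("glia_slope", "neuron_slope")) -> np.ndarray:
    x = features.loc[:, list(cols)].to_numpy(dtype=float)
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)


def kmeans_groups(
    features: pd.DataFrame,
    k: int = 6,
    n_starts: int = 100,
    seed: int = 0,
    cols=("glia_slope", "neuron_slope"),
) -> dict:
    """Best-of-``n_starts`` Lloyd k-means on the slope plane.

    Returns labels (1..k), centroids, within-cluster SS, and a semantic name
    per group ("increasing glial / decreasing neuronal", ...) assigned by the
    sign pattern of each centroid (|slope| below 10% of the largest centroid
    slope counts as static).
    """
    x = features.loc[:, list(cols)].to_numpy(dtype=float)
    if len(x) < k:
        raise ValueError(f"k = {k} exceeds the {len(x)} available regions")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed,
                algorithm="lloyd").fit(x)
    centroids = km.cluster_centers_
    thresh = 0.10 * np.abs(centroids).max()

    def word(v):
        if abs(v) < thresh:
            return "static"
        return "increasing" if v > 0 else "decreasing"

    names = [f"{word(c[0])} glial / {word(c[1])} neuronal" for c in centroids]
    return {
        "labels": km.labels_ + 1,
        "centroids": centroids,
        "wss": float(km.inertia_),
        "names": names,
    }


def select_k_aic(features_standardized: np.ndarray, k_range=range(1, 11),
                 n_starts: int = 25, seed: int = 0) -> pd.DataFrame:
    """k-means AIC curve on standardised features: AIC(k) = WSS + 2 k d.

    The penalty 2kd per extra centroid stops adding clusters once the
    marginal WSS reduction falls below it; the argmin row is flagged.
    """
    x = np.asarray(features_standardized, dtype=float)
    d = x.shape[1]
    rows = []
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed,
                    algorithm="lloyd").fit(x)
        rows.append({"k": k, "wss": float(km.inertia_),
                     "aic": float(km.inertia_) + 2.0 * k * d})
    out = pd.DataFrame(rows)
    out["best"] = out["aic"] == out["aic"].min()
    return out


def effect_ratio(features: pd.DataFrame) -> float:
    """median |neuron slope| / median |glia slope| across regions."""
    if len(features) == 0:
        raise ValueError("no trajectory features")
    num = float(np.median(np.abs(features["neuron_slope"])))
    den = float(np.median(np.abs(features["glia_slope"])))
    if den == 0:
        logger.warning("glia median absolute slope is zero; ratio infinite")
        return np.inf
    return num / den


def sample_distances(
    matrix: CytosineMatrix,
    regions: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Euclidean distances between samples over beta at region cytosines.

    Missing beta is imputed by the site mean; all-missing sites are dropped.
    Returns the distance matrix, average-linkage tree and its leaf order.
    """
    idx = np.unique(np.concatenate([
        _sites_in_region(matrix.sites, r) for _, r in regions.iterrows()
    ])) if len(regions) else np.array([], dtype=int)
    beta = matrix.beta()[idx]
    keep = ~np.isnan(beta).all(axis=1)
    beta = beta[keep]
    site_mean = np.nanmean(beta, axis=1)
    beta = np.where(np.isnan(beta), site_mean[:, None], beta)
    dist = squareform(pdist(beta.T, metric="euclidean"))
    link = hierarchy.linkage(pdist(beta.T), method="average")
    order = hierarchy.leaves_list(link)
    return {
        "distance": pd.DataFrame(dist, index=matrix.samples, columns=matrix.samples),
        "linkage": link,
        "order": [matrix.samples[i] for i in order],
    }


# ---------------------------------------------------------------------------
# autocorrelation

def _biased_acf(x: np.ndarray, max_lag: int) -> np.ndarray | None:
    """Biased (divide by n) ACF at lags 1..max_lag; pairwise-complete over
    missing values. None when variance is zero or undefined."""
    ok = ~np.isnan(x)
    n = ok.sum()
    if n < 2:
        return None
    mean = np.nanmean(x)
    dev = np.where(ok, x - mean, 0.0)
    denom = float((dev**2).sum())
    if denom == 0:
        return None
    out = np.full(max_lag, np.nan)
    for lag in range(1, max_lag + 1):
        if len(x) <= lag:
            break
        valid = ok[:-lag] & ok[lag:]
        if not valid.any():
            continue
        # rescale the pairwise-complete sum to the full-length convention
        num = float((dev[:-lag] * dev[lag:])[valid].sum()) * (n - lag) / max(valid.sum(), 1)
        out[lag - 1] = num / denom
    return out


def autocorrelation(
    matrix: CytosineMatrix,
    meta: pd.DataFrame,
    context: str = "CpG",
    max_gap: int = 1000,
    min_sites: int = 5,
    max_lag: int = 4,
    scope_regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean ACF per cell fraction, genome-wide (1-kb clusters) or within
    regions. Clusters/regions with fewer than ``min_sites`` cytosines of the
    requested context, or zero variance, are skipped (and counted).

    Returns a tidy frame: context, scope, cell_fraction, lag, acf,
    n_units, n_skipped.
    """
    sub = matrix.select_context(context)
    order = np.lexsort((sub.sites["pos"].to_numpy(), sub.sites["chrom"].to_numpy()))
    sub = sub.subset(order)
    beta = sub.beta()
    pos = sub.sites["pos"].to_numpy()
    chroms = sub.sites["chrom"].to_numpy()

    if scope_regions is None:
        labels = cluster_positions(pos, max_gap, chroms)
        scope = "genome"
        groups = [np.flatnonzero(labels == l) for l in np.unique(labels)]
    else:
        scope = "regions"
        groups = [g for g in (_sites_in_region(sub.sites, r)
                              for _, r in scope_regions.iterrows()) if len(g)]

    per_sample = np.full((len(sub.samples), max_lag), 0.0)
    counts = np.zeros((len(sub.samples), max_lag))
    n_units = 0
    n_skipped = 0
    for g in groups:
        if len(g) < min_sites:
            n_skipped += 1
            continue
        used = False
        for s in range(len(sub.samples)):
            r = _biased_acf(beta[g, s], max_lag)
            if r is None:
                continue
            ok = ~np.isnan(r)
            per_sample[s, ok] += r[ok]
            counts[s, ok] += 1
            used = True
        if used:
            n_units += 1
        else:
            n_skipped += 1
    with np.errstate(invalid="ignore"):
        mean_acf = per_sample / counts

    frac = meta.set_index("sample_id").loc[sub.samples, "cell_fraction"].to_numpy()
    rows = []
    for f in pd.unique(frac):
        sel = frac == f
        for lag in range(1, max_lag + 1):
            vals = mean_acf[sel, lag - 1]
            finite = vals[np.isfinite(vals)]
            rows.append({"context": context, "scope": scope, "cell_fraction": f,
                         "lag": lag,
                         "acf": float(finite.mean()) if len(finite) else np.nan,
                         "n_units": n_units, "n_skipped": n_skipped})
    return pd.DataFrame(rows)
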