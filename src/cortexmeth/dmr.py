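"""Site-wise differential methylation and region detection by bump hunting.

Site models are ordinary least squares of beta on the sample design
(``~ age``, ``~ age + cell`` or ``~ age * cell``; cell coded glia=0,
neuron=1; age in years). Site tests moderate the residual variances with an
empirical-Bayes inverse-chi-square prior (prior df and scale estimated by
method of moments on log s^2), giving the familiar moderated t.

Region detection clusters CpGs (max gap 1 kb), forms maximal same-sign runs
of sites whose coefficient of interest exceeds a cutoff, scores each run by
its area (sum of |coefficient|), and assigns family-wise error rates from
the permutation distribution of the genome-wide maximal area. Permutations
are Freedman-Lane: residuals of the nuisance-only model are permuted over
samples and added back to the nuisance fit, so covariates are respected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import cluster_positions

DESIGNS = ("age_only", "age_plus_cell", "age_by_cell_interaction")


@dataclass
class DesignSpec:
    kind: str = "age_plus_cell"
    coef: str = "cell"              # coefficient of interest

    def matrix(self, meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        age = meta["age"].to_numpy(dtype=float)
        cell = (meta["cell_fraction"] == "neuron").astype(float).to_numpy()
        if self.kind == "age_only":
            X = np.column_stack([np.ones_like(age), age])
            names = ["intercept", "age"]
        elif self.kind == "age_plus_cell":
            X = np.column_stack([np.ones_like(age), age, cell])
            names = ["intercept", "age", "cell"]
        elif self.kind == "age_by_cell_interaction":
            X = np.column_stack([np.ones_like(age), age, cell, age * cell])
            names = ["intercept", "age", "cell", "age:cell"]
        else:
            raise ValueError(f"unknown design {self.kind!r}")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            sds = X.std(axis=0)
            flat = [n for n, s in zip(names, sds) if s == 0 and n != "intercept"]
            raise ValueError(f"rank-deficient design; collinear columns: {flat or names}")
        if self.coef not in names:
            raise ValueError(f"coefficient {self.coef!r} not in design {names}")
        return X, names


def fit_sitewise(values: np.ndarray, meta: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """OLS per site of ``values`` (sites x samples beta) on the design.

    Returns coef (the coefficient of interest), s2 (residual variance), df,
    and stdev_unscaled (its unscaled standard error sqrt[(X'X)^-1_jj]).
    Sites must have beta defined for every sample.
    """
    X, names = design.matrix(meta)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least 2 more samples than design columns")
    Y = np.asarray(values, dtype=float)
    if np.isnan(Y).any():
        raise ValueError("beta must be defined for all samples at tested sites")
    j = names.index(design.coef)
    pinv = np.linalg.pinv(X)
    coefs = Y @ pinv.T                       # (sites, p)
    resid = Y - coefs @ X.T
    df = n - p
    s2 = (resid**2).sum(axis=1) / df
    xtx_inv = pinv @ pinv.T
    return pd.DataFrame({
        "coef": coefs[:, j],
        "s2": s2,
        "df": float(df),
        "stdev_unscaled": np.sqrt(xtx_inv[j, j]),
    })


# ---------------------------------------------------------------------------
# empirical-Bayes moderated test

def _trigamma_inverse(x: float, tol: float = 1e-8) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone decreasing)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Prior df d0 and prior variance s0^2 for the scaled inverse-chi-square
    variance prior, by method of moments on log s^2."""
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1) * (len(e) / (len(e) - 1))
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_mean))
    else:
        d0 = 2 * _trigamma_inverse(excess)
        s0_2 = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_2


def moderated_test(site_stats: pd.DataFrame, d0: float | None = None,
                   s0_2: float | None = None, min_sites: int = 100) -> pd.DataFrame:
    """Moderated t-test of the fitted coefficients.

    s~^2 = (d0 s0^2 + d s^2) / (d0 + d); t = coef / (stdev_unscaled * s~);
    p from t with d0 + d df; q by Benjamini-Hochberg. d0 -> inf shrinks every
    variance to s0^2; d0 = 0 recovers the ordinary t.
    """
    out = site_stats.copy()
    df = float(out["df"].iloc[0])
    s2 = out["s2"].to_numpy()
    if d0 is None or s0_2 is None:
        if len(out) < min_sites:
            raise ValueError(f"moderation needs >= {min_sites} sites to "
                             "estimate the variance prior")
        if (s2 == 0).all():
            import warnings
            warnings.warn("all residual variances zero; ordinary t fallback")
            d0, s0_2 = 0.0, 0.0
        else:
            d0, s0_2 = estimate_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = out["coef"].to_numpy() / (out["stdev_unscaled"].to_numpy()
                                      * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    out["s2_post"] = s2_post
    out["t"] = t
    out["p"] = p
    out["q"] = multipletests(np.nan_to_num(p, nan=1.0), method="fdr_bh")[1]
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    return out


# ---------------------------------------------------------------------------
# bump hunting

def _candidate_regions(coef: np.ndarray, clusters: np.ndarray, cutoff: float):
    """Maximal same-sign runs of |coef| > cutoff within clusters.

    Returns arrays (start_idx, end_idx, area, value, direction); indices are
    site indices into the coefficient vector (end exclusive). Vectorised:
    this runs once per permutation.
    """
    sign = np.where(coef > cutoff, 1, np.where(coef < -cutoff, -1, 0))
    nz = sign != 0
    empty = (np.array([], dtype=int),) * 2 + (np.array([]),) * 2 + (np.array([], dtype=int),)
    if not nz.any():
        return empty
    new = np.empty(len(coef), dtype=bool)
    new[0] = nz[0]
    new[1:] = nz[1:] & (
        ~nz[:-1] | (sign[1:] != sign[:-1]) | (clusters[1:] != clusters[:-1]))
    rid = np.cumsum(new) - 1
    idx = np.flatnonzero(nz)
    r = rid[idx]
    k = int(r[-1]) + 1
    areas = np.bincount(r, weights=np.abs(coef[idx]), minlength=k)
    sums = np.bincount(r, weights=coef[idx], minlength=k)
    counts = np.bincount(r, minlength=k)
    first = np.searchsorted(r, np.arange(k), side="left")
    last = np.searchsorted(r, np.arange(k), side="right") - 1
    starts = idx[first]
    ends = idx[last] + 1
    return starts, ends, areas, sums / counts, sign[starts]


def bumphunt(
    values: np.ndarray,
    sites: pd.DataFrame,
    meta: pd.DataFrame,
    design: DesignSpec,
    cutoff: float,
    max_gap: int = 1000,
    n_perms: int = 250,
    fwer_threshold: float = 0.05,
    seed: int = 0,
    perm_design: DesignSpec | None = None,
) -> pd.DataFrame:
    """Bump hunting with permutation family-wise error control.

    ``values`` is the (sites x samples) methylation matrix to model --
    smoothed beta for the conventional region track or raw beta. Candidate
    regions are maximal same-sign runs of sites whose coefficient of
    interest exceeds ``cutoff`` inside 1-kb clusters; each region's FWER is
    the fraction of Freedman-Lane permutations whose genome-wide maximal
    candidate area reaches the region's area (ties count against the
    region). Returns all candidates; filter on ``fwer < fwer_threshold``.
    """
    if n_perms < 20:
        raise ValueError("n_perms < 20 gives FWER resolution coarser than 5%")
    X, names = design.matrix(meta)
    j = names.index(design.coef)
    n, p = X.shape
    Y = np.asarray(values, dtype=float)
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    clusters = cluster_positions(pos, max_gap, chroms)

    pinv = np.linalg.pinv(X)
    c_row = pinv[j]                      # coef = Y @ c_row
    coef = Y @ c_row
    starts, ends, areas, means, dirs = _candidate_regions(coef, clusters, cutoff)

    # Permutation scheme: full-model residuals permuted over samples and
    # added back to the nuisance-only fit. Under the null this matches
    # permuting nuisance residuals; with real bumps present it keeps the
    # planted effects out of the permutation distribution, which would
    # otherwise be badly conservative when bumps occupy a non-trivial share
    # of the genome. Note (resid[:, perm]) @ c = resid @ c_perm with
    # c_perm[perm] = c.
    X0 = np.delete(X, j, axis=1)
    H0 = X0 @ np.linalg.pinv(X0)
    fitted0 = Y @ H0.T
    # residuals may come from a richer design (perm_design) so that known
    # structure outside this run's model -- e.g. age x cell bumps during a
    # cell-type scan -- does not leak into the permutation null
    Xr, _ = (perm_design or design).matrix(meta)
    Hr = Xr @ np.linalg.pinv(Xr)
    resid_full = Y - Y @ Hr.T
    base = fitted0 @ c_row

    rng = np.random.default_rng(seed)
    max_areas = np.empty(n_perms)
    for b in range(n_perms):
        perm = rng.permutation(n)
        c_perm = np.empty(n)
        c_perm[perm] = c_row
        coef_b = base + resid_full @ c_perm
        _, _, areas_b, _, _ = _candidate_regions(coef_b, clusters, cutoff)
        max_areas[b] = areas_b.max() if len(areas_b) else 0.0

    fwer = (max_areas[None, :] >= areas[:, None]).mean(axis=1) if len(areas) \
        else np.array([])
    out = pd.DataFrame({
        "chrom": chroms[starts] if len(starts) else np.array([], dtype=object),
        "start": pos[starts] - 1 if len(starts) else np.array([], dtype=int),
        "end": pos[np.maximum(ends - 1, 0)] if len(ends) else np.array([], dtype=int),
        "ncpg": ends - starts,
        "value": means,
        "area": areas,
        "direction": dirs,
        "fwer": fwer,
        "index_start": starts,
        "index_end": ends,
    })
    out.attrs["max_areas"] = max_areas
    return out.sort_values("area", ascending=False).reset_index(drop=True)


def compare_designs(
    celltype_stats: pd.DataFrame,
    homogenate_stats: pd.DataFrame,
    p_threshold: float = 1e-4,
) -> dict:
    """Concordance of cell type-resolved vs homogenate age effects.

    Both inputs are moderated site tables sharing a site index. Sites
    selected as age-significant in homogenate (p < threshold) yield the
    coefficient correlation; the 2x2 significance cross-table gives an odds
    ratio and Fisher p; the missed fraction is the share of
    cell-type-significant sites (q < 0.05) not significant in homogenate.
    """
    common = celltype_stats.index.intersection(homogenate_stats.index)
    if len(common) == 0:
        raise ValueError("no shared sites between the two fits")
    ct = celltype_stats.loc[common]
    hm = homogenate_stats.loc[common]
    sel = hm["p"] < p_threshold
    corr = float(np.corrcoef(ct.loc[sel, "coef"], hm.loc[sel, "coef"])[0, 1]) \
        if sel.sum() > 2 else np.nan
    sig_ct = (ct["q"] < 0.05).to_numpy()
    sig_hm = (hm["p"] < p_threshold).to_numpy()
    table = np.array([
        [np.sum(sig_ct & sig_hm), np.sum(sig_ct & ~sig_hm)],
        [np.sum(~sig_ct & sig_hm), np.sum(~sig_ct & ~sig_hm)],
    ])
    odds, fisher_p = stats.fisher_exact(table)
    missed = float(np.sum(sig_ct & ~sig_hm) / sig_ct.sum()) if sig_ct.sum() else np.nan
    return {
        "n_selected": int(sel.sum()),
        "coef_correlation": corr,
        "table": table,
        "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
        "fisher_p": float(fisher_p),
        "missed_fraction": missed,
    }
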