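"""Synthetic WGBS study generator with a machine-readable truth ledger.

Emulates the statistical structure a cell type-resolved developmental
methylome analysis assumes: a highly methylated CpG background (roughly
three quarters of CpGs above 80% methylation at ~15x coverage), sparse
low-level CpH methylation that accumulates with age in neurons, planted
UMR/LMR/PMD/DMV segmentation features, planted cell-type and
age-by-cell-type (trajectory) DMRs in six archetypes, and planted cis
methylation-expression effects. Counts are drawn as

    total ~ NegBin(coverage_mean, dispersion),   meth ~ Binomial(total, beta)

where beta is the site's true methylation surface
``clamp01(b0 + b_cell*cell + b_age*age + b_int*age*cell)`` plus the planted
regional overrides.

Everything is reproducible from ``SimulationConfig.seed``; the same seed and
config give byte-identical output. The :class:`TruthSet` records every
planted region and association, sufficient to score any downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CytosineMatrix, make_sample_meta
from . import intervals

# six trajectory archetypes as (glia direction, neuron direction); +1 gaining
# methylation with age, -1 losing, 0 static. Groups 1, 2 and 6 are the
# "increasing neuronal and/or decreasing glial" patterns that dominate.
ARCHETYPES = (
    (0, 1),    # group 1: static glia, increasing neuron
    (-1, 1),   # group 2: decreasing glia, increasing neuron
    (0, -1),   # group 3: static glia, decreasing neuron
    (1, 0),    # group 4: increasing glia, static neuron
    (1, -1),   # group 5: increasing glia, decreasing neuron
    (-1, 0),   # group 6: decreasing glia, static neuron
)

CHROMHMM_STATES = [
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
]


@dataclass
class FeatureLayout:
    """Counts and sizes of planted methylome features."""

    n_umr: int = 20
    umr_width: tuple[int, int] = (2800, 4500)
    umr_beta: float = 0.05
    n_lmr: int = 30
    lmr_width: tuple[int, int] = (800, 1500)
    lmr_beta: float = 0.30
    n_dmv: int = 6
    dmv_width: tuple[int, int] = (6000, 10000)
    dmv_beta: float = 0.04
    n_pmd: int = 2
    pmd_width: tuple[int, int] = (250_000, 350_000)
    pmd_beta_ab: tuple[float, float] = (2.0, 2.0)
    n_dmr_cell: int = 30
    dmr_cell_ncpg: tuple[int, int] = (8, 20)
    dmr_cell_delta: float = 0.2
    n_dmr_inter: int = 20
    dmr_inter_ncpg: tuple[int, int] = (8, 20)
    hypo_density_mult: float = 2.0   # CpG density boost in UMR/DMV (CpG islands)
    lmr_density_mult: float = 1.5    # CpG density boost in LMRs (enhancers)
    margin: int = 1500               # minimum spacing between planted elements


@dataclass
class TrajectoryEffects:
    """Per-fraction age slopes (beta per year) used by the six archetypes.

    The neuron/glia magnitude ratio of 1.5 mirrors the stronger neuronal
    developmental remodeling the analysis is designed to detect.
    """

    neuron_slope: float = 0.03
    glia_slope: float = 0.02
    inc_intercept: float = 0.20
    dec_intercept: float = 0.80
    static_intercept: float = 0.50
    profile_amp: float = 0.12        # smooth within-region positional profile
    site_jitter: float = 0.02


@dataclass
class AssocEffects:
    """Planted cis methylation-expression effect structure."""

    n_genes: int = 60
    gene_width: tuple[int, int] = (3000, 8000)
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_width: tuple[int, int] = (150, 300)
    promoter_width: int = 2000
    n_gene_assoc: int = 12
    n_exon_assoc: int = 12
    n_psi_assoc: int = 8
    frac_cph: float = 0.5            # planted effects carried by a CpH
    frac_cph_exclusive: float = 0.5  # of CpH effects: no CpG partner nearby
    r_squared: float = 0.5           # target R^2 at the planted cytosine
    slope: float = -1.5              # log2(FPKM+1) per unit beta
    psi_slope: float = -0.5
    beta_range: tuple[float, float] = (0.05, 0.95)
    frac_low_expressed: float = 0.15


@dataclass
class SimulationConfig:
    seed: int = 0
    n_neuron: int = 12
    n_glia: int = 12
    n_homogenate: int = 0
    age_range: tuple[float, float] = (0.0, 23.0)
    ages: tuple | None = None        # explicit per-donor ages, else linspace
    chrom: str = "chr1"
    genome_length: int = 3_000_000
    cpg_rate: float = 0.01
    cph_rate: float = 0.04
    coverage_mean: float = 15.0
    coverage_dispersion: float = 8.0
    # CpG background: mixture of a high mode and a broad low component, drawn
    # per block of consecutive sites to induce neighbour correlation
    cpg_high_frac: float = 0.78
    cpg_high_ab: tuple[float, float] = (26.0, 2.0)
    cpg_low_ab: tuple[float, float] = (5.0, 2.5)   # partially methylated shoulder
    cpg_block_sites: int = 8
    cpg_block_noise_sd: float = 0.04
    high_beta_band: tuple[float, float] = (0.70, 0.80)   # expected obs P(beta>0.8)
    # CpH background: mostly near zero, uncorrelated site to site
    cph_low_frac: float = 0.94
    cph_low_ab: tuple[float, float] = (0.4, 15.0)
    cph_mid_ab: tuple[float, float] = (1.5, 5.0)
    low_beta_band: tuple[float, float] = (0.90, 0.98)    # expected obs P(beta<0.2)
    # neuronal CpH accumulation with age; CAC proportionally faster than CAG
    cph_age_frac: float = 0.25
    cph_age_slope: float = 0.004
    cph_cac_mult: float = 1.3
    cph_cag_mult: float = 0.9
    n_gaps: int = 2
    gap_width: tuple[int, int] = (20_000, 40_000)
    layout: FeatureLayout = field(default_factory=FeatureLayout)
    trajectory: TrajectoryEffects = field(default_factory=TrajectoryEffects)
    assoc: AssocEffects = field(default_factory=AssocEffects)


@dataclass
class TruthSet:
    """Ledger of planted structure; the oracle for parameter-recovery tests."""

    regions: pd.DataFrame            # planted features, 0-based half-open
    assoc: pd.DataFrame              # planted (cytosine, feature) effects
    genes: pd.DataFrame
    exons: pd.DataFrame
    psi_events: pd.DataFrame
    true_beta: np.ndarray | None = None   # (n_sites, n_samples) true surface
    config: SimulationConfig | None = None

    def regions_of(self, kind: str) -> pd.DataFrame:
        return self.regions[self.regions["kind"] == kind].reset_index(drop=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": self.regions.to_dict(orient="list"),
            "assoc": self.assoc.to_dict(orient="list"),
            "genes": self.genes.to_dict(orient="list"),
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(payload, default=list, indent=1))


# ---------------------------------------------------------------------------
# layout planning (shared deterministically by methylome / annotation / expression)

def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def _place(rng, occupied: list, genome: int, width: int, margin: int) -> int:
    for _ in range(500):
        s = int(rng.integers(0, max(genome - width, 1)))
        e = s + width
        if all(e + margin <= os or s >= oe + margin for os, oe in occupied):
            occupied.append((s, e))
            occupied.sort()
            return s
    raise ValueError("infeasible feature layout: could not place all features")


def plan_layout(config: SimulationConfig) -> dict:
    """Deterministic placement of every planted element (seed stream 1)."""
    rng = _rng(config, 1)
    lay = config.layout
    occupied: list[tuple[int, int]] = []
    rows = []

    def add(kind, width, **attrs):
        s = _place(rng, occupied, config.genome_length, width, lay.margin)
        rows.append({"chrom": config.chrom, "start": s, "end": s + width,
                     "kind": kind, **attrs})
        return rows[-1]

    for _ in range(lay.n_pmd):
        add("PMD", int(rng.integers(*lay.pmd_width)))
    for _ in range(config.n_gaps):
        label = "heterochromatin" if rng.random() < 0.5 else "telomere"
        add("gap", int(rng.integers(*config.gap_width)), label=label)
    for _ in range(lay.n_dmv):
        add("DMV", int(rng.integers(*lay.dmv_width)), beta=lay.dmv_beta)
    for _ in range(lay.n_umr):
        add("UMR", int(rng.integers(*lay.umr_width)), beta=lay.umr_beta)
    for _ in range(lay.n_lmr):
        add("LMR", int(rng.integers(*lay.lmr_width)), beta=lay.lmr_beta)
    spacing = 1.0 / config.cpg_rate
    for _ in range(lay.n_dmr_cell):
        ncpg = int(rng.integers(lay.dmr_cell_ncpg[0], lay.dmr_cell_ncpg[1] + 1))
        width = max(int(ncpg * spacing * rng.uniform(0.8, 1.2)), 100)
        direction = 1 if rng.random() < 0.5 else -1
        add("DMR", width, ncpg=ncpg, direction=direction, delta=lay.dmr_cell_delta)
    for i in range(lay.n_dmr_inter):
        ncpg = int(rng.integers(lay.dmr_inter_ncpg[0], lay.dmr_inter_ncpg[1] + 1))
        width = max(int(ncpg * spacing * rng.uniform(0.8, 1.2)), 100)
        group = i % len(ARCHETYPES) + 1
        add("cdDMR", width, ncpg=ncpg, group=group)

    # gene models for the expression layer
    a = config.assoc
    genes = []
    for g in range(a.n_genes):
        width = int(rng.integers(*a.gene_width))
        s = _place(rng, occupied, config.genome_length, width, lay.margin)
        genes.append({"gene_id": f"G{g:04d}", "chrom": config.chrom,
                      "start": s, "end": s + width, "strand": "+",
                      "protein_coding": bool(rng.random() < 0.9)})
    gene_cols = ["gene_id", "chrom", "start", "end", "strand", "protein_coding"]
    genes = pd.DataFrame(genes, columns=gene_cols)
    genes["protein_coding"] = genes["protein_coding"].astype(bool)
    exons = []
    for _, g in genes.iterrows():
        for k in range(int(rng.integers(a.exons_per_gene[0], a.exons_per_gene[1] + 1))):
            w = int(rng.integers(*a.exon_width))
            s = int(rng.integers(g["start"], g["end"] - w))
            exons.append({"exon_id": f"{g['gene_id']}.E{k}", "gene_id": g["gene_id"],
                          "chrom": config.chrom, "start": s, "end": s + w})
    exon_cols = ["exon_id", "gene_id", "chrom", "start", "end"]
    exons = pd.DataFrame(exons, columns=exon_cols).sort_values(["start"]).reset_index(drop=True) \
        if exons else pd.DataFrame(columns=exon_cols)
    psi = exons.sample(frac=0.5, random_state=int(rng.integers(2**31))).copy()
    psi = psi.rename(columns={"exon_id": "event_id"}).reset_index(drop=True)
    psi["min_denominator"] = rng.integers(4, 40, size=len(psi))

    # planted associations: each picks a cytosine inside the feature span
    assoc_rows = []
    coding = genes[genes["protein_coding"]]

    def pick_site(feat):
        lo, hi = int(feat["start"]) + 5, int(feat["end"]) - 5
        return int(rng.integers(lo, max(hi, lo + 1)))

    used_features: set[tuple[str, str]] = set()

    def plan_assoc(ftype, table, id_col, n):
        if ftype == "gene":
            pool = coding.rename(columns={"gene_id": id_col})
        else:
            pool = table[table["gene_id"].isin(coding["gene_id"])]
            if "min_denominator" in pool:
                pool = pool[pool["min_denominator"] >= 10]
        pool = pool.reset_index(drop=True)
        order = rng.permutation(len(pool))
        taken = 0
        for idx in order:
            if taken >= n:
                break
            feat = pool.iloc[idx]
            if (ftype, feat[id_col]) in used_features:
                continue
            used_features.add((ftype, feat[id_col]))
            is_cph = rng.random() < a.frac_cph
            exclusive = bool(is_cph and rng.random() < a.frac_cph_exclusive)
            pos = pick_site(feat)
            partner = pos + int(rng.integers(80, 400)) * (1 if rng.random() < 0.5 else -1)
            assoc_rows.append({
                "feature_id": feat[id_col], "feature_type": ftype,
                "gene_id": feat["gene_id"] if "gene_id" in feat else feat[id_col],
                "chrom": config.chrom, "pos": pos,
                "context": "CpH" if is_cph else "CpG",
                "exclusive": exclusive,
                "partner_pos": -1 if (not is_cph or exclusive) else partner,
                "slope": (a.psi_slope if ftype == "psi" else a.slope),
            })
            taken += 1

    plan_assoc("gene", genes, "feature_id", a.n_gene_assoc)
    plan_assoc("exon", exons, "exon_id", a.n_exon_assoc)
    plan_assoc("psi", psi, "event_id", a.n_psi_assoc)
    assoc = pd.DataFrame(assoc_rows, columns=[
        "feature_id", "feature_type", "gene_id", "chrom", "pos", "context",
        "exclusive", "partner_pos", "slope"])
    assoc["exclusive"] = assoc["exclusive"].astype(bool)

    region_cols = ["chrom", "start", "end", "kind", "label", "beta", "ncpg",
                   "direction", "delta", "group"]
    regions = pd.DataFrame(rows)
    for col in region_cols:
        if col not in regions:
            regions[col] = pd.Series(dtype=object)
    regions = regions[region_cols]
    return {"regions": regions, "genes": genes, "exons": exons, "psi": psi,
            "assoc": assoc}


# ---------------------------------------------------------------------------
# methylome

def _draw_counts(rng, true_beta, mean, disp):
    p = disp / (disp + mean)
    total = rng.negative_binomial(disp, p, size=true_beta.shape)
    meth = rng.binomial(total, np.clip(true_beta, 0.0, 1.0))
    return meth.astype(np.int64), total.astype(np.int64)


def _sorted_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elements of sorted unique ``a`` not present in sorted unique ``b``."""
    if len(a) == 0 or len(b) == 0:
        return a
    idx = np.searchsorted(b, a)
    idx = np.minimum(idx, len(b) - 1)
    return a[b[idx] != a]


def _poisson_positions(rng, start, end, rate):
    n = rng.poisson(rate * (end - start))
    if n == 0:
        return np.array([], dtype=np.int64)
    return np.unique(rng.integers(start, end, size=n))


def simulate_methylome(config: SimulationConfig):
    """Generate (CytosineMatrix, sample metadata, TruthSet) for one study."""
    plan = plan_layout(config)
    rng = _rng(config, 2)
    regions = plan["regions"]
    L = config.genome_length

    # --- samples -----------------------------------------------------------
    def donor_ages(n):
        if config.ages is not None:
            return np.asarray(config.ages, dtype=float)[:n]
        return np.linspace(config.age_range[0], config.age_range[1], n)

    ids, fracs, ages = [], [], []
    for frac, n in (("neuron", config.n_neuron), ("glia", config.n_glia),
                    ("homogenate", config.n_homogenate)):
        a = donor_ages(n)
        for i in range(n):
            ids.append(f"{frac[0].upper()}{i:02d}")
            fracs.append(frac)
            ages.append(a[i])
    meta = make_sample_meta(ids, fracs, ages)
    meta["donor"] = [f"D{i:02d}" for f, n in (("n", config.n_neuron), ("g", config.n_glia),
                                              ("h", config.n_homogenate)) for i in range(n)]
    age = meta["age"].to_numpy()
    is_neuron = (meta["cell_fraction"] == "neuron").to_numpy()
    is_glia = (meta["cell_fraction"] == "glia").to_numpy()
    is_homog = (meta["cell_fraction"] == "homogenate").to_numpy()
    S = len(meta)

    # --- CpG site positions ------------------------------------------------
    dense = regions[regions["kind"].isin(["UMR", "DMV"])]
    lmr_dense = regions[regions["kind"] == "LMR"]
    dmrs = regions[regions["kind"].isin(["DMR", "cdDMR"])]
    carved = pd.concat([dense, lmr_dense, dmrs])[["chrom", "start", "end"]]
    # exclusion zones around CpH-exclusive association sites keep their 1-kb
    # windows CpG-poor (these planted effects live in CpG-sparse neighbourhoods)
    excl = plan["assoc"][plan["assoc"]["exclusive"]]
    excl_iv = intervals.make_regions(
        config.chrom, np.maximum(excl["pos"] - 1100, 0), excl["pos"] + 1100
    ) if len(excl) else pd.DataFrame(columns=["chrom", "start", "end"])
    background = intervals.subtract(
        intervals.make_regions([config.chrom], [0], [L]),
        pd.concat([carved, excl_iv]) if len(excl_iv) else carved,
    )
    pos_parts = [
        _poisson_positions(rng, s, e, config.cpg_rate)
        for s, e in zip(background["start"], background["end"])
    ]
    for _, r in dense.iterrows():
        pos_parts.append(_poisson_positions(
            rng, r["start"], r["end"], config.cpg_rate * config.layout.hypo_density_mult))
    for _, r in lmr_dense.iterrows():
        pos_parts.append(_poisson_positions(
            rng, r["start"], r["end"], config.cpg_rate * config.layout.lmr_density_mult))
    for _, r in dmrs.iterrows():
        k = int(r["ncpg"])
        grid = np.linspace(r["start"] + 3, r["end"] - 3, k)
        jitter = rng.uniform(-0.3, 0.3, k) * (r["end"] - r["start"]) / max(k, 1)
        pos_parts.append(np.unique(np.round(grid + jitter).astype(np.int64)))
    cpg_pos = np.unique(np.concatenate(pos_parts))

    # --- CpH site positions ------------------------------------------------
    cph_pos = _poisson_positions(rng, 0, L, config.cph_rate)
    cph_pos = _sorted_diff(cph_pos, cpg_pos)

    # planted association cytosines (exact positions, exact contexts)
    assoc = plan["assoc"]
    a_cpg = assoc.loc[assoc["context"] == "CpG", "pos"].to_numpy()
    a_cph = assoc.loc[assoc["context"] == "CpH", "pos"].to_numpy()
    partners = assoc.loc[assoc["partner_pos"] >= 0, "partner_pos"].to_numpy()
    cpg_pos = np.unique(np.concatenate([cpg_pos, a_cpg, partners]))
    cph_pos = _sorted_diff(np.unique(np.concatenate([cph_pos, a_cph])), cpg_pos)

    # --- true beta surfaces -------------------------------------------------
    n_cpg, n_cph = len(cpg_pos), len(cph_pos)
    # background CpG: block-level mixture draw + site noise (neighbour correlation)
    # block-level draw of the high mode gives neighbour correlation; the low
    # mode is isolated site-level outliers (regional hypomethylation exists
    # only as planted features)
    blocks = np.arange(n_cpg) // config.cpg_block_sites
    n_blocks = blocks[-1] + 1 if n_cpg else 0
    block_mean = rng.beta(*config.cpg_high_ab, n_blocks)
    cpg_base = np.clip(block_mean[blocks] + rng.normal(0, config.cpg_block_noise_sd, n_cpg),
                       0.001, 0.999)
    outlier = rng.random(n_cpg) >= config.cpg_high_frac
    cpg_base[outlier] = rng.beta(*config.cpg_low_ab, int(outlier.sum()))
    cpg_beta = np.repeat(cpg_base[:, None], S, axis=1)

    # background CpH: uncorrelated, mostly near zero
    lo = rng.random(n_cph) < config.cph_low_frac
    cph_base = np.where(lo, rng.beta(*config.cph_low_ab, n_cph),
                        rng.beta(*config.cph_mid_ab, n_cph))
    cph_beta = np.repeat(np.clip(cph_base, 0.0, 0.999)[:, None], S, axis=1)

    # trinucleotides / strand
    cpg_tri = np.array(["CG" + b for b in rng.choice(list("ACT"), n_cpg)])
    first2 = rng.choice(["CA", "CT", "CC"], n_cph, p=[0.6, 0.25, 0.15])
    third = rng.choice(list("GACT"), n_cph, p=[0.35, 0.3, 0.2, 0.15])
    cph_tri = np.array([a + b for a, b in zip(first2, third)])
    cph_ctx = np.where(np.char.endswith(cph_tri, "G"), "CHG", "CHH")

    # neuronal CpH accumulation with age (trinucleotide-dependent rate)
    aging = rng.random(n_cph) < config.cph_age_frac
    tri_mult = np.ones(n_cph)
    tri_mult[cph_tri == "CAC"] = config.cph_cac_mult
    tri_mult[cph_tri == "CAG"] = config.cph_cag_mult
    slope = config.cph_age_slope * tri_mult * aging
    cph_beta = np.clip(cph_beta + slope[:, None] * (age[None, :] * is_neuron[None, :]),
                       0.0, 0.999)

    tr = config.trajectory

    def region_profile(r, pos_in):
        width = float(r["end"]) - float(r["start"])
        lam = max(width / 1.5, 1.0)
        rel = np.asarray(pos_in, dtype=float) - float(r["start"])
        return tr.profile_amp * np.sin(2 * np.pi * rel / lam)

    def override(pos_arr, beta_mat, is_cph_track):
        for _, r in regions.iterrows():
            inside = (pos_arr >= r["start"]) & (pos_arr < r["end"])
            if not inside.any():
                continue
            k = r["kind"]
            idx = np.flatnonzero(inside)
            if k in ("UMR", "LMR", "DMV") and not is_cph_track:
                site = np.clip(r["beta"] + rng.normal(0, 0.02, len(idx)), 0.001, 0.6)
                beta_mat[idx] = site[:, None]
            elif k == "PMD" and not is_cph_track:
                site = rng.beta(*config.layout.pmd_beta_ab, len(idx))
                beta_mat[idx] = site[:, None]
            elif k == "DMR" and not is_cph_track:
                d = r["direction"]
                glia_level = 0.6 + d * r["delta"] / 2
                neuron_level = 0.6 - d * r["delta"] / 2
                jit = rng.normal(0, tr.site_jitter, len(idx))[:, None]
                lvl = np.where(is_neuron[None, :], neuron_level, glia_level)
                lvl = np.where(is_homog[None, :], (neuron_level + glia_level) / 2, lvl)
                beta_mat[idx] = np.clip(lvl + jit, 0.001, 0.999)
            elif k == "cdDMR":
                # CpH inside trajectory DMRs shares the CpG surface (the
                # within-region context convergence phenomenon)
                gdir, ndir = ARCHETYPES[int(r["group"]) - 1]
                icpt = {1: tr.inc_intercept, -1: tr.dec_intercept, 0: tr.static_intercept}
                prof = region_profile(r, pos_arr[idx])[:, None]
                surf_n = icpt[ndir] + ndir * tr.neuron_slope * age[None, :]
                surf_g = icpt[gdir] + gdir * tr.glia_slope * age[None, :]
                surf = np.where(is_neuron[None, :], surf_n, surf_g)
                surf = np.where(is_homog[None, :], (surf_n + surf_g) / 2, surf)
                jit = rng.normal(0, tr.site_jitter, len(idx))[:, None]
                beta_mat[idx] = np.clip(surf + prof + jit, 0.001, 0.999)
        return beta_mat

    cpg_beta = override(cpg_pos, cpg_beta, is_cph_track=False)
    cph_beta = override(cph_pos, cph_beta, is_cph_track=True)

    # planted association cytosines: inter-individual variable surfaces
    lo_b, hi_b = config.assoc.beta_range
    assoc = assoc.copy()
    assoc_beta = {}
    for i, row in assoc.iterrows():
        b = rng.uniform(lo_b, hi_b, S)
        assoc_beta[int(row["pos"])] = b
        if row["partner_pos"] >= 0:
            assoc_beta[int(row["partner_pos"])] = np.clip(
                b + rng.normal(0, 0.03, S), 0.0, 0.999)
    for pos_arr, beta_mat in ((cpg_pos, cpg_beta), (cph_pos, cph_beta)):
        for p, b in assoc_beta.items():
            j = np.searchsorted(pos_arr, p)
            if j < len(pos_arr) and pos_arr[j] == p:
                beta_mat[j] = b

    # --- assemble matrix ----------------------------------------------------
    sites = pd.DataFrame({
        "chrom": config.chrom,
        "pos": np.concatenate([cpg_pos, cph_pos]) + 1,  # 1-based report coords
        "strand": "+",
        "context": np.concatenate([np.repeat("CpG", n_cpg), cph_ctx]),
        "trinucleotide": np.concatenate([cpg_tri, cph_tri]),
    })
    true_beta = np.vstack([cpg_beta, cph_beta]) if n_cpg + n_cph else np.empty((0, S))
    order = np.argsort(sites["pos"].to_numpy(), kind="mergesort")
    sites = sites.iloc[order].reset_index(drop=True)
    true_beta = true_beta[order]
    # strands drawn independently of position; flip ~half for realism
    strands = np.where(rng.random(len(sites)) < 0.5, "+", "-")
    sites["strand"] = strands

    meth, total = _draw_counts(rng, true_beta, config.coverage_mean,
                               config.coverage_dispersion)
    # planted association cytosines are testable by construction: coverage
    # floor keeps them (and their CpG partners) past the coverage filters
    if assoc_beta:
        floor = 5
        all_pos0 = sites["pos"].to_numpy() - 1
        for p in assoc_beta:
            j = np.searchsorted(all_pos0, p)
            if j < len(all_pos0) and all_pos0[j] == p:
                low = total[j] < floor
                if low.any():
                    add = floor - total[j][low]
                    extra = rng.binomial(add, np.clip(true_beta[j][low], 0, 1))
                    total[j][low] += add
                    meth[j][low] += extra
    matrix = CytosineMatrix(sites, meth, total, meta["sample_id"].tolist())

    truth = TruthSet(regions=regions, assoc=assoc, genes=plan["genes"],
                     exons=plan["exons"], psi_events=plan["psi"],
                     true_beta=true_beta, config=config)
    truth._site_positions = sites["pos"].to_numpy() - 1  # 0-based genome coords
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# expression

def simulate_expression(config: SimulationConfig, truth: TruthSet, meta: pd.DataFrame):
    """Expression tables (gene/exon log-scale FPKM, splice PSI) keyed to the
    neuronal donors. Planted features follow
    ``expression = intercept + slope * beta(cytosine) + N(0, sd)`` with sd set
    from the configured target R^2; everything else is independent of
    methylation.
    """
    rng = _rng(config, 4)
    a = config.assoc
    donors = meta.loc[meta["cell_fraction"] == "neuron", "sample_id"].tolist()
    donor_idx = [meta.index[meta["sample_id"] == d][0] for d in donors]
    n = len(donors)

    planted = truth.assoc.set_index(["feature_type", "feature_id"])
    lo_b, hi_b = a.beta_range
    var_true = (hi_b - lo_b) ** 2 / 12.0
    # the R^2 target describes the regression the scan runs: expression on
    # *measured* beta, which carries binomial sampling noise at the study
    # coverage. Solve for the Gaussian noise SD that yields that R^2.
    disp, mean_cov = config.coverage_dispersion, config.coverage_mean
    tots = np.maximum(_rng(config, 5).negative_binomial(
        disp, disp / (disp + mean_cov), 4000), 1)
    mu_b = (lo_b + hi_b) / 2
    e_b2 = var_true + mu_b**2
    w_obs = float((mu_b - e_b2) * np.mean(1.0 / tots))   # E[beta(1-beta)/T]
    shrink = var_true / (a.r_squared * (var_true + w_obs)) - 1.0
    if shrink <= 0:
        raise ValueError("target R^2 unattainable at this coverage")

    def noise_sd(slope):
        return abs(slope) * np.sqrt(var_true * shrink)

    def beta_at(pos):
        if truth.true_beta is None:
            raise ValueError("truth set lacks the true beta surface")
        return np.asarray([truth.true_beta[_site_index(truth, pos), j] for j in donor_idx])

    # cache site index by position for speed
    site_pos = None

    def _site_index(tr, pos):
        nonlocal site_pos
        if site_pos is None:
            site_pos = {}
            mat_pos = tr._site_positions  # set by caller below
            for i, p in enumerate(mat_pos):
                site_pos[p] = i
        return site_pos[pos]

    tables = {}
    for ftype, table, id_col in (("gene", truth.genes, "gene_id"),
                                 ("exon", truth.exons, "exon_id"),
                                 ("psi", truth.psi_events, "event_id")):
        vals = np.empty((len(table), n))
        for i, fid in enumerate(table[id_col]):
            key = (ftype, fid)
            if key in planted.index:
                row = planted.loc[key]
                b = beta_at(int(row["pos"]))
                slope = float(row["slope"])
                if ftype == "psi":
                    base = 0.55
                    vals[i] = np.clip(base + slope * (b - 0.5)
                                      + rng.normal(0, noise_sd(slope), n), 0, 1)
                else:
                    base = rng.normal(3.0, 0.5)
                    vals[i] = base + slope * b + rng.normal(0, noise_sd(slope), n)
            else:
                if ftype == "psi":
                    vals[i] = np.clip(rng.normal(rng.uniform(0.2, 0.8), 0.08, n), 0, 1)
                else:
                    low = rng.random() < a.frac_low_expressed
                    base = rng.normal(-2.8, 0.3) if low else rng.normal(2.5, 1.0)
                    vals[i] = base + rng.normal(0, 0.4, n)
        df = pd.DataFrame(vals, columns=donors)
        df.insert(0, "feature_id", table[id_col].to_numpy())
        if ftype in ("gene", "exon"):
            # convert log2(FPKM+1)-scale latent values to FPKM
            df[donors] = np.maximum(np.exp2(df[donors].to_numpy()) - 1, 0.0)
        tables[ftype] = df
    return tables


def attach_site_positions(truth: TruthSet, matrix: CytosineMatrix) -> None:
    """Register the matrix's (sorted) 0-based positions on the truth set so
    expression simulation can look up planted cytosines."""
    truth._site_positions = (matrix.sites["pos"].to_numpy() - 1)


# ---------------------------------------------------------------------------
# annotation tracks

def simulate_annotation(config: SimulationConfig) -> dict:
    """BED-like annotation: a 15-state chromatin tiling of the genome (with a
    planted enhancer-state enrichment inside UMR/DMV features), gene models,
    gene sets, and assembly gaps (some labelled heterochromatin)."""
    plan = plan_layout(config)
    rng = _rng(config, 3)
    L = config.genome_length
    # state tiling: exponential segment lengths, exact partition of [0, L)
    edges = [0]
    while edges[-1] < L:
        edges.append(edges[-1] + int(rng.exponential(5000)) + 200)
    edges[-1] = L
    starts = np.array(edges[:-1])
    ends = np.array(edges[1:])
    labels = rng.choice(CHROMHMM_STATES, len(starts))
    # planted enrichment: segments inside hypomethylated features lean Enh/TssA
    hypo = plan["regions"][plan["regions"]["kind"].isin(["UMR", "DMV"])]
    mids = (starts + ends) // 2
    for _, r in hypo.iterrows():
        inside = (mids >= r["start"]) & (mids < r["end"])
        pick = rng.random(inside.sum()) < 0.7
        lab = np.where(rng.random(inside.sum()) < 0.5, "Enh", "TssA")
        labels[np.flatnonzero(inside)[pick]] = lab[pick]
    states = pd.DataFrame({"chrom": config.chrom, "start": starts, "end": ends,
                           "state": labels})

    gaps = plan["regions"][plan["regions"]["kind"] == "gap"][
        ["chrom", "start", "end", "label"]].reset_index(drop=True)

    genes = plan["genes"]
    sets = []
    gene_ids = genes["gene_id"].to_numpy()
    for name, frac in (("synaptic", 0.15), ("disorder_risk", 0.1), ("housekeeping", 0.2)):
        chosen = rng.choice(gene_ids, max(int(frac * len(gene_ids)), 1), replace=False)
        sets.extend({"set_name": name, "gene_id": g} for g in chosen)
    gene_sets = pd.DataFrame(sets)
    return {"states": states, "genes": genes, "exons": plan["exons"],
            "psi_events": plan["psi"], "gaps": gaps, "gene_sets": gene_sets}


# ---------------------------------------------------------------------------
# purpose-built small generators for estimator validation

def simulate_ar1_methylome(
    n_clusters: int = 50,
    cluster_size: int = 200,
    rho: float = 0.7,
    seed: int = 0,
    mean: float = 0.5,
    amp: float = 0.12,
    spacing: int = 40,
    cluster_gap: int = 5000,
    context: str = "CpG",
    n_samples: int = 4,
) -> CytosineMatrix:
    """Methylation field with an exact AR(1) beta sequence per cluster.

    Counts encode beta essentially noiselessly (total = 10000) so the
    autocorrelation estimator can be scored against the analytic lag
    structure rho**lag. ``rho = 0`` gives an i.i.d. field.
    """
    rng = np.random.default_rng(seed)
    pos_parts, beta_parts = [], []
    cursor = 1
    innov_sd = np.sqrt(max(1 - rho**2, 1e-12))
    for _ in range(n_clusters):
        pos = cursor + np.arange(cluster_size) * spacing
        cursor = pos[-1] + cluster_gap
        z = np.empty((cluster_size, n_samples))
        z[0] = rng.normal(0, 1, n_samples)
        eps = rng.normal(0, innov_sd, (cluster_size - 1, n_samples))
        for i in range(1, cluster_size):
            z[i] = rho * z[i - 1] + eps[i - 1]
        beta_parts.append(np.clip(mean + amp * z, 0.0, 1.0))
        pos_parts.append(pos)
    positions = np.concatenate(pos_parts)
    beta = np.vstack(beta_parts)
    total = np.full(beta.shape, 10_000, dtype=np.int64)
    meth = np.round(beta * total).astype(np.int64)
    tri = "CGA" if context == "CpG" else ("CAG" if context == "CHG" else "CAC")
    ctx = "CpG" if context == "CpG" else ("CHG" if tri == "CAG" else "CHH")
    sites = pd.DataFrame({"chrom": "chrSim", "pos": positions, "strand": "+",
                          "context": ctx, "trinucleotide": tri})
    samples = [f"S{i:02d}" for i in range(n_samples)]
    return CytosineMatrix(sites, meth, total, samples)
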