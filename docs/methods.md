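# Methods

`cortexmeth` implements the post-alignment analysis of a cell type-resolved
developmental WGBS study: per-cytosine counts in, segmentation / differential
methylation / trajectory / autocorrelation / expression-association results
out. This note records the models, the parameters that matter, the design
choices that were genuinely open, and what the synthetic validation does and
does not establish.

## Data model

A `CytosineMatrix` holds one row per cytosine (chromosome, 1-based
position, strand, context, trinucleotide) and methylated/total read counts
per sample. Methylation level β = meth/total is derived lazily and is
*missing* (NaN) wherever total = 0 — never zero, which would bias means
toward hypomethylation. Context is a pure function of the trinucleotide
(second base G → CpG, else third base G → CHG, else CHH). Complementary
CpGs are **not** pooled into dinucleotide units: each cytosine is an
independent observation, which the per-cytosine site tests and all CpH
analyses require. Coordinates are 1-based in report I/O (the native
per-cytosine report convention) and 0-based half-open in every region
structure and BED output.

Coverage filters follow the study conventions: CpG analyses require
coverage ≥ 3 in every sample; CpH analyses require coverage ≥ 5 in every
sample and at least 5 samples with β > 0. Postnatal ages are grouped as
infant [0, 1], child (1, 10], teen (10, 17], adult (17, ∞).

## Smoothing

`smooth_sample` is a local-likelihood smoother: at each CpG a weighted
polynomial (degree 2 by default) is fit over the smallest symmetric window
containing ≥ `min_sites` sites and spanning ≥ `min_width` bp, with weights
tricube(distance/half-span) × read depth, and evaluated at the site.
Zero-coverage sites get zero weight but are still evaluated; chromosomes
with fewer than `min_sites` sites pass through raw with a warning; output
is clamped to [0, 1]. Two parameterisations are used deliberately:

- **Region-detection track**: `min_sites = 70`, `min_width = 1000` — the
  wide-window convention of bisulfite smoothers, appropriate when the
  signal of interest spans many CpGs.
- **Segmentation track**: `min_sites = 5`, `min_width = 100`, degree 0 — a
  light running mean over a few CpGs, the convention of UMR/LMR callers.
  With a 3-site window the tricube weight of the outermost site is exactly
  zero, so 5 sites are needed for any effective averaging; degree 0 avoids
  edge extrapolation at segment boundaries.

The normal equations are solved with a ~1e-9 ridge so windows with few
distinct positions stay solvable (they then reduce to a weighted mean).

## Segmentation

**PMDs.** The per-sample disorder statistic is the fraction of sites in a
centred 101-CpG window whose raw β lies in (0.3, 0.7). A two-state Gaussian
hidden-state model with fixed parameters (ordered state at the 25th
percentile of the score; disordered at max(95th percentile, ordered + 0.25,
0.4); SD 0.12; stay probability 0.999) is decoded by Viterbi. Fixing the
emission parameters rather than fitting them by EM makes the decode
deterministic and robust on genomes with no PMDs at all (the disordered
mean then sits far above every score and nothing is called). Candidate
PMDs keep only runs longer than 100 kb, and assembly-gap sequence is
subtracted — except gaps labelled heterochromatin, which are genuinely
PMD-like. The statistic and decoder are plain functions and can be swapped.

**Cutoff calibration.** For a grid of cutoffs (0.02 … m = 0.5, step 0.02),
hypomethylated segments (≥ 4 consecutive CpGs below cutoff, never spanning
intersite gaps > 5 kb) are counted in the observed and in
methylation-shuffled data (5 seeded shuffles, averaged); FDR(c) =
100 × null/observed, and the *largest* cutoff with FDR ≤ 10 is chosen. PMD
sites are masked first. Averaging several shuffles matters on small
genomes, where a single shuffle makes the FDR curve noisy near the target.

**UMR/LMR/DMV.** Maximal runs of ≥ 4 consecutive CpGs below the calibrated
cutoff become segments; ≥ 30 CpGs → UMR, fewer → LMR (both thresholds
config-exposed; neither is printed in the source study, so the cited
caller's conventions are used). Segment boundaries extend to the midpoint
of the gap to the neighbouring above-cutoff CpG (capped at 500 bp), since
hypomethylation plausibly continues into the unsampled gap; without the
extension, boundary scoring systematically penalises sparse regions. The
run-breaking rule at > 5 kb intersite gaps prevents segments from bridging
masked holes (PMDs, assembly gaps). DMVs are the UMRs with pmeth ≤ 0.15
and width ≥ 5000 bp, both boundaries inclusive; pmeth is the mean
*smoothed* β over segment CpGs (whether the study used raw or smoothed β is
unstated; smoothed is the default and raw values can be passed instead).

## Site tests and bump hunting

`fit_sitewise` is vectorised OLS of β (raw for site tests, optionally
smoothed for regions) on the design; `moderated_test` shrinks residual
variances with a scaled inverse-chi-square prior whose df d₀ and scale s₀²
are estimated by method of moments on log s² (digamma/trigamma matching,
with a Newton trigamma inverse), giving s̃² = (d₀s₀² + d·s²)/(d₀ + d) and a
t statistic on d₀ + d df. The limits are exact: d₀ → ∞ replaces every
variance by s₀², d₀ = 0 recovers the ordinary t. BH adjustment is applied
within each run.

`bumphunt` forms candidate regions as maximal same-sign runs of sites with
|coefficient| > cutoff within 1-kb position clusters; a region's area is
Σ|coefficient| and single-CpG regions are legitimate candidates. FWER is
the fraction of permutations whose genome-wide maximal candidate area
reaches the region's area (ties count against the region, a conservative
choice). Default cutoffs follow the study: 0.1 for cell type (10 %
methylation difference), 0.005 for age (5 % per decade), 0.009 for the
interaction; B = 250; regions reported at FWER < 5 %.

**Permutation scheme.** Permutations operate on residuals added back to
the nuisance-only fit. The residuals are taken from the *full* model — or
from an explicitly richer `perm_design` — rather than from the nuisance
model. Under the global null the two choices coincide; when real bumps
occupy a non-trivial share of the genome (always true on a compact
simulated genome, and true of strong cell-type differences generally),
nuisance-model residuals still contain the planted group structure, every
permutation regenerates coherent pseudo-bumps over those same regions, and
the max-area null becomes badly inflated. Passing the interaction design
as `perm_design` to a cell-type scan likewise keeps known age × cell
structure out of that scan's null. FWER control under the null is verified
empirically (20 global-null replicates in the acceptance suite).

**Raw vs smoothed track.** DMP tests use raw β. For DMRs both tracks are
accepted; the validation runs use raw β because the planted bumps span
8–20 CpGs and a 70-site pre-smoother would dilute an 8-CpG bump roughly
five-fold, pushing it under any fixed cutoff. On genome-scale data with
broader targets the pre-smoothed track is the natural choice.

## Trajectories, distances, autocorrelation

Each interaction DMR ("cdDMR") is summarised by the mean per-cytosine age
slope fitted within glia samples and within neuron samples (β/year), plus
the mean interaction coefficient. k-means (Lloyd, best of 100 starts,
seeded) partitions the (glia, neuron) slope plane; centroids get semantic
names (increasing/decreasing/static per fraction, |slope| below 10 % of
the largest centroid slope counting as static). Model size is chosen by
the k-means AIC heuristic **AIC(k) = WSS + 2·k·d** on centred and scaled
features. The Gaussian log-likelihood variant n·d·ln(WSS/(n·d)) + 2·k·d was
considered and rejected: for a few hundred observations its penalty cannot
offset the ~5 % WSS drop from splitting any tight cluster, so its argmin
drifts to the top of the k range regardless of the true structure; the
WSS-scale penalty stops precisely when the marginal WSS gain falls below
2·d. The neuron/glia effect ratio is median|neuron slope| / median|glia
slope| (infinite, with a warning, if the glia median is zero). Sample
distances are Euclidean over per-site β restricted to region cytosines
(site-mean imputation for missing values; all-missing sites dropped) with
average-linkage clustering.

Autocorrelation is the biased (divide-by-n) ACF of the β sequence in
position order, lags 1–4 **in site index** (lag spacing is proportional to
genomic distance within a context), computed per cluster (positions ≤ 1 kb
apart, ≥ 5 cytosines) or per region, with pairwise-complete terms over
missing β to avoid imputation bias in sparse CpH; zero-variance clusters
are skipped and counted. Cluster means are averaged, then samples within a
cell fraction — cluster-mean-then-sample-mean, matching the description of
the original computation.

## Methylation–expression association

Expression tables are filtered (genes: mean FPKM > 0.22, strict; exons:
> 0.26; PSI events: splice denominator ≥ 10) and transformed
(log2(FPKM+1); PSI raw). The cis scan regresses expression on β for every
(cytosine, feature) pair within 1 kb of the feature span — a closed
window: a cytosine exactly 1000 bp from the nearest feature base is tested
— keeping pairs with p < 5·10⁻⁴ and BH-adjusting with the full tested-pair
count. CpGs within ±1 kb of each FDR < 5 % CpH hit are rescanned at
p < 0.01; a feature with no marginal CpG association is CpH-exclusive.
Records then drop cytosines with fewer than 11 donors at β > 0 or fewer
than 11 at β < 1 (the extreme-methylation rule, applied after scanning and
before interpretation), non-protein-coding features, and infinite t. The
age check refits expression ~ β + age and flags records whose methylation
coefficient is no longer FDR < 5 % within the rechecked set (β collinear
with age, |r| > 0.999, is flagged directly). Promoter = 2 kb upstream of
the start; flanking = ±5 kb beyond the span excluding the promoter — both
config-exposed, as the source conventions are unstated. The reported
expression change is slope × the cytosine's observed β range.

## Enrichment

State composition is the base-pair share of each chromatin state inside a
region set vs the genome (log2 ratio); regions outside the annotated span
are clipped and the clipped base count reported. Region and gene-set
Fisher tests use explicit backgrounds (the region universe must contain
the hits; gene sets are intersected with the expressed-gene background
first) and report both the sample odds ratio ad/bc and the
conditional-MLE odds ratio, since "OR" is ambiguous in summaries;
zero-margin tables get a flagged Haldane-corrected sample OR. BH runs per
named comparison batch. The base-overlap fraction merges both region sets
and reports |a∩b|/|a| — asymmetric by construction unless the merged
lengths happen to be equal.

## The synthetic generator

`simulate_methylome` draws total counts as NegBin(mean 15, dispersion 8)
and methylated counts as Binomial(total, β) from a true per-site,
per-sample β surface:

- **CpG background**: a high mode Beta(26, 2) drawn per 8-site block (plus
  site noise, SD 0.04) with probability 0.78, and isolated site-level
  partially-methylated outliers Beta(5, 2.5) otherwise. The block draw
  gives the neighbour correlation CpG methylation actually shows; the
  outliers are deliberately *not* regional — regional hypomethylation
  exists only as planted features. The mixture is calibrated so the
  observed fraction of CpGs with β > 0.8 sits near 0.75 (the configured
  band 0.70–0.80), matching the bimodal landscape such studies report.
- **CpH background**: uncorrelated, 94 % Beta(0.4, 15) + 6 % Beta(1.5, 5),
  putting the observed fraction below 20 % methylation near 0.94 (band
  0.90–0.98). A quarter of CpH sites gain neuronal methylation with age
  (0.004 β/yr, ×1.3 for CAC, ×0.9 for CAG), reproducing the
  trinucleotide-specific accumulation statistic.
- **Planted features**: UMR β ≈ 0.05 (2.8–4.5 kb, 2× CpG density), LMR
  β ≈ 0.30 (0.8–1.5 kb, 1.5× density, < 30 CpGs), DMV β ≈ 0.04 (6–10 kb),
  PMD site-level β ~ Beta(2, 2) i.i.d. (the disorder signature), cell-type
  DMRs with a ±0.2 neuron−glia difference over 8–20 CpGs, and interaction
  DMRs cycling through six archetypes — (glia, neuron) direction pairs
  (0,+), (−,+), (0,−), (+,0), (+,−), (−,0) — with slopes 0.03 β/yr
  (neuron) and 0.02 β/yr (glia), i.e. the 1.5 neuron/glia effect ratio,
  intercepts 0.2/0.5/0.8 by direction, clamped to [0, 1]. β changes of
  0.02–0.03/yr match regions whose methylation moves by ~0.5 over two
  decades. Inside interaction DMRs, CpH sites share the CpG surface and a
  smooth sinusoidal positional profile (amplitude 0.12) — the
  within-region context convergence the mixed-context ACF detects.
  Homogenate samples are the 50/50 neuron/glia mixture.
- **Associations**: planted (cytosine, feature) pairs with donor-level
  β ~ U(0.05, 0.95) and expression = intercept + slope·β + Gaussian noise.
  The noise SD is solved so the target R² (default 0.5 at n = 22) describes
  the regression the scan runs — expression on *measured* β — i.e. it
  accounts for the binomial attenuation at 15× coverage. CpH-exclusive
  effects are placed in CpG-sparse neighbourhoods (a ±1.1 kb CpG exclusion
  zone), shared effects get a CpG partner 80–400 bp away whose β tracks
  the CpH within SD 0.03. Planted association sites carry a coverage floor
  of 5 reads: they represent testable sites by construction.
- **Annotation**: an exponential-length 15-state chromatin tiling (states
  inside UMRs/DMVs lean Enh/TssA, a planted enrichment), gene models with
  exons and PSI events, gene sets, and labelled assembly gaps.

Everything derives from `SimulationConfig.seed`; identical config ⇒
byte-identical output. The truth ledger records every planted region,
archetype and association.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: read-level artefacts (mapping bias,
bisulfite conversion error, hydroxymethylation), genuine genomic sequence
(CpG positions are a Poisson process; no SNPs, so the C/T-polymorphism
confound is absent), long-range methylation gradients beyond the 8-site
block scale, batch or donor random effects (samples are exchangeable given
the design), and realistic expression count noise (FPKMs are Gaussian on
the log scale). Genome sizes are 0.5–4 Mb rather than 3 Gb, so all
validation quantities are properties (power, error control, recovery),
not reproductions of genome-scale counts.

## Validation problem sizes

The acceptance suite and `scripts/acceptance.py` use: a 2-Mb genome with
30 + 20 planted DMRs and B = 250 permutations for DMR power; twenty 0.5-Mb
global-null replicates at B = 100 for FWER control; the 3-Mb default
landscape for segmentation; 300 interaction DMRs on 4 Mb for trajectory
clustering; 50 clusters × 200 sites for the AR(1)/i.i.d. ACF checks; and
three n = 22 cohorts on 2 Mb for the association scan. These sizes give
tight Monte-Carlo error at interactive runtimes on a single CPU.

## Known limitations

- With n = 22 donors and population R² = 0.5, the noncentral-t power of a
  single (cytosine, feature) test at two-sided p < 5·10⁻⁴ is ≈ 0.64
  analytically, and count-noise attenuation puts the measured planted-pair
  recovery near 0.6; single-cytosine effects of this size are simply not
  reliably detectable at that threshold and sample size. The acceptance
  suite asserts a 0.9 power target for this stage and therefore reports it
  as failing; the measured value is what the script writes.
- The shuffle-based segment FDR assumes exchangeable smoothed values
  outside segments; smoothing-induced autocorrelation makes it slightly
  anti-conservative for marginal cutoffs (mitigated by averaging shuffles).
- The moderated test assumes a common residual df across sites (true for
  complete-case β matrices, the only input `fit_sitewise` accepts).
- `bumphunt` FWER is estimated from B permutations, so its resolution is
  1/B; B < 20 is refused outright.
- Interval utilities assume in-memory region sets (fine up to millions of
  regions; no streaming).
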