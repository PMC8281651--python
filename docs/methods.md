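# Methods

`mesohet` analyzes intra-tumor heterogeneity from two biopsies taken at
different anatomical sites of the same tumor (sites coded A–D, e.g. apex vs
costo-diaphragmatic). This note documents the models, the rules and their
thresholds, the numerical choices, and what the synthetic cohorts do and do
not emulate.

## Cancer cell fraction and clonality

For a variant with allele frequency `vaf = alt / depth` in a sample of
purity `p`, lying on a segment of tumor copy number `CN_t` (normal copy
number `CN_n = 2`):

```
raw = vaf * (p * CN_t + (1 - p) * CN_n) / p          # = CCF x multiplicity
multiplicity = clamp(round(raw), 1, major_cn)         # mutated copies/cell
CCF = raw / multiplicity
```

Without a covering segment the locus is assumed diploid with multiplicity 1,
giving the closed form `CCF = 2 * vaf / p`. The 95% interval applies the
same linear transform to an exact Clopper–Pearson binomial interval on the
VAF; we make no claim of numeric identity with any other CCF tool's interval
construction. Estimates above a configurable cap (default 1.5) are capped
with a warning rather than renormalized — over-unity CCFs usually mean the
purity or copy-number input is off, and hiding that would be worse than an
odd number.

Classification across a pair: *shared* means observed in both biopsies
(a variant drawing zero alt reads is treated as absent — there is no
genotyping-error model; real calls were orthogonally validated upstream of
this kind of analysis). A variant is *subclonal* iff its CCF is below 0.5
**and** the upper CI bound is below 1, applied in **both** samples for
shared variants (the conservative reading; applying it to one sample is a
config change) and in the single observed sample for private variants.
CNV clonality uses `CCF = cellular_fraction / purity` (capped at 1, warning
beyond 1.1) with the 0.5 threshold and no CI rule. Segments are matched
across samples by chromosome, state class (gain / loss / copy-neutral LOH)
and ≥50% reciprocal overlap; copy-neutral 1+1 segments are not events;
homozygous deletions are listed separately because a variant cannot reside
on zero copies.

A *shared subclonal population* — the genomic signature of polyclonal
dissemination — is flagged when at least `min_variants = 2` variant calls
are subclonal shared (one variant is too fragile an observation; subclonal
shared CNVs are reported as corroboration, not counted). The schematic
clonal tree places clonal shared variants in the trunk, the shared subclone
as a child present in both sites, and private variants on site branches,
each node annotated with its variant count.

## Paired expression and methylation rules

All pairwise rules are taken literally, including strict vs inclusive
inequalities:

| rule | condition | boundary |
|---|---|---|
| DE gene | not(FPKM < 1 in both) and &#124;ΔVST&#124; > 1 | strict |
| DM CpG | both detection p < 0.05 and &#124;Δβ&#124; ≥ 0.2 | inclusive |
| E/S heterogeneity | &#124;ΔE.score&#124; > 0.10 | strict |
| checkpoint flag | max(FPKM) > 1 and fold change ≥ 2 | inclusive |

The inclusive DM threshold is padded by 1e-12 so that a β-shift of exactly
0.2 is not lost to floating-point subtraction. "VST" is any
variance-stabilized (log2-like) expression scale; the DE delta is taken on
it, the FPKM filter on the linear scale. Checkpoint fold changes put a
pseudo-count of 0.1 on the denominator so a zero-FPKM biopsy yields a
finite, still-flagged value. A DE_DM gene is a DE gene with ≥1 DM CpG; the
direction-consistency filter keeps a DE_DM gene when its expression change
tracks the E-score change (for E-correlated genes) or opposes it (for
S-correlated genes); methylation direction (hyper/hypo) is reported but not
part of the filter.

Cohort-level clustering uses cosine distance with Ward linkage on the 500
most variable features; variability is the per-feature range across samples
(configurable to variance), with lexicographic tie-breaks so selection is
deterministic.

## E/S deconvolution and subtyping

The histo-molecular gradient is modeled as a two-component mixture of an
epithelioid-like and a sarcomatoid-like reference profile. Scores solve
`min_w ||x - (w*E + (1-w)*S)||^2` with `w ∈ [0,1]`; for two components the
simplex-constrained least squares is closed-form (project onto the E−S axis
and clip). This is a deliberate, documented approximation of published
multi-component deconvolution approaches; numeric identity with published
scores is not claimed. Near-collinear profiles (|r| > 0.999) are rejected
because the mixture weight is then unidentifiable. Discrete subtypes use a
nearest-centroid classifier under Pearson correlation.

## Pathway scoring

ORA uses the exact hypergeometric upper tail against a background universe
of the expressed genes (not the genome), with Benjamini–Hochberg control
within each gene-set collection and significance at FDR < 0.05; gene ratio
is overlap / set size. ssGSEA is the rank-weighted ECDF-difference score
(weight `rank^0.25`), computed per sample after removing genes with FPKM < 1
in all samples, and rescaled by the global score range; a set with no
expressed member scores NaN, never 0. Intra-tumor pathway heterogeneity is
the absolute per-pair score delta. Monotonicity (up-ranking in-set genes
raises the score) holds on the unnormalized scores; after range
normalization the rescaling factor itself shifts, so comparisons across
re-scored matrices should use `normalize=False`.

## Microenvironment

Population scores are the arithmetic mean of log2-scale expression of the
population's marker genes (`log2(FPKM + 1)` for raw FPKM). Markers are
first refined against a tumor cell-line panel: a marker with FPKM ≥ 1 in
any line is dropped (a marker the tumor cells themselves express would
confound infiltration), named exclusions can be added from config, and a
population losing all markers is an error. For cross-cohort integration
each feature is z-standardized within each dataset (population sd; constant
rows become 0 with a warning; the operation is idempotent). Hot/cold
assignment clusters the **standardized** scores (cosine/Ward, k = 2) — the
cosine metric is scale-invariant, and z-scoring is what turns high- vs
low-infiltration profiles into separable (anti-parallel) directions — and
labels the higher grand-mean cluster hot. Patients whose two biopsies land
in different clusters are the hot/cold-switching cases. Paired profiles are
compared with an exact Wilcoxon signed-rank test over populations (exact
null up to 25 populations).

## Synthetic cohorts

The generator emulates the statistical structure of a paired-biopsy study:

- **Clones.** A trunk clone plus subclones as children of the trunk,
  cumulative mutation sets (a descendant carries all ancestral mutations).
  The true CCF of a mutation at a site is the summed fraction of carrying
  clones; trunk mutations are CCF 1 everywhere. Scenarios: all subclones
  private; a subclone below 0.5 in both sites (the polyclonal-dissemination
  configuration); and a mixed scenario that also plants private clones
  above 0.5 so all four categories occur. Subclone fractions are drawn in
  (0.1, 0.45), total subclone mass capped at 0.8 per site.
- **Reads.** Depth ~ Poisson(mean) floored at 20; alt ~
  Binomial(depth, CCF·m·p / (p·CN_t + (1−p)·2)); zero alt reads ⇒ absent.
  Purity defaults to Uniform(0.3, 0.9) — wide, because low-purity biopsies
  are exactly where clonality analysis degrades.
- **Expression.** VST = E.score·E-profile + S.score·S-profile + immune
  abundances on marker genes + Gaussian noise (sd 0.3 by default); FPKM
  linked as `2^VST − 1` floored at 0 so the FPKM<1 and VST<1 filters
  coincide; planted DE genes get a ±1.5 shift in site A.
- **Methylation.** Bimodal Beta(10,2)/Beta(2,10) baselines, planted DM CpGs
  shifted by ±0.3 toward the free end of [0,1], detection p small except a
  configurable failure fraction.

Not emulated: base-resolution CNV breakpoints, fusion transcripts, FFPE or
array batch artifacts, genotyping error, germline contamination. Passing
recovery tests therefore shows the estimators invert this generative model
correctly under realistic sampling noise — not that they are robust to
every artifact of real tumor data.

## Problem sizes and determinism

Package-level checks run at: 100 simulated cohorts of 200 variants (depth
500, purity ≥ 0.5) for category recovery; 5,000 variants at depth 100 for
interval coverage; 10,000 cases for the closed-form identity; 100
replicates each for deconvolution, hot/cold and mixed-pair recovery; an
8-patient, all-layer cohort (~1,200 genes, ~1,500 CpGs) for the end-to-end
run. These sizes make the whole battery complete in well under a minute
each while keeping Monte-Carlo error far from the decision thresholds.
Every stochastic step takes an explicit seed; pipeline outputs are
byte-identical across re-runs of the same config, and the run manifest
records version, seed and thresholds (all of the rule thresholds above are
config keys with the defaults listed here).

## Known limitations

- The CCF interval inherits Clopper–Pearson conservatism; coverage is above
  nominal rather than exact.
- Multiplicity is a point estimate (nearest integer); uncertainty in
  multiplicity is not propagated into the CI.
- Two-sample pairs only; >2 biopsies per patient are reduced to the pair
  with the closest purities before analysis.
- The E/S deconvolution is two-component; partial immune/stromal
  contamination of the expression signal is absorbed into the residual.
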