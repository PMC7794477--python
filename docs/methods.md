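# Methods

`meltmark` implements the analytical layer of a multi-cancer liquid-biopsy
evaluation of *ZNF154* CpG-island methylation (array probe cg21790626). Four
computational stages are covered: tissue-level marker screening, digital
melt-curve (DREAMing) fragment counting, ddPCR mutant-allele-fraction
computation, and ROC-based case/control classification, together with
synthetic-data generators that stand in for array, plasma, and droplet
inputs.

## Tissue-level marker screening

For each cancer type with tumor and normal-tissue beta values at the probe,
the hypermethylation cutoff *c* is the empirical 95% quantile of the control
betas (the `exclusion` parameter; quantile convention = linear interpolation
between order statistics, the default of the scientific Python stack, exposed
as `quantile_method`). A tumor is hypermethylated iff β > *c*, strictly: a
tumor exactly at the cutoff is not called, because the cutoff is defined to
be *exceeded* by ~5% of controls. With tumors drawn from the control
distribution this calibrates to ≈ 5% positives, which the test suite checks
at n = 2,000 over 20 seeds.

The mutation comparator is the fraction of tumors carrying a non-silent SNV
in any gene of a per-cancer driver gene set. The gene sets, their per-gene
prevalences, the per-cancer cutoffs and frequencies, and cohort sizes ship
as packaged data (`data/marker_reference.json`). The kidney papillary
carcinoma set is a single gene (MET, 7.5%) — the documented exception where
no gene passed the 10% recurrence threshold — encoded as data, not logic.

Percentages destined for summary tables are rounded half away from zero to
one decimal, matching how such tables are conventionally printed; raw
fractions are retained everywhere else. Samples with missing beta are
dropped with a logged count, never imputed. Age-association summaries bin
ages into decades by default ([20,30), [30,40), …); the bin edges are a
parameter since no convention is canonical.

## DREAMing forward model and peak calling

The melt derivative curve of a well is modeled as a sum of Gaussian peaks on
a temperature grid (default 65–90 °C at 0.1 °C):

- the unmethylated background melts at `tm_u` (default 74.0 °C) with area
  `background_copies / 200` — proportional to input, normalized so the
  standard 200-copy background has unit area;
- each methylated epiallele of density *d* (number of methylated CpGs among
  the 14 internal sites) adds a peak at `tm_u + d · delta_per_cpg`
  (default 0.4 °C/CpG) with area `methylated_amplitude` (default 1.0).

The unit methylated-peak area relative to a 200-fold molar excess of
background encodes the assay's methylation-biased primers: a single
methylated template amplifies to an endpoint product comparable to the
background, which is what makes single-molecule detection possible at all.
Peak width is σ = 0.25 °C. This value is constrained by two requirements
pulling in opposite directions: two equal Gaussians separated by Δ merge
into a unimodal curve when Δ < 2σ, so σ must be small enough that a d = 2
epiallele (Δ = 0.8 °C) yields a resolvable second peak with a deep valley
(at σ = 0.25 the secondary peak's prominence is ≈ 45% of the curve maximum,
versus ≈ 3% at σ = 0.35), yet large enough that d = 1 (Δ = 0.4 °C < 2σ)
remains unresolved — the assay's genuine hard case. None of the melt-shape
constants is a claim about the real 175-bp amplicon; all are `MeltModel`
fields.

Peak calling smooths the curve with a narrow Gaussian filter (0.15 °C) and
takes local maxima with topographic prominence ≥ 10% of the tallest signal.
A well is methylated iff a peak sits at or above `tm_u + min_separation`
(default 0.3 °C); the hottest such peak is reported and its density inferred
by inverting the linear Tm model (rounded, clipped to [1,14]). Wells with
multiple methylated epialleles report the hottest peak but still count one
fragment — the same undercount the physical assay makes. A curve whose
maximum is below 5% of a unit peak is flagged "no amplification" and excluded
from both numerator and denominator. Under this configuration, calls at
d ≥ 2 are ≥ 99% correct (density exactly recovered) at additive noise up to
σ_noise = 0.05 signal units (~3% of peak height), with no background false
positives, verified over 1,000 seeded replicates.

Copies are partitioned across wells multinomially (each copy uniform over
wells), the finite-well form of Poisson partitioning; the expected number of
occupied wells is `W(1 − (1 − 1/W)^n)`. Fragment counting is the raw number
of methylated wells. The Poisson occupancy correction
`λ̂ = −W ln(1 − k/W)` is provided (`poisson_corrected_count`) but off by
default, since the assay reports peak counts directly as fragment proxies.

Normalization: the equivalent plasma volume is starting plasma volume × the
fraction of bisulfite-converted beta-actin targets loaded into the wells;
normalized output is fragments per mL = count / equivalent volume. The
spike-in sensitivity experiment (3 or 5 fully methylated targets across 12
wells of 200 background copies, 5 replicates) reports detected counts per
replicate and the mean absolute error; in noiseless runs, co-occupancy is
the only loss source, so detected equals occupied wells.

## ddPCR mutant allele fraction

Reactions are pooled by summing droplets — raw MtAF = Σ mutant / Σ (mutant +
wild-type) — making the result invariant to how droplets split across
reactions. The normalized MtAF divides the raw fraction by the mL of plasma
assayed (starting volume × fraction of the elution used); the resulting
per-mL unit is unusual but kept verbatim and surfaced in output headers. A
sample with zero amplified droplets is reported as missing (assay failure),
not as MtAF 0. Detection is ≥ 1 mutant droplet in any reaction. The 7-target
KRAS screen is collapsed to one mutant channel, as the screening assay
reports it.

## Classification statistics

ROC curves use the "higher score ⇒ case" convention with positivity at
score ≥ cutoff, so every reported cutoff is an attainable sample value.
Thresholds are the distinct observed scores plus a +∞ sentinel; AUC is the
trapezoidal area, identical to the Mann–Whitney U scaled by
n_case · n_control with ties counted ½ (verified against a brute-force
pairwise oracle and scikit-learn). The optimal cutoff maximizes the Youden
index TPR − FPR; ties prefer lower FPR, then higher cutoff — the
screening-oriented choice favoring specificity. Whether the equality case
belongs to the positive class is a convention the data cannot decide; ≥ is
recorded and overridable via the `direction` argument and threshold set.

The Wilcoxon rank-sum test uses exact enumeration for combined n ≤ 12
without ties and a tie-corrected normal approximation with continuity
correction otherwise (via `scipy.stats.mannwhitneyu`); the crossover keeps
small worked examples exact while scaling to cohort sizes. Pearson
correlations on constant input are reported as absent (`None`), never 0.

## Synthetic cohorts: what they emulate, and what not

The generators reproduce the *reported statistical structure* of the study
data, not its biology:

- **Tissue**: controls ~ Beta(2, 48) (mean 0.04, the lowly methylated
  regime); tumors are a mixture of a hypermethylated component Beta(6, 3)
  and the control component, weighted so the expected hypermethylation
  frequency matches the packaged per-cancer reference values. Mutations are
  independent Bernoulli draws at the packaged prevalences; TP53 is included
  as an extra column where it is not part of the driver set, so the
  hypermethylation/TP53 ratio is computable for every type.
- **Plasma**: per sample, plasma volume ~ U(1.5, 4) mL and fraction loaded
  ~ U(0.3, 1); the methylated fragment count is negative binomial with mean
  = rate × equivalent volume. Group rates are specified as target *medians*
  (controls 11.38, late pancreatic 19.47, early pancreatic 18.6, ovarian
  27.30, liver 14.56, colon 64.49 fragments/mL) and converted to NB means
  through the gamma-quantile median/mean ratio, so the configured medians
  are recovered (within 10% at n = 200, 20 seeds). The dispersion default of
  12 was calibrated once so that the late-stage pancreatic vs control
  comparison at study sizes (17 vs 20) yields a mean AUC ≈ 0.85 given those
  medians — the jointly reported effect size; the calibration script result
  is frozen and the knob is per-group. A smaller dispersion (heavier spread)
  is incompatible with that AUC at those medians: at dispersion 2 the
  achievable AUC is ≈ 0.69.
- **ddPCR**: detection ~ Bernoulli(9/17 late pancreatic, 7/20 controls, 0
  early pancreatic); a detected sample carries 1 + Poisson(4) mutant
  droplets split across 2 reactions of ~2,500 wild-type droplets each,
  placing normalized MtAFs in the 10⁻⁴–10⁻³ per-mL range.

Age and sex annotations mimic the reported cohort skew (controls median
~71.5 y, ovarian 59, pancreatic 60) so demographic summaries have realistic
inputs. An optional multiplicative age effect on control fragment rates
exists for sensitivity analyses but is off by default — no established
effect is asserted. The methylation-density spectrum of plasma epialleles is
uniform on 1..14; no per-density spectrum is reported to emulate. The number
of DREAMing wells per patient sample is not a published quantity; the
default is 96, and patient-level counts bypass well materialization unless
requested, matching the raw-count bookkeeping of the assay.

Passing generator-based tests therefore demonstrates correctness of the
*computational pipeline* under the reported group-level statistics; it says
nothing about array normalization, bisulfite chemistry, primer behavior on
real amplicons, or biological covariates beyond those modeled.

## Determinism and numerical choices

Every stochastic operation accepts a seed or Generator; cohort generators
fan a single root seed out through counter-based `SeedSequence` streams
keyed by stream tag, group-name CRC, and sample index, so any subset of a
simulation is bit-reproducible in isolation. Problem sizes in the test and
acceptance workloads (10,000 partition draws, 20-seed recovery suites,
1,000-replicate call-accuracy checks, n = 200 per group for median
recovery) were chosen as the smallest sizes at which Monte-Carlo error is
comfortably below the asserted tolerances. Floating-point tie handling in
the ROC scan uses a 1e-12 slack; melt-peak positions are quantized to the
0.1 °C grid, bounding density-inference error at ±0.125 CpG — below the
rounding threshold.

## Known limitations

- Exact per-cancer cutoffs from the original arrays are not reproducible
  without the underlying beta matrices; the packaged reference stores the
  printed values, and the pipeline recomputes cutoffs only for data it is
  given.
- The melt forward model is phenomenological: no thermodynamic nearest-
  neighbor calculation, no heteroduplex or salt effects, no baseline drift.
- The per-mL-normalized MtAF inherits the source definition's odd units.
- Patient-sample fragment counting applies no occupancy correction by
  default; at high fragment loads relative to well count this undercounts.
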