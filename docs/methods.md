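# Methods

## Measurement model

Each CpG dyad in each sample carries true levels (m, h) on the simplex
m ≥ 0, h ≥ 0, m + h ≤ 1, for 5mC and 5hmC. Sequencing reads report C
(protected) or T (converted). With conversion-failure rate ε_f (unmodified C
reads as C), over-conversion rate ε_o (protected base reads as T) and
oxidation efficiency η (probability a 5hmC in the oxBS library is oxidised
and then converts), the per-read probability of a C call is

    p_BS   = (m + h)(1 − ε_o) + (1 − m − h) ε_f
    p_oxBS = m(1 − ε_o) + h(1 − η)(1 − ε_o) + (1 − m − h) ε_f

Counts are Binomial(n, p) with per-site, per-library coverage n drawn from a
negative binomial (RRBS depth is overdispersed; BS and oxBS are independent
libraries). Under perfect chemistry (ε_f = ε_o = 0, η = 1),
E[β_BS − β_oxBS] = h exactly, which is what makes the subtraction estimator
the natural target.

Defaults: ε_f = ε_o = 0.005 (bisulfite conversion is typically > 99%
complete), η = 0.95 (oxBS oxidation is efficient but not perfect). These are
package defaults for realistic simulation, not estimates from any dataset;
all three are configurable, and the validation studies that probe estimator
identities use perfect chemistry explicitly.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes and
nothing more. Features emulated: simplex-constrained (m, h) with a bimodal
5mC baseline (high gene-body-like component Beta(6,2) with weight 0.55, low
promoter-like component Beta(1.5,8)) and a low unimodal 5hmC baseline
(Beta(1.5,20), mean ≈ 0.07, as in somatic tissue); region-level group
effects applied homogeneously to case samples, optionally coupled to an
opposite shift of the other mark (anti-correlated remodelling); optional
per-(sample, region) Gaussian heterogeneity for biological between-sample
variance (default off); overdispersed coverage; clustered, RRBS-island-like
CpG spacing (gaps mostly 20–120 bp with occasional 0.5–3 kb jumps); a
minimal two-transcripts-per-chromosome gene model so every annotation
category is realisable.

Features *not* emulated: read-level artefacts (PCR duplication, MspI
digestion, mapping bias), spatial autocorrelation of methylation beyond the
planted regions, CpG-density-dependent coverage, batch effects, impure
tumour samples. Passing tests therefore demonstrate correctness of the
estimators and the calling logic under the stated sampling model, not
robustness to those real-data artefacts.

Shifts that would leave the simplex are clipped with 5mC priority (m is
clipped to [0,1], then h to [0, 1−m]); a planted shift at an extreme
baseline is consequently only partially realised, which is intended — it is
how a hypo-5hmC effect at a low-5hmC locus behaves in reality.

## Estimation

`raw` mode is the default for group-difference and correlation analyses
because it is unbiased; `clamp` projects onto [0,1] for reportable
per-sample levels; `mle` maximises the product of the two binomial
likelihoods over the simplex. The likelihood is separable in (m, t = m + h),
so the constrained optimum has closed form: the subtraction estimate when
β_oxBS ≤ β_BS, else the pooled boundary estimate
m = (c_BS + c_oxBS)/(n_BS + n_oxBS), h = 0. This is verified against an
exhaustive 0.001-lattice likelihood search.

Sites need ≥ 5 reads in *both* libraries by default (`min_cov`), a standard
RRBS practice; the filter is configurable and the validation studies state
theirs. Because ĥ and m̂ share the −β_oxBS/+β_oxBS term, their estimation
errors are negatively correlated even under independent noise — a known
artefact of subtraction-based 5hmC estimation that inflates apparent
5mC/5hmC anti-correlation. The package tests the sign of this artefact
explicitly, and the planted-coupling studies use effects large enough that
the biological signal, not the artefact, dominates.

## DMR calling

Sites retained for a contrast must be covered in ≥ 80% of the samples of
each group. Retained CpGs are grouped into runs with inter-CpG gaps
≤ 300 bp; each run is split recursively at the breakpoint maximising the
contrast between child mean differences, accepted while both children keep
≥ 5 CpGs and the best child |mean difference| improves on the parent's by
≥ 0.05. Leaves are candidates. This is an explicit, documented segmentation;
it is deliberately conservative (a step must improve the achievable effect
size to justify a split) and is not a byte-for-byte re-implementation of any
external tool.

Candidates are tested on per-sample region means — samples, not CpGs, are
the replication unit, so the test is valid under within-region correlation
of CpGs. The two-sided Mann–Whitney p is computed from the exact permutation
distribution (complete enumeration over mid-rank assignments, hence correct
under ties) when n₁+n₂ ≤ 12, and by the tie-corrected normal approximation
with continuity correction otherwise. BH adjustment is applied within each
(contrast, mark) family, since the three mark families are reported
separately. Significance requires q < 0.05 *and* |Δ| above the mark gate:
0.2 for 5mC and BS, 0.1 for 5hmC — the smaller 5hmC gate reflecting the
mark's lower dynamic range.

## Annotation

Midpoint assignment with precedence promoter > exon > TTS > intron >
intergenic guarantees a partition (every DMR exactly one category).
Promoter = TSS −1000..+100 bp and TTS window = −100..+1000 bp, strand-aware,
HOMER-like defaults; both windows configurable. Any-overlap annotation was
considered and rejected as the default because it requires an arbitrary
multi-category resolution rule anyway; precedence-on-midpoint is
deterministic and auditable.

## Biomarker screening and signal comparison

Each significant DMR is scored by the rank-based AUC of its per-sample
region means (U/(n₁n₀), mid-rank ties), oriented by the marker's direction —
a hypomethylated marker classifies by lower values, so its raw
case-vs-control AUC a is reported as 1 − a. The screen keeps significant
DMRs with oriented AUC > 0.8. No cross-validation is applied: these are
apparent AUCs, appropriate for screening and comparison but optimistic as
estimates of out-of-sample performance.

`compare_signals` evaluates one region on 5mC (β_oxBS), 5hmC (subtraction)
and BS (β_BS) with un-oriented AUCs so the directions remain visible. The
attenuation phenomenon follows from arithmetic: if the case group shifts by
δ_m on 5mC and δ_h (opposite sign) on 5hmC, the BS shift is δ_m + δ_h, while
between-sample noise on BS is no smaller — so the BS effect size, hence AUC,
is attenuated; with δ_h = −δ_m the BS signal carries no group information at
all. Profile correlations (Pearson default, Spearman available) operate on
region-level mean-difference vectors over shared regions; region-level units
average out the site-level subtraction artefact better than site-level
correlations would.

## Validation studies (experiments module)

Problem sizes were chosen desk-scale so the full battery runs in about half
a minute, while keeping Monte-Carlo error well inside each assertion's
margin:

- **Recovery**: 1 sample, 1000 CpGs, 50× near-fixed depth, perfect
  chemistry, true h = 0.2 constant; mean ĥ asserted within 0.02 (≈ 3 SE).
- **Oracle agreements**: 200 random count pairs for the MLE vs lattice
  (tolerance 0.002, twice the lattice step); 100 random small-sample inputs
  for exact MWU vs full permutation enumeration (equality to 1e-12); 1000
  random p-vectors for BH vs an independent step-up implementation (1e-12);
  500 random tie-rich inputs for rank AUC vs pair counting (1e-12).
- **Null error control**: 50 cohorts, 10 vs 10, 2000 CpGs, no effects; the
  fraction of replicates with any significant DMR (either mark) must stay
  ≤ 0.1. The dual gate makes the empirical rate ≈ 0.
- **Recall**: 20 planted regions of 10 CpGs in isolated CpG clusters,
  30× depth, 10 vs 10, fixed moderate baselines (m = 0.45, h = 0.25) so
  ±0.3 (5mC) and ±0.15 (5hmC) shifts are fully realisable; recall ≥ 0.9 and
  ≥ 0.7 respectively at the standard thresholds. Clusters are isolated
  because the study probes calling power; breakpoint placement has its own
  unit tests.
- **Attenuation**: 100 replicates of a single 10-CpG region, 10 vs 10, with
  +0.3 5mC coupled to −0.15 5hmC, baselines m = 0.35, h = 0.40 (the
  high-5hmC regime where anti-correlated remodelling is plausible), and
  per-sample regional heterogeneity sd 0.1 — without between-sample
  biological variance both AUCs saturate at 1 and the comparison is
  degenerate. AUC_BS < AUC_5mC must hold in ≥ 90% of replicates; with
  exactly cancelling shifts (−0.3) the mean BS AUC must sit within 0.05 of
  0.5.
- **Anti-correlation**: 50 replicates of 20 regions whose 5mC shifts
  (uniform ±0.1–0.3) are each coupled to an opposite-sign 5hmC shift at
  half size; the region-level Δ5mC-vs-Δ5hmC Pearson r must be negative in
  ≥ 95% of replicates.

## Known limitations

- The subtraction estimator's variance is the *sum* of the two library
  variances; at low coverage ĥ is noisy and often negative. The MLE mode
  removes the negativity but not the noise.
- Oxidation efficiency η < 1 biases ĥ downward by (1−η)h(1−ε_o); no
  spike-in-based correction is implemented.
- The segmentation is greedy binary splitting; a region whose effect decays
  smoothly across a run can be split at a data-dependent breakpoint.
- Paired designs, covariates and cell-composition deconvolution are out of
  scope; groups are compared marginally.
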