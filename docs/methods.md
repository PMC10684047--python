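# Methods

## The models

Calving difficulty is a producer-recorded 1–4 score (1 = unassisted, 4 =
veterinary assistance).  It is analysed linearly with an animal–dam mixed
model:

    y = sex + het_a + het_d + rec_a + rec_d + parity|age
        + Σ_k breed_ka + Σ_k breed_kd + MSTN_a + MSTN_d
        + CG + Calf_a + Dam_m + Dam_pe + e

with fixed effects: calf sex; general heterosis and recombination-loss
coefficients of calf and dam; the dam-parity × age-deviation class; the
calf's and dam's breed fractions over the 12 breeds as covariates; and the
myostatin genotype (or haplotype-copy) classes of calf (`MSTN_a`) and dam
(`MSTN_d`), coded as unordered 0/1/2-copy classes with the 0-copy (`+/+`)
class as reference.  Random effects: contemporary group
`CG ~ N(0, I σ²_CG)`; the calf's direct polygenic effect
`Calf_a ~ N(0, A σ²_g)`; the dam's maternal genetic effect
`Dam_m ~ N(0, A σ²_m)`; the dam's permanent environmental effect
`Dam_pe ~ N(0, I σ²_pe)` (constant across her parities); and residual
`e ~ N(0, I σ²_e)`.  `A` is the pedigree numerator relationship matrix.
The direct–maternal genetic covariance is fixed at zero: the model lists
independent distributions for the two effects and no covariance is
estimated.

Carcass weight (kg), conformation and fat (EUROP 1–15) use the animal
model

    y = het_a + rec_a + parity + age|sex + CG + Σ_k breed_ka + MSTN_a
        + Animal_a + e

where contemporary group is a *fixed* herd-year-sex effect, `age|sex` is
slaughter age in whole months crossed with sex class (heifer / steer /
young bull), and the only pedigree-structured random effect is the
animal's direct polygenic effect.

Covariates:

* heterosis = 1 − Σ_i sire_i · dam_i over breed fractions;
* recombination loss = 1 − Σ_i (sire_i² + dam_i²)/2.  The squares are
  placed so that every purebred × purebred mating scores exactly 0; the
  alternative reading (product of squares) would assign purebred matings a
  nonsensical loss of 0.5.
* parity|age: the deviation of age at calving from the parity median is
  banded into 30-day bins rounded away from zero (deviation 0 → band 0,
  (0, 30] → +1, …), capped by the ±425-day edit.  Banding is used because
  the term enters as a class effect; the band width is configurable.  The
  source analysis does not state whether the deviation is banded or
  continuous — this is this package's choice, flagged as such.

## Record editing and contemporary groups

Calving edits, applied in order, each removal attributed to the first rule
that catches it: parity > 15; |age − parity median| > 425 d; first parity
younger than 660 d (660 kept); twin births and embryo transfers; herd-years
without variability in the score; herd-years with < 5 genotyped dam-progeny
pairs; missing sire; breed-society registration.  Carcass edits: slaughter
age outside 14–36 mo (steers, heifers) or 12–24 mo (young bulls); weight
outside 100–800 kg (bounds kept); dam parity > 10 or embryo transfer; more
than two lifetime herds or a herd move within 100 d of slaughter
(inclusive); breed-society registration.  Bounds are inclusive unless the
source wording is strict.

Calving contemporary groups (herd-year-season): within herd, records chain
into clusters while consecutive calvings are ≤ 10 d apart; clusters of
< 10 records merge with the nearest-in-time adjacent cluster provided the
merged first-to-last span stays < 90 d, iterating until stable (ties merge
with the earlier neighbour — determinism over an unstated order); groups
with < 3 records are discarded.  "Season" is emergent from the clustering,
not a calendar lookup.  Whether the merge loop is applied once or to
convergence is unstated; iterating to a fixed point was chosen.  Carcass
groups chain herd × sex records at ≤ 60 d gaps and are retained with ≥ 5
genotyped members.

## Pedigree machinery

`A` is never formed at scale.  Its sparse inverse comes from Henderson's
rules with inbreeding: the Mendelian-sampling variance ratio `d_i`
(1 for founders; 0.5 − 0.25(F_s + F_d) with both parents known;
0.75 − 0.25 F_p with one) uses inbreeding coefficients from the
Meuwissen–Luo ancestor-walk recursion.  Unknown parents are base-population
animals; unknown-parent groups are not implemented (the source analysis
does not use them).  Animals are ordered topologically (parents first, ties
by birth date then identifier) for deterministic sparse structure.
`log |A| = Σ log d_i` feeds the REML likelihood.

## REML

Variance components maximise the exact restricted log-likelihood

    −2ℓ_R = (n − p) log σ̂²_e + Σ_i [q_i log γ_i + log|G_i|] + log|C*| + const

profiled over the residual variance (σ̂²_e = y'Py/(n − p)), where
γ_i = σ²_i/σ²_e, and `C*` is the full MME coefficient matrix at unit
residual variance.  `log|C*|` comes from a sparse LDLᵀ factorisation.
Optimisation is derivative-free on log γ: Brent for one component,
Nelder-Mead (adaptive, with restarts from the incumbent on simplex
collapse) otherwise; convergence is judged on the restricted
log-likelihood (tolerance 1e-6), with ratios bounded in [1e-5, 1e5] and
components at the bound reported as boundary estimates.  Scoring-type
updates (AI-REML) would need traces of inverse blocks, i.e. a selected
sparse inversion; direct likelihood maximisation reaches the same optimum
with factorisations only.  Starting values split 30% of the phenotypic
variance evenly over the random terms unless supplied; replicated studies
warm-start each fit from the previous replicate's estimates, which changes
the path, not the optimum.

### Sparse solver

MMEs for herd-structured data are nearly block-diagonal with a few hub
columns (AI sires used across herds, dense covariate columns).  The
factorisation is an up-looking sparse LDLᵀ (numba) over the *entire*
coefficient matrix — fixed and random equations together — under a plain
minimum-degree ordering computed on the low-degree subgraph, with hub
columns (degree ≥ cutoff) appended last.  Symbolic analysis (ordering,
elimination tree, row patterns) is done once per model structure; each
REML evaluation only redoes the numeric phase (~0.1 s at 34,000
equations).  The ordering affects speed only; correctness is guarded by an
oracle test suite in which every MME solution is compared with dense GLS.

### Estimability

Class levels whose design column is empty or linearly dependent on earlier
columns are flagged NE (non-estimable) by an ordered-pivot Cholesky on
X'X (pivot tolerance 1e-9 relative): earlier-listed columns win, matching
the convention that later-listed aliased units are dropped in concurrent
fits.  Wald F-tests use the term's estimable columns with denominator
degrees of freedom n − rank(X), a containment-style residual
approximation (Kenward–Roger is out of scope).  For a single-df term the
F statistic equals (estimate/SE)² identically.

### Dam-by-calf interaction

The interaction model adds a concatenated dam-calf genotype class in
*deviation coding*: combinations in which either animal carries 0 copies
collapse into the reference, so each remaining dummy is directly the
deviation of that combination from the sum of the marginal class effects.
Mendelian transmission empties two cells of the 3×3 grid (a mh/mh dam
cannot produce a +/+ calf and vice versa), which aliases two of the
deviation dummies with the marginal classes.  Interaction levels are
ordered with the homozygote-by-homozygote cell first, so the two
identification constraints land on the mixed cells; under the simulated
truth (deviation only in the mh/mh × mh/mh cell) the constrained cells'
true deviations are zero and the reported deviation is unbiased.  Absent
combinations appear as NE cells in the interaction matrix.

## Synthetic data

The generator emulates the study's data structure with known truth:

* **Pedigree/herds (calving).**  40 herds; per herd: 10 purebred
  great-granddams and shared ancestral sires (so foundation dams are
  themselves crossbred and the heterosis/recombination covariates span
  their range — with exclusively purebred sires the recombination
  covariates are exact linear combinations of the heterosis covariates),
  25 foundation dams, a 3–4 bull herd sire team plus one crossbred F1
  bull, 5 service bulls plus one F1, 75 replacement dams; 10 AI sires
  shared across herds; 2–5 parities per dam (~10,000 dam-progeny pairs).
  Breed draws follow a Belgian-Blue-enriched mix (BB 0.25, CH/LM/AA 0.15,
  HE/HO 0.10, SI/FR 0.05) so that mh/mh dams and calves at nt821 are
  common enough (several hundred per replicate) for the homozygote effects
  to be estimable; mating is part-assortative by breed.
* **Dates.**  Three seasonal calving blocks per herd-year, ~12 days wide,
  so the contemporary-group assigner recovers valid groups by construction
  (~480 groups); blocks under 10 records merge or survive naturally.
* **Genotypes.**  Founders draw two haplotypes from their breed's pool —
  the 22-haplotype catalogue at the published within-breed frequencies,
  renormalised (the printed tables omit haplotypes under 1%, so columns do
  not reach 100%).  Offspring receive one unrecombined parental haplotype
  each (the gene spans a few kb; no within-locus recombination).  The
  genotype table is the allele count implied by the haplotype pair, always.
* **Phenotypes.**  y is the sum of the configured fixed effects, genotype
  class effects of calf and dam (plus any interaction deviation), and
  random draws: contemporary group on the generative blocks, direct and
  maternal genetic effects by Mendelian-sampling cascade (exactly
  N(0, A σ²)), dam permanent environment, residual.  Scores are simulated
  and analysed on the continuous scale, matching the linear treatment of
  the 1–4 score; `discretize_scores` can impose the national category
  proportions (~90.9/7.5/1.3/0.3%) for robustness experiments only.
* **Carcass design.**  Two-generation progeny structure, slaughter batches
  forming ~480 herd-year-sex groups of ≥ 5.  For a focal variant the
  founder sires are guaranteed carriers (carrier-sire progeny design):
  at the survey's frequencies, homozygous Q204X animals would number ~6
  per 10,000 and the homozygote effect could not be measured.  True
  variances: σ²_g = 900, σ²_e = 1600 (kg²; phenotypic SD ≈ 52 kg at
  h² ≈ 0.36), fixed contemporary-group effects with SD 20 kg.

Calving variance components default to σ²_CG = 0.02, σ²_g = 0.04,
σ²_m = 0.02, σ²_pe = 0.01, σ²_e = 0.30 (score²).  All randomness flows
from one seed through named, crc32-keyed substreams of a single generator.

### What the generator does not emulate

Genotyping error, phasing error (truth phase is carried), missing
genotypes, unknown parents, selection (parents are not chosen on the
trait), genotype-by-environment interaction, and real LD with flanking
markers.  Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the stated model, not robustness to these
real-data features.

## Replicated studies

Parameter-recovery studies share one design (pedigree, herd structure,
contemporary groups) across replicates and redraw genotypes, genetic
effects and noise; inference is conditional on the design, as is standard
for such simulation studies, and the sharing lets the symbolic
factorisation be reused.  Recovery is assessed as |mean estimate − truth|
≤ 2 Monte-Carlo SEs over ≥ 20 replicates.  The null-calibration study
(size of the genotype F-test) fixes the design *including* the genotype
draw and redraws phenotypes only — exactly the conditional sampling model
under which the F-test claims its 5% size — re-estimating REML components
every replicate (1,000 replicates, ~2,000 records each).

Problem sizes: the calving studies run ~10,200 dam-progeny pairs in ~670
groups per replicate (34,000 mixed-model equations); the carcass studies
~9,500 records; the test suite runs the full 20-replicate studies and the
analysis drivers a 5-replicate summary.

## Known limitations

* Ordinal scores are treated linearly throughout; no threshold model.
* Denominator df are a containment-style approximation; with ~10⁴ records
  the F-test is effectively a chi-square test and the approximation is
  immaterial, but small-sample df will differ from Kenward–Roger.
* No multiple-testing correction across variants by default (matching the
  original analysis plan); a Bonferroni option exists.
* Component SEs are not reported (the likelihood optimiser is
  derivative-free); recovery studies assess components via replicate
  scatter instead.
* The across-breed summaries include zeros for breeds where a haplotype is
  absent — required for the unweighted-mean convention — so they are not
  comparable to frequency estimates over carriers only.
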