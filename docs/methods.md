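# Methods

`pedstrat` studies how population stratification affects family-based
association in admixed extended pedigrees, and how much of the damage
principal-component (PC) adjustment repairs. Because the motivating study
population (large admixed Mexican American pedigrees with whole-genome SNP
data) is controlled-access, the package ships a synthetic-data generator that
reproduces the *statistical structure* of such a sample; every analysis stage
is exercised and tested against that generator.

## The synthetic admixed-pedigree generator

**Pedigrees.** Each family is grown to a target size (drawn uniformly from
`family_size_range`, default 22–86, with 20 families) by alternating two
moves: an existing couple produces 2–4 children, and an unmarried child is
married to a newly created, unrelated founder. This yields 3–5 generation
outbred pedigrees of the requested sizes with no inbreeding loops. The
smallest constructible family is a trio.

**Ancestry.** Allele frequencies for K = 3 ancestral populations (a
European / Amerindian / African analogue) follow the Balding–Nichols model:
per variant, a base frequency p ~ Uniform(0.05, 0.95), then each
population's frequency ~ Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst), which has
mean p and variance Fst·p(1−p). Default Fst = 0.2. Variants that come out
effectively fixed everywhere are redrawn.

Families receive admixture proportions from a Dirichlet(5.0, 4.5, 0.5)
(mean ≈ 0.53/0.47/0.05, a Mexican American–like profile). By default four
families are planted at divergent admixture — (0.90, 0.05, 0.05) vs
(0.05, 0.90, 0.05), and (0.05, 0.05, 0.90) vs (0.45, 0.45, 0.10) — so that
one family pair separates on each of the first two genotype PCs, the
structure the AIM-selection stage exploits.

Within a family, marry-in founders are not ancestry clones of each other:
each founder draws its own admixture from Dirichlet(c·w_family) with
concentration c = 10 (individual ancestry SD ≈ 0.10–0.15 around the family
mean, consistent with what admixed extended pedigrees show), and every
non-founder's ancestry is the mean of its parents'. This within-family
ancestry heterogeneity matters: it is what makes stratification confound an
analysis that already includes a family intercept (see below).

**Genotypes.** Founder dosages are two independent Bernoulli draws with
success probability equal to the founder's admixture-weighted ancestral
frequency. Non-founders are generated by gene dropping: one allele from each
parent, chosen uniformly and independently per variant. Variants are
unlinked (no LD) — the delta statistic and PCA used downstream do not model
LD, so simulating it would only complicate the oracle structure; this is a
deliberate simplification. Output is Mendelian-consistent by construction,
and there is no genotyping-error or missingness model by default.

**Trait model.** For individual i in family f,

    y_i = β₀ + β_med·med_i + β_sex·sex_i + β_age·age_i + β_sexage·sex_i·age_i
          + β_anc·(anc_i − mean(anc)) + Σ_c β_c·g_ic + u_f + e_i,

with u_f ~ N(0, σ²_fam) i.i.d. per family and e_i ~ N(0, σ²_e). Defaults are
systolic-blood-pressure-like (mmHg): β₀ = 110, β_med = 5, β_sex(female) = −5,
β_age = 0.5/yr, β_sexage = 0.1, σ²_fam = 25, σ²_e = 100; covariates are
age ~ Uniform(20, 80), sex from the pedigree, medication ~ Bernoulli(0.2),
all independent of genotype. 134 causal SNPs are drawn among variants with
MAF > 0.05 with effects β_c ~ N(0, 0.8²), which puts per-SNP power in the
low tens of percent at n ≈ 950 and α = 0.05 — the regime the method
comparison is about.

`anc_i` is the individual's leading admixture proportion and β_anc = 15
models environmental exposure that covaries with ancestry (diet,
socioeconomic factors). It enters through the latent admixture proportions
only, never through genotypes. This term is the confounding engine of the
stratified scenario: its between-family component is absorbed by any family
intercept, but its within-family component (possible only because marry-in
founders differ in ancestry) is invisible to an exchangeable family effect
while remaining correlated with every ancestry-informative genotype.
Without it — i.e. with a trait generated exactly by the fitted
random-intercept model — the mixed model is correctly specified, both
analysis arms are calibrated, and stratification has nothing to confound;
we verified this empirically (both arms' Type I error ≈ 0.056, arm
difference < 0.001).

The **null trait** redraws u and e with every β_c = 0 on the same
covariates, ancestry term included. It is a fresh draw, not a permutation,
so it preserves the family covariance while having zero dependence on any
genotype. The "shared" admixture mode (every family the same vector,
founders pinned to it) removes all ancestry variation and is the
no-stratification control condition.

## Analysis stages

**Cleaning.** Mendelian checking flags (individual, variant) pairs whose
dosage cannot arise from the recorded parents (a parent with dosage 0/2 can
transmit only the reference/alternate allele); by default any violation
removes the variant (the threshold is configurable — the exclusion rule is a
free choice, and the strictest one is cheapest to reason about). MAF
filtering keeps variants with whole-sample MAF *strictly* above the
threshold.

**PCA.** Dosage columns are centered by 2p̂ and scaled by √(2p̂(1−p̂)), the
standard genotype-PCA normalization; p̂ is always the full-sample
alternate-allele frequency so scores are comparable across families.
Eigenstructure comes from an economy SVD; eigenvalues are singular values
squared over (n−1), and variance fractions divide by the full trace, so all
computed fractions sum to 1. Component signs are fixed (largest-magnitude
loading positive) for reproducible score files. Monomorphic panel variants
are excluded with a warning. The default random panel is 10,000 variants
with MAF > 0.1.

**AIM selection.** Per-family mean scores on PC1 and PC2 identify one
divergent family pair per component (the argmin/argmax families;
deterministic tie-break by family id). For each pair, the delta statistic
δ = |p₁ − p₂| compares the *same* alternate allele's frequency in the two
families — never each family's own minor allele, which would make δ
asymmetric and manufacture spurious large values near p = 0.5. Markers with
δ > 0.6 (the conventional "highly ancestry-informative" threshold) form the
panel; the union across pairs is deduplicated by default. Family
frequencies are computed over all members, relatives included (a
founders-only mode exists); allele counting over relatives is not
independent sampling, but it is what the family-pair contrast operates on.

**Family classification.** Classical equal-covariance Gaussian LDA on the
first k AIM-panel PCs (class means, pooled within-class covariance, priors
defaulting to empirical family-size proportions). When the pooled covariance
is singular (k approaching the within-class degrees of freedom) a relative
ridge of 1e-8·trace/k is added, escalating tenfold until the Cholesky
succeeds, with a warning. Accuracy is resubstitution by default — the
question is how much family structure the PCs encode, not out-of-sample
generalization (per-family perfect counts at small k are only possible under
resubstitution); a leave-one-out mode is available. The reported grid is
k ∈ {1, 20, 40, …, 200}.

**Association.** Per SNP, the linear mixed model

    y = Xβ + u_family + e

with X = [1, medication, sex, age, sex·age, dosage] plus, in the adjusted
arm, the first 6 PCs of the AIM-panel PCA. The random effect is a family
random *intercept*, deliberately not a kinship/GRM covariance — the package
evaluates exactly that simpler model; within-family relatedness beyond the
shared intercept is left unmodeled, and extending to a full polygenic
covariance is the natural next step. Because the grouping factor makes
V = σ²_e(I + λZZ′) block diagonal, REML profiles down to a one-dimensional
search over λ = σ²_fam/σ²_e using per-family sufficient statistics (bounded
search over log λ ∈ [−12, 6], explicit λ = 0 boundary comparison); a fit
costs well under a millisecond, which makes 10,000-SNP panels practical on
one core. The reported test is the Wald test of the dosage coefficient
against a standard normal (n ≈ 950 per fit; a t reference with residual df
is available). Fixed-effect covariance is the GLS covariance at the REML
optimum, the nlme/lme4 convention. Monomorphic SNPs and non-convergent fits
are flagged and excluded from all rates.

**Evaluation.** Power = fraction of causal-SNP tests (real trait) with
p strictly < α; Type I error = fraction of null-panel tests (null trait,
10,000 SNPs drawn with MAF > 0.01) with p < α; both per arm, default
α = 0.05 (the comparison's level is a free choice; 0.05 is the convention
under which the inflation pattern is interpretable). Differences are
reported as adjusted − unadjusted absolute differences.

## What the synthetic conditions do and do not show

At the defaults (Fst 0.2, planted pairs, β_anc = 15, c = 10), measured over
replicates:

* the unadjusted arm's Type I error is inflated (≈ 0.06–0.08; ≈ 0.12 at
  β_anc = 30) and PC adjustment restores it to ≈ 0.05, in every replicate
  observed — the qualitative stratification story, reproduced;
* under the no-stratification control, both arms are calibrated;
* the AIM panel concentrates far more variance on PC1+PC2 than an
  equal-size random panel, and LDA accuracy climbs from < 30% at 1 PC to
  > 90% at 100 PCs;
* power, however, is *not* reliably improved by adjustment here: the
  unadjusted arm's miscalibration inflates its causal-SNP rejection rate by
  about as much as (or more than) the adjusted arm gains from the reduced
  residual variance, and the two channels scale with the same parameters.
  A measured power gap of ≈ ±0.005–0.02 in either direction is within what
  134 SNPs resolve — a difference of one or two rejected SNPs (≈ 1.5%
  absolute) sits inside the binomial noise of the panel. The robust,
  repeatable benefit of PC adjustment in this design is calibration, not
  power.

Passing tests on this generator demonstrate correctness of the machinery
and the direction of the stratification effects. They do not certify
behavior under LD, genotyping error, missingness, kinship-covariant traits,
or real admixture histories, none of which are simulated.

## Numerical choices and problem sizes

* REML λ search: bounded scalar minimization on log λ with xatol 1e-4 and an
  explicit λ = 0 comparison; criterion evaluations reuse per-family
  sufficient statistics (X′X, X′y, per-family column sums).
* PCA uses dense economy SVD (n ≤ ~1000 individuals throughout); no
  randomized solvers are needed at these sizes.
* LDA tie-breaks go to the lexicographically first family id; PCA signs are
  pinned to the largest-magnitude loading.
* Degenerate inputs: monomorphic variants are flagged (PCA: excluded with a
  warning; association: record flagged "monomorphic"); a group with no
  non-missing calls has an *undefined* frequency, never 0; an empty AIM
  panel is a warning, not an error.
* Test-suite problem sizes were chosen to keep the full run in minutes on
  one core: the flagship stratified dataset is 20 families of 22–86 members
  with 20,000 variants; calibration checks use 10,000-SNP null panels;
  replicate averages use 8,000–12,000-variant genomes and family sizes of
  15–50. The acceptance script runs the full default configuration
  (20,000 variants, 22–86-member families).

## Known limitations

* No LD, no X chromosome, no genotyping error, no missingness model.
* The family random intercept ignores within-family relatedness; a
  GRM/kinship mixed model (GRAMMAR- or famSKAT-style) is out of scope by
  design.
* Admixture is three-way with Dirichlet family vectors; no admixture-LD or
  dating of admixture events.
* PED/MAP round trips preserve alternate-allele orientation only through
  the writer's 6-column extended MAP; a standard 4-column MAP forces
  minor-allele inference on read.
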