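# Methods

## Scope and model

`polyblup` estimates additive breeding values in an autotetraploid,
dioecious crop from the single-trait animal model

    y = Xb + Za + e,   a ~ N(0, K σ²ₐ),   e ~ N(0, I σ²ₑ).

`y` holds one trait's records over multiple years; `X` is an intercept plus
treatment-coded year contrasts (the population mean and year effects are
confounded as written in the field's usual formulation, so the mean is
absorbed into the intercept to keep `X` full rank); `Z` maps records to
individuals, with repeated yearly records pointing at the same additive
effect. All individuals present in `K` receive BLUPs whether or not they
have records — that is the point of the exercise in a dioecious crop, where
males never express fruit traits. The phenotypic variance for narrow-sense
heritability is `σ²ₐ + σ²ₑ` exactly (year is fixed; no permanent-environment
term), matching the model's random terms.

## Relationship matrices

**A2** is Henderson's tabular numerator relationship matrix, treating the
pedigree as diploid: `a_kj = (a_sj + a_dj)/2`, `a_kk = 1 + a_sd/2`.

**A4 / A4ω** is four times the coancestry matrix Θ under tetrasomic
inheritance with double reduction. The recursion tracks, per individual,
the internal identity `F_k = P(two distinct allele copies of k are IBD)`:

    θ_kj = (θ_sj + θ_dj)/2                      (j any earlier individual)
    F_k  = (φ_s + φ_d)/6 + (2/3) θ_sd
    φ_p  = ω + (1 − ω) F_p                      (within-gamete IBD)
    θ_kk = (1 + 3 F_k)/4

The 1/6–1/6–4/6 weights are the probabilities that a random pair of the
offspring's four allele copies falls within the sire gamete, within the dam
gamete, or across gametes. Double reduction is modelled as whole-gamete
duplication with probability ω, ignoring locus position (the single-ω
parameterisation; the telomere-proximal gradient of real double reduction
has no map to hang on here). A missing parent is a fresh, non-inbred,
unrelated founder whose gametes still undergo double reduction — the
standard NRM convention extended to tetrasomy. Founders have diagonal
exactly 1 under both conventions; A2 and A4(ω=0) agree wherever parents are
non-inbred and diverge on the offspring of inbred parents, because only the
tetrasomic recursion propagates parental internal identity through
within-gamete IBD (tested explicitly).

ω is deliberately a **required argument** with no default: the motivating
literature quotes both 0.01 and 0.1 for kiwiberry-like multivalent rates,
so a silent default would bake in one side of that disagreement. Example
configurations use 0.1.

**G4** is the VanRaden cross-product estimator on tetraploid dosage,
`G = WW′ / (4 Σⱼ pⱼ(1−pⱼ))` with `W = M − 4p`: the denominator is the summed
Hardy-Weinberg dosage variance for ploidy 4, so an unstructured population
has mean diagonal 1. **G2** is the Yang (GCTA-style) estimator on
pseudo-diploid codes (0/{1,2,3}/4 → 0/1/2), whose bias-adjusted diagonal
`1 + (x² − (1+2p)x + 2p²)/(2p(1−p))` estimates `1 + F` and may legitimately
fall below 1 — it is reported as computed, not clipped. Allele frequencies
always come from the full genotyped set, never a training subset. The
minor-allele-frequency filter (default 0.05) also removes zero-variance
columns, since pseudo-diploidisation can collapse a polymorphic tetraploid
marker into a constant (p = 0.5 but information-free) column; for G2 the
filter runs after recoding, for G4 on tetraploid frequencies, keeping the
two pipelines parallel.

Marker-based K is rank-deficient whenever individuals outnumber effective
markers, so before inversion the model can blend `K* = (1−α)K + αI`
(default α = 0.01 in the CLI for G matrices, logged). Every inversion uses
dense Cholesky with escalating diagonal jitter (1e-10 ×10 up to 1e-6, then
a hard failure).

## REML

Variance components maximise the restricted likelihood via
average-information (AI) updates with step-halving into the feasible region
and a positivity-preserving multiplicative fallback; convergence is a
relative parameter change below 1e-8 (default) within 200 iterations, with
a separate boundary rule accepting fits pinned at σ²ₐ = 0 (the relative
criterion cannot fire on a geometrically collapsing component).
Implementation-wise everything runs on the spectral reparameterisation
`ZKZ′ = U diag(d) U′`: after one symmetric eigendecomposition per design,
each iteration costs O(np) — this is what keeps ~100 per-fold REML refits
of a cross-validation affordable. The engine is validated against a direct
dense-matrix restricted-likelihood oracle and, for the MME solutions,
against the closed GLS form. Approximate standard errors come from the
inverse AI matrix; a near-singular AI matrix (condition number ≥ 1e8, e.g.
K = I with one record per individual, where only σ²ₐ + σ²ₑ is estimable) is
flagged as non-identifiable rather than hidden. Non-convergence flags the
result; it never raises.

## PEV, accuracy, and the K_ii convention

From the mixed-model-equation coefficient matrix, the inverse diagonal
`d_i` of the individual block gives `PEV_i = d_i σ²ₑ`, `SEP_i = √PEV_i` and
`accuracy_i = √(1 − PEV_i/(σ²ₐ K_ii))`. The field often writes
`K_ii = 1 + F`, a diploid convention, although the tetrasomic pedigree
diagonal is `1 + 3F`. The default uses the **actual diagonal** of the
supplied matrix — self-consistent with `a ~ N(0, K σ²ₐ)` — and a
`kii_convention="one-plus-f"` switch provides the literal reading, decoding
F from the diagonal by the matrix's method tag. Arguments under the square
root are clamped to [0, 1] (possible with blended G), with clamping logged.

## Cross-validation

Only phenotyped females are partitioned (k = 10 folds, 10 repeats by
default); parents and males never enter validation sets. Variance
components are re-estimated inside every training fold, so masking
propagates into σ̂² — perturbing a validation record provably leaves the
training fit bit-identical (tested). Fold statistics compare each
validation individual's phenotype averaged over years with its predicted
breeding value: Pearson predictive ability, the regression slope of
observations on predictions (1 = no inflation), mean squared difference,
and expected genetic gain ΔG = ½·PA·σ̂ₐ·i/L with i = L = 1 by default.
Because predictions are centred breeding values while observations carry
the fixed-effect mean, MSE is offset-dominated and meaningful only between
models fitted to the same data. Per-fold statistics aggregate as unweighted
means over all (repeat, fold) cells; a pooled-per-repeat mode and a
per-record mode exist behind flags. Folds with non-converged REML are
excluded and counted. Undefined correlations (constant vectors, < 3 pairs)
propagate as missing, not as errors.

## Synthetic data

The generator emulates the structure the estimators assume, with defaults
set to the motivating kiwiberry design: two incomplete factorial blocks
(14 females × 2 males and 13 males × 2 females — 31 parents), 50 crosses
drawn from the combined grids, progeny counts from a truncated negative
binomial (mean 36, dispersion 4, range 2–80, matching the reported mean/
spread), even sex ratio, 11 distant ancestors above the parents, two years
of records on female progeny only. Founder allele frequencies are
Uniform(0.1, 0.9) — wide enough to keep markers informative after the maf
filter; loci are unlinked because none of the relationship-matrix methods
uses linkage. Genotypes descend by explicit tetrasomic meiosis (two copies
without replacement, or a duplicated copy with probability ω), so realized
genomic relationships carry true Mendelian sampling variance. Phenotypes
follow the same LMM the estimator fits, in two modes: `pedigree` (a drawn
from N(0, A(ω)σ²ₐ)) and `marker` (a an exact linear combination of centred
dosages rescaled to σ²ₐ — the regime where markers fully determine the
additive value). An optional rubric mode discretises records through the
0.5–9 fruit-load scoring bins, dropping zero-count records.

What the simulator does **not** emulate: linkage and LD structure, QTL
architectures with few large effects, selection or drift across
generations, genotyping error and dosage-call uncertainty, non-additive
variance, genotype×year interaction, and non-Gaussian trait skew (except
through the rubric). Passing tests therefore certify the estimators under
their own assumptions — they do not certify robustness of real-data
conclusions to these violations.

The same meiosis code drives **gene-dropping Monte Carlo** (numba kernels):
unique founder labels are dropped through the pedigree and pairwise IBD is
scored as the fraction of ordered allele-pair label matches, yielding
ploidy-scaled coancestry estimates with per-entry Monte-Carlo standard
errors. This is the independent oracle for A2 and A4(ω): the oracle suite
runs 20 randomized pedigrees (8–14 individuals, depth ≤ 4 — sizes chosen to
keep the million-replicate suite at a few minutes on one CPU) × four
method/ω settings at 10⁶ replicates. Because the z-scores of a correct
recursion are standard normal, agreement is asserted family-wise — ≥ 99.5%
of stochastic entries within 3 MC SE and every entry within 4.5 MC SE — a
genuine coefficient error displaces entries by ≥ 1e-2 (z ≫ 5) and fails
both bounds, while the literal every-entry-3σ reading would fail with
probability ≈ 1 across thousands of comparisons even for an exact
implementation.

## Statistical-suite design sizes

Heritability recovery runs 20 replicate studies at the full design (50
crosses, records subsampled to 800 phenotyped females, 2 years) with h²
cycling through {0.2, 0.5, 0.8} and requires mean |ĥ² − h²| < 0.1 against
the true A4. G-matrix calibration uses 200 HWE founders × 5000 markers
(mean diagonal 1 ± 0.05) and a 10-cross pedigree for the G4-on-A4
regression slope ∈ [0.8, 1.2]. The null cross-validation (σ²ₐ = 0) runs at
the full ~900-female design because per-fold PA noise scales as
1/√(fold size) and folds are correlated across repeats of one dataset — a
small population would leave the ±0.05 band by chance alone. The
G4-versus-A4 accuracy contrast for unphenotyped males uses 10 marker-mode
datasets (15 crosses × ~16 progeny, 1000 markers) and a paired one-sided
test.

## Numerical conventions and degenerate inputs

Quantiles use linear interpolation (R type-7, the `summary()` convention);
skewness is the moment estimator m₃/m₂^{3/2} (the R "moments" convention).
Missing dosages are imputed per marker to the rounded mean dosage and
counted in the log — the minimal-assumption default for G construction; an
all-missing marker is an error. Unknown pedigree parents accept "", "0",
"NA" or "." and normalise to one internal sentinel. Topological ordering is
a stable Kahn pass, deterministic given input order. A single year level
collapses X to the intercept (allowed, logged). σ²ₐ = 0 short-circuits the
MME to the total-shrinkage limit (all BLUPs 0, accuracy 0). All randomness
flows from user-supplied seeds through `numpy.random.Generator`; CV fold
plans derive per-repeat sub-seeds so repeats differ but the whole plan is
reproducible from one integer.

## Known limitations

Single-trait, additive-only models; no dominance or epistasis (substantial
in autotetraploids), no genotype×environment terms, no single-step
pedigree+marker H-matrix, no mixed-ploidy pedigrees. A-inverses are formed
by dense factorisation, not Henderson's sparse rules — fine at breeding-
program scale (thousands), wrong tool at national-evaluation scale. The
marker count reported for real pipelines depends on upstream dosage-calling
filters that are out of scope here; the maf/variance filter sequence is
explicit and configurable instead.
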