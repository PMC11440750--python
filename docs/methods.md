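# Methods

This note documents the models implemented in `mfblup`, the defaults of
the synthetic-data generator, the numerical choices, and the limits of
what the test suite demonstrates.

## The evaluation model

All evaluations are multitrait animal models solved through Henderson's
mixed-model equations. With phenotypes assumed pre-adjusted for known
fixed effects, the only fixed effect is the contemporary group (flock ×
birth year):

    y = X β + Z_a u + Z_m u_m + Z_mpe mpe + Z_sfy sfy + e

* `u` — direct additive genetic effects, all traits;
* `u_m` — maternal genetic effects (correlated with `u`), maternal traits
  only; the maternal design column points at the record's dam, or at the
  dam's genetic group when she is unrecorded;
* `mpe` — maternal permanent environment, one level per recorded dam,
  Var = M0 ⊗ I (diagonal M0);
* `sfy` — sire × flock × year interaction, Var = S0 ⊗ I (diagonal S0);
* `e` — residual, Var = R0 ⊗ I; records with missing traits contribute
  through the inverse of the observed sub-block of R0 (records are grouped
  by missingness pattern at assembly).

The joint direct+maternal covariance is G0 ⊗ K, where G0 stacks direct
slots for every trait and maternal slots for the maternal traits (the
stock `default_wool` set is 5 × 5), and K is the relationship matrix
implied by the chosen model:

| variant | K |
| --- | --- |
| BLUP-UPG | group-augmented A* (Quaas "QP" blocks) + random groups G0⁻¹ ⊗ I |
| ssGBLUP-UPG | H*_QΣ: A* plus the (G⁻¹ − A₂₂⁻¹) block and its Q₂ couplings |
| BLUP-Meta{GLS,Trend} | A_Γ with metafounders as correlated pseudo-parents |
| ssGBLUP-Meta{GLS,Trend} | H_Γ⁻¹: A_Γ⁻¹ plus (G₀₅⁻¹ − A_Γ₂₂⁻¹) in the genotyped block |

G is VanRaden's matrix, centred with observed allele frequencies for the
UPG models (scaling 2Σp(1−p), monomorphic markers reported and excluded
from the scale) and with 0.5 for the metafounder models (scaling n/2).
Both are blended 0.95 G + 0.05 A-block before inversion. Variance
components are inputs, never estimated; the UPG random-group variance is
taken equal to the genetic variance (Var(g) = G0 ⊗ I).

Group effects under UPG are solved explicitly in the QP-transformed
system, so animal solutions are total breeding values and the group
solutions remain retrievable; under metafounders the animal solutions are
expressed against the correlated metafounder base.

## Genetic groups and Γ

Groups are population × 5-year birth-cohort cells, anchored at each
population's earliest recorded year; a population spanning at most one
interval keeps a single group. Unknown parents map to the group of their
offspring's population and cohort.

Γ estimation:

* **GLS route** — per-marker base allele frequencies for all groups are
  solved by least squares against the group-fraction design,
  2p̂ᵢ = (Q'Q)⁻¹Q'mᵢ, then Γ entries follow from
  Γ₀ = (2/n)Σ(2pᵢ−1)² and γ_kl = (2/n)Σ(2p_{i(k)}−1)(2p_{i(l)}−1).
  Ordinary least squares is used as the weighting (the simplest member of
  the GLS family); estimated frequencies are clipped to [0, 1] with a
  clip count reported, and every group must carry nonzero genomic
  representation (the per-group effective count is reported).
* **Trend route** — within a population, cohort r ≤ s gets
  Γ₀ + (r−1)·interval·2ΔF(γ), with ΔF(γ) = ΔF(1−Γ₀/2) and ΔF from an OLS
  fit of pedigree inbreeding (animals with both parents known only) on
  ancestry fractions, birth year and their interaction. Because ancestry
  fractions sum to one, the shared year slope is exactly collinear with
  the per-population slopes and is dropped (fitted as 0) whenever the
  design is rank-deficient; when estimable, it is folded into ΔF only if
  |c| ≥ 1e−3/year. Non-positive ΔF estimates (impossible in closed
  populations) are replaced by the mean of the strictly positive ones.
  Between-population blocks are constant γ_kl.

Any Γ entering a model is checked for symmetry and positive
semidefiniteness; an indefinite matrix is projected to the nearest PSD
matrix by eigenvalue clipping, with a warning reporting the largest
adjustment.

## Relationship matrices

Pedigree inbreeding uses the Meuwissen–Luo-style T·D·T' traversal; sparse
inverses are assembled from Mendelian-sampling variances by Henderson's
rules. Under Γ-augmentation every animal has two parents (metafounders
fill the gaps), and m_i = 0.5 − (F_s + F_d)/4 remains exact with the
metafounder "inbreeding" F_g = Γ_gg − 1; Γ⁻¹ (pseudo-inverse when Γ is
singular, e.g. the Γ = 0 reduction) is added to the group block. Dense
matrices (tabular method) back the A₂₂/A_Γ₂₂ blocks and all oracle
comparisons, gated at 6,000 entities — this package targets desk-scale
studies, not national evaluations.

The UPG model's A₂₂ is computed from the classical (non-augmented)
relationship matrix; the metafounder model uses the Γ-augmented block.
A*_Σ is stored without the random-group identity, which is added at MME
assembly where the variance bookkeeping lives.

## Solving

The assembled system is solved by preconditioned conjugate gradients
(Jacobi preconditioner) with a relative-residual tolerance of 1e−10 —
tight enough that LR metrics are stable to four decimals — falling back
to a sparse direct factorisation if PCG stalls. Zero right-hand sides
short-circuit to zero solutions.

## LR validation

Validation (focal) animals are the genotyped and phenotyped animals born
during or after the cutoff year. A scenario's *partial* dataset removes
(i) the focal phenotypes and (ii) the phenotypes *and* genotypes of
pre-cutoff genotyped animals whose breed label is outside the reference
composition; phenotyped-but-not-genotyped records are always retained.
The *whole* dataset adds back the phenotypes of all focal animals, so
whole − partial is exactly the focal phenotype set, and both runs share
one relationship matrix. Metrics per validation breed: Δ̂p, b_p, the
partial–whole correlation, and the LR accuracy with the model-appropriate
denominator — (1−F̄+mean diag(QQ')−mean(QQ'))σ²ₐ for UPG (groups random
with covariance Iσ²ₐ), (1−F̄)σ²ₐ for metafounders. F̄ is classical
pedigree inbreeding of the focal animals; QQ' means are taken over the
focal rows only; σ²ₐ,∞ is taken equal to σ²ₐ. Confidence intervals come
from the OLS regression of û_w on û_p (slope) and the iid standard error
of the mean difference (bias) — an approximation that treats focal EBVs
as equally accurate and unrelated.

## The synthetic generator

The generator emulates the statistical structure of a multi-line,
partially crossed, incompletely recorded sheep population:

* **Base populations.** Ancestral marker frequencies are uniform on
  [0.05, 0.95]; each population drifts with variance F_pop·p(1−p)
  (expected pairwise Fst ≈ (F_k+F_l)/2). The default seven-population
  drift vector (0.010, 0.075, 0.004, 0.008, 0.002, 0.006, 0.002) puts one
  divergent line at Fst ≈ 0.04 against the rest and the remaining pairs
  at 0.002–0.01, the differentiation scale of closely related Merino-type
  lines. Realized Γ₀ values land around 0.5–0.6.
* **Demography.** Discrete yearly cohorts per flock; parents sampled
  uniformly from animals born 1–5 years earlier; directed crossing by
  per-pair mating rates (crossbred offspring labelled `C`); a configurable
  fraction of founders ("immigrants") enters after the first year so late
  cohorts retain base-population mass; recorded dams are erased with
  probability `missing_dam_rate` *after* inheritance, so the biological
  dam still transmits genes and maternal effects, as in field data.
  Mating is random by default; a truncation-selection switch exists for
  robustness experiments only, because the LR calibration properties
  assume no selection.
* **Breeding values.** TBVs are sums of marker effects: every simulated
  marker is a QTL with per-marker effect covariance G0/(2Σp̄(1−p̄)), so
  base-animal variance matches G0 and genotypes are genuinely informative
  about merit. (A purely pedigree-driven Mendelian-sampling recursion was
  considered and rejected: with marker-independent TBVs, genomic data adds
  no information beyond the pedigree, and single-step evaluations could
  never beat pedigree BLUP, contrary to the behaviour the pipeline must
  exhibit.) Gene dropping keeps inheritance pedigree-consistent at linear
  cost.
* **Phenotypes.** Exact sums of drawn components (cg ~ N(0, 0.25),
  direct TBV, the biological dam's maternal TBV, mpe, sfy, residual),
  stored in a truth table so bookkeeping is testable to machine
  precision. The stock three-trait set targets h² = 0.74/0.57/0.38 on a
  unit phenotypic scale, with maternal genetic (0.08, 0.10), mpe
  (0.05, 0.07) and sfy (0.04, 0.05) variances on the last two traits and
  moderate genetic correlations (0.3 direct–direct, −0.1
  direct–maternal). Animals without a recorded/biological parent receive
  fresh base-level draws for the missing components; mpe/sfy design
  columns for records with unknown dams/sires are dropped from the model
  (singleton levels are absorbed by the residual).

What the generator does **not** emulate: linkage and recombination maps
(loci segregate independently), genotyping errors or missingness after
QC, overlapping-generation demography realism, selection-driven trends,
and genotype-environment correlation. Passing tests therefore demonstrate
the correctness and calibration of the machinery under the stated
assumptions, not performance on real, selected, LD-structured data.

## Test-problem sizes

The heavier properties run at sizes chosen to keep the whole suite
desk-scale while the statistics remain informative: the no-genotype
reduction at ~2,000 animals with the full three-trait model; dense-oracle
equivalence at ≤300 animals; Γ recovery at 7 populations × 5,000 markers
× ≥500 genotypes per population; LR calibration over 20 replicates of a
~3,000-animal, 25-flock population with 25% genotyping and 2,500 markers
(many small flocks and a minority-genotyped population keep the CI
approximation's assumptions — large, mostly unrelated focal groups with
well-estimated contemporary groups — tenable; a denser panel keeps the
replicate-level fluctuation of realized genetic variance small); and the
two-breed design at ~3,000 animals with the large breed's reference about
six times the small breed's. The LR calibration uses the ssGBLUP-UPG
model: with variance components held fixed across models, the metafounder
parameterisation shifts the EBV level between partial and whole runs (the
Γ-scale compatibility question), which makes UPG the cleaner vehicle for
the calibration property.

## Known limitations

* Dense relationship blocks gate the pipeline at a few thousand animals;
  no APY-style approximations are provided.
* The GLS Γ uses identity weighting; full GLS weighting by pedigree
  relationships is not implemented.
* Variance components are never estimated (no REML/Gibbs); they are part
  of the model definition, as in routine evaluations.
* Γ-scale rescaling of variance components for metafounder models is not
  applied (official-component convention); metafounder accuracies rely on
  the internal cancellation in the LR accuracy denominator.
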