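# Methods

This note records the statistical models implemented in `exped`, the
estimation and numerical choices, the defaults and why they were chosen,
and the known limits of the synthetic-data generator.

## 1. Phenotype scoring

Weekly exercise volume is scored in MET-minutes:

```
weekly METmin(activity) = MET value × sessions/week × minutes/session
```

summed over reported activities. Records flagged obligatory (school or
work-mandated), transport-only, or seasonal are excluded from all scores.
Each activity carries three binary classifications — team vs solitary
membership, competitive vs non-competitive, externally vs internally paced —
and the scorer accumulates one subtotal per class, so each axis partitions
the total exactly (a tested invariant). The bundled activity table
(`exped/data/activities.csv`, 26 activities) is replaceable by any CSV with
columns `name,met,team,competition,pacing`; MET values below 1 and unknown
class labels are rejected at load time with row numbers.

**Wave selection.** With multiple survey waves, one wave is chosen per
family: the wave in which most family members responded (earliest on ties);
members absent from it contribute their nearest-in-time survey; if the
nearest is more than `gap_years` (default 10) away, their last survey is
used. Respondents must be 16–65 years old at the selected survey and must
have at least one other responding family member. The 10-year gap default
keeps phenotypes loosely contemporaneous while retaining families surveyed
in disjoint waves; the 16–65 window restricts to ages where voluntary
exercise, not school sport or frailty, drives the phenotype.

## 2. Relationship matrices

Kinship coefficients Φ are computed by the standard tabular recursion over
a topological order (founders Φ_ii = ½; Φ_ij = ½(Φ_f(j)i + Φ_m(j)i);
Φ_jj = ½(1 + Φ_f(j)m(j))). MZ co-twins are handled inside the recursion:
when the second member of an MZ group is reached, its row is copied from
the first, before any descendants are processed — so MZ pairs get Φ = ½
(A = 1) and each twin's children relate to the co-twin as to a genetic
parent. The additive matrix is A = 2Φ.

Fraternity (dominance) coefficients use the product formula
Δ_ij = Φ_ff'Φ_mm' + Φ_fm'Φ_mf' over the parents of i and j, with Δ = 1 for
MZ pairs. Inbred pedigrees are rejected (the formula assumes
non-inbreeding); none occur in twin-register-like data.

Both recursions are verified in the test suite against exact enumeration of
all allele inheritance patterns (4 per non-founder) on small pedigrees, and
the additive matrix against gene-dropping covariance at 20,000 replicates.

**Household matrices** H encode shared-home exposure under four
definitions: `full` (parents + children + twins all share), `spouse` (only
spouse pairs), `sib` (only siblings, twins included), `twin` (only twin
pairs). DZ twins carry no explicit marker in the pedigree format and are
detected as full siblings sharing a birth year; the generator keeps
singleton siblings' birth years distinct from the twins'.

## 3. ACDE variance components

For each pedigree's phenotyped members, y ~ MVN(Xβ, Σ) with

```
Σ = σ²A·A + σ²D·D + σ²C·H + σ²E·I
```

and X = [1, age−mean(age), sex, age×sex] (sex coded 0 male / 1 female; age
centered at the phenotyped-sample mean). Estimation is maximum likelihood:
variances are parameterized as exp(θ) (non-negativity by construction,
L-BFGS-B in θ), and β is profiled out by GLS inside every objective
evaluation — the optimizer only searches the variance space. Three seeded
restarts guard against local optima. ML (not REML) is used because the
fixed-effect design is small (4 columns) relative to the sample, making the
REML correction negligible, and ML keeps the nested-model LRTs coherent.

For speed, pedigrees with identical (A, D, H) structure are grouped and
evaluated with stacked triangular solves from a single Cholesky factor per
group; a non-positive-definite Σ during search returns a large penalty.
Model comparison fits nested subsets (D only alongside A; E always free)
and selects the most complex model from which every drop is rejected by a
naive χ² LRT at α = 0.05. Because variances sit on the boundary under the
null, the naive χ² p-value is conservative for variance components; the
comparison table flags tests whose dropped components were estimated at
the boundary.

## 4. Kinship correlations

Each trait is residualized on intercept + age + sex + age×sex by OLS over
all phenotyped individuals, then Pearson correlations are computed within
each relation: spouse pairs, parents of twins, twin-spouse pairs, twin
pairs by zygosity and sex (MZM/MZF/DZM/DZF/DOS), sibling pairs by sex
composition (twin pairs excluded), and the four parent-offspring
combinations. Symmetric relations are double-entered so the estimate does
not depend on an arbitrary within-pair ordering; directed relations use
parent-first ordering. Twins who themselves have twin children are counted
with their spouse in the twin-spouse row and their couple is excluded from
parents-of-twins, so no pair appears in both rows. Cells with fewer than 3
complete pairs report NaN.

## 5. Six-role spousal model

Families with a same-sex twin pair contribute a six-role vector (father,
mother, twin1, twin2, spouse1, spouse2) modeled as MVN with a structured
correlation matrix per zygosity group:

* r1 — twin with own spouse; r2 — twin with co-twin's spouse (per
  zygosity); r3 — spouse1 with spouse2 (per zygosity); r4 — father with
  mother; plus nuisance structure r_po (parent-offspring), r_pos
  (parent-in-law), r_tw (twin-twin per zygosity).

Estimation is full-information ML: families are grouped by (zygosity,
missingness pattern), each group's marginal MVN likelihood is evaluated on
the observed entries, β (age/sex effects) is profiled by GLS, and a common
scale σ² is profiled analytically (optionally one free variance per role).
Correlations are bounded in (−0.99, 0.99); the implied matrices are checked
for positive semidefiniteness at the optimum.

The hypothesis battery tests, against the free model: r1 = 0, r4 = 0 (1 df
each), r1 = r2 and r2 = r3 (2 df each — the constraint ties both zygosity
variants), r2_MZ = r2_DZ, r3_MZ = r3_DZ, r4 = r1 (1 df each). A result is
"supported" only if the LRT rejects *and* the free-model point estimates
lie in the hypothesized direction. Constrained fits are warm-started from
the base fit; if a constrained fit ever exceeds the base likelihood
(optimizer slack), the base is refit from the constrained solution.
Because all tested parameters are correlations in the interior of their
space, the naive χ² reference distribution is calibrated — verified
empirically in the test suite (type-I error within [α/2, 2α] over 200 null
simulations for every 1-df test).

Mechanism flags: *phenotypic assortment* when both zygosity comparisons
reject with MZ > DZ, or when the full ordering r1 > r2 > r3 rejects;
*social homogamy* when resemblance is present but all assortment-
discriminating equalities are retained; *marital interaction* when r4 = r1
is rejected with r̂4 > r̂1. These signatures can co-occur (strong
interaction also induces an r1 > r2 ordering); the flags report each test
pattern honestly rather than forcing a single label.

## 6. Mid-parent regression

Phenotypes are residualized jointly (one OLS over all individuals) on age,
sex, and age×sex. For each family with both parents phenotyped, one
phenotyped child is drawn uniformly at random (seeded) to avoid
within-family dependence, and the child's residual is regressed on the
mid-parent residual within bins of mean parental age (default
[20,45), [45,50), [50,55), [55,70]). The slope estimates the additive
proportion directly: parent-offspring pairs share neither dominance nor
sibling-household variance, and any spousal-resemblance process that
preserves the parental sum (convergence toward the couple mean in
particular) leaves the mid-parent value — and hence the slope — unchanged.
Bins with fewer than 2 families are omitted; the last bin is closed at its
upper edge.

## 7. Synthetic data generator

`generate_structure` emulates a twin-register composition: every family
has two parents and a twin pair (zygosity mix 0.46 MZ / 0.28 same-sex DZ /
0.26 opposite-sex DZ), plus extra non-twin siblings (Binomial(2, 0.34)),
spouses of twins (probability 0.25 per twin), and children of twin couples
(probability 0.4 per couple; the child's age is twin age − 23, which can
fall under 16 — present in the pedigree but unphenotyped). Ages: parents
~ N(47, 7.5²), twins ~ N(28, 11²) truncated to the respondent window.
Spouses of twins are founders (no in-law genotypes), as in real registers.

`simulate_acde_phenotypes` draws each pedigree's phenotype vector from the
exact fitted model: y = Xβ + chol(Σ)z with Σ assembled from that
pedigree's A, D, H under the configured proportions (unit total variance)
and β = (0, −0.01, 0.2, 0.005) on (1, age−40, sex, age×sex). Simulating D
and C through the joint MVN draw (rather than allelically) guarantees the
estimators' assumptions hold exactly in recovery tests; gene-dropping is
retained separately as an independent oracle for A. Members outside 16–65
are retained in pedigrees but unphenotyped.

Mating mechanisms generate six-role records directly: *assortment* couples
each spouse's phenotype to the partner's with Gaussian coupling μ (the
spouse's breeding value is back-sampled from its conditional given the
phenotype, keeping the genetic bookkeeping consistent); *homogamy* adds a
family-level social factor with variance share s to every member;
*interaction* pairs mates at random and moves each partner toward the
couple mean by 1 − exp(−λ·duration), with parents assigned 20 years and
twin couples 5.

**Realism limits.** The generator is a study-condition emulator, not a
population model: it fixes the family template (always exactly one twin
pair), uses clipped normal ages rather than register age structure,
ignores secular trends, cohort effects, longitudinal waves, non-response
correlated with the phenotype, and measurement error in self-reported
exercise; MET-minute phenotypes are treated as Gaussian after covariate
adjustment, whereas real exercise volumes are zero-inflated and
right-skewed (the real analysis's transformation step is out of scope).
Recovery tolerances in the tests reflect Monte-Carlo error only.

## 8. Numerical choices

* Cholesky factorizations everywhere (no explicit inverses); log-dets from
  factor diagonals; structure-grouped stacked triangular solves make the
  3,000-family ACDE fit take ~2–3 s.
* exp-parameterized variances and (−0.99, 0.99)-bounded correlations keep
  the search in the valid region without constrained optimizers.
* All simulation and fitting routines take integer seeds and are
  deterministic given them; replicate seeds are spawned from a single
  `numpy` generator and kept below 2³¹.

## 9. Limitations

* LRT p-values for variance components are naive χ²; boundary-corrected
  mixtures (e.g. ½χ²₀ + ½χ²₁) are not implemented — p-values are
  conservative and flagged when boundary estimates are involved.
* The spousal model estimates correlations, not the underlying mechanism
  parameters; classification is by test pattern, and overlapping patterns
  (e.g. strong interaction producing an assortment-like ordering) are
  reported as-is.
* The dominance recursion rejects inbred pedigrees rather than extending
  to the full 9-coefficient identity system.
* No ascertainment correction: analyses assume families enter the sample
  independently of phenotype.
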