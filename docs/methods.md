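# Methods

## Estimators

All statistics are plug-in (maximum-likelihood) functionals of the 3×3×2
contingency tensor X_ijk of one SNP pair against disease status, in bits
(log₂) except GenoCMI (nats).  The convention 0·log 0 := 0 is applied
throughout: terms with zero numerator are skipped, so the estimator is the
plug-in restricted to the observed support.  No pseudocounts or shrinkage
are applied anywhere — the gamma calibration below is for the raw plug-in.

Two algebraically distinct forms of the main-effect-free statistic are
provided:

* **Subtraction form** `igmod = IG(D|G) − IG(D|G₁) − IG(D|G₂)`.
* **Stratified-CMI form** `igmod0 = Σₖ P̂(Dₖ) · MI(G₁;G₂ | Dₖ)` (the
  case-weighted plus control-weighted within-stratum mutual information);
  `geno_cmi` is the same sum in natural logs.

The exact identity `igmod = igmod0 − MI(G₁;G₂)` (interaction information)
holds for every table and is enforced by tests to 10⁻¹².  The two forms
estimate the same population quantity when the loci are in linkage
equilibrium, but their *sampling* distributions differ, which matters for
calibration (next section).  Negative values of `igmod` are possible (the
pooled-MI term is sampling noise under the null); p-value routines clamp
small negatives to zero.

## Gamma null calibration

Under the full-independence null (no main effects, no LD), standard
log-likelihood-ratio asymptotics partition the second-order G-statistic
2N ln2·IG(D|G) ~ χ²(8) into independent components 2N ln2·IG(D|Gᵢ) ~ χ²(2)
and a remainder: hence

* `igmod`  ~ gamma(shape 2, scale 1/(N ln2))  (χ²(4) in nats·2N),
* `igmod0` ~ gamma(shape 4, scale 1/(N ln2))  (χ²(8) in nats·2N), the
  conditional-independence law, which holds for `igmod0` even when main
  effects are present.

Both laws are verified empirically by the test suite on simulated null
pairs with MAF ∈ (0.05, 0.5).  Because the study drivers' null design mixes
allele frequencies and includes sparse tables, the shape-2 law for the
subtraction form is the operationally calibrated choice there: the
empirical type-I error at nominal 5×10⁻² / 5×10⁻³ under the shape-2 gamma
is ≈ 5.4×10⁻² / 5.4×10⁻³ (computed by `scripts/acceptance.py`), while
shape-2 p-values applied to the CMI form would reject at ≈ 0.3.  The scan
therefore reports `p_liberal` (shape 2, on `igmod`) and `p_conservative`
(shape 4, on `igmod0`) for every pair, and the studies default to
`statistic="igmod"` with the liberal criterion; both are configurable.

Thresholds are upper-tail quantiles at a Bonferroni-corrected per-test
level, computed with `scipy.stats.gamma` (survival function and its
inverse; exact closed forms `(1+y)e⁻ʸ` and `e⁻ʸ(1+y+y²/2+y³/6)` with
`y = stat·N·ln2` serve as test oracles).  Reference settings: per-test
level 10⁻⁵ with shape 2 at N = 1600 gives 0.012837 bits; 5×10⁻⁸ with
shape 4 at N = 2062 gives 0.017332 bits.

## Disease models and the (α, θ) solver

Four parameterized two-locus odds models (multiplicative, epistasis,
two-allele, XOR) place odds α or α(1+θ)^m on the nine genotype cells; the
fifth ("no margin") is a fixed table at MAF 0.25 with interaction but
essentially flat margins.  Odds convert to penetrances p = o/(1+o).  With
Hardy-Weinberg genotype probabilities and independent loci, prevalence is
K = Σ P(G)f(G) and heritability h² = Σ P(G)(f(G)−K)²/(K(1−K)).

`solve_model_params` meets targets (K, h²) by nested Brent root finding:
the inner solve finds α for K at fixed θ (K is strictly increasing in α on
(10⁻⁹, 10³)), the outer finds θ for h² (increasing in θ).  Both constraints
are satisfied to 10⁻⁸; the solution is deterministic.  Study defaults:
K = 0.1, h² = 0.03 (multiplicative) or 0.02 (others), MAF ∈ {0.1, 0.2, 0.4},
both interacting loci sharing one MAF — twelve configurations.

The no-margin table is read as odds (its published header) and converted to
penetrances by default; an option reads the same numbers directly as
penetrances, the convention of the model's original source.  Its zero cell
yields penetrance 0 under either reading.

## Data generator

The generator emulates a GAMETES-style retrospective case-control design:
cases' two-locus genotypes are drawn from the 9-cell categorical law
P(G|D₁) ∝ P(G)f(G), controls from P(G|D₀) ∝ P(G)(1−f(G)), so case/control
counts (default 800/800) are exact in every replicate.  Null SNPs get an
independent MAF ~ U(0.05, 0.5) per SNP per replicate and i.i.d.
Hardy-Weinberg genotypes.  Defaults: 100 SNPs, the interacting pair in
columns 0–1, 1000 replicates.  Randomness derives from
`SeedSequence([seed, replicate])`, so replicate subsets are reproducible
and the power driver's pair-only draws coincide bit-for-bit with the first
two columns of the full dataset.

What the generator does *not* emulate: LD between SNPs, missing genotypes,
genotyping error, covariates or population structure.  Passing simulation
tests therefore demonstrate calibration and power under idealized
linkage-equilibrium sampling, not robustness to real-data artefacts.
Missing data are nonetheless supported in the estimators themselves by
pairwise-complete deletion (N varies per pair) — imputation is out of
scope.

## Comparators

The 1-df test is a Wald test of the product term in
logit P(D₁) = β₀ + β₁g₁ + β₂g₂ + β₃g₁g₂ with additive coding (the PLINK
epistasis convention); the 4-df test is an LRT of the 9-parameter full
model against intercept + additive + dominance ({0,1,0}) terms for both
loci.  All logistic likelihoods depend on the data only through the nine
genotype-cell counts, so fits use Newton/IRLS on aggregated cells —
identical likelihoods, much faster in studies; statsmodels individual-level
fits act as test oracles.  The full model saturates the observed cells
whenever its design spans them, so its maximized likelihood is evaluated in
closed form — this sidesteps separation when near-empty cells are pure.
Empty genotype classes reduce the LRT df (pivoted-QR column selection,
flagged).  Non-converged fits are flagged and counted as non-detections by
the power driver.

T_IG (genotype MI in controls minus cases; the sign is conventional, the
test two-sided) is assessed by label permutation with class sizes fixed,
implemented exactly as multivariate hypergeometric resampling of the
per-cell case counts; p = (1 + #{|T*| ≥ |T|})/(1 + n_perm).

## HLO classification and submodels

Each genotype cell is labeled High/Low/undetermined by a per-cell test at
`cell_alpha` (default 0.1, the conventional MB-MDR screening level); cells
with fewer than `min_cell_n = 10` individuals are O regardless.  The
default test is a score (Rao) test of the cell indicator added to a
logistic model with codominant main effects of both loci — one null fit
per pair, nine score statistics.  The main-effect adjustment is what makes
the labels an interaction readout: under a multiplicative model the common
(aa,bb) cell carries *more* cases than its margins predict and is
correctly labeled H, which an unadjusted cell-versus-rest comparison can
never produce (that cell has the lowest penetrance).  The unadjusted
two-proportion test remains available via `adjust_main_effects=False`.

Two catalogued ideal cells follow other conventions and are documented as
exceptions in the convergence tests: the two-allele (aa,bb) cell (its
adjusted residual is asymptotically ≈ 0; the catalogued L reflects the
raw-odds reading) and the no-margin (AA,BB) cell (catalogued O because the
cell is nearly empty at study scale; its penetrance is 0, so with enough
data the test reads L).

Submodel matching walks an ordered catalog (Multi → Epi → XOR →
Multi-incomplete → Other), each category holding its published wildcard
pattern ("H or O" / "L or O" cells) plus, where the wildcards do not admit
it, the exact ideal matrix of the generating model; unmatched matrices are
"Other".  Matching is first-match and deterministic.

## Scan

The scan enumerates unordered pairs i < j, excludes pairs with pooled
squared genotype correlation r² above `ld_r2_max` (default 0.01; the
estimator assumes linkage equilibrium), computes both statistic forms via a
vectorized indicator-matrix kernel (9 × 2 matrix products per dataset),
attaches both p-values, flags pairs by the configured criterion, and
classifies flagged pairs.  The cutoff comes from a direct per-test level
or from `alpha_global` Bonferroni-corrected by the number of *tested*
pairs.  Caveat: in case-control data a strong interaction itself induces
pooled genotype correlation that can exceed 0.01, so the LD filter should
be disabled when scanning data simulated under interaction models; it is
meant for physically linked markers in real genotypes.

## Study sizes and numerical choices

The type-I study at its defaults processes the full 12-configuration design
with 100 replicates each (≈ 5.9 million null pairs, about half a minute);
replicate counts are configurable, and Monte-Carlo standard errors in the
tests are computed with replicate-level clustering.  Power studies use the
design's 1000 replicates.  Solver brackets and tolerances, the IRLS
iteration caps (60 Newton steps, step tolerance 10⁻⁹–10⁻¹⁰) and the
linear-algebra fallbacks (pinv/lstsq on singular information matrices) are
fixed constants chosen for determinism; no routine depends on wall-clock
or environment state.

## Known limitations

* Only second-order interactions; no higher orders, no quantitative traits,
  no covariates.
* The conditional power of the entropy statistic within a given HLO
  submodel depends on the estimator form: at the liberal cutoff the
  subtraction form is strictly less powerful than the CMI form (which the
  liberal criterion would not calibrate).  Published figures for this class
  of estimator can fall between the two forms, depending on unstated
  sparse-table conventions of other implementations; this package commits
  to the exact plug-in formulas and documents both forms' behavior.
* The per-cell HLO test and its α are conventions; submodel frequencies
  are robust to them, conditional powers less so.
* Text PED/MAP and CSV readers only (no binary PLINK formats); desk-scale
  performance (hundreds of SNPs), not genome-wide engineering.
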