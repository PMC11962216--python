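# Methods notes

This note records the modelling assumptions, numerical choices and known
limitations behind `targetmr`, in the spirit of a statistical software
methods appendix. Nothing here reports an empirical number that the test
suite or `scripts/acceptance.py` does not itself compute.

## Pharmacovigilance arm

Spontaneous-report databases hold one *case* in multiple *versions*; we keep
the highest version per case id, breaking ties by latest year and then input
order, and raise on conflicting content for the same (case, version). This
keep-latest rule is the standard deterministic simplification of regulatory
deduplication guidance, whose full criteria are not public.

The 2×2 table counts deduplicated reports; with `suspect_only` (default) a
report counts as drug-exposed only when the target drug is the primary
suspect, and concomitant target-drug reports fall to the comparator row so
the table always sums to the report count. Zero cells get the
Haldane–Anscombe 0.5 correction applied to all four cells, flagged via
`corrected`, keeping the ROR finite without changing `n_target`. The signal
rule is `n_target ≥ 3` (inclusive) and CI lower bound strictly above 1.
Characteristic-table percentages are rounded half-up to one decimal, the
convention used in published report tables; within each stratified variable
the level counts (including an explicit Missing level) sum to the column
total by construction.

## Instrument selection

All thresholds are strict inequalities: instrument p < 1e-5, MAF > 0.01,
clump r² < 0.3 (a pair at exactly the clumping threshold is *rejected*),
F > 10. The cis window is ±1 Mb from the gene body (start/end, not TSS),
inclusive at both edges, positions 1-based. Records with missing EAF skip
the MAF filter rather than being dropped — the filter is simply not
applicable — while missing effect estimates are dropped at harmonization.

LD clumping is greedy: SNPs sorted by ascending p (ties by position then
id), each accepted iff r² with every already-accepted SNP within the 10 Mb
window is below threshold. The result is therefore independent of input
order, and for small regions it equals the significance-lexicographic
optimum over all maximal admissible subsets (tested by enumeration).

Harmonization aligns outcome effects to the exposure effect allele:
swapped-allele records have the outcome beta negated, palindromic (A/T,
C/G) SNPs are always dropped (no allele-frequency rescue), as are
allele-set mismatches. The Steiger directionality filter keeps SNPs
explaining strictly more variance in the exposure than the outcome, with
r² = 2p(1−p)β² / (2p(1−p)β² + 2p(1−p)·se²·n); when EAF is missing it falls
back to F/(F+n−2), and when n is also missing the pair passes with a
warning rather than being silently removed. Every input SNP ends up either
in the surviving instrument set or in a dropped ledger with the stage that
removed it.

## MR estimators

The Wald ratio SE uses the first-order delta approximation se_out/|β_exp|
(the common convention); the second-order form is available behind a flag
and agrees within 5% for F > 100. IVW is fixed-effect by default —
appropriate when Cochran's Q shows no heterogeneity — with multiplicative
random effects (SE inflated by max(1, √(Q/df))) as an option. MR-Egger is
weighted least squares with intercept (weights 1/se²_out), pairs oriented
to positive exposure effects, slope and intercept tested on t(nsnp−2);
the t reference adds small-sample conservatism where a regression df
exists, while Wald/IVW/median/mode use the normal. The weighted median
interpolates the weighted CDF of ratio estimates linearly at the 50% weight
point; the weighted mode maximizes a normal-kernel weighted density of the
ratios with a MAD-based modified-Silverman bandwidth (×1.0 by default) on a
512-point grid, clipped to the observed ratio range. Both get SEs from a
seeded parametric bootstrap (1000 draws by default; `n_boot=0` falls back
to the IVW-style weight-based SE when only a point estimate is needed, as
in the large simulation sweeps). No multiple-testing correction is applied
across genes; nominal p-values are reported.

Sensitivity: Q = Σ wᵢ(ratioᵢ − β_IVW)² on χ²(nsnp−1) with the IVW weights;
the Egger intercept (nsnp ≥ 3); leave-one-out IVW refits. Q is only
calibrated (mean ≈ df) when instruments are strong enough that
exposure-side noise is negligible — the inflation is approximately
θ²·n_out/n_exp, which the test suite exercises at n_exp = 5×10⁵.

## SMR and HEIDI

SMR uses the smallest-exposure-p SNP: b_smr = β_GWAS/β_eQTL, tested by
T = z²_x z²_y/(z²_x+z²_y) against χ²(1); se_smr = |b_smr|/√T. HEIDI
eligibility follows the published defaults of the method it implements:
exposure p < 1.57e-3, r² with the top SNP in [0.05, 0.9], at most 20 SNPs
by ascending exposure p, at least 3 to run (otherwise NA with a warning).
The deviations dᵢ = b_smr(i) − b_smr(top) get a delta-method covariance
from the LD correlations of the two z-score fields (independent between
samples), and Σ z²_d is referred to Σ λₖχ²₁ with λ the eigenvalues of the
correlation matrix of d (negative eigenvalues clipped at 0). The tail
probability uses Imhof's characteristic-function inversion
(scipy quadrature), preferred over a one-moment χ² approximation for
accuracy in the far tail. "Passing HEIDI" means p ≥ 0.01 (configurable).

## Colocalization

Wakefield log-ABFs with effect-prior SDs 0.15 (quantitative trait 1) and
0.2 (case-control trait 2) and per-SNP priors p1 = p2 = 1e-4, p12 = 1e-5 —
the defaults of the method this implements, all exposed as arguments. All
hypothesis sums use log-sum-exp; the H3 term subtracts the diagonal in log
space with a cancellation guard, so a single-SNP region yields PP.H3 = 0
exactly. Verdicts: PP.H4 ≥ 0.8 highly likely, > 0.5 possible, else none
(the 0.8 boundary is inclusive, "reached"). The beta+SE path is primary;
regions are intersected on SNP id.

## Meta-analysis

Fixed-effect IVW pooling is the default (two outcome sources, no observed
heterogeneity in the motivating application); DerSimonian–Laird τ² with
weights 1/(se²+τ²) behind a flag. Single-study input passes through with a
warning rather than failing. When a study provides p instead of se, the SE
is back-derived via |β|/Φ⁻¹(1−p/2); bound p-values ("<0.01") are rejected
rather than guessed.

## Synthetic data: what it does and does not emulate

Summary statistics are simulated directly at the z-score level — the
asymptotic law z ~ MVN(√n·R·b, R) with R the AR(1) LD matrix
(r = ρ^|i−j|) — never through individual genotypes. True joint eQTL
effects live on the standardized-genotype scale and are drawn uniformly
from [0.5, 1.5]× a base effect (0.05 by default, z ≈ 9 at the default
n_exp = 31,684, i.e. strong instruments with realistic spread); per-allele
betas are z·se with se = 1/√(2·MAF·(1−MAF)·n). Outcome joint effects are
θ·(eQTL effects) plus pleiotropy specified on the per-allele scale, so an
injected directional pleiotropy of 0.02 is exactly the quantity the Egger
intercept estimates. Default sample sizes (n_exp ≈ 3×10⁴ blood eQTL,
n_out = 2×10⁵ biobank GWAS) and the reference reporting conditions
(200-SNP cis regions, ρ = 0.8; 10⁵ case reports, target-drug prevalence
0.3, baseline event reporting rate 0.0135, reporting risk ratio 1.672,
demographic mixes patterned on a large published antipsychotic extract)
were fixed once as desk-scale study conditions. One global seed expands
into named substreams (truth, MAF, alleles, exposure z, outcome z,
reports), so components are independently reproducible and identical seeds
give byte-identical files.

Not emulated: individual-level genotypes, real MedDRA vocabularies,
ancestry or sex structure, multi-gene pleiotropic networks, non-AR(1) LD,
case duplication with *changed* content. Passing tests therefore show the
estimators are correct under their own asymptotic model with known truth —
not that real eQTL/GWAS resources would yield the same biology.

## Simulation scales in tests and the acceptance script

Replicate counts follow the designed calibration/recovery checks: 1000
seeds for IVW type-I error, 500 for effect and Egger-intercept recovery,
200 for weighted-median robustness and HEIDI power, 500 for HEIDI null
calibration, 100 for colocalization recovery, with 20-SNP independent
instrument panels and 60–500-SNP LD regions. Reporting-arm convergence
checks use 2×10⁴-report extracts over 30–40 seeds. These sizes keep the
whole suite at about a minute while leaving Monte-Carlo error well inside
each check's tolerance.

## Known limitations

* HEIDI's delta-method covariance degrades when the top-SNP eQTL z-score is
  modest (< ~4); replicates whose region yields fewer than three eligible
  SNPs return NA and are excluded from calibration summaries.
* The weighted-mode bandwidth rule is one of several in circulation; the
  estimate is reported with its bootstrap SE, and only the plurality-valid
  consistency property is relied on.
* The Steiger filter ignores sampling error in the two r² estimates (no
  z-test on the difference), matching the simple strict-inequality screen.
* Colocalization assumes a single causal variant per trait; multi-causal
  regions dilute PP.H4.
* ROR is a reporting-disproportionality measure, not an incidence ratio;
  the simulation's reporting risk ratio is recovered as an odds ratio,
  which coincides only for rare events.
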