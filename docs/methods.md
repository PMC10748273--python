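# Methods

## The assessment model

A site table carries, per sampling point, total heavy-metal concentrations
(mg/kg), the four BCR sequential-extraction fractions per metal, and
optionally soil physicochemical properties. Three layers of assessment are
computed.

**Geoaccumulation index.** `Igeo = log2(Cn / (1.5 Bn))` with the factor
1.5 absorbing natural background fluctuation. Classified into seven
degrees over integer boundaries 0–5; intervals are half-open `[lower,
upper)` everywhere in the package, so a value sitting exactly on a
boundary takes the upper class. This convention is a package choice — the
grading tables in the literature write ranges like "0–1, 1–2" without
stating boundary ownership — and it makes classification deterministic.

**Hakanson hazard indices.** `Cf_i = C_i / C0_i`, `Er_i = Tr_i · Cf_i`,
`RI = Σ Er_i`. Two modes:

* *classic*: `C_i` is the measured total. No secondary correction is
  applied, so `Cf < 1` (and `Er < Tr`) is possible at clean sites. This
  is deliberate: published classic-mode results report per-metal Er minima
  below the metal's `Tr`, which is impossible if the fold is applied, so
  the fold belongs to the modified mode only.
* *modified*: `C_i` is the corrected concentration
  `Cr = θ1·F1 + θ2·(F2+F3) + θ3·F4` with θ = (1.6, 1.0, 0.6) weighting
  mobility/bioavailability, then folded above background,
  `Cr' = |Cr − C0| + C0`. The fold guarantees `Cf ≥ 1` and `Er ≥ Tr`,
  which the grading assumes.

**Threshold re-derivation.** Grading criteria depend on the pollutant set.
For the assessed set the lowest Er boundary is `max(Tr)` — the Er of an
uncontaminated site (`Cf = 1`) for the most toxic metal. The lowest RI
boundary rescales the original scheme: the original lowest RI limit (150)
over the original eight-pollutant toxicity sum (133) gives a unit toxicity
coefficient, multiplied by the assessed set's `ΣTr` and rounded to the
nearest multiple of ten (31.58 → 30 for the six-metal set; floor-to-ten
gives the same value here, nearest was chosen for symmetry). When that
rounding would collapse a very small toxicity sum to zero, the unrounded
value is kept. Boundaries above the lowest limit double (b, 2b, 4b, 8b),
the conventional geometric progression; it is also the unique geometric
scheme consistent with the published per-metal class fractions. Five
classes for both Er and RI, configurable.

## Monte Carlo propagation

The random variables are the per-metal corrected concentrations `Cr_i`
(not the four fractions separately; a fraction-level mode could be added
but the corrected concentration is what the deterministic index consumes).
Per metal:

1. **Outlier screening**: boxplot fences `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`
   (linear-interpolation quartiles); flagged sites are removed before
   fitting and recorded on the fitted spec. Below 4 observations no
   screening is done.
2. **Family selection**: Shapiro–Wilk on the raw values at α = 0.05
   (α is a package default; sources in this literature rarely state one);
   if rejected, Shapiro–Wilk on the logs; if both reject, the family with
   the larger p is used and a warning attached. Normal fits use the sample
   mean/sd; lognormal fits use the mean/sd of the logs. At survey size
   (n = 16) the test has low power, so a generating lognormal with modest
   skew is often accepted as normal — that mirrors how the procedure
   behaves on real surveys and is harmless for propagation because the
   fitted moments still match.
3. **Propagation**: 50,000 draws per metal (default), metals independent —
   no correlation structure is asserted between metals, matching the
   defaults of commercial risk-simulation tools when no correlations are
   defined. Each draw is folded (`|x − C0| + C0`) and pushed through
   `Cf → Er`; RI per draw is the sum across metals. Negative draws from a
   normal family are rejected and redrawn (concentrations are
   non-negative); rejection counts are logged and reported. The generator
   is seeded (`numpy.random.default_rng`), and metals are sampled in
   sorted-name order, so a result is exactly reproducible from its seed.

**Summaries.** Class probabilities are empirical frequencies over the
half-open class intervals (a draw equal to a boundary counts to the upper
class, consistent with `classify`). The "95% confidence interval" of the
propagated indices is reported as the 2.5–97.5 percentile band of the
draws, not as a truncation of sampling. Sensitivity is
contribution-to-variance: the squared Spearman rank correlation of each
metal's Er draws with the RI draws, normalized to sum to 100% — the
documented method of the commercial tool this replaces. The analytic
cross-check used in the tests folds the fitted CDF in closed form:
`P(Er < b) = F(C0·b/Tr) − F(C0·(2 − b/Tr))` for `b/Tr > 1` (with F the
zero-truncated CDF for normal specs), and 0 otherwise.

## Descriptive layer

CV uses the sample (n−1) standard deviation (the denominator is not
standardized in this literature; n−1 is the conservative default).
Exceedance is strict (`conc > background`); a value equal to background is
not an exceedance. Fraction profiles report percent shares of the fraction
sum with a stable F1→F4 tie-break. The correlation screen is Pearson with
two-sided t-based p by default (Spearman available), pairwise-complete
over missing values, starring p ≤ 0.05 and p ≤ 0.01, with no
multiple-testing correction (none is customary in the source literature
for this screen); zero-variance columns are flagged, not fatal.

Two background sets play distinct roles and are never conflated: the
provincial set (Shaanxi: Cr 67.0, Ni 33.9, Cu 26.4, Zn 72.2, As 14.10,
Pb 17.0 mg/kg) is the reference for Igeo and the contamination factors;
a national set is the reference for exceedance rates only. The national
values shipped (Cr 61.0, Ni 26.9, Cu 22.6, Zn 74.2, As 11.2, Pb 26.0
mg/kg, labelled "China") are standard national soil-background literature
values and are user-overridable.

## Synthetic data generator

`generate_study` draws each metal's four fractions from configured
normal/lognormal marginals (lognormal parameterized by method-of-moments
inversion from target mean and CV, so configuration speaks in mg/kg and
percent); totals are the fraction sum times a multiplicative recovery
factor Normal(1, 0.03), emulating the closure of sequential-extraction
recoveries against the independently measured total. Variables named in
the correlation map (selected fractions and soil properties) are drawn
jointly through a Gaussian copula at the target latent correlation; the
matrix is checked for positive semi-definiteness and the offending
eigenvalue reported otherwise. Negative draws from independent normal
marginals are redrawn; copula-coupled normal draws are clipped at zero to
preserve the correlation structure (rare under the shipped settings).

`study_fixture` configures 16 sites and six metals so that the generated
survey matches published summary statistics: total means at the stated
multiples of the national background (1.34, 1.51, 2.31, 1.53, 91.60, 1.57
for Cr, Ni, Cu, Zn, As, Pb), mean acid-soluble shares (27.29, 17.31,
23.95, 34.20, 38.43% for Cr–As), residual-dominant speciation orderings
(F4 > F1 > F2 > F3, except Pb: F4 > F2 > F1 > F3), and total CVs ordered
As > Cr > Cu = Pb > Zn > Ni within 14–64%. The F2/F3/F4 share splits are
not published; they were fixed once to honor the orderings. Per-fraction
CVs are set to `target_total_CV / sqrt(Σ w_k²)` (w = mean shares) so the
realized total CV approximates the target under independent fractions;
fractions whose implied CV exceeds 50% (arsenic and chromium) use a
lognormal marginal, giving arsenic its strong right skew. Property
marginals emulate a low-fertility alkaline tailings soil (SOM ≈ 1.56 g/kg
lognormal, pH ≈ 8.43 normal, right-skewed nutrient pools), with negative
latent correlations between the mobile As fractions and SOM/N pools and a
positive one with pH.

**What the fixture does not emulate:** spatial autocorrelation between
sites, inter-metal correlation of totals, per-fraction CV heterogeneity
within a metal, measurement censoring, and the exact per-site values of
any real survey. Tests passing on the fixture therefore demonstrate that
the pipeline reproduces the published *structure* (orderings, class
assignments, dominance patterns) — not the survey's exact per-site
numbers, which would require the original per-site data.

## Numerical choices and degenerate inputs

- Classification is total over finite inputs; non-finite values raise.
- `fit_distribution` requires ≥ 8 observations after screening and raises
  on constant samples; fitting tolerates Shapiro–Wilk's reduced p-value
  accuracy above n = 5000 since only the comparison with α matters.
- `propagate` requires ≥ 1000 draws; class probability tables sum to 1 to
  1e−9 by construction; sensitivity contributions sum to 100 ± 0.1.
- Mass-balance disagreement between a fraction sum and the measured total
  beyond 15% (default, motivated by typical BCR recovery spreads of
  ~96–105%) logs a warning, never rejects a site.
- Problem sizes in the shipped analyses: 16 sites, 6 metals, 50,000 Monte
  Carlo draws — the full pipeline runs in a few seconds on one CPU.

## Known limitations

- Metals are propagated independently; correlated multivariate sampling is
  out of scope for this version.
- No RAC/ICF/TCLP indices; no spatial interpolation or mapping.
- The correlation screen is exploratory: at n = 16 only |r| ≳ 0.5 is
  detectable and no multiplicity correction is applied.
- Shapiro–Wilk at survey sizes has low power; the fitted family should be
  read as "not contradicted by the data", not as established.
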