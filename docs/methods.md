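# Methods

This note records the models implemented in `tetragwas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Dosage genotypes and QC

Genotypes are alternate-allele dosages 0–4 at biallelic SNPs, stored as a
markers × samples float matrix with `NaN` for missing calls. Dosage is
derived from ploidy-4 GT calls (count of `1` alleles) or, where GT is
absent, from a numeric DS field. Genotype-level filters (DP ≥ 15,
GQ ≥ 10 set calls missing; site QD ≥ 2.0) follow common post-calling
practice for GBS data.

Marker QC applies, in a fixed and logged order: monomorphic removal,
missingness > 0.20, MAF < 0.01, and modal dosage-class frequency > 0.98.
The order affects only the per-rule attribution in the report, never the
surviving marker set; a marker violating several rules is charged to the
first. MAF is mean dosage / 4 over non-missing calls — the standard
allele-frequency estimator for autotetraploid dosages. "Maximum genotype
frequency" is the frequency of the modal dosage class among {0..4},
computed after missingness masking. The 5 kb genic flank for the
genic / gene-associated / intergenic classification is inclusive
(a marker exactly 5000 bp from a gene boundary is gene-associated), and
gene-body membership takes precedence over a neighbouring gene's flank.

Printed-table summaries (SNP rates, category percentages, decay-table
averages and fold ratios) round half away from zero at the printed
precision, because published tables do; plain float rounding would turn
an exact `x.xx5` down.

## Genomic relationships and structure

The GRM is the ploidy-generalized VanRaden form: with `p_j` the
alt-allele frequency (mean dosage / 4) and `W` the dosage matrix
column-centred by `4 p_j`,

    G = W W' / Σ_j 4 p_j (1 − p_j).

Under tetraploid Hardy–Weinberg (dosage ~ Binomial(4, p)) the expected
diagonal is 1, so a diagonal histogram centred near 1 is the standard
sanity check; under population structure the diagonal inflates (roughly
1 + 3F between-group variance contribution), which is expected, not an
error. Missing dosages are mean-imputed before centring — neutral for
the GRM. Column centring forces zero row sums, hence the exact identity
mean(off-diagonal) = −mean(diagonal)/(n−1), which the tests assert.

PCA is the eigendecomposition of G with scores `U √λ`; negative
eigenvalues (numerical) are clipped at zero with a warning. The scree
elbow helper returns `1 + argmax` of the second difference of the
eigenvalue sequence: with Q subpopulations the Q−1 leading eigenvalues
separate from the bulk and the helper returns Q.

The number of subpopulations is chosen by k-means (k-means++, 50 starts,
seeded) minimizing `BIC(k) = n ln(WSS_k/n) + k ln(n)`, ties to the
smaller k. **Clustering runs on all PC score columns by default**, not
just the leading three: on a few structure-bearing PCs the WSS shrinks
multiplicatively with every added cluster and this BIC is monotone
decreasing (argmin would always return k_max); retaining many PCs — the
practice of adegenet's `find.clusters`, which recommends keeping as many
PCs as possible — adds a high-dimensional noise floor that k-means
cannot carve, and the criterion then attains an interior minimum at the
true k. The three-PC default applies only to the Q covariate matrix of
the association models, where the scree analysis motivates it.

## LD decay

LD between markers on the same chromosome is the squared Pearson
correlation of dosage vectors over pairwise-complete samples (pairs with
fewer than 10 complete samples are skipped and counted). When the pair
count exceeds `max_pairs` (default 5·10⁵) a seeded uniform subsample is
taken.

The decay of the upper envelope is summarized by fitting

    r²(d) = a / (1 + b d),    a ∈ (0, 1],  b > 0

to the 90th percentile by minimizing the pinball loss at τ = 0.90 — a
nonlinear quantile regression with a single-parameter hyperbolic (Sved
type) curve, giving closed forms `LD_1/2max,90 = 1/b` and
`LD_1/10,90 = (a/0.1 − 1)/b` (the latter defined only when the fitted
maximum exceeds 0.1). An exponential form `a·exp(−bd)` sits behind a
config switch. The quantile loss is non-smooth, so optimization is a
coarse grid over a × log₁₀ b followed by bounded Nelder–Mead from the
best grid points; on noise-free curve data this recovers (a, 1/b) to
better than 1e−6 relative.

Two caveats the tests respect: (i) population structure adds
distance-independent (admixture) LD that lifts the 90th percentile at
all distances and flattens the fitted curve — decay-recovery checks
therefore use unstructured panels; (ii) the decay can only be resolved
if the inter-marker spacing is well below the decay length.

## Association models

Eight gene-action encodings map dosage to design columns: additive (x);
general (indicators for dosage classes 1–4, 4 df); simplex dominance
1[x ≥ 1] (alt) and 1[x ≤ 3] (ref); duplex dominance 1[x ≥ 2] (alt) and
1[x ≤ 2] (ref); diplo-general (indicators for {1,2,3} and {4}, 2 df);
diplo-additive ({0→0, 1–3→1, 4→2}). A marker is dropped for an encoding
when one encoded class exceeds 0.98 of samples (near-constant design),
so retained marker sets — and hence thresholds — differ per encoding.
Missing dosages are mean-imputed for design columns only; class-based
encodings round the imputed value to the nearest dosage class.

The K/QK mixed model `y = 1μ + PCγ + g + e`, `g ~ N(0, σ²_g K)` is
fitted per trait by REML profiled over λ = σ²_g/σ²_e on the eigenbasis
of K (grid over log λ ∈ [−10, 10] plus bounded scalar refinement), and
variance components are then frozen for the scan (P3D): per marker, the
rotated, whitened design enters a GLS regression and an F-test on the
encoding's degrees of freedom; `score = −log₁₀ p`; the effect estimate
is reported for 1-df encodings. Naïve/Q fix σ²_g = 0 (ordinary least
squares, optionally with PC covariates); with K = I the K model is
numerically identical to OLS. Collinear covariate columns are dropped by
pivoted QR; a marker whose rotated design falls in the covariate span is
flagged with score 0.

λ_GC converts each p-value to a 1-df χ² quantile and divides the median
by 0.4549364, making inflation comparable across encodings of different
df. Note the sampling noise: at m = 2000 markers a median-based λ has
sd ≈ 0.05 even for independent tests, and under LD the effective test
count is smaller still. The K model can also deflate (λ ≈ 0.7) on a
trait with *no* kinship structure when REML spuriously loads σ²_g onto
the panel's structure axes — a known EMMA-family boundary effect.
Calibration checks therefore use medians over replicates, and KS
uniformity is assessed on a 1 Mb distance-thinned marker subset because
the KS test assumes iid samples.

Significance thresholds use the LD-aware effective number of tests
(Moskvina–Schmidt-type bound): per chromosome
`M.eff = 1 + Σ_{j≥2} √(1 − r*²_j)` where `r*_j` is the largest absolute
correlation between marker j's encoded columns and those of the
preceding `window` retained markers (default 100; a windowless oracle
backs the tests); the genome M.eff is the sum over chromosomes and the
threshold is `−log₁₀(α / M.eff)` at α = 0.05, computed per encoding on
that encoding's retained markers.

A documented power property: a QTL carried by a strongly differentiated
marker (frequency differences across subpopulations) is partially
absorbed by the kinship/PC corrections — at Fst 0.3 the same marker can
score 25+ under the Naïve model and < 2 under K. This is the designed
trade-off of structure correction, so power guarantees are stated for
weakly structured panels, matching real tetraploid potato panels where
structure is subtle.

## QTL post-processing

Significant MTAs are markers whose score exceeds the encoding-specific
threshold under K or QK (both models' scores and effects travel
together). Thinning to one QTL-MTA per LD window is greedy best-first
(peak removal): accept the top score, discard markers within
`window_bp` (default 1,520,000 bp — the genome-average LD_1/10,90 of the
reference panel) on the same chromosome, repeat; score ties break to the
smaller position, and the output spacing invariant is asserted on every
run. Cross-encoding deduplication keeps, per (trait, marker), the record
with the highest best score (ties: lexicographically first encoding
name); the same SNP significant for several traits is deliberately kept
once per trait. Hotspots are single-linkage chains of retained QTL-MTAs
with gaps ≤ 2 Mb covering at least two distinct traits.

## Phenotypes

Disease severity from category counts is the count-weighted mean of
category midpoints. The 7-category scheme (percent surface affected
0–1, >1–5, >5–10, >10–25, >25–50, >50–75, >75–100) has midpoints 0.5, 3,
7.5, 17.5, 37.5, 62.5, 87.5; the 6-category scheme (0–1, >1–10, >10–25,
>25–50, >50–75, >75–100) has 0.5, 5.5, 17.5, 37.5, 62.5, 87.5 —
arithmetic midpoints of the printed ranges.

Genotype values per environment come from a two-way additive
fixed-effect fit (genotype + replicate) solved by least squares — a
deliberate simplification of REML BLUEs that is exact for the balanced
two-replicate designs these trials use and equals plain genotype means
absent block effects; the across-environment value is the unweighted
mean of environment values, with missing genotype × environment cells
excluded and noted. Plot-basis H² per environment is
σ̂²_g/(σ̂²_g + σ̂²_e) from a one-way random-effects ANOVA with
σ̂²_g = max(0, (MS_g − MS_e)/r₀), r₀ the effective replicate number for
unbalanced layouts; a single-replicate environment is undefined (NaN).
Trait correlations are pairwise-complete Pearson with two-sided t-test
p-values multiplied by the number of *tested* pairs (Bonferroni, capped
at 1); constant traits or pairs with < 3 complete observations are
flagged undefined and not counted as tested.

## Synthetic panels: what they emulate and what they do not

`simulate_population` draws, per marker, an ancestral frequency
~U(0.05, 0.95) and per-subpopulation frequencies from the
Balding–Nichols Beta distribution with divergence Fst; each sample is
the sum of four haplotypes; along a chromosome each haplotype's latent
uniform is copied from the previous marker with probability
`exp(−ρ·d)` (first-order Markov), so inter-marker correlation decays as
`exp(−ρ·d)` while marginal frequencies are preserved exactly.
Missingness is completely at random. Defaults are the validation world:
300 samples, 3 subpopulations, Fst 0.3, 4 × 60 Mb chromosomes with
500 markers each, 5% missing calls.

The default decay rate ρ = 1e−6 per bp is fixed by a scaling argument:
the reference panel spans ~741.6 Mb with LD_1/2max,90 ≈ 1.1 Mb, i.e.
~670 effectively independent LD regions; preserving that count on the
240 Mb simulated genome requires an LD half-distance of
240/670 ≈ 0.36 Mb, i.e. ρ = ln 2/(2 × 0.36e6) ≈ 1e−6. Preserving the
independent-region count keeps the panel's test-statistic behaviour
(λ_GC stability, threshold scale) comparable to the real panel at
reduced marker count.

`simulate_phenotypes` builds genotypic values from planted QTL (scalar
genotype-value maps per gene-action model; "general"/"diplo-general"
use fixed non-additive class maps, valid members of those families)
plus a polygenic term drawn N(0, G) from the realized GRM — making the
K model the correctly specified analysis — and adds environment,
replicate and residual noise. With target heritabilities given, QTL and
polygenic components are rescaled to the requested phenotypic-variance
fractions, and the polygenic draw is first orthogonalized against the
QTL values so the realized decomposition is exact; the non-genetic
within-environment variance is split 10% replicate / 90% residual.
Note that "h²" here is a phenotypic-variance fraction: on structured
panels (GRM diagonal > 1) the REML variance-component ratio
σ²_g/(σ²_g+σ²_e) differs from it by roughly the mean GRM diagonal, so
component-recovery checks use unstructured panels. With
`standardize=False` raw effects and explicit variances are used
(noise-free limits).

Not emulated: read-level sequencing and genotype-likelihood dosage
calling (dosages are exact), selfing/pedigree structure, non-random
missingness, marker ascertainment bias, and genotype × environment
interaction (environment effects are additive).

## Pipeline and reproducibility

All randomness flows through seeded `numpy` generators; every output
TSV carries a provenance header (package version, hash of the analysis
parameters — paths excluded — and seed), and a re-run with the same
configuration is byte-identical. Stage funnels (marker counts in, per
rule, out; MTA counts through thinning and dedup) are logged.

## Known limitations

- P3D fixes variance components at the null fit; per-marker REML would
  change borderline scores slightly.
- The kinship matrix includes the tested marker (no leave-one-chromosome
  -out), matching the reference methodology but mildly deflating strong
  signals (proximal contamination).
- The hyperbolic quantile curve is a declared substitute for the
  unspecified published quantreg model; its estimators are validated by
  their own properties (quantile coverage, scale consistency), not
  against the published per-chromosome values, which are data-dependent.
- Multi-df encodings report no single effect size.
- BLUEs are fixed-effect approximations; multi-environment REML with
  G×E components is out of scope.
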