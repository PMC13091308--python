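# Methods

This note records the statistical models implemented by `crossgwas`, the
generative model behind the synthetic scenes, the defaults and why they
were chosen, and the numerical decisions a maintainer would want stated.

## Sampling model

All layers operate on GWAS summary statistics under the standard
infinitesimal sampling model for standardized genotypes. For a trait with
sample size `n`, per-SNP standardized effects `β` and LD correlation `R`,
the marginal association z-vector of an LD block is

    z ~ N( √n · R β , R )

The synthetic generator draws from this model directly (block by block,
via the Cholesky factor of each AR(1) block) rather than simulating
individual-level genotypes. This is exact under the model, fast enough for
20,000-SNP scenes in about a second, and matches the assumptions of every
downstream estimator — which is precisely what makes ground-truth
validation meaningful.

Effect pairs for two traits are bivariate normal per SNP with variances
`(h²/m)·multiplierⱼ` and correlation `rg_true`, then rescaled so each
trait's realized `Σβ²` equals `h²` exactly. Annotation multipliers are
normalized to a SNP-weighted mean of 1 so total heritability is preserved;
a 2.0× multiplier on 10% of SNPs therefore corresponds to a true
enrichment of 2.0/1.1 ≈ 1.82 after normalization.

### LD reference

The reference is block-diagonal with AR(1) blocks, `r_ij = ρ^|i−j|`. The
default scene uses 200 blocks of 100 SNPs with ρ cycling through
{0.2, 0.35, 0.5, 0.65, 0.8} (mean 0.5). The heterogeneity is deliberate:
LD score regression identifies `h²` from the *spread* of LD scores, and a
genome with one uniform ρ has nearly constant `l_j` (every interior SNP of
every block sees the same neighborhood), leaving the regression slope
essentially unidentified (slope SE ≈ 0.05 at this scene size). Cycling ρ
across blocks produces LD scores from ~1.04 to ~4.6 and slope SEs around
0.005, while keeping the mean LD level at the ρ = 0.5 reference point.

### What the generator does and does not emulate

It reproduces: polygenic architecture, block LD, annotation-specific
per-SNP heritability, cross-trait effect correlation (including rg = 0),
case-control effective sample sizes, both file dialects, and injectable
allele corruption (swaps, strand complements, palindromic variants) with
recorded ground truth for harmonization tests.

It does not emulate: allele-frequency-dependent effect sizes (genotypes
are standardized; frequencies exist only as allele labels), coalescent
haplotype structure, population stratification, imputation error, sample
overlap between traits, or cross-block LD. Passing tests therefore
demonstrate correctness of the estimators under their own sampling model,
not robustness to the confounders of real GWAS.

## Gene-based association

SNPs map to genes with windows of 35,000 bp upstream and 10,000 bp
downstream of the gene body, mirrored for minus-strand genes (upstream is
5′ of the gene; strand is in the gene record). The gene statistic is
`t = mean(z²)` over mapped SNPs. Under the null, `m·t ~ Σ λᵢ χ²₁` with λ
the eigenvalues of the local LD matrix. The p-value comes from
Satterthwaite two-moment matching: `m·t ≈ g·χ²_df` with `g = Σλ²/Σλ`,
`df = (Σλ)²/Σλ²`. This is exact for independent SNPs (λ all 1) and for a
gene in perfect LD (rank-1 spectrum), the two regimes the tests pin down;
between them it is a standard, deterministic approximation. Small negative
eigenvalues (numerical noise) are clipped at zero; matrices indefinite
beyond `1e-6·m` are rejected with advice rather than silently repaired.
Genes with zero mapped SNPs are excluded rather than assigned p = 1, which
would distort the competitive background.

Gene Z is the probit `Φ⁻¹(1−p)`, clamped at ±37.5 (the double-precision
representable extreme) with clamping visible in the value itself.

The competitive set test is a one-sided Welch t-test (member Z greater
than background Z). Welch rather than pooled-variance because set sizes
are small and member variance need not match the genome-wide background;
one-sided because the question is enrichment. A panel run reports raw,
Bonferroni (α/k) and Benjamini–Hochberg p-values. Panel deduplication
keeps each gene only in its highest-priority set and is idempotent.

## GSEA and differential GSEA

Preranked GSEA on the gene-Z ranking (descending, ties broken by gene id
so runs are reproducible). Hits increment the running sum by
`|score|^w / Σ|score|^w` (w = 1 by default), misses decrement by
`1/(N−n)`; ES is the maximum-magnitude excursion, with exact ties resolved
toward the positive side. At w = 0 this reduces to the classic two-sample
KS statistic, which the tests verify directly.

The null is gene-label permutation — random same-size sets — because with
summary statistics there are no phenotypes to permute. NES divides ES by
the mean |null ES| of matching sign; p uses the `(1+b)/(1+n_same_sign)`
rule and can never be exactly zero. FDR is Benjamini–Hochberg across the
sets of the run, a deliberate simplification of the canonical pooled-NES
GSEA FDR estimator: it is deterministic given the null draws and requires
no cross-set pooling heuristics. Sets outside [5, 500] members after
intersection with the universe are reported as skipped.

DGSEA compares NES between two disorders' rankings over every ordered
pair of distinct sets (`k(k−1)` comparisons; 56 for k = 8). The null
pairs, per permutation index, the normalized null ES of set A's size on
ranking A with that of set B's size on ranking B; `p_diff` is two-sided
with the +1 rule and BH across comparisons. An unordered within-disorder
mode (2·C(k,2), the same count) is available behind a flag. Same-set
cross-disorder differences are exposed descriptively via
`nes_difference`.

## Summary TWAS

`Z_gene = Σ wₗ σₗ zₗ / √(wᵀΣw)` with weights `w`, reference SNP standard
deviations σ (1 under the standardized-genotype convention) and reference
covariance Σ. Model SNPs absent from the study are dropped and the
prediction variance recomputed over the retained subset — the standard
summary-TWAS fallback; a strict mode raises instead. σ and Σ always come
from the LD reference, never from the GWAS file.

Set enrichment within a tissue is a one-sided Mann–Whitney U on |Z|
(members stochastically greater). The `enrichment_ratio` is defined as
mean |Z| of members divided by mean |Z| of the background — the simplest
summary consistent with the Mann–Whitney framing; tables built on this
column depend on that definition. FDR is applied per tissue. The
best-tissue summary takes the tissue maximizing |Z| per gene, ties broken
by lexicographic tissue label.

## LD score regression

LD scores are `l_j = Σ_k r²_jk` within the block (self term included);
per-annotation scores restrict k to annotation members, so scores are
additive over a partition of SNPs.

Univariate fit: weighted least squares of χ² on `n·l/m` with a free
intercept. Weights are `1/max(1, l_j)` — a plain heteroskedasticity/
overcounting proxy. The canonical method iterates weights that include the
`(1 + n h² l/m)²` variance term; the simple weights are deterministic,
adequate at synthetic scale (jackknife SEs ≈ 0.005 on the default scene),
and are stated here as a deviation from the canonical scheme. No χ²
ceiling is applied by default (the usual χ² > 80 filter matters for real
data outliers, not for these scenes); it is configurable.

Partitioned fit: χ² regressed on the base (all-SNP) score column plus one
column per annotation, all scaled by n. Per-SNP heritability is the
coefficient-weighted sum of memberships, so overlapping annotations are
handled by construction; `prop_h2(c)` sums per-SNP h² over members,
enrichment is `prop_h2 / prop_snps`, and the one-tailed p for
enrichment > 1 uses the jackknife-normal approximation. Two degenerate
designs are handled explicitly: annotations that exactly partition the
SNPs (their columns sum to the base column — the base is dropped), and an
annotation covering all SNPs (its proportion is 1 by construction and is
reported exactly). Note that under annotation enrichment the *univariate*
regression is mildly misspecified and attenuates h²; heritability-recovery
checks therefore use scenes without annotations.

Fallback enrichment — the simplified cross-check — is the per-unit-LD
excess χ² ratio: `[(mean χ²_in − 1)/mean l_in] / [(mean χ²_out − 1)/mean
l_out]`, the minimal estimator consistent with `E[χ²−1] ∝ (per-SNP h²)·l`.
Negative excess signal is floored at 1e-6 with a flag. It is validated
only by concordance with the full partitioned estimator on synthetic
truth (direction agreement on every seed of the 2× scene; magnitudes
within ~10% of each other on average).

Genetic correlation: `z_a·z_b` regressed on `√(n_a n_b)·l/m` with a free
cross-trait intercept (which absorbs sample overlap; the per-trait
intercepts and the cross-intercept are all reported for monitoring).
`rg = gencov/√(h²_a h²_b)`, with h² from univariate fits on the same
SNPs. Standard errors jackknife the *full* rg statistic over 200
contiguous equal-count SNP blocks (delete-one-block refits are cheap
because per-block `X'WX`/`X'Wy` are precomputed). A 30-seed calibration
check shows the jackknife SE matches the across-seed spread of estimates
almost exactly, so "within 2 SE" statements behave like genuine ~95%
statements — individual seeds will exceed 2 SE about 5% of the time, as
they should.

## Harmonization

Variants match on chrom:pos; rsID is a fallback used only for keys absent
from the positional index, and an rsID match with conflicting coordinates
is rejected (`position_conflict`). Allele handling per match: exact match
kept; swapped alleles kept with study-2 z negated; strand-complemented
alleles complemented first and then the same rules; palindromic (A/T,
C/G) variants are always dropped — the schemas carry no allele
frequencies, so frequency-based disambiguation is impossible and dropping
is the conservative standard. Duplicated keys keep the first occurrence.
Every input variant ends in the shared table or exactly one ledger
category, and the ledger satisfies per-study conservation; harmonization
is an involution (applying it to its own output changes nothing). Genome
builds must match — there is no liftover; mismatched build labels are a
fatal error.

p-values that underflow to zero on parsing are floored at the smallest
positive double with a flag, never left at zero.

### File dialects and precision

Dialect A is tab-separated text with configurable column mapping (OR
columns are log-transformed; case/control counts produce the effective
sample size `4/(1/N_ca + 1/N_co)`). Dialect B is GWAS-VCF with one sample
column and `ES:SE:LP` (plus `SS`) FORMAT fields; ALT is the effect allele,
the convention of the ES field. The VCF is read by a dedicated text-level
parser: binary VCF Float encodings are 32-bit, which would truncate
beta/SE and break both the bit-exact round-trip contract and the
guarantee that TSV- and VCF-encoded copies of one study produce identical
downstream results. Emitted VCFs are validated against an independent VCF
library in the test suite. All floats are written with shortest
round-trip precision, and intermediate CSVs are re-read with round-trip
parsing so resumed pipeline runs are byte-identical to fresh ones.

## Pipeline and reproducibility

`run_all` executes harmonize → gene scores/set tests → GSEA/DGSEA → TWAS
→ LDSC, writing one CSV bundle per layer plus a manifest (config hash,
software version, per-layer seeds, timings, warnings, failure point).
Layers resume from existing outputs, and deleting a layer's files and
re-running reproduces the original bundle byte-for-byte.

One global seed deterministically derives every per-layer seed by hashing
`(seed, layer_name)` (SHA-256, reduced below 2³¹), so adding a layer never
shifts another layer's random stream. All stochastic outputs are
byte-reproducible for a fixed seed.

## Problem sizes and defaults

| Parameter | Default | Notes |
| --- | --- | --- |
| m (SNPs) | 20,000 | 200 AR(1) blocks of 100 |
| block ρ | cycle 0.2–0.8 | mean 0.5; see LD reference above |
| n per trait | 50,000 | balanced two-trait design |
| h² per trait | 0.3 | rescaled to hold exactly |
| SNP spacing | 1 kb | single synthetic chromosome |
| genes | 400 × 20 SNPs | non-overlapping bodies, alternating strand |
| panel | 8 sets × 30 genes | priority hierarchy, configurable overlap |
| gene windows | 35 kb up / 10 kb down | strand-aware |
| annotation pad | 10 kb | merged BED, 0-based half-open |
| GSEA permutations | 10,000 | size filters 5–500, weight exponent 1 |
| jackknife blocks | 200 | contiguous equal-count |

Calibration and recovery checks average 10 seeds per scene: per-seed noise
on the LDSC intercept is ~0.023 SD, so a 10-seed mean (SEM ≈ 0.007)
resolves a ±0.02 band; the same sizing covers the h² and mean-χ² checks.
These scenes run in seconds each, keeping the full validation suite in
the low minutes on one CPU.

## Known limitations

- The Satterthwaite gene p-value is an approximation between its two
  exact regimes; an exact quadratic-form inversion is a natural extension
  hook.
- GSEA FDR is BH on permutation p-values, not the canonical pooled-NES
  estimator; q-values are not comparable across methods.
- The competitive test is the plain Welch t; a covariate-adjusted variant
  (gene length, SNP count) is a natural extension and matters more on
  real annotations than on the uniform synthetic gene grid.
- LDSC weights are not iterated; on real data with strong stratification
  the canonical weighting and χ² ceiling would be preferable.
- No liftover, no allele-frequency-based strand inference, no
  imputation-quality filtering, no MHC special-casing, no cM windows.
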