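# Methods

## The gene-level model

The package tests, per gene, the global null that none of the gene's
assigned SNPs is associated with the phenotype, using only GWAS summary
statistics (per-SNP two-sided p-values) and a genotype reference panel for
LD. Each p-value is transformed to the 1-df chi-square value it implies,
$q_j = F^{-1}_{\chi^2_1}(1-p_j)$, and the gene statistic is the mean
$T = m^{-1}\sum_j q_j$ ("snp-wise mean"). Because the transform uses only
p-values, effect directions never enter: the statistic is two-sided by
construction and no allele alignment between summary statistics and panel
is needed (correlation signs flip with allele coding, but the null
distribution of $z^\top z$ depends on $R$ only through its eigenvalues,
which are invariant to sign flips $R \to DRD$ with diagonal $\pm 1$ $D$).

Assumptions: under the null the SNP z-scores are jointly multivariate
normal with correlation equal to the genotype correlation $R$ of the panel
(the standard summary-statistic LD approximation; accurate when the GWAS
sample is large and the panel matches its ancestry), and the panel is large
enough that $\hat R$ estimation noise is second-order. Genes are tested
marginally; no conditional or joint gene model, no sample-overlap
correction, no covariates.

## Evaluating the weighted chi-square tail

Under the null $mT = \sum_i \lambda_i w_i$ with $\lambda_i$ the eigenvalues
of $R$ and $w_i$ i.i.d. $\chi^2_1$. Three evaluators:

* **satterthwaite** (default): $mT \approx c\,\chi^2_\nu$, $c =
  \Sigma\lambda^2/\Sigma\lambda$, $\nu = (\Sigma\lambda)^2/\Sigma\lambda^2$.
  Exact when all eigenvalues are equal (in particular $R=I$). Its relative
  error in the distribution body grows with eigenvalue spread: across
  random LD-like spectra ($m \le 30$) the worst absolute deviation from the
  Monte-Carlo tail at true $p \in [0.01, 0.5]$ is of order 0.01–0.025 —
  small enough for screening, and large enough that a Kolmogorov–Smirnov
  test on a few thousand null genes detects it. Use `imhof` when exact
  calibration matters.
* **imhof**: numerical inversion of the characteristic function (Imhof's
  integral), adaptive quadrature with tolerance 1e-8, result floored at
  1e-300; a single positive eigenvalue short-circuits to the exact scaled
  chi-square. Agrees with the Monte-Carlo oracle to ~1e-3 everywhere tested,
  including true p = 1e-4.
* **montecarlo**: empirical tail from simulated draws with add-one
  smoothing $\hat p = (k+1)/(B+1)$, default $B = 10^5$, seeded. Slow but
  assumption-free; serves as the independent oracle in the test suite.

Per-gene LD blocks use per-SNP mean imputation of missing hard calls,
column standardization, and the sample Pearson correlation; eigenvalues
below 1e-8 are clipped to zero (rank deficiency with $m >$ panel size is
legitimate and appears as zero eigenvalues). Optional ridge shrinkage
$R \gets (1-\gamma)R + \gamma I$ (default $\gamma = 0$) is exposed for
ill-conditioned blocks. Zero-variance columns are dropped with a warning.

## Numerical and policy choices

* P-values of exactly 0 are clamped to 1e-300 (the chi-square quantile
  diverges at 0); p > 1 rows are rejected. Gene p-values are floored at
  1e-300.
* Coordinates: `.bim` and `gene.loc` are 1-based inclusive (PLINK/MAGMA
  convention); BEDPE contact anchors are 0-based half-open; anchor–feature
  overlap means ≥ 1 bp intersection under half-open arithmetic.
* Chromosome labels are normalized by stripping a `chr` prefix; the
  autosome test is integer 1–22. Strand-ambiguous SNPs are the A/T and C/G
  allele pairs. Panel QC (MAF ≥ 0.01, drop ambiguous, autosomes only)
  applies per-SNP independent filters, so filter order cannot change the
  result.
* Duplicate identifiers anywhere (panel SNPs, summary rows, QTL pairs,
  annotation genes) keep the first occurrence and log the rest —
  deterministic and auditable.
* Unknown strand: gene windows and promoters are applied as on the plus
  strand. Promoter default: 2 kb upstream of the TSS, configurable.
* Gene identity in the meQTL collapse resolves Ensembl id first, then
  symbol; a symbol matching several loci is expanded to all of them with a
  warning (array annotations routinely carry many-to-one symbol maps).
  CpG→gene links whose gene is absent from the gene model are dropped with
  a count, tolerating gene-model version skew.
* The meQTL FDR filter (default 5%) is applied to the pair table even if
  the source was pre-thresholded; re-filtering is idempotent. The ±500 kb
  cis-window check is advisory (a validation report), not enforced, since
  pair tables are typically pre-constructed upstream.
* Multiple-testing adjustment (BH via statsmodels, Bonferroni) is applied
  per analysis run — per phenotype × annotation layer — and $m$ is the
  number of genes actually tested (≥ 1 usable SNP), not annotated.

## The synthetic-fixtures model

The generator emulates the pipeline's inputs with planted ground truth.

**Panel.** Each gene contributes an LD block with target correlation
$R_{ij} = \rho^{|i-j|}$ (AR; default $\rho = 0.8$). A haplotype's allele
indicators follow a stationary two-state Markov chain along the block with
stationary frequency $f$ and second eigenvalue $\rho$ (each step copies the
previous indicator with probability $\rho$, else redraws Bernoulli($f$)),
whose autocorrelation at lag $d$ is exactly $\rho^d$; a genotype is the sum
of two independent haplotypes, so genotype correlations equal the target
exactly in expectation and marginals are Binomial(2, $f$) (Hardy–Weinberg).
A latent-Gaussian threshold construction was considered and rejected:
thresholding attenuates Pearson correlations, and calibrating the latent
pairwise correlations to an AR(0.8) genotype target produces a jointly
infeasible (indefinite) latent matrix. The allele frequency is drawn per
gene from `maf_range` (default [0.1, 0.5]) and shared by the block's SNPs —
tightly linked SNPs on a common haplotype background do have similar
frequencies, and sharing $f$ is what makes the exact-AR construction
possible. Within-block frequency variation is therefore *not* emulated.

**Summary statistics.** Per gene, $z \sim N(\mu, R_{\text{target}})$ with
$\mu = 0$ (null) or $\delta \mathbf{1}$ (causal; default $\delta = 2$), and
$p = 2\Phi(-|z|)$. Drawing z from the *target* rather than the realized
panel correlation is deliberate: the calibration experiments then test the
whole loop panel → $\hat R$ → null distribution, including estimation
noise.

**meQTL fixture.** Pair and link tables are constructed so the SNP–CpG–gene
join has exactly the planted cardinalities (CpGs, SNPs, triplets): one CpG
gets a single dedicated pair, the remaining SNPs/CpGs are paired
round-robin (every SNP and CpG appears, all pairs distinct), and the
triplet deficit is closed by granting extra gene links greedily (adding a
link to a CpG with $k$ pairs adds exactly $k$ triplets; the single-pair CpG
guarantees termination). Cardinalities below max(#SNPs, #CpGs) are
infeasible and rejected. Unmapped CpGs (pairs without links) and
supra-threshold FDR rows are appended to exercise the filters.

What the fixtures do **not** emulate: realistic allele-frequency spectra,
recombination maps or cross-gene LD; dosage genotypes; case/control
liability; meQTL effect sizes estimated from methylation data. Passing
tests therefore demonstrate the statistical machinery is correct under its
stated model, not that real-data idiosyncrasies (stratification, allele
mismatches, build skew) are handled beyond the documented QC.

## Study conditions of the calibration experiments

The calibration, power and FDR experiments run at 2 000 genes × 10 SNPs,
AR(0.8) LD, 2 000 panel individuals, $\delta = 2$ for causal genes, 5% FDR
— sizes chosen so each experiment completes in minutes on one CPU while
keeping Monte-Carlo error well below the effect sizes under test. The
calibration experiments use the `imhof` evaluator: they are meant to test
the null model and the LD-estimation loop, not the two-moment
approximation (whose error is quantified separately by the evaluator
cross-check). Of note, the exact power of the mean-chi-square test at
$\delta = 2$, $m = 10$, AR(0.8), $\alpha = 0.05$ is ≈ 0.757 (weighted
chi-square quantile + 2·10⁶-draw Monte Carlo): the strong positive LD
inflates the null variance of $\sum z_j^2$ enough to hold power below 0.8
at these settings, so 200-replicate power measurements fluctuate around
0.76 with seed-to-seed binomial noise of ±0.03.

## Known limitations

* The Satterthwaite evaluator's body error (see above) makes default-method
  p-values unsuitable for exact uniformity claims; switch to `imhof` for
  calibration-sensitive work.
* LD is estimated per gene independently from hard calls; no cross-gene
  statistics, no dosage support, no allele-frequency alignment checks
  between summary statistics and panel beyond SNP-id intersection.
* The chromatin-contact annotator consumes loop calls (BEDPE); it does not
  call loops from contact matrices, and inter-chromosomal contacts are
  dropped.
* eQTL/meQTL pair tables are consumed as given; the package does not fit
  QTL models.
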