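# Methods

## Estimation model

All estimation works on two-sample GWAS summary statistics: per-variant
effects of an exposure from one sample and of an outcome from a second,
non-overlapping sample. For instruments $j = 1,\dots,m$ the outcome effects
$y$ are regressed on the exposure effects $x$ by generalised least squares
with weight matrix $\Omega^{-1}$, $\Omega = D R D$, where $D$ holds the
outcome standard errors and $R$ is the signed LD correlation of the
instruments. Because clumping is applied at $r^2 \le 0.3$ rather than full
independence, residual instrument correlation is expected and the GLS
whitening is what keeps the standard errors honest.

The fit is computed through the Cholesky factor of $\Omega$: with
$\Omega = LL^\top$, the design and response are whitened
($X^* = L^{-1}X$, $y^* = L^{-1}y$) and an ordinary solve follows. This gives,
at no extra cost, the quantities the pruning step needs:

- **Cochran's Q** is the squared norm of the whitened residual;
- **outlier statistics** are the per-coordinate squared whitened residuals
  (they sum to Q, and under the model each is approximately $\chi^2_1$);
  the cutoff 10.83 is the $\chi^2_1$ quantile at 0.999;
- **leverage** is the diagonal of the whitened hat matrix (entries in
  [0, 1], summing to the number of fitted parameters).

With correlated instruments the whitened coordinates are linear combinations
of variants; coordinate $j$ is attributed to variant $j$ (the Cholesky
factor is lower triangular, so coordinate $j$ is variant $j$ conditioned on
its predecessors). This is the natural generalisation of per-variant
residuals to the correlated case and reduces to them exactly for identity
LD.

Without an intercept the GLS fit is the IVW estimator (for identity LD it
reproduces textbook $1/\sigma^2$ weighting exactly, which the tests assert
to 10 significant digits); with a free intercept it is MR-Egger, unbiased
under directional horizontal pleiotropy provided instrument strength and
pleiotropy are independent. Model selection follows the Rücker logic:
because the models are nested, $Q_{\mathrm{IVW}} \ge Q_{\mathrm{Egger}}$
always, and Egger is preferred when the difference exceeds
$\chi^2_{1,1-\alpha}$ with $\alpha = 0.05$ (3.841). A larger drop in
heterogeneity than chance allows is evidence that the intercept is doing
real work. $Q_{\mathrm{IVW}} < Q_{\mathrm{Egger}}$ beyond numerical
tolerance raises an internal-consistency error rather than being clipped.

Inference uses normal reference distributions (summary-statistic MR
convention) and the multiplier 1.96 verbatim for 95% intervals, so that
printed odds-ratio intervals round-trip exactly through
`to_reported_effect`.

## Analysis pipeline and its defaults

`run_mr` chains: instrument filter → optional cis window → harmonisation →
clumping → iterated pruning → model selection → reporting. The defaults are
the constants of the study design this package implements:

| knob | default | meaning |
| --- | --- | --- |
| `f_min` | 24 | minimum per-variant F-statistic $(\beta/\mathrm{SE})^2$ |
| `maf_min` | 0.01 | minimum folded allele frequency $\min(f, 1-f)$ |
| `flank` | 200 000 bp | cis window: gene body ± flank, closed interval, 1-based |
| `r2_max` | 0.3 | LD clumping ceiling |
| `min_variants` | 6 | analyses below this at any stage are discarded |
| `leverage_factor` | 3 | prune leverage > factor × mean leverage |
| `outlier_cut` | 10.83 | prune squared standardised residual above this |
| `selection_alpha` | 0.05 | Rücker chi-square level |
| `ridge` | 1e-8 | diagonal regularisation of R before inversion |

Choices that were genuinely open, and how they were settled:

- **Pipeline order** is filter → cis → harmonise → clump. Clumping after
  harmonisation means instruments absent from the outcome GWAS cannot crowd
  out usable ones.
- **Pruning is iterative**: leverage/outlier statistics are recomputed from
  the IVW fit after each removal pass, until no variant is flagged, fewer
  than `min_variants` remain, or 10 rounds have run. Single-pass pruning is
  order-dependent in a way that is hard to audit; the iteration is
  deterministic and capped. Statistics are always taken from the IVW fit,
  not the selected model's.
- **Clumping ranks** by exposure p-value with lexicographic variant-id
  tie-breaks, so results are reproducible under row permutation.
- **Palindromic variants** (A/T, C/G) are dropped when the folded frequency
  exceeds 0.42 in either sample — the standard two-sample harmonisation
  default for strand-ambiguous variants.
- **LD orientation**: the LD matrix is defined in the exposure table's
  effect-allele orientation. Harmonisation re-orients the outcome to the
  exposure, so outcome-side allele swaps never touch the LD signs; when an
  LD panel is supplied in a different orientation, `ld_effect_alleles`
  applies the corresponding row/column sign flips.
- **Bonferroni thresholds** are applied at their exact value
  $\alpha/(m_1 m_2)$; the one-significant-figure value is used only for
  reporting, since filtering at the rounded value would be more lenient
  than $\alpha/m$.
- **Concordance signs** are taken from the slope (mean-difference or
  log-odds) scale, never from the odds-ratio scale, avoiding the OR = 1
  ambiguity. The verdict is invariant to recoding the direction of any
  single trait, which flips the two incident edges.
- **Enrichment** compares the proportion of prioritised proteins in a group
  against the background proportion with a Wald z using the background
  proportion's variance under the null,
  $z = (\hat p_1 - \hat p_0)/\sqrt{\hat p_0(1-\hat p_0)/n_1}$; a pooled-SE
  variant is available behind the `pooled` switch. A degenerate background
  proportion (0 or 1) returns p = 1 with a flag. Two-sided by default,
  one-sided available.
- **Cardiac overexpression** is a provisional one-sided z of cardiac
  abundance against the mean and SD of the other 60 tissues; "expressed" is
  abundance above a configurable minimum (default 0). Both stand in for a
  full differential-expression treatment and are labelled as such.
- **Replication** requires the same effect direction as discovery plus
  p < 0.05 (nominal) or p < 0.05/n (conservative, so conservative implies
  nominal); summaries count distinct proteins and report percentages of the
  number of proteins with replication data.

## The synthetic-data generator

The simulator emulates exactly the structure the estimator assumes, which
is what makes the calibration experiments sharp tests of the implementation:

- true per-variant exposure effects drawn uniformly from
  `exposure_effect_range`, observed with noise of SD $1/\sqrt{n_X}$;
- outcome effects $\theta b_j + \alpha_j$ observed with noise of covariance
  $\sigma^2 R$ (the correlated-instrument model the GLS assumes), with
  exposure and outcome noise independent (two-sample independence);
- pleiotropy $\alpha_j$ zero, balanced (mean 0), or directional (mean
  $\mu \ne 0$);
- AR(1) LD blocks: correlation $\rho^{|i-j|}$ within a block, zero across;
- 10% of variants have their allele coding swapped between the two samples
  so harmonisation is always exercised; alleles are drawn from {A,C,G,T},
  so roughly a third of variants are palindromic and a few of those are
  dropped as strand-ambiguous.

Defaults mirror the study conditions the package targets: exposure sample
n = 86 507 (a large metabolite GWAS meta-analysis), outcome effective sample
n = 20 000 on the log-odds scale (binary cardiac outcome GWAS), per-variant
exposure effects up to 0.5 SD per allele (metabolite/pQTL scale), blocks of
5 at $\rho = 0.5$.

What the simulator does **not** emulate — and hence what passing tests do
not establish about real data: realistic allele-frequency spectra and
frequency-dependent standard errors, sample overlap between the two GWAS,
winner's-curse selection of instruments, misspecified LD reference panels,
strand errors that survive palindrome filtering, and pleiotropy correlated
with instrument strength (InSIDE violations). On real data these produce
biases the calibration experiments here cannot see.

`simulate_toy_study` plants a closed linear system for the end-to-end
pipeline: each protein has a cis locus, each metabolite a locus of its own
plus inherited effects $B_{pm}$ at the cis loci of its regulating proteins,
and each binary outcome is driven by metabolites ($B_{mo}$) plus occasional
direct protein effects ($D_{po}$) whose presence breaks directional
concordance for some triples — so the expected triangle set is known and is
cross-checked by a brute-force triple scan.

## Numerical notes

- $\Omega$ inversion always goes through a Cholesky factorisation of
  $D(R + 10^{-8}I)D$; failure raises `IllConditionedLDError` instead of
  silently switching to a pseudo-inverse.
- Monte-Carlo experiment sizes are 1000 replicates for null calibration,
  500 for slope recovery/coverage, and 200 paired replicates for the
  model-selection comparison, at 50–100 variants per dataset; at these sizes
  the whole suite and the acceptance script each run in well under a minute
  on one CPU.
- p-values are floored at the smallest positive double so they stay in
  (0, 1].
- All tie-breaks (clumping order, primary-study selection, table sort
  orders) are lexicographic, making every pipeline output byte-reproducible
  under a fixed config.

## Known limitations

- No weighted-median/mode estimators, multivariable MR, Steiger filtering,
  or winner's-curse correction; no proxy-variant lookup; no colocalisation
  or mediation quantification along triangles.
- Egger standard errors are not overdispersion-scaled; under strong balanced
  pleiotropy its CIs are anti-conservative (the Monte-Carlo mean remains
  unbiased, which is what the tests check).
- The druggability, pathway and expression tables are local fixtures shaped
  like the public resources they stand in for; no live queries are made.
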