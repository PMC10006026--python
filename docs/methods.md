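# Methods

## Scope and data model

The package operates on *complete* two-way phenotype tables: one finite
value per (genotype, environment) cell, for one trait at a time. On disk
the canonical shape is long format (`genotype`, `environment`, one column
per trait); in memory a `GxETable` is the wide genotype-by-environment
matrix. Incomplete tables are a hard error — every index formula below
assumes complete marginals and no imputation scheme is offered.
Environments are opaque composite keys: site, season, CO₂, nitrogen or
sowing-date labels may exist as columns upstream, but the analysis treats
each combination as one atomic environment.

All randomness flows from a single user seed through named substreams
(`substream(seed, *keys)`, built on `numpy.random.SeedSequence`), so each
stage — genotype draws, environment draws, generator noise — is
reproducible independently of the others.

## Stability indices

Eleven per-genotype indices are implemented from their defining sums (see
README for formulas): environmental variance, Taylor-adjusted CV,
Finlay–Wilkinson regression slope and its R², deviation mean squares,
Wricke's ecovalence plus the environment-count-normalized variant
`W′_i = W_i/E` (which makes ecovalences comparable between analyses run
with different numbers of environments), Hanson's genotypic stability,
Lin & Binns' superiority measure, Eskridge's safety-first index, Shukla's
stability variance and Nassar & Hühn's variance of corrected ranks.

Numerical and interpretation choices:

* **Marginals are sample-local.** When indices are computed inside a
  sampled population (SPG×SPE), the environment means, grand mean,
  environment maxima `M_j` and `b_min` are all taken over that subset
  only. Sampled populations are self-contained; nothing leaks in from the
  pool.
* **Safety-first orientation.** `SF_i = Φ((λ − x̄_i.)/S_i)` is the
  *failure* probability (trait below the critical level λ), so it
  decreases with the genotype mean. λ has no default — it is a biological
  choice (e.g. an economic break-even yield) — and the CLI requires
  `--lambda` when the index is requested.
* **Shukla's variance** is computed in the ecovalence-based closed form
  `σ²_i = G·W_i/((G−2)(E−1)) − ΣW_k/((G−1)(G−2)(E−1))`; the test suite
  cross-checks it against an independent ANOVA-residual oracle. Negative
  estimates are legitimate (unbiased variance-component estimator).
* **Ranks** are ascending with average-rank tie handling.
* **Adjusted CV**: the Taylor slope `b` is fitted by OLS of log₁₀ variance
  on log₁₀ mean across genotypes; each genotype's log-variance is moved to
  the slope-2 line before forming the CV, so the index collapses to the
  ordinary CV exactly when `b = 2`. Genotypes with nonpositive mean are a
  domain error; zero-variance genotypes are excluded with a warning.
* **Unit transform.** Indices in squared trait units (`P_i`, `W_i`,
  `W′_i`, `S⁽⁴⁾_i`; optionally also `S²_i`, `s²_d,i`, `D²_i`, `σ²_i`) are
  square-rooted so index-versus-trait relationships stay dimensionally
  linear; the square root is monotone, so genotype rankings are unchanged.
  A column containing negative values (possible only for Shukla's
  variance) is left raw and flagged rather than mixing transformed and
  untransformed values within one column.
* Degenerate inputs: `E < 2` (variance), `E < 3` (deviation MS), `G < 3`
  (Shukla), equal environment means (undefined slope) and constant
  genotypes (undefined R²) raise or warn per index; `compute_all` converts
  per-index failures into missing columns with warnings and continues.

## Sampling schemes

Three genotype-sampling schemes reflect how breeding populations are
assembled: `random` (simple random sample, approximately normal mean-yield
distribution), `even` (the pool is cut into mean-yield deciles computed on
the *full* pool with the inclusive linear-interpolation quantile
convention, and n/10 genotypes are drawn per decile; remainders go one
each to the lowest deciles and are logged) and `top20` (random among
genotypes whose pool mean is *strictly* above the 80th percentile —
elite-fraction selection). Environment samples are always simple random
draws. Everything is without replacement, and environment draws for
different grid sizes or replicates use independent substreams.

## Synthetic generator

The generator emulates the statistical structure of a large crop-model
experiment (thousands of virtual genotypes created by perturbing ~90
physiological parameters within ±20% of a reference cultivar, grown over
thousands of environments) with the smallest model that produces every
structure the downstream statistics consume:

    θ_ip ~ U(1−δ, 1+δ)                            (parameters, δ = 0.2)
    a_i  = Σ_p w_mean[p]·(θ_ip − 1)               (additive main effect)
    s_i  = Σ_p w_sens[p]·(θ_ip − 1)               (multiplicative sensitivity)
    q_j  ~ N(0, σ_q²)                             (environment quality)
    x_ij = (1 + s_i)·(μ + q_j) + a_i + ε_ij,      ε_ij ~ N(0, σ_ε²), clipped at 0

Defaults: P = 90 parameters, μ = 4.0 t ha⁻¹, σ_q = 1.5 t ha⁻¹ (broad
environment range, as in multi-site multi-season trials), σ_ε = 0.3 t ha⁻¹,
`w_mean` = 3.0 on parameters 1–3, `w_sens` = 0.5 on parameters 4–6, all
other parameters inert.

Design rationale:

* **Multiplicative sensitivity.** Sensitivity parameters scale the whole
  environmental response `(μ + q_j)`, the way radiation-use-efficiency-like
  parameters scale yield potential. This gives them a coherent loading on
  both the genotype mean (through `μ·s_i`) and the G×E interaction, which
  is what makes the tendency index discriminate: a purely additive
  sensitivity (`x = μ + a + (1+s)q` with centered q) leaves `s_i` with no
  first-order correlation to either mean yield or P_i, and T becomes a
  ratio of noise. The Finlay–Wilkinson slope is `(1+s_i)` up to the
  population normalization, so slope recovery tests compare `b_i` against
  the recorded `s_i`.
* **Weight calibration.** Loading magnitudes were set so the correlation
  between a loaded parameter and mean yield or √P_i lands in the 0.2–0.8
  band at the default sample sizes (measured ≈0.31–0.47) — strong enough
  to detect at N_gen = 100, weak enough that single SPGs disagree and the
  similarity analysis has something to measure.
* **Truncation at zero** is physical plausibility only; under defaults it
  touches well below 1% of cells.
* Secondary traits (straw yield, grain protein, grain number, grain size,
  LAI) are affine in the primary trait plus noise, with a negative
  protein–yield trade-off and positive straw/grain-number couplings; only
  the signs are contractual.
* Ground truth (`a_i`, `s_i`, `q_j`, loaded-parameter names) is recorded
  exactly as used, enabling recovery tests.

What the generator does *not* emulate: crop phenology, weather structure,
nitrogen dynamics, parameter interactions, or any nonlinearity of a real
crop model. Passing tests therefore demonstrate that the *statistical
machinery* behaves correctly on data with the assumed structure (linear
main effects, multiplicative G×E, Gaussian environment qualities), not
that a particular crop or dataset needs a particular number of
environments or genotypes. Quantities like the power-law intercept α or
the similarity constant k are dataset-specific; on synthetic data they are
checked structurally (exponent band, monotonicity, CI coverage), not
against published magnitudes. One published structural claim is knowingly
not reproduced: the slight increase of the SPE-mean of P_i with N_env.
Under this generator P_i averages i.i.d. per-environment terms, so its
expectation is exactly flat in N_env; the tests assert flatness plus
shrinking spread instead.

## Environment-requirement analysis

For a fixed SPG, `index_over_spe` recomputes an index over `n_spe`
independent SPE draws at each grid size; `cv_across_spe` summarizes the
draw-to-draw spread as CV = sd(ddof=1)/mean per genotype and grid point
(cells with nonpositive mean are flagged undefined). The CV–N_env relation
is fitted as `CV = α·N_env^β` by nonlinear least squares on the original
scale (a log–log OLS seeds the optimizer and is the flagged fallback),
because standard errors for α and β and an original-scale R² are the
quantities of interest. Sampling theory puts β near −1/2 (the CV of a
mean); the fitted exponent band [−0.6, −0.4] is the structural check. The
minimal environment number solves `α·N^β ≤ threshold` as
`ceil((α/threshold)^(−1/β))`, with a 1e−9 tolerance so exact integer
crossings are not rounded up; "at least N environments" dictates rounding
up otherwise. A cross-SPG aggregation variant (CV pooled over genotypes)
is exposed as an option.

## Network analysis

The per-SPG analysis table holds mean trait, √P_i and the parameter values
of the sampled genotypes. Pearson correlation is used throughout (not rank
correlation). The r-vector keeps the 2P+1 entries involving the trait or
P_i — with P = 90 that is 181 of the 4186 column pairs, dropping the 4005
parameter–parameter pairs — in a fixed documented order (trait~P_i first,
then trait~param, then P_i~param). The display threshold |r| > 0.33
(strict) only filters which edges are written to GraphML; no computation
is ever thresholded.

Similarity `S` is the mean of squared correlations over the *off-diagonal*
upper triangle of the edge-r-matrix: the diagonal self-correlations are
identically 1 and would inflate S by 1/n while carrying no similarity
information. `S = N_gen/(k + N_gen)` is fitted by least squares with a
closed-form median initialization (`k = N(1−S)/S`); observations at
different N_env are pooled, since similarity saturates in genotype number
and is flat in environment number. The genotype requirement solves
`N/(k+N) ≥ S_target` as `ceil(k·S/(1−S))`.

Tendency values with a near-zero denominator (|r(trait, param)| < 1e−6)
are reported infinite and flagged rather than dropped, since "explains
stability only" is a meaningful extreme.

## Problem sizes

The bundled experiments run at desk scale, chosen so each completes in
seconds to minutes on one core while keeping every estimate's sampling
error far below the margins being asserted: the environment-requirement
experiment uses 100 genotypes against a 2000-environment pool
(N_env ∈ {3, 10, 30, 100, 300}, 100 SPE), the similarity experiment a
2000-genotype × 600-environment pool (N_gen ∈ {5, 25, 100, 400},
N_env ∈ {50, 200}, 50 SPG), and the tendency experiment 100 SPGs of
100 × 100. Full-scale emulation (9100 × 9000, ~82 million cells) is
supported by the chunked dataset writer and the same CLI flags, but is a
storage/runtime exercise, not part of the routine suite.

## Known limitations

* The adjusted-CV algebra follows the limiting behaviors stated above;
  published variants differ in detail, and no attempt is made to match any
  specific software's output beyond the slope-2 identity.
* Shukla's variance is undefined for G < 3 and the safety-first index
  degenerates to a step function for zero-variance genotypes; both are
  surfaced as errors/warnings, not silently patched.
* The asymptotic similarity law is an empirical summary, not a derived
  result; k depends on the pool's correlation structure and noise level.
* No AMMI/GGE biplots, multivariate stability statistics, imputation, or
  partial-correlation/causal network inference.
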