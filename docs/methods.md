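# Methods

## The mixture model

The data are the frequencies `x₁,…,xₙ ∈ (0,1)` of somatic mutations from
one bulk tumour sample — VAFs, or CCFs divided by two so that a clonal
mutation in a pure diploid sample sits at 0.5. The likelihood is a
univariate finite mixture with one optional Pareto Type-I component at
fixed index 1 and `k ≥ 1` Beta components:

    f(D | θ, π) = Π_i [ π₁ g(x_i | x*, α) + Σ_{w=2}^{k+1} π_w h(x_i | a_{w−1}, b_{w−1}) ]

with `g(x) = α x*^α / x^{α+1}` for `x ≥ x*` (zero below) and `h` the
standard Beta density. The tail encodes the neutral within-clone site
frequency spectrum `M(f) ∝ 1/f` predicted for mutant alleles spreading in
an exponentially expanding population; the Betas encode clonal peaks.

Assumptions worth stating explicitly:

- Frequencies are exchangeable draws from one stationary mixture; linkage
  between mutations is ignored.
- The Pareto scale `x*` is fixed at the minimum retained frequency. The
  ML estimate of a Pareto scale is the sample minimum, and freezing it
  removes a degenerate direction from model selection; `x*` is therefore
  not counted among the free parameters.
- The Pareto density is the standard (untruncated) one even though the
  data live below 1. The mass it implies above 1 is ≈ `x*^α` (about 1%
  for `x* = 0.05, α = 1.5`). A consequence, quantified under
  *Limitations*: the ML tail shape is biased upward by roughly +0.1 to
  +0.2 in that regime.

## Fitting

The fit alternates an E-like responsibility step
`z_ic ∝ π_c f_c(x_i)` with component refits:

- mixing proportions: column means of `z` (the standard M-step);
- Beta components: weighted moment matching,
  `a = m(m(1−m)/v − 1)`, `b = (1−m)(m(1−m)/v − 1)` from the
  responsibility-weighted mean `m` and variance `v` (default), or the
  weighted Beta MLE via L-BFGS on log-shapes (`beta_estimator="mle"`),
  which makes the procedure an exact EM — the M-step keeps the previous
  parameters whenever the optimiser fails to improve the weighted
  likelihood, so the NLL trace is non-increasing by construction;
- Pareto shape: the closed-form weighted Hill MLE
  `α̂ = Σw / Σ w·log(x/x*)`, clamped to `[0.01, 100]` for numerical
  safety.

Convergence: relative NLL change below `epsilon = 1e-6`, capped at
`max_iter = 500`. Each candidate is restarted `restarts = 10` times from
random initialisations; the best final NLL wins. Initialisation draws
Beta means from data quantiles with N(0, 0.03) jitter, Beta variances at
a factor of the maximal variance `m(1−m)` that alternates between 0.05
and 0.25 across restarts, tail shape uniform in [0.5, 3], uniform
mixing proportions. The two variance factors matter: broad-only
initialisations (factor 0.25 alone) make the responsibilities of two
overlapping peaks nearly identical, and moment matching then collapses
them onto the global moments — a reproducible local optimum in which a
bimodal spectrum is fit as one wide Beta.

Degenerate components (vanishing weight, weighted variance reaching the
Bernoulli bound `m(1−m)` or numerically zero) abort the restart; a fit
fails only if every restart degenerates. Restart and candidate seeds are
derived from the master seed with `numpy.random.SeedSequence`, so results
are identical under any execution order and any `parallel` worker count.

Canonical form: Beta components are sorted by decreasing mean (clonal
cluster first), the tail is always component 0, and hard assignment is
the responsibility argmax with ties broken toward the lowest index.

## Model selection

Every `(k, tail)` candidate on the grid (`k_range = {1,2,3}`,
tail ∈ {on, off} under `tail_mode="auto"`) is scored with

    BIC   = 2·NLL + λ·log n,           λ = 2k + [tail] + (#components − 1)
    ICL   = BIC + H(z)
    reICL = BIC + H(ẑ)

using natural logarithms; `H(z) = −Σ z log z` over the whole matrix. For
`ẑ`, rows hard-assigned to the tail are dropped, the tail column is
removed, and the remaining rows are renormalised, so `H(ẑ) ≤ H(z)` and
reICL penalises only Beta–Beta overlap. reICL is the default criterion;
ranking minimises the chosen score with a deterministic tie-break
(smaller λ, then smaller k, then tail-free first). `k = 1` is reported as
monoclonal, `k > 1` as polyclonal.

The post-hoc cluster filter (off unless requested; defaults
`min_pi = 0.02`, `min_count = 10`) removes small Beta clusters, never the
tail, renormalises the weights and recomputes responsibilities; a full
refit of the surviving architecture is available behind a flag. Unseen
mutations can be assigned to a fitted model without refitting.

## Bootstrap

The non-parametric bootstrap resamples the n mutations with replacement;
the parametric bootstrap samples n fresh points from the fitted mixture
(Pareto draws inverse-CDF-truncated to below 1). Every resample is refit
with full model selection; the fraction of resamples electing each
`(k, tail)` signature is the model frequency. Parameter draws (tail
shape, Beta means/variances, mixing proportions) are pooled only from
resamples whose winning signature matches the input model, with
components matched by their mean-sorted canonical order; confidence
intervals are percentile intervals at the requested α-level. Resamples
that fail to fit are recorded and excluded; more than 20% failures is an
error.

For the non-parametric flavour the co-clustering matrix is computed:
entry (i, j) is the number of resamples in which i and j both appear and
share a hard cluster, divided by the total number of resamples (default)
or by their co-occurrence count (conditional variant). Under the default
normalisation each entry is bounded by the pair's empirical co-sampling
frequency — asserted exactly in the tests. Per-resample seeds derive from
the master seed and the resample index.

## Evolutionary estimators and the shared time/rate convention

- Mutation rate: `μ̂ = N_tail(f_min, f_max) / (1/f_min − 1/f_max)`, where
  `N_tail` counts tail-assigned mutations with frequency in the window.
  This inverts the neutral prediction `M(f) = μ(1/f − 1/f_max)`. Default
  window: `f_min` = max(dataset cutoff, 5th percentile of tail points),
  `f_max` = 95th percentile — the extremes are dominated by detection
  censoring below and by the Beta shoulders above. Units: mutations per
  effective tumour doubling.
- Subclone age: `t̂ = N_sub / μ̂` with `N_sub` the count of mutations
  hard-assigned to the subclonal Beta (every Beta except the
  highest-mean, clonal one). The subclone's founder lineage accumulated
  its private mutations at rate μ̂ per doubling, so the count is a clock.
- Selection coefficient: with subclone cell fraction `x = 2·(subclonal
  Beta mean)` (diploid-heterozygous; the same doubling restores the CCF
  for halved-CCF input) and sampling time `T` in doublings (supplied, or
  `N_clonal/μ̂`), exponential outgrowth gives `x/(1−x) = 2^{(ŝ−1)(T−t̂)}`,
  i.e. `ŝ = 1 + log₂(x/(1−x))/(T − t̂)`, ancestor baseline 1. `ŝ` is
  undefined (reported as None, or an error in strict mode) when the
  subclone fraction reaches 1 or `T ≤ t̂`.

One convention ties the estimators to the simulator: a simulator
generation is one effective population doubling, and rates are per
effective doubling. The simulator's `mu_sim` is a per-daughter,
per-division Poisson mean; a surviving lineage (size-biased over the
population) divides with probability `2b(1−d)/m` per generation
(`m = (1−d)(1+b)` the growth factor), so the per-doubling rate that both
μ̂ and `N_sub/driver_time` measure is

    effective_mutation_rate = mu_sim · 2b(1−d) / m

exposed as `SimulationConfig.effective_mutation_rate` (13.3 at the
defaults). Recovery is assessed against this quantity; comparing the
window estimator to the raw per-division rate only makes sense in the
special case `b = 1, d = 0` where one generation is one exact doubling.
These conventions are internally consistent and verified end-to-end, but
may differ from other tools' definitions by constant factors.

## The simulator

Discrete, non-overlapping generations from one founder cell carrying
`n_clonal` truncal mutations. Per generation each cell dies with
probability `death_prob`, and each survivor divides with probability
`birth_prob`; both daughters inherit the parent's mutations and each
gains Poisson(`mu_sim`) new unique mutations (infinite sites). Genealogy
is tracked in blocks — one block per daughter holding its new mutations —
so all mutations in a block are perfectly linked and share one carrier
count, computed at sampling by accumulating live-cell counts up the block
tree.

Conditioning on establishment: while a clone is smaller than
`establishment_size = 32` cells its cells neither die nor skip division.
A near-critical Galton–Watson process started from one cell has a
final-size limit W with coefficient of variation near 1, dominated by the
first few generations; real tumour datasets are implicitly conditioned on
the tumour (and any observed subclone) having established. Forcing the
first five doublings removes that founder-effect variance (final
population CV ≈ 0.1) while leaving untouched the per-mutation subtree
noise that produces a continuous power-law tail. The cost is that the
first five generations contribute dyadic (power-of-two) carrier counts;
sequencing noise smears them.

Driver: at `driver_time` one uniformly chosen live cell founds the driver
lineage. Driver cells face the per-generation death once and then pass
through `fitness_multiplier` division rounds per generation (the
fractional part as one per-cell partial round) — a division-*rate*
advantage, the discrete analogue of a birth-rate ratio in continuous-time
branching. A division-probability multiplier capped at one cannot make a
clone founded four doublings before sampling detectable (it could reach
at most 2⁴ cells against ~10⁴), whereas a rate multiplier reproduces the
canonical late subclonal sweep. Runs in which the population or the
driver lineage goes extinct are re-drawn from derived seeds (the study
design conditions on an established, driver-bearing tumour).

Sequencing: true VAF = purity·carriers/(2·cells) (diploid heterozygous),
depth ~ Poisson(`coverage_rate`), variant reads ~ Binomial(depth, true
VAF), observed VAF strictly above `vaf_cutoff` retained. Mutations with
true VAF below `vaf_cutoff/5` are not expanded individually (their
probability of passing the cutoff at 120× is negligible); the floor is
configurable and 0 expands everything.

Default study conditions (chosen once to mirror the canonical walkthrough
of a sweeping subclone, and then used by tests and the acceptance
script): `birth_prob 0.5`, `death_prob 0.1`, `mu_sim 20`, `n_clonal 500`,
`driver_time 13`, `sampling_time 17`, `fitness_multiplier 3.8`,
`coverage_rate 120`, `purity 1`, `vaf_cutoff 0.05`. They produce ~2–4k
cells, ~950 observed mutations, a subclone at cell fraction ≈ 0.6 (VAF
≈ 0.3), a clonal peak at 0.5 and a visible tail — an architecture in
which default model selection returns `K2+tail` in ≈ 9–10 of 10 seeds and
a no-driver control returns `K1+tail` in ≈ 8–9 of 10.

What the generator does *not* emulate: copy-number changes and non-diploid
states, impure samples' subclonal-CNA interactions, sequencing error
substitutions (pure sampling noise only), multi-region sampling, and
mutation linkage beyond shared genealogy blocks. Passing tests therefore
demonstrate correct recovery of the model's own generative assumptions at
desk scale, not robustness to the full messiness of real tumour data.

## Numerical choices

- Log-space densities with `logsumexp`; a point with zero total mixture
  density raises an error naming the point (only possible for tail-only
  models with data below the scale).
- Pareto shape clamped to `[0.01, 100]`; Beta moment matching rejects
  numerically-zero variance (`v ≤ 1e-10·m(1−m)`).
- Responsibility rows and mixing proportions are simplex-normalised to
  1e-8 by construction; ties in hard assignment break toward the tail.
- All seeds below 2³¹, derived via `SeedSequence`; parallelism never
  changes results.

## Limitations

- Tail-shape truncation bias: with `x* = 0.05` and α ≈ 1.5 the mixture's
  ML tail shape overshoots the generative value by ≈ +0.2 (+0.08 from
  fitting the untruncated density to draws confined below 1, the rest
  from the optimum re-allocating the unplaceable above-1 mass). An
  oracle-start EM converges to the same optimum, so this is a property of
  the likelihood, not the optimiser. Weights and Beta means are
  unaffected (recovered to ±0.03 / ±0.005 at n = 5000).
- μ̂ window physics: at 120× coverage the observable tail window (VAF
  0.05–0.2) probes mutations that arose when their clone had ~2–10
  cells, where the `1/f` law is only approximate; μ̂ carries a modest
  (≈ +10%) bias relative to the effective per-doubling rate, and t̂
  inherits it with the opposite sign.
- reICL penalises Beta–Beta overlap only, so a small spurious Beta placed
  on a clump of tail mutations is cheap; in ~1–2 of 10 neutral
  simulations selection returns a second Beta inside the tail region. The
  post-hoc cluster filter removes most such clusters.
- The selection-coefficient formula assumes a single subclone in
  exponential outgrowth against the ancestor; with `k > 2` each subclone
  is dated and scored independently, ignoring nesting.
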