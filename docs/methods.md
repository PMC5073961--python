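# Methods

`dtmtox` models time-series toxicogenomics experiments — compounds profiled
against matched controls at several ordered time points — as a time-sliced
document collection and fits a dynamic topic model (DTM) whose topics are
interpreted as biological processes whose gene content can drift over time.
This note records the model, the inference scheme, the defaults and the
design choices, and what the synthetic benchmarks do and do not demonstrate.

## From expression matrix to corpus

For every compound `c` and time point `t` with both dose groups present,
replicates are averaged in log2 space and the contrast
`d_g = mean(log2 treated) − mean(log2 control)` is computed per gene.  The
fold change is direction-normalized and linear, `FC_g = 2^|d_g|` (≥ 1), with
direction `up` iff `d_g ≥ 0`; a zero difference is deterministically `up`.
Genes with `|d_g| ≥ θ` are the differentially expressed genes (DEGs) of the
condition; the default cutoff is θ = 1 (two-fold), exposed as
`deg_threshold`.  An optional replicate-level test gate is deliberately not
part of v1: with the small replicate numbers typical of these designs a
plain fold-change cutoff is transparent and reproducible.

Each condition becomes one document.  Its words are the DEGs split by
direction (`Acot1_up`, `Stac3_down`), so the vocabulary has exactly two
words per gene in the universe.  Word counts encode effect size:
`count = round(100 × FC)` (half away from zero), floored at 1.  Reading the
×100 rule on the direction-normalized linear fold change weights induction
and repression symmetrically; using raw treated/control ratios would give
down-regulated genes counts below 100 and systematically underweight
repression.  Counts are uncapped by default (`count_cap` available).
Compounds missing any time point are dropped entirely (keeps slices
compound-balanced); `keep_partial=True` retains them.

## The model

With K topics, W words and T slices:

* each topic k is a chain of natural parameters
  `β_{1,k} ~ N(0, σ₀² I)`, `β_{t,k} | β_{t−1,k} ~ N(β_{t−1,k}, σ² I)`,
  mapped to word distributions by `π_{t,k} = softmax(β_{t,k})`;
* each document d in slice t draws topic proportions
  `θ_d ~ Dirichlet(α 1_K)` and tokens from the mixture `Σ_k θ_{dk} π_{t,k}`.

The Dirichlet document prior (rather than a logistic-normal one) matches the
widely used reference implementation of the model and keeps the per-document
E step the standard LDA fixed point.  Defaults: K = 20, α = 0.01
(sparse document mixtures), σ² = 0.005 (`chain_variance`; smaller values
force more similar word distributions across consecutive time points).

## Variational inference

Inference is coordinate ascent on a single evidence lower bound (ELBO).

**E step.**  Per document, the standard mean-field pair (γ_d, φ_d):
`φ_{nk} ∝ exp(ψ(γ_k)) exp(E[log π_{t,k,w_n}])`,
`γ_k = α + Σ_n c_n φ_{nk}`, iterated until mean |Δγ| < `doc_tol` (1e-3) or
`doc_max_iter` (100).  γ is warm-started from the previous EM sweep, which
makes every sweep a pair of exact coordinate maximizations and hence keeps
the bound non-decreasing.  Documents with no DEGs contribute a prior
posterior and zero bound.

**Topic chains.**  The variational family treats per-slice vectors `β̂_t`
with fixed variance ν̂ (`obs_variance`) as pseudo-observations of the chain;
the chain posterior q(β) is then the exact Gaussian posterior of that
linear-Gaussian model, computed by a forward filter / backward (RTS)
smoother.  Because ν̂ is shared across words, the smoothed variances Ṽ_t
depend only on the slice.  The intractable `E[log Σ_w exp β_w]` is bounded
by `log ζ_t` with `ζ_t = Σ_w exp(m̃_{tw} + Ṽ_t/2)` (the expected-exp bound,
tight at the optimum of ζ), giving
`E[log π_{t,k,w}] ≥ m̃_{t,k,w} − log ζ_{t,k}`.

**M step.**  Per topic, the bound terms that depend on β̂ are

    F(β̂) = Σ_t [ n_t·m̃_t − N_t log ζ_t ] − KL(q ‖ p),

with `n_{tw} = Σ_d c_{dw} φ_{dwk}` the expected counts and `m̃ = S β̂` a
fixed linear map (the smoother matrix).  Since both q and the chain prior p
factor over words into T-dimensional Gaussians with shared covariance
structure, KL(q‖p) is computed exactly from T×T matrices plus a per-word
quadratic form.  F is concave in β̂; it is ascended with L-BFGS (analytic
gradient, `m_step_iter` = 15 inner iterations), and an update is accepted
only if F did not decrease.  Both steps therefore monotonically increase the
same ELBO; the recorded `elbo_trace_` is checked for monotonicity in the
test suite on fuzzed corpora.

**Initialization.**  A pooled (time-blind) static LDA — the same E step with
point-estimate topics and a closed-form M step — is fitted for
`init_lda_iter` (20) sweeps; every slice of chain k starts at the centered
log of static topic k.  The static topics are seeded from documents chosen
greedily to be maximally dissimilar (k-means++ style): DEG-list documents
are often near-pure mixtures, and document seeding reaches the dominant
ELBO basin far more reliably than random topics.  `n_init` independent
restarts can be requested, keeping the run with the highest final ELBO.
A single integer `random_state` makes the whole fit reproducible
bit-for-bit; sweep orders are fixed.

### Numerical choices and defaults

* `init_variance` σ₀² defaults to `1000 σ²`: a wide, near-uninformative
  first-slice prior, following the reference implementation's convention.
  A tight first-slice prior (order σ²) shrinks slice-1 topics almost to
  uniform and visibly degrades both fitting and recovery.
* `obs_variance` ν̂ defaults to 0.005 and is fixed, not optimized.  The
  pseudo-observations summarize per-slice expected counts that are large for
  fold-change-scaled corpora (a single two-fold DEG already contributes ~200
  tokens), so the posterior over chains should be confident; a large ν̂
  (e.g. 0.5) leaves Ṽ/2 ≈ 0.23 nats per token of slack in the bound and
  blurs the correspondence with a static LDA at T = 1.  Cross-time smoothing
  is carried by the explicit chain prior in F, not by ν̂.
* All probability math is in log space with log-sum-exp; probabilities are
  floored at `eps` = 1e-12 before any log.
* Convergence: relative ELBO change < `em_rel_tol` (1e-4) or `em_max_iter`
  (50); non-convergence returns the fit with `converged_ = False` and a
  warning.
* Ties: argmax topic assignment and equal-probability gene ranks break
  toward the lower index; zero expression difference breaks toward `up`.

### The single-slice reduction

At T = 1 the model is a static LDA with a Gaussian prior over log topic
weights.  The two fits are compared on their document-side (data-likelihood)
bounds, since the dynamic ELBO additionally carries the chain KL term that
has no static counterpart (`doc_bound_` and `chain_kl_` are exposed
separately).  Because an unsmoothed static LDA's closed-form M step can park
it in coordinate-ascent fixed points with hard-zero tails that the
regularized chain update escapes, the reduction is checked in the stable
direction: a static LDA initialized at the dynamic fit's topics converges to
a bound within 0.1 % of the dynamic model's document-side bound.

## Interpretation

Documents are assigned to their argmax topic of P(T|D).  Genes are ranked
per topic per slice by P(W|T)_t (descending, ties by word id);
`top_n` defaults to 300.  *Representative* genes of a topic are those ranked
within the top n at **every** slice (the strict reading of "within 300 at
all time points"; the permissive any-slice variant is what
`topic_membership_counts` uses by default, with a `per_slice` option).
Enrichment strips `_up`/`_down` tags, collapses duplicates, and tests each
gene set one-sided (over-representation) against the corpus gene universe
with the hypergeometric tail `P(X ≥ a)`; Benjamini–Hochberg correction is
applied across the sets of one (topic, slice) query.  The universe defaults
to the corpus's gene universe because gene-set collections are gene-keyed
and direction-blind.

## Synthetic data: what it shows and what it does not

`generate_dtm_corpus` samples exactly from the generative process above, so
it tests inference against a correctly specified model.  Defaults
(K = 3, W = 200, T = 4, 120 docs/slice, ~150 tokens/doc negative-binomially
dispersed, α = 0.05, σ² = 0.005, σ₀² = 1.0) give well-separated topics with
realistic document-length variation.

`generate_expression_study` emulates a two-dose repeated-treatment design:
per-gene baselines `N(8, 1.5²)` log2 units, i.i.d. `N(0, noise_sd²)` noise
(default 0.4), and disjoint per-group gene modules whose log2 effect is
modulated over slices by a time profile (sustained, transient, delayed,
progressive, early, late).  The default end-to-end benchmark plants four
groups of six compounds with 40-gene modules at 2.0 log2 effect.  Its
profiles are chosen with multipliers ≥ 0.6 so that every condition keeps its
module above the two-fold DEG cutoff: profiles that hit zero (transient,
delayed) produce conditions with no true signal at all, which no clustering
method could label and which would only measure the noise floor.  Those
profiles remain available for studying partially-informative designs.

Neither generator simulates probe-level artifacts, batch effects,
correlated noise between genes, dose-response beyond two groups, or
overlapping modules (unless configured).  Passing the recovery benchmarks
therefore shows the inference machinery is correct and the pipeline wiring
is sound — not that real TG-GATEs-scale data will cluster as cleanly.
The recovery thresholds used in the tests (matched mean cosine ≥ 0.9,
adjusted Rand ≥ 0.8) are harness constants for well-separated simulations,
not empirical claims.

## Problem sizes

The shipped benchmarks use K ≤ 4, W ≤ 4000, T = 4 and ≤ 500 documents,
sizes at which a full fit takes seconds to a few minutes on one core.  The
implementation is vectorized over words and documents and handles the
full-scale corpus (24,176 words, ~500 documents, K = 20) in memory without
any changes; only the benchmarks are kept small.

## Known limitations

* ν̂ and the hyperparameters (α, σ²) are fixed, not learned; no held-out
  perplexity machinery is included.
* The logistic-normal document prior variant and wavelet-regression
  inference alternative are not implemented.
* The ELBO is a bound family, not the marginal likelihood; comparisons
  across different ν̂ values are not meaningful.
* Enrichment assumes the query and universe use the same gene identifiers;
  no identifier mapping or GO-graph propagation is performed.
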