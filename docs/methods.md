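# Methods

## Model and assumptions

`pathflow` models drug response as the change in pathway activity caused
by treatment. Three assumptions carry the whole construction:

1. **Additive, independent gene contributions.** An alteration of driver
   gene *j* adds a fixed amount to pathway activity — A_m[j] for a
   mutation, A_v[j] for a copy-number change — independent of other
   genes. Copy-number gain and loss collapse to a single 0/1 indicator
   because the model has one copy-number coefficient per gene; different
   mutation types of one gene are likewise not distinguished.
2. **Multiplicative drug attenuation.** Drug *d* removes the fraction
   rho[j,d] * alpha[d] of gene *j*'s activity term: rho[j,d] is how much
   of the gene's activity flows through the drug's targets, alpha[d] how
   strongly the drug inhibits what it reaches. Two drugs applied together
   act independently, so their attenuations multiply.
3. **Linear link.** The pre/post-treatment activity difference satisfies
   dA = k*sens + b[d], with sensitivity on whatever scale the input
   provides (IC50-relative in the motivating data; no internal log
   transform). k is a fixed global scale, default 1, exposed for
   completeness but never fitted — the solved objective absorbs it.

A gene appearing in several pathways contributes **once**: pathway
membership is metadata, not multiplicity; per-pathway multiplicity would
silently rescale coefficients.

## Parameters

| parameter | per | bounds | meaning |
|---|---|---|---|
| A_m, A_v | gene | [-5, 5] | activity added by mutation / CNV (sensitivity units via the link) |
| rho | gene x drug | [0, 1] | fraction of the gene's activity the drug can reach |
| alpha | drug | [0, 1] | fractional inhibition at the drug's targets |
| b | drug | [-20, 20] | intercept of the linear link |
| k | global | fixed, 1 | link scale |

The alpha bound is a modelling choice: a "percent off" inhibition is
naturally a fraction, and no other bound is defensible. The per-fit error
is reported as RMSE = sqrt(SSE / N) over the N observed (line, drug)
pairs — at the 13-gene, 10-drug scale the model has
2*13 + 13*10 + 10 = 166 free parameters.

## Fitting

The objective — squared residuals dA(s,d) - sens(s,d) - b(d) summed over
observed pairs only (a line contributes exactly its screened drugs) — is
a smooth non-convex quartic, minimized with L-BFGS-B under the box
constraints, using analytic gradients (verified against central
differences in the tests). Multi-start with `n_restarts = 10` by default;
restart r seeds `numpy.random.default_rng(seed + r)` and draws
A ~ U(-1,1), alpha ~ U(0,1), rho uniform in [0,1] (or the topology prior,
or 1/2), while b[d] starts at its unconditional optimum
-mean(observed sens of d) clipped to bounds, which removes a large
nuisance mode. Convergence uses scipy's ftol = 1e-12, gtol = 1e-10,
maxiter = 5000; the lowest-SSE restart is returned with all restart SSEs
logged. A restart that raises or returns a non-finite objective is
dropped with a warning; if every restart fails the fit errors out with
diagnostics.

### Identifiability and canonical products

The objective sees theta only through A_m[j]*(1 - rho[j,d]alpha[d]),
A_v[j]*(1 - rho[j,d]alpha[d]) and b[d]. Hence (i) rho and alpha are
constrained only through their product, and (ii) each gene has a scale
freedom t_j > 0: A -> t*A with (1 - rho*alpha) -> (1 - rho*alpha)/t
leaves every residual unchanged while the bounds permit. Reported raw
parameters are therefore one point on an optimum manifold.
`canonical_products` maps any such point to the unique representative
whose least-influenced drug per gene has product exactly 0 — the natural
convention when each gene has at least one drug whose targets it cannot
reach, which is how the synthetic truth is drawn. Parameter-recovery
claims are made on canonicalized products (and on per-gene totals where
mutation and CNV columns are collinear), never on raw rho or alpha.

## Topology prior

The influence coefficient has a structural reading: inject unit activity
at the altered gene and let it flow along directed pathway edges,
dividing equally over out-edges at every branch; a drug target absorbs
everything that enters it (complete blockade — partial inhibition is
alpha's job); a node without out-edges is a terminal. The absorbed
fraction is the prior for rho. On a DAG absorbed + terminal flux equals 1
to 1e-9. Real pathway graphs have cycles and the flow narrative gives no
rule for them, so propagation iterates until the circulating residual is
below 1e-9 (or 10,000 sweeps) and the trapped remainder is truncated and
reported. The prior is only an optional initializer: the fitted model
keeps rho free. This quantitative rule is one formalization of a
qualitative idea ("close to 1 when the target lies on the only route
downstream") and is documented as such.

## Evaluation

- **Cross-validation** is per drug over observed pairs: each drug's pairs
  are shuffled (seeded) and dealt round-robin into k = 10 folds (sizes
  differ by <= 1). Each fold's model is refit jointly on all drugs'
  training pairs — held-out cells are removed from the observation mask
  and set to NaN, so leakage is structurally impossible (and asserted by
  instrumentation in the tests). One Pearson r per drug is computed over
  the pooled out-of-fold predictions; per-fold r at ~40 test points is
  too unstable to average. r is reported missing for constant predictions
  or fewer than 3 test pairs. No stratification (by tissue or response)
  is applied. Note a small estimator artifact: with no signal at all, the
  fold-wise constant prediction -b_fit equals the training mean, which is
  anticorrelated with the held-out fold mean, biasing pooled |r| to about
  1/sqrt(fold size) (~0.16 at 400 pairs, k=10) rather than 0.
- **Association screen**: per (gene, drug), the drug's screened lines are
  split by the gene's mutation status and compared with the two-sided
  Wilcoxon rank-sum test — exact enumeration when the smaller group has
  <= 10 observations and the pooled sample is tie-free, otherwise the
  normal approximation with tie and continuity corrections. Cells where
  the gene has no mutant among the screened lines are missing. Raw
  p-values are primary (log10 alongside for heatmaps); a
  Benjamini-Hochberg column is emitted for convenience but drives no
  decision.
- A paired t-test over two drugs' per-gene influence products is provided
  as a convenience contrast for same-target inhibitors.

## Synthetic data

The generator emulates a single-pathway pharmacogenomic screen:
13 genes, 10 drugs, 450 cell lines, Bernoulli alterations (mutation rate
0.08, CNV rate 0.05), 15% of (line, drug) cells unscreened at random, and
sensitivities drawn from the model itself plus Gaussian noise with sd
1.7753 — chosen to match the residual scale of the real MAPK-pathway fit
so synthetic difficulty mirrors the real problem. Ground-truth
parameters respect the fitting bounds: |A| ~ U(0.5, 3) with random sign,
alpha ~ U(0.3, 1), b ~ U(-3, 3), and rho sparse (zero with probability
0.35, else U(0.2, 1)) with at least one zero-influence drug per gene,
which pins the per-gene scale (see identifiability above).

What the generator does **not** emulate — and hence what passing tests do
not demonstrate about real screens: co-occurrence structure of
alterations (e.g. BRAF/RAS mutual exclusivity; an optional
`exclusive_pairs` flag exists for stress-testing collinearity),
drug-specific missingness mechanisms, tissue covariates, measurement
error in the binarized alteration calls, and any violation of the
linear-link or independence assumptions. Recovery and calibration
results on synthetic data certify the estimator, not the biology.

## Problem sizes and runtimes

Tests and the acceptance script run at the study scale (13 genes, 10
drugs, ~3,800-3,900 observed pairs after missingness): one 10-restart fit
takes well under a second, a 10-fold CV with 2-3 restarts per fold a few
seconds, and the 200-replicate null calibration of the association screen
(~26,000 p-values) about half a minute. Whole-suite runtime is under a
minute on one CPU.

## Degenerate inputs and tie-breaks

- A drug with zero observed sensitivities is rejected before fitting.
- An all-zero alteration profile is fittable: dA = 0 and the optimal
  intercepts are the negated per-drug means (tested against that closed
  form).
- Combination ranking reports each unordered pair once (drug1 < drug2
  lexicographically), sorted ascending by effect; equal effects break
  lexicographically. Self-pairs are computable but excluded by default.
  The pair score is the activity reduction itself, with no intercept
  added — the pairwise formula contains none.
- Duplicate edges in pathway lists are collapsed; self-loops dropped with
  a warning; genes absent from the graph get prior 0 with a warning.

## Known limitations

Beyond the generator's idealizations: the model treats all mutation
types of a gene identically, ignores expression and epigenetic state,
assumes drug independence in combinations (no synergy or antagonism),
and fits one pathway at a time — the joint multi-pathway, full-panel
problem is within the machinery's reach but non-convexity makes global
optimization at that scale unreliable, which is why defaults and tests
target the single-pathway scale.
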