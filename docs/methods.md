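# Methods

## The model

Each wing-pattern character is a binary trait (1 = the leaf-mimic-like
condition of a nymphalid-ground-plan element, 0 = anything else) evolving
along a rooted, branch-length phylogeny under a continuous-time Markov chain.
For a single character the generator has a gain rate (0 → 1) and a loss rate
(1 → 0).  For a pair of characters the joint process lives on the four
states (0,0), (0,1), (1,0), (1,1) — first-character-major order — with
simultaneous changes of both characters forbidden, leaving eight transition
rates q12, q13, q21, q24, q31, q34, q42, q43 (1-based state indices).  The
*dependent* model frees all eight; the *independent* model imposes
q12 = q34, q13 = q24, q21 = q43, q31 = q42 so each character's gain and loss
ignore the other's background, leaving four free rates.  Likelihoods are
computed by the standard postorder pruning recursion with per-node rescaling;
a polymorphic/ambiguous tip contributes a partial likelihood of one for each
allowed state.  The root prior is uniform over states by default and
configurable (the model's stationary distribution, or any fixed vector).
Phylogenetic uncertainty enters by treating the tree index into a posterior
tree sample as a latent variable of the MCMC.

## Reversible-jump MCMC over rate models

The sampler explores not just rate values but *rate models*: each named rate
is either in the zero bin (the transition is impossible) or assigned to one
of a set of rate classes, with one positive value per class.  The prior is
uniform over models (choice of zero subset × set partition of the remaining
rates) with class values i.i.d. from the rate prior.  Moves:

* **value update** — sliding-window perturbation of one class value; the
  window width ("ratedev") is tuned multiplicatively during burn-in toward a
  30% acceptance rate and frozen afterwards;
* **split/merge** — uniform-allocation split of a class (the new class draws
  a fresh value from the prior) and its reverse merge of an ordered class
  pair, with the usual Hastings corrections;
* **zero-bin hop** — a rate moves between the zero bin and either an
  existing class or a fresh singleton.  An earlier draft restricted this
  move to singleton classes; that kernel mixed the zero-bin indicator far
  too slowly for Z-scores to be usable, so the general hop (with its
  1/(k+1) destination correction) replaced it.  Both kernels were validated
  against exhaustive enumeration of the 21,147-model space for eight rates
  (prior-only sampling; chi-square on rate-class counts);
* **tree move** — uniform proposal of a new tree index;
* **hyperparameter move** — under the gamma hyperprior (below), Metropolis
  updates of the gamma mean and shape.

Rate priors: uniform on (0, 100) by default, or a hierarchical gamma whose
shape and mean are themselves uniform on (0, 10) and resampled within the
chain.  Chains report the realized rate vector, zero-bin flags, class count,
log-likelihood and tree index at each thinned iteration, written as TSV
traces readable by generic trace viewers.

Two priors, two jobs.  The flat (0, 100) prior is deliberately vague; on
weakly informative data (one binary character on one tree) it leaves
substantial posterior mass in a high-rate saturation regime where tip data
carry no information about rate magnitude, and chains visiting that regime
produce harmonic-mean estimates dominated by downward likelihood excursions.
The gamma hyperprior regularizes both problems.  In this package the gamma
hyperprior is therefore the prior of choice wherever rate *values* or
marginal likelihoods matter (rate recovery, Bayes factors), while the flat
prior is the prior of choice for *Z-scores*, where the contrast "exactly
zero vs any positive value" should not be diluted by a prior density that
itself spikes at zero (a gamma with shape < 1 does; under it the zero bin of
a true structural zero saturates near 30–45% rather than approaching 100%).
The pipeline exposes the prior per stage; its defaults (uniform for
reconstruction and the dependence scan, gamma for contingency
classification) follow the published analysis and can be overridden.

## Marginal likelihoods and the dependence test

The log marginal likelihood of a model is estimated by the harmonic mean of
the sampled likelihoods, computed in log space.  The estimator is noisy, so
every analysis runs at least three independent chains; a model's estimate is
the median across runs, the spread is reported, and spreads above 2 log
units raise a warning.  A character pair's evidence is

    log-BF = 2 (lnHM_dependent − lnHM_independent)

and values strictly greater than 2 count as evidence for dependent
evolution.  Both models of a pair always share the same trees, prior and
chain settings.  No multiple-comparison correction is applied across the 55
pairs of an 11-character matrix — that is the published rule — and the raw
log-BFs are reported so a user can apply one; with 55 tests at the measured
~15–20% desk-scale false-positive rate, several flagged pairs are expected
under a global null.

## Ancestral states

States at a clade of interest are reconstructed by the MRCA approach: in
each posterior draw (rate model + tree index), the most recent common
ancestor of the clade's taxa is located in that draw's tree — the minimal
containing node, possibly subtending extra taxa, when the exact clade is
absent — the marginal state probabilities at that node are computed by an
outside–inside pass conditional on the draw, and the estimate averages the
per-draw probabilities (never the probabilities of averaged rates).  The
fraction of draws in which the exact clade existed is reported as coverage.
Labels follow the published confidence tiers: winning-state posterior
probability ≥ 0.95 "strong", ≥ 0.85 "moderate" (the asterisk class),
otherwise "unresolved"; both comparisons inclusive.

## Z-scores and the contingency network

A rate's Z-score is the percentage of dependent-model posterior samples in
which it occupies the zero bin — a measure of evolutionary restriction.
Contingency between two characters' gains is read from the critical pairs
(q12 vs q34) and (q13 vs q24): a gain restricted (Z > 70) on the partner's
ancestral background but unrestricted on its derived background gives a
directed *temporal* edge (the unlocking character precedes); symmetric
restriction of both gains on both empty backgrounds gives an undirected
*mutual* edge; anything else stays "dependent-unclassified".  Loss-rate
restrictions are computed and reported but generate no edges: the events of
the network are the 0 → 1 changes.  Edge tiers are weak ≥ 70, moderate
≥ 90, strong ≥ 95 (inclusive), drawn in DOT output as pen widths, with
mutual edges dotted and arrowless, and nodes ranked by longest-path depth so
earlier changes sit at the top.  Cycles are never silently broken; strongly
connected components of size > 1 are listed in the network object and its
JSON export.  Z-scores in the validation studies are pooled over ≥ 3
independent chains, because single desk-scale chains are sticky across the
posterior's modes (e.g. occasional role-swapped background histories).

## Synthetic data

The generators emulate the shape of the real study — by default 47 taxa,
11 characters, and a posterior-like sample of trees — without simulating
sequences or tree inference:

* **Trees**: pure-birth (Yule) trees, birth rate 1.0, so a 47-taxon tree has
  expected root-to-tip depth ≈ 3.9 and a 200-taxon tree ≈ 4.9 (the analysis
  is conditional on trees, so topological realism is secondary).  Posterior
  spread is emulated by lognormal branch-length jitter (mean-corrected,
  σ = 0.1) and single NNI moves on 10% of the sample.
* **Characters**: exact stochastic simulation down each branch by
  exponential waiting times, with a full event log.  Baseline independent
  characters use gain = loss = 0.3, giving a handful of changes per tree.
* **Planted dependence**: pairs share a dependent generator with q12 = 0 —
  the second character cannot be gained until the first is present — and a
  fast q34 = 2.0.
* **Planted order**: a chain of contingent gains, each character's gain rate
  a structural zero until its predecessor is in state 1, implemented by
  simulating each character against its predecessor's recorded piecewise
  history (so contingency holds exactly, not just in distribution).  Chain
  rates: the first character gains at 0.4 and is nearly persistent
  (loss 0.05), later characters gain fast (2.5) once unlocked.  Slow
  background losses matter: if a background character is often lost while
  its dependent character persists, the resulting states mimic direct gains
  of the dependent character on the empty background and genuinely support
  q12 > 0 — the planted zero then cannot be recovered by any sampler,
  because the data no longer carry it.

What the generator does not emulate: real morphological correlation
structure, model misspecification (characters truly evolving under
non-Markovian or hidden-rate processes), informative taxon sampling, or
posterior tree samples from actual sequence data.  Passing validation
therefore demonstrates internal correctness and statistical power under the
assumed model, not robustness to its violation.

## Validation studies and problem sizes

The studies in `kallima.validation` (shared by the test suite and
`scripts/acceptance.py`) use these frozen sizes, chosen to keep the full
suite in the tens of minutes on one core:

1. structure: pair enumeration on an 11-character fixture; free-rate counts
   recomputed from generators built with distinct inputs;
2. likelihood: 50 random 4–6-leaf instances per state count against
   brute-force enumeration (tolerance 1e-9); independence factorization on a
   47-taxon simulated pair;
3. prior recovery: 10,000 prior-only samples (thinning 30) against the exact
   model-space enumeration; chi-square with small-expectation bins pooled;
4. rate recovery: 20 replicates, 200-taxon trees, true rates 1.0/0.5, gamma
   hyperprior, 12k-iteration chains; joint coverage of both central 95%
   intervals.  The measured operating point of this design over 100
   replicates is ≈ 89% joint coverage, so a 20-replicate draw sits near the
   90% requirement by construction;
5. dependence: 10 dependent and 12 matched-independent replicates, 200-taxon
   trees, gamma hyperprior, 3 runs per model (12k/18k-iteration chains);
6. contingency: 10 planted-zero pair replicates (200 taxa) and 10
   planted-order chain replicates (100 taxa), flat prior, Z pooled over 3
   runs;
7. ancestral oracle: degenerate (fixed-rate, single-tree) reconstruction
   against the clamped-node Bayes-rule computation via brute-force
   enumeration; label tiers at their boundaries.

## Numerical choices

* 4×4 transition probabilities by eigendecomposition, validated per call by
  reconstructing the generator (tolerance 1e-9, relative); a
  scaling-and-squaring `expm` fallback covers defective or ill-conditioned
  cases.  2-state probabilities use the closed form.
* Pruning partial likelihoods are rescaled at every internal node; the inner
  loop is JIT-compiled with numba when available, with a pure-Python
  fallback of the same code path.
* Harmonic means via log-sum-exp; medians across runs for Bayes factors.
* Tie-breaks: `classify_state` awards the winning state to state 1 on an
  exact 0.5/0.5 split (irrelevant in practice; documented for determinism).
  `find_mrca` returns the unique deepest node containing the clade.
* Degenerate inputs: single-leaf trees are accepted; zero-length branches
  give identity transition matrices; an all-zero generator is valid (the
  likelihood is the root prior mass of the observed pattern).

## Known limitations

* Harmonic-mean marginal likelihoods remain unstable at desk scale even
  under the gamma hyperprior; the ~15–20% false-positive rate of the log-BF
  > 2 rule at 18k-iteration chains is intrinsic to the estimator, improves
  only slowly with chain length, and is reported rather than corrected.
* Z-score magnitudes are conservative at desk scale.  With a single
  simulated pair on one tree, the posterior Z of a true structural zero is
  frequently in the 50–70% range rather than above 90%: when a dataset
  leaves the restricted rate unidentified, the uniform-over-models prior
  caps its zero-bin share well below 1, and occasional role-swapped
  background reconstructions depress it further.  Recovering the published
  three-tier behavior (70/90/95) reliably needs the cluster-scale setup —
  thousands of posterior trees and 10^8-scale chains — that the "paper"
  settings profile encodes.  Consequently the planted-order chain of the
  contingency validation is recovered at the 70% tier in only a minority of
  desk-scale replicates, with the restriction *ordering* (restricted rate
  ≫ its critical partner) recovered essentially always.
* The rj proposal kernel documented above is this package's own; the
  original software's kernel and hyperprior ranges are not published, so
  numerical agreement with it is not claimed.
* One chain is run per character (ancestral stage) and per pair
  (dependence/contingency stages); no joint model across characters is
  attempted.
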