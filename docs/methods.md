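# Methods

## The additive logical model

Each gene/protein node i carries two variables in [0, 1]: a *fast* variable
(protein activity) and a *slow* variable (gene expression).  The node's
total activity is always their product, x_i = fast_i · slow_i.  Edges are
signed, weighted and assigned to a fast or slow priority class; the class
determines which of the two variables the edge drives.

The regulatory input of a node for one class is the normalized signed
weighted sum of upstream total activities,

    s_i = ( Σ_{activators} w_ji·x_j − Σ_{inhibitors} w_ji·x_j ) / Σ_j |w_ji| ,

taken over incoming edges of that class, so s_i ∈ [−1, 1] regardless of
in-degree and inputs are comparable across nodes.  A variable with no
incoming edges of its class holds its value: nodes without regulators act
as clamped external stimuli (growth factors).

**Activation function.**  f(s) = 1/(1 + exp(−k·(s − θ))), clipped to
[0, 1], with steepness k (default 10) and threshold θ (default 0).  A
`step` variant (f = 1 iff s > θ) is the k → ∞ limit and recovers Boolean
semantics; with unit weights and all-fast edges the model's fixed points
coincide with a brute-force Boolean fixed-point enumeration, which the test
suite checks exhaustively on ≤4-node networks.  The literature behind this
model family states the additive update but not a specific squashing
function; the logistic is this package's own choice because it provides the
continuous "any value between 0 and 1" resolution while containing the
Boolean special case.

**Priority classes and updating.**  One macro-step first relaxes all fast
variables by random-order asynchronous updates until no fast variable moves
by more than `convergence_tol` (default 1e−6, at most
`fast_relaxation_max_iters` = 1000 sweeps), then updates exactly one
randomly chosen slow variable.  This quasi-steady-state reading of the
fast/slow priority classes is the package's interpretation of "fast
reactions first"; it is documented as a faithful-in-spirit reconstruction,
not a bit-exact port of the original MATLAB implementation, whose exact
scheduler is not published.

**Stable states and basins.**  `find_stable_states` simulates from all
2^n Boolean corners when they fit in the requested budget, otherwise from
uniform random levels (an initial level v sets fast = v, slow = 1, i.e.
full expression at activity v; clamped nodes are pinned).  A state is
accepted as stable only if it passes the fixed-point certificate: every
unclamped variable with inputs satisfies |f(s) − value| ≤ tol.  Endpoints
within 1e−3 (max-norm on totals) are grouped; a group's basin fraction is
its share of initial conditions, giving basins that sum to ≤ 1 (trajectories
that fail to converge within `max_steps` = 10·n² raise a warning and are
reported as non-converged with basin 0).  Asynchronous updates make basin
fractions seed-dependent; the fixed points themselves are not.

**Markers and screens.**  A stable state is labelled "M+" when marker M's
total exceeds 0.5 (e.g. SOX9+ proliferative vs RUNX2+ hypertrophic).  The
perturbation screen clamps each node at 0 (knockout) or 1 (over-activation)
and reports the marker-positive basin fraction; a factor is flagged
`required` when its knockout leaves no marker-positive stable state.  Dose
responses clamp an input node along a level grid, with level 0/1 equal to
the KO/over-activation rows by construction.

## Inference methods

All methods consume a genes × samples matrix and emit a square confidence
matrix (diagonal zero, symmetric when undirected).  Hyperparameters below
are package defaults; the study that motivated this package does not state
the original settings.

* **Correlation** — |Pearson| or |Spearman|.
* **Mutual information** — plug-in estimate in bits on equal-frequency
  bins; `n_bins` defaults to ⌊√n_samples⌋.  Parameter-light and standard.
* **CLR** — each MI value z-scored against both genes' background MI
  distributions (negative z clipped to 0), score = √(z_i² + z_j²).
* **ARACNE** — MI with data-processing-inequality pruning: in every
  triangle the weakest edge is zeroed when below (1 − tolerance) times the
  smaller of the other two; tolerance defaults to the conventional 0.15.
* **MRNET-style MRMR** — per target, greedy forward selection by relevance
  minus mean redundancy with the already-selected set; pairwise score =
  max of the two directed scores, floored at 0.
* **GENIE3-style trees** — per target, extremely-randomized-trees
  regression on all other genes; importances normalized to sum 1.
* **TIGRESS-style stability selection** — per target, frequency with which
  each regulator enters the first `n_select` (default 5) LARS steps across
  `n_resamples` (default 50) half-sample resamples with predictor weights
  drawn from U(0.3, 1).
* **GGM** — absolute partial correlations from a Ledoit–Wolf
  shrinkage-regularized covariance.  Shrinkage introduces a small bias
  away from exact conditional independence, visible when correlations are
  very strong; tests use moderately noisy chains accordingly.
* **Bayesian scoring** — exhaustive BDeu scoring (equivalent sample size
  1) of all parent sets up to `max_parents` (default 2) on discretized
  data; edge confidence is the posterior-weighted frequency of parent sets
  containing the regulator.  Deliberately gated to ≤ 15 genes: this is an
  honest desk-scale enumeration, not an MCMC structure sampler.

**Consensus.**  Every method's ranking is collapsed to undirected pairs
(score of a pair = max of its two directed scores — an inferred interaction
is an existence claim, so the stronger direction carries the evidence) and
converted to descending-score ranks with average-rank ties.  Pairs missing
from a method's list are charged that method's worst rank (absence of
evidence ranks last and keeps pair sets aligned).  The consensus sorts
pairs by mean rank, breaking ties lexicographically.  The returned
`RankedEdgeList` stores the *negated* mean rank in its score field so the
type's "scores non-increasing with rank" invariant holds; mean ranks are
recovered with `consensus_mean_ranks`.  Being rank-based, the consensus is
invariant to method order and to any strictly monotone rescaling of a
method's scores.

## Prior-weighted inference

The prior is a square sign matrix over the gene set (−1/0/+1).  It enters
the stability-selection regression through penalty rescaling: regulator r's
sparsity penalty for target t is divided by (1 + g·|prior(r,t)|),
implemented by scaling the predictor column (the adaptive-lasso identity).
This transparent one-parameter surrogate carries the same semantics as the
published prior-weighted Inferelator variant, whose exact mechanism is not
reproduced in the motivating text.  Prior signs act only through their
magnitude during selection; the fitted coefficient's sign can be compared
with the prior sign in reports but never constrains the fit, because no
sign-constraint is documented.

Because g = 0 leaves every penalty factor at 1 and the random number stream
is untouched by the prior, the g = 0 run is bit-identical to the no-prior
method at equal seed (tested).

Coefficients are fit by per-target OLS restricted to regulators selected at
frequency ≥ 0.5; SSR is the sum of squared residuals of these linear
predictions on gene-wise standardized expression (standardization makes
g's effect comparable across genes).  The g-scan reuses one seed across g
values and reports (g, AUROC vs the prior network, SSR).  The per-pair
report carries StoT/TtoS — the two directed selection frequencies — plus
the signed Pearson correlation and, when a prior is attached, the prior
signs of both orientations.  StoT/TtoS are documented as selection
frequencies; whether the original quantities were frequencies or posterior
probabilities is not stated in the source material.

## Evaluation

The candidate universe is every non-self pair over the gold network's node
set (unordered in undirected mode, ordered in directed mode); predicted
pairs outside the ranking are appended at score −∞ in lexicographic order
so every method is judged on the complete ranking.  In undirected mode a
pair is true iff the gold network links the two nodes in either direction.
Self-loops are excluded by default because no in-scope inference method
scores self-regulation.

ROC/PR curves step once per distinct-score block, which makes the
trapezoidal AUROC exactly the Mann–Whitney statistic with ties counted one
half (property-tested against a brute-force pair-counting oracle).  AUPR is
the non-interpolated step sum Σ precision·Δrecall, the deterministic
convention of GRN benchmarking; a gold-edges-first ranking scores exactly
1.  Because full-curve PR and top-of-list behaviour can disagree,
`precision_at_k` is also provided.

## Synthetic data generator

The default generator draws a random signed directed graph (no self-loops;
edge probability = `edge_density`, sign +1 with probability
`activating_fraction`, weights U(0.5, 1.5); resampled until every node has
an incident edge) and solves the steady-state linear-Gaussian system
x = Aᵀx + u per sample, with A scaled to spectral radius 0.8 so a unique
stable solution exists.  The designs mirror the growth-plate microarray
corpus:

* **multifactorial** — u ~ N(0, perturbation_sd²) on every gene (patients /
  biological replicates);
* **knockout** — one gene per sample clamped to exactly 0 (round-robin);
* **zones** — declared driver genes clamped along an ordered gradient over
  the growth-plate zones (Resting, Proliferating, Maturing, Hypertrophic;
  configurable to three zones), with replicates — driver profiles are
  exactly monotone across zones at zero noise;
* **treatment** — treated samples receive an input shift on target genes
  versus controls.

`growth_plate_study_emulation` concatenates five such studies (12/8/15/12/18
samples, 65 in total) to match the multi-study, mixed-design shape of the
real compendium.  Defaults — 13 genes, density 0.15, 60 multifactorial
samples, perturbation SD 1.0, measurement noise SD 0.25 — are the
benchmark's study conditions; the perturbation-to-noise ratio (4:1) was set
once to the signal strength of well-behaved multifactorial microarray
compendia, since the real studies' perturbation magnitudes are not
characterized.  A linear-Gaussian generator was chosen over sampling the
logical model because it gives analytically controllable signal for
inference benchmarks; what it does **not** emulate — probe-level artifacts,
normalization residue, saturation, nonlinear regulation, hidden confounders
across studies — bounds what passing tests say about real microarray data:
they validate the machinery, not biological discovery performance.

The packaged fixture (13 TF names incl. Greek-letter spellings, and the
curated 9-interaction prior sign matrix) is shipped as plain-text data
files and exercised by the tests; the complete literature-derived network
topology exists only as a figure in the source material and is not
reconstructible from text, so a packaged toy/prior network stands in for
simulator demonstrations, and the original headline comparison values
(which additionally require the unavailable microarray compendium) are out
of scope.

## Numerical and design choices

* Canonical unordered pair = lexicographic name order; all tie-breaks are
  lexicographic after average-rank scoring, making every output
  deterministic at fixed seed.
* Node-name canonicalization runs through an alias table shipped with the
  growth-plate genes (NFκB/NF-κB/NFkB; HIF-2α/HIF-α2; δ-EF1/dEF1, …),
  since the literature mixes spellings; matching is case- and
  separator-insensitive and idempotent.
* SIF dialect: `source<TAB>relation<TAB>target` with relation ∈
  {activates, inhibits}; optional 4th/5th columns carry weight and
  kinetics, `#node` records carry categories, so write→read round-trips
  exactly.
* Degenerate inputs fail loudly: zero-variance genes (correlation),
  one-bin discretizations (MI family), empty TF sets (node selection),
  gold networks without positives (evaluation), g lists of length < 2
  (g-scan).
* CLI numeric output is printed at 6 significant digits so repeated runs
  diff byte-identically.

## Known limitations

* The logical model is a reconstruction of the published additive
  framework's spirit, not a port; basin fractions depend on the
  asynchronous schedule (seed) even though fixed points do not.
* Only fixed points are reported as stable states; limit cycles are
  flagged as non-convergence rather than characterized.
* The Bayesian method ignores global acyclicity (per-target parent sets)
  and is capped at 15 genes.
* Shrinkage GGM confidences are biased away from exact zero partial
  correlation when marginal correlations are extreme.
* AUROC/AUPR against a curated network treat it as a *pseudo*-gold
  standard; absent edges are counted as negatives even though they may
  simply be uncurated.
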