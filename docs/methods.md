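# Methods

## Problem and model

Given a directed simple graph G = (V, E) without self-loops, a node score
s : V → ℝ summarizing per-gene evidence of deregulation, optional receptor
(R) and terminal (T) role sets, optional include/exclude sets, and size
bounds k_min ≤ k_max, the package finds a node set V* ⊆ V with a
distinguished root that maximizes (or minimizes) the **average** score

    s(V*) / |V*|,   s(V*) = Σ_{v ∈ V*} s(v),

subject to:

* the root is selected, unique, and — when R ≠ ∅ — a receptor;
* every selected node is reachable from the root by a directed path inside
  V* (rooted connectivity);
* when T ≠ ∅, every selected node with no selected out-neighbor is a
  terminal;
* include ⊆ V*, exclude ∩ V* = ∅, and k_min ≤ |V*| ≤ k_max.

Averaging rather than summing removes the need to fix the subgraph size in
advance, which is what lets the model connect receptor-type sources to
terminal-type sinks freely within the size window.  The fixed-size
comparator (`solve_fixed_size`) maximizes the *total* score at one exact
cardinality under the same connectivity machinery and is the baseline the
average-score model is benchmarked against; `solve_union_over_sizes` unions
its solutions over every size in the window, which is the standard way a
fixed-size method is run when the true size is unknown.

In matrix form over indicator vectors x (selection) and y (root flag) the
feasible set is linear: y ≤ x; eᵀy = 1; k_min ≤ eᵀx ≤ k_max;
x_v − y_v − Σ_{u ∈ δ⁻(v)} x_u ≤ 0 per node; for every strongly connected
node set S with |S| > 1 the cover row Σ_{v∈S}(x_v − y_v) − Σ_{u∈δ⁻(S)} x_u ≤
|S| − 1; root restriction to R; sink rows for v ∉ T; fixed variables for
include/exclude.  The per-node in-neighbor rows together with the full
(exponential) family of strongly-connected-set rows are equivalent to rooted
reachability; the test suite checks this equivalence against a
breadth-first-search oracle.

## Solution scheme

The fractional objective is solved by a Dinkelbach iteration: for a weight
λ, solve the MILP

    max  sᵀx − λ eᵀx   over the feasible set,

then update λ to the incumbent's average score; at the optimum the
parametric value is zero.  The λ iterates are non-decreasing (for
maximization) and, because the feasible family is finite, the scheme
terminates after finitely many steps; we stop when |sᵀx − λ eᵀx| ≤ ε with
ε = 1e−6 (`gap_tolerance`), max_iterations = 50.  λ is initialized from a
greedy feasible subgraph (breadth-first growth from the best-scoring
admissible root up to k_min nodes); when greedy construction fails, the
minimum node score is a valid lower bound for any feasible average.  In
practice instances at benchmark scale converge in about two parametric
solves.

Minimization is solved as maximization of the negated score;
`absolute=True` replaces s by |s| first; reverse mode (finding subgraphs
that *converge on* a target) solves the forward problem on the
edge-reversed network with R and T swapped and reports the result in the
original orientation.

**Lazy connectivity separation.** The strongly-connected-set family is
exponential, so only violated rows are added: solve, compute the strongly
connected components of the selected subgraph (networkx), add a row for
every component that has more than one node, lacks the root, and receives no
edge from another selected node, and re-solve until the incumbent is clean.
This iterative resolve loop has the same fixed point as solver-callback lazy
constraints and keeps the implementation backend-agnostic.  Generated rows
are kept for subsequent parametric solves (they are valid for every λ).

**MILP backend.** Subproblems are solved with HiGHS through
`scipy.optimize.milp` with `mip_rel_gap = 0` so parametric optima are exact;
model rows are built in sorted node order, making solves deterministic.

**Tie-breaking toward maximal optima.** The average-score optimum is often
non-unique — with binary scores, every feasible all-ones subgraph of any
admissible size ties at average 1 — and which tied optimum a MILP backend
returns is arbitrary.  After convergence the solver therefore runs one
secondary MILP maximizing |V*| subject to the average being optimal (within
1e−9), and falls back to the incumbent on any numerical degradation.
Reporting the maximal optimal subgraph makes output deterministic in
substance and is what makes planted-subgraph recovery size-accurate; it can
be disabled via `SolverSettings(maximal_optimum=False)`.

**Suboptimal enumeration.** The optimal and the next n best node sets are
enumerated by re-solving after adding, for each previous solution V*, the
no-good cut Σ_{v∈V*} x_v − Σ_{v∉V*} x_v ≤ |V*| − 1.  This cut excludes
exactly the set V* and nothing else; the one-sided variant (dropping the
negative terms) would also forbid all supersets, silently skipping valid
next-best solutions such as a superset with a slightly lower average.

## Probabilistic interpretation

Binary scores are modeled as independent Bernoulli draws: rate p′ inside an
unknown subgraph V′ from the feasible family, rate p < p′ outside.
Two estimation statements connect the optimizer to this model:

* **Fixed size.** Among feasible subgraphs of one fixed size, maximizing
  the total score is maximum profile-likelihood estimation of V′ — the
  profile log-likelihood is monotone in the inside hit count at fixed size.
  This is the sense in which the fixed-size comparator is an MLE.
* **Free size (matched rates).** The average-score maximizer V* with
  optimal average λ* is the maximum-likelihood subgraph for *any* fixed
  rates (p, p′) whose induced parametric weight
  λ(p, p′) = ln((1−p)/(1−p′)) / ln(p′(1−p)/(p(1−p′))) equals λ*: for fixed
  rates the log-likelihood is an affine function of (sᵀx, eᵀx), and
  maximizing it is exactly the Dinkelbach parametric problem at that weight.

The stronger statement "the average maximizer also maximizes the *jointly
profiled* likelihood (both rates estimated per subgraph)" is **not** true in
general: joint profiling rewards larger subgraphs that absorb more of the
marked nodes, and small exhaustively-enumerable counterexamples exist (e.g.
a two-node all-ones set versus a five-node set with four ones).  The test
suite asserts the two true statements and logs joint-profile disagreements
as diagnostics.  `profile_log_likelihood` uses the convention 0·ln 0 = 0 and
reports the pooled-rate supremum when the estimated ordering p̂′ < p̂ is
degenerate, rather than clamping.

## Node scores

* **Trinary cohort score**: +1 if log2 fold change > 2.0 at p < 0.05, −1 if
  < −2.0 at p < 0.05, else 0.  The cuts are strict and sign-symmetric; both
  cutoffs are arguments.
* **Personalized fold change**: log2((tumor + c) / (mean(controls) + c))
  with pseudocount c = 1 added to both numerator and denominator, so
  zero-expression genes score 0; the trinary personalized cut is ±2, strict.
* **Methylation gene score**: a probe is called +1/−1 when the median tumor
  beta minus the median control beta exceeds +0.2 / falls below −0.2
  (strict); a gene is +1 with ≥1 up-probe and no down-probe in its promoter
  window, −1 in the mirrored case, 0 otherwise including conflicts and
  unprobed genes.  The probe→gene promoter map is an input (it comes from
  array metadata), never computed from annotation.
* **Consistency score**: indicator that the transcription call and the
  methylation call strictly oppose (product < 0) — the canonical
  promoter-hypermethylation/repression pattern — used to extract subgraphs
  whose deregulation is plausibly epigenetically driven.

Differential statistics and normalized beta matrices are consumed as plain
TSV inputs; the package does not re-implement count normalization,
differential testing, or array normalization.  Score tables are aligned to
the network with missing nodes scored 0 (neutral) and off-network ids
dropped with a logged count.

## Simulation benchmark

`generate_network` produces a seeded directed scale-free graph
(networkx preferential-attachment generator; self-loops removed,
multi-edges collapsed), emulating the heavy-tailed degree structure of
curated signaling networks.  It does **not** emulate edge semantics
(activation/inhibition), pathway modularity, or the specific hub identity
of a curated network, so benchmark results demonstrate recovery of rooted
connected structure under the score model — not biological fidelity.

A true subgraph is grown by outward random expansion: uniform random root,
then repeatedly a uniform random current member contributes a uniform
random unselected out-neighbor until a size drawn uniformly from
[size_min, size_max] is reached; dead ends restart with a fresh root (at
most 1000 retries).  Scores are independent Bernoulli draws at rate p′
inside and p outside.

Default benchmark conditions: 300-node network, p′ = 0.99, p = 0.01,
planted sizes 8–12, solver bounds k ∈ [6, 15], 20 instances, free root
(R = T = ∅) for both algorithms — a desk-scale rendition of the full-scale
protocol (thousands-node curated network, planted sizes 30–45, bounds
25–50, 100 instances, 600 s solver limit) that preserves the
planted-size-to-bound geometry.  Per-instance random streams derive from
(seed, instance index), so any instance is reproducible in isolation.
Recovery is scored by node-level confusion counts (tp/fp/fn/tn against the
planted set), sensitivity, precision, F1, Jaccard, Matthews correlation,
and size efficiency |V_pred|/|V_true|; each emitted subgraph also gets an
upper-tail hypergeometric enrichment p-value against the simulated scores
(scipy.stats.hypergeom).  Runtime is recorded but never asserted.

## Survival stratification

For each gene appearing in at least one patient's personalized subgraph,
patients are split by membership and compared with the standard unweighted
log-rank test (lifelines); Kaplan–Meier curves use the product-limit
estimator with conventional handling of tied event times.  Genes must yield
both strata of size ≥ 3 by default (`min_group_size`, configurable — the
appropriate floor depends on cohort size).  Benjamini–Hochberg adjustment
is applied by default with raw p-values always reported alongside, since
single-gene follow-up typically quotes the raw value.  Groups with no
events in either stratum give the degenerate (χ² = 0, p = 1) with a logged
notice.

## Numerical and design choices

* ε = 1e−6 Dinkelbach tolerance; integer-score instances converge exactly,
  continuous scores to well below the tolerance.
* `mip_rel_gap = 0`; optional per-solve `time_limit` (seconds), exceeded
  limits raise a timeout carrying the incumbent when one exists.
* Tie-break acceptance slack 1e−9 on the average in the secondary
  cardinality MILP, with fallback to the incumbent if the tied candidate's
  recomputed average falls short by more than 1e−12.
* Exhaustive oracle (`brute_force_optimal`) capped at 15 nodes; feasibility
  in the oracle is decided by BFS reachability, independently of the MILP
  row semantics it certifies.
* Deterministic iteration order everywhere (sorted node ids); identical
  inputs give identical models and, with HiGHS, identical solutions.
  Determinism across *different* MILP backends is not guaranteed for tied
  optima beyond the cardinality tie-break.
* Self-loops in input networks are dropped with a warning (the model
  requires their absence; real exports contain them); duplicate edges
  collapse to one, keeping a single interaction label.

## Limitations

* The average objective is scale-sensitive: adding a constant to all
  scores shifts every feasible average equally (argmax invariant), but
  multiplying scores by node-specific factors changes the problem.
* The benchmark's synthetic topology understates the difficulty of hub
  disambiguation on real curated networks with very high-degree nodes.
* The secondary cardinality tie-break reports *one* maximal optimum; a
  complete enumeration of tied optima requires `solve_suboptimal`.
* Timeout handling returns the incumbent of the interrupted solve only;
  there is no warm-start across parametric iterations.
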