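# Methods

## Model

A network over nodes $V$ is modeled geometrically: node $i$ has latent
coordinates $z_i \in \mathbb{R}^d$, and the probability that a pair
interacts decreases smoothly with their squared Euclidean distance.  The
margin $\xi_{ij} = b - \lVert z_i - z_j\rVert^2$ passes through the
two-class t-exponential link

$$F_t(u) = \exp_t\!\big(u/2 - G_t(u)\big), \qquad
\exp_t(x) = [1 + (1-t)x]_+^{1/(1-t)},$$

with $G_t(u)$ defined by $F_t(u) + F_t(-u) = 1$.  The squared (not plain)
distance is used because only then does the stationarity condition of the
likelihood take the weighted-average form $z_i = \sum_j W_{ij} z_j /
\sum_j W_{ij}$ with per-pair mixing coefficients $W_{ij}$ — the property
that motivates the preconditioners below.  The bias $b$ is a single
global squared-distance cutoff; at $\lVert z_i - z_j\rVert^2 = b$ the
interaction probability is exactly 1/2.

The loss of a labeled pair is the ordinary negative log-probability
$\ell_t(u) = -\log F_t(u)$, so $t = 1$ recovers logistic regression
exactly.  For $1 < t < 2$ the gradient magnitude
$|\ell_t'(u)| = F_t(u)^{t-1} F_t(-u)^t / (F_t(u)^t + F_t(-u)^t)$ rises to
a maximum near $u \approx -1$ and then *decays* as $u \to -\infty$:
grossly misclassified pairs (false links between distant points, or
missing links between close points) progressively lose influence.  This
bounded-influence property is the robustness mechanism; at $t = 1$ the
magnitude instead saturates at 1 and outliers retain full pull.

### Loss parameter t

$t$ must lie in $[1, 2)$; the default is 1.9.  Values very close to 2
behave almost identically to 1.9 but with an increasingly extreme tail;
$t = 1$ is the convex reference.  Robustness comparisons in the tests are
run at exactly these two settings.

## Numerics of the link

$G_t(u)$ has no closed form for $t > 1$.  The residual
$r(g) = \exp_t(u/2 - g) + \exp_t(-u/2 - g) - 1$ is strictly decreasing
and convex in $g$, and $r(|u|/2) = \exp_t(-|u|) \ge 0$, so Newton's
method started at $g_0 = |u|/2$ converges monotonically from the left
without safeguarding; iterations use the identities
$p^t = p/\mathrm{bracket}$ and $p^{t-1} = 1/\mathrm{bracket}$ to avoid
extra power evaluations.  Convergence is declared at residual
$\le 10^{-12}$ or when the Newton step falls below a few ulps of $g$ (the
residual floor for $|u| \gtrsim 10^7$).  At $t = 1$ the closed form
$G_1(u) = \log 2\cosh(u/2)$ is used in the overflow-safe form
$|u|/2 + \log(1 + e^{-|u|})$.  The loss for $t > 1$ is computed as
$\log(\mathrm{bracket})/(t-1)$, avoiding underflow of $F_t$ itself.  The
loss derivative (the closed form above) is validated against central
finite differences in the tests, since it is a derived identity.

## Objective and negative sampling

Positives are the network's edges.  Using all $\binom{n}{2} - |E|$
non-edges is quadratic, so by default $\rho\,|E|$ non-edges (ρ = 5) are
sampled uniformly once per fit and each carries weight
(#non-edges / #sampled), making the sampled objective an unbiased
estimate of the full one; `exact_negatives=True` switches to the full set
(practical to ~2000 nodes).  Sampling once per fit (not per iteration)
keeps the minimized function fixed so monotone descent is well defined.

## Optimization

Each outer iteration alternates:

1. **Bias update** — 1-D gradient descent with backtracking, run to local
   optimality.  Candidates are projected onto the observed range of
   squared pair distances: outside that window the cutoff classifies
   every pair identically, and for $t$ near 2 the heavy-tailed loss makes
   $b \to -\infty$ ("reject everything") a genuine descent path whose
   saturated gradients then freeze the coordinates.  The projection keeps
   $b$ identifiable while preserving monotone descent.
2. **Coordinate step** — one step along $D = -M^{-1}\nabla_Z$ with a line
   search satisfying the Wolfe conditions (Armijo $c_1 = 10^{-4}$,
   curvature $c_2 = 0.9$, bracketing + bisection zoom; a step achieving
   only plain decrease after the backtrack budget is accepted and flagged
   "weak").  Two SPD preconditioners are available:
   * `diagonal` (default): $M = \mathrm{diag}(\sum_j |W_{ij}| + \lambda)$,
     the Jacobi scaling of the mixing-coefficient mass.  Using absolute
     values keeps $M$ positive definite even though repulsive (non-edge)
     coefficients are negative.
   * `sparse_system`: $M = \mathrm{diag}(\sum_j W^+_{ij}) - W^+ +
     \lambda I$ on the attractive support — a graph-Laplacian system
     solved column-wise with LSQR.
   Either way $\langle D, \nabla\rangle < 0$ is verified, with a fallback
   to $-\nabla$; combined with the Wolfe line search this guarantees
   convergence to a stationary point (Zoutendijk).

Stopping: relative objective decrease below `tol_rel_obj` ($10^{-6}$)
across a full outer iteration, or 500 outer iterations.  One integer seed
drives initialization and negative sampling through independent
substreams; fits are bit-reproducible.

### Initialization and continuation

The loss is non-convex for $t > 1$ and the final quality depends strongly
on the starting point.  Two design choices, made after the optimizer's
behavior was understood and kept fixed thereafter:

* **Warm start** (default `init="mdsgeo"`): coordinates start from the
  classical-MDS embedding of hop distances (per connected component, plus
  a small random jitter).  Random Gaussian init (`init="random"`,
  scale 0.1) is retained as an option but reliably finds poorer optima of
  the non-convex objective.
* **Continuation** (default `continuation=True`): for $t > 1$ the solver
  first runs the same alternating scheme on the convex $t = 1$ objective
  (same pair sample), then refines at the target $t$ from that solution.
  This is graduated non-convexity: the convex stage supplies a globally
  sensible structure, and the robust stage prunes the influence of
  outlying (noise) pairs.  Empirically the refinement improves edge
  recovery on both clean and perturbed geometric graphs, and it is what
  realizes the robustness advantage of $t = 1.9$ over $t = 1$ at high
  noise levels.

The bias is initialized to the median squared distance among positive
pairs (probability ≈ 1/2 on a typical edge) and carried across stages.

## MDS-GEO baseline

Hop distances from BFS, double-centered ($B = -\tfrac12 J D^{\circ 2} J$),
eigendecomposed; coordinates are the top-$d$ eigenvectors scaled by
$\sqrt{\lambda}$, using positive eigenvalues only, with eigenvector signs
fixed (largest-magnitude entry positive) for reproducibility.  Hop
distances are defined only within a connected component, so components
are embedded independently; for whole-network scoring the components are
laid out along the first axis with gaps wider than the largest component,
which makes cross-component pairs score as distant — consistent with
their non-interaction status.  The baseline's bias is set post hoc to the
squared-distance cutoff maximizing Youden's J on the training edges, so
its outputs are threshold-compatible with t-LSE's.

## Null models and the synthetic ground truth

The generators reproduce the standard comparison set, each consuming only
its declared input information: ER (n, m; exact edge count), ER-DD
(degree distribution, via the stubs method — stub pairs joined at random,
self-loops/duplicates rejected; on deadlock the matching restarts, up to
10 attempts, before discarding the unplaceable residue), SF
(Barabási–Albert preferential attachment; per-node attachment counts are
randomized between ⌊m/n⌋ and ⌈m/n⌉ so the expected edge count matches the
target, since the classical fixed-m growth cannot hit an arbitrary edge
count), and Sticky ($\theta_i = \deg i/\sqrt{\sum_k \deg k}$, pair
probability $\min(1, \theta_i\theta_j)$, clipping logged).

The **geometric random graph** is the synthetic stand-in for real PPI
networks: n points uniform in the unit $d$-cube, edges = the m closest
pairs (radius set by the m-th smallest distance, ties broken by pair
index).  It makes the geometric assumption *exact* and returns the
generating coordinates, so scoring by true distances yields AUC 1 by
construction — the ceiling against which recovery is judged.  The study
instance used in the tests is n = 300, $d_{\text{true}} = 2$, m = 1200
(mean degree 8, matching the sparsity regime of curated PPI data).  What
this emulates: sparsity, metric structure, noise injected as uniform
random edge rewiring.  What it does not: hubs/power-law degree tails,
modular community structure, ascertainment bias of bait–prey screens, or
correlated (systematic) false positives.  Passing the robustness tests
therefore demonstrates the mechanism of bounded-influence fitting, not a
performance guarantee on any particular real interactome.

**Perturbation**: `perturb(net, frac, seed)` deletes ⌊frac·|E|⌋ random
edges and inserts an equal number of uniform random non-edges, conserving
|E| — simulated false negatives and false positives.

## Graphlets and GDD agreement

Orbit counting enumerates every connected induced subgraph on 2–k nodes
exactly once (ESU) and resolves each node's automorphism orbit through a
cached canonical-form table (≤ 2¹⁰ local adjacency patterns, each
canonicalized once by brute force over ≤ 5! permutations).  Orbits 0–14
(graphlets up to 4 nodes) follow the standard numbering, reconstructed by
ordering canonical graphs by (size, edge count, max degree) and orbit
classes by degree; the 58 orbits of 5-node graphlets get ids 15–72 in the
same deterministic canonical order.  Default `max_graphlet_size=4` keeps
desk-scale runtimes; size 5 is available behind the flag and
oracle-tested.

The GDD of orbit $j$ histograms how many nodes touch the orbit exactly
$k$ times; bins are scaled by $1/k$ and normalized to unit mass.  The
per-orbit agreement is $A_j = 1 - \lVert N^A_j - N^B_j\rVert_2/\sqrt 2
\in [0, 1]$; the overall agreement averages $A_j$ (arithmetic by default,
geometric optional) over orbits where at least one network has mass —
orbits empty in both networks are uninformative and skipped.

## Evaluation

Pairs are scored by embedding distance (smaller = more likely
interacting).  AUC is computed exactly in rank form (probability that a
random interacting pair scores below a random non-interacting one, ties
half) rather than by integrating the swept ROC curve, which avoids
threshold-grid artifacts; the sweep (sensitivity, 1−specificity, and the
TP/TN/FP/FN counts per threshold) is still emitted for plotting.
Conditional densities use Gaussian KDE with Silverman bandwidth on a
shared grid padded by 6 bandwidths (degenerate single-valued classes get
a sharp Gaussian two grid steps wide).  For evaluation, negatives are all
non-edges up to 2000 nodes, else a seeded sample of 10·|E|.

The noise experiment perturbs the network at each level, re-embeds the
*perturbed* graph with each method (t = 1.9, t = 1.0, MDS-GEO), and
computes AUC against the *original* labels; replicate seeds derive from
one master seed.  The experiment sizes used in the acceptance checks
(n = 300, levels 5/10/25%, 5 replicates) keep the full suite in the
tens-of-minutes range on a single CPU while leaving the qualitative
ordering stable across seeds.

## Known limitations

* The non-convex objective has no global guarantee; different seeds can
  reach different local optima (multi-restart via `restarts`).
* The bias is a single global cutoff; per-node propensities (cf. the
  sticky model) are out of scope.
* Negative sampling makes the fitted objective itself a random variable;
  variance is visible for very small ρ.
* 5-node orbit ids above 14 follow this package's canonical order, which
  need not match other tools' numbering (agreement values are unaffected
  as long as both profiles come from this package).
* The robustness conclusions are demonstrated on geometric synthetic
  graphs; real interactomes violate the generator's assumptions in the
  ways listed above.
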