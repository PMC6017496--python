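# Methods

## The landscape model

`basinsel` treats a decoy ensemble Ω with energies f as a discrete sample
of a fitness landscape (X, N(X), f). The neighborhood structure N(X) is
estimated by the ε-graph: vertices are decoys, and (u, v) is an edge iff
d(u, v) ≤ ε. All landscape operations are metric-agnostic; d can be any
conformational distance (see *Distance backends*).

**Local minima and basins.** u is a local minimum iff f(u) ≤ f(v) for all
neighbors v (isolated vertices vacuously qualify; on an exact energy
plateau every plateau vertex with no strictly lower neighbor is its own
minimum). Every other vertex carries a discrete negative gradient: the
incident edge maximising (f(u) − f(v)) / d(u, v) over strictly lower
neighbors, ties broken toward the lowest vertex index. Following that edge
repeatedly strictly decreases f, so descent terminates; vertices reaching
the same minimum form its basin. Basins therefore partition each connected
component, and a defensive cycle guard covers the (unreachable) degenerate
case.

**Pseudo-saddles, persistence, stability.** The pseudo-saddle of basin B
is the lowest member u of B that has a *strictly lower* neighbor draining
to a different basin; persistence(B) = f(saddle) − f(B), and stability is
the perpendicular distance of the point (f(B), f(saddle)) from the identity
line, i.e. persistence/√2. A basin with no qualifying member — the deepest
basin of its component, and also any one-point basin whose focal has only
higher neighbors — has persistence +∞. Among multiple qualifying saddle
vertices the lowest-energy one is chosen, making persistence the minimal
escape barrier (the topological-persistence convention). Note the
definition is asymmetric: at a boundary between two basins, the finite
persistence accrues to the basin that *contains* the crossing vertex, not
necessarily to the shallower basin.

**Persistence merging.** Given p_thresh ≥ 0, the lowest-persistence basin
below the threshold is merged into the basin its saddle drains to (the
basin of the saddle's lowest lower neighbor); the focal of the union is its
deepest member, and saddles/persistences are recomputed after every merge
(rather than frozen from the initial pass — recomputation keeps the merged
landscape self-consistent and makes the filtration idempotent:
merge(p₁) then merge(p₂ ≥ p₁) equals merge(p₂)). p_thresh defaults to 1,
i.e. close to no filtering: aggressive merging demonstrably hurts selection
purity, because protein energy landscapes are rugged and large pure basins
can have low persistence.

## Choosing ε

ε defaults to 1 Å and, in the end-to-end driver, is increased in 0.5 Å
steps until the largest leader cluster has at least two members (a
singleton cluster exists at any ε, so the adaptation rule is read as
requiring genuine aggregation); the same ε is reused for the basin graph.
`build_nngraph` reports the component count but never silently repairs a
disconnected graph; `connect_epsilon` implements the explicit remedy of
raising ε to the connectivity threshold. Its `margin_steps` option adds
extra increments past bare connectivity: at the connectivity threshold,
fringe vertices see only one or two neighbors — too few to estimate a
descent direction — and their noise dimples survive as one-point basins
with infinite persistence (see the asymmetry above). The planted-recovery
analyses use one margin step. A k-nearest-neighbor graph is a possible
alternative repair; only ε-graphs are implemented, and the graph builder is
the single hook a k-NN variant would replace.

## Selection strategies

Strong dominance on (size, −focal energy): a ≻ b iff size(a) > size(b) and
f(a) < f(b), strict in both. PR(B) counts dominators of B, PC(B) counts
basins B dominates; both are computed exhaustively (the basin count is
small). Rankings:

| strategy | keys |
|---|---|
| Basin-Size | size ↓ |
| Basin-Size+Energy | focal energy ↑ within the 10 largest (pool size configurable) |
| Basin-PR | PR ↑ |
| Basin-PR+PC | PR ↑, then PC ↓ |

After each strategy's stated keys, ties break by focal energy ascending,
then basin founding index — a declared convention (any fixed chain works;
determinism is required for testing, and energy-ascending favors deeper
basins, consistent with the strategies' intent). Persistence and stability
are deliberately *not* selection objectives by default: they neither
improve selection nor admit a useful ordering, and filtering by low
stability discards high-purity basins. An experimental three-objective mode
(size, −energy, stability) exists behind `pareto_scores(...,
include_stability=True)` to make that negative result reproducible.

Cluster-Size uses follow-the-leader clustering: decoys are shuffled (seeded,
recorded) and scanned once; each joins the first cluster whose
representative is within ε, else founds one. Order dependence is real and
controlled by the seed. Cluster-Random draws groups uniformly at random
without replacement within a group (with-replacement would only blur the
calibration), sized like the top clusters, over 5 independent runs whose
metrics are averaged.

## Distance backends

* `reference_superposed_rmsd` (default): every decoy is Kabsch-superposed
  once onto an arbitrary reference (the first decoy), after which plain
  coordinate RMSD is the pairwise distance. This is the standard O(n)
  shortcut; the resulting distances upper-bound the true pairwise lRMSD.
* `full_lrmsd`: exact pairwise Kabsch lRMSD, O(n²) superpositions — the
  gold standard for small sets and cross-checks.
* `precomputed_features`: Euclidean distance on fixed-length feature
  vectors (synthetic data, or tabular inputs). A table carrying only
  `native_dist` is embedded on that single coordinate so downstream
  operations remain usable, with the obvious caveat that |Δ native_dist|
  only lower-bounds conformational distance.

lRMSD uses Cα atoms by default with uniform weights; atom selection and
weighting are configurable (`ca_only`), since side-chain naming makes
all-atom correspondence fragile. Superposition is delegated to the SVD
Kabsch solver; the test suite cross-checks it against an independent
rotation-grid + simplex minimisation over SO(3) to ≤ 1e-3 Å.

## Evaluating a selection

Natives are decoys within `dist_thresh` lRMSD of the native reference.
`dist_thresh` follows a per-target rule driven by min_dist, the lowest
native distance in Ω: easy targets (min_dist ≤ 0.7 Å) use 2 Å; medium
targets (0.7–2 Å) scan 2–4.5 Å in 0.5 Å steps and take the first value
admitting a native into the largest leader cluster; hard targets
(min_dist ≥ 2 Å) start the same scan at 6 Å (cap 10 Å), so the threshold
is always ≥ 6 Å and the native set is non-empty whenever the cap allows. A
scan that exhausts its range returns the range maximum with a
`scan_exhausted` flag. With zero total natives, n and p are reported as
not-applicable rather than 0, keeping "nothing to find" distinguishable
from "found nothing".

n and s are non-decreasing in x (unions grow); the purity of G1–x is the
size-weighted mean of per-group purities. Both identities are asserted in
the tests.

## Synthetic data

`generate_planted` samples k wells in a low-dimensional feature space
(default 2-D): isotropic Gaussians of width σ_w around centers at least
4·max σ apart, energies −Σ_w depth_w·exp(−‖x−c_w‖²/2σ_w²) plus
N(0, noise_sd²) observation noise. Defaults: depths from 10 down to 5
energy units, unit widths, centers spaced 5σ on a line, 150 samples per
well, noise_sd at 5% of the shallowest depth — so persistence thresholds of
1–3 times noise_sd separate noise basins from planted ones. Wells sample a
*truncated* Gaussian (3σ cutoff) so the separation invariant genuinely
separates the clouds and far-tail stragglers do not form spurious
single-point components. The generating well of each sample is its
ground-truth label, and the analytic watershed (the well whose energy term
dominates at x) is an independent membership oracle.

What the generator does *not* emulate: Rosetta score12 energetics, the
heavy-tailed and anisotropic geometry of real decoy clouds, multi-modal
native states, and energy–distance correlations beyond the planted wells.
Passing tests therefore certify the machinery — graph, descent, merging,
ranking, metrics — on landscapes with known structure, not selection
accuracy on real Rosetta ensembles.

`generate_toy_conformations` covers the coordinate path instead: groups of
decoys perturb an ideal α-helix Cα trace (radius 2.3 Å, rise 1.5 Å/residue,
100°/residue) with per-group Gaussian jitter and a pseudo-energy rising
with the jitter scale, exercising PDB round-trips, superposition and lRMSD
end to end.

## Numerical choices and problem sizes

* Descent ties (equal best ratios) and all ranking ties resolve toward the
  lowest index; exact float equality is intended, matching hand-traceable
  fixtures.
* Edge inclusion is d ≤ ε inclusive; KD-tree and distance-matrix graph
  builders are cross-checked for equality.
* Infinite persistence/stability propagate as `math.inf` and serialise as
  the string `"inf"` in JSON reports; disk plots place infinite-stability
  basins at a sentinel x with a distinct marker.
* The high-energy prefilter (`prefilter_high_energy`) drops only the *top*
  energy quantile and is off by default; removing low-energy decoys deletes
  focal minima and fabricates basins.
* Test and acceptance workloads use planted sets of 240–720 points
  (recovery sweeps), a 2,650-point two-well benchmark for the
  cluster-vs-basin purity comparison, 200-instance oracle sweeps on ≤ 30
  vertex graphs and ≤ 50 basin lists, and 10,000-draw random-baseline
  calibrations — sizes at which every exact oracle is cheap while all
  asymptotic behaviors (dense cores, sparse fringes, disconnection) appear.

## Known limitations

* Leader clustering and basin membership depend on the shuffle/scan order;
  this is inherent to the algorithm and controlled by explicit seeds, not
  removed.
* One-point basins at sparse fringes carry infinite persistence by the
  saddle definition and cannot be merged; the margin-step ε rule avoids
  creating them, but extremely sparse ensembles may still need a larger ε.
* The reference-superposed distance is an upper bound on lRMSD; with highly
  dissimilar decoys the bound loosens, which can fragment clusters. The
  exact backend exists for when that matters and n is small.
* mmCIF inputs, GDT-TS/TM-score evaluation, disconnectivity graphs and
  decoy generation itself are out of scope.
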