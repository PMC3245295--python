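# Methods

`qkdbn` implements probabilistic inference on signed gene-regulatory
networks when no quantitative training data exist.  The only inputs are the
network topology (who regulates whom) and the sign of each regulation; the
model turns those signs into constraints on conditional probability tables
(CPTs), samples an ensemble of constraint-satisfying parameterizations, and
answers quantitative questions — steady-state expression beliefs,
perturbation phenotypes, cell-state potentials, reprogramming efficiencies —
by model averaging over the ensemble.

## Model

Each gene (or protein complex) is a binary variable: 1 = maximally
expressed/active, 0 = minimally expressed.  A cell state is a complete 0/1
assignment; the belief P(g = 1 | E) under evidence E is treated as linearly
proportional to the gene's expression level, so belief *ratios* between two
conditions predict expression fold changes with all unknown per-gene
proportionality scalars cancelling.

Feedback loops preclude a single acyclic Bayesian network, so the cyclic
network is unrolled into a two-time-slice Bayesian network (2TBN).  Cycle
breaking is greedy: all simple directed cycles are enumerated
(Johnson-style, with a configurable cap), each candidate node is scored
B/(1−A) where B counts the cycles through it and A = 1 marks a must-cut node
(auto-regulation), and the highest-scoring node repeatedly has its outgoing
on-cycle edges redirected across slices until no cycle survives (ties break
toward the lexicographically smallest id).  The selected nodes form the
*outgoing interface*: their joint distribution (a table of size 2^n) is the
only message that must be carried from one time slice to the next.

## Parameter constraints and sampling

An activating edge p → c imposes ceteris-paribus monotonicity: for every
pair of parent configurations differing only in p, P(c = 1 | parents) is
non-decreasing in p (non-increasing for repression).  The prior over the
constrained region is uniform, so the ensemble of CPT samples is an
empirical representation of the model average defined by the qualitative
knowledge alone.

Three samplers cover the practical range:

- **plain rejection** (default, in-degree ≤ 3): i.i.d. uniform tables,
  rejected unless all constraints hold.  Exactly uniform.  Acceptance equals
  the fraction of linear extensions of the parent hypercube and collapses
  combinatorially with in-degree (already ~8·10⁻⁸ at four constrained
  parents), hence:
- **Gibbs within the polytope** (in-degree ≥ 4): each table entry
  conditioned on its hypercube neighbours is uniform on an interval, so
  coordinate sweeps remain feasible and converge to the uniform law on the
  region.  Defaults: 200 burn-in sweeps, 20-sweep thinning; a feasible
  interior start is constructed from the per-configuration count of
  satisfied influences.
- **stratified** (optional): plain rejection followed by occupancy balancing
  across effect-size cells.  It deliberately trades exact uniformity for
  coverage and is therefore *not* the default — the package's own
  uniformity checks (Kolmogorov–Smirnov of the single-activator order
  statistics against Beta(1,2)/Beta(2,1)) would reject it.

Protein complexes are AND gates: P(complex = 1) is 0 unless every component
is present and 1 when all are.  The binding interpretation is physical —
the heterodimer exists exactly when its subunits do — and it is also a
numerical necessity: a uniformly sampled all-present entry has mean 1/2, so
the ensemble-averaged dynamics would dissolve the complex in half of all
ensembles and with it any attractor that depends on it.

Determinism: one child RNG per node, spawned in sorted-node order from the
user seed; identical (seed, n, network) reproduce the ensemble bit for bit.

## Inference

The two-slice model (one slice of all nodes plus previous-slice copies of
the interface) is compiled into a junction tree: moralization, an extra
clique over each interface copy set, greedy min-fill triangulation, and a
maximum-weight spanning forest over clique intersections.  Hugin-style
two-pass message passing yields a consistent tree; the joint probability of
a full state is the product of cluster potentials over sepset potentials,
normalized by the evidence mass.  Zero-mass evidence raises an explicit
impossible-evidence error.

The DBN is rolled forward by attaching the current interface potential to
the previous-slice copies, calibrating, and reading off the new interface
marginal; iteration stops when the L∞ change of that potential drops below
1e−6 (default; `max_steps` 50).  Per-sample steady-state beliefs are then
averaged uniformly over the ensemble.  With no initial state the rollout
starts from the uniform interface distribution (the chain's stationary law
is unique for the strictly positive CPTs the sampler produces); an initial
cell state may be supplied as a point mass instead.

**Clamping is an intervention.**  A hard clamp (overexpression to 1,
knockdown to 0) replaces the node's CPT by a point mass; a soft clamp to
level q replaces it by the prior Bernoulli(q).  Both sever the node's
incoming edges (graph surgery) while the forced value still propagates to
descendants.  The alternative — conditioning, i.e. keeping the clamped
node's CPT as a likelihood term — was implemented first and rejected: in
joint MAP dynamics the likelihood term anti-causally rewards successor
states that "explain" the transgene (e.g. inferring that NANOG's natural
activators must be on because NANOG is overexpressed), which produced
reprogramming by recipes lacking the master regulators entirely.  A
transgene carries no information about its natural regulators, so the
interventional reading is the faithful one.

## MAP state-transition paths

Given a complete previous state, the transition distribution factorizes
over nodes; because CPTs are sampled independently per node, the
ensemble-averaged transition equals (up to Monte-Carlo error) the
transition under per-node ensemble-mean CPTs.  The successor of a state is
the joint argmax over next states of that averaged transition with clamped
nodes held fixed — computed exactly by max-product variable elimination
with traceback, each local argmax preferring the inactive value on
near-ties (relative tolerance 1e−9).  A successor depends on the previous
state only through its interface-node values, so successors are memoized on
those bits; paths terminate at a fixed point, on revisiting a state (limit
cycle, reported as non-converged) or at the step cap.

The per-step potential U(S) = −ln P(S | condition) is evaluated against the
*converged* model: the DBN is first rolled to its steady state once per
ensemble sample, after which any state's probability is a cheap product of
reduced factors summed over the interface copies, normalized exactly so
that potentials satisfy Σ exp(−U) = 1.

## Phenotypes, landscape, screens

- **Reference state**: all master regulators hard-clamped active; this is
  the undisturbed pluripotent condition used as the denominator of
  expression ratios and as the target of similarity scores.
- **Expression ratios**: per unclamped gene, the ratio of steady-state
  beliefs under two conditions, with log2 transform; clamped genes are
  inputs, not predictions, and are excluded; zero denominators are reported
  as missing with a reason.  Validation against measured log2 fold changes
  uses Pearson correlation (pooled and per experiment; standard
  t-approximation p-values from scipy).
- **Landscape**: the master regulators are scanned over a level grid
  (default 0 to 1 in steps of 0.2, soft clamps); each condition's
  steady-state distribution over the projection (default: the 22 markers)
  is normalized, summed and renormalized; U = −ln of the summed
  probability.  Exact variable elimination is used up to a 20-node
  projection, seeded ancestral Monte-Carlo sampling beyond.
- **Recipes**: a recipe overexpresses k genes (and optionally knocks down
  others); complexes cannot be clamped directly.  Efficiency = fraction of
  initial states (markers at the differentiated pattern, the non-markers
  i.i.d. Bernoulli(1/2)) whose MAP path reaches the hESC-marker attractor
  (exact 11-on/11-off match).  When the non-marker space has ≤ `n_init`
  states it is enumerated exhaustively (exact basin fractions); otherwise
  seeded sampling is used (default `n_init` 10,000; raise it for
  publication-scale screens).  Clamps persist for the whole evolution
  (sustained transgene expression) but are *not* written into the step-0
  state: step 0 records the unperturbed differentiated cell, and the
  perturbation acts from the first transition.  Non-converged paths count as
  failures.  Similarity (RMSD, Pearson, Spearman over all nodes; clamped
  genes excludable by flag) compares the recipe's converged belief vector
  with the reference state.  Ranking averages per-criterion ranks
  (efficiency and correlations descending, RMSD ascending, average ranks on
  ties) and flags recipes passing a favourable-side mean ± 3·SD cutoff per
  similarity criterion, computed over the efficiency-positive subset — the
  favourable side is the only reading under which the cutoff prunes.
- **Knockdown screen**: every (base recipe, gene) pair produces one
  evaluation; pairs whose gene is already overexpressed in the base skip
  the knockdown with a warning and report the unaugmented base.  One shared
  ensemble is used for a whole screen.
- **Paths**: dynamical flux = number of MAP paths through each projected
  (step, state); states above a cutoff (default 1000 on the 100,000-path
  scale, rescaled proportionally to the simulated path count) are reported
  as transition states with flux-weighted mean marker vectors.  Trajectory
  averaging treats converged paths as absorbed in their final state;
  absorbed repetition is excluded from flux by default.

## Synthetic fixtures

`make_random_network` draws seeded Erdős–Rényi signed digraphs.
`make_bistable_fixture` plants two mutually repressing activation cycles
(hESC-marker and differentiation-marker modules) with feeder non-markers
and deterministic majority-rule CPTs; both planted patterns are fixed
points and the exact basin of every one of the 2^n initial states is
computed by direct iteration, giving the oracle for efficiency tests.

`make_hesc_skeleton` is a 30-node reduced network carrying the 22 published
marker genes, the OCT4/SOX2/NANOG master flags, the Oct4-Sox2 complex, the
handful of regulations named in the primary literature (GATA6 ⊣ NANOG,
LMCD1 ⊣ GATA6, GATA4 ⊣ GATA6, PBX1 → NANOG, ZIC3 → NANOG, OCT4 ⊣ GATA6)
and an explicitly synthetic scaffold (`SCAFFOLD_EDGES`) that wires the rest
into a bistable switch:

- every ES-side activation runs through the Oct4-Sox2 AND gate, so the
  pluripotency module is structurally unreachable unless OCT4 and SOX2 are
  both active — this plants the finding that recipes with fewer than two
  master regulators never reprogram;
- ES markers, NANOG, GATA6 and the booster non-markers (LMCD1, MYC,
  PRDM14) auto-regulate, so previous-slice values pin both modules and
  single-step global flips between attractors pay a multiplicative cost per
  pinned node;
- the differentiation module is a self-sustaining GATA6 hub whose collapse
  under a recipe requires particular persistent-booster initial states,
  which is what spreads efficiency strictly between 0 and 1 and makes
  clamping MYC or PRDM14 (or knocking down GATA6) genuinely raise it.

The skeleton is deliberately **not** the published 52-node network: every
output derived from it carries provenance `"skeleton"`, and the
quantitative screen-reproduction test refuses to run against it.  Known
fixture limitations: SOX2 is not replaceable by NANOG (OCT4+NANOG recipes
score 0 here, unlike on the full network), and KLF4/MYC contribute through
the differentiation side only, so the skeleton's efficiency *ordering*
among productive recipes is coarser than the published one.  Passing tests
on the skeleton therefore demonstrate the engine's mechanics and the
qualitative laws, not the published efficiencies.

## Numerical choices and problem sizes

Potential products are evaluated in log space with explicit zero guards;
Hugin division defines 0/0 = 0; calibration consistency is audited to
1e−10.  The junction-tree cluster cap is 22 variables; CPT sampling warns
at in-degree 9 and errors beyond 12.  The test suite and the acceptance
script run the oracle-equivalence checks on 25–50 random networks of 5–8
nodes, sampler calibration at n = 5000, the landscape on the 8-node
bistable fixture with a 3-level master grid, and the skeleton screens with
100-sample ensembles and 256 exhaustive initializations — sizes chosen so
exhaustive enumeration oracles remain exact while the whole pipeline is
exercised end to end.

## Known limitations

Variables are binary (m = 2); approximate inference is out of scope, so
treewidth guards rather than sampling protect against dense inputs.  The
data-likelihood path of full Bayesian model averaging is not implemented —
the engine operates in the no-quantitative-data regime by design.  Absolute
expression levels are not identifiable (only ratios and rank correlations
are exposed).  MAP paths report a single most-probable successor; mass
split across near-tied successors is not tracked.
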