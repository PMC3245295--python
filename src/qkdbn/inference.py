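"""Exact inference on the two-slice template.

The template is compiled into a junction tree over one slice of variables
plus the previous-slice copies of the interface nodes.  Rolling the DBN
forward only requires the joint potential over the outgoing interface (size
2^n for n interface nodes): at each step the tree is calibrated with the
current interface potential attached to the previous-slice copies, and the
new interface potential is read off the current slice.  Iterating to a fixed
point of that potential yields steady-state (filtering) marginals; model
averaging takes the uniform mean of the per-sample beliefs.

MAP evolution freezes the previous slice at a concrete cell state and picks
the successor state maximizing the ensemble-averaged transition probability,
which factorizes over nodes because CPTs are sampled independently per node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._factors import Factor, _elimination_order, eliminate, product
from .constraints import ParameterEnsemble
from .network import TwoSliceTemplate, prev_var

CellState = dict[str, int]

DEFAULT_MAX_STEPS = 50
DEFAULT_TOL = 1e-6
#: relative tolerance under which two candidate MAP scores count as tied
MAP_TIE_RTOL = 1e-9


class ImpossibleEvidenceError(RuntimeError):
    """All calibrated potentials are zero: the evidence has probability 0."""


class TreewidthError(RuntimeError):
    """A junction-tree cluster exceeds the configured size cap."""


# ---------------------------------------------------------------------------
# Evidence
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Evidence:
    """Hard and soft clamps on node activities.

    Hard clamps condition a node to 0/1 (knockdown / overexpression); a soft
    clamp to level q replaces the node's CPT by the prior P(node=1)=q, pinning
    its marginal at every slice.  ``scope`` controls whether clamps apply at
    every slice (sustained perturbation, the default) or only to the initial
    slice.
    """

    hard: Mapping[str, int] = field(default_factory=dict)
    soft: Mapping[str, float] = field(default_factory=dict)
    scope: str = "every_slice"

    def __post_init__(self) -> None:
        overlap = set(self.hard) & set(self.soft)
        if overlap:
            raise ValueError(f"nodes in both hard and soft clamps: {sorted(overlap)}")
        for node, v in self.hard.items():
            if v not in (0, 1):
                raise ValueError(f"hard clamp {node}={v!r} not in {{0,1}}")
        for node, q in self.soft.items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"soft clamp {node}={q!r} outside [0,1]")
        if self.scope not in ("every_slice", "initial_only"):
            raise ValueError(f"unknown evidence scope {self.scope!r}")

    @property
    def clamped(self) -> set[str]:
        return set(self.hard) | set(self.soft)

    def level(self, node: str) -> float:
        if node in self.hard:
            return float(self.hard[node])
        return float(self.soft[node])


EMPTY_EVIDENCE = Evidence()


# ---------------------------------------------------------------------------
# Junction tree
# ---------------------------------------------------------------------------

@dataclass
class JunctionTree:
    """A junction tree (forest) over one slice plus previous-slice interface."""

    clusters: list[tuple[str, ...]]
    edges: list[tuple[int, int, tuple[str, ...]]]  # (i, j, sepset)
    template: TwoSliceTemplate

    def neighbors(self) -> dict[int, list[tuple[int, tuple[str, ...]]]]:
        adj: dict[int, list[tuple[int, tuple[str, ...]]]] = {
            i: [] for i in range(len(self.clusters))
        }
        for i, j, sep in self.edges:
            adj[i].append((j, sep))
            adj[j].append((i, sep))
        return adj

    def cluster_containing(self, variables: Iterable[str]) -> int:
        want = set(variables)
        for i, c in enumerate(self.clusters):
            if want <= set(c):
                return i
        raise KeyError(f"no cluster contains {sorted(want)}")


def _triangulate(
    adjacency: dict[str, set[str]], size_cap_vars: int
) -> list[tuple[str, ...]]:
    """Min-fill elimination; returns the maximal cliques of the chordal fill-in."""
    adj = {v: set(ns) for v, ns in adjacency.items()}
    cliques: list[frozenset[str]] = []
    remaining = set(adj)
    while remaining:

        def fill_count(v: str) -> int:
            ns = sorted(adj[v])
            return sum(
                1 for i, a in enumerate(ns) for b in ns[i + 1 :] if b not in adj[a]
            )

        v = min(sorted(remaining), key=fill_count)
        clique = frozenset(adj[v] | {v})
        if len(clique) > size_cap_vars:
            raise TreewidthError(
                f"cluster of {len(clique)} variables exceeds cap {size_cap_vars}"
            )
        cliques.append(clique)
        ns = set(adj[v])
        for a in ns:
            adj[a].update(ns - {a})
            adj[a].discard(v)
        del adj[v]
        remaining.discard(v)
    maximal = [c for c in cliques if not any(c < other for other in cliques)]
    # deduplicate while preserving deterministic order
    seen: set[frozenset[str]] = set()
    out: list[tuple[str, ...]] = []
    for c in maximal:
        if c not in seen:
            seen.add(c)
            out.append(tuple(sorted(c)))
    return out


def build_junction_tree(
    template: TwoSliceTemplate, size_cap_vars: int = 22
) -> JunctionTree:
    """Compile the two-slice model into a junction tree.

    The moral graph gets two extra cliques -- the previous-slice interface
    copies and the current-slice interface set -- so the interface potential
    (the forwarding message of size 2^n) can be attached and extracted.
    """
    variables = set(template.network.node_ids)
    prev_vars = [prev_var(i) for i in template.interface_sorted()]
    variables.update(prev_vars)

    adjacency: dict[str, set[str]] = {v: set() for v in sorted(variables)}

    def connect(group: Sequence[str]) -> None:
        for a in group:
            for b in group:
                if a != b:
                    adjacency[a].add(b)

    for node in template.network.node_ids:
        family = [node] + [
            prev_var(src) if inter else src
            for src, _, inter in template.cpt_parents(node)
        ]
        connect(family)
    if prev_vars:
        connect(prev_vars)
        connect(list(template.interface_sorted()))

    clusters = _triangulate(adjacency, size_cap_vars)

    # Maximum-weight spanning forest over cluster intersections (Kruskal).
    candidates = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            sep = tuple(sorted(set(clusters[i]) & set(clusters[j])))
            if sep:
                candidates.append((-len(sep), i, j, sep))
    candidates.sort()
    parent = list(range(len(clusters)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[int, int, tuple[str, ...]]] = []
    for _, i, j, sep in candidates:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            edges.append((i, j, sep))
    return JunctionTree(clusters=clusters, edges=edges, template=template)


# ---------------------------------------------------------------------------
# Factor construction for one slice
# ---------------------------------------------------------------------------

def node_cpt_factors(
    template: TwoSliceTemplate,
    sample: Mapping[str, np.ndarray],
    evidence: Evidence = EMPTY_EVIDENCE,
    apply_evidence: bool = True,
) -> dict[str, Factor]:
    """Per-node CPT factors of one slice (inter-slice parents read from the
    previous-slice copies).

    Clamps are interventions (graph surgery): a hard clamp replaces the
    node's CPT by a point mass and a soft clamp by the prior Bernoulli(q),
    severing the incoming edges.  The forced value still propagates to
    descendants, but does not act as anti-causal evidence on the regulators
    -- an overexpressed transgene does not imply its natural activators were
    active."""
    out: dict[str, Factor] = {}
    for node in template.network.node_ids:
        if apply_evidence and node in evidence.hard:
            out[node] = Factor.indicator(node, evidence.hard[node])
            continue
        if apply_evidence and node in evidence.soft:
            out[node] = Factor.bernoulli(node, evidence.soft[node])
            continue
        parents = template.cpt_parents(node)
        names = [prev_var(src) if inter else src for src, _, inter in parents]
        out[node] = Factor.cpt(node, names, np.asarray(sample[node]))
    return out


def slice_factors(
    template: TwoSliceTemplate,
    sample: Mapping[str, np.ndarray],
    evidence: Evidence = EMPTY_EVIDENCE,
    interface_potential: Factor | None = None,
    apply_evidence: bool = True,
) -> list[Factor]:
    """Factors of one slice: per-node CPTs (with clamps applied as
    interventions) plus the interface potential on the previous-slice
    copies."""
    factors = list(
        node_cpt_factors(template, sample, evidence, apply_evidence).values()
    )
    if template.n_interface:
        if interface_potential is None:
            interface_potential = uniform_interface_potential(template)
        factors.append(interface_potential)
    return factors


def uniform_interface_potential(template: TwoSliceTemplate) -> Factor:
    n = template.n_interface
    prev_names = tuple(prev_var(i) for i in template.interface_sorted())
    return Factor(prev_names, np.full((2,) * n, 0.5**n))


def point_interface_potential(
    template: TwoSliceTemplate, state: Mapping[str, int]
) -> Factor:
    """Point-mass interface potential at a concrete previous-slice state."""
    prev_names = tuple(prev_var(i) for i in template.interface_sorted())
    table = np.zeros((2,) * len(prev_names))
    table[tuple(state[i] for i in template.interface_sorted())] = 1.0
    return Factor(prev_names, table)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibratedTree:
    """A consistent junction tree: cluster/sepset potentials plus mass."""

    jt: JunctionTree
    potentials: list[Factor]
    sepset_potentials: dict[tuple[int, int], Factor]
    log_mass: float  # log of the total unnormalized mass (product over trees)
    roots: list[int]

    def marginal(self, variables: Sequence[str]) -> Factor:
        """Normalized marginal over variables jointly contained in a cluster."""
        i = self.jt.cluster_containing(variables)
        return self.potentials[i].marginalize_to(variables).normalize()

    def belief(self, node: str) -> float:
        return float(self.marginal([node]).table[1])

    def log_joint(self, state: Mapping[str, int]) -> float:
        """log P(state | evidence) for a complete assignment over tree vars."""
        total = 0.0
        for pot in self.potentials:
            v = pot.value(state)
            if v <= 0.0:
                return -math.inf
            total += math.log(v)
        for sep_pot in self.sepset_potentials.values():
            v = sep_pot.value(state)
            if v <= 0.0:
                return -math.inf
            total -= math.log(v)
        return total - self.log_mass

    def joint_probability(self, state: Mapping[str, int]) -> float:
        missing = {v for c in self.jt.clusters for v in c} - set(state)
        if missing:
            raise ValueError(f"incomplete state; missing {sorted(missing)}")
        return math.exp(self.log_joint(state))

    def max_consistency_gap(self) -> float:
        """Largest disagreement between neighbouring cluster/sepset marginals
        (after normalization); ~0 for a calibrated tree."""
        worst = 0.0
        for i, j, sep in self.jt.edges:
            mi = self.potentials[i].marginalize_to(sep).normalize()
            mj = self.potentials[j].marginalize_to(sep).normalize()
            worst = max(worst, float(np.abs(mi.table - mj.table).max()))
        return worst


def calibrate(
    jt: JunctionTree,
    factors: Sequence[Factor],
) -> CalibratedTree:
    """Two-pass Hugin message passing to a consistent tree.

    Raises :class:`ImpossibleEvidenceError` when the evidence has zero mass.
    """
    potentials = [Factor.ones(c) for c in jt.clusters]
    for f in factors:
        i = jt.cluster_containing(f.vars)
        potentials[i] = potentials[i] * f
    sepsets: dict[tuple[int, int], Factor] = {
        (min(i, j), max(i, j)): Factor.ones(sep) for i, j, sep in jt.edges
    }
    sep_of = {(min(i, j), max(i, j)): sep for i, j, sep in jt.edges}
    adj = jt.neighbors()

    def pass_message(src: int, dst: int) -> None:
        key = (min(src, dst), max(src, dst))
        sep = sep_of[key]
        psi = potentials[src].marginalize_to(sep)
        potentials[dst] = potentials[dst] * psi.divide(sepsets[key])
        sepsets[key] = psi

    visited: set[int] = set()
    roots: list[int] = []
    for start in range(len(jt.clusters)):
        if start in visited:
            continue
        roots.append(start)
        # iterative DFS to get a traversal order within this component
        order: list[tuple[int, int]] = []  # (node, parent)
        stack = [(start, -1)]
        while stack:
            u, p = stack.pop()
            if u in visited:
                continue
            visited.add(u)
            order.append((u, p))
            for v, _ in adj[u]:
                if v not in visited:
                    stack.append((v, u))
        # collect: leaves toward root
        for u, p in reversed(order):
            if p >= 0:
                pass_message(u, p)
        # distribute: root toward leaves
        for u, p in order:
            if p >= 0:
                pass_message(p, u)

    log_mass = 0.0
    for r in roots:
        z = float(potentials[r].table.sum())
        if z <= 0.0:
            raise ImpossibleEvidenceError("evidence has zero probability")
        log_mass += math.log(z)
    return CalibratedTree(
        jt=jt,
        potentials=potentials,
        sepset_potentials=sepsets,
        log_mass=log_mass,
        roots=roots,
    )


# ---------------------------------------------------------------------------
# Model-averaged steady-state marginals
# ---------------------------------------------------------------------------

@dataclass
class MarginalProfile:
    """Model-averaged beliefs P(node = 1 | evidence) at steady state."""

    belief: dict[str, float]
    evidence: Evidence
    converged: bool
    steps: int

    def vector(self, nodes: Sequence[str]) -> np.ndarray:
        return np.array([self.belief[n] for n in nodes])


def _rollout_sample(
    jt: JunctionTree,
    template: TwoSliceTemplate,
    sample: Mapping[str, np.ndarray],
    evidence: Evidence,
    initial_state: Mapping[str, int] | None,
    max_steps: int,
    tol: float,
) -> tuple[CalibratedTree, Factor | None, bool, int]:
    """Iterate the interface potential to its fixed point for one sample."""
    if template.n_interface == 0:
        cal = calibrate(jt, slice_factors(template, sample, evidence))
        return cal, None, True, 1
    if initial_state is not None:
        alpha = point_interface_potential(template, initial_state)
    else:
        alpha = uniform_interface_potential(template)
    cur_iface = list(template.interface_sorted())
    prev_names = tuple(prev_var(i) for i in cur_iface)
    converged = False
    steps = 0
    cal: CalibratedTree | None = None
    for step in range(1, max_steps + 1):
        steps = step
        apply_ev = evidence.scope == "every_slice" or step == 1
        factors = slice_factors(
            template, sample, evidence, interface_potential=alpha,
            apply_evidence=apply_ev,
        )
        cal = calibrate(jt, factors)
        new_table = cal.marginal(cur_iface).table
        alpha_new = Factor(prev_names, new_table)
        if float(np.abs(alpha_new.table - alpha.table).max()) < tol:
            converged = True
            alpha = alpha_new
            break
        alpha = alpha_new
    assert cal is not None
    return cal, alpha, converged, steps


def infer_marginals(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    evidence: Evidence = EMPTY_EVIDENCE,
    max_steps: int = DEFAULT_MAX_STEPS,
    tol: float = DEFAULT_TOL,
    initial_state: Mapping[str, int] | None = None,
    jt: JunctionTree | None = None,
) -> MarginalProfile:
    """Steady-state beliefs averaged uniformly over the CPT ensemble.

    Each sample's DBN is rolled forward via the interface potential until the
    L-infinity change of that potential drops below ``tol`` (or ``max_steps``
    is hit, in which case ``converged`` is False).  Clamped nodes report
    their clamped level exactly.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    if jt is None:
        jt = build_junction_tree(template)
    nodes = template.network.node_ids
    acc = np.zeros(len(nodes))
    all_converged = True
    max_used = 0
    for sample in ensemble.samples:
        cal, _, conv, steps = _rollout_sample(
            jt, template, sample, evidence, initial_state, max_steps, tol
        )
        all_converged &= conv
        max_used = max(max_used, steps)
        acc += np.array([cal.belief(n) for n in nodes])
    beliefs = dict(zip(nodes, acc / len(ensemble)))
    for node in evidence.clamped:
        beliefs[node] = evidence.level(node)
    return MarginalProfile(
        belief=beliefs, evidence=evidence, converged=all_converged, steps=max_used
    )


# ---------------------------------------------------------------------------
# Steady-state potential evaluation
# ---------------------------------------------------------------------------

class PotentialEvaluator:
    """Evaluates steady-state probabilities / potentials of full cell states.

    Converges the DBN once per ensemble sample under a fixed condition, then
    evaluates P(state | condition) cheaply per state by reducing the slice
    factors at the state and summing out the previous-slice interface copies.
    The cell-state potential is U(S) = -ln P(S | condition).
    """

    def __init__(
        self,
        ensemble: ParameterEnsemble,
        template: TwoSliceTemplate,
        condition: Evidence = EMPTY_EVIDENCE,
        max_steps: int = DEFAULT_MAX_STEPS,
        tol: float = DEFAULT_TOL,
        jt: JunctionTree | None = None,
    ):
        self.template = template
        self.condition = condition
        if jt is None:
            jt = build_junction_tree(template)
        self.jt = jt
        # per sample: (all factors, log normalizer, per-node CPTs, interface pot.)
        self._per_sample: list[
            tuple[list[Factor], float, dict[str, Factor], Factor | None]
        ] = []
        self.converged = True
        for sample in ensemble.samples:
            _, alpha, conv, _ = _rollout_sample(
                jt, template, sample, condition, None, max_steps, tol
            )
            self.converged &= conv
            cpts = node_cpt_factors(template, sample, condition)
            factors = list(cpts.values())
            if alpha is not None:
                factors.append(alpha)
            # exact normalizer of this factor set, so potentials sum to one
            mass = float(eliminate(factors, ()).table)
            if mass <= 0.0:
                raise ImpossibleEvidenceError("condition has zero probability")
            self._per_sample.append((factors, math.log(mass), cpts, alpha))

    def probability(self, state: Mapping[str, int]) -> float:
        """Model-averaged steady-state P(state | condition)."""
        missing = set(self.template.network.node_ids) - set(state)
        if missing:
            raise ValueError(f"incomplete state; missing {sorted(missing)}")
        vals = []
        for factors, log_mass, _, _ in self._per_sample:
            reduced = [f.reduce(state) for f in factors]
            mass = product(reduced).marginalize_to(()).table
            vals.append(float(mass) / math.exp(log_mass))
        return float(np.mean(vals))

    def potential(self, state: Mapping[str, int]) -> float:
        """U(S) = -ln P(S | condition); +inf for zero-probability states."""
        p = self.probability(state)
        return -math.log(p) if p > 0 else math.inf

    def projection_distribution(
        self,
        projection: Sequence[str],
        exact_cap: int = 20,
        n_draws: int = 100_000,
        seed: int = 0,
    ) -> Factor:
        """Model-averaged steady-state distribution over a node subset.

        Exact variable elimination when the projection is small enough, else
        seeded Monte-Carlo forward sampling.
        """
        projection = tuple(sorted(projection))
        if len(projection) <= exact_cap:
            acc = np.zeros((2,) * len(projection))
            for factors, _, _, _ in self._per_sample:
                marg = eliminate(factors, projection).normalize()
                acc += marg.table
            return Factor(projection, acc / len(self._per_sample))
        return self._mc_projection(projection, n_draws, seed)

    def _mc_projection(
        self, projection: tuple[str, ...], n_draws: int, seed: int
    ) -> Factor:
        """Seeded ancestral sampling over the steady-state slice, with
        rejection of draws inconsistent with hard evidence."""
        rng = np.random.default_rng(seed)
        counts = np.zeros((2,) * len(projection))
        order = self.template.topological_order()
        per = max(n_draws // len(self._per_sample), 1)
        total = 0
        for _, _, cpts, iface_f in self._per_sample:
            for _ in range(per):
                state: dict[str, int] = {}
                if iface_f is not None:
                    probs = (iface_f.table / iface_f.table.sum()).ravel()
                    flat = rng.choice(probs.size, p=probs)
                    bits = np.unravel_index(flat, iface_f.table.shape)
                    state.update(dict(zip(iface_f.vars, map(int, bits))))
                ok = True
                for node in order:
                    f = cpts[node]
                    p1 = float(
                        f.reduce({v: state[v] for v in f.vars if v != node}).table[1]
                    )
                    val = int(rng.uniform() < p1)
                    if node in self.condition.hard and val != self.condition.hard[node]:
                        ok = False
                        break
                    state[node] = val
                if not ok:
                    continue
                counts[tuple(state[v] for v in projection)] += 1
                total += 1
        if total == 0:
            raise ImpossibleEvidenceError("no Monte-Carlo draw satisfied evidence")
        return Factor(projection, counts / total)


# ---------------------------------------------------------------------------
# MAP evolution
# ---------------------------------------------------------------------------

@dataclass
class PathRecord:
    """A MAP state-transition path from an initial cell state."""

    states: list[CellState]
    potentials: list[float] | None
    converged_to: str  # hesc_attractor | other_attractor | none
    fixed_point: bool
    steps: int


def _lex_map_assignment(
    factors: list[Factor], variables: Sequence[str], rtol: float = MAP_TIE_RTOL
) -> dict[str, int]:
    """Joint argmax of a product of factors by max-product elimination with
    traceback.  Each per-variable argmax prefers 0 on (near-)ties, so exact
    ties resolve deterministically toward inactive states."""
    live = list(factors)
    order = _elimination_order(live, set(variables))
    trace: list[tuple[str, Factor]] = []
    for v in order:
        bucket = [f for f in live if v in f.vars]
        live = [f for f in live if v not in f.vars]
        prod = product(bucket) if bucket else Factor.ones((v,))
        trace.append((v, prod))
        live.append(prod.marginalize_to(set(prod.vars) - {v}, op="max"))
    assignment: dict[str, int] = {}
    for v, prod in reversed(trace):
        t = prod.reduce({u: assignment[u] for u in prod.vars if u != v}).table
        assignment[v] = 0 if t[0] >= t[1] * (1.0 - rtol) else 1
    for v in variables:
        assignment.setdefault(v, 0)
    return assignment


class MapEvolver:
    """Deterministic MAP successor function of the averaged transition model.

    The successor of a state depends on the previous slice only through the
    interface-node values (inter-slice edges all originate there), so results
    are memoized on those bits; clamped nodes are held fixed.
    """

    def __init__(
        self,
        ensemble: ParameterEnsemble,
        template: TwoSliceTemplate,
        clamps: Evidence = EMPTY_EVIDENCE,
    ):
        self.template = template
        self.clamps = clamps
        self.mean = ensemble.mean_cpts()
        self._cache: dict[tuple[int, ...], CellState] = {}
        self._iface = template.interface_sorted()

    def successor(self, state: Mapping[str, int]) -> CellState:
        key = tuple(int(state[i]) for i in self._iface)
        hit = self._cache.get(key)
        if hit is not None:
            return dict(hit)
        fixed: dict[str, int] = dict(self.clamps.hard)
        factors: list[Factor] = []
        free: list[str] = []
        for node in self.template.network.node_ids:
            if node in fixed:
                # intervention: the clamped node's CPT is cut out entirely
                continue
            free.append(node)
            if node in self.clamps.soft:
                factors.append(Factor.bernoulli(node, self.clamps.soft[node]))
                continue
            parents = self.template.cpt_parents(node)
            table = np.asarray(self.mean[node])
            # freeze inter-slice parents at the previous state's values
            idx = tuple(
                int(state[src]) if inter else slice(None)
                for src, _, inter in parents
            )
            intra = [src for src, _, inter in parents if not inter]
            factors.append(Factor.cpt(node, intra, table[idx]))
        factors = [
            f.reduce({v: fixed[v] for v in f.vars if v in fixed}) for f in factors
        ]
        nxt = dict(fixed)
        nxt.update(_lex_map_assignment(factors, free))
        self._cache[key] = dict(nxt)
        return nxt


def evolve_map(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    initial: Mapping[str, int],
    clamps: Evidence = EMPTY_EVIDENCE,
    max_steps: int = DEFAULT_MAX_STEPS,
    evolver: MapEvolver | None = None,
    potential_evaluator: PotentialEvaluator | None = None,
) -> PathRecord:
    """Follow the MAP state-transition path from an initial cell state.

    At each step the successor maximizes the ensemble-averaged transition
    probability given the previous state, with clamped nodes fixed.  The path
    terminates at a fixed point, on revisiting a state (limit cycle, flagged
    ``none``), or at ``max_steps``.  Per-step potentials U = -ln P(state) are
    recorded when a :class:`PotentialEvaluator` is supplied.
    """
    missing = set(template.network.node_ids) - set(initial)
    if missing:
        raise ValueError(f"initial state missing nodes {sorted(missing)}")
    if evolver is None:
        evolver = MapEvolver(ensemble, template, clamps)
    state: CellState = {k: int(initial[k]) for k in template.network.node_ids}
    states = [dict(state)]
    seen = {tuple(sorted(state.items()))}
    fixed_point = False
    for _ in range(max_steps):
        nxt = evolver.successor(state)
        if nxt == state:
            fixed_point = True
            break
        key = tuple(sorted(nxt.items()))
        states.append(dict(nxt))
        state = nxt
        if key in seen:
            break
        seen.add(key)

    if fixed_point:
        hes = template.network.hesc_pattern()
        marker_bits = {m: state[m] for m in hes}
        converged_to = "hesc_attractor" if marker_bits == hes else "other_attractor"
    else:
        converged_to = "none"
    potentials = None
    if potential_evaluator is not None:
        potentials = [potential_evaluator.potential(s) for s in states]
    return PathRecord(
        states=states,
        potentials=potentials,
        converged_to=converged_to,
        fixed_point=fixed_point,
        steps=len(states),
    )
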