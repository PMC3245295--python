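"""Qualitative parameter constraints and constraint-satisfying CPT ensembles.

Each signed edge is translated into a ceteris-paribus monotonicity constraint
on the child's conditional probability table: for every pair of parent
configurations differing only in that parent, P(child = 1 | parents) must be
non-decreasing in an activator and non-increasing in a repressor.  The prior
over the constrained region is uniform, so a sampled ensemble of CPTs is an
empirical draw from the model average defined by the qualitative knowledge.

Samplers
--------
plain rejection
    i.i.d. uniform proposals for each table, rejected unless every
    monotonicity constraint holds.  Exactly uniform on the constrained
    region; feasible up to in-degree ~3 (the acceptance probability is the
    fraction of linear extensions of the parent hypercube and collapses
    combinatorially beyond that).
Gibbs
    coordinate-wise resampling inside the constraint polytope: each table
    entry conditioned on its hypercube neighbours is uniform on an interval,
    so sweeps stay exactly inside the region and converge to the uniform
    distribution.  Used automatically for in-degree >= 4.
stratified
    plain rejection followed by occupancy balancing across effect-sign
    cells; kept as an exploration option (it deliberately trades exact
    uniformity for coverage).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .network import RegulatoryNetwork, TwoSliceTemplate

#: in-degree above which a warning / hard error is raised
WARN_IN_DEGREE = 8
MAX_IN_DEGREE = 12

#: in-degree at which the sampler switches from rejection to Gibbs
GIBBS_IN_DEGREE = 4


class SamplingError(RuntimeError):
    """Raised when the rejection sampler cannot reach its quota."""


@dataclass(frozen=True)
class Constraint:
    """Monotonicity of P(node=1 | parents) in one parent."""

    node: str
    parent: str
    direction: int  # +1 increasing (activator), -1 decreasing (repressor)


@dataclass
class ConstraintSet:
    """Per-node qualitative constraints plus the conjunctive-complex flag."""

    by_node: dict[str, tuple[Constraint, ...]]
    conjunctive_complexes: frozenset[str] = frozenset()

    def for_node(self, node: str) -> tuple[Constraint, ...]:
        return self.by_node.get(node, ())

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_node.values())


def build_constraints(
    net: RegulatoryNetwork, conjunctive_complexes: bool = True
) -> ConstraintSet:
    """One monotonicity constraint per edge; activation -> increasing,
    repression -> decreasing.

    With ``conjunctive_complexes`` (the default), protein-complex nodes are
    additionally pinned to P(complex=1 | any component absent) = 0 --
    physical binding requires every component.
    """
    by_node: dict[str, list[Constraint]] = {}
    for src, tgt, sign in net.edges:
        by_node.setdefault(tgt, []).append(Constraint(tgt, src, sign))
    conj = frozenset(net.complexes) if conjunctive_complexes else frozenset()
    return ConstraintSet(
        by_node={k: tuple(v) for k, v in by_node.items()},
        conjunctive_complexes=conj,
    )


# ---------------------------------------------------------------------------
# Constraint checking
# ---------------------------------------------------------------------------

def _directions_for(
    template: TwoSliceTemplate, constraints: ConstraintSet, node: str
) -> list[int]:
    """Per-CPT-axis monotonicity direction (0 = unconstrained parent)."""
    parents = template.cpt_parents(node)
    cons = {c.parent: c.direction for c in constraints.for_node(node)}
    return [cons.get(src, 0) for src, _, _ in parents]


def table_satisfies(
    table: np.ndarray, directions: list[int], atol: float = 0.0
) -> bool:
    """Check coordinate-wise monotonicity of a CPT in each constrained axis."""
    for axis, d in enumerate(directions):
        if d == 0:
            continue
        diff = np.diff(table, axis=axis)
        if d > 0 and np.any(diff < -atol):
            return False
        if d < 0 and np.any(diff > atol):
            return False
    return True


def _complex_table_ok(table: np.ndarray) -> bool:
    mask = np.ones_like(table, dtype=bool)
    mask[(slice(1, 2),) * table.ndim] = False  # all-components-present corner
    return bool(np.all(table[mask] == 0.0))


def audit_sample(
    sample: Mapping[str, np.ndarray],
    template: TwoSliceTemplate,
    constraints: ConstraintSet,
) -> bool:
    """Post-hoc audit: does every CPT of a sample satisfy its constraints?"""
    for node, table in sample.items():
        if not table_satisfies(np.asarray(table), _directions_for(template, constraints, node)):
            return False
        if node in constraints.conjunctive_complexes and table.ndim > 0:
            if not _complex_table_ok(np.asarray(table)):
                return False
        if np.any((table < 0) | (table > 1)):
            return False
    return True


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _rejection_tables(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    directions: list[int],
    n: int,
    max_proposals: int,
) -> tuple[np.ndarray, int, int]:
    """Vectorized rejection sampling of ``n`` monotone tables."""
    kept: list[np.ndarray] = []
    proposed = accepted = 0
    batch = max(4 * n, 256)
    while sum(len(k) for k in kept) < n:
        if proposed >= max_proposals:
            raise SamplingError(
                f"rejection sampler exhausted {max_proposals} proposals "
                f"(acceptance {accepted}/{proposed}); in-degree too high?"
            )
        cand = rng.uniform(size=(batch,) + shape)
        ok = np.ones(batch, dtype=bool)
        for axis, d in enumerate(directions):
            if d == 0:
                continue
            diff = np.diff(cand, axis=axis + 1)
            flat = diff.reshape(batch, -1)
            ok &= np.all(flat >= 0, axis=1) if d > 0 else np.all(flat <= 0, axis=1)
        proposed += batch
        accepted += int(ok.sum())
        kept.append(cand[ok])
    stacked = np.concatenate(kept, axis=0)[:n]
    return stacked, accepted, proposed


def _feasible_start(shape: tuple[int, ...], directions: list[int]) -> np.ndarray:
    """A point strictly inside the monotone polytope: the normalized count of
    satisfied qualitative influences at each parent configuration."""
    d = len(shape)
    table = np.zeros(shape)
    for config in itertools.product((0, 1), repeat=d):
        score = sum(
            (v if sg > 0 else 1 - v) if sg != 0 else 0.5
            for v, sg in zip(config, directions)
        )
        table[config] = (score + 0.5) / (d + 1)
    return table


def _gibbs_tables(
    rng: np.random.Generator,
    shape: tuple[int, ...],
    directions: list[int],
    n: int,
    burn_in: int = 200,
    thin: int = 20,
) -> np.ndarray:
    """Gibbs sampling of monotone tables: each entry, given its hypercube
    neighbours along constrained axes, is uniform on an interval."""
    d = len(shape)
    configs = list(itertools.product((0, 1), repeat=d))
    # Precompute, per entry, the neighbour entries bounding it below/above.
    lowers: dict[tuple[int, ...], list[tuple[int, ...]]] = {c: [] for c in configs}
    uppers: dict[tuple[int, ...], list[tuple[int, ...]]] = {c: [] for c in configs}
    for c in configs:
        for axis, sg in enumerate(directions):
            if sg == 0:
                continue
            other = list(c)
            other[axis] = 1 - c[axis]
            other_t = tuple(other)
            # increasing: entry with parent=1 must be >= entry with parent=0
            hi_is_self = (c[axis] == 1) if sg > 0 else (c[axis] == 0)
            if hi_is_self:
                lowers[c].append(other_t)
            else:
                uppers[c].append(other_t)

    table = _feasible_start(shape, directions)
    out = np.empty((n,) + shape)
    collected = 0
    sweeps_needed = burn_in + thin * n
    uniforms = rng.uniform(size=(sweeps_needed, len(configs)))
    for sweep in range(sweeps_needed):
        for j, c in enumerate(configs):
            lo = max((table[o] for o in lowers[c]), default=0.0)
            hi = min((table[o] for o in uppers[c]), default=1.0)
            table[c] = lo + (hi - lo) * uniforms[sweep, j]
        if sweep >= burn_in and (sweep - burn_in) % thin == thin - 1:
            out[collected] = table
            collected += 1
            if collected == n:
                break
    return out


def _sign_cell(table: np.ndarray, directions: list[int]) -> tuple[int, ...]:
    """Occupancy cell of a table: per constrained axis, whether the average
    effect of that parent exceeds the single-parent expectation (1/3)."""
    cell = []
    for axis, d in enumerate(directions):
        if d == 0:
            cell.append(0)
            continue
        gap = float(np.abs(np.diff(table, axis=axis)).mean())
        cell.append(int(gap > 1.0 / 3.0))
    return tuple(cell)


@dataclass
class ParameterEnsemble:
    """A seeded ensemble of constraint-satisfying CPT parameterizations.

    ``samples[k][node]`` is P(node=1 | parent config) with shape
    (2,)**in-degree, axes ordered as ``template.cpt_parents(node)``.
    """

    samples: list[dict[str, np.ndarray]]
    seed: int
    n_requested: int
    acceptance_rate: float
    mode: str = "plain"
    _mean_cache: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.samples)

    def mean_cpts(self) -> dict[str, np.ndarray]:
        """Per-node ensemble-mean CPT (the averaged transition model)."""
        if not self._mean_cache:
            for node in self.samples[0]:
                self._mean_cache[node] = np.mean(
                    [s[node] for s in self.samples], axis=0
                )
        return self._mean_cache


def sample_cpt_ensemble(
    template: TwoSliceTemplate,
    constraints: ConstraintSet,
    n: int = 100,
    seed: int = 0,
    mode: str = "plain",
    max_proposals: int = 2_000_000,
) -> ParameterEnsemble:
    """Draw ``n`` constraint-satisfying CPT parameterizations.

    Identical ``(seed, n, network)`` reproduce the ensemble bit-for-bit: each
    node gets an independent child RNG spawned in sorted-node order.  Nodes
    with in-degree >= 4 use the Gibbs sampler (rejection acceptance rates are
    astronomically small there); the reported ``acceptance_rate`` covers the
    rejection-sampled nodes only.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("plain", "stratified"):
        raise ValueError(f"unknown sampling mode {mode!r}")
    nodes = template.network.node_ids
    seeds = np.random.SeedSequence(seed).spawn(len(nodes))
    per_node: dict[str, np.ndarray] = {}
    accepted_total = proposed_total = 0
    for node, ss in zip(nodes, seeds):
        rng = np.random.default_rng(ss)
        parents = template.cpt_parents(node)
        d = len(parents)
        if d > MAX_IN_DEGREE:
            raise SamplingError(f"node {node!r} in-degree {d} exceeds {MAX_IN_DEGREE}")
        if d > WARN_IN_DEGREE:
            warnings.warn(f"node {node!r} has in-degree {d}; CPT has {2**d} rows")
        shape = (2,) * d
        directions = _directions_for(template, constraints, node)
        if node in constraints.conjunctive_complexes and d > 0:
            # complexes are AND gates: formation requires every component
            tables = np.zeros((n,) + shape)
            tables[(slice(None),) + (slice(1, 2),) * d] = 1.0
        elif d == 0:
            tables = rng.uniform(size=(n,))
        elif d < GIBBS_IN_DEGREE:
            tables, acc, prop = _rejection_tables(
                rng, shape, directions, n, max_proposals
            )
            accepted_total += acc
            proposed_total += prop
            if mode == "stratified":
                tables = _stratify(rng, tables, shape, directions, max_proposals)
        else:
            tables = _gibbs_tables(rng, shape, directions, n)
        per_node[node] = tables

    samples = [
        {node: np.asarray(per_node[node][k]) for node in nodes} for k in range(n)
    ]
    rate = accepted_total / proposed_total if proposed_total else 1.0
    return ParameterEnsemble(
        samples=samples,
        seed=seed,
        n_requested=n,
        acceptance_rate=rate,
        mode=mode,
    )


def _stratify(
    rng: np.random.Generator,
    tables: np.ndarray,
    shape: tuple[int, ...],
    directions: list[int],
    max_proposals: int,
) -> np.ndarray:
    """Occupancy balancing: re-propose into under-occupied effect-sign cells."""
    n = len(tables)
    cells = [_sign_cell(t, directions) for t in tables]
    counts: dict[tuple[int, ...], int] = {}
    for c in cells:
        counts[c] = counts.get(c, 0) + 1
    target = n / max(len(counts), 1)
    proposals = 0
    while proposals < max_proposals // 10:
        under = {c for c, k in counts.items() if k < target - 1}
        if not under:
            break
        extra, _, prop = _rejection_tables(
            rng, shape, directions, 64, max_proposals
        )
        proposals += prop
        for t in extra:
            c = _sign_cell(t, directions)
            if c in under:
                over = max(counts, key=lambda k: counts[k])
                idx = cells.index(over)
                tables[idx] = t
                cells[idx] = c
                counts[over] -= 1
                counts[c] = counts.get(c, 0) + 1
                under = {cc for cc, k in counts.items() if k < target - 1}
                if not under:
                    break
    return tables


def network_hash(net: RegulatoryNetwork) -> str:
    """Stable content hash of a network's nodes and signed edges."""
    import hashlib

    h = hashlib.sha256()
    for i in net.node_ids:
        rec = net.nodes[i]
        h.update(f"{rec.id}|{rec.role}|{rec.is_master}|{rec.components}\n".encode())
    for e in sorted(net.edges):
        h.update(f"{e}\n".encode())
    return h.hexdigest()[:16]


def save_ensemble(
    ensemble: ParameterEnsemble, path, net: RegulatoryNetwork | None = None
) -> None:
    """Serialize an ensemble to a single .npz archive (CPT stacks + metadata)."""
    import json

    arrays = {}
    nodes = sorted(ensemble.samples[0])
    for node in nodes:
        arrays[f"cpt::{node}"] = np.stack(
            [np.asarray(s[node]) for s in ensemble.samples]
        )
    meta = {
        "seed": ensemble.seed,
        "n_requested": ensemble.n_requested,
        "acceptance_rate": ensemble.acceptance_rate,
        "mode": ensemble.mode,
        "network_hash": network_hash(net) if net is not None else None,
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8
    )
    np.savez_compressed(path, **arrays)


def load_ensemble(path) -> ParameterEnsemble:
    """Load an ensemble saved by :func:`save_ensemble`."""
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        nodes = [k[len("cpt::"):] for k in data.files if k.startswith("cpt::")]
        stacks = {node: data[f"cpt::{node}"] for node in nodes}
    n = len(next(iter(stacks.values())))
    samples = [{node: stacks[node][k] for node in nodes} for k in range(n)]
    return ParameterEnsemble(
        samples=samples,
        seed=meta["seed"],
        n_requested=meta["n_requested"],
        acceptance_rate=meta["acceptance_rate"],
        mode=meta["mode"],
    )


def audit_ensemble(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    constraints: ConstraintSet,
) -> float:
    """Fraction of ensemble samples passing the post-hoc constraint audit."""
    ok = sum(
        audit_sample(s, template, constraints) for s in ensemble.samples
    )
    return ok / len(ensemble.samples)
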