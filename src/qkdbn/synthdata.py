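"""Seeded synthetic fixtures: random signed networks, bistable toy networks
with planted attractors and exactly known basins, and a reduced hESC-like
skeleton network.

The bistable fixture plants two mutually repressing, self-reinforcing
modules (an "embryonic-stem-like" module of hESC markers and a
"differentiated" module of differentiation markers).  Under deterministic
majority-rule CPTs both planted patterns are fixed points of the two-slice
dynamics, and the full basin table is computed by exhaustive iteration over
every initial state.

The hESC skeleton is explicitly NOT the published 52-node network: it
contains the 22 marker genes, the master-regulator flags, the Oct4-Sox2
complex and the handful of regulations named in the primary literature
(GATA6 -| NANOG, LMCD1 -| GATA6, GATA4 -| GATA6, PBX1 -> NANOG,
ZIC3 -> NANOG, OCT4 -| GATA6), plus a clearly flagged synthetic scaffold
that wires the remaining markers into a bistable switch so the machinery is
exercisable end-to-end.  Outputs derived from it carry provenance
"skeleton"; quantitative comparison against published screen numbers
requires the user-encoded full network instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .constraints import ParameterEnsemble
from .network import (
    NodeRecord,
    RegulatoryNetwork,
    TwoSliceTemplate,
    read_network,
    unroll_to_2tbn,
)


# ---------------------------------------------------------------------------
# Random signed networks
# ---------------------------------------------------------------------------

def make_random_network(
    n_nodes: int,
    density: float = 0.2,
    fraction_repressive: float = 0.3,
    seed: int = 0,
    self_loops: bool = False,
) -> RegulatoryNetwork:
    """A seeded Erdos-Renyi signed digraph.

    Each ordered pair (self-pairs only when ``self_loops``) carries an edge
    with probability ``density``; edge signs are repressive with probability
    ``fraction_repressive``.  The same seed reproduces the same network.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must be in [0,1]")
    rng = np.random.default_rng(seed)
    names = [f"g{i:02d}" for i in range(n_nodes)]
    edges = []
    for s in names:
        for t in names:
            if s == t and not self_loops:
                continue
            if rng.uniform() < density:
                sign = -1 if rng.uniform() < fraction_repressive else 1
                edges.append((s, t, sign))
    return RegulatoryNetwork(
        [NodeRecord(n) for n in names], edges, provenance="synthetic"
    )


# ---------------------------------------------------------------------------
# Deterministic CPTs and exact basins
# ---------------------------------------------------------------------------

def deterministic_cpts(template: TwoSliceTemplate) -> dict[str, np.ndarray]:
    """Majority-rule deterministic CPTs: a node switches on iff strictly more
    of its activators than its repressors are active; parentless nodes decay
    to 0.  Complex nodes are AND gates over their components."""
    net = template.network
    sample: dict[str, np.ndarray] = {}
    for node in net.node_ids:
        parents = template.cpt_parents(node)
        d = len(parents)
        table = np.zeros((2,) * d)
        is_complex = net.nodes[node].is_complex
        for config in itertools.product((0, 1), repeat=d):
            if is_complex:
                table[config] = float(all(config))
                continue
            acts = sum(v for v, (_, sg, _) in zip(config, parents) if sg > 0)
            reps = sum(v for v, (_, sg, _) in zip(config, parents) if sg < 0)
            table[config] = float(acts > reps)
        sample[node] = table if d else np.asarray(0.0)
    return sample


def ensemble_from_samples(
    samples: list[dict[str, np.ndarray]], seed: int = 0
) -> ParameterEnsemble:
    """Wrap explicit CPT samples (e.g. deterministic fixtures) as an ensemble."""
    return ParameterEnsemble(
        samples=samples,
        seed=seed,
        n_requested=len(samples),
        acceptance_rate=1.0,
        mode="explicit",
    )


def propagate_deterministic(
    template: TwoSliceTemplate,
    sample: Mapping[str, np.ndarray],
    state: Mapping[str, int],
    clamps: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """One-step successor under deterministic CPTs by direct topological
    propagation: intra-slice parents are read from the new slice, inter-slice
    parents from the previous state.  Independent of the junction-tree code
    path, so it doubles as a cross-check oracle."""
    clamps = clamps or {}
    new: dict[str, int] = {}
    for node in template.topological_order():
        if node in clamps:
            new[node] = int(clamps[node])
            continue
        parents = template.cpt_parents(node)
        idx = tuple(
            (int(state[src]) if inter else new[src]) for src, _, inter in parents
        )
        p = float(np.asarray(sample[node])[idx])
        new[node] = int(p >= 0.5)
    return new


@dataclass
class BistableFixture:
    """A toy bistable network with planted attractors and exact basins."""

    network: RegulatoryNetwork
    template: TwoSliceTemplate
    attractors: dict[str, dict[str, int]]  # "hesc" and "differentiated"
    ensemble: ParameterEnsemble  # single deterministic sample
    basin_fractions: dict[str, float]  # over all 2^n initial states
    basin_assignment: dict[tuple[int, ...], str]  # state bits -> basin label

    @property
    def node_order(self) -> list[str]:
        return self.network.node_ids


def make_bistable_fixture(
    module_size: int = 3, n_non_markers: int = 2, max_steps: int = 64
) -> BistableFixture:
    """Two mutually repressing activation cycles with feeder non-markers.

    Module A nodes (``a0..``) are hESC markers (the first two flagged as
    master regulators), module B nodes (``b0..``) differentiation markers;
    each module is a directed activation cycle and the module heads repress
    each other.  Non-markers ``u0..`` feed alternate module heads.  The
    planted patterns (A on / B off and the reverse, feeders off) are fixed
    points; basins are computed exactly over all 2^n initial states.
    """
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if 2 * module_size + n_non_markers > 12:
        raise ValueError("fixture too large for exact basin computation")
    a = [f"a{i}" for i in range(module_size)]
    b = [f"b{i}" for i in range(module_size)]
    u = [f"u{i}" for i in range(n_non_markers)]
    nodes = [
        NodeRecord(n, role="hesc_marker", is_master=(i < 2)) for i, n in enumerate(a)
    ]
    nodes += [NodeRecord(n, role="diff_marker") for n in b]
    nodes += [NodeRecord(n) for n in u]
    edges = []
    for i in range(module_size):
        edges.append((a[i], a[(i + 1) % module_size], 1))
        edges.append((b[i], b[(i + 1) % module_size], 1))
    edges.append((a[0], b[0], -1))
    edges.append((b[0], a[0], -1))
    for j, feeder in enumerate(u):
        edges.append((feeder, (a if j % 2 == 0 else b)[0], 1))
    net = RegulatoryNetwork(nodes, edges, provenance="synthetic")
    template = unroll_to_2tbn(net)
    sample = deterministic_cpts(template)

    order = net.node_ids
    hesc = {**{n: 1 for n in a}, **{n: 0 for n in b}, **{n: 0 for n in u}}
    diff = {**{n: 0 for n in a}, **{n: 1 for n in b}, **{n: 0 for n in u}}
    attractors = {"hesc": hesc, "differentiated": diff}

    assignment: dict[tuple[int, ...], str] = {}
    for bits in itertools.product((0, 1), repeat=len(order)):
        state = dict(zip(order, bits))
        seen = {tuple(bits)}
        label = "none"
        for _ in range(max_steps):
            nxt = propagate_deterministic(template, sample, state)
            if nxt == state:
                if nxt == hesc:
                    label = "hesc"
                elif nxt == diff:
                    label = "differentiated"
                else:
                    label = "other"
                break
            key = tuple(nxt[n] for n in order)
            if key in seen:
                break
            seen.add(key)
            state = nxt
        assignment[bits] = label
    total = len(assignment)
    fractions = {
        lab: sum(1 for v in assignment.values() if v == lab) / total
        for lab in ("hesc", "differentiated", "other", "none")
    }
    return BistableFixture(
        network=net,
        template=template,
        attractors=attractors,
        ensemble=ensemble_from_samples([sample]),
        basin_fractions=fractions,
        basin_assignment=assignment,
    )


# ---------------------------------------------------------------------------
# hESC skeleton
# ---------------------------------------------------------------------------

HESC_MARKERS = (
    "OCT4", "SOX2", "NANOG", "Oct4-Sox2", "KLF4", "FOXD3",
    "ZIC3", "ZFP42", "GDF3", "TDGF1", "PBX1",
)
DIFF_MARKERS = (
    "GATA2", "GATA3", "hCGb", "hCGa", "CDX2", "GATA4",
    "GATA6", "FOXA2", "AFP", "SOX17", "T",
)
MASTERS = ("OCT4", "SOX2", "NANOG")
SKELETON_NON_MARKERS = (
    "MYC", "PRDM14", "LMCD1", "FOXO1A", "ZNF206", "SP1", "PIAS1", "FOXA1",
)

#: regulations named in the primary literature on the hESC network
CURATED_EDGES: tuple[tuple[str, str, int], ...] = (
    ("GATA6", "NANOG", -1),
    ("LMCD1", "GATA6", -1),
    ("GATA4", "GATA6", -1),
    ("PBX1", "NANOG", 1),
    ("ZIC3", "NANOG", 1),
    ("OCT4", "GATA6", -1),
    ("OCT4", "Oct4-Sox2", 1),
    ("SOX2", "Oct4-Sox2", 1),
)

#: synthetic scaffold wiring the markers into a bistable switch; NOT curated.
#: All ES-side activation is gated through the Oct4-Sox2 AND-gate complex, so
#: the pluripotent module is structurally unreachable unless both OCT4 and
#: SOX2 are active; heterogeneity of differentiated cells is carried by the
#: persistent (auto-regulating) repressors of the GATA6 hub.
SCAFFOLD_EDGES: tuple[tuple[str, str, int], ...] = (
    # complex stabilizes its components (positive feedback through the gate)
    ("Oct4-Sox2", "OCT4", 1),
    ("Oct4-Sox2", "SOX2", 1),
    # ES markers and NANOG driven by the complex; auto-regulation keeps the
    # pluripotency module history-dependent (previous-slice values pin it)
    ("Oct4-Sox2", "NANOG", 1),
    ("NANOG", "NANOG", 1),
    ("Oct4-Sox2", "KLF4", 1),
    ("KLF4", "KLF4", 1),
    ("Oct4-Sox2", "FOXD3", 1),
    ("FOXD3", "FOXD3", 1),
    ("Oct4-Sox2", "ZIC3", 1),
    ("ZIC3", "ZIC3", 1),
    ("Oct4-Sox2", "ZFP42", 1),
    ("ZFP42", "ZFP42", 1),
    ("Oct4-Sox2", "GDF3", 1),
    ("GDF3", "GDF3", 1),
    ("Oct4-Sox2", "TDGF1", 1),
    ("TDGF1", "TDGF1", 1),
    ("Oct4-Sox2", "PBX1", 1),
    ("PBX1", "PBX1", 1),
    # the GATA6 hub antagonizes the pluripotency module and vice versa
    ("NANOG", "GATA6", -1),
    ("GATA6", "KLF4", -1),
    ("GATA6", "FOXD3", -1),
    ("GATA6", "ZIC3", -1),
    ("GATA6", "ZFP42", -1),
    ("GATA6", "GDF3", -1),
    ("GATA6", "TDGF1", -1),
    ("GATA6", "PBX1", -1),
    # self-sustaining differentiation module around GATA6
    ("GATA6", "GATA6", 1),
    ("GATA6", "GATA2", 1),
    ("GATA6", "GATA3", 1),
    ("GATA6", "hCGa", 1),
    ("GATA6", "hCGb", 1),
    ("GATA6", "CDX2", 1),
    ("GATA6", "GATA4", 1),
    ("GATA6", "FOXA2", 1),
    ("GATA6", "AFP", 1),
    ("GATA6", "SOX17", 1),
    ("GATA6", "T", 1),
    ("GATA2", "GATA6", 1),
    ("GATA3", "GATA6", 1),
    # persistent non-marker repressors of the differentiation module
    ("MYC", "MYC", 1),
    ("PRDM14", "PRDM14", 1),
    ("LMCD1", "LMCD1", 1),
    ("MYC", "GATA2", -1),
    ("LMCD1", "GATA2", -1),
    ("PRDM14", "GATA3", -1),
    ("LMCD1", "GATA3", -1),
    # the re-established pluripotency module keeps the hubs shut
    ("NANOG", "GATA2", -1),
    ("NANOG", "GATA3", -1),
    ("KLF4", "GATA2", -1),
    ("KLF4", "GATA3", -1),
    # remaining non-markers follow a persistent or hub node
    ("MYC", "SP1", 1),
    ("LMCD1", "PIAS1", 1),
    ("GATA6", "FOXA1", 1),
    ("PRDM14", "FOXO1A", 1),
    ("Oct4-Sox2", "ZNF206", 1),
)


def make_hesc_skeleton(
    merge_path: str | Path | None = None,
    merge_annotation_path: str | Path | None = None,
    include_scaffold: bool = True,
) -> RegulatoryNetwork:
    """The reduced hESC-like network: 22 markers, master flags, the
    Oct4-Sox2 complex, literature-named edges and (by default) the synthetic
    bistable scaffold.  A user-encoded full network can be merged in from an
    edge-list/annotation file pair; merging an empty file is a no-op.

    The result carries ``provenance == "skeleton"`` (or ``"merged"``) so
    downstream reports cannot silently pose as the published network.
    """
    nodes = [
        NodeRecord(
            n,
            role="hesc_marker",
            is_master=n in MASTERS,
            components=("OCT4", "SOX2") if n == "Oct4-Sox2" else (),
        )
        for n in HESC_MARKERS
    ]
    nodes += [NodeRecord(n, role="diff_marker") for n in DIFF_MARKERS]
    nodes += [NodeRecord(n) for n in SKELETON_NON_MARKERS]
    edges: list[tuple[str, str, int]] = list(CURATED_EDGES)
    if include_scaffold:
        edges += list(SCAFFOLD_EDGES)

    records = {n.id: n for n in nodes}
    provenance = "skeleton"
    if merge_path is not None:
        user = read_network(merge_path, merge_annotation_path)
        if user.edges or len(user) > 0:
            provenance = "merged"
        for rec in user.nodes.values():
            records.setdefault(rec.id, rec)
        have = {(s, t) for s, t, _ in edges}
        for s, t, sg in user.edges:
            if (s, t) not in have:
                edges.append((s, t, sg))
    return RegulatoryNetwork(records.values(), edges, provenance=provenance)
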