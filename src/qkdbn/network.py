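"""Signed regulatory networks and their unrolling into a two-time-slice template.

A regulatory network is a signed directed graph: nodes are genes or protein
complexes, edges carry a sign (+1 activation, -1 repression).  Cyclic
regulation (feedback) cannot live inside a single Bayesian-network slice, so
the network is unrolled into a 2-time-slice Bayesian network (2TBN): a greedy
loop-breaking procedure selects an *outgoing interface* -- the node set whose
previous-slice values carry all information forward -- and every cut edge
becomes an inter-slice edge while the remaining intra-slice graph is acyclic.

Candidate interface nodes are ranked by the heuristic score B/(1-A): A = 1
marks a must-cut node (e.g. auto-regulation), making the score infinite;
otherwise the score is B, the number of simple cycles through the node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

ROLES = ("hesc_marker", "diff_marker", "complex", "non_marker")

SIGN_TOKENS = {
    "+": 1,
    "-": -1,
    "activate": 1,
    "activates": 1,
    "repress": -1,
    "represses": -1,
    "1": 1,
    "-1": -1,
    "+1": 1,
}


class NetworkError(ValueError):
    """Raised for malformed network files or inconsistent network objects."""


@dataclass(frozen=True)
class NodeRecord:
    """A node of the regulatory network.

    Parameters
    ----------
    id : str
        Unique node identifier (gene or complex name).
    role : str
        One of ``hesc_marker``, ``diff_marker``, ``complex``, ``non_marker``.
    is_master : bool
        True for the master pluripotency regulators (OCT4/SOX2/NANOG in the
        human ES-cell network).  Implies ``role == "hesc_marker"``.
    components : tuple of str
        Component nodes, non-empty only for ``role == "complex"``.
    """

    id: str
    role: str = "non_marker"
    is_master: bool = False
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkError(f"unknown role {self.role!r} for node {self.id!r}")
        if self.is_master and self.role != "hesc_marker":
            raise NetworkError(f"master node {self.id!r} must be an hESC marker")
        if self.components and len(self.components) < 2:
            raise NetworkError(f"complex {self.id!r} needs >= 2 components")
        if self.role == "complex" and not self.components:
            raise NetworkError(f"complex {self.id!r} lists no components")

    @property
    def is_complex(self) -> bool:
        """Protein complexes are nodes with components; a complex may double
        as a marker (the Oct4-Sox2 heterodimer is an hESC marker)."""
        return bool(self.components)


Edge = tuple[str, str, int]


class RegulatoryNetwork:
    """A validated signed directed regulatory network with node annotations.

    ``provenance`` records where the network came from (``"user"`` for
    encoded real networks, ``"skeleton"``/``"synthetic"`` for fixtures) and
    is propagated into screen outputs.
    """

    def __init__(
        self,
        nodes: Iterable[NodeRecord],
        edges: Iterable[Edge],
        provenance: str = "user",
    ):
        self.provenance = provenance
        node_list = list(nodes)
        ids = [n.id for n in node_list]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkError(f"duplicate node ids: {dup}")
        self._nodes: dict[str, NodeRecord] = {n.id: n for n in node_list}

        seen: dict[tuple[str, str], int] = {}
        edge_list: list[Edge] = []
        for src, tgt, sign in edges:
            if sign not in (1, -1):
                raise NetworkError(f"edge {src}->{tgt}: sign must be +1/-1, got {sign!r}")
            for endpoint in (src, tgt):
                if endpoint not in self._nodes:
                    raise NetworkError(f"edge {src}->{tgt}: unknown node {endpoint!r}")
            key = (src, tgt)
            if key in seen:
                if seen[key] != sign:
                    raise NetworkError(f"conflicting duplicate edge {src}->{tgt}")
                continue
            seen[key] = sign
            edge_list.append((src, tgt, sign))
        self._edges = tuple(edge_list)

        for rec in node_list:
            for comp in rec.components:
                if comp not in self._nodes:
                    raise NetworkError(
                        f"complex {rec.id!r}: component {comp!r} is not a node"
                    )

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> dict[str, NodeRecord]:
        return dict(self._nodes)

    @property
    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    @property
    def edges(self) -> list[Edge]:
        return list(self._edges)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    def role_of(self, node_id: str) -> str:
        return self._nodes[node_id].role

    @property
    def hesc_markers(self) -> list[str]:
        return sorted(
            i for i, n in self._nodes.items() if n.role == "hesc_marker"
        )

    @property
    def diff_markers(self) -> list[str]:
        return sorted(i for i, n in self._nodes.items() if n.role == "diff_marker")

    @property
    def markers(self) -> list[str]:
        return sorted(self.hesc_markers + self.diff_markers)

    @property
    def non_markers(self) -> list[str]:
        """All nodes that are neither hESC nor differentiation markers."""
        m = set(self.markers)
        return sorted(i for i in self._nodes if i not in m)

    @property
    def masters(self) -> list[str]:
        return sorted(i for i, n in self._nodes.items() if n.is_master)

    @property
    def complexes(self) -> list[str]:
        return sorted(i for i, n in self._nodes.items() if n.is_complex)

    @property
    def single_genes(self) -> list[str]:
        """Nodes that are individual genes (complexes excluded)."""
        return sorted(i for i, n in self._nodes.items() if not n.is_complex)

    def parents_of(self, node_id: str) -> list[tuple[str, int]]:
        """Sorted ``(source, sign)`` pairs of incoming edges."""
        return sorted((s, sg) for s, t, sg in self._edges if t == node_id)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        for s, t, sg in self._edges:
            g.add_edge(s, t, sign=sg)
        return g

    def differentiated_pattern(self) -> dict[str, int]:
        """Marker pattern of the differentiated state: ES markers 0, diff markers 1."""
        out = {m: 0 for m in self.hesc_markers}
        out.update({m: 1 for m in self.diff_markers})
        return out

    def hesc_pattern(self) -> dict[str, int]:
        """Marker pattern of the hESC state: ES markers 1, diff markers 0."""
        out = {m: 1 for m in self.hesc_markers}
        out.update({m: 0 for m in self.diff_markers})
        return out


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _parse_sign(token: str, errors: list[str], lineno: int) -> int | None:
    sign = SIGN_TOKENS.get(token.strip())
    if sign is None:
        errors.append(f"line {lineno}: unknown sign token {token!r}")
    return sign


def read_network(
    path: str | Path,
    annotation_path: str | Path | None = None,
    fmt: str = "tsv",
) -> RegulatoryNetwork:
    """Read a signed edge list (and optional node annotations) from disk.

    ``tsv`` rows are ``source<TAB>target<TAB>sign`` with sign in
    {+, -, activate, repress}; the ``sif`` dialect is
    ``source<WS>activates|represses<WS>target``.  Lines starting with ``#``
    are ignored.  The annotation file has rows
    ``node<TAB>role<TAB>is_master<TAB>components`` (components
    semicolon-separated; trailing columns optional).  Unannotated nodes
    default to ``non_marker``.  All malformed rows are reported together.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    errors: list[str] = []
    edges: list[Edge] = []
    node_ids: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t") if fmt == "tsv" else line.split()
        if len(cols) != 3:
            errors.append(f"line {lineno}: expected 3 columns, got {len(cols)}")
            continue
        if fmt == "tsv":
            src, tgt, sign_tok = cols
        elif fmt == "sif":
            src, sign_tok, tgt = cols
        else:
            raise NetworkError(f"unknown format {fmt!r}")
        sign = _parse_sign(sign_tok, errors, lineno)
        if sign is None:
            continue
        edges.append((src.strip(), tgt.strip(), sign))
        node_ids.update((src.strip(), tgt.strip()))

    records: dict[str, NodeRecord] = {}
    if annotation_path is not None:
        apath = Path(annotation_path)
        if not apath.exists():
            raise FileNotFoundError(apath)
        for lineno, raw in enumerate(apath.read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            node = cols[0].strip()
            role = cols[1].strip() if len(cols) > 1 and cols[1].strip() else "non_marker"
            if role not in ROLES:
                role = "non_marker"
            is_master = len(cols) > 2 and cols[2].strip().lower() in ("1", "true", "yes")
            components: tuple[str, ...] = ()
            if len(cols) > 3 and cols[3].strip():
                components = tuple(c.strip() for c in cols[3].split(";") if c.strip())
            try:
                records[node] = NodeRecord(node, role, is_master, components)
            except NetworkError as exc:
                errors.append(f"annotation line {lineno}: {exc}")
            node_ids.add(node)
            node_ids.update(components)

    if errors:
        raise NetworkError("malformed input:\n  " + "\n  ".join(errors))

    nodes = [records.get(i, NodeRecord(i)) for i in sorted(node_ids)]
    return RegulatoryNetwork(nodes, edges)


def write_network(
    net: RegulatoryNetwork,
    path: str | Path,
    annotation_path: str | Path | None = None,
) -> None:
    """Write the edge list (and optionally annotations) as TSV."""
    lines = ["#source\ttarget\tsign"]
    for s, t, sg in sorted(net.edges):
        lines.append(f"{s}\t{t}\t{'+' if sg > 0 else '-'}")
    Path(path).write_text("\n".join(lines) + "\n")
    if annotation_path is not None:
        alines = ["#node\trole\tis_master\tcomponents"]
        for i in net.node_ids:
            rec = net.nodes[i]
            alines.append(
                f"{rec.id}\t{rec.role}\t{int(rec.is_master)}\t{';'.join(rec.components)}"
            )
        Path(annotation_path).write_text("\n".join(alines) + "\n")


# ---------------------------------------------------------------------------
# Cycle enumeration and interface selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CycleSet:
    """All simple directed cycles of a network, canonicalized up to rotation."""

    cycles: tuple[tuple[str, ...], ...]

    def __len__(self) -> int:
        return len(self.cycles)

    def nodes(self) -> set[str]:
        return {n for c in self.cycles for n in c}

    def containing(self, node: str) -> list[tuple[str, ...]]:
        return [c for c in self.cycles if node in c]


def _canonical_rotation(cycle: Sequence[str]) -> tuple[str, ...]:
    k = min(range(len(cycle)), key=lambda i: cycle[i])
    return tuple(cycle[k:]) + tuple(cycle[:k])


def enumerate_simple_cycles(
    net: RegulatoryNetwork, cap: int = 10**6
) -> CycleSet:
    """Enumerate every simple directed cycle (self-loops included).

    Uses Johnson-style enumeration; raises if more than ``cap`` cycles are
    found, which guards against pathological dense inputs.
    """
    cycles: list[tuple[str, ...]] = []
    for cyc in nx.simple_cycles(net.to_digraph()):
        cycles.append(_canonical_rotation(cyc))
        if len(cycles) > cap:
            raise NetworkError(f"more than {cap} simple cycles; raise the cap")
    return CycleSet(tuple(sorted(cycles)))


@dataclass(frozen=True)
class InterfaceScore:
    """Heuristic loop-breaking score of one interface candidate."""

    A: int  # 1 iff must-cut (self-loop)
    B: int  # number of simple cycles through the node
    score: float  # +inf iff A == 1, else B


@dataclass
class InterfaceSelection:
    """Result of greedy interface selection: nodes, cut edges and scores."""

    interface_nodes: tuple[str, ...]
    cut_edges: tuple[Edge, ...]
    scores: dict[str, InterfaceScore] = field(default_factory=dict)


def score_interface_candidates(
    net: RegulatoryNetwork, cycles: CycleSet
) -> dict[str, InterfaceScore]:
    """Score every node by B/(1-A) over the given cycle set.

    Nodes outside all loops get B = 0, score 0.  Nodes with a self-loop are
    must-cut (A = 1) and score +inf.
    """
    out: dict[str, InterfaceScore] = {}
    for node in net.node_ids:
        b = sum(1 for c in cycles.cycles if node in c)
        a = int(any(len(c) == 1 and c[0] == node for c in cycles.cycles))
        out[node] = InterfaceScore(A=a, B=b, score=math.inf if a else float(b))
    return out


def _cycle_edges(cycle: tuple[str, ...]) -> list[tuple[str, str]]:
    return [(cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))]


def select_outgoing_interface(
    net: RegulatoryNetwork, cap: int = 10**6
) -> InterfaceSelection:
    """Greedy loop breaking: pick the highest-scoring node, cut its outgoing
    loop edges, and repeat until no cycle survives.

    Ties are broken toward the lexicographically smallest node id.  An edge is
    "part of a loop" iff it lies on at least one currently unbroken simple
    cycle; membership is recomputed after each cut.
    """
    all_cycles = enumerate_simple_cycles(net, cap=cap)
    initial_scores = score_interface_candidates(net, all_cycles)

    sign_of = {(s, t): sg for s, t, sg in net.edges}
    unbroken = list(all_cycles.cycles)
    interface: list[str] = []
    cut: list[Edge] = []
    while unbroken:
        best: str | None = None
        best_score = -1.0
        for node in net.node_ids:
            b = sum(1 for c in unbroken if node in c)
            if b == 0:
                continue
            a = any(len(c) == 1 and c[0] == node for c in unbroken)
            score = math.inf if a else float(b)
            if score > best_score:
                best, best_score = node, score
        assert best is not None
        loop_edges = {
            e for c in unbroken if best in c for e in _cycle_edges(c) if e[0] == best
        }
        for s, t in sorted(loop_edges):
            cut.append((s, t, sign_of[(s, t)]))
        interface.append(best)
        cut_pairs = {(s, t) for s, t, _ in cut}
        unbroken = [
            c for c in unbroken if not any(e in cut_pairs for e in _cycle_edges(c))
        ]
    return InterfaceSelection(
        interface_nodes=tuple(interface),
        cut_edges=tuple(cut),
        scores=initial_scores,
    )


# ---------------------------------------------------------------------------
# Unrolling
# ---------------------------------------------------------------------------

PREV_SUFFIX = "@prev"


def prev_var(node_id: str) -> str:
    """Name of a node's copy in the previous time slice."""
    return node_id + PREV_SUFFIX


@dataclass
class TwoSliceTemplate:
    """The acyclic two-time-slice template of an unrolled cyclic network.

    ``intra_edges`` act within a slice and form a DAG; ``inter_edges`` run
    from interface nodes at slice t-1 to their targets at slice t.  The union
    of the two edge sets equals the original network's edges.
    """

    network: RegulatoryNetwork
    intra_edges: tuple[Edge, ...]
    inter_edges: tuple[Edge, ...]
    interface_nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.network.node_ids)
        g.add_edges_from((s, t) for s, t, _ in self.intra_edges)
        if not nx.is_directed_acyclic_graph(g):
            raise NetworkError("intra-slice graph is not acyclic")
        self._intra_dag = g

    @property
    def n_interface(self) -> int:
        return len(self.interface_nodes)

    def interface_sorted(self) -> tuple[str, ...]:
        return tuple(sorted(self.interface_nodes))

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self._intra_dag))

    def cpt_parents(self, node: str) -> list[tuple[str, int, bool]]:
        """Parents of ``node`` in the template as ``(source, sign, is_inter)``,
        sorted by source id.  This fixed order defines CPT axis layout."""
        out = [(s, sg, False) for s, t, sg in self.intra_edges if t == node]
        out += [(s, sg, True) for s, t, sg in self.inter_edges if t == node]
        return sorted(out)

    def in_degree(self, node: str) -> int:
        return len(self.cpt_parents(node))


def unroll_to_2tbn(
    net: RegulatoryNetwork, sel: InterfaceSelection | None = None
) -> TwoSliceTemplate:
    """Unroll a (possibly cyclic) network into its 2TBN template.

    Cut edges become inter-slice edges read from slice t-1; all other edges
    stay within the slice.  The edge multiset is conserved.
    """
    if sel is None:
        sel = select_outgoing_interface(net)
    cut_pairs = {(s, t) for s, t, _ in sel.cut_edges}
    for s, t, _ in sel.cut_edges:
        if s not in sel.interface_nodes:
            raise NetworkError(f"cut edge {s}->{t} does not start at an interface node")
    intra = tuple(e for e in net.edges if (e[0], e[1]) not in cut_pairs)
    inter = tuple(e for e in net.edges if (e[0], e[1]) in cut_pairs)
    return TwoSliceTemplate(
        network=net,
        intra_edges=intra,
        inter_edges=inter,
        interface_nodes=tuple(sorted(sel.interface_nodes)),
    )
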