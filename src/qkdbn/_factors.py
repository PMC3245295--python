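"""Discrete factor algebra over binary variables.

Factors are dense numpy tables indexed by a sorted tuple of variable names;
axis k corresponds to ``vars[k]`` and has size 2.  Multiplication aligns
variables by name via broadcasting; marginalization supports both sum- and
max-product semantics, which is all the junction-tree calibration and MAP
decoding in this package need.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np


class Factor:
    __slots__ = ("vars", "table")

    def __init__(self, variables: Sequence[str], table: np.ndarray):
        variables = tuple(variables)
        table = np.asarray(table, dtype=float)
        if tuple(sorted(variables)) != variables:
            order = sorted(range(len(variables)), key=lambda i: variables[i])
            table = np.transpose(table, order)
            variables = tuple(sorted(variables))
        if table.shape != (2,) * len(variables):
            raise ValueError(
                f"table shape {table.shape} does not match {len(variables)} binary vars"
            )
        self.vars = variables
        self.table = table

    # -- constructors ----------------------------------------------------
    @classmethod
    def ones(cls, variables: Sequence[str]) -> "Factor":
        return cls(tuple(variables), np.ones((2,) * len(variables)))

    @classmethod
    def indicator(cls, var: str, value: int) -> "Factor":
        t = np.zeros(2)
        t[value] = 1.0
        return cls((var,), t)

    @classmethod
    def bernoulli(cls, var: str, p_one: float) -> "Factor":
        return cls((var,), np.array([1.0 - p_one, p_one]))

    @classmethod
    def cpt(cls, node: str, parents: Sequence[str], p_one: np.ndarray) -> "Factor":
        """CPT factor over ``parents + (node,)`` from P(node=1 | parent config).

        ``p_one`` has shape (2,)*len(parents), axis k = parents[k].
        """
        p_one = np.asarray(p_one, dtype=float)
        table = np.stack([1.0 - p_one, p_one], axis=-1)
        return cls(tuple(parents) + (node,), table)

    # -- algebra ---------------------------------------------------------
    def _aligned(self, union: tuple[str, ...]) -> np.ndarray:
        """View of the table broadcastable over the union variable set."""
        idx = [slice(None) if v in self.vars else None for v in union]
        return self.table[tuple(idx)]

    def __mul__(self, other: "Factor") -> "Factor":
        union = tuple(sorted(set(self.vars) | set(other.vars)))
        return Factor(union, self._aligned(union) * other._aligned(union))

    def divide(self, other: "Factor") -> "Factor":
        """Hugin-style safe division: 0/0 is defined as 0."""
        union = tuple(sorted(set(self.vars) | set(other.vars)))
        num = np.broadcast_to(self._aligned(union), (2,) * len(union))
        den = np.broadcast_to(other._aligned(union), (2,) * len(union))
        out = np.zeros_like(num)
        np.divide(num, den, out=out, where=den != 0)
        return Factor(union, out)

    def marginalize_to(self, keep: Iterable[str], op: str = "sum") -> "Factor":
        keep = set(keep)
        axes = tuple(i for i, v in enumerate(self.vars) if v not in keep)
        remaining = tuple(v for v in self.vars if v in keep)
        if not axes:
            return Factor(remaining, self.table.copy())
        table = self.table.sum(axis=axes) if op == "sum" else self.table.max(axis=axes)
        return Factor(remaining, table)

    def reduce(self, assignment: Mapping[str, int]) -> "Factor":
        """Condition on observed values, dropping the observed axes."""
        idx = tuple(
            assignment[v] if v in assignment else slice(None) for v in self.vars
        )
        remaining = tuple(v for v in self.vars if v not in assignment)
        return Factor(remaining, self.table[idx])

    def normalize(self) -> "Factor":
        z = self.table.sum()
        if z <= 0:
            raise ZeroDivisionError("cannot normalize an all-zero factor")
        return Factor(self.vars, self.table / z)

    def value(self, assignment: Mapping[str, int]) -> float:
        return float(self.table[tuple(assignment[v] for v in self.vars)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"Factor({self.vars}, sum={self.table.sum():.4g})"


def product(factors: Sequence[Factor]) -> Factor:
    if not factors:
        return Factor((), np.array(1.0))
    out = factors[0]
    for f in factors[1:]:
        out = out * f
    return out


def _elimination_order(
    factors: Sequence[Factor], eliminate: set[str]
) -> list[str]:
    """Greedy min-fill order (lexicographic tie-break) over an interaction graph."""
    neighbors: dict[str, set[str]] = {}
    for f in factors:
        for v in f.vars:
            neighbors.setdefault(v, set()).update(f.vars)
    for v, ns in neighbors.items():
        ns.discard(v)
    todo = {v for v in eliminate if v in neighbors}
    order: list[str] = []
    while todo:

        def fill(v: str) -> int:
            ns = [u for u in neighbors[v] if u in neighbors]
            return sum(
                1
                for i, a in enumerate(ns)
                for b in ns[i + 1 :]
                if b not in neighbors[a]
            )

        v = min(sorted(todo), key=fill)
        order.append(v)
        ns = {u for u in neighbors[v] if u in neighbors and u != v}
        for a in ns:
            neighbors[a].update(ns - {a})
            neighbors[a].discard(v)
        del neighbors[v]
        todo.discard(v)
    order.extend(sorted(eliminate - set(order)))
    return order


def eliminate(
    factors: Sequence[Factor],
    keep: Iterable[str],
    op: str = "sum",
) -> Factor:
    """Variable elimination down to the ``keep`` set (sum- or max-product)."""
    keep = set(keep)
    live = [f for f in factors]
    all_vars = {v for f in live for v in f.vars}
    order = _elimination_order(live, all_vars - keep)
    for v in order:
        bucket = [f for f in live if v in f.vars]
        live = [f for f in live if v not in f.vars]
        if bucket:
            prod = product(bucket)
            live.append(prod.marginalize_to(set(prod.vars) - {v}, op=op))
    return product(live).marginalize_to(keep, op=op)


def max_value(factors: Sequence[Factor]) -> float:
    """Maximum of the product over all joint assignments."""
    return float(eliminate(factors, keep=(), op="max").table)
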