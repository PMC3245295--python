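"""Shared fixtures: small networks, templates and ensembles.

Everything is generated programmatically and seeded; session scope is used
for the expensive ensembles so the suite stays fast.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import qkdbn as q
from qkdbn import synthdata as sd


@pytest.fixture(scope="session")
def bistable():
    return sd.make_bistable_fixture()


@pytest.fixture(scope="session")
def skeleton():
    return sd.make_hesc_skeleton()


@pytest.fixture(scope="session")
def skeleton_model(skeleton):
    """Skeleton network with template and a moderate sampled ensemble."""
    tpl = q.unroll_to_2tbn(skeleton)
    cons = q.build_constraints(skeleton)
    ens = q.sample_cpt_ensemble(tpl, cons, n=100, seed=7)
    return skeleton, tpl, cons, ens


@pytest.fixture(scope="session")
def chain_model():
    """Two-node activator chain A -> B with a sampled ensemble."""
    net = q.RegulatoryNetwork(
        [q.NodeRecord("A"), q.NodeRecord("B")], [("A", "B", 1)]
    )
    tpl = q.unroll_to_2tbn(net)
    cons = q.build_constraints(net)
    ens = q.sample_cpt_ensemble(tpl, cons, n=5000, seed=11)
    return net, tpl, cons, ens


# ---------------------------------------------------------------------------
# Independent oracles (no junction tree, no MAP elimination)
# ---------------------------------------------------------------------------

def brute_force_joint(template, sample, nodes):
    """Exhaustive joint distribution of a single acyclic slice."""
    probs = {}
    for bits in itertools.product((0, 1), repeat=len(nodes)):
        st = dict(zip(nodes, bits))
        p = 1.0
        for n in nodes:
            parents = template.cpt_parents(n)
            idx = tuple(st[s] for s, _, _ in parents)
            p1 = float(np.asarray(sample[n])[idx])
            p *= p1 if st[n] else 1 - p1
        probs[bits] = p
    return probs


def transition_matrix(template, cpts, nodes):
    """Full 2^n x 2^n one-step transition matrix T[next, prev]."""
    states = list(itertools.product((0, 1), repeat=len(nodes)))
    T = np.zeros((len(states), len(states)))
    for j, sbits in enumerate(states):
        s = dict(zip(nodes, sbits))
        for i, tbits in enumerate(states):
            t = dict(zip(nodes, tbits))
            p = 1.0
            for n in nodes:
                parents = template.cpt_parents(n)
                idx = tuple(
                    (s[src] if inter else t[src]) for src, _, inter in parents
                )
                p1 = float(np.asarray(cpts[n])[idx])
                p *= p1 if t[n] else 1 - p1
            T[i, j] = p
    return states, T


def map_successor_oracle(template, mean_cpts, state, clamps=None, rtol=1e-9):
    """Argmax successor by exhaustive enumeration of all next states, ties
    broken toward the lexicographically smallest assignment."""
    clamps = clamps or {}
    nodes = template.network.node_ids
    free = [n for n in nodes if n not in clamps]
    best_p, best_bits = -1.0, None
    for bits in itertools.product((0, 1), repeat=len(free)):
        t = dict(clamps)
        t.update(zip(free, bits))
        p = 1.0
        for n in nodes:
            parents = template.cpt_parents(n)
            idx = tuple(
                (state[src] if inter else t[src]) for src, _, inter in parents
            )
            p1 = float(np.asarray(mean_cpts[n])[idx])
            p *= p1 if t[n] else 1 - p1
        if p > best_p * (1 + rtol):
            best_p, best_bits = p, bits
    t = dict(clamps)
    t.update(zip(free, best_bits))
    return t
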