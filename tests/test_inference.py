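"""Junction-tree inference, steady-state rollout and MAP evolution,
checked against exhaustive-enumeration and transition-matrix oracles."""

import itertools
import math

import numpy as np
import pytest

import qkdbn as q
from qkdbn import synthdata as sd
from qkdbn.inference import (
    EMPTY_EVIDENCE,
    Evidence,
    ImpossibleEvidenceError,
    MapEvolver,
    PotentialEvaluator,
    build_junction_tree,
    calibrate,
    slice_factors,
)

from conftest import brute_force_joint, map_successor_oracle, transition_matrix


def make_model(seed, n=6, density=0.3, n_samples=2, self_loops=False):
    net = sd.make_random_network(n, density=density, seed=seed, self_loops=self_loops)
    tpl = q.unroll_to_2tbn(net)
    cons = q.build_constraints(net)
    ens = q.sample_cpt_ensemble(tpl, cons, n=n_samples, seed=seed)
    return net, tpl, ens


class TestEvidence:
    def test_overlapping_clamp_maps_rejected(self):
        with pytest.raises(ValueError):
            Evidence(hard={"A": 1}, soft={"A": 0.5})

    def test_soft_target_range_checked(self):
        with pytest.raises(ValueError):
            Evidence(soft={"A": 1.5})


class TestJunctionTree:
    def test_two_node_chain_single_cluster(self):
        net = q.RegulatoryNetwork(
            [q.NodeRecord("A"), q.NodeRecord("B")], [("A", "B", 1)]
        )
        tpl = q.unroll_to_2tbn(net)
        jt = build_junction_tree(tpl)
        assert any(set(c) == {"A", "B"} for c in jt.clusters)

    def test_interface_nodes_share_a_cluster(self, skeleton):
        tpl = q.unroll_to_2tbn(skeleton)
        jt = build_junction_tree(tpl)
        iface = set(tpl.interface_sorted())
        assert any(iface <= set(c) for c in jt.clusters)

    @pytest.mark.parametrize("seed", range(6))
    def test_calibration_is_consistent(self, seed):
        net, tpl, ens = make_model(seed)
        jt = build_junction_tree(tpl)
        cal = calibrate(jt, slice_factors(tpl, ens.samples[0]))
        assert cal.max_consistency_gap() < 1e-10

    def test_isolated_node_marginal(self):
        net = q.RegulatoryNetwork([q.NodeRecord("A"), q.NodeRecord("B")], [])
        tpl = q.unroll_to_2tbn(net)
        sample = {"A": np.asarray(0.7), "B": np.asarray(0.2)}
        jt = build_junction_tree(tpl)
        cal = calibrate(jt, slice_factors(tpl, sample))
        assert cal.belief("A") == pytest.approx(0.7)

    def test_impossible_evidence_raises(self):
        net = q.RegulatoryNetwork(
            [q.NodeRecord("A"), q.NodeRecord("B")], [("A", "B", 1)]
        )
        tpl = q.unroll_to_2tbn(net)
        # B is deterministically equal to A=0's row: P(B=1|A)=0 for both rows
        sample = {"A": np.asarray(1.0), "B": np.array([0.0, 0.0])}
        jt = build_junction_tree(tpl)
        from qkdbn._factors import Factor

        factors = slice_factors(tpl, sample) + [Factor.indicator("B", 1)]
        with pytest.raises(ImpossibleEvidenceError):
            calibrate(jt, factors)


class TestJointAgainstEnumeration:
    @pytest.mark.parametrize("seed", [0, 8, 14, 19, 30])
    def test_joint_and_marginals_match_brute_force(self, seed):
        """On acyclic slices the calibrated tree reproduces every joint and
        marginal from exhaustive enumeration to 1e-9."""
        net = sd.make_random_network(7, density=0.25, seed=seed)
        tpl = q.unroll_to_2tbn(net)
        assert tpl.n_interface == 0  # seeds chosen to give acyclic draws
        cons = q.build_constraints(net)
        ens = q.sample_cpt_ensemble(tpl, cons, n=1, seed=seed)
        sample = ens.samples[0]
        jt = build_junction_tree(tpl)
        cal = calibrate(jt, slice_factors(tpl, sample))
        nodes = net.node_ids
        probs = brute_force_joint(tpl, sample, nodes)
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)
        worst = 0.0
        for bits, p in probs.items():
            st = dict(zip(nodes, bits))
            worst = max(worst, abs(cal.joint_probability(st) - p))
        assert worst < 1e-9
        for k, node in enumerate(nodes):
            marg = sum(p for b, p in probs.items() if b[k])
            assert cal.belief(node) == pytest.approx(marg, abs=1e-9)

    def test_deterministic_chain_joint(self):
        net = q.RegulatoryNetwork(
            [q.NodeRecord(n) for n in "ABC"], [("A", "B", 1), ("B", "C", 1)]
        )
        tpl = q.unroll_to_2tbn(net)
        sample = {
            "A": np.asarray(1.0),
            "B": np.array([0.0, 1.0]),
            "C": np.array([0.0, 1.0]),
        }
        jt = build_junction_tree(tpl)
        cal = calibrate(jt, slice_factors(tpl, sample))
        assert cal.joint_probability({"A": 1, "B": 1, "C": 1}) == pytest.approx(1.0)
        assert cal.joint_probability({"A": 1, "B": 0, "C": 1}) == 0.0


class TestSteadyState:
    @pytest.mark.parametrize("seed", [1, 2, 3, 6])
    def test_marginals_match_transition_matrix_fixed_point(self, seed):
        """Steady-state beliefs equal the stationary distribution of the
        exhaustive 2^n transition matrix, per sample, then averaged."""
        net, tpl, ens = make_model(seed, n=6, n_samples=2)
        assert tpl.n_interface > 0  # seeds chosen to give cyclic draws
        nodes = net.node_ids
        oracle = np.zeros(len(nodes))
        for sample in ens.samples:
            states, T = transition_matrix(tpl, sample, nodes)
            pi = np.full(len(states), 1 / len(states))
            for _ in range(20_000):
                nxt = T @ pi
                nxt /= nxt.sum()
                if np.abs(nxt - pi).max() < 1e-14:
                    break
                pi = nxt
            for k in range(len(nodes)):
                oracle[k] += sum(p for b, p in zip(states, pi) if b[k])
        oracle /= len(ens.samples)
        prof = q.infer_marginals(ens, tpl, tol=1e-12, max_steps=1000)
        assert prof.converged
        assert np.abs(prof.vector(nodes) - oracle).max() < 1e-6

    def test_hard_clamp_reported_exactly(self, chain_model):
        _, tpl, _, ens = chain_model
        small = q.ParameterEnsemble(ens.samples[:10], ens.seed, 10, 1.0)
        prof = q.infer_marginals(small, tpl, Evidence(hard={"A": 1}))
        assert prof.belief["A"] == 1.0

    def test_soft_clamp_pins_marginal(self, chain_model):
        _, tpl, _, ens = chain_model
        small = q.ParameterEnsemble(ens.samples[:10], ens.seed, 10, 1.0)
        prof = q.infer_marginals(small, tpl, Evidence(soft={"A": 0.3}))
        assert prof.belief["A"] == pytest.approx(0.3)

    def test_monotone_response_to_activator(self, chain_model):
        """Clamping an activator high can only raise the target's belief,
        for every ensemble sample (consequence of the CPT constraints)."""
        _, tpl, _, ens = chain_model
        for sample in ens.samples[:50]:
            single = q.ParameterEnsemble([sample], 0, 1, 1.0)
            b1 = q.infer_marginals(single, tpl, Evidence(hard={"A": 1}))
            b0 = q.infer_marginals(single, tpl, Evidence(hard={"A": 0}))
            assert b1.belief["B"] >= b0.belief["B"] - 1e-12

    def test_parentless_belief_is_ensemble_mean_prior(self):
        net = q.RegulatoryNetwork([q.NodeRecord("A")], [])
        tpl = q.unroll_to_2tbn(net)
        ens = q.sample_cpt_ensemble(tpl, q.build_constraints(net), n=50, seed=1)
        prof = q.infer_marginals(ens, tpl)
        expected = np.mean([float(s["A"]) for s in ens.samples])
        assert prof.belief["A"] == pytest.approx(expected)


class TestMapEvolution:
    @pytest.mark.parametrize("seed", [2, 4, 9, 15])
    def test_successors_match_exhaustive_argmax(self, seed):
        """MAP successor equals exhaustive enumeration of all next states
        under the ensemble-mean transition model, for every current state."""
        net, tpl, ens = make_model(seed, n=5, n_samples=3, self_loops=True)
        mean = ens.mean_cpts()
        evolver = MapEvolver(ens, tpl)
        nodes = net.node_ids
        for bits in itertools.product((0, 1), repeat=len(nodes)):
            state = dict(zip(nodes, bits))
            assert evolver.successor(state) == map_successor_oracle(
                tpl, mean, state
            )

    def test_bistable_paths_match_basin_table(self, bistable):
        fix = bistable
        order = fix.network.node_ids
        for bits, label in fix.basin_assignment.items():
            rec = q.evolve_map(fix.ensemble, fix.template, dict(zip(order, bits)))
            if label == "hesc":
                assert rec.fixed_point and rec.states[-1] == fix.attractors["hesc"]
            elif label == "differentiated":
                assert (
                    rec.fixed_point
                    and rec.states[-1] == fix.attractors["differentiated"]
                )

    def test_fixed_point_input_is_length_one_path(self, bistable):
        fix = bistable
        rec = q.evolve_map(fix.ensemble, fix.template, fix.attractors["hesc"])
        assert rec.fixed_point and len(rec.states) == 1
        assert rec.converged_to == "hesc_attractor"

    def test_clamped_nodes_stay_fixed_along_path(self, bistable):
        fix = bistable
        clamps = Evidence(hard={"a0": 1})
        rec = q.evolve_map(
            fix.ensemble, fix.template, fix.attractors["differentiated"], clamps
        )
        assert all(s["a0"] == 1 for s in rec.states[1:])

    def test_map_path_deterministic(self, skeleton_model):
        net, tpl, cons, ens = skeleton_model
        init = {**net.differentiated_pattern(), **{n: 0 for n in net.non_markers}}
        a = q.evolve_map(ens, tpl, init)
        b = q.evolve_map(ens, tpl, init)
        assert a.states == b.states and a.converged_to == b.converged_to


class TestPotentialEvaluator:
    def test_uniform_two_node_potential(self):
        net = q.RegulatoryNetwork([q.NodeRecord("A"), q.NodeRecord("B")], [])
        tpl = q.unroll_to_2tbn(net)
        sample = {"A": np.asarray(0.5), "B": np.asarray(0.5)}
        ens = sd.ensemble_from_samples([sample])
        ev = PotentialEvaluator(ens, tpl)
        for bits in itertools.product((0, 1), repeat=2):
            u = ev.potential(dict(zip(["A", "B"], bits)))
            assert u == pytest.approx(-math.log(0.25))

    def test_probabilities_normalize(self, bistable):
        ens = q.sample_cpt_ensemble(
            bistable.template, q.build_constraints(bistable.network), n=3, seed=5
        )
        ev = PotentialEvaluator(ens, bistable.template)
        order = bistable.network.node_ids
        total = sum(
            ev.probability(dict(zip(order, bits)))
            for bits in itertools.product((0, 1), repeat=len(order))
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_projection_distribution_matches_full(self, bistable):
        ens = q.sample_cpt_ensemble(
            bistable.template, q.build_constraints(bistable.network), n=2, seed=8
        )
        ev = PotentialEvaluator(ens, bistable.template)
        proj = ("a0", "b0")
        dist = ev.projection_distribution(proj)
        order = bistable.network.node_ids
        expect = np.zeros((2, 2))
        for bits in itertools.product((0, 1), repeat=len(order)):
            st = dict(zip(order, bits))
            expect[st["a0"], st["b0"]] += ev.probability(st)
        assert np.abs(dist.table - expect).max() < 1e-8
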