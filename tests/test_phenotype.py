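"""Expression-ratio phenotype predictions, validation and potential landscape."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import qkdbn as q
from qkdbn import synthdata as sd
from qkdbn.inference import Evidence, MarginalProfile, PotentialEvaluator
from qkdbn.phenotype import (
    compute_landscape,
    predict_expression_ratio,
    reference_hesc_state,
    state_potential,
    validate_against_measurements,
)


@pytest.fixture(scope="module")
def bistable_ensemble(bistable):
    cons = q.build_constraints(bistable.network)
    return q.sample_cpt_ensemble(bistable.template, cons, n=20, seed=17)


class TestReferenceState:
    def test_masters_report_their_clamp(self, bistable, bistable_ensemble):
        prof = reference_hesc_state(bistable_ensemble, bistable.template)
        for m in bistable.network.masters:
            assert prof.belief[m] == 1.0

    def test_deterministic_toy_propagation(self):
        """Masters activating X and repressing Y with deterministic CPTs
        drive X on and Y off in the reference state."""
        net = q.RegulatoryNetwork(
            [
                q.NodeRecord("M", role="hesc_marker", is_master=True),
                q.NodeRecord("X"),
                q.NodeRecord("Y"),
            ],
            [("M", "X", 1), ("M", "Y", -1)],
        )
        tpl = q.unroll_to_2tbn(net)
        sample = sd.deterministic_cpts(tpl)
        ens = sd.ensemble_from_samples([sample])
        prof = reference_hesc_state(ens, tpl)
        assert prof.belief["X"] == pytest.approx(1.0)
        assert prof.belief["Y"] == pytest.approx(0.0)

    def test_requires_declared_masters(self):
        net = q.RegulatoryNetwork([q.NodeRecord("A")], [])
        tpl = q.unroll_to_2tbn(net)
        ens = q.sample_cpt_ensemble(tpl, q.build_constraints(net), n=2, seed=0)
        with pytest.raises(ValueError, match="master"):
            reference_hesc_state(ens, tpl)

    def test_skeleton_reference_reproduces_marker_pattern(self, skeleton_model):
        """With the masters clamped active, thresholding marker beliefs at
        0.5 recovers the hESC attractor pattern (11 on / 11 off)."""
        net, tpl, cons, ens = skeleton_model
        prof = reference_hesc_state(ens, tpl)
        pattern = {m: int(prof.belief[m] > 0.5) for m in net.markers}
        assert pattern == net.hesc_pattern()


class TestExpressionRatios:
    def test_identical_conditions_give_unit_ratios(self, bistable, bistable_ensemble):
        e = Evidence(hard={"a0": 1})
        pred = predict_expression_ratio(
            bistable_ensemble, bistable.template, e, e
        )
        for g, r in pred.ratio.items():
            assert r == pytest.approx(1.0)
            assert pred.log2_ratio[g] == pytest.approx(0.0)

    def test_clamped_genes_excluded(self, bistable, bistable_ensemble):
        e1 = Evidence(hard={"a0": 1})
        e2 = Evidence(hard={"a0": 0})
        pred = predict_expression_ratio(
            bistable_ensemble, bistable.template, e1, e2
        )
        assert "a0" not in pred.ratio

    def test_ratios_match_enumeration_oracle(self):
        """5-node chain with known CPTs: belief ratios under control vs
        knockdown equal exhaustively enumerated conditional marginals."""
        net = q.RegulatoryNetwork(
            [q.NodeRecord(n) for n in "ABCDE"],
            [("A", "B", 1), ("B", "C", 1), ("C", "D", -1), ("B", "E", 1)],
        )
        tpl = q.unroll_to_2tbn(net)
        assert tpl.n_interface == 0
        cons = q.build_constraints(net)
        ens = q.sample_cpt_ensemble(tpl, cons, n=3, seed=6)
        e1 = Evidence(hard={"A": 1})
        e2 = Evidence(hard={"A": 0})
        pred = predict_expression_ratio(ens, tpl, e1, e2)

        def oracle_belief(sample, clamp_val):
            # interventional clamp: A's CPT replaced by the point mass
            nodes = net.node_ids
            margs = dict.fromkeys(nodes, 0.0)
            for bits in itertools.product((0, 1), repeat=len(nodes)):
                st = dict(zip(nodes, bits))
                if st["A"] != clamp_val:
                    continue
                p = 1.0
                for n in nodes:
                    if n == "A":
                        continue
                    parents = tpl.cpt_parents(n)
                    idx = tuple(st[s] for s, _, _ in parents)
                    p1 = float(np.asarray(sample[n])[idx])
                    p *= p1 if st[n] else 1 - p1
                for n in nodes:
                    if st[n]:
                        margs[n] += p
            return margs

        for gene in pred.ratio:
            num = np.mean([oracle_belief(s, 0)[gene] for s in ens.samples])
            den = np.mean([oracle_belief(s, 1)[gene] for s in ens.samples])
            assert pred.ratio[gene] == pytest.approx(num / den, abs=1e-9)

    def test_zero_denominator_reported_missing(self):
        net = q.RegulatoryNetwork(
            [q.NodeRecord("A"), q.NodeRecord("B")], [("A", "B", 1)]
        )
        tpl = q.unroll_to_2tbn(net)
        sample = {"A": np.asarray(1.0), "B": np.array([0.0, 0.0])}
        ens = sd.ensemble_from_samples([sample])
        pred = predict_expression_ratio(
            ens, tpl, Evidence(hard={"A": 1}), Evidence(hard={"A": 0})
        )
        assert "B" in pred.missing and "B" not in pred.ratio


class TestValidation:
    def _pred(self, values):
        return q.ExpressionRatioPrediction(
            ratio={g: 2.0**v for g, v in values.items()},
            log2_ratio=dict(values),
            missing={},
            e1=Evidence(),
            e2=Evidence(),
        )

    def test_perfect_agreement(self):
        vals = {f"g{i}": x for i, x in enumerate([-1.0, 0.2, 0.8, 1.5, -0.4])}
        pred = self._pred(vals)
        measured = pd.DataFrame(
            {"gene": list(vals), "log2fc": list(vals.values())}
        )
        rep = validate_against_measurements(pred, measured)
        assert rep.pooled_r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        vals = {f"g{i}": x for i, x in enumerate([-1.0, 0.2, 0.8, 1.5, -0.4])}
        pred = self._pred(vals)
        measured = pd.DataFrame(
            {"gene": list(vals), "log2fc": [-v for v in vals.values()]}
        )
        rep = validate_against_measurements(pred, measured)
        assert rep.pooled_r == pytest.approx(-1.0)

    def test_attenuated_correlation_within_fisher_band(self):
        """measured = 2*predicted + noise: the sample r must fall inside the
        95% Fisher-z interval around the construction's true correlation."""
        rng = np.random.default_rng(3)
        n = 200
        x = rng.normal(size=n)
        sigma = 1.0
        y = 2 * x + rng.normal(scale=sigma, size=n)
        true_r = 2 / math.sqrt(4 + sigma**2)
        pred = self._pred({f"g{i}": float(v) for i, v in enumerate(x)})
        measured = pd.DataFrame(
            {"gene": [f"g{i}" for i in range(n)], "log2fc": y}
        )
        rep = validate_against_measurements(pred, measured)
        z = 0.5 * math.log((1 + rep.pooled_r) / (1 - rep.pooled_r))
        z_true = 0.5 * math.log((1 + true_r) / (1 - true_r))
        assert abs(z - z_true) < 1.96 / math.sqrt(n - 3)

    def test_insufficient_overlap_raises(self):
        pred = self._pred({"g0": 1.0})
        measured = pd.DataFrame({"gene": ["g0"], "log2fc": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            validate_against_measurements(pred, measured)

    def test_per_experiment_mode(self):
        vals = {f"g{i}": float(i) for i in range(6)}
        pred = self._pred(vals)
        measured = pd.DataFrame(
            {
                "gene": list(vals) * 2,
                "log2fc": list(vals.values()) + [-v for v in vals.values()],
                "experiment": ["e1"] * 6 + ["e2"] * 6,
            }
        )
        rep = validate_against_measurements(pred, measured)
        per = rep.per_experiment.set_index("experiment")
        assert per.loc["e1", "r"] == pytest.approx(1.0)
        assert per.loc["e2", "r"] == pytest.approx(-1.0)


class TestPotentials:
    def test_certain_state_has_zero_potential(self):
        net = q.RegulatoryNetwork(
            [q.NodeRecord("A"), q.NodeRecord("B")], [("A", "B", 1)]
        )
        tpl = q.unroll_to_2tbn(net)
        sample = {"A": np.asarray(1.0), "B": np.array([0.0, 1.0])}
        ens = sd.ensemble_from_samples([sample])
        u = state_potential(ens, tpl, {"A": 1, "B": 1})
        assert u == pytest.approx(0.0, abs=1e-12)
        assert state_potential(ens, tpl, {"A": 0, "B": 0}) == math.inf

    def test_potential_matches_enumeration(self, bistable, bistable_ensemble):
        ev = PotentialEvaluator(bistable_ensemble, bistable.template)
        order = bistable.network.node_ids
        rng = np.random.default_rng(2)
        for _ in range(20):
            bits = tuple(rng.integers(0, 2, len(order)))
            st = dict(zip(order, bits))
            u = ev.potential(st)
            assert math.exp(-u) == pytest.approx(ev.probability(st), rel=1e-8)


class TestLandscape:
    def test_single_condition_normalizes(self, bistable, bistable_ensemble):
        scape = compute_landscape(
            bistable_ensemble,
            bistable.template,
            projection=bistable.network.node_ids,
            levels=(1.0,),
        )
        assert scape.distribution.table.sum() == pytest.approx(1.0, abs=1e-8)

    def test_grid_conditions_each_normalize(self, bistable, bistable_ensemble):
        scape = compute_landscape(
            bistable_ensemble,
            bistable.template,
            projection=bistable.network.node_ids,
            levels=(0.0, 0.5, 1.0),
        )
        for mass in scape.per_condition_mass:
            assert mass == pytest.approx(1.0, abs=1e-8)
        assert scape.distribution.table.sum() == pytest.approx(1.0, abs=1e-8)

    def test_planted_attractors_are_local_minima(self, bistable, bistable_ensemble):
        """Both planted attractor marker patterns must have strictly lower
        potential than every single-bit neighbour (the barrier property).
        Cell states are defined over the markers; the feeder non-markers
        carry flat priors and are marginalized out."""
        markers = bistable.network.markers
        scape = compute_landscape(
            bistable_ensemble,
            bistable.template,
            projection=markers,
            levels=(0.0, 0.5, 1.0),
        )
        for name in ("hesc", "differentiated"):
            pattern = {m: bistable.attractors[name][m] for m in markers}
            assert scape.is_local_minimum(pattern, strict=True)

    def test_two_deepest_minima_are_the_attractors(self, bistable, bistable_ensemble):
        """On the unclamped steady-state landscape the two highest-
        probability marker states are exactly the planted attractors."""
        markers = bistable.network.markers
        scape = compute_landscape(
            bistable_ensemble,
            bistable.template,
            projection=markers,
            scan_nodes=[],
        )
        top2 = scape.minima(2)
        expected = [
            {m: bistable.attractors[a][m] for m in markers}
            for a in ("hesc", "differentiated")
        ]
        assert all(s in expected for s in top2)

    def test_potential_ordering_invariant_to_rescaling(
        self, bistable, bistable_ensemble
    ):
        """Adding a constant log-offset (positive rescaling of unnormalized
        potentials) leaves the potential ordering unchanged."""
        scape = compute_landscape(
            bistable_ensemble,
            bistable.template,
            projection=bistable.network.node_ids,
            levels=(1.0,),
        )
        frame = scape.to_frame()
        finite = frame[np.isfinite(frame["potential"])]
        order1 = finite.sort_values("potential")["state"].tolist()
        shifted = finite.assign(potential=finite["potential"] + 3.7)
        order2 = shifted.sort_values("potential")["state"].tolist()
        assert order1 == order2
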