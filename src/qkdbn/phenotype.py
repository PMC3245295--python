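"""Perturbation phenotypes and the cell-state potential landscape.

Node beliefs P(g=1 | E) are treated as linearly proportional to expression
level, so the ratio of steady-state beliefs under two conditions predicts the
expression fold change with all unknown per-gene proportionality scalars
cancelling.  The potential of a cell state is U(S) = -ln P(S); attractors are
potential minima.  The landscape is assembled by scanning the master
regulators over a grid of clamped activity levels, normalizing each
condition's state distribution and summing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._factors import Factor
from .constraints import ParameterEnsemble
from .inference import (
    EMPTY_EVIDENCE,
    CellState,
    Evidence,
    MarginalProfile,
    PotentialEvaluator,
    infer_marginals,
)
from .network import TwoSliceTemplate

DEFAULT_MASTER_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


def reference_hesc_state(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    **kwargs,
) -> MarginalProfile:
    """Steady-state beliefs with every master regulator hard-clamped to 1.

    This is the undisturbed hESC reference condition (OCT4/SOX2/NANOG active).
    """
    masters = template.network.masters
    if not masters:
        raise ValueError("network declares no master regulators")
    evidence = Evidence(hard={m: 1 for m in masters})
    return infer_marginals(ensemble, template, evidence, **kwargs)


# ---------------------------------------------------------------------------
# Expression-ratio prediction
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRatioPrediction:
    """Per-gene belief ratios P(g=1|E2)/P(g=1|E1) and their log2 values.

    Genes clamped in either condition are excluded (clamped levels are inputs,
    not predictions); zero-denominator genes are reported as missing with a
    reason instead of infinities.
    """

    ratio: dict[str, float]
    log2_ratio: dict[str, float]
    missing: dict[str, str]
    e1: Evidence
    e2: Evidence

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.ratio)
        return pd.DataFrame(
            {
                "gene": genes,
                "ratio": [self.ratio[g] for g in genes],
                "log2_ratio": [self.log2_ratio[g] for g in genes],
            }
        ).set_index("gene")


def predict_expression_ratio(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    e1: Evidence,
    e2: Evidence,
    profiles: tuple[MarginalProfile, MarginalProfile] | None = None,
    **kwargs,
) -> ExpressionRatioPrediction:
    """Predicted expression change between conditions E1 (e.g. control) and
    E2 (e.g. knockdown) as the ratio of steady-state beliefs."""
    if profiles is None:
        p1 = infer_marginals(ensemble, template, e1, **kwargs)
        p2 = infer_marginals(ensemble, template, e2, **kwargs)
    else:
        p1, p2 = profiles
    ratio: dict[str, float] = {}
    log2_ratio: dict[str, float] = {}
    missing: dict[str, str] = {}
    clamped = e1.clamped | e2.clamped
    for gene in template.network.node_ids:
        if gene in clamped:
            continue
        denom = p1.belief[gene]
        num = p2.belief[gene]
        if denom == 0.0:
            missing[gene] = "zero belief under E1"
            continue
        r = num / denom
        ratio[gene] = r
        log2_ratio[gene] = math.log2(r) if r > 0 else -math.inf
    return ExpressionRatioPrediction(
        ratio=ratio, log2_ratio=log2_ratio, missing=missing, e1=e1, e2=e2
    )


@dataclass
class CorrelationReport:
    """Pearson agreement between predicted and measured log2 fold changes."""

    pooled_r: float
    pooled_p: float
    n_pooled: int
    per_experiment: pd.DataFrame  # columns: experiment, r, p, n


def validate_against_measurements(
    pred: ExpressionRatioPrediction,
    measured: pd.DataFrame,
) -> CorrelationReport:
    """Correlate predicted log2 ratios with measured log2 fold changes.

    ``measured`` needs columns ``gene`` and ``log2fc`` and may carry an
    ``experiment`` column for per-experiment reporting.  At least three
    overlapping genes are required.
    """
    if "experiment" not in measured.columns:
        measured = measured.assign(experiment="all")
    rows = []
    pooled_pred: list[float] = []
    pooled_meas: list[float] = []
    for exp, grp in measured.groupby("experiment", sort=True):
        xs, ys = [], []
        for gene, value in zip(grp["gene"], grp["log2fc"]):
            lr = pred.log2_ratio.get(gene)
            if lr is None or not math.isfinite(lr):
                continue
            xs.append(lr)
            ys.append(float(value))
        pooled_pred.extend(xs)
        pooled_meas.extend(ys)
        if len(xs) >= 3:
            r, p = stats.pearsonr(xs, ys)
            rows.append({"experiment": exp, "r": r, "p": p, "n": len(xs)})
        else:
            rows.append({"experiment": exp, "r": np.nan, "p": np.nan, "n": len(xs)})
    if len(pooled_pred) < 3:
        raise ValueError(
            f"insufficient overlap: {len(pooled_pred)} genes in common (need >= 3)"
        )
    r, p = stats.pearsonr(pooled_pred, pooled_meas)
    return CorrelationReport(
        pooled_r=float(r),
        pooled_p=float(p),
        n_pooled=len(pooled_pred),
        per_experiment=pd.DataFrame(rows),
    )


# ---------------------------------------------------------------------------
# Potentials and landscape
# ---------------------------------------------------------------------------

def state_potential(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    state: CellState,
    condition: Evidence = EMPTY_EVIDENCE,
    evaluator: PotentialEvaluator | None = None,
) -> float:
    """U(S) = -ln of the model-averaged steady-state P(S | condition).

    Finite for states of positive probability; +inf sentinel otherwise.
    Pass a prebuilt :class:`PotentialEvaluator` to amortize convergence cost
    over many states.
    """
    if evaluator is None:
        evaluator = PotentialEvaluator(ensemble, template, condition)
    return evaluator.potential(state)


@dataclass
class Landscape:
    """Cell-state potential landscape over a node-subset projection.

    ``distribution`` is the grid-summed, renormalized state distribution over
    the projection; potentials are U = -ln of that probability.
    """

    projection: tuple[str, ...]
    distribution: Factor
    conditions: list[Evidence]
    per_condition_mass: list[float] = field(default_factory=list)

    def potential_of(self, state: Mapping[str, int]) -> float:
        p = float(self.distribution.table[tuple(state[v] for v in self.projection)])
        return -math.log(p) if p > 0 else math.inf

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = len(self.projection)
        flat = self.distribution.table.ravel()
        for flat_idx, p in enumerate(flat):
            bits = np.unravel_index(flat_idx, (2,) * n)
            rows.append(
                {
                    "state": "".join(str(b) for b in bits),
                    "probability": float(p),
                    "potential": -math.log(p) if p > 0 else math.inf,
                }
            )
        return pd.DataFrame(rows)

    def minima(self, k: int = 2) -> list[dict[str, int]]:
        """The k lowest-potential (highest-probability) projected states."""
        n = len(self.projection)
        flat = self.distribution.table.ravel()
        best = np.argsort(-flat, kind="stable")[:k]
        out = []
        for flat_idx in best:
            bits = np.unravel_index(int(flat_idx), (2,) * n)
            out.append(dict(zip(self.projection, map(int, bits))))
        return out

    def is_local_minimum(self, state: Mapping[str, int], strict: bool = True) -> bool:
        """Is the state's potential below that of every single-bit neighbour?"""
        u0 = self.potential_of(state)
        for v in self.projection:
            nb = dict(state)
            nb[v] = 1 - nb[v]
            u = self.potential_of(nb)
            if (u <= u0) if strict else (u < u0):
                return False
        return True


def compute_landscape(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    projection: Sequence[str] | None = None,
    levels: Sequence[float] = DEFAULT_MASTER_GRID,
    scan_nodes: Sequence[str] | None = None,
    projection_cap: int = 20,
    mc_draws: int = 100_000,
    seed: int = 0,
    **kwargs,
) -> Landscape:
    """Scan the master regulators over a soft-clamp grid and assemble the
    summed, renormalized state distribution over the projection.

    By default the scan runs over all ``levels``-tuples for the network's
    master regulators and the projection is the 22 marker genes (all nodes if
    the network has no markers).  Projections above ``projection_cap`` nodes
    fall back to seeded Monte-Carlo sampling.
    """
    net = template.network
    if scan_nodes is None:
        scan_nodes = net.masters
    if projection is None:
        projection = net.markers or net.node_ids
    projection = tuple(sorted(projection))
    if len(projection) > projection_cap and mc_draws <= 0:
        raise ValueError(f"projection of {len(projection)} nodes exceeds cap")

    if scan_nodes:
        grids = np.meshgrid(*[list(levels)] * len(scan_nodes), indexing="ij")
        combos = np.stack([g.ravel() for g in grids], axis=-1)
        conditions = [
            Evidence(soft={n: float(q) for n, q in zip(scan_nodes, combo)})
            for combo in combos
        ]
    else:
        conditions = [EMPTY_EVIDENCE]

    acc = np.zeros((2,) * len(projection))
    masses: list[float] = []
    for cond in conditions:
        ev = PotentialEvaluator(ensemble, template, cond, **kwargs)
        dist = ev.projection_distribution(
            projection, exact_cap=projection_cap, n_draws=mc_draws, seed=seed
        )
        masses.append(float(dist.table.sum()))
        acc += dist.table / dist.table.sum()
    acc /= acc.sum()
    return Landscape(
        projection=projection,
        distribution=Factor(projection, acc),
        conditions=conditions,
        per_condition_mass=masses,
    )
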