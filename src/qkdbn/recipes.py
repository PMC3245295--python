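"""Combinatorial screening of reprogramming recipes.

A recipe is a set of overexpressed genes (clamped active) plus optionally
knocked-down genes (clamped inactive).  Reprogramming efficiency is the
fraction of randomly initialized differentiated states (markers at the
differentiated pattern, non-markers i.i.d. Bernoulli(1/2)) whose MAP
evolution under the recipe's sustained clamps reaches the hESC-marker
attractor (all ES markers on, all differentiation markers off).  Expression
similarity compares the recipe's converged belief vector against the
reference hESC state (masters clamped active) by RMSD and Pearson/Spearman
correlation.  Candidate recipes are ranked by averaged rank over the four
criteria with 3-standard-deviation similarity cutoffs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constraints import ParameterEnsemble
from .inference import (
    Evidence,
    MapEvolver,
    MarginalProfile,
    PathRecord,
    evolve_map,
    infer_marginals,
)
from .network import TwoSliceTemplate
from .phenotype import reference_hesc_state


@dataclass(frozen=True)
class Recipe:
    """Overexpression / knockdown clamp sets defining one perturbation."""

    overexpress: frozenset[str]
    knockdown: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        overlap = self.overexpress & self.knockdown
        if overlap:
            raise ValueError(f"genes both over- and under-expressed: {sorted(overlap)}")

    @property
    def label(self) -> str:
        lab = "_".join(sorted(self.overexpress))
        if self.knockdown:
            lab += "&" + "_".join(sorted(self.knockdown))
        return lab

    def evidence(self) -> Evidence:
        hard = {g: 1 for g in self.overexpress}
        hard.update({g: 0 for g in self.knockdown})
        return Evidence(hard=hard)


def enumerate_overexpression_recipes(genes: list[str], k: int) -> list[Recipe]:
    """All C(len(genes), k) unordered overexpression combinations, in
    deterministic lexicographic order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(genes):
        warnings.warn(f"k={k} exceeds {len(genes)} genes; no recipes")
        return []
    return [
        Recipe(overexpress=frozenset(combo))
        for combo in itertools.combinations(sorted(genes), k)
    ]


@dataclass
class RecipeEvaluation:
    """Efficiency plus expression-similarity criteria for one recipe."""

    recipe: Recipe
    efficiency: float
    rmsd: float
    pearson: float
    spearman: float
    n_init: int
    seed: int
    n_converged: int = 0
    provenance: str = "user"
    skipped_knockdown: frozenset[str] = frozenset()
    paths: list[PathRecord] | None = None

    def criteria(self) -> dict[str, float]:
        return {
            "efficiency": self.efficiency,
            "rmsd": self.rmsd,
            "pearson": self.pearson,
            "spearman": self.spearman,
        }


def _similarity(
    profile: MarginalProfile,
    reference: MarginalProfile,
    nodes: list[str],
) -> tuple[float, float, float]:
    x = profile.vector(nodes)
    y = reference.vector(nodes)
    rmsd = float(np.sqrt(np.mean((x - y) ** 2)))
    if np.std(x) == 0 or np.std(y) == 0:
        return rmsd, math.nan, math.nan
    pear = float(stats.pearsonr(x, y).statistic)
    spear = float(stats.spearmanr(x, y).statistic)
    return rmsd, pear, spear


@dataclass
class EfficiencyResult:
    """Reprogramming efficiency of one recipe over sampled initial states."""

    efficiency: float
    n_init: int
    n_converged: int
    paths: list[PathRecord] | None = None


def _check_recipe(net, recipe: Recipe) -> None:
    if not net.markers:
        raise ValueError("network defines no marker roles")
    for g in recipe.overexpress | recipe.knockdown:
        if g not in net:
            raise ValueError(f"recipe gene {g!r} not in network")
        if net.nodes[g].is_complex:
            raise ValueError(f"recipe gene {g!r} is a complex; clamp its components")


def reprogramming_efficiency(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    recipe: Recipe,
    n_init: int = 10_000,
    seed: int = 0,
    max_steps: int = 50,
    return_paths: bool = False,
) -> EfficiencyResult:
    """Fraction of randomly initialized differentiated states whose MAP
    evolution under the recipe's clamps reaches the hESC-marker attractor.

    Initial states fix the markers at the differentiated pattern and draw
    the non-markers i.i.d. Bernoulli(1/2); when the non-marker state space
    is no larger than ``n_init`` every initial state is enumerated exactly.
    Non-converged paths (limit cycles, step cap) count as failures.
    """
    net = template.network
    _check_recipe(net, recipe)
    clamps = recipe.evidence()
    evolver = MapEvolver(ensemble, template, clamps)
    diff_pattern = net.differentiated_pattern()
    non_markers = net.non_markers

    n_space = 2 ** len(non_markers)
    if n_space <= n_init:
        initials = itertools.product((0, 1), repeat=len(non_markers))
        n_used = n_space
    else:
        rng = np.random.default_rng(seed)
        draws = rng.integers(0, 2, size=(n_init, len(non_markers)))
        initials = (tuple(int(b) for b in row) for row in draws)
        n_used = n_init

    n_success = n_converged = 0
    paths: list[PathRecord] | None = [] if return_paths else None
    for bits in initials:
        state = dict(diff_pattern)
        state.update(zip(non_markers, bits))
        rec = evolve_map(
            ensemble, template, state, clamps, max_steps=max_steps, evolver=evolver
        )
        if rec.fixed_point:
            n_converged += 1
            if rec.converged_to == "hesc_attractor":
                n_success += 1
        if paths is not None:
            paths.append(rec)
    return EfficiencyResult(
        efficiency=n_success / n_used,
        n_init=n_used,
        n_converged=n_converged,
        paths=paths,
    )


def evaluate_recipe(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    recipe: Recipe,
    n_init: int = 10_000,
    seed: int = 0,
    reference: MarginalProfile | None = None,
    max_steps: int = 50,
    exclude_clamped: bool = False,
    return_paths: bool = False,
    **infer_kwargs,
) -> RecipeEvaluation:
    """Evaluate one recipe: efficiency over random differentiated initials
    and similarity of the converged belief vector to the hESC reference."""
    net = template.network
    clamps = recipe.evidence()
    eff = reprogramming_efficiency(
        ensemble, template, recipe, n_init=n_init, seed=seed,
        max_steps=max_steps, return_paths=return_paths,
    )
    if reference is None:
        reference = reference_hesc_state(ensemble, template, **infer_kwargs)
    init_state = dict(net.differentiated_pattern())
    init_state.update({n: 0 for n in net.non_markers})
    profile = infer_marginals(
        ensemble, template, clamps, initial_state=init_state, **infer_kwargs
    )
    nodes = net.node_ids
    if exclude_clamped:
        nodes = [n for n in nodes if n not in clamps.clamped]
    rmsd, pear, spear = _similarity(profile, reference, nodes)
    return RecipeEvaluation(
        recipe=recipe,
        efficiency=eff.efficiency,
        rmsd=rmsd,
        pearson=pear,
        spearman=spear,
        n_init=eff.n_init,
        seed=seed,
        n_converged=eff.n_converged,
        provenance=net.provenance,
        paths=eff.paths,
    )


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

@dataclass
class RankedRecipeList:
    """Per-criterion ranks, averaged rank score, and 3-SD pass flags."""

    table: pd.DataFrame
    cutoffs: dict[str, float]
    sd_multiplier: float

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.nsmallest(k, "avg_rank")


def rank_recipes(
    evals: list[RecipeEvaluation], sd_multiplier: float = 3.0
) -> RankedRecipeList:
    """Rank recipes on each criterion (efficiency/correlations descending,
    RMSD ascending; ties get average ranks), average the ranks, and flag
    recipes passing the favorable-side mean +/- k*SD cutoff of each
    similarity criterion, computed over the efficiency>0 subset."""
    if len(evals) < 2:
        raise ValueError("need at least 2 evaluations to rank")
    df = pd.DataFrame(
        {
            "label": [e.recipe.label for e in evals],
            "efficiency": [e.efficiency for e in evals],
            "rmsd": [e.rmsd for e in evals],
            "pearson": [e.pearson for e in evals],
            "spearman": [e.spearman for e in evals],
        }
    )
    df["rank_efficiency"] = stats.rankdata(-df["efficiency"])
    df["rank_rmsd"] = stats.rankdata(df["rmsd"])
    df["rank_pearson"] = stats.rankdata(-df["pearson"])
    df["rank_spearman"] = stats.rankdata(-df["spearman"])
    df["avg_rank"] = df[
        ["rank_efficiency", "rank_rmsd", "rank_pearson", "rank_spearman"]
    ].mean(axis=1)

    positive = df[df["efficiency"] > 0]
    basis = positive if len(positive) >= 2 else df
    cutoffs = {
        "rmsd": float(basis["rmsd"].mean() + sd_multiplier * basis["rmsd"].std(ddof=1)),
        "pearson": float(
            basis["pearson"].mean() - sd_multiplier * basis["pearson"].std(ddof=1)
        ),
        "spearman": float(
            basis["spearman"].mean() - sd_multiplier * basis["spearman"].std(ddof=1)
        ),
    }
    df["pass_rmsd"] = df["rmsd"] <= cutoffs["rmsd"]
    df["pass_pearson"] = df["pearson"] >= cutoffs["pearson"]
    df["pass_spearman"] = df["spearman"] >= cutoffs["spearman"]
    df["pass_all"] = df[["pass_rmsd", "pass_pearson", "pass_spearman"]].all(axis=1)
    df = df.sort_values("avg_rank", kind="stable").reset_index(drop=True)
    return RankedRecipeList(table=df, cutoffs=cutoffs, sd_multiplier=sd_multiplier)


# ---------------------------------------------------------------------------
# Knockdown-augmentation screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    """Evaluations of base recipes and their single-knockdown augmentations."""

    base_evaluations: dict[str, RecipeEvaluation]
    evaluations: list[RecipeEvaluation]
    pairs: list[tuple[Recipe, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (base, gene), ev in zip(self.pairs, self.evaluations):
            base_ev = self.base_evaluations[base.label]
            rows.append(
                {
                    "base": base.label,
                    "knockdown": gene,
                    "label": ev.recipe.label,
                    "skipped": bool(ev.skipped_knockdown),
                    "efficiency": ev.efficiency,
                    "delta_efficiency": ev.efficiency - base_ev.efficiency,
                    "rmsd": ev.rmsd,
                    "delta_rmsd": ev.rmsd - base_ev.rmsd,
                    "pearson": ev.pearson,
                    "delta_pearson": ev.pearson - base_ev.pearson,
                    "spearman": ev.spearman,
                    "delta_spearman": ev.spearman - base_ev.spearman,
                    "provenance": ev.provenance,
                }
            )
        return pd.DataFrame(rows)


def knockdown_screen(
    ensemble: ParameterEnsemble,
    template: TwoSliceTemplate,
    base_recipes: list[Recipe],
    genes: list[str],
    n_init: int = 10_000,
    seed: int = 0,
    reference: MarginalProfile | None = None,
    **eval_kwargs,
) -> ScreenResult:
    """Augment each base recipe with every single-gene knockdown.

    One evaluation is produced per (base, gene) pair.  When the gene already
    belongs to the base's overexpression set the knockdown is skipped with a
    warning and the pair reports the unaugmented base evaluation.
    """
    if reference is None:
        reference = reference_hesc_state(ensemble, template)
    base_evals: dict[str, RecipeEvaluation] = {}
    for base in base_recipes:
        base_evals[base.label] = evaluate_recipe(
            ensemble, template, base, n_init=n_init, seed=seed,
            reference=reference, **eval_kwargs,
        )
    evaluations: list[RecipeEvaluation] = []
    pairs: list[tuple[Recipe, str]] = []
    cache: dict[str, RecipeEvaluation] = {}
    for base in base_recipes:
        for gene in genes:
            pairs.append((base, gene))
            if gene in base.overexpress:
                warnings.warn(
                    f"knockdown {gene} already overexpressed in {base.label}; skipped"
                )
                ev = base_evals[base.label]
                ev = RecipeEvaluation(
                    **{**ev.__dict__, "skipped_knockdown": frozenset({gene})}
                )
                evaluations.append(ev)
                continue
            aug = Recipe(
                overexpress=base.overexpress,
                knockdown=base.knockdown | {gene},
            )
            if aug.label not in cache:
                cache[aug.label] = evaluate_recipe(
                    ensemble, template, aug, n_init=n_init, seed=seed,
                    reference=reference, **eval_kwargs,
                )
            evaluations.append(cache[aug.label])
    return ScreenResult(
        base_evaluations=base_evals, evaluations=evaluations, pairs=pairs
    )
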