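"""Aggregate MAP reprogramming paths into dynamical-flux statistics.

The dynamical flux of a (step, cell state) pair is the number of MAP paths
traversing that state at that step; states whose flux exceeds a cutoff are
reported as probable transition states of reprogramming.  Cell states are
projected onto the marker genes by default.  Marker trajectories average
marker expression per simulation step over the active paths, with paths that
converged early treated as absorbed in their final state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import PathRecord

#: the published screens used 100,000 initializations; flux cutoffs are
#: rescaled proportionally when fewer paths are simulated
REFERENCE_PATHS = 100_000
DEFAULT_FLUX_CUTOFF = 1000


def _project(state: dict[str, int], projection: Sequence[str]) -> str:
    return "".join(str(state[v]) for v in projection)


@dataclass
class FluxTable:
    """Per-(step, projected state) path counts."""

    table: pd.DataFrame  # columns: step, state, flux
    projection: tuple[str, ...]
    total_paths: int

    def flux_at(self, step: int, state: str) -> int:
        sel = self.table[(self.table["step"] == step) & (self.table["state"] == state)]
        return int(sel["flux"].sum())

    def active_paths(self, step: int) -> int:
        return int(self.table.loc[self.table["step"] == step, "flux"].sum())


def compute_flux(
    paths: list[PathRecord],
    projection: Sequence[str],
    include_absorbed: bool = False,
) -> FluxTable:
    """Count paths traversing each projected state at each step.

    Steps are aligned at the initialization (step 0).  By default only the
    recorded states are counted; with ``include_absorbed`` converged paths
    keep contributing their final state at later steps up to the longest
    path.
    """
    if not paths:
        raise ValueError("no paths given")
    projection = tuple(sorted(projection))
    counts: dict[tuple[int, str], int] = {}
    horizon = max(len(p.states) for p in paths)
    for p in paths:
        for step, state in enumerate(p.states):
            key = (step, _project(state, projection))
            counts[key] = counts.get(key, 0) + 1
        if include_absorbed and p.fixed_point:
            final = _project(p.states[-1], projection)
            for step in range(len(p.states), horizon):
                counts[(step, final)] = counts.get((step, final), 0) + 1
    df = pd.DataFrame(
        [{"step": s, "state": st, "flux": c} for (s, st), c in sorted(counts.items())]
    )
    return FluxTable(table=df, projection=projection, total_paths=len(paths))


@dataclass
class TransitionStateReport:
    """High-flux (step, state) entries and their flux-weighted summaries."""

    entries: pd.DataFrame  # step, state, flux (flux > cutoff)
    weighted_means: pd.DataFrame  # per step: flux-weighted mean marker values
    cutoff: float
    projection: tuple[str, ...]

    def states(self) -> list[str]:
        return sorted(self.entries["state"].unique())

    def step_range(self, state: str) -> tuple[int, int]:
        steps = self.entries.loc[self.entries["state"] == state, "step"]
        return int(steps.min()), int(steps.max())


def transition_states(
    flux: FluxTable,
    cutoff: float = DEFAULT_FLUX_CUTOFF,
    reference_paths: int = REFERENCE_PATHS,
    scale: bool = True,
) -> TransitionStateReport:
    """Filter the flux table to probable transition states.

    ``cutoff`` is interpreted on the ``reference_paths`` scale and rescaled
    proportionally to the actual number of simulated paths unless ``scale``
    is disabled.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    eff_cutoff = cutoff * flux.total_paths / reference_paths if scale else cutoff
    entries = flux.table[flux.table["flux"] > eff_cutoff].reset_index(drop=True)

    rows = []
    bits = np.array(
        [[int(ch) for ch in state] for state in entries["state"]]
    ) if len(entries) else np.zeros((0, len(flux.projection)))
    for step, grp_idx in entries.groupby("step").groups.items():
        w = entries.loc[grp_idx, "flux"].to_numpy(dtype=float)
        sub = bits[list(grp_idx)]  # positional: entries has a fresh range index
        mean = (sub * w[:, None]).sum(axis=0) / w.sum()
        rows.append({"step": step, **dict(zip(flux.projection, mean))})
    weighted = pd.DataFrame(rows)
    return TransitionStateReport(
        entries=entries,
        weighted_means=weighted,
        cutoff=eff_cutoff,
        projection=flux.projection,
    )


def marker_trajectory(
    paths: list[PathRecord],
    markers: Sequence[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean marker expression per step plus the number of distinct projected
    states per step.

    Converged paths are absorbed: their final state repeats for trailing
    steps so every path contributes to every step; non-converged paths only
    contribute their recorded steps.
    """
    if not paths:
        raise ValueError("no paths given")
    markers = tuple(sorted(markers))
    horizon = max(
        len(p.states) for p in paths
    )
    sums = np.zeros((horizon, len(markers)))
    counts = np.zeros(horizon)
    distinct: list[set[str]] = [set() for _ in range(horizon)]
    for p in paths:
        for step in range(horizon):
            if step < len(p.states):
                state = p.states[step]
            elif p.fixed_point:
                state = p.states[-1]
            else:
                continue
            sums[step] += [state[m] for m in markers]
            counts[step] += 1
            distinct[step].add(_project(state, markers))
    means = pd.DataFrame(
        sums / counts[:, None], columns=list(markers)
    )
    means.index.name = "step"
    n_distinct = pd.Series(
        [len(d) for d in distinct], name="n_distinct_states"
    )
    return means, n_distinct
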