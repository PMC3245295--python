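# qkdbn — qualitative-knowledge dynamic Bayesian networks for regulatory networks

`qkdbn` answers quantitative questions about a gene-regulatory network when
the only available knowledge is qualitative: the network's topology and the
sign of each regulation (activation or repression).  It was built for the
systems-biology setting exemplified by human embryonic stem cells (hESCs),
where a literature-curated signed network exists but temporal expression
data to train a dynamical model do not, and where the questions are:

- What does the cell-state potential landscape look like — which states
  are attractors, which are barriers?
- What happens to every gene's expression when one gene is knocked down or
  overexpressed?
- Which combinations of overexpressed transcription factors reprogram a
  differentiated cell into an induced pluripotent stem cell (iPSC), with
  what efficiency, and which additional knockdowns improve a recipe?

## The model in brief

Every gene g is a binary variable (1 = maximally expressed); P(g = 1 | E)
under condition E is treated as proportional to expression level.  Feedback
loops are unrolled into a two-time-slice Bayesian network (2TBN): a greedy
procedure scores loop nodes by B/(1−A) (B = number of simple cycles through
the node, A = 1 for must-cut auto-regulators) and redirects cut edges
across time slices, leaving an acyclic intra-slice graph and an *outgoing
interface* whose joint potential (size 2^n) carries the dynamics forward.

Signed edges become qualitative parameter constraints Ω on the conditional
probability tables θ: activation means P(g = 1 | parents) is monotone
non-decreasing in that parent, repression non-increasing; protein complexes
are AND gates over their components.  With a uniform prior over the
constrained region, inference integrates over models,

    P(X | E, Ω) = ∫ P(X | E, θ) P(θ | Ω) dθ ,

realized empirically by a seeded ensemble of constraint-satisfying CPT
samples (rejection sampling, with Gibbs-within-the-polytope sweeps for
high in-degree nodes).  Exact junction-tree message passing on the 2TBN,
iterated through the interface potential to its fixed point, yields
steady-state beliefs per sample; averaging over the ensemble gives the
model-averaged answer.  Derived quantities:

- expression ratios  r_g = P(g=1|E₂) / P(g=1|E₁)  (fold-change predictions
  in which unknown per-gene scalars cancel),
- cell-state potentials  U(S) = −ln P(S | E)  and master-regulator-scanned
  landscapes (attractors are potential minima),
- maximum-a-posteriori (MAP) state-transition paths under sustained clamps,
  from which reprogramming efficiency, dynamical flux and transition states
  are computed.

## Worked example

```python
import qkdbn as q
from qkdbn import synthdata as sd

net = sd.make_hesc_skeleton()          # 30 nodes, 22 marker genes, provenance "skeleton"
tpl = q.unroll_to_2tbn(net)            # interface of 13 nodes, all loops broken
cons = q.build_constraints(net)        # one monotonicity constraint per edge
ens = q.sample_cpt_ensemble(tpl, cons, n=60, seed=7)

from qkdbn.recipes import Recipe, evaluate_recipe
from qkdbn.phenotype import reference_hesc_state

ref = reference_hesc_state(ens, tpl)   # OCT4/SOX2/NANOG clamped active
osk = Recipe(frozenset({"OCT4", "SOX2", "KLF4"}))
osk_kd = Recipe(frozenset({"OCT4", "SOX2", "KLF4"}), frozenset({"GATA6"}))
for r in (osk, osk_kd):
    ev = evaluate_recipe(ens, tpl, r, n_init=256, seed=1, reference=ref)
    print(f"{r.label}: efficiency={ev.efficiency:.3f} rmsd={ev.rmsd:.3f} "
          f"pearson={ev.pearson:.3f}")
```

prints (ensemble seed 7):

```
KLF4_OCT4_SOX2: efficiency=0.375 rmsd=0.050 pearson=0.978
KLF4_OCT4_SOX2&GATA6: efficiency=1.000 rmsd=0.071 pearson=0.982
```

Efficiency is the fraction of 256 randomly initialized differentiated
states whose MAP evolution under the recipe's clamps reaches the
hESC-marker attractor (all 11 ES markers on, all 11 differentiation markers
off); knocking down GATA6 — a repressor of NANOG that sustains the
differentiation module — raises it to 1.  RMSD/Pearson measure how close
the converged expression profile is to the reference hESC state.  On this
synthetic skeleton the numbers illustrate mechanisms, not the published
screen values.

The `examples/` directory holds one short script per capability (interface
selection, constrained sampling, knockdown prediction, landscape, recipe
screen, reprogramming paths); each prints what it computes and what the
numbers mean.  A thin CLI wraps the same functions:

```bash
qkdbn fixtures --kind skeleton --out fixture/
qkdbn interface --network fixture/network.tsv --annotations fixture/annotations.tsv
qkdbn screen --network fixture/network.tsv --annotations fixture/annotations.tsv \
      --k 2 --genes OCT4,SOX2,KLF4,MYC --n-init 256 --seed 42 --out recipes.csv
```

## File formats

- Edge list TSV: `source<TAB>target<TAB>sign`, sign ∈ {+, -, activate,
  repress}; `#` comments; SIF dialect (`source activates target`) via
  `--format sif`.
- Annotations TSV: `node<TAB>role<TAB>is_master<TAB>components` with role ∈
  {hesc_marker, diff_marker, complex, non_marker} and semicolon-separated
  components for complexes.
- Evidence TSV: `node<TAB>hard|soft<TAB>value`.

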