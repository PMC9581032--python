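# dyncubeprod

Reaction-deletion strain design for **growth-coupled** metabolite production
in constraint-based metabolic models, by LP-based solution-space division:
**GridProd** (2-D grid), **CubeProd** (static 3-D cubes), and
**DynCubeProd** (dynamic cube refinement with infeasibility pruning and
early stopping).

## The problem

Given a stoichiometric model — matrix *S* ∈ ℝ^{m×n} over the internal
metabolites, flux bounds *LB* ≤ *x* ≤ *UB*, a growth reaction
*v*<sub>growth</sub> and a target-production reaction *v*<sub>target</sub> —
find a knockout set *K* (reactions forced to *x* = 0) such that when growth
is maximized over the steady-state polytope

&nbsp;&nbsp;&nbsp;&nbsp;max *x*<sub>growth</sub> s.t. *Sx* = 0,
*LB* ≤ *x* ≤ *UB*, *x<sub>j</sub>* = 0 for *j* ∈ *K*,

the design satisfies GR = *x*<sub>growth</sub> ≥ min\_growth **and**
PR = *x*<sub>target</sub> ≥ min\_target even at the *minimum* production
compatible with that maximal growth — i.e. the target is a mandatory
by-product of optimal growth. Exact bilevel formulations of this problem do
not scale to genome-scale models, so these methods search heuristically but
verify every candidate exactly.

## The algorithm

Let TMGR, TMPR, TMSF be the maxima of the growth rate GR, production rate
PR, and total absolute flux SF = Σ|x<sub>j</sub>| (TMSF measured on the
optimal face of growth-constrained production maximization). The box
[0, TMGR] × [0, TMPR] × [0, 2·TMSF] is cut into P³ cubes. In each cube:

1. **First LP** — minimize Σ|x<sub>j</sub>| subject to steady state, bounds,
   and the cube's GR/PR/SF intervals. If infeasible, mark the cube.
2. **Candidate** — collect K = { j : |x<sub>j</sub>| < 10⁻⁵ } minus
   protected reactions (target, growth, uptakes, maintenance).
3. **Second LP (validation)** — maximize growth with K deleted (no cube
   constraints), then minimize production at that maximal growth; accept K
   iff GR ≥ min\_growth and PR ≥ min\_target.

CubeProd sweeps all P³ cubes at a fixed P; GridProd is the 2-D ancestor
(no SF axis). **DynCubeProd** starts at P = 1 and doubles P, skipping all
8 children of any cube whose first LP was infeasible — a subset of an
infeasible region is infeasible — and stops at the first accepted K. It
reaches the same success/failure verdict as CubeProd at the same P while
solving far fewer LPs.

## Worked example

The packaged example network has 7 reactions and 4 internal metabolites: a
fixed influx of 3 into C1, a direct route R3 to the growth precursor C4, a
two-step route R2, R4 to C3 (exported by the target reaction R7), and a
capacity-limited shunt R5 (≤ 1) from C3 to C4 (growth export R6).

```bash
dyncubeprod fixture --kind toy --out toy.json
dyncubeprod -v design --model toy.json --target C3 \
    --min-growth 1 --min-target 1 --out result.json
```

prints

```
INFO dyncubeprod: level P=1: examined=1 infeasible=0 rejected=1 accepted=0 skipped=0
INFO dyncubeprod: level P=2: examined=4 infeasible=1 rejected=2 accepted=1 skipped=0
```

and exits 0 (accepted; 3 = no strategy, 4 = data error, 5 = solver error).
At P = 1 the whole-space flux minimum (3, 0, 3, 0, 0, 3, 0) proposes
K = {R2, R4, R5}, which validates to (GR, PR) = (3, 0) — growth without
production, rejected. At P = 2 the cube GR ∈ [0, 1.5], PR ∈ [1.5, 3],
SF ∈ [13, 26] admits only the flux vector (3, 3, 0, 3, 1, 1, 2); its idle
reaction R3 is the candidate, and `result.json` records the accepted
strategy:

```json
"strategy": {"GR": 1.0, "K": ["R3"], "PR": 2.0, "accepted": true,
             "found_at": [2, 1, 2, 2], "lp_count": 17}
```

Deleting R3 forces all influx through the production route: growth is
capped at 1 by the shunt while production is pinned at 2 — growth coupling.
The same search through the library:

```python
import dyncubeprod as dcp

toy = dcp.build_toy_network()
params = dcp.SearchParams(min_growth=1.0, min_target=1.0)
result = dcp.run_dyncubeprod(toy, params=params)
print(sorted(result.strategy.K), result.strategy.GR, result.strategy.PR)
# ['R3'] 1.0 2.0
```

For genome-scale work, read a BiGG JSON or SBML model
(`dcp.read_model("iJO1366.json")`), pick a medium
(`--condition aerobic --gur 10 --ngam 3.15`, anaerobic forces OUR = 0) and
a target metabolite; `add_target_exchange` inserts an auxiliary export when
the metabolite has none. `batch` sweeps a file of target ids and reports
the success ratio.

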