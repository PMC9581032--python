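# Methods

## Model and problem

A constraint-based metabolic model is the polytope
{ x ∈ ℝⁿ : S·x = 0, LB ≤ x ≤ UB } of steady-state flux vectors, with S the
m×n stoichiometric matrix over internal metabolites. Boundary transport is
carried by exchange reactions (single-entry columns); uptake is the negative
flux direction of an exchange, so a medium with glucose uptake rate GUR sets
the glucose-exchange lower bound to −GUR, oxygen to −OUR (OUR = 0 is
anaerobic), and ATP maintenance imposes a lower bound NGAM on the ATPM flux.
A knockout set K replaces the bounds of its reactions with [0, 0].

A design is *accepted* (growth-coupled) when, with K applied, the maximal
growth rate GRmax is at least `min_growth` and the **minimum** production
rate over the maximal-growth face, PRmin, is at least `min_target`. The
minimum is what makes the coupling claim worst-case: production is then
unavoidable at optimal growth, not merely possible.

## LP layer

All programs are linear and solved with HiGHS (dual simplex via
`scipy.optimize.linprog`), with a fixed variable ordering derived from the
model's reaction order; repeated runs on the same inputs return the same
vertex, which matters because candidate extraction reads the vertex, not
just the optimum.

**Absolute values.** Σ|x| is linearized by splitting each reversible
reaction (LB < 0) into non-negative forward/backward components with
x = f − b; irreversible reactions keep a single component. The component
sum Σ(f + b) equals Σ|x| except when a futile forward+backward pair is
active, which (a) cannot happen at a minimum of the component sum unless
constraints force it, and (b) cannot happen at all in fully irreversible
models, where the representation is exact. The SF *lower* bound of a cube —
not convex in Σ|x| — is enforced on the component sum: the standard
LP-expressible relaxation. Consequently, for models with reversible
reactions a cube's SF interval is measured on the component-sum scale; the
pruning logic is unaffected because the same surrogate is used at every
level, so subset-infeasibility still holds.

**Theoretical maxima.** TMGR and TMPR are plain FBA maxima of the growth
and target fluxes with no extra constraints. TMSF must be a *deterministic*
scale, not "Σ|x| at whatever vertex the PR-max LP returned", so it is
defined constructively: maximize PR subject to growth ≥ `min_growth`, fix
PR at that optimum (lower bound with 10⁻⁹ relative slack), and maximize the
component sum over the optimal face. On the packaged example network this
gives TMSF = 13. If growth ≥ `min_growth` is itself infeasible the TMSF
scale is reported as 0 (no strategy can be accepted under such thresholds);
a base model that admits *no* steady state at all raises
`ModelInfeasibleError` instead of returning zeros, so "the optimum is 0"
and "the model is broken" stay distinguishable.

**Validation tolerance.** Stage 2 of validation holds growth at
GRmax·(1 − 10⁻⁶) as a lower bound rather than an equality; exact equality
on a floating-point optimum is brittle. An infeasible stage collapses to
the degenerate pair (0, 0), which no threshold ≥ 0 accepts... except the
trivial thresholds (0, 0) themselves, which a caller should not use.

**Candidate extraction.** K = { j : |x_j| < ε }, ε = 10⁻⁵ absolute, strict.
The protected set defaults to every role-designated reaction (target,
growth, glucose/oxygen uptake, ATP maintenance, and any auxiliary export):
deleting the target is explicitly disallowed by the problem; deleting the
others contradicts the experiment's semantics (the organism must still grow
on the stated medium). The set is overridable per search.

## Subdivision search

Cube (i, j, k) at level n (P = 2ⁿ divisions per axis) has the closed box
GR ∈ [(i−1)·TMGR/P, i·TMGR/P], PR analogous, SF ∈ [(k−1)·2·TMSF/P,
k·2·TMSF/P]. The SF axis deliberately spans **twice** TMSF: TMSF is
measured on one particular optimal face, and feasible vectors elsewhere in
the box can carry a larger flux sum, so the doubled axis keeps the top of
the solution space inside the search region. Closed intervals mean shared
faces belong to both neighbours — harmless double coverage, and essential:
measure-zero boundary slices (e.g. an SF value attained by exactly one flux
vector) are often precisely where the informative candidates live.

DynCubeProd visits levels n = 0, 1, …, `n_max` (default 5, i.e. P ≤ 32).
The explore mask at level 2P assigns each of the 8 children the parent's
first-LP feasibility flag; children of infeasible cubes are never solved.
This pruning is sound because a cube's box is a subset of its parent's box:
infeasibility is inherited downward. A cube whose candidate merely *fails
validation* stays feasible and is refined — only first-LP infeasibility
prunes. Cubes are traversed in ascending (i, j, k) lexicographic order
(growth outermost, SF innermost), which together with solver determinism
fixes *which* accepted strategy is reported first. The P = 1 root cube is
examined explicitly by default so its candidate is also tested; a
compatibility flag (`examine_root=False`) instead assumes it
examined-and-feasible and starts refinement at P = 2 — the two modes differ
only in whether the whole-space candidate gets a validation pass.

CubeProd runs one fixed level exhaustively and returns every accepted
strategy plus the feasibility grid; GridProd does the same over the P²
GR×PR grid with no SF constraint in the first LP. On the example network
GridProd fails at every P — its cells always admit a cheaper
non-producing flux pattern — while the SF axis lets CubeProd/DynCubeProd
isolate the flux vector whose idle reaction is the correct knockout. One
boundary subtlety is worth recording: at P = 2 the example's only feasible
point in the upper SF half lies exactly on the SF = TMSF face, so under the
closed-interval convention that cube is feasible (and accepted); treating
the face as exclusive would prune the entire lineage of cubes that can ever
propose the correct knockout, so closedness is load-bearing, not cosmetic.

## Synthetic networks

`generate_random_network(m, n, seed)` builds fully irreversible test
networks: a fixed integer influx u ∈ {2..5} into M1, a backbone chain
M1→…→Mm with capacity 10 ≥ u (so a nonzero growth flux exists by
construction and every metabolite has a producer and a consumer), a growth
export from Mm, a target export from a random metabolite, and random
cross-edges of which ~40% get tight integer capacities that create
bottlenecks like the example's shunt. Property tests run them with
thresholds min\_growth = u/2, min\_target = u/4. Bounds and coefficients
are integers, so an exact rational-arithmetic vertex-enumeration oracle
(tests/helpers\_oracle.py) can certify TMSF and PRmin on instances of ~10
reactions.

What these networks do **not** emulate: reversibility (so the Σ|x|
surrogate is exact in every property test — the relaxation is exercised
only through the LP layer's code path), cofactor/currency coupling,
biomass stoichiometry with many substrates, and genome-scale degeneracy.
Passing tests certify the search machinery and LP contracts, not biological
performance on a genome-scale model; the CLI defaults for such models
(GUR = 10, OUR = 1000 aerobic / 0 anaerobic, NGAM = 3.15,
min\_growth = min\_target = 10⁻³) are conventional E. coli settings,
echoed into every result record so runs are self-documenting.

## Problem sizes and numerical choices

Tests and the acceptance script use the 7-reaction example network for all
deterministic values, and 5-metabolite / 10-reaction generated networks for
the property guarantees — pruning soundness on 50 networks through level
n = 3 (585 cubes per network before pruning), static/dynamic parity for
P ∈ {1, 2, 4, 8}, and LP-count economy through level 2. These sizes give
thousands of independently verified cubes while keeping the whole suite at
about a minute. Solver feasibility tolerances are HiGHS defaults (~10⁻⁹);
post-hoc steady-state checks use 10⁻⁶.

## Known limitations

- The SF interval measures the component sum, not true Σ|x|, when
  reversible futile pairs are forced active (see above); for genome-scale
  models this can make a cube's effective SF window slightly conservative.
- Maximizing the component sum (the TMSF face step) requires finite bounds;
  models with unbounded reactions should be capped (BiGG models use ±1000).
- Reported first-found strategies depend on the documented traversal order
  and on HiGHS vertex selection among degenerate optima; a different LP
  solver may report a different (equally valid) K.
- Gene–protein–reaction rules are out of scope: deletions are per-reaction.
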