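# Methods

## Model

A vaccine is a set of `n` polypeptides, each an ordered list of
epitopes. On the design graph G(Ṽ, Ẽ, w) with Ṽ = V ∪ {s}, each
polypeptide is a simple tour that starts and ends at the depot `s`
(the N/C-termini) and otherwise visits distinct epitope vertices. The
optimizer maximizes a linear immunogenicity functional

    I(P) = Σ_{v∈P} Σ_{a∈A} p_a · i_va

under per-tour and joint constraints. Linearity assumes epitopes
contribute independently to the immune response; immunodominance
interactions between epitopes are not modelled (no reliable predictor
exists), so I(P) is additive and monotone by construction.

Per-epitope scores `i_va` come from predicted binding affinities.
Three sources are supported: IC50 in nM mapped by
`clamp(1 − log(IC50)/log(50000), 0, 1)` (1 nM → 1, ≥ 50 μM → 0; the
50 000 nM cap is configurable), percentile rank flipped to `100 − rank`,
and precomputed scores taken verbatim. An epitope *binds* an allele
when IC50 ≤ 500 nM, boundary inclusive; pairs without a measurement
are non-binders. Binding prediction itself is out of scope — the
package consumes tables produced by tools such as NetMHCpan or
MHCflurry.

### Edge weights

* **mixture** — all weights 0, weight budget `h = ∞`; only the vertex
  budget `k` binds.
* **string-of-beads** — w(e_ij) is the junction weight of
  concatenating epitope i before j:
  `w = −φ(e_i e_j, ℓ) + β Σ_{k=1..K} [φ(ℓ−k) + φ(ℓ+k)]` with ℓ = |e_i|,
  defaults K = 2, β = 0.1, where `φ(s, k) = Σ_{i=−4..1} ψ(s_{k+i}, i)`
  is a PSSM cleavage score. Position `k` denotes the bond before
  residue `k` (0-based), so the window spans four residues on the
  N-terminal and two on the C-terminal side of the bond, matching the
  P4–P2′ convention of cleavage matrices. A negative junction weight
  marks a predicted cleavage site. Depot edges weigh 0. The *cleavage
  score* of a tour is the negative sum of its edge weights; higher is
  better.
* **mosaic** — w(e_ij) = |e_j| − (longest suffix-prefix overlap), with
  w(s→v) = |v| and w(v→s) = 0, so a tour's weight sum equals the
  assembled polypeptide's length exactly, and `h` bounds the construct
  size in residues. Overlaps are computed by direct scan over all
  overlap lengths (quadratic in the pair, linear in epitope length);
  a suffix-structure implementation would have to be bit-identical.
* **custom** — a user-supplied pairwise table (e.g. weights from an
  external spacer-design optimizer) used verbatim, with no rescaling;
  unspecified depot edges default to 0, missing epitope pairs are an
  error.

### Integer program

Binary `x_vwt` (edge used by tour t), `y_vt` (vertex in tour t),
coverage indicators `θ_s`, `θ_a`, and integer MTZ potentials
`u_vt ∈ [1, |V|−1]`. Constraints: flow conservation between x and y
(C1), MTZ subtour elimination over epitope-epitope edges (C2), vertex
disjointness across tours (C3), one depot departure per tour (C4,
implemented by fixing the depot's y to 1, which with C1 is equivalent
to the aggregate form), per-tour weight budget `h` (C5), per-tour
vertex budget `k` (C6), joint pathogen/allele coverage floors (C7,
C8), and an average-conservation floor Γ (C9), accepted as a fraction
and scaled by |S| inside the constraint. Epitopes binding no allele
are legal vertices.

Numerical choices:

* `h = ∞` omits C5 entirely rather than using a big-M.
* C5 sums over **all** tour edges including the depot's. For mixtures
  and string-of-beads the depot edges weigh zero so this is
  indistinguishable from summing over epitope-epitope edges only; for
  mosaics it is what makes the tour weight equal the construct length.
* Every tour is non-empty (C1 + C4 force exactly one depot departure
  per tour); requesting more tours than epitopes is infeasible.
* The MTZ bound `u ≤ |V|−1` can order at most |V|−1 visited vertices,
  so a single tour through *every* vertex of the graph is excluded by
  the formulation; designs should keep `k < |V|` (in practice the
  candidate set is always much larger than the budget). For |V| = 1
  the bound is clamped to 1.
* `exact_k` turns C6 into an equality for fixed-size designs (used by
  the permutation and frontier experiments, where every vaccine has
  the same epitope count).
* Objective modes are weight presets (w_i, w_p, w_c) on
  immunogenicity, covered-pathogen count, and summed conservation
  fraction: `immunogenicity` = (1,0,0), `coverage` = (1,1,0),
  `conservation` = (1,0,1), `weighted` = (1,1,1), all overridable.
  With unit weights the immunogenicity term is typically orders of
  magnitude smaller than the coverage term, so it acts as a
  tie-breaker among equally covering designs.
* Solved with HiGHS via `scipy.optimize.milp`; MIP gap defaults to 0
  (exact) and can be relaxed, along with a time limit, for large
  instances. Tie-breaking among equal-objective optima is
  solver-dependent and not part of any contract; tests compare
  objective values, never tour identity.
* Infeasibility raises an explicit error, never an empty solution.
* `validate_solution` re-derives C3/C5/C6/C7b/C8b/C9 satisfaction from
  the tours alone, independent of solver variables.
* `brute_force_design` enumerates every assignment of disjoint
  non-empty ordered tours (guarded to ≤ 9 epitopes, ≤ 2 tours). For
  each vertex set it keeps the weight-minimal ordering, which
  dominates under every supported objective because only C5, the
  cleavage constraint, and the augmentation term depend on order.
  Ties break lexicographically for determinism.

### Pareto frontier

The immunogenicity/cleavage-score trade-off is traced with the
augmented ε-constraint method. The payoff table comes from two
two-stage lexicographic solves (max I then max CS; max CS then max I).
ε sweeps an evenly spaced inclusive grid of `n_points` levels between
the cleavage score at the immunogenicity optimum and the best
achievable cleavage score; each solve maximizes `I + δ·CS` subject to
CS ≥ ε, with `δ = 10⁻³ · (I range / CS range)` (configurable) keeping
the augmentation sub-dominant while discarding weakly efficient
solutions. Duplicates and dominated points are filtered; the result is
mutually non-dominated with I non-increasing in ε. Because the
augmentation rewards cleavage among near-optimal immunogenicities,
every returned point's ordering is cleavage-optimal for its epitope
set — the property the permutation experiment checks exhaustively.

An evenly spaced grid recovers the *complete* Pareto set only when the
spacing is finer than the smallest cleavage-score gap between adjacent
efficient points; the exactness test therefore uses a six-epitope
instance with deliberately separated frontier points (cleavage scores
3, 6, 10 from three planted favourable pairs), while random instances
are checked for the guaranteed properties: every returned point is
efficient, mutually non-dominated, and monotone in ε. Cross-method
score normalization (dividing each frontier by its own maximum) is a
reporting transform only and never enters the solver.

### Evaluation

* Population coverage treats loci as independent and individuals as
  diploid: `1 − Π_i (1 − Σ_{a∈A_i} y_a p_a)²`. The relative variant
  divides by the panel ceiling computed with every allele covered.
* Pathogen coverage counts sequences containing ≥ 1 vaccine epitope;
  conservation is the mean fraction of sequences containing each
  epitope (undefined, and an error, for an empty vaccine).
* Positional entropy works on a gapped alignment (produced externally,
  e.g. by MAFFT): columns whose consensus is a gap are dropped
  (consensus ties break by a fixed residue order); remaining columns
  get Shannon entropy in bits with the gap as a 21st symbol by default
  (configurable to ignore gaps), smoothed by a centred moving average
  of 9 columns (one epitope length) by default.
* Positional coverage maps every occurrence of every vaccine epitope
  in every ungapped sequence through the alignment; it reports per
  column the distinct pathogens covered, the distinct epitopes
  covering it, a max-normalized pathogen count, and the summed
  per-epitope immunogenicity of covering epitopes.
* The shuffle experiment draws seeded random permutations of a
  single-tour string-of-beads, reporting each permutation's cleavage
  score, its decrease from the original, and its junction cleavage
  sites (negative-weight junctions, at most #epitopes − 1).

## Synthetic data

The generator emulates the statistical shape of real inputs at desk
scale: antigens descend from one random ancestral sequence with
independent per-site substitutions (default 20 pathogens × 60
residues at 2% divergence, giving the conserved cores that mosaics
exploit); allele frequencies are Dirichlet draws per locus scaled to
0.9 total (panel alleles never exhaust a locus); IC50 values are
log-normal (median 5 μM, σ = 2) with 10% of pairs redrawn uniformly
into the 10–500 nM binder range so the binder rate is controlled; the
cleavage PSSM is i.i.d. normal with an optional planted motif at
offset −1. Each generator uses an independent stream derived from the
one spec seed, so outputs are bit-reproducible and mutually
independent.

What the generator does **not** emulate: realistic viral phylogeny
(sites mutate independently — no linkage, recombination, or selection),
predictor error structure (IC50 values are independent across alleles,
real predictors correlate), anchor-position binding motifs, and
alignment gaps (synthetic antigens are gap-free; gapped inputs are
exercised with hand-written alignments). Passing tests therefore
demonstrate correctness of the optimization and scoring machinery on
inputs with the assumed structure, not predictive validity on real
pathogen data.

## Problem sizes

The verification experiments run at sizes where exhaustive enumeration
is exact and fast: oracle comparisons use 54 instances of 7 epitopes
with tour budgets of 2 across all three design kinds, tour counts 1–2,
and coverage/conservation constraint variants; the permutation
experiment uses 6-epitope vaccines (720 orderings, checked
exhaustively) over 5 frontier points × 50 shuffles; frontier
exactness uses the separated six-epitope instance with an 11-level
sweep. The solver itself scales to the thousands of epitopes typical
of real antigen sets, where graph pruning and a nonzero MIP gap are
the intended levers.

## Known limitations

* Within-epitope cleavage is not modelled for mosaics or
  string-of-beads; only junction sites enter the objective.
* Spacer sequences are supported only through precomputed pairwise
  edge tables; the spacer design problem itself is external.
* One fixed epitope length per run (default 9); MHC class II epitopes
  of variable length are out of scope.
* The MTZ bound excludes a tour visiting every graph vertex (see
  above); this is immaterial when budgets are below the candidate
  count.
* Bit-stability of outputs is guaranteed for fixed inputs, seed, and
  solver with MIP gap 0; with a nonzero gap the returned solution may
  depend on solver timing.
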