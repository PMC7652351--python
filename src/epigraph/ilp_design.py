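"""Team-orienteering ILP for epitope vaccine design.

The generalized design problem seeks ``n`` vertex-disjoint simple tours
through the design graph, each anchored at the depot, maximizing total
immunogenicity subject to per-tour vertex (``k``) and edge-weight (``h``)
budgets plus optional joint pathogen-coverage, allele-coverage and
average-conservation constraints.  Each tour is one polypeptide of the
vaccine (a cocktail when ``n > 1``).

The integer program uses binary edge indicators ``x_vwt`` and vertex
indicators ``y_vt`` per tour, Miller-Tucker-Zemlin integer node
potentials ``u_vt`` for subtour elimination, and binary coverage
indicators ``theta_s`` / ``theta_a``:

    max  w_i * sum_t,v,a y_vt p_a i_va
       + w_p * sum_s theta_s
       + w_c * sum_t,v y_vt cons_v / |S|

    s.t. flow conservation x <-> y          (C1)
         MTZ subtour elimination            (C2a, C2b)
         tours share only the depot         (C3)
         every tour leaves/enters the depot (C4)
         per-tour edge weight <= h          (C5)
         per-tour vertex count <= k         (C6)
         joint pathogen cover >= Theta_s    (C7)
         joint allele cover   >= Theta_a    (C8)
         average conservation >= Gamma      (C9)

Solved with HiGHS through :func:`scipy.optimize.milp`.  A brute-force
enumerator over all feasible tour assignments serves as an independent
optimality oracle on small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .catalog import EpitopeCatalog
from .edge_weights import DesignGraph, overlap_weight
from .immunogenicity import AffinityMatrix, AlleleTable, epitope_immunogenicities

OBJECTIVE_MODES = ("immunogenicity", "coverage", "conservation", "weighted")

#: (w_i, w_p, w_c) presets per objective mode
_MODE_WEIGHTS = {
    "immunogenicity": (1.0, 0.0, 0.0),
    "coverage": (1.0, 1.0, 0.0),
    "conservation": (1.0, 0.0, 1.0),
    "weighted": (1.0, 1.0, 1.0),
}


class InfeasibleDesignError(RuntimeError):
    """The constraint set admits no vaccine."""


@dataclass(frozen=True)
class DesignConfig:
    """Budgets, coverage requirements and solver options for one design.

    ``gamma`` is a conservation *fraction* of the pathogen set; internally
    it is scaled to ``gamma * |S|`` in the average-conservation constraint.
    ``h=None`` falls back to the design graph's kind-default budget.
    ``exact_k`` turns the vertex budget into an equality, fixing every
    polypeptide at exactly ``k`` epitopes (the fixed-size designs used
    when comparing vaccines of equal epitope count).
    """

    n_tours: int = 1
    k: int = 10
    exact_k: bool = False
    h: float | None = None
    min_pathogen_cover: int = 0
    min_allele_cover: int = 0
    gamma: float = 0.0
    objective: str = "immunogenicity"
    objective_weights: tuple[float, float, float] | None = None
    time_limit: float | None = None
    mip_gap: float = 0.0

    def __post_init__(self) -> None:
        if self.n_tours < 1 or self.k < 1:
            raise ValueError("n_tours and k must be >= 1")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma is a fraction in [0, 1]")
        if self.objective not in OBJECTIVE_MODES:
            raise ValueError(f"unknown objective mode {self.objective!r}")

    def weights(self) -> tuple[float, float, float]:
        if self.objective_weights is not None:
            return self.objective_weights
        return _MODE_WEIGHTS[self.objective]


@dataclass
class VaccineSolution:
    """Tours plus bookkeeping returned by the solver or the oracle."""

    tours: list[tuple[str, ...]]
    tour_weights: list[float]
    objective_value: float
    status: str
    immunogenicity: float
    theta_s: np.ndarray
    theta_a: np.ndarray
    mip_gap: float = 0.0

    @property
    def epitopes(self) -> tuple[str, ...]:
        return tuple(ep for tour in self.tours for ep in tour)


@dataclass(frozen=True)
class _Instance:
    """Aligned numeric views of one design instance."""

    graph: DesignGraph
    prizes: np.ndarray  # sum_a p_a i_va per graph epitope
    conservation: np.ndarray  # cons_v per graph epitope
    tau_s: np.ndarray  # (m, |S|) epitope-pathogen incidence
    tau_a: np.ndarray  # (m, |A|) epitope-allele binder indicators

    @property
    def n_pathogens(self) -> int:
        return self.tau_s.shape[1]

    @property
    def n_alleles(self) -> int:
        return self.tau_a.shape[1]


def _build_instance(
    graph: DesignGraph,
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
) -> _Instance:
    idx_m = matrix.epitope_index(graph.epitopes)
    idx_c = np.asarray([catalog.index(ep) for ep in graph.epitopes])
    prizes = epitope_immunogenicities(matrix, alleles)[idx_m]
    cons = catalog.conservation[idx_c].astype(float)
    tau_s = catalog.incidence[idx_c]
    # binder indicators aligned to the allele table's panel
    col = {name: j for j, name in enumerate(matrix.alleles)}
    tau_a = np.zeros((len(graph.epitopes), len(alleles)), dtype=bool)
    for j, name in enumerate(alleles.names):
        if name in col:
            tau_a[:, j] = matrix.binder[idx_m, col[name]]
    return _Instance(graph, prizes, cons, tau_s, tau_a)


# --- ILP formulation --------------------------------------------------------

class _VarIndex:
    """Flat variable layout: per tour [x, y, u], then theta_s, theta_a."""

    def __init__(self, m: int, n_tours: int, n_path: int, n_allele: int):
        self.m = m
        self.n_tours = n_tours
        self.pairs = [
            (i, j) for i in range(m + 1) for j in range(m + 1) if i != j
        ]
        self.pair_pos = {p: q for q, p in enumerate(self.pairs)}
        self.nx = len(self.pairs)
        self.ny = m + 1
        self.per_tour = self.nx + self.ny + m
        self.theta_s0 = n_tours * self.per_tour
        self.theta_a0 = self.theta_s0 + n_path
        self.total = self.theta_a0 + n_allele

    def x(self, i: int, j: int, t: int) -> int:
        return t * self.per_tour + self.pair_pos[(i, j)]

    def y(self, v: int, t: int) -> int:
        return t * self.per_tour + self.nx + v

    def u(self, v: int, t: int) -> int:
        return t * self.per_tour + self.nx + self.ny + v

    def th_s(self, s: int) -> int:
        return self.theta_s0 + s

    def th_a(self, a: int) -> int:
        return self.theta_a0 + a


def design_vaccine(
    graph: DesignGraph,
    config: DesignConfig,
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
    min_cleavage_score: float | None = None,
    augment_delta: float = 0.0,
    min_immunogenicity: float | None = None,
) -> VaccineSolution:
    """Solve the design ILP and return the optimal vaccine.

    ``min_cleavage_score`` adds the epsilon-constraint
    ``-sum_t sum_e w(e) x_et >= eps`` used by the Pareto sweep, and
    ``augment_delta`` adds ``delta * cleavage_score`` to the objective
    (the augmentation term that discards weakly efficient solutions).
    ``min_immunogenicity`` bounds ``I(P)`` from below (lexicographic
    payoff-table solves).  Raises :class:`InfeasibleDesignError` when no
    vaccine satisfies the constraints.
    """
    inst = _build_instance(graph, matrix, alleles, catalog)
    m = graph.n_epitopes
    n = config.n_tours
    depot = m
    h = config.h if config.h is not None else graph.h
    V = _VarIndex(m, n, inst.n_pathogens, inst.n_alleles)
    w_i, w_p, w_c = config.weights()

    # objective (milp minimizes; negate)
    c = np.zeros(V.total)
    for t in range(n):
        for v in range(m):
            c[V.y(v, t)] -= w_i * inst.prizes[v]
            if inst.n_pathogens:
                c[V.y(v, t)] -= w_c * inst.conservation[v] / inst.n_pathogens
        if augment_delta:
            for (i, j) in V.pairs:
                c[V.x(i, j, t)] += augment_delta * graph.weights[i, j]
    for s in range(inst.n_pathogens):
        c[V.th_s(s)] -= w_p

    rows, cols, vals, lo, hi = [], [], [], [], []
    r = 0

    def add(coefs: list[tuple[int, float]], lb: float, ub: float) -> None:
        nonlocal r
        for col_idx, val in coefs:
            rows.append(r)
            cols.append(col_idx)
            vals.append(val)
        lo.append(lb)
        hi.append(ub)
        r += 1

    for t in range(n):
        # C1: in/out degree of every vertex equals its indicator
        for w in range(m + 1):
            add(
                [(V.x(w, v, t), 1.0) for v in range(m + 1) if v != w]
                + [(V.y(w, t), -1.0)],
                0.0,
                0.0,
            )
            add(
                [(V.x(v, w, t), 1.0) for v in range(m + 1) if v != w]
                + [(V.y(w, t), -1.0)],
                0.0,
                0.0,
            )
        # C2a: MTZ subtour elimination on epitope-epitope edges
        big = max(m - 1, 1)
        for i in range(m):
            for j in range(m):
                if i != j:
                    add(
                        [
                            (V.u(i, t), 1.0),
                            (V.u(j, t), -1.0),
                            (V.x(i, j, t), float(big)),
                        ],
                        -math.inf,
                        float(big - 1),
                    )
        # C5: per-tour edge-weight budget over all tour edges incl. depot
        if math.isfinite(h):
            add(
                [(V.x(i, j, t), graph.weights[i, j]) for (i, j) in V.pairs],
                -math.inf,
                h,
            )
        # C6: per-tour vertex budget (equality when the size is fixed)
        c6_lo = float(config.k) if config.exact_k else -math.inf
        add([(V.y(v, t), 1.0) for v in range(m)], c6_lo, float(config.k))
    # C3: tours only share the depot
    for v in range(m):
        add([(V.y(v, t), 1.0) for t in range(n)], -math.inf, 1.0)
    # C7a/C7b: pathogen coverage
    for s in range(inst.n_pathogens):
        covering = np.flatnonzero(inst.tau_s[:, s])
        add(
            [(V.y(v, t), 1.0) for t in range(n) for v in covering]
            + [(V.th_s(s), -1.0)],
            0.0,
            math.inf,
        )
    if config.min_pathogen_cover > 0 or w_p > 0:
        add(
            [(V.th_s(s), 1.0) for s in range(inst.n_pathogens)],
            float(config.min_pathogen_cover),
            math.inf,
        )
    # C8a/C8b: allele coverage
    for a in range(inst.n_alleles):
        covering = np.flatnonzero(inst.tau_a[:, a])
        add(
            [(V.y(v, t), 1.0) for t in range(n) for v in covering]
            + [(V.th_a(a), -1.0)],
            0.0,
            math.inf,
        )
    if config.min_allele_cover > 0:
        add(
            [(V.th_a(a), 1.0) for a in range(inst.n_alleles)],
            float(config.min_allele_cover),
            math.inf,
        )
    # C9: average conservation at least gamma * |S|
    if config.gamma > 0:
        bar = config.gamma * inst.n_pathogens
        add(
            [
                (V.y(v, t), inst.conservation[v] - bar)
                for t in range(n)
                for v in range(m)
            ],
            0.0,
            math.inf,
        )
    # lower bound on total immunogenicity (lexicographic solves)
    if min_immunogenicity is not None:
        add(
            [
                (V.y(v, t), inst.prizes[v])
                for t in range(n)
                for v in range(m)
            ],
            min_immunogenicity,
            math.inf,
        )
    # epsilon-constraint on the cleavage score (Pareto sweep)
    if min_cleavage_score is not None:
        add(
            [
                (V.x(i, j, t), graph.weights[i, j])
                for t in range(n)
                for (i, j) in V.pairs
            ],
            -math.inf,
            -min_cleavage_score,
        )

    A = sparse.csr_array(
        (vals, (rows, cols)), shape=(r, V.total)
    )
    constraints = LinearConstraint(A, np.asarray(lo), np.asarray(hi))

    lb = np.zeros(V.total)
    ub = np.ones(V.total)
    for t in range(n):
        lb[V.y(depot, t)] = 1.0  # C4: every tour is anchored at the depot
        for v in range(m):
            lb[V.u(v, t)] = 1.0
            ub[V.u(v, t)] = float(max(m - 1, 1))
    bounds = Bounds(lb, ub)
    integrality = np.ones(V.total)

    options: dict = {"mip_rel_gap": config.mip_gap}
    if config.time_limit is not None:
        options["time_limit"] = config.time_limit
    res = milp(
        c,
        constraints=constraints,
        bounds=bounds,
        integrality=integrality,
        options=options,
    )
    if res.status == 2 or (res.x is None and not res.success):
        raise InfeasibleDesignError(
            "no feasible vaccine under the given constraints"
        )
    status = "optimal" if res.status == 0 else "feasible-at-gap"
    x = res.x

    tours: list[tuple[str, ...]] = []
    tour_weights: list[float] = []
    for t in range(n):
        succ = {}
        for (i, j) in V.pairs:
            if x[V.x(i, j, t)] > 0.5:
                succ[i] = j
        tour: list[str] = []
        node = succ.get(depot)
        while node is not None and node != depot:
            tour.append(graph.epitopes[node])
            node = succ.get(node)
        tours.append(tuple(tour))
        tour_weights.append(graph.tour_weight(tour))

    sel = [v for t in range(n) for v, ep in enumerate(graph.epitopes)
           if ep in set(tours[t])]
    theta_s = np.array(
        [x[V.th_s(s)] > 0.5 for s in range(inst.n_pathogens)], dtype=bool
    )
    theta_a = np.array(
        [x[V.th_a(a)] > 0.5 for a in range(inst.n_alleles)], dtype=bool
    )
    imm = float(sum(inst.prizes[v] for v in sel))
    gap = float(getattr(res, "mip_gap", 0.0) or 0.0)
    return VaccineSolution(
        tours=tours,
        tour_weights=tour_weights,
        objective_value=-float(res.fun),
        status=status,
        immunogenicity=imm,
        theta_s=theta_s,
        theta_a=theta_a,
        mip_gap=gap,
    )


# --- assembly ---------------------------------------------------------------

def assemble_polypeptide(tour: Sequence[str], kind: str) -> str:
    """Assemble the polypeptide encoded by one tour.

    Mixture/string-of-beads tours concatenate their epitopes in order;
    mosaic tours iteratively merge each next epitope onto the construct
    at the longest suffix-prefix overlap, so the assembled length equals
    the tour's edge-weight sum in a mosaic graph.
    """
    if not tour:
        return ""
    if kind in ("mixture", "string_of_beads", "custom"):
        return "".join(tour)
    if kind == "mosaic":
        out = tour[0]
        for nxt in tour[1:]:
            added = overlap_weight(out[-len(nxt):] if len(out) >= len(nxt) else out, nxt)
            out += nxt[len(nxt) - added:] if added else ""
        return out
    raise ValueError(f"unknown design kind {kind!r}")


# --- independent constraint validation --------------------------------------

def validate_solution(
    solution: VaccineSolution,
    graph: DesignGraph,
    config: DesignConfig,
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
) -> list[str]:
    """Re-derive constraint satisfaction from the tours alone.

    Returns the named constraints that are violated (empty list = valid).
    The check is independent of the solver's decision variables: every
    quantity is recomputed from the tour orderings.
    """
    inst = _build_instance(graph, matrix, alleles, catalog)
    violations: list[str] = []
    h = config.h if config.h is not None else graph.h

    seen: set[str] = set()
    disjoint = True
    for tour in solution.tours:
        for ep in tour:
            if ep in seen:
                disjoint = False
            seen.add(ep)
    if not disjoint:
        violations.append("C3")
    if math.isfinite(h) and any(
        graph.tour_weight(tour) > h + 1e-9 for tour in solution.tours
    ):
        violations.append("C5")
    if any(len(tour) > config.k for tour in solution.tours) or (
        config.exact_k
        and any(len(tour) != config.k for tour in solution.tours)
    ):
        violations.append("C6")

    sel = sorted({ep for tour in solution.tours for ep in tour})
    idx = [graph.epitopes.index(ep) for ep in sel]
    covered_s = (
        inst.tau_s[idx].any(axis=0).sum() if idx else 0
    )
    if covered_s < config.min_pathogen_cover:
        violations.append("C7b")
    covered_a = (
        inst.tau_a[idx].any(axis=0).sum() if idx else 0
    )
    if covered_a < config.min_allele_cover:
        violations.append("C8b")
    if config.gamma > 0 and idx:
        bar = config.gamma * inst.n_pathogens
        if (inst.conservation[idx] - bar).sum() < -1e-9:
            violations.append("C9")
    return violations


# --- brute-force oracle -----------------------------------------------------

BRUTE_FORCE_VERTEX_LIMIT = 9
BRUTE_FORCE_TOUR_LIMIT = 2


def _best_ordering(
    subset: tuple[int, ...], graph: DesignGraph
) -> tuple[float, tuple[int, ...]]:
    """Minimum tour weight over all orderings of ``subset`` (depot-anchored)."""
    W = graph.weights
    d = graph.depot_index
    best_w = math.inf
    best_perm: tuple[int, ...] = subset
    for perm in itertools.permutations(subset):
        total = W[d, perm[0]] + W[perm[-1], d]
        for a, b in zip(perm, perm[1:]):
            total += W[a, b]
        if total < best_w - 1e-12:
            best_w = total
            best_perm = perm
    return float(best_w), best_perm


def brute_force_design(
    graph: DesignGraph,
    config: DesignConfig,
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
    min_cleavage_score: float | None = None,
    augment_delta: float = 0.0,
    min_immunogenicity: float | None = None,
) -> VaccineSolution:
    """Exhaustive enumeration oracle for small instances.

    Enumerates every assignment of vertex-disjoint non-empty tours (each
    tour at its weight-minimal ordering, which dominates for every
    supported objective), applies every constraint, and returns the true
    optimum with a deterministic lexicographic tie-break.  Guarded to at
    most 9 epitopes and 2 tours.
    """
    m = graph.n_epitopes
    n = config.n_tours
    if m > BRUTE_FORCE_VERTEX_LIMIT or n > BRUTE_FORCE_TOUR_LIMIT:
        raise ValueError(
            f"brute force limited to {BRUTE_FORCE_VERTEX_LIMIT} epitopes "
            f"and {BRUTE_FORCE_TOUR_LIMIT} tours"
        )
    inst = _build_instance(graph, matrix, alleles, catalog)
    h = config.h if config.h is not None else graph.h
    w_i, w_p, w_c = config.weights()

    vertices = list(range(m))
    sizes = (
        [config.k]
        if config.exact_k
        else list(range(1, min(config.k, m) + 1))
    )
    subsets = [
        tuple(sub)
        for r in sizes
        if r <= m
        for sub in itertools.combinations(vertices, r)
    ]
    ordering = {sub: _best_ordering(sub, graph) for sub in subsets}

    def assignments():
        if n == 1:
            for sub in subsets:
                yield (sub,)
        else:
            for s1, s2 in itertools.combinations(subsets, 2):
                if not set(s1) & set(s2):
                    yield (s1, s2)

    best = None
    best_key = None
    for combo in assignments():
        weights = [ordering[sub][0] for sub in combo]
        if math.isfinite(h) and any(w > h + 1e-9 for w in weights):
            continue
        total_cs = -sum(weights)
        if min_cleavage_score is not None and total_cs < min_cleavage_score - 1e-9:
            continue
        sel = sorted(v for sub in combo for v in sub)
        cov_s = inst.tau_s[sel].any(axis=0)
        cov_a = inst.tau_a[sel].any(axis=0)
        if cov_s.sum() < config.min_pathogen_cover:
            continue
        if cov_a.sum() < config.min_allele_cover:
            continue
        if config.gamma > 0:
            bar = config.gamma * inst.n_pathogens
            if (inst.conservation[sel] - bar).sum() < -1e-9:
                continue
        imm = float(inst.prizes[sel].sum())
        if min_immunogenicity is not None and imm < min_immunogenicity - 1e-9:
            continue
        obj = w_i * imm + w_p * float(cov_s.sum())
        if inst.n_pathogens:
            obj += w_c * float(inst.conservation[sel].sum()) / inst.n_pathogens
        if augment_delta:
            obj += augment_delta * total_cs
        key = (-obj, tuple(ordering[sub][1] for sub in combo))
        if best_key is None or key < best_key:
            best_key = key
            best = (combo, weights, imm, obj, cov_s, cov_a)
    if best is None:
        raise InfeasibleDesignError("no feasible vaccine (brute force)")
    combo, weights, imm, obj, cov_s, cov_a = best
    tours = [
        tuple(graph.epitopes[v] for v in ordering[sub][1]) for sub in combo
    ]
    return VaccineSolution(
        tours=tours,
        tour_weights=[float(w) for w in weights],
        objective_value=float(obj),
        status="optimal",
        immunogenicity=imm,
        theta_s=cov_s,
        theta_a=cov_a,
    )
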