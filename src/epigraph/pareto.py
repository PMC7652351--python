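"""Immunogenicity vs cleavage-score Pareto frontier.

For string-of-beads designs the total immunogenicity and the cleavage
score (the negative sum of junction edge weights) compete: epitopes that
bind well need not form cleavable junctions.  The frontier of this
bi-objective problem is traced with the augmented epsilon-constraint
method: the cleavage score is bounded below at a sweep of epsilon
levels while immunogenicity is maximized, plus a small multiple of the
cleavage-score slack so that each solve returns a properly (not weakly)
efficient solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import EpitopeCatalog
from .edge_weights import DesignGraph
from .ilp_design import (
    DesignConfig,
    InfeasibleDesignError,
    VaccineSolution,
    design_vaccine,
)
from .immunogenicity import AffinityMatrix, AlleleTable


@dataclass(frozen=True)
class ParetoPoint:
    """One efficient design: its solution and both objective values."""

    solution: VaccineSolution
    immunogenicity: float
    cleavage_score: float
    epsilon: float


def _cleavage_score(solution: VaccineSolution) -> float:
    return -float(sum(solution.tour_weights))


def pareto_frontier(
    graph: DesignGraph,
    config: DesignConfig,
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
    n_points: int = 11,
    delta_scale: float = 1e-3,
) -> list[ParetoPoint]:
    """Trace the immunogenicity/cleavage-score Pareto frontier.

    The epsilon range is the payoff table of the secondary objective:
    from the cleavage score attained at the immunogenicity optimum
    (lexicographically cleavage-maximal) up to the best achievable
    cleavage score.  ``n_points`` evenly spaced epsilon levels are
    solved, dominated and duplicate solutions are discarded, and the
    returned points are mutually non-dominated with immunogenicity
    non-increasing in epsilon.

    ``delta_scale`` scales the augmentation coefficient:
    ``delta = delta_scale * (immunogenicity range / cleavage range)``.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    from dataclasses import replace

    cs_config = replace(config, objective_weights=(0.0, 0.0, 0.0))

    # payoff table via two lexicographic solves per corner:
    # corner 1: max I, then max CS among I-optimal solutions
    stage1 = design_vaccine(graph, config, matrix, alleles, catalog)
    best_imm = design_vaccine(
        graph,
        cs_config,
        matrix,
        alleles,
        catalog,
        augment_delta=1.0,
        min_immunogenicity=stage1.immunogenicity - 1e-9,
    )
    cs_at_best_imm = _cleavage_score(best_imm)
    # corner 2: max CS, then max I among CS-optimal solutions
    cs_stage1 = design_vaccine(
        graph, cs_config, matrix, alleles, catalog, augment_delta=1.0
    )
    cs_max = _cleavage_score(cs_stage1)
    cs_corner = design_vaccine(
        graph,
        config,
        matrix,
        alleles,
        catalog,
        min_cleavage_score=cs_max - 1e-9,
    )

    if n_points == 1 or cs_max <= cs_at_best_imm + 1e-12:
        return [
            ParetoPoint(
                best_imm, best_imm.immunogenicity, cs_at_best_imm, cs_at_best_imm
            )
        ]

    imm_range = max(abs(best_imm.immunogenicity - cs_corner.immunogenicity), 1e-9)
    cs_range = max(abs(cs_max - cs_at_best_imm), 1e-9)
    delta = delta_scale * imm_range / cs_range

    levels = np.linspace(cs_at_best_imm, cs_max, n_points)
    points: list[ParetoPoint] = []
    for eps in levels:
        try:
            sol = design_vaccine(
                graph,
                config,
                matrix,
                alleles,
                catalog,
                min_cleavage_score=float(eps) - 1e-9,
                augment_delta=delta,
            )
        except InfeasibleDesignError:
            continue
        points.append(
            ParetoPoint(sol, sol.immunogenicity, _cleavage_score(sol), float(eps))
        )

    return _filter_nondominated(points)


def _filter_nondominated(points: list[ParetoPoint]) -> list[ParetoPoint]:
    """Drop duplicates and dominated points; keep epsilon order."""
    kept: list[ParetoPoint] = []
    for p in points:
        dominated = False
        for q in points:
            if q is p:
                continue
            better_one = (
                q.immunogenicity > p.immunogenicity + 1e-9
                or q.cleavage_score > p.cleavage_score + 1e-9
            )
            no_worse = (
                q.immunogenicity >= p.immunogenicity - 1e-9
                and q.cleavage_score >= p.cleavage_score - 1e-9
            )
            if better_one and no_worse:
                dominated = True
                break
        if dominated:
            continue
        if any(
            abs(k.immunogenicity - p.immunogenicity) < 1e-9
            and abs(k.cleavage_score - p.cleavage_score) < 1e-9
            for k in kept
        ):
            continue
        kept.append(p)
    return sorted(kept, key=lambda p: p.epsilon)


def normalize_scores(values: list[float]) -> list[float]:
    """Report-side transform: scores relative to the method's maximum.

    Used only for cross-method comparison of frontiers (e.g. spacer vs
    direct junctions); never applied inside the optimizer.
    """
    top = max(values)
    if top == 0:
        return [0.0 for _ in values]
    return [v / top for v in values]


def frontier_frame(points: list[ParetoPoint]) -> pd.DataFrame:
    """Frontier as a data frame (one row per point)."""
    return pd.DataFrame(
        {
            "epsilon": [p.epsilon for p in points],
            "immunogenicity": [p.immunogenicity for p in points],
            "cleavage_score": [p.cleavage_score for p in points],
            "epitopes": [
                ";".join(ep for tour in p.solution.tours for ep in tour)
                for p in points
            ],
        }
    )
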