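"""Vaccine evaluation metrics and positional analyses.

Metrics for a set of vaccine epitopes ``P``:

* **population coverage** — probability that a diploid individual
  carries at least one MHC allele bound by some epitope of ``P``,
  ``1 - prod_i (1 - sum_{a in A_i} y_a p_a)^2`` over loci ``i``;
* **pathogen coverage** — number (and fraction) of pathogen sequences
  containing at least one epitope of ``P``;
* **conservation** — mean fraction of pathogen sequences containing
  each epitope of ``P``.

Positional analyses work on a gapped multiple alignment of the
pathogens: per-column Shannon entropy quantifies sequence variability,
and per-column coverage/immunogenicity tracks show which regions a
vaccine targets.  A seeded shuffle experiment quantifies how much the
optimized epitope ordering of a string-of-beads contributes to its
cleavage score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import RESIDUES, EpitopeCatalog
from .edge_weights import DesignGraph, cleavage_score
from .ilp_design import VaccineSolution
from .immunogenicity import (
    AffinityMatrix,
    AlleleTable,
    epitope_immunogenicities,
    vaccine_immunogenicity,
)

GAP = "-"

#: consensus tie-break order: canonical residues first, then X, then the gap
CONSENSUS_ORDER = RESIDUES + "X" + GAP


@dataclass(frozen=True)
class AlignedAntigenSet:
    """Equal-length gapped sequences from a multiple alignment."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, j: int) -> str:
        return "".join(seq[j] for seq in self.sequences.values())

    def consensus(self) -> str:
        """Per-column most frequent symbol; ties break by residue order."""
        out = []
        for j in range(self.n_columns):
            col = self.column(j)
            counts = {sym: col.count(sym) for sym in set(col)}
            best = max(
                counts,
                key=lambda sym: (counts[sym], -CONSENSUS_ORDER.index(sym)),
            )
            out.append(best)
        return "".join(out)

    def ungapped(self, sid: str) -> str:
        return self.sequences[sid].replace(GAP, "")

    def column_map(self, sid: str) -> np.ndarray:
        """Map from ungapped residue position to alignment column."""
        return np.flatnonzero(
            np.frombuffer(self.sequences[sid].encode(), dtype=np.uint8)
            != ord(GAP)
        )


@dataclass(frozen=True)
class MetricsReport:
    """Headline evaluation metrics for one vaccine."""

    immunogenicity: float
    population_coverage: float
    population_coverage_relative: float
    pathogen_coverage_count: int
    pathogen_coverage_fraction: float
    mean_conservation: float

    def to_dict(self) -> dict[str, float]:
        return {
            "immunogenicity": self.immunogenicity,
            "population_coverage": self.population_coverage,
            "population_coverage_relative": self.population_coverage_relative,
            "pathogen_coverage_count": self.pathogen_coverage_count,
            "pathogen_coverage_fraction": self.pathogen_coverage_fraction,
            "mean_conservation": self.mean_conservation,
        }


def population_coverage(
    epitopes: Iterable[str], matrix: AffinityMatrix, alleles: AlleleTable
) -> float:
    """Probability that a random individual presents >= 1 vaccine epitope.

    Treats loci as independent and individuals as diploid (two draws per
    locus), hence the squared factor per locus.
    """
    idx = matrix.epitope_index(epitopes)
    covered = (
        matrix.binder[idx].any(axis=0)
        if idx.size
        else np.zeros(len(matrix.alleles), dtype=bool)
    )
    col = {name: j for j, name in enumerate(matrix.alleles)}
    prob = 1.0
    for locus, allele_idx in alleles.locus_groups().items():
        mass = 0.0
        for a in allele_idx:
            name = alleles.names[a]
            if name in col and covered[col[name]]:
                mass += alleles.frequencies[a]
        prob *= (1.0 - mass) ** 2
    return 1.0 - prob


def max_population_coverage(alleles: AlleleTable) -> float:
    """Panel ceiling of the coverage formula (every allele counted as covered)."""
    prob = 1.0
    for locus, allele_idx in alleles.locus_groups().items():
        mass = float(alleles.frequencies[allele_idx].sum())
        prob *= (1.0 - mass) ** 2
    return 1.0 - prob


def pathogen_coverage(
    epitopes: Iterable[str], catalog: EpitopeCatalog
) -> tuple[int, float]:
    """Pathogens containing at least one vaccine epitope (count, fraction)."""
    eps = list(epitopes)
    if not eps:
        return 0, 0.0
    idx = [catalog.index(ep) for ep in eps]
    count = int(catalog.incidence[idx].any(axis=0).sum())
    return count, count / catalog.n_pathogens


def mean_conservation(epitopes: Iterable[str], catalog: EpitopeCatalog) -> float:
    """Mean fraction of pathogens containing each vaccine epitope."""
    eps = list(epitopes)
    if not eps:
        raise ValueError("mean conservation is undefined for an empty vaccine")
    idx = [catalog.index(ep) for ep in eps]
    return float(catalog.conservation[idx].mean()) / catalog.n_pathogens


def evaluate_vaccine(
    epitopes: Iterable[str],
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
) -> MetricsReport:
    """All headline metrics for one vaccine epitope set."""
    eps = list(epitopes)
    cov = population_coverage(eps, matrix, alleles)
    ceiling = max_population_coverage(alleles)
    count, frac = pathogen_coverage(eps, catalog)
    return MetricsReport(
        immunogenicity=vaccine_immunogenicity(eps, matrix, alleles),
        population_coverage=cov,
        population_coverage_relative=cov / ceiling if ceiling > 0 else 0.0,
        pathogen_coverage_count=count,
        pathogen_coverage_fraction=frac,
        mean_conservation=mean_conservation(eps, catalog) if eps else 0.0,
    )


# --- positional tracks ------------------------------------------------------

def positional_entropy(
    alignment: AlignedAntigenSet,
    window: int = 9,
    include_gaps: bool = True,
) -> pd.DataFrame:
    """Shannon entropy (bits) per alignment column with gap consensus dropped.

    Columns whose consensus symbol is a gap are removed before anything
    else; the smoothed track is a centered moving average of width
    ``window`` over the retained columns.  With ``include_gaps`` the gap
    acts as a 21st symbol inside retained columns; otherwise gapped rows
    are ignored per column.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    consensus = alignment.consensus()
    keep = [j for j in range(alignment.n_columns) if consensus[j] != GAP]
    entropies = []
    for j in keep:
        col = alignment.column(j)
        if not include_gaps:
            col = col.replace(GAP, "")
        if not col:
            entropies.append(0.0)
            continue
        counts = pd.Series(list(col)).value_counts().to_numpy(float)
        p = counts / counts.sum()
        entropies.append(float(-(p * np.log2(p)).sum()))
    ent = np.asarray(entropies)
    smoothed = (
        pd.Series(ent).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )
    return pd.DataFrame(
        {"column": keep, "entropy": ent, "smoothed_entropy": smoothed}
    )


def positional_coverage(
    alignment: AlignedAntigenSet,
    epitopes: Sequence[str],
    matrix: AffinityMatrix,
    alleles: AlleleTable,
    catalog: EpitopeCatalog,
) -> pd.DataFrame:
    """Per-column coverage and potential-immunogenicity tracks for a vaccine.

    Every occurrence of every vaccine epitope in every ungapped pathogen
    sequence is mapped through the alignment to columns.  Returned per
    column: the number of distinct pathogens covered, the number of
    distinct epitopes covering it, that pathogen count max-normalized to
    [0, 1], and the summed per-epitope immunogenicity of the covering
    epitopes.
    """
    eps = list(epitopes)
    n_cols = alignment.n_columns
    path_cov: list[set[str]] = [set() for _ in range(n_cols)]
    epi_cov: list[set[str]] = [set() for _ in range(n_cols)]
    if eps:
        per_epitope = dict(
            zip(matrix.epitopes, epitope_immunogenicities(matrix, alleles))
        )
        found = {ep: False for ep in eps}
        for sid in alignment.ids:
            seq = alignment.ungapped(sid)
            cmap = alignment.column_map(sid)
            for ep in eps:
                start = seq.find(ep)
                while start != -1:
                    found[ep] = True
                    for pos in range(start, start + len(ep)):
                        path_cov[cmap[pos]].add(sid)
                        epi_cov[cmap[pos]].add(ep)
                    start = seq.find(ep, start + 1)
        missing = [ep for ep, ok in found.items() if not ok]
        if missing:
            raise ValueError(
                f"epitopes absent from every aligned pathogen: {missing}"
            )
    counts = np.array([len(s) for s in path_cov], dtype=float)
    epi_counts = np.array([len(s) for s in epi_cov], dtype=float)
    top = counts.max()
    imm = np.zeros(n_cols)
    if eps:
        for j in range(n_cols):
            imm[j] = sum(per_epitope.get(ep, 0.0) for ep in epi_cov[j])
    return pd.DataFrame(
        {
            "column": np.arange(n_cols),
            "coverage_count": counts,
            "epitope_count": epi_counts,
            "normalized_count": counts / top if top > 0 else counts,
            "potential_immunogenicity": imm,
        }
    )


# --- shuffle experiment -----------------------------------------------------

def shuffle_experiment(
    solution: VaccineSolution,
    graph: DesignGraph,
    permutations: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly permute a string-of-beads and score each permutation.

    For each of ``permutations`` seeded random orderings of the
    solution's single tour, reports the permuted cleavage score, its
    decrease from the original ordering, and the number of junctions
    with negative edge weight (junction cleavage sites; at most
    ``len(tour) - 1``).
    """
    if len(solution.tours) != 1:
        raise ValueError("shuffle experiment expects a single-tour solution")
    tour = list(solution.tours[0])
    if len(tour) < 2:
        raise ValueError("need at least 2 epitopes to shuffle")
    rng = np.random.default_rng(seed)
    original_cs = -graph.tour_weight(tour)
    rows = []
    for p in range(permutations):
        perm = list(tour)
        rng.shuffle(perm)
        cs = -graph.tour_weight(perm)
        rows.append(
            {
                "permutation": p,
                "cleavage_score": cs,
                "decrease": original_cs - cs,
                "cleavage_sites": junction_cleavage_sites(perm, graph),
            }
        )
    return pd.DataFrame(rows)


def junction_cleavage_sites(tour: Sequence[str], graph: DesignGraph) -> int:
    """Number of adjacent-epitope junctions with negative edge weight."""
    idx = [graph.epitopes.index(ep) for ep in tour]
    return int(
        sum(graph.weights[a, b] < 0 for a, b in zip(idx, idx[1:]))
    )


def best_ordering_cleavage_score(
    tour_epitopes: Sequence[str], graph: DesignGraph
) -> float:
    """Best cleavage score over all orderings of a fixed epitope set.

    Exhaustive; intended for small vaccines (the shuffle experiment's
    optimality check).
    """
    import itertools

    best = -math.inf
    for perm in itertools.permutations(tour_epitopes):
        best = max(best, -graph.tour_weight(list(perm)))
    return best


def sequential_enumeration_size(n_epitopes: int, k: int) -> float:
    """Search-space size of naive sequential enumeration of k-epitope vaccines.

    The product ``prod_{i=0..k} (N - k)`` of candidate choices, i.e.
    ``(N - k)**(k + 1)`` — the count a stage-wise method would have to
    enumerate to explore selection/assembly trade-offs by brute force.
    """
    return float(n_epitopes - k) ** (k + 1)


# --- aligned FASTA ----------------------------------------------------------

def read_aligned_fasta(path) -> AlignedAntigenSet:
    from Bio import SeqIO

    records = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    return AlignedAntigenSet(records)
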