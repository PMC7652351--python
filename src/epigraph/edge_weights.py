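"""Design-dependent edge weights and the epitope design graph.

The vaccine design problem lives on a complete directed graph whose
vertices are candidate epitopes plus a depot vertex ``s`` standing for
the N- and C-termini of each polypeptide.  Edge weights encode the
design principle:

* **mixture** — weights are all zero and the weight budget is infinite;
  only the vertex budget matters.
* **string_of_beads** — the weight of edge (i, j) is the negative
  proteasomal cleavage log-likelihood of the junction formed by
  concatenating epitope i before epitope j, computed from a
  position-specific scoring matrix; depot edges weigh zero.
* **mosaic** — the weight of edge (i, j) is the number of residues
  appended to the growing polypeptide when j is merged onto i at their
  longest suffix-prefix overlap, so a tour's weight sum equals the
  assembled mosaic's length.
* **custom** — user-supplied pairwise weights, e.g. from an external
  spacer-design optimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import RESIDUES

#: window offsets relative to a cleavage site, N-terminal to C-terminal
PSSM_OFFSETS = tuple(range(-4, 2))

#: sentinel depot vertex
DEPOT = "s"

DESIGN_KINDS = ("mixture", "string_of_beads", "mosaic", "custom")


@dataclass(frozen=True)
class CleavagePSSM:
    """Position-specific scoring matrix for proteasomal cleavage.

    ``matrix[a][i]`` is the log-likelihood contribution of amino acid
    ``a`` observed at offset ``i`` in {-4, ..., +1} relative to the
    cleaved bond.  All 20 canonical residues must be present at every
    offset.
    """

    matrix: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        for res in RESIDUES:
            if res not in self.matrix:
                raise ValueError(f"PSSM missing residue {res}")
            for off in PSSM_OFFSETS:
                val = self.matrix[res].get(off)
                if val is None or not math.isfinite(val):
                    raise ValueError(f"PSSM missing finite value at ({res}, {off})")

    def __call__(self, residue: str, offset: int) -> float:
        return self.matrix[residue][offset]


def cleavage_site_score(sequence: str, k: int, pssm: CleavagePSSM) -> float:
    """Cleavage log-likelihood score at position ``k`` of ``sequence``.

    Position ``k`` denotes the peptide bond before residue index ``k``
    (0-based), so the scored window spans residues ``k-4 .. k+1``.  A
    positive score is conventionally taken to indicate a cleavage site.
    """
    if k + PSSM_OFFSETS[0] < 0 or k + PSSM_OFFSETS[-1] >= len(sequence):
        raise ValueError(
            f"cleavage window at position {k} out of bounds for length {len(sequence)}"
        )
    return sum(pssm(sequence[k + i], i) for i in PSSM_OFFSETS)


def cleavage_edge_weight(
    e_i: str,
    e_j: str,
    pssm: CleavagePSSM,
    K: int = 2,
    beta: float = 0.1,
) -> float:
    """Junction edge weight between two concatenated epitopes.

    The weight is the negative cleavage score at the junction (position
    ``len(e_i)`` of the concatenation) plus ``beta`` times the cleavage
    scores at the ``K`` flanking positions on either side, penalising
    junctions whose neighbourhood also looks cleavable:

        w = -phi(e_i e_j, L) + beta * sum_{k=1..K} [phi(L-k) + phi(L+k)]

    A negative weight marks a junction cleavage site.  Defaults K=2,
    beta=0.1.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    joined = e_i + e_j
    ell = len(e_i)
    weight = -cleavage_site_score(joined, ell, pssm)
    for k in range(1, K + 1):
        weight += beta * (
            cleavage_site_score(joined, ell - k, pssm)
            + cleavage_site_score(joined, ell + k, pssm)
        )
    return weight


def overlap_weight(v_i: str, v_j: str) -> int:
    """Residues added to a mosaic when ``v_j`` is appended after ``v_i``.

    Depot edges: leaving the depot costs the full length of the first
    epitope; returning to the depot is free.  Between epitopes the cost
    is ``|v_j|`` minus their longest suffix-prefix overlap.
    """
    if v_i == DEPOT and v_j == DEPOT:
        raise ValueError("at most one endpoint may be the depot")
    if v_i == DEPOT:
        return len(v_j)
    if v_j == DEPOT:
        return 0
    best = 0
    for l in range(1, min(len(v_i), len(v_j)) + 1):
        if v_i[-l:] == v_j[:l]:
            best = l
    return len(v_j) - best


def cleavage_score(tour_edge_weights: Iterable[float]) -> float:
    """Cleavage score of a string-of-beads: negative sum of its edge weights."""
    return -float(sum(tour_edge_weights))


@dataclass(frozen=True)
class DesignGraph:
    """Complete directed graph over epitopes plus the depot.

    ``weights`` has shape ``(m+1, m+1)`` where index ``m`` is the depot;
    the diagonal is unused.  ``h`` is the kind's natural edge-weight
    budget default (infinity for mixtures); a design configuration may
    override it.
    """

    epitopes: tuple[str, ...]
    kind: str
    weights: np.ndarray
    h: float = math.inf

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}")
        m = len(self.epitopes)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (m + 1, m + 1):
            raise ValueError("weights must be (m+1, m+1) with the depot last")
        off_diag = w[~np.eye(m + 1, dtype=bool)]
        if not np.all(np.isfinite(off_diag)):
            raise ValueError("edge weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def n_epitopes(self) -> int:
        return len(self.epitopes)

    @property
    def depot_index(self) -> int:
        return len(self.epitopes)

    def weight(self, i: int | str, j: int | str) -> float:
        """Weight of edge i -> j; endpoints may be indices, epitopes or 's'."""
        return float(self.weights[self._resolve(i), self._resolve(j)])

    def _resolve(self, v: int | str) -> int:
        if isinstance(v, (int, np.integer)):
            return int(v)
        if v == DEPOT:
            return self.depot_index
        return self.epitopes.index(v)

    def tour_weight(self, tour: Sequence[str]) -> float:
        """Weight sum of the closed tour s -> tour[0] -> ... -> tour[-1] -> s."""
        if not tour:
            return 0.0
        d = self.depot_index
        idx = [self.epitopes.index(ep) for ep in tour]
        total = self.weights[d, idx[0]] + self.weights[idx[-1], d]
        total += sum(self.weights[a, b] for a, b in zip(idx, idx[1:]))
        return float(total)


def build_design_graph(
    epitopes: Sequence[str],
    kind: str,
    pssm: CleavagePSSM | None = None,
    edge_table: pd.DataFrame | None = None,
    h: float | None = None,
    K: int = 2,
    beta: float = 0.1,
) -> DesignGraph:
    """Assemble the design graph for the requested vaccine kind.

    ``string_of_beads`` requires a cleavage PSSM, ``custom`` a pairwise
    edge table (columns from_epitope, to_epitope, weight) covering every
    ordered epitope pair; ``mixture`` and ``mosaic`` need nothing extra.
    """
    epitopes = tuple(epitopes)
    m = len(epitopes)
    d = m
    w = np.zeros((m + 1, m + 1))
    if kind == "mixture":
        default_h = math.inf
    elif kind == "string_of_beads":
        if pssm is None:
            raise ValueError("string-of-beads design requires a cleavage PSSM")
        for i, ei in enumerate(epitopes):
            for j, ej in enumerate(epitopes):
                if i != j:
                    w[i, j] = cleavage_edge_weight(ei, ej, pssm, K=K, beta=beta)
        default_h = math.inf
    elif kind == "mosaic":
        for i, ei in enumerate(epitopes):
            for j, ej in enumerate(epitopes):
                if i != j:
                    w[i, j] = overlap_weight(ei, ej)
        for j, ej in enumerate(epitopes):
            w[d, j] = len(ej)
            w[j, d] = 0.0
        default_h = math.inf
    elif kind == "custom":
        if edge_table is None:
            raise ValueError("custom design requires a pairwise edge table")
        lookup = {
            (row.from_epitope, row.to_epitope): float(row.weight)
            for row in edge_table.itertuples(index=False)
        }
        names = epitopes + (DEPOT,)
        for i, ei in enumerate(names):
            for j, ej in enumerate(names):
                if i == j:
                    continue
                if (ei, ej) in lookup:
                    w[i, j] = lookup[(ei, ej)]
                elif DEPOT in (ei, ej):
                    w[i, j] = 0.0
                else:
                    raise ValueError(f"edge table missing pair ({ei}, {ej})")
        default_h = math.inf
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    return DesignGraph(epitopes, kind, w, h if h is not None else default_h)


# --- PSSM / edge-table files ------------------------------------------------

def read_pssm(path: str | Path) -> CleavagePSSM:
    """Read a whitespace-delimited PSSM: header of offsets, 20 residue rows."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = [int(tok) for tok in lines[0]]
    if sorted(header) != sorted(PSSM_OFFSETS):
        raise ValueError(f"PSSM header must contain offsets {PSSM_OFFSETS}")
    matrix: dict[str, dict[int, float]] = {}
    for row in lines[1:]:
        res, values = row[0], [float(tok) for tok in row[1:]]
        matrix[res] = dict(zip(header, values))
    return CleavagePSSM(matrix)


def write_pssm(pssm: CleavagePSSM, path: str | Path) -> None:
    lines = [" ".join(str(off) for off in PSSM_OFFSETS)]
    for res in RESIDUES:
        vals = " ".join(f"{pssm(res, off):.6f}" for off in PSSM_OFFSETS)
        lines.append(f"{res} {vals}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"from_epitope", "to_epitope", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    return df
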