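"""Allele frequencies, binding-score transforms, and vaccine immunogenicity.

The immunogenicity of a vaccine ``P`` (a set of epitopes) is modelled as a
linear functional

    I(P) = sum_{v in P} sum_{a in A} p_a * i_va

where ``p_a`` is the population frequency of MHC allele ``a`` and ``i_va``
the individual immunogenicity of epitope ``v`` presented on allele ``a``.
Individual immunogenicities are approximated from predicted binding
affinities: either a log-transformed IC50 mapped to [0, 1], or a flipped
percentile rank mapped to [0, 100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: IC50 (nM) above which an epitope is considered a non-binder with score 0
DEFAULT_IC50_CAP_NM = 50_000.0

#: IC50 (nM) at or below which an epitope is considered to bind the allele
DEFAULT_BINDER_THRESHOLD_NM = 500.0


def ic50_to_immunogenicity(ic50_nM: float, cap_nM: float = DEFAULT_IC50_CAP_NM) -> float:
    """Map an IC50 affinity (nM) to an immunogenicity score in [0, 1].

    Uses the log transform ``1 - log(IC50) / log(cap)``, clamped to [0, 1]:
    strong binders (IC50 -> 1 nM) score 1, binders at or beyond the cap
    score 0.  Monotonically decreasing in IC50.
    """
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    score = 1.0 - math.log(ic50_nM) / math.log(cap_nM)
    return min(1.0, max(0.0, score))


def rank_to_immunogenicity(rank: float) -> float:
    """Flip a percentile rank in [0, 100] so that 100 is the most immunogenic."""
    if not 0.0 <= rank <= 100.0:
        raise ValueError(f"rank must be in [0, 100], got {rank}")
    return 100.0 - rank


@dataclass(frozen=True)
class AlleleTable:
    """MHC alleles with population frequencies and locus assignment."""

    names: tuple[str, ...]
    frequencies: np.ndarray
    loci: tuple[str, ...]

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("allele names must be unique")
        if len(self.names) != len(freq) or len(self.names) != len(self.loci):
            raise ValueError("names, frequencies and loci must have equal length")
        if np.any(freq < 0) or np.any(freq > 1):
            raise ValueError("allele frequencies must lie in [0, 1]")
        for locus in set(self.loci):
            total = freq[[l == locus for l in self.loci]].sum()
            if total > 1 + 1e-9:
                raise ValueError(
                    f"frequencies at locus {locus!r} sum to {total:.4f} > 1"
                )
        object.__setattr__(self, "frequencies", freq)

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleTable":
        return cls(
            tuple(df["allele"]),
            df["frequency"].to_numpy(float),
            tuple(df["locus"].astype(str)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"allele": self.names, "frequency": self.frequencies, "locus": self.loci}
        )

    def locus_groups(self) -> dict[str, np.ndarray]:
        """Allele index arrays keyed by locus."""
        groups: dict[str, list[int]] = {}
        for i, locus in enumerate(self.loci):
            groups.setdefault(locus, []).append(i)
        return {k: np.asarray(v) for k, v in groups.items()}


@dataclass
class AffinityMatrix:
    """Per epitope-by-allele binding data.

    ``ic50`` holds raw affinities in nM with NaN for unmeasured pairs;
    ``immunogenicity`` holds nonnegative scores i_va; ``binder`` holds the
    binary indicators tau_va (1 iff the epitope binds the allele).
    """

    epitopes: tuple[str, ...]
    alleles: tuple[str, ...]
    immunogenicity: np.ndarray
    ic50: np.ndarray | None = None
    binder: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n_e, n_a = len(self.epitopes), len(self.alleles)
        imm = np.asarray(self.immunogenicity, dtype=float)
        if imm.shape != (n_e, n_a):
            raise ValueError("immunogenicity must be (n_epitopes, n_alleles)")
        if not np.all(np.isfinite(imm)) or np.any(imm < 0):
            raise ValueError("immunogenicity scores must be finite and >= 0")
        self.immunogenicity = imm
        if self.ic50 is not None:
            ic50 = np.asarray(self.ic50, dtype=float)
            if ic50.shape != (n_e, n_a):
                raise ValueError("ic50 must be (n_epitopes, n_alleles)")
            self.ic50 = ic50
        if self.binder is None:
            self.binder = np.zeros((n_e, n_a), dtype=bool)
        else:
            self.binder = np.asarray(self.binder, dtype=bool)
        self._index = {ep: i for i, ep in enumerate(self.epitopes)}

    def epitope_index(self, epitopes: Iterable[str]) -> np.ndarray:
        idx = []
        for ep in epitopes:
            if ep not in self._index:
                raise KeyError(f"epitope {ep!r} not in affinity matrix")
            idx.append(self._index[ep])
        return np.asarray(idx, dtype=int)


def binder_indicators(
    matrix: AffinityMatrix, threshold_nM: float = DEFAULT_BINDER_THRESHOLD_NM
) -> AffinityMatrix:
    """Set tau_va = 1 iff the measured IC50 is at most ``threshold_nM``.

    The boundary is inclusive ("at most 500 nM"); pairs with no IC50
    measurement are non-binders.
    """
    if matrix.ic50 is None:
        raise ValueError("affinity matrix has no raw IC50 values")
    with np.errstate(invalid="ignore"):
        binder = matrix.ic50 <= threshold_nM
    binder &= ~np.isnan(matrix.ic50)
    return AffinityMatrix(
        matrix.epitopes, matrix.alleles, matrix.immunogenicity, matrix.ic50, binder
    )


def _aligned_frequencies(matrix: AffinityMatrix, alleles: AlleleTable) -> np.ndarray:
    """Frequency vector aligned to the matrix's allele axis.

    Alleles missing from the frequency table contribute zero (logged).
    """
    table = dict(zip(alleles.names, alleles.frequencies))
    freq = np.zeros(len(matrix.alleles))
    for j, name in enumerate(matrix.alleles):
        if name in table:
            freq[j] = table[name]
        else:
            logger.warning("allele %s has no frequency entry; contributes 0", name)
    return freq


def vaccine_immunogenicity(
    epitopes: Iterable[str], matrix: AffinityMatrix, alleles: AlleleTable
) -> float:
    """Total vaccine immunogenicity I(P) = sum_v sum_a p_a i_va.

    Additive over disjoint epitope sets and monotone under epitope
    addition (scores are nonnegative).
    """
    idx = matrix.epitope_index(epitopes)
    if idx.size == 0:
        return 0.0
    freq = _aligned_frequencies(matrix, alleles)
    return float((matrix.immunogenicity[idx] @ freq).sum())


def epitope_immunogenicities(
    matrix: AffinityMatrix, alleles: AlleleTable
) -> np.ndarray:
    """Per-epitope contribution sum_a p_a i_va, aligned to matrix.epitopes."""
    freq = _aligned_frequencies(matrix, alleles)
    return matrix.immunogenicity @ freq


# --- CSV interfaces ---------------------------------------------------------

def read_allele_csv(path: str | Path) -> AlleleTable:
    return AlleleTable.from_frame(pd.read_csv(path))


def write_allele_csv(alleles: AlleleTable, path: str | Path) -> None:
    alleles.to_frame().to_csv(path, index=False)


def read_affinity_csv(
    path: str | Path,
    score_source: str = "ic50",
    cap_nM: float = DEFAULT_IC50_CAP_NM,
    binder_threshold_nM: float = DEFAULT_BINDER_THRESHOLD_NM,
    epitopes: Sequence[str] | None = None,
) -> AffinityMatrix:
    """Load a long-format affinity CSV (epitope, allele, ic50_nM[, ...]).

    ``score_source`` selects how i_va is derived: ``ic50`` (log transform),
    ``rank`` (flipped percentile, needs a ``rank`` column) or
    ``precomputed`` (needs an ``immunogenicity`` column).  If ``epitopes``
    is given, rows for unknown epitopes are dropped with a warning.
    """
    df = pd.read_csv(path)
    if epitopes is not None:
        known = set(epitopes)
        unknown = ~df["epitope"].isin(known)
        if unknown.any():
            logger.warning("dropping %d affinity rows for unknown epitopes", unknown.sum())
            df = df[~unknown]
        ep_list = tuple(sorted(known))
    else:
        ep_list = tuple(sorted(df["epitope"].unique()))
    al_list = tuple(sorted(df["allele"].unique()))
    e_pos = {e: i for i, e in enumerate(ep_list)}
    a_pos = {a: j for j, a in enumerate(al_list)}
    n_e, n_a = len(ep_list), len(al_list)
    ic50 = np.full((n_e, n_a), np.nan)
    imm = np.zeros((n_e, n_a))
    for row in df.itertuples(index=False):
        i, j = e_pos[row.epitope], a_pos[row.allele]
        if hasattr(row, "ic50_nM") and not pd.isna(row.ic50_nM):
            ic50[i, j] = float(row.ic50_nM)
        if score_source == "ic50":
            if not np.isnan(ic50[i, j]):
                imm[i, j] = ic50_to_immunogenicity(ic50[i, j], cap_nM)
        elif score_source == "rank":
            imm[i, j] = rank_to_immunogenicity(float(row.rank))
        elif score_source == "precomputed":
            imm[i, j] = float(row.immunogenicity)
        else:
            raise ValueError(f"unknown score source {score_source!r}")
    matrix = AffinityMatrix(ep_list, al_list, imm, ic50)
    if not np.all(np.isnan(ic50)):
        matrix = binder_indicators(matrix, binder_threshold_nM)
    return matrix


def write_affinity_csv(matrix: AffinityMatrix, path: str | Path) -> None:
    rows = []
    for i, ep in enumerate(matrix.epitopes):
        for j, al in enumerate(matrix.alleles):
            ic50 = matrix.ic50[i, j] if matrix.ic50 is not None else np.nan
            if np.isnan(ic50) and matrix.immunogenicity[i, j] == 0:
                continue
            rows.append(
                {
                    "epitope": ep,
                    "allele": al,
                    "ic50_nM": ic50,
                    "immunogenicity": matrix.immunogenicity[i, j],
                }
            )
    pd.DataFrame(rows, columns=["epitope", "allele", "ic50_nM", "immunogenicity"]).to_csv(
        path, index=False
    )
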