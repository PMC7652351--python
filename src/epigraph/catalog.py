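"""Candidate epitope extraction from antigen sequences.

Candidate epitopes are all distinct fixed-length substrings (by default
9-mers, the canonical MHC class I ligand length) of a set of antigen
protein sequences.  For each epitope the catalog records which pathogen
sequences contain it (binary incidence) and its conservation, i.e. the
number of pathogen sequences containing it.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

#: canonical residues in the fixed order used for deterministic tie-breaks
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: residues accepted in antigen input; 'X' marks an ambiguous position
ANTIGEN_ALPHABET = frozenset(RESIDUES) | {"X"}


@dataclass(frozen=True)
class AntigenSet:
    """An ordered collection of pathogen protein sequences.

    Parameters
    ----------
    sequences
        Mapping of unique sequence id to upper-case amino-acid sequence.
        Allowed characters are the 20 canonical residues plus ``X`` for an
        ambiguous position.  Iteration order of the mapping fixes the
        pathogen index used throughout the package.
    """

    sequences: Mapping[str, str]
    ids: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("no input sequences")
        ids = tuple(self.sequences)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        for sid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")
            bad = set(seq) - ANTIGEN_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {sid!r} contains invalid characters: {sorted(bad)}"
                )
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterable[str]:
        return iter(self.ids)

    def __getitem__(self, sid: str) -> str:
        return self.sequences[sid]


@dataclass(frozen=True)
class EpitopeCatalog:
    """Unique epitopes with epitope-by-pathogen incidence.

    Attributes
    ----------
    epitopes
        Lexicographically sorted unique epitope sequences.
    pathogen_ids
        Pathogen ids in the order of the source :class:`AntigenSet`.
    incidence
        Boolean array of shape ``(n_epitopes, n_pathogens)``;
        ``incidence[v, s]`` is true iff epitope ``v`` occurs as a substring
        of pathogen ``s``.  An epitope occurring several times in the same
        pathogen still counts once (incidence is binary).
    """

    epitopes: tuple[str, ...]
    pathogen_ids: tuple[str, ...]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        inc = np.asarray(self.incidence, dtype=bool)
        if inc.shape != (len(self.epitopes), len(self.pathogen_ids)):
            raise ValueError("incidence shape does not match epitopes/pathogens")
        object.__setattr__(self, "incidence", inc)

    @property
    def n_pathogens(self) -> int:
        return len(self.pathogen_ids)

    @property
    def conservation(self) -> np.ndarray:
        """Number of pathogen sequences containing each epitope."""
        return self.incidence.sum(axis=1)

    def index(self, epitope: str) -> int:
        import bisect

        i = bisect.bisect_left(self.epitopes, epitope)
        if i == len(self.epitopes) or self.epitopes[i] != epitope:
            raise KeyError(f"epitope {epitope!r} not in catalog")
        return i

    def __contains__(self, epitope: str) -> bool:
        try:
            self.index(epitope)
        except KeyError:
            return False
        return True

    def __len__(self) -> int:
        return len(self.epitopes)

    def to_frame(self) -> pd.DataFrame:
        """Catalog as a data frame: epitope, conservation, pathogen id list."""
        rows = []
        for i, ep in enumerate(self.epitopes):
            covered = [
                self.pathogen_ids[j] for j in np.flatnonzero(self.incidence[i])
            ]
            rows.append(
                {
                    "epitope": ep,
                    "conservation": int(self.incidence[i].sum()),
                    "pathogens": ";".join(covered),
                }
            )
        return pd.DataFrame(rows, columns=["epitope", "conservation", "pathogens"])


def extract_epitopes(antigens: AntigenSet, length: int = 9) -> EpitopeCatalog:
    """Extract every distinct length-``length`` substring as a candidate epitope.

    Windows containing an ambiguous residue ``X`` are excluded (binding
    predictors cannot score them).  Sequences shorter than ``length``
    contribute nothing.  Epitopes are indexed lexicographically, so the
    catalog is independent of input order.
    """
    if length < 1:
        raise ValueError("epitope length must be >= 1")
    seen: dict[str, set[int]] = {}
    for s_idx, sid in enumerate(antigens.ids):
        seq = antigens[sid]
        for start in range(len(seq) - length + 1):
            window = seq[start : start + length]
            if "X" in window:
                continue
            seen.setdefault(window, set()).add(s_idx)
    epitopes = tuple(sorted(seen))
    incidence = np.zeros((len(epitopes), len(antigens)), dtype=bool)
    for i, ep in enumerate(epitopes):
        incidence[i, sorted(seen[ep])] = True
    return EpitopeCatalog(epitopes, antigens.ids, incidence)


# --- FASTA / CSV interfaces -------------------------------------------------

def read_fasta(path: str | Path) -> AntigenSet:
    """Read antigens from a plain or gzip-compressed FASTA file."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    return AntigenSet(records)


def write_catalog_csv(catalog: EpitopeCatalog, path: str | Path) -> None:
    catalog.to_frame().to_csv(path, index=False)


def read_catalog_csv(path: str | Path, pathogen_ids: Iterable[str]) -> EpitopeCatalog:
    """Rebuild a catalog from :func:`write_catalog_csv` output.

    ``pathogen_ids`` supplies the full ordered pathogen index (the CSV
    only stores the covering subset per epitope).
    """
    df = pd.read_csv(path, keep_default_na=False)
    pathogen_ids = tuple(pathogen_ids)
    pos = {sid: j for j, sid in enumerate(pathogen_ids)}
    epitopes = tuple(sorted(df["epitope"]))
    order = {ep: i for i, ep in enumerate(epitopes)}
    incidence = np.zeros((len(epitopes), len(pathogen_ids)), dtype=bool)
    for _, row in df.iterrows():
        i = order[row["epitope"]]
        for sid in str(row["pathogens"]).split(";"):
            if sid:
                incidence[i, pos[sid]] = True
    return EpitopeCatalog(epitopes, pathogen_ids, incidence)
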