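"""Input/output plumbing: run configuration, bundle loading, result writing.

File dialects
-------------
* antigens: FASTA (plain or gzip)
* affinities: long CSV with columns ``epitope, allele, ic50_nM``
  (optionally ``immunogenicity`` / ``rank``)
* alleles: CSV with columns ``allele, frequency, locus``
* cleavage PSSM: whitespace matrix, offset header then 20 residue rows
* pairwise edge table: CSV with ``from_epitope, to_epitope, weight``
* solutions: JSON + FASTA of assembled polypeptides
* metrics: CSV; Pareto frontier: CSV; positional tracks: TSV

All CSV files are comma-separated UTF-8 with a mandatory header and
``.`` decimals; multi-valued cells are semicolon-joined.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import AntigenSet, EpitopeCatalog, extract_epitopes, read_fasta
from .edge_weights import CleavagePSSM, read_edge_table, read_pssm
from .ilp_design import DesignConfig, VaccineSolution, assemble_polypeptide
from .immunogenicity import AffinityMatrix, AlleleTable, read_affinity_csv, read_allele_csv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and settings for one CLI run."""

    fasta: Path
    affinity_csv: Path
    allele_csv: Path
    pssm: Path | None = None
    edge_table: Path | None = None
    aligned_fasta: Path | None = None
    output_dir: Path = Path(".")
    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    epitope_length: int = 9
    score_source: str = "ic50"
    seed: int = 0
    log_level: str = "INFO"


@dataclass
class InputBundle:
    antigens: AntigenSet
    catalog: EpitopeCatalog
    matrix: AffinityMatrix
    alleles: AlleleTable
    pssm: CleavagePSSM | None = None
    edge_table: pd.DataFrame | None = None


def load_inputs(config: RunConfig) -> InputBundle:
    """Load and cross-validate the input bundle.

    Affinity rows for epitopes absent from the catalog are dropped with
    a warning (tolerant join); allele frequency validation happens in
    :class:`AlleleTable`.
    """
    antigens = read_fasta(config.fasta)
    catalog = extract_epitopes(antigens, config.epitope_length)
    alleles = read_allele_csv(config.allele_csv)
    matrix = read_affinity_csv(
        config.affinity_csv,
        score_source=config.score_source,
        epitopes=catalog.epitopes,
    )
    pssm = read_pssm(config.pssm) if config.pssm else None
    edge_table = read_edge_table(config.edge_table) if config.edge_table else None
    logger.info(
        "loaded %d pathogens, %d epitopes, %d alleles",
        len(antigens),
        len(catalog),
        len(alleles),
    )
    return InputBundle(antigens, catalog, matrix, alleles, pssm, edge_table)


def solution_to_dict(solution: VaccineSolution, kind: str) -> dict:
    return {
        "tours": [list(t) for t in solution.tours],
        "tour_weights": solution.tour_weights,
        "polypeptides": [assemble_polypeptide(t, kind) for t in solution.tours],
        "objective_value": solution.objective_value,
        "immunogenicity": solution.immunogenicity,
        "status": solution.status,
        "theta_s": [bool(b) for b in solution.theta_s],
        "theta_a": [bool(b) for b in solution.theta_a],
    }


def write_outputs(
    outputs: dict[str, object],
    output_dir: str | Path,
    seed: int,
    config_echo: dict | None = None,
) -> dict:
    """Write result files plus a manifest.

    ``outputs`` maps file names to payloads: dicts become JSON, data
    frames become CSV (or TSV for ``.tsv`` names), strings are written
    verbatim (e.g. FASTA text).  The manifest lists each file with its
    SHA-256 checksum, the seed, the tool version and a config echo, and
    is itself written as ``manifest.json``.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, payload in outputs.items():
        path = out / name
        if isinstance(payload, pd.DataFrame):
            sep = "\t" if path.suffix == ".tsv" else ","
            payload.to_csv(path, index=False, sep=sep)
        elif isinstance(payload, (dict, list)):
            path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        elif isinstance(payload, str):
            path.write_text(payload)
        else:
            raise TypeError(f"cannot serialize output {name!r}: {type(payload)}")
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        entries.append({"file": name, "sha256": digest})
    manifest = {
        "files": entries,
        "seed": seed,
        "version": __version__,
        "config": config_echo or {},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def polypeptide_fasta(solution: VaccineSolution, kind: str) -> str:
    """FASTA text with one record per assembled tour."""
    lines = []
    for i, tour in enumerate(solution.tours):
        lines.append(f">tour_{i + 1} epitopes={len(tour)}")
        lines.append(assemble_polypeptide(tour, kind))
    return "\n".join(lines) + "\n"


def antigen_fasta(antigens: AntigenSet) -> str:
    lines = []
    for sid in antigens.ids:
        lines.append(f">{sid}")
        lines.append(antigens[sid])
    return "\n".join(lines) + "\n"
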