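"""Synthetic input generation for self-contained experiments.

Real inputs to the designer are antigen sequence sets (e.g. HIV-1 Nef
variants), epitope-by-allele binding predictions, MHC allele frequency
panels, and a proteasomal-cleavage PSSM.  This module generates stand-in
data with the statistical structure the method relies on:

* antigens evolve from one random ancestral sequence by independent
  per-site substitution, so a low mutation rate yields the conserved
  regions that mosaic designs exploit;
* IC50 affinities are log-normal with a configurable fraction of strong
  binders (below the 500 nM binding threshold), mirroring the sparsity
  of real binding tables;
* allele frequencies are drawn on a per-locus simplex scaled below 1 so
  the diploid population-coverage formula stays valid;
* the cleavage PSSM is random with an optional planted motif (elevated
  contribution for one residue at offset -1) so that some junctions
  score positive, as real PCM matrices do.

All draws are seeded; every generator derives an independent stream
from the same spec seed, so outputs are bit-reproducible and adding a
generator does not shift the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import RESIDUES, AntigenSet, EpitopeCatalog
from .edge_weights import PSSM_OFFSETS, CleavagePSSM
from .immunogenicity import (
    DEFAULT_BINDER_THRESHOLD_NM,
    AffinityMatrix,
    AlleleTable,
    binder_indicators,
    ic50_to_immunogenicity,
)

# stream ids keep the per-operation random streams independent
_STREAM_ANTIGENS = 1
_STREAM_ALLELES = 2
_STREAM_AFFINITIES = 3
_STREAM_PSSM = 4


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic data generator.

    Defaults describe a desk-scale instance: 20 pathogen variants of a
    60-residue antigen at 2% per-site divergence (high conservation,
    like the conserved core of a viral protein), a 6-allele panel over
    the three classical MHC-I loci, log-normal IC50 centred near 5000 nM
    with 10% of epitope-allele pairs forced into the binder range.
    """

    seed: int = 0
    n_pathogens: int = 20
    sequence_length: int = 60
    mutation_rate: float = 0.02
    n_alleles: int = 6
    loci: tuple[str, ...] = ("A", "B", "C")
    locus_total_frequency: float = 0.9
    ic50_median_nM: float = 5000.0
    ic50_sigma: float = 2.0
    binder_fraction: float = 0.1
    pssm_scale: float = 1.0
    motif_strength: float = 0.0
    motif_residue: str = "K"

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.binder_fraction <= 1.0:
            raise ValueError("binder_fraction must lie in [0, 1]")
        if self.n_pathogens < 1 or self.sequence_length < 1 or self.n_alleles < 1:
            raise ValueError("counts and lengths must be positive")
        if not 0.0 < self.locus_total_frequency <= 1.0:
            raise ValueError("locus_total_frequency must lie in (0, 1]")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


def generate_antigens(spec: SyntheticSpec) -> AntigenSet:
    """Draw an ancestral sequence and mutate it independently per pathogen.

    Each site of each pathogen is substituted with probability
    ``mutation_rate`` by a uniform draw over the 19 other residues.
    """
    rng = spec._rng(_STREAM_ANTIGENS)
    residues = np.frombuffer(RESIDUES.encode(), dtype=np.uint8)
    ancestor = rng.choice(residues, size=spec.sequence_length)
    sequences = {}
    for i in range(spec.n_pathogens):
        seq = ancestor.copy()
        hit = rng.random(spec.sequence_length) < spec.mutation_rate
        for pos in np.flatnonzero(hit):
            alternatives = residues[residues != seq[pos]]
            seq[pos] = rng.choice(alternatives)
        sequences[f"P{i:03d}"] = seq.tobytes().decode()
    return AntigenSet(sequences)


def generate_alleles(spec: SyntheticSpec) -> AlleleTable:
    """Draw allele frequencies on a per-locus simplex.

    Alleles are dealt round-robin over the loci; within each locus the
    frequencies are a Dirichlet draw scaled to ``locus_total_frequency``
    (leaving probability mass for alleles outside the panel, as in real
    frequency tables).
    """
    rng = spec._rng(_STREAM_ALLELES)
    loci = [spec.loci[i % len(spec.loci)] for i in range(spec.n_alleles)]
    names = []
    freqs = np.zeros(spec.n_alleles)
    for locus in dict.fromkeys(loci):
        members = [i for i, l in enumerate(loci) if l == locus]
        simplex = rng.dirichlet(np.ones(len(members)))
        for i, frac in zip(members, simplex):
            freqs[i] = frac * spec.locus_total_frequency
    for i, locus in enumerate(loci):
        names.append(f"HLA-{locus}*{i + 1:02d}:01")
    return AlleleTable(tuple(names), freqs, tuple(loci))


def generate_affinities(
    spec: SyntheticSpec, catalog: EpitopeCatalog, alleles: AlleleTable
) -> AffinityMatrix:
    """Log-normal IC50 per epitope-allele pair with planted strong binders.

    Every pair gets ``IC50 ~ LogNormal(log median, sigma)``; a
    ``binder_fraction`` subset of pairs is then redrawn uniformly in
    (10, 500] nM so the binder rate is controlled regardless of the
    log-normal tail.  Immunogenicity scores are the log-transformed
    IC50 values; binder indicators use the 500 nM threshold.
    """
    if len(catalog) == 0:
        raise ValueError("catalog is empty")
    rng = spec._rng(_STREAM_AFFINITIES)
    n_e, n_a = len(catalog), len(alleles)
    ic50 = rng.lognormal(
        mean=np.log(spec.ic50_median_nM), sigma=spec.ic50_sigma, size=(n_e, n_a)
    )
    ic50 = np.maximum(ic50, 1.0)
    if spec.binder_fraction > 0:
        force = rng.random((n_e, n_a)) < spec.binder_fraction
        ic50[force] = rng.uniform(10.0, DEFAULT_BINDER_THRESHOLD_NM, force.sum())
    elif spec.binder_fraction == 0:
        ic50 = np.maximum(ic50, DEFAULT_BINDER_THRESHOLD_NM + 1.0)
    imm = np.vectorize(ic50_to_immunogenicity)(ic50)
    matrix = AffinityMatrix(
        catalog.epitopes, alleles.names, imm.astype(float), ic50
    )
    return binder_indicators(matrix)


def generate_pssm(spec: SyntheticSpec) -> CleavagePSSM:
    """Random zero-mean cleavage PSSM with an optional planted motif.

    Entries are i.i.d. normal with scale ``pssm_scale``;
    ``motif_strength`` is added to the contribution of
    ``motif_residue`` at offset -1 (the residue N-terminal of the
    cleaved bond, where real proteasomal preferences concentrate).
    """
    rng = spec._rng(_STREAM_PSSM)
    matrix: dict[str, dict[int, float]] = {}
    for res in RESIDUES:
        values = rng.normal(0.0, spec.pssm_scale, len(PSSM_OFFSETS))
        matrix[res] = dict(zip(PSSM_OFFSETS, values))
    if spec.motif_strength:
        matrix[spec.motif_residue][-1] += spec.motif_strength
    return CleavagePSSM(matrix)


def generate_bundle(spec: SyntheticSpec):
    """Generate the full input bundle (antigens, catalog, alleles, affinities, PSSM)."""
    from .catalog import extract_epitopes

    antigens = generate_antigens(spec)
    catalog = extract_epitopes(antigens)
    alleles = generate_alleles(spec)
    matrix = generate_affinities(spec, catalog, alleles)
    pssm = generate_pssm(spec)
    return antigens, catalog, alleles, matrix, pssm
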