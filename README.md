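# epigraph

Graph-based design of epitope vaccines: mixtures, string-of-beads,
mosaics, and cocktails thereof, via a single team-orienteering integer
linear program.

## The problem

Epitope vaccines deliver short peptides (here 9-mers) presented on MHC
class I molecules to T-cells. Designing one means (1) enumerating
candidate epitopes from a set of antigen sequences, (2) selecting a
subset with high predicted immune response across a target population,
and (3) assembling the selection into deliverable polypeptides —
either concatenated directly (string-of-beads, where efficacy hinges on
correct proteasomal cleavage at epitope junctions) or merged at
overlapping ends (mosaic, which packs more epitopes per residue).
Stage-wise pipelines optimize these steps separately and cannot trade
selection quality against assembly quality.

`epigraph` treats selection and assembly as one combinatorial problem
on a weighted directed graph G(V ∪ {s}, E, w): vertices are epitopes,
`s` is a depot standing for the polypeptide termini, and edge weights
encode the design principle — all zero for mixtures, negative cleavage
log-likelihoods ψ-scored from a PSSM for string-of-beads, and
added-suffix lengths for mosaics. A vaccine of `n` polypeptides is `n`
vertex-disjoint depot-anchored tours, found by maximizing

    I(P) = Σ_{v∈P} Σ_{a∈A} p_a · i_va

(the population-frequency-weighted sum of per-epitope binding scores
`i_va`, from log-transformed IC50 or flipped percentile rank) subject
to per-tour vertex budgets `k`, edge-weight budgets `h`, and optional
joint floors on pathogen coverage, allele coverage, and average
epitope conservation. The ILP uses Miller–Tucker–Zemlin subtour
elimination and is solved with HiGHS (`scipy.optimize.milp`); on small
instances the optimum is verified against exhaustive tour enumeration.

The bi-objective trade-off between immunogenicity and the cleavage
score (the negative sum of junction weights) is explored with the
augmented ε-constraint method. Designs are evaluated with diploid
population coverage `1 − Π_i (1 − Σ_{a∈A_i} y_a p_a)²`, pathogen
coverage, mean conservation, and positional entropy/coverage tracks on
aligned sequences.

## Worked example

Design a single mosaic of at most 4 epitopes and 24 residues on a
synthetic antigen set (8 variants of a 60% conserved 20-residue
protein, 6 HLA alleles across the A/B/C loci):

```python
import epigraph as eg

spec = eg.SyntheticSpec(seed=11, n_pathogens=8, sequence_length=20,
                        mutation_rate=0.05, binder_fraction=0.25)
antigens, catalog, alleles, matrix, pssm = eg.generate_bundle(spec)

graph = eg.build_design_graph(catalog.epitopes[:8], "mosaic")
config = eg.DesignConfig(n_tours=1, k=4, h=24.0)
sol = eg.design_vaccine(graph, config, matrix, alleles, catalog)
poly = eg.assemble_polypeptide(sol.tours[0], "mosaic")
report = eg.evaluate_vaccine(sol.epitopes, matrix, alleles, catalog)
```

which prints:

```
8 pathogens, 56 candidate epitopes, 6 alleles
tour: CRMFRPQPP -> FRPQPPKHI -> CRHHRPPPP -> HHRPPPPKH
polypeptide: CRMFRPQPPKHICRHHRPPPPKH (23 aa = tour weight 23)
immunogenicity I(P) = 3.5697
population coverage = 1.0000 (relative 1.0000)
pathogen coverage   = 2/8
mean conservation   = 0.1250
```

Four 9-mers fit in 23 residues instead of 36 because consecutive tour
epitopes are merged at their longest suffix-prefix overlap; the tour's
edge-weight sum equals the assembled length by construction. The
immunogenicity is the linear sum I(P) above; population coverage 1.0
means every allele in the panel binds at least one selected epitope
(relative coverage divides by the panel's theoretical ceiling).

The same workflow is available from the shell:

```bash
epigraph synth --seed 11 --out bundle/
epigraph design --fasta bundle/antigens.fasta --affinities bundle/affinities.csv \
    --alleles bundle/alleles.csv --kind mosaic --max-epitopes 4 --out run/
epigraph pareto --fasta ... --pssm bundle/pssm.txt --points 11 --out pareto/
```

plus `evaluate`, `tracks` (positional entropy/coverage TSV on an
aligned FASTA) and `shuffle` (random-permutation cleavage experiment).

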