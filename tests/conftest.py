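"""Shared fixtures: synthetic bundles and hand-built toy instances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import epigraph as eg


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale synthetic bundle: 8 pathogens, ~30 epitopes, 6 alleles."""
    spec = eg.SyntheticSpec(
        seed=11,
        n_pathogens=8,
        sequence_length=20,
        mutation_rate=0.15,
        binder_fraction=0.25,
    )
    antigens, catalog, alleles, matrix, pssm = eg.generate_bundle(spec)
    return {
        "spec": spec,
        "antigens": antigens,
        "catalog": catalog,
        "alleles": alleles,
        "matrix": matrix,
        "pssm": pssm,
    }


def make_toy_instance(epitopes, prizes, incidence=None, n_pathogens=1):
    """Single-allele instance with prescribed per-epitope immunogenicities.

    One allele with frequency 1 makes each epitope's contribution equal
    its prize, so objective values can be computed by hand.
    """
    order = sorted(range(len(epitopes)), key=lambda i: epitopes[i])
    eps = tuple(epitopes[i] for i in order)
    pr = [prizes[i] for i in order]
    if incidence is None:
        inc = np.ones((len(eps), n_pathogens), dtype=bool)
    else:
        inc = np.asarray(incidence, dtype=bool)[order]
    catalog = eg.EpitopeCatalog(
        eps, tuple(f"P{j}" for j in range(inc.shape[1])), inc
    )
    matrix = eg.AffinityMatrix(
        eps, ("HLA-A*01:01",), np.array([[p] for p in pr], dtype=float)
    )
    alleles = eg.AlleleTable(("HLA-A*01:01",), np.array([1.0]), ("A",))
    return catalog, matrix, alleles


@pytest.fixture()
def separated_pareto_instance():
    """Custom-weight instance whose exact Pareto frontier is 3 separated points.

    Six epitopes with prizes 1.0..1.5 and symmetric pair weights: three
    favoured pairs with weights -10, -6, -3 (cleavage scores 10, 6, 3)
    and +5 everywhere else.  With tours of exactly two epitopes the
    non-dominated (immunogenicity, cleavage score) pairs are
    (2.1, 10), (2.5, 6) and (2.9, 3).
    """
    eps = sorted(
        ["AAAAAAAAA", "CCCCCCCCC", "DDDDDDDDD", "EEEEEEEEE", "FFFFFFFFF", "GGGGGGGGG"]
    )
    catalog, matrix, alleles = make_toy_instance(
        eps, [1.0, 1.1, 1.2, 1.3, 1.4, 1.5]
    )
    special = {
        (eps[0], eps[1]): -10.0,
        (eps[1], eps[0]): -10.0,
        (eps[2], eps[3]): -6.0,
        (eps[3], eps[2]): -6.0,
        (eps[4], eps[5]): -3.0,
        (eps[5], eps[4]): -3.0,
    }
    rows = [
        {"from_epitope": a, "to_epitope": b, "weight": special.get((a, b), 5.0)}
        for a in eps
        for b in eps
        if a != b
    ]
    graph = eg.build_design_graph(eps, "custom", edge_table=pd.DataFrame(rows))
    config = eg.DesignConfig(n_tours=1, k=2, exact_k=True)
    exact_front = {(2.1, 10.0), (2.5, 6.0), (2.9, 3.0)}
    return graph, config, matrix, alleles, catalog, exact_front
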