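"""Evaluation metrics, positional tracks, and the shuffle experiment."""

import math

import numpy as np
import pytest

import epigraph as eg
from conftest import make_toy_instance


def coverage_instance(binder_matrix, freqs, loci):
    """AffinityMatrix + AlleleTable with prescribed binder indicators."""
    n_e, n_a = binder_matrix.shape
    eps = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"[i] * 9 for i in range(n_e)))
    names = tuple(f"HLA-{loci[j]}*{j:02d}" for j in range(n_a))
    matrix = eg.AffinityMatrix(
        eps, names, np.zeros((n_e, n_a)), binder=np.asarray(binder_matrix, bool)
    )
    alleles = eg.AlleleTable(names, np.asarray(freqs, float), tuple(loci))
    return eps, matrix, alleles


class TestPopulationCoverage:
    def test_no_bound_alleles_is_zero(self):
        eps, matrix, alleles = coverage_instance(np.zeros((1, 2)), [0.5, 0.4], "AB")
        assert eg.population_coverage(eps, matrix, alleles) == 0.0

    def test_single_locus_diploid_closed_form(self):
        eps, matrix, alleles = coverage_instance(np.array([[1]]), [0.5], "A")
        assert eg.population_coverage(eps, matrix, alleles) == pytest.approx(0.75)

    def test_two_loci_product(self):
        eps, matrix, alleles = coverage_instance(
            np.array([[1, 1]]), [0.5, 0.5], "AB"
        )
        assert eg.population_coverage(eps, matrix, alleles) == pytest.approx(0.9375)

    def test_monotone_under_epitope_addition(self, small_bundle):
        matrix, alleles = small_bundle["matrix"], small_bundle["alleles"]
        eps = list(small_bundle["catalog"].epitopes)
        values = [
            eg.population_coverage(eps[:i], matrix, alleles) for i in range(0, 8)
        ]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_panel_ceiling_bounds_any_vaccine(self, small_bundle):
        matrix, alleles = small_bundle["matrix"], small_bundle["alleles"]
        all_eps = list(small_bundle["catalog"].epitopes)
        assert eg.population_coverage(all_eps, matrix, alleles) <= (
            eg.max_population_coverage(alleles) + 1e-12
        )


class TestPathogenCoverageAndConservation:
    def test_empty_vaccine(self, small_bundle):
        assert eg.pathogen_coverage([], small_bundle["catalog"]) == (0, 0.0)

    def test_union_by_hand(self):
        # e1 covers {s0, s1}, e2 covers {s1, s2}, 4 pathogens
        incidence = np.array(
            [[1, 1, 0, 0], [0, 1, 1, 0]], dtype=bool
        )
        catalog, _, _ = make_toy_instance(
            ["AAAAAAAAA", "CCCCCCCCC"], [1.0, 1.0], incidence=incidence
        )
        count, frac = eg.pathogen_coverage(list(catalog.epitopes), catalog)
        assert (count, frac) == (3, 0.75)

    def test_fully_conserved_epitope_covers_everything(self, small_bundle):
        cat = small_bundle["catalog"]
        full = [ep for ep, c in zip(cat.epitopes, cat.conservation) if c == cat.n_pathogens]
        if full:
            assert eg.pathogen_coverage([full[0]], cat) == (cat.n_pathogens, 1.0)

    def test_mean_conservation_hand_value(self):
        incidence = np.array(
            [[1, 1, 0, 0], [1, 1, 1, 1]], dtype=bool
        )
        catalog, _, _ = make_toy_instance(
            ["AAAAAAAAA", "CCCCCCCCC"], [1.0, 1.0], incidence=incidence
        )
        assert eg.mean_conservation(list(catalog.epitopes), catalog) == pytest.approx(0.75)

    def test_empty_vaccine_conservation_undefined(self, small_bundle):
        with pytest.raises(ValueError):
            eg.mean_conservation([], small_bundle["catalog"])


class TestPositionalEntropy:
    def make_alignment(self, rows):
        return eg.AlignedAntigenSet({f"s{i}": r for i, r in enumerate(rows)})

    def test_conserved_column_zero_bits(self):
        track = eg.positional_entropy(self.make_alignment(["AA", "AA"]), window=1)
        assert track["entropy"].tolist() == [0.0, 0.0]

    def test_fifty_fifty_column_one_bit(self):
        track = eg.positional_entropy(self.make_alignment(["A", "C"]), window=1)
        assert track["entropy"].tolist() == [1.0]

    def test_three_symbol_column(self):
        track = eg.positional_entropy(
            self.make_alignment(["A", "A", "C", "G"]), window=1
        )
        assert track["entropy"].iloc[0] == pytest.approx(1.5)

    def test_gap_consensus_columns_dropped(self):
        track = eg.positional_entropy(
            self.make_alignment(["A-C", "A-C", "AGC"]), window=1
        )
        assert track["column"].tolist() == [0, 2]

    def test_entropy_bounds(self, small_bundle):
        rows = [small_bundle["antigens"][sid] for sid in small_bundle["antigens"].ids]
        track = eg.positional_entropy(self.make_alignment(rows), window=9)
        assert (track["entropy"] >= 0).all()
        assert (track["entropy"] <= math.log2(21)).all()
        mono = track["entropy"] == 0
        # zero iff monomorphic
        for j, is_zero in zip(track["column"], mono):
            col = {r[j] for r in rows}
            assert is_zero == (len(col) == 1)

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError):
            eg.AlignedAntigenSet({})


class TestPositionalCoverage:
    def test_empty_vaccine_all_zero(self, small_bundle):
        rows = {sid: small_bundle["antigens"][sid] for sid in small_bundle["antigens"].ids}
        alignment = eg.AlignedAntigenSet(rows)
        track = eg.positional_coverage(
            alignment, [], small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"]
        )
        assert (track["coverage_count"] == 0).all()
        assert (track["potential_immunogenicity"] == 0).all()

    def test_single_occurrence_covers_nine_columns(self):
        seq = "ACDEFGHIKLMN"
        catalog, matrix, alleles = make_toy_instance(["ACDEFGHIK"], [1.0])
        alignment = eg.AlignedAntigenSet({"P0": seq})
        track = eg.positional_coverage(alignment, ["ACDEFGHIK"], matrix, alleles, catalog)
        assert track["coverage_count"].tolist() == [1] * 9 + [0] * 3
        assert track["normalized_count"].max() == 1.0

    def test_gapped_mapping(self):
        catalog, matrix, alleles = make_toy_instance(["ACDEFGHIK"], [1.0])
        alignment = eg.AlignedAntigenSet({"P0": "AC--DEFGHIKL"})
        track = eg.positional_coverage(alignment, ["ACDEFGHIK"], matrix, alleles, catalog)
        covered = track.loc[track["coverage_count"] > 0, "column"].tolist()
        assert covered == [0, 1, 4, 5, 6, 7, 8, 9, 10]

    def test_absent_epitope_signals(self, small_bundle):
        rows = {sid: small_bundle["antigens"][sid] for sid in small_bundle["antigens"].ids}
        alignment = eg.AlignedAntigenSet(rows)
        with pytest.raises(ValueError, match="absent"):
            eg.positional_coverage(
                alignment,
                ["WWWWWWWWW"],
                small_bundle["matrix"],
                small_bundle["alleles"],
                small_bundle["catalog"],
            )


class TestShuffleExperiment:
    def design(self, bundle, n_eps=5):
        # keep the tour strictly smaller than the graph so the MTZ node
        # potentials (bounded by |V| - 1) can order every visited vertex
        eps = bundle["catalog"].epitopes[: n_eps + 1]
        g = eg.build_design_graph(eps, "string_of_beads", pssm=bundle["pssm"])
        cfg = eg.DesignConfig(n_tours=1, k=n_eps, exact_k=True)
        sol = eg.design_vaccine(
            g, cfg, bundle["matrix"], bundle["alleles"], bundle["catalog"]
        )
        return g, sol

    def test_reproducible_and_bounded_sites(self, small_bundle):
        g, sol = self.design(small_bundle)
        a = eg.shuffle_experiment(sol, g, permutations=20, seed=7)
        b = eg.shuffle_experiment(sol, g, permutations=20, seed=7)
        assert a.equals(b)
        assert (a["cleavage_sites"] <= len(sol.tours[0]) - 1).all()

    def test_identity_permutation_has_zero_decrease(self, small_bundle):
        g, _ = self.design(small_bundle)
        tour = g.epitopes[:2]
        sol = eg.VaccineSolution(
            tours=[tour],
            tour_weights=[g.tour_weight(tour)],
            objective_value=0.0,
            status="optimal",
            immunogenicity=0.0,
            theta_s=np.zeros(1, bool),
            theta_a=np.zeros(1, bool),
        )
        res = eg.shuffle_experiment(sol, g, permutations=30, seed=3)
        orig_cs = -g.tour_weight(tour)
        identity_rows = res[np.isclose(res["cleavage_score"], orig_cs)]
        assert not identity_rows.empty  # with 2 epitopes both orders appear
        assert np.allclose(identity_rows["decrease"], 0.0)

    def test_fewer_than_two_epitopes_rejected(self, small_bundle):
        g, _ = self.design(small_bundle)
        sol = eg.VaccineSolution(
            tours=[(g.epitopes[0],)],
            tour_weights=[0.0],
            objective_value=0.0,
            status="optimal",
            immunogenicity=0.0,
            theta_s=np.zeros(1, bool),
            theta_a=np.zeros(1, bool),
        )
        with pytest.raises(ValueError):
            eg.shuffle_experiment(sol, g, permutations=5, seed=0)


def test_sequential_enumeration_size_printed_formula():
    # (N - k) ** (k + 1): the stage-wise enumeration count for N=13,500, k=10
    value = eg.sequential_enumeration_size(13_500, 10)
    assert value == pytest.approx((13_500 - 10) ** 11)
    exponent = math.floor(math.log10(value))
    leading = value / 10**exponent
    assert (round(leading), exponent) == (3, 45)
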