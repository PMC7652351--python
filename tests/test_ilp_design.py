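"""ILP correctness against the enumeration oracle; assembly; validation."""

import math

import numpy as np
import pytest

import epigraph as eg
from conftest import make_toy_instance


def graph_for(bundle, kind, n_epitopes):
    eps = bundle["catalog"].epitopes[:n_epitopes]
    return eg.build_design_graph(eps, kind, pssm=bundle["pssm"])


class TestDesignVaccine:
    def test_k1_selects_best_single_epitope(self, small_bundle):
        g = graph_for(small_bundle, "mixture", 6)
        cfg = eg.DesignConfig(n_tours=1, k=1)
        sol = eg.design_vaccine(
            g, cfg, small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"]
        )
        from epigraph.immunogenicity import epitope_immunogenicities

        prizes = epitope_immunogenicities(small_bundle["matrix"], small_bundle["alleles"])
        idx = small_bundle["matrix"].epitope_index(g.epitopes)
        assert sol.tours[0][0] == g.epitopes[int(np.argmax(prizes[idx]))]
        assert sol.objective_value == pytest.approx(float(prizes[idx].max()))

    def test_unsatisfiable_allele_cover_is_infeasible(self):
        # one allele that no epitope binds
        catalog, matrix, alleles = make_toy_instance(
            ["AAAAAAAAA", "CCCCCCCCC"], [1.0, 2.0]
        )
        g = eg.build_design_graph(catalog.epitopes, "mixture")
        cfg = eg.DesignConfig(n_tours=1, k=2, min_allele_cover=1)
        with pytest.raises(eg.InfeasibleDesignError):
            eg.design_vaccine(g, cfg, matrix, alleles, catalog)

    @pytest.mark.parametrize("kind", ["mixture", "string_of_beads", "mosaic"])
    @pytest.mark.parametrize("n_tours", [1, 2])
    def test_matches_brute_force(self, small_bundle, kind, n_tours):
        g = graph_for(small_bundle, kind, 6)
        cfg = eg.DesignConfig(n_tours=n_tours, k=2)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        sol = eg.design_vaccine(g, cfg, *args)
        oracle = eg.brute_force_design(g, cfg, *args)
        assert sol.objective_value == pytest.approx(oracle.objective_value, abs=1e-6)
        assert eg.validate_solution(sol, g, cfg, *args) == []

    def test_relaxing_budgets_never_hurts(self, small_bundle):
        g = graph_for(small_bundle, "mosaic", 7)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        values_k = [
            eg.design_vaccine(g, eg.DesignConfig(n_tours=1, k=k), *args).objective_value
            for k in (1, 2, 3)
        ]
        assert values_k == sorted(values_k)
        values_h = [
            eg.design_vaccine(
                g, eg.DesignConfig(n_tours=1, k=3, h=h), *args
            ).objective_value
            for h in (12.0, 20.0, 30.0)
        ]
        assert values_h == sorted(values_h)

    def test_mosaic_tour_weight_bounded_by_h(self, small_bundle):
        g = graph_for(small_bundle, "mosaic", 7)
        cfg = eg.DesignConfig(n_tours=1, k=4, h=20.0)
        sol = eg.design_vaccine(
            g, cfg, small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"]
        )
        assert sol.tour_weights[0] <= 20.0 + 1e-9
        assembled = eg.assemble_polypeptide(sol.tours[0], "mosaic")
        assert len(assembled) == pytest.approx(sol.tour_weights[0])

    def test_cocktail_joint_coverage(self):
        """Four tours jointly reach a pathogen-coverage floor no single tour can."""
        eps = [r * 9 for r in "ACDEFGHI"]
        incidence = np.eye(8, dtype=bool)  # epitope i occurs only in pathogen i
        catalog, matrix, alleles = make_toy_instance(
            eps, [1.0] * 8, incidence=incidence
        )
        g = eg.build_design_graph(catalog.epitopes, "mixture")
        cfg = eg.DesignConfig(n_tours=4, k=2, min_pathogen_cover=8)
        sol = eg.design_vaccine(g, cfg, matrix, alleles, catalog)
        assert eg.validate_solution(sol, g, cfg, matrix, alleles, catalog) == []
        # jointly all 8 pathogens are covered, but each tour alone misses the floor
        for tour in sol.tours:
            single = eg.VaccineSolution(
                tours=[tour],
                tour_weights=[g.tour_weight(tour)],
                objective_value=0.0,
                status="optimal",
                immunogenicity=0.0,
                theta_s=np.zeros(8, dtype=bool),
                theta_a=np.zeros(1, dtype=bool),
            )
            assert "C7b" in eg.validate_solution(
                single, g, cfg, matrix, alleles, catalog
            )


class TestValidateSolution:
    def hand_solution(self, tours, g):
        return eg.VaccineSolution(
            tours=[tuple(t) for t in tours],
            tour_weights=[g.tour_weight(t) for t in tours],
            objective_value=0.0,
            status="optimal",
            immunogenicity=0.0,
            theta_s=np.zeros(1, dtype=bool),
            theta_a=np.zeros(1, dtype=bool),
        )

    def test_optimal_solution_has_no_violations(self, small_bundle):
        g = graph_for(small_bundle, "string_of_beads", 6)
        cfg = eg.DesignConfig(n_tours=2, k=2)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        sol = eg.design_vaccine(g, cfg, *args)
        assert eg.validate_solution(sol, g, cfg, *args) == []

    def test_repeated_epitope_across_tours_violates_C3(self, small_bundle):
        g = graph_for(small_bundle, "mixture", 4)
        cfg = eg.DesignConfig(n_tours=2, k=2)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        ep = g.epitopes[0]
        sol = self.hand_solution([[ep], [ep]], g)
        assert eg.validate_solution(sol, g, cfg, *args) == ["C3"]

    def test_overweight_tour_violates_C5(self, small_bundle):
        g = graph_for(small_bundle, "mosaic", 4)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        tour = list(g.epitopes[:2])
        cfg = eg.DesignConfig(n_tours=1, k=3, h=g.tour_weight(tour) - 1.0)
        sol = self.hand_solution([tour], g)
        assert eg.validate_solution(sol, g, cfg, *args) == ["C5"]

    def test_oversized_tour_violates_C6(self, small_bundle):
        g = graph_for(small_bundle, "mixture", 4)
        cfg = eg.DesignConfig(n_tours=1, k=1)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        sol = self.hand_solution([list(g.epitopes[:3])], g)
        assert eg.validate_solution(sol, g, cfg, *args) == ["C6"]

    def test_coverage_floors_violations(self):
        eps = [r * 9 for r in "ACDE"]
        incidence = np.eye(4, dtype=bool)
        catalog, matrix, alleles = make_toy_instance(eps, [1.0] * 4, incidence=incidence)
        g = eg.build_design_graph(catalog.epitopes, "mixture")
        sol = eg.VaccineSolution(
            tours=[(catalog.epitopes[0],)],
            tour_weights=[0.0],
            objective_value=0.0,
            status="optimal",
            immunogenicity=0.0,
            theta_s=np.zeros(4, dtype=bool),
            theta_a=np.zeros(1, dtype=bool),
        )
        cfg = eg.DesignConfig(n_tours=1, k=2, min_pathogen_cover=3)
        assert eg.validate_solution(sol, g, cfg, matrix, alleles, catalog) == ["C7b"]
        cfg = eg.DesignConfig(n_tours=1, k=2, min_allele_cover=1)
        assert eg.validate_solution(sol, g, cfg, matrix, alleles, catalog) == ["C8b"]

    def test_low_conservation_violates_C9(self):
        eps = [r * 9 for r in "ACDE"]
        incidence = np.zeros((4, 4), dtype=bool)
        incidence[:, 0] = True  # every epitope conserved in 1 of 4 pathogens
        catalog, matrix, alleles = make_toy_instance(eps, [1.0] * 4, incidence=incidence)
        g = eg.build_design_graph(catalog.epitopes, "mixture")
        cfg = eg.DesignConfig(n_tours=1, k=2, gamma=0.5)
        sol = eg.VaccineSolution(
            tours=[(catalog.epitopes[0],)],
            tour_weights=[0.0],
            objective_value=0.0,
            status="optimal",
            immunogenicity=0.0,
            theta_s=np.zeros(4, dtype=bool),
            theta_a=np.zeros(1, dtype=bool),
        )
        assert eg.validate_solution(sol, g, cfg, matrix, alleles, catalog) == ["C9"]


class TestAssemblePolypeptide:
    def test_string_of_beads_concatenates(self):
        out = eg.assemble_polypeptide(["ACDEFGHIK", "KLMNPQRST"], "string_of_beads")
        assert out == "ACDEFGHIKKLMNPQRST"
        assert len(out) == 18

    def test_mosaic_merges_at_overlap(self):
        out = eg.assemble_polypeptide(["ACDEFGHIK", "EFGHIKLMN"], "mosaic")
        assert out == "ACDEFGHIKLMN"
        assert len(out) == 12

    def test_empty_tour(self):
        assert eg.assemble_polypeptide([], "mosaic") == ""

    def test_every_epitope_is_substring_of_mosaic(self, small_bundle):
        eps = list(small_bundle["catalog"].epitopes[:6])
        out = eg.assemble_polypeptide(eps, "mosaic")
        assert all(ep in out for ep in eps)


class TestBruteForce:
    def test_guard_limits(self, small_bundle):
        g = graph_for(small_bundle, "mixture", 6)
        args = (small_bundle["matrix"], small_bundle["alleles"], small_bundle["catalog"])
        with pytest.raises(ValueError, match="brute force limited"):
            eg.brute_force_design(g, eg.DesignConfig(n_tours=3, k=2), *args)

    def test_infeasible_matches_ilp(self):
        catalog, matrix, alleles = make_toy_instance(["AAAAAAAAA"], [1.0])
        g = eg.build_design_graph(catalog.epitopes, "mixture")
        cfg = eg.DesignConfig(n_tours=1, k=1, min_allele_cover=1)
        with pytest.raises(eg.InfeasibleDesignError):
            eg.brute_force_design(g, cfg, matrix, alleles, catalog)
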