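import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rarefam.pedigree import (
    Individual,
    Pedigree,
    PedigreeError,
    build_relatedness_graph,
    construct_pseudocases,
    construct_pseudocontrols,
    contributing_sample_size,
    kinship_coefficient,
    read_ped,
    select_unrelated,
    write_ped,
)
from conftest import gene_drop_kinship, random_three_generation_pedigree


class TestKinship:
    def test_textbook_values(self, nuclear_family, half_sib_family, three_generations):
        assert kinship_coefficient(nuclear_family, "dad", "sib1") == 0.25
        assert kinship_coefficient(nuclear_family, "dad", "dad") == 0.5
        assert kinship_coefficient(nuclear_family, "sib1", "sib2") == 0.25
        assert kinship_coefficient(half_sib_family, "h1", "h2") == 0.125
        assert kinship_coefficient(three_generations, "gpa", "kid") == 0.125
        assert kinship_coefficient(three_generations, "gma", "mom") == 0.0

    def test_symmetry(self, three_generations):
        for a, b in [("gpa", "kid"), ("dad", "kid"), ("mom", "gpa")]:
            assert kinship_coefficient(three_generations, a, b) == kinship_coefficient(
                three_generations, b, a
            )

    def test_unknown_id_raises(self, trio):
        with pytest.raises(KeyError):
            kinship_coefficient(trio, "dad", "nobody")

    def test_sibling_values_match_gene_dropping_oracle(self, nuclear_family, half_sib_family):
        # >= 1e6 gene drops: Monte Carlo SE ~ 2e-4 on these coefficients
        full = gene_drop_kinship(nuclear_family, "sib1", "sib2", n_drops=1_000_000, seed=1)
        half = gene_drop_kinship(half_sib_family, "h1", "h2", n_drops=1_000_000, seed=2)
        assert full == pytest.approx(0.25, abs=2e-3)
        assert half == pytest.approx(0.125, abs=2e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_pedigrees_match_oracle(self, seed):
        ped = random_three_generation_pedigree(seed)
        rng = np.random.default_rng(seed + 100)
        ids = list(ped.members)
        n_drops = 100_000
        for _ in range(3):
            a, b = rng.choice(ids, 2, replace=False)
            phi = kinship_coefficient(ped, a, b)
            mc = gene_drop_kinship(ped, a, b, n_drops=n_drops, seed=seed)
            # 5 sigma of a Bernoulli mean at the observed rate
            tol = 5 * math.sqrt(max(phi * (1 - phi), 1e-4) / n_drops) + 1e-9
            assert mc == pytest.approx(phi, abs=max(tol, 0.004))


class TestPedigreeStructure:
    def test_missing_parent_raises(self):
        with pytest.raises(PedigreeError):
            Pedigree("f", [Individual("c", "f", father_id="ghost")])

    def test_father_must_be_male(self):
        with pytest.raises(PedigreeError):
            Pedigree(
                "f",
                [
                    Individual("p", "f", sex="female"),
                    Individual("c", "f", father_id="p"),
                ],
            )

    def test_cyclic_links_raise(self):
        with pytest.raises(PedigreeError):
            Pedigree(
                "f",
                [
                    Individual("a", "f", father_id="b", sex="male"),
                    Individual("b", "f", father_id="a", sex="male"),
                ],
            )

    def test_ped_round_trip(self, tmp_path, nuclear_family):
        nuclear_family["sib2"].twin_group = "tw1"
        nuclear_family["sib2"].cognitive_impairment = True
        path = tmp_path / "fam.ped"
        write_ped([nuclear_family], path)
        (back,) = read_ped(path)
        assert set(back.members) == set(nuclear_family.members)
        assert back["sib1"].affected and not back["sib2"].affected
        assert back["sib2"].twin_group == "tw1"
        assert back["sib2"].cognitive_impairment is True
        assert back["dad"].sex == "male"


class TestRelatednessGraph:
    def test_trio_has_two_parent_child_edges(self, trio):
        g = build_relatedness_graph([trio])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        assert not g.has_edge("dad", "mom")  # spouses are unrelated

    def test_inferred_threshold(self):
        singles = [
            Pedigree("s1", [Individual("a", "s1")]),
            Pedigree("s2", [Individual("b", "s2")]),
        ]
        low = pd.DataFrame({"id1": ["a"], "id2": ["b"], "kinship": [0.05]})
        high = pd.DataFrame({"id1": ["a"], "id2": ["b"], "kinship": [0.12]})
        assert build_relatedness_graph(singles, low).number_of_edges() == 0
        g = build_relatedness_graph(singles, high)
        assert g.number_of_edges() == 1
        assert g.edges["a", "b"]["source"] == "inferred_kinship"

    def test_x_mode_drops_father_son(self):
        ped = Pedigree(
            "f",
            [
                Individual("dad", "f", sex="male"),
                Individual("mom", "f", sex="female"),
                Individual("son", "f", father_id="dad", mother_id="mom", sex="male"),
            ],
        )
        g = build_relatedness_graph([ped], x_mode=True)
        assert not g.has_edge("dad", "son")
        assert g.has_edge("mom", "son")


class TestSelectUnrelated:
    def test_one_per_component(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
        assert len(select_unrelated(g)) == 1

    def test_isolated_nodes_all_selected(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("c")
        assert select_unrelated(g) == {"a", "c"}
        g2 = nx.Graph()
        g2.add_nodes_from("abcdef")
        assert select_unrelated(g2) == set("abcdef")

    def test_affected_preferred_and_deterministic(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "z")])
        assert select_unrelated(g, affected_ids={"z"}) == {"z"}
        assert select_unrelated(g) == {"a"}

    def test_output_is_independent_set(self, nuclear_family, half_sib_family):
        g = build_relatedness_graph([nuclear_family, half_sib_family])
        chosen = select_unrelated(g)
        assert all(not g.has_edge(a, b) for a in chosen for b in chosen if a != b)
        assert len(chosen) == nx.number_connected_components(g)


class TestContributingSampleSize:
    def test_both_parents(self, trio):
        assert contributing_sample_size(trio, "kid").weight == 0.5

    def test_duo(self):
        ped = Pedigree(
            "d",
            [
                Individual("mom", "d", sex="female"),
                Individual("kid", "d", mother_id="mom", affected=True),
            ],
        )
        assert contributing_sample_size(ped, "kid").weight == 0.75

    def test_no_sequenced_ancestors(self):
        ped = Pedigree("s", [Individual("kid", "s", affected=True)])
        assert contributing_sample_size(ped, "kid").weight == 1.0

    def test_excluded_parent_replaced_by_grandparent(self, three_generations):
        # father affected -> search ascends to his unaffected parents
        three_generations["dad"].affected = True
        cw = contributing_sample_size(three_generations, "kid")
        assert set(cw.ancestors) == {"gpa", "gma", "mom"}
        assert cw.weight == pytest.approx(1 - (0.125 + 0.125 + 0.25))

    def test_unaffected_case_rejected(self, trio):
        with pytest.raises(ValueError):
            contributing_sample_size(trio, "dad")


class TestPseudoSamples:
    def _family(self, i, transmitted: bool, parent_affected: bool = False):
        fid = f"f{i}"
        return Pedigree(
            fid,
            [
                Individual(f"{fid}_F", fid, sex="male", affected=parent_affected),
                Individual(f"{fid}_M", fid, sex="female"),
                Individual(
                    f"{fid}_C", fid, father_id=f"{fid}_F", mother_id=f"{fid}_M", affected=True
                ),
            ],
        )

    def test_untransmitted_allele_counted(self, variant_table):
        peds = [self._family(0, False), self._family(1, True)]
        rows = [
            # fam 0: father carries, child does not -> untransmitted
            ("f0_F", "f0", "G1", "lof", "a1", 1e-6, True, 1.0, "inherited", "autosomal"),
            # fam 1: mother carries and transmits -> not a pseudocontrol allele
            ("f1_M", "f1", "G1", "lof", "a2", 1e-6, True, 1.0, "inherited", "autosomal"),
            ("f1_C", "f1", "G1", "lof", "a2", 1e-6, True, 1.0, "inherited", "autosomal"),
        ]
        counts, n_eff = construct_pseudocontrols(peds, variant_table(rows))
        assert counts["G1"] == 1.0
        assert n_eff == 0.5 * 4  # 4 eligible parents

    def test_affected_parent_contributes_nothing(self, variant_table):
        peds = [self._family(0, False, parent_affected=True)]
        rows = [("f0_F", "f0", "G1", "lof", "a1", 1e-6, True, 1.0, "inherited", "autosomal")]
        counts, n_eff = construct_pseudocontrols(peds, variant_table(rows))
        assert len(counts) == 0
        assert n_eff == 0.5 * 1  # only the mother remains eligible

    def test_pseudocase_exclusions_and_weights(self, variant_table):
        duo = Pedigree(
            "d",
            [
                Individual("mom", "d", sex="female"),
                Individual("kid", "d", mother_id="mom", affected=True),
            ],
        )
        rows = [
            ("mom", "d", "G1", "lof", "shared", 1e-6, True, 1.0, "inherited", "autosomal"),
            ("kid", "d", "G1", "lof", "shared", 1e-6, True, 1.0, "inherited", "autosomal"),
            ("kid", "d", "G2", "lof", "paternal", 1e-6, True, 1.0, "unknown", "autosomal"),
            ("kid", "d", "G3", "lof", "newmut", 1e-6, True, 1.0, "denovo", "autosomal"),
        ]
        counts, n_eff = construct_pseudocases([duo], variant_table(rows), dnv_alleles={"newmut"})
        assert "G1" not in counts  # seen in the sampled unaffected mother
        assert "G3" not in counts  # de novo removed
        assert counts["G2"] == pytest.approx(0.75)
        assert n_eff == pytest.approx(0.75)

    def test_pseudocase_disjoint_from_ancestor_alleles(self, variant_table):
        """No allele present in a sampled unaffected ancestor reaches pseudocases."""
        rng = np.random.default_rng(0)
        peds, rows = [], []
        for i in range(30):
            ped = self._family(i, False)
            peds.append(ped)
            for g in ("G1", "G2"):
                if rng.random() < 0.5:
                    carrier = f"f{i}_F" if rng.random() < 0.5 else f"f{i}_M"
                    allele = f"{g}:{carrier}"
                    rows.append((carrier, f"f{i}", g, "lof", allele, 1e-6, True, 1.0, "inherited", "autosomal"))
                    if rng.random() < 0.5:
                        rows.append((f"f{i}_C", f"f{i}", g, "lof", allele, 1e-6, True, 1.0, "inherited", "autosomal"))
        variants = variant_table(rows)
        counts, _ = construct_pseudocases(peds, variants)
        # every child allele here is parental, so pseudocases must be empty
        assert counts.sum() == 0
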