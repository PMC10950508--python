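"""CTET vectors, Russell-Rao similarity, DDI calling, regimens and networks."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from pgxddi import synthetic_data
from pgxddi.catalog_io import DrugGeneCatalog, Regimen
from pgxddi.ddi_model import (
    CTETVector,
    build_drug_gene_network,
    build_universe,
    build_vector,
    count_regimen_ddis,
    detect_ddis,
    eliminate_zero_vectors,
    russell_rao,
)


def cat(*entries) -> DrugGeneCatalog:
    return DrugGeneCatalog(entries=frozenset(entries))


class TestUniverseAndVectors:
    def test_role_universe_is_union(self):
        c = cat(("a", "enzyme", "CYP3A4"), ("b", "enzyme", "CYP3A4"), ("b", "enzyme", "CYP2C9"))
        u = build_universe(c, ["a", "b"], "enzyme")
        assert u.elements == ("CYP2C9", "CYP3A4")
        assert u.d == 2

    def test_hybrid_keyed_by_role_gene(self):
        c = cat(("a", "enzyme", "G"), ("a", "target", "G"))
        u = build_universe(c, ["a"], "hybrid")
        assert u.elements == (("enzyme", "G"), ("target", "G"))

    def test_hybrid_gene_keying_collapses_roles(self):
        c = cat(("a", "enzyme", "G"), ("a", "target", "G"))
        u = build_universe(c, ["a"], "hybrid", hybrid_keying="gene")
        assert u.elements == ("G",)

    def test_drug_order_irrelevant(self):
        c = cat(("a", "enzyme", "X"), ("b", "carrier", "Y"))
        assert build_universe(c, ["a", "b"], "hybrid") == build_universe(c, ["b", "a"], "hybrid")

    def test_vector_bits_and_popcount(self):
        c = cat(("a", "enzyme", "X"), ("b", "enzyme", "Y"))
        u = build_universe(c, ["a", "b"], "enzyme")
        v = build_vector("a", u, c)
        assert v.bits == (1, 0)
        assert v.popcount == 1

    def test_zero_and_full_vectors(self):
        c = cat(("a", "enzyme", "X"), ("a", "enzyme", "Y"))
        u = build_universe(c, ["a", "b"], "enzyme")
        assert build_vector("b", u, c).popcount == 0
        assert build_vector("a", u, c).bits == (1, 1)


class TestRussellRao:
    def test_single_match_over_d4(self):
        assert russell_rao([1, 0, 1, 0], [1, 1, 0, 0]) == 0.25

    def test_all_ones(self):
        assert russell_rao([1] * 6, [1] * 6) == 1.0

    def test_disjoint_supports(self):
        assert russell_rao([1, 0], [0, 1]) == 0.0

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            d = rng.integers(1, 30)
            x, y = rng.integers(0, 2, d), rng.integers(0, 2, d)
            s = russell_rao(x.tolist(), y.tolist())
            assert s == russell_rao(y.tolist(), x.tolist())
            assert 0.0 <= s <= 1.0

    def test_self_similarity_is_density(self):
        v = CTETVector("a", "hybrid", (1, 0, 1, 1, 0))
        assert russell_rao(v, v) == v.popcount / 5

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            russell_rao([1, 0], [1, 0, 1])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            russell_rao([], [])


class TestZeroVectorElimination:
    def test_split(self):
        vs = [CTETVector("a", "hybrid", (1, 0)), CTETVector("b", "hybrid", (0, 0)),
              CTETVector("c", "hybrid", (1, 1))]
        kept, dropped = eliminate_zero_vectors(vs)
        assert [v.drug for v in kept] == ["a", "c"]
        assert dropped == ["b"]

    def test_all_zero_downstream_empty(self):
        c = cat()
        results, dropped = detect_ddis(["a", "b"], c)
        assert results == [] and set(dropped) == {"a", "b"}


class TestDetectDdis:
    def test_planted_single_pair(self):
        c = cat(("a", "enzyme", "G"), ("b", "enzyme", "G"), ("c", "target", "H"))
        results, _ = detect_ddis(["a", "b", "c"], c)
        flagged = {frozenset((r.drug_a, r.drug_b)) for r in results if r.is_ddi}
        assert flagged == {frozenset(("a", "b"))}

    def test_role_mismatch_is_not_a_match_under_role_gene_keying(self):
        c = cat(("a", "enzyme", "G"), ("b", "target", "G"))
        results, _ = detect_ddis(["a", "b"], c)
        (r,) = results
        assert r.similarity == 0.0 and not r.is_ddi

    def test_role_mismatch_matches_under_gene_keying(self):
        c = cat(("a", "enzyme", "G"), ("b", "target", "G"))
        (r,), _ = detect_ddis(["a", "b"], c, hybrid_keying="gene")
        assert r.is_ddi

    def test_hybrid_matches_decompose_over_roles(self):
        rng = np.random.default_rng(3)
        for seed in range(10):
            catalog, _ = synthetic_data.simulate_ctet_catalog(
                5, 8, 0.3, [], seed=seed
            )
            names = [f"drug{i + 1:02d}" for i in range(5)]
            results, _ = detect_ddis(names, catalog)
            for r in results:
                role_matches = sum(
                    len(catalog.genes_for(r.drug_a, role) & catalog.genes_for(r.drug_b, role))
                    for role in ("carrier", "transporter", "enzyme", "target")
                )
                assert r.positive_matches == role_matches

    def test_ddi_flag_matches_brute_force_intersection_oracle(self):
        for seed in range(30):
            catalog, truth = synthetic_data.simulate_ctet_catalog(
                8, 12, 0.15, [("drug01", "drug05")], seed=seed
            )
            names = [f"drug{i + 1:02d}" for i in range(8)]
            results, _ = detect_ddis(names, catalog)
            flagged = {frozenset((r.drug_a, r.drug_b)) for r in results if r.is_ddi}
            assert flagged == truth.true_ddi_pairs

    def test_adding_unrelated_drugs_never_flips_the_flag(self):
        c = cat(("a", "enzyme", "G"), ("b", "enzyme", "G"), ("b", "target", "T"),
                ("x", "carrier", "C1"), ("y", "transporter", "T9"))
        small, _ = detect_ddis(["a", "b"], c)
        big, _ = detect_ddis(["a", "b", "x", "y"], c)
        flag_small = {frozenset((r.drug_a, r.drug_b)): r.is_ddi for r in small}
        for r in big:
            key = frozenset((r.drug_a, r.drug_b))
            if key in flag_small:
                assert r.is_ddi == flag_small[key]
        # but d grows, so S shrinks for the shared pair
        s_small = [r.similarity for r in small][0]
        s_big = [r.similarity for r in big
                 if frozenset((r.drug_a, r.drug_b)) == frozenset(("a", "b"))][0]
        assert s_big < s_small

    def test_similarity_increases_with_added_shared_elements(self):
        base = [("a", "enzyme", "G1"), ("b", "enzyme", "G1"),
                ("a", "enzyme", "G2"), ("b", "target", "G3")]
        c1 = cat(*base)
        c2 = cat(*base, ("a", "target", "G3"))  # one more shared element
        (r1,), _ = detect_ddis(["a", "b"], c1)
        (r2,), _ = detect_ddis(["a", "b"], c2)
        assert r2.positive_matches == r1.positive_matches + 1
        assert r2.similarity > r1.similarity


class TestRegimenCounting:
    def test_within_cross_union(self):
        c = cat(("A", "enzyme", "G1"), ("B", "enzyme", "G1"),   # (A,B)
                ("C", "target", "G2"), ("D", "target", "G2"),   # (C,D)
                ("A", "carrier", "G3"), ("C", "carrier", "G3"))  # (A,C)
        r = count_regimen_ddis(Regimen("r1", ("A", "B")), Regimen("r2", ("C", "D")), c)
        assert (r.within_a, r.within_b, r.cross, r.union_count) == (1, 1, 1, 3)

    def test_regimen_vs_itself(self):
        c = cat(("A", "enzyme", "G"), ("B", "enzyme", "G"))
        reg = Regimen("r", ("A", "B"))
        r = count_regimen_ddis(reg, reg, c)
        assert r.cross == 0 and r.union_count == r.within_a

    def test_single_regimen(self):
        c = cat(("A", "enzyme", "G"), ("B", "enzyme", "G"), ("C", "target", "H"))
        r = count_regimen_ddis(Regimen("r", ("A", "B", "C")), None, c)
        assert r.union_count == r.within_a == 1

    def test_counts_match_brute_force_scan_on_planted_catalogs(self):
        for seed in range(25):
            catalog, truth = synthetic_data.simulate_ctet_catalog(
                10, 15, 0.12, [("drug01", "drug06"), ("drug03", "drug09")], seed=seed
            )
            names = [f"drug{i + 1:02d}" for i in range(10)]
            ra = Regimen("a", tuple(names[:5]))
            rb = Regimen("b", tuple(names[5:]))
            r = count_regimen_ddis(ra, rb, catalog)
            wa = sum(1 for p in truth.true_ddi_pairs if p <= set(ra.drugs))
            wb = sum(1 for p in truth.true_ddi_pairs if p <= set(rb.drugs))
            assert r.union_count == len(truth.true_ddi_pairs)
            assert (r.within_a, r.within_b) == (wa, wb)
            assert r.union_count == r.within_a + r.within_b + r.cross

    def test_empty_union_after_elimination(self):
        c = cat()
        r = count_regimen_ddis(Regimen("r", ("A", "B")), None, c)
        assert r.union_count == 0 and r.n_drugs_after_elimination == 0


class TestNetwork:
    def test_degrees(self):
        c = cat(("a", "enzyme", "G"), ("b", "enzyme", "G"), ("c", "target", "G"),
                ("a", "carrier", "H1"), ("a", "target", "H2"), ("a", "enzyme", "H3"))
        g, degrees = build_drug_gene_network(c, ["a", "b", "c"])
        table = degrees.set_index("name")["degree"]
        assert table["G"] == 3    # three drugs share gene G
        assert table["a"] == 4    # drug a touches 4 distinct genes

    def test_edge_count_is_unique_drug_gene_pairs(self):
        c = cat(("a", "enzyme", "G"), ("a", "target", "G"), ("b", "carrier", "H"))
        g, _ = build_drug_gene_network(c, ["a", "b"])
        assert g.number_of_edges() == 2  # (a,G) collapsed across roles, (b,H)
        assert g.edges[("a", "G")]["roles"] == "enzyme;target"

    def test_degrees_match_independent_recount(self):
        for seed in range(10):
            catalog, _ = synthetic_data.simulate_ctet_catalog(6, 10, 0.25, [], seed=seed)
            names = [f"drug{i + 1:02d}" for i in range(6)]
            _, degrees = build_drug_gene_network(catalog, names)
            pairs = {(d, g) for (d, _, g) in catalog.entries}
            for row in degrees.itertuples(index=False):
                if row.kind == "gene":
                    assert row.degree == sum(1 for d, g in pairs if g == row.name)
                else:
                    assert row.degree == sum(1 for d, g in pairs if d == row.name)
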