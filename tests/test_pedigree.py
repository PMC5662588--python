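"""Pedigree parsing, cleaning, relation classification and A matrices."""

import numpy as np
import pytest

from pedherit.errors import ParseError, ValidationError
from pedherit.pedigree import (
    Pedigree,
    RelationClass,
    build_A_inverse,
    build_relationship_structure,
    classify_relation,
    clean_pedigree,
    founderize_adoptees,
    kinship,
    kinship_matrix,
    prune_noninformative,
    read_pedigree,
    relatedness_coefficient,
    remove_loops,
    truncate_generations,
    write_pedigree,
)
from pedherit.simulate import preset, simulate_pedigree

from conftest import make_pedigree


# ---------------------------------------------------------------------- I/O


class TestReadPedigree:
    def test_minimal_trio(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("C1,F1,M1\nF1,0,0\nM1,0,0\n")
        ped = read_pedigree(p)
        assert len(ped) == 3
        assert ped["C1"].parents() == ("F1", "M1")
        assert ped["F1"].parents() == (None, None)

    def test_self_parentage_rejected(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("X,X,0\n")
        with pytest.raises(ValidationError, match="own parent"):
            read_pedigree(p)

    def test_duplicate_ids_listed(self, tmp_path):
        rows = [f"I{k},0,0" for k in range(12)] + ["I3,0,0", "I7,0,0"]
        p = tmp_path / "ped.csv"
        p.write_text("\n".join(rows) + "\n")
        with pytest.raises(ValidationError) as err:
            read_pedigree(p)
        assert "I3" in str(err.value) and "I7" in str(err.value)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("A,0,0\nB,0\n")
        with pytest.raises(ParseError, match=":2"):
            read_pedigree(p)

    def test_unknown_tokens_and_tabs(self, tmp_path):
        p = tmp_path / "ped.tsv"
        p.write_text("C1\tF1\tNA\nF1\t\t0\n")
        ped = read_pedigree(p)
        assert ped["C1"].parents() == ("F1", None)

    def test_round_trip(self, tmp_path, full_cousins):
        path = tmp_path / "out.tsv"
        write_pedigree(full_cousins, path)
        back = read_pedigree(path)
        assert set(back.ids) == set(full_cousins.ids)
        for ind in full_cousins:
            assert back[ind.id].parents() == ind.parents()

    def test_referenced_parents_become_founders(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("C1,F1,M1\n")
        ped = read_pedigree(p)
        assert len(ped) == 3 and ped["F1"].parents() == (None, None)


# ----------------------------------------------------------------- cleaning


class TestFounderize:
    def test_noop_without_adoptees(self, trio):
        out, n = founderize_adoptees(trio)
        assert n == 0
        assert out["C1"].parents() == ("F1", "M1")

    def test_adoptee_loses_parents(self):
        ped = make_pedigree(
            [("F", None, None), ("M", None, None), ("A", "F", "M", True)]
        )
        out, n = founderize_adoptees(ped)
        assert n == 1
        assert out["A"].parents() == (None, None)
        assert out["A"].adopted


class TestRemoveLoops:
    def test_acyclic_unchanged(self, full_cousins):
        out, removed = remove_loops(full_cousins)
        assert removed == []
        assert set(out.ids) == set(full_cousins.ids)

    def test_two_cycle_removed(self):
        ped = make_pedigree(
            [("A", "B", None), ("B", "A", None), ("C", "A", None)]
        )
        out, removed = remove_loops(ped)
        assert removed == ["A", "B"]
        assert out["C"].parents() == (None, None)

    def test_no_individual_is_own_ancestor_after_cleaning(self):
        cfg = preset("tiny", n_loops=7, seed=3)
        ped, truth = simulate_pedigree(cfg)
        cleaned, removed = remove_loops(ped)
        assert removed == truth.loop_members
        # independent oracle: exhaustive ancestor walk on the cleaned graph
        for ind in cleaned:
            stack, seen = list(ind.known_parents()), set()
            while stack:
                p = stack.pop()
                if p in seen or p not in cleaned:
                    continue
                seen.add(p)
                stack.extend(cleaned[p].known_parents())
            assert ind.id not in seen

    def test_idempotent(self):
        ped, _ = simulate_pedigree(preset("tiny", n_loops=3, seed=4))
        once, removed1 = remove_loops(ped)
        twice, removed2 = remove_loops(once)
        assert removed2 == []
        assert set(twice.ids) == set(once.ids)


class TestTruncateGenerations:
    def chain(self):
        return make_pedigree(
            [("GGP", None, None), ("GP", "GGP", None), ("P", "GP", None),
             ("C", "P", None)],
            phenotyped={"C"},
        )

    def test_great_grandparent_dropped_at_depth_2(self):
        out, removed = truncate_generations(self.chain(), depth=2)
        assert removed == ["GGP"]
        assert out["GP"].parents() == (None, None)

    def test_depth_beyond_height_is_noop(self):
        out, removed = truncate_generations(self.chain(), depth=5)
        assert removed == []

    def test_boundary_inclusive_for_shared_grandparents(self, full_cousins):
        out, removed = truncate_generations(full_cousins, depth=2)
        assert removed == []
        assert "GF" in out and "GM" in out

    def test_depth_zero_rejected(self, trio):
        with pytest.raises(ValidationError):
            truncate_generations(trio, depth=0)

    def test_deeper_then_shallower_equals_shallower(self):
        ped, _ = simulate_pedigree(preset("tiny", generations=4, seed=6))
        d2, _ = truncate_generations(ped, 2)
        d3_then_d2, _ = truncate_generations(truncate_generations(ped, 3)[0], 2)
        assert set(d2.ids) == set(d3_then_d2.ids)


class TestPrune:
    def test_branch_without_phenotype_removed(self):
        ped = make_pedigree(
            [("F", None, None), ("M", None, None), ("C", "F", "M"),
             ("U", None, None), ("X", "U", None)],  # U's line unphenotyped
            phenotyped={"C"},
        )
        out, removed = prune_noninformative(ped)
        assert set(removed) == {"U", "X"}

    def test_grandparent_with_phenotyped_grandchild_kept(self, full_cousins):
        out, removed = prune_noninformative(full_cousins)
        assert "GF" in out and removed == []

    def test_all_phenotyped_unchanged(self):
        ped = make_pedigree(
            [("A", None, None), ("B", "A", None)], phenotyped={"A", "B"}
        )
        out, removed = prune_noninformative(ped)
        assert removed == [] and len(out) == 2

    def test_fixpoint_cascades(self):
        # GGP -> GP(unphenotyped) chain: removing GP's childless sibling makes
        # nothing new removable, but removing leaf X makes U removable next pass
        ped = make_pedigree(
            [("U", None, None), ("X", "U", None), ("Y", "X", None),
             ("F", None, None), ("C", "F", None)],
            phenotyped={"C"},
        )
        out, removed = prune_noninformative(ped)
        assert set(removed) == {"U", "X", "Y"}
        assert set(out.ids) == {"F", "C"}


# ----------------------------------------------- classification and kinship


class TestClassifyRelation:
    def test_full_siblings(self, sibship3):
        assert classify_relation(sibship3, "S1", "S2") is RelationClass.FULL_SIBLING

    def test_half_siblings(self, half_sibs):
        assert classify_relation(half_sibs, "H1", "H2") is RelationClass.HALF_SIBLING

    def test_full_cousins(self, full_cousins):
        assert classify_relation(full_cousins, "C1", "C2") is RelationClass.FULL_COUSIN

    def test_half_cousins(self, half_cousins):
        assert classify_relation(half_cousins, "C1", "C2") is RelationClass.HALF_COUSIN

    def test_unrelated(self, trio, sibship3):
        ped = make_pedigree(
            [("A", None, None), ("B", None, None)], phenotyped={"A", "B"}
        )
        assert classify_relation(ped, "A", "B") is RelationClass.OTHER

    def test_symmetric(self, half_cousins):
        assert classify_relation(half_cousins, "C2", "C1") is RelationClass.HALF_COUSIN

    def test_same_id_rejected(self, trio):
        with pytest.raises(ValidationError):
            classify_relation(trio, "C1", "C1")


class TestKinship:
    def test_founder_self(self, trio):
        assert kinship(trio, "F1", "F1") == 0.5

    def test_parent_offspring(self, trio):
        assert kinship(trio, "F1", "C1") == 0.25

    def test_full_cousins(self, full_cousins):
        assert kinship(full_cousins, "C1", "C2") == 0.0625

    @pytest.mark.parametrize(
        "fixture,expected",
        [("sibship3", 0.5), ("half_sibs", 0.25),
         ("full_cousins", 0.125), ("half_cousins", 0.0625)],
    )
    def test_twice_kinship_matches_class_coefficient(self, fixture, expected, request):
        ped = request.getfixturevalue(fixture)
        ids = ped.phenotyped_ids()
        rc = classify_relation(ped, ids[0], ids[1])
        assert relatedness_coefficient(rc) == expected
        assert 2.0 * kinship(ped, ids[0], ids[1]) == expected

    def test_agrees_with_classification_on_simulated_census(self, oracle_sim):
        ped = oracle_sim.pedigree
        rel = build_relationship_structure(ped)
        ids = rel.ids
        A = rel.A.tocoo()
        # every classified pair matches twice the recursive kinship exactly
        cache = {}
        for i, j, v in zip(A.row, A.col, A.data):
            if i < j:
                assert 2.0 * kinship(ped, ids[i], ids[j], cache) == v
        # spot-check zeros: unclassified pairs have zero kinship too
        rng = np.random.default_rng(0)
        Ad = rel.A.todia() if False else rel.A
        for _ in range(300):
            i, j = rng.integers(0, len(ids), size=2)
            if i != j and Ad[i, j] == 0.0:
                assert kinship(ped, ids[i], ids[j], cache) == 0.0


class TestRelatednessCoefficient:
    def test_mapping(self):
        assert relatedness_coefficient(RelationClass.FULL_SIBLING) == 0.5
        assert relatedness_coefficient(RelationClass.HALF_SIBLING) == 0.25
        assert relatedness_coefficient(RelationClass.FULL_COUSIN) == 0.125
        assert relatedness_coefficient(RelationClass.HALF_COUSIN) == 0.0625
        assert relatedness_coefficient(RelationClass.OTHER) == 0.0


# ------------------------------------------------------ relationship matrix


class TestRelationshipStructure:
    def test_singletons_give_identity(self):
        ped = make_pedigree(
            [("A", None, None), ("B", None, None)], phenotyped={"A", "B"}
        )
        rel = build_relationship_structure(ped)
        assert np.allclose(rel.A.toarray(), np.eye(2))
        assert len(rel.families) == 2

    def test_sibship_block_is_positive_definite(self, sibship3):
        rel = build_relationship_structure(sibship3)
        B = rel.A.toarray()
        assert np.allclose(B, np.where(np.eye(3), 1.0, 0.5))
        assert np.linalg.eigvalsh(B).min() > 0

    def test_family_blocks_are_psd(self, tiny_sim):
        rel = build_relationship_structure(tiny_sim.pedigree)
        for B in rel.family_blocks():
            assert np.linalg.eigvalsh(B).min() >= -1e-10

    def test_entries_are_the_four_coefficients(self, tiny_sim):
        import scipy.sparse as sp

        rel = build_relationship_structure(tiny_sim.pedigree)
        off = (rel.A - sp.eye(rel.n)).tocoo()
        assert set(np.round(off.data, 10)) - {0.0} <= {0.5, 0.25, 0.125, 0.0625}

    def test_invariant_to_input_row_order(self, tiny_sim):
        ped = tiny_sim.pedigree
        rel1 = build_relationship_structure(ped)
        rng = np.random.default_rng(1)
        shuffled = list(ped)
        rng.shuffle(shuffled)
        rel2 = build_relationship_structure(Pedigree(shuffled))
        assert rel1.ids == rel2.ids
        assert (rel1.A != rel2.A).nnz == 0

    def test_no_phenotyped_is_an_error(self, tmp_path):
        ped = make_pedigree([("A", None, None)])
        with pytest.raises(ValidationError):
            build_relationship_structure(ped)

    def test_export_matrix_round_trip(self, sibship3, tmp_path):
        import scipy.io

        from pedherit.pedigree import export_matrix

        rel = build_relationship_structure(sibship3)
        mpath, ipath = tmp_path / "A.mtx", tmp_path / "A.ids"
        export_matrix(rel, mpath, ipath)
        back = scipy.io.mmread(mpath)
        assert np.allclose(back.toarray(), rel.A.toarray())
        assert ipath.read_text().split() == rel.ids


class TestAInverse:
    def test_single_founder(self):
        ped = make_pedigree([("A", None, None)], phenotyped={"A"})
        rel = build_A_inverse(ped)
        assert np.allclose(rel.A_inverse.toarray(), [[1.0]])

    def test_trio_matches_dense_inverse(self, trio):
        rel = build_A_inverse(trio)
        order = rel.A_inverse_ids
        A = kinship_matrix(trio, order)
        assert np.allclose(
            rel.A_inverse.toarray(), np.linalg.inv(A), atol=1e-10
        )

    def test_henderson_times_recursive_A_is_identity(self):
        ped, _ = simulate_pedigree(preset("tiny", n_families=18, seed=9))
        ped, _ = clean_pedigree(ped)
        assert 50 <= len(ped) <= 300
        rel = build_A_inverse(ped)
        A = kinship_matrix(ped, rel.A_inverse_ids)
        prod = rel.A_inverse.toarray() @ A
        assert np.abs(prod - np.eye(len(A))).max() < 1e-8


class TestCleanPipeline:
    def test_counts_reported(self):
        cfg = preset("tiny", adoption_rate=0.05, n_loops=2, seed=12)
        ped, truth = simulate_pedigree(cfg)
        cleaned, counts = clean_pedigree(ped)
        assert counts["adoptees_founderized"] == len(truth.adoptees)
        assert counts["loop_members_removed"] == len(truth.loop_members)
        assert counts["final_size"] == len(cleaned)
        # every phenotyped individual survives cleaning
        assert set(ped.phenotyped_ids()) == set(cleaned.phenotyped_ids())
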