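"""Pedigree parsing, repair, trimming and relationship machinery.

The dense tabular relationship matrix serves as the brute-force oracle
for the Meuwissen-Luo inbreeding traversal, Henderson's A-inverse rules
and the pedigree Cholesky factor; networkx provides an independent
ancestor-closure oracle for trimming.
"""

import io

import networkx as nx
import numpy as np
import pytest

from kennelquant.pedigree import (
    Pedigree,
    PedigreeRecord,
    build_a_inverse,
    cholesky_factor,
    compute_inbreeding,
    parse_pedigree,
    show_breeding_score,
    tabular_relationship,
    trim_to_phenotyped,
    validate_and_correct,
)

from conftest import make_pedigree, random_pedigree


class TestParsing:
    def test_minimal_three_row_file(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,sex,dob,colour,sbn,registration\n"
                     "A,,,male,2000-01-01,fawn,1,RKC\n"
                     "B,,,female,2000-05-01,blue,0,RKC\n"
                     "C,A,B,male,2002-01-01,fawn,0,RKC\n")
        ped = parse_pedigree(p, {"fawn": "BS", "blue": "NBS"})
        assert len(ped) == 3
        assert ped["A"].sire_id is None and ped["A"].dam_id is None
        assert ped["C"].sire_id == "A"
        assert ped["A"].colour_group == "BS" and ped["B"].colour_group == "NBS"
        assert ped["A"].has_sbn and not ped["B"].has_sbn

    def test_implicit_founder_gets_sex_from_role(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam\nA,X,\nB,,\nC,A,B\n")
        ped = parse_pedigree(p)
        assert len(ped) == 4
        assert ped["X"].sex == "male"
        assert ped["X"].sire_id is None

    def test_duplicate_id_raises_naming_the_id(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam\nA,,\nA,,\n")
        with pytest.raises(ValueError, match="A"):
            parse_pedigree(p)

    def test_unreadable_date_becomes_missing(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,dob\nA,,,not-a-date\n")
        ped = parse_pedigree(p)
        assert ped["A"].dob is None

    def test_unmapped_colour_is_unknown(self, tmp_path):
        p = tmp_path / "ped.csv"
        p.write_text("id,sire,dam,colour\nA,,,lilac\n")
        ped = parse_pedigree(p, {"fawn": "BS"})
        assert ped["A"].colour_group == "unknown"


class TestValidation:
    def test_chronology_nulls_parent_link(self):
        from datetime import date

        recs = [
            PedigreeRecord("S", None, None, "male", dob=date(2010, 1, 1)),
            PedigreeRecord("D", None, None, "female", dob=date(2000, 1, 1)),
            PedigreeRecord("O", "S", "D", "male", dob=date(2005, 1, 1)),
        ]
        ped, log = validate_and_correct(Pedigree(recs))
        assert ped["O"].sire_id is None and ped["O"].dam_id == "D"
        assert [(c.id, c.field, c.reason) for c in log] == [("O", "sire_id", "chronology")]

    def test_own_grandparent_cycle_is_broken(self):
        recs = [
            PedigreeRecord("A", "C", None),
            PedigreeRecord("B", "A", None),
            PedigreeRecord("C", "B", None),
        ]
        ped, log = validate_and_correct(Pedigree(recs))
        assert ped.is_ordered()
        assert any(c.reason == "cycle" for c in log)

    def test_sex_conflict_nulls_both_roles(self):
        recs = [
            PedigreeRecord("B", None, None),
            PedigreeRecord("D", None, None, "female"),
            PedigreeRecord("X", "B", "D"),
            PedigreeRecord("Y", None, "B"),
        ]
        ped, log = validate_and_correct(Pedigree(recs))
        assert ped["X"].sire_id is None and ped["Y"].dam_id is None
        assert {c.reason for c in log} == {"sex-conflict"}

    def test_self_parent_nulled(self):
        # constructed directly since the constructor itself accepts it
        recs = [PedigreeRecord("A", "A", None)]
        ped, log = validate_and_correct(Pedigree(recs))
        assert ped["A"].sire_id is None
        assert log[0].reason == "self-parent"

    @pytest.mark.parametrize("seed", range(5))
    def test_fixpoint_on_simulated_pedigrees(self, seed):
        ped = random_pedigree(seed)
        ped1, log1 = validate_and_correct(ped)
        assert log1 == []  # simulated pedigrees are already consistent
        ped2, log2 = validate_and_correct(ped1)
        assert log2 == []
        assert ped2.ids == ped1.ids


class TestTrim:
    def test_all_leaves_keeps_everything(self):
        ped = random_pedigree(1)
        sire, dam = ped._parent_positions()
        parents = set(sire[sire >= 0]) | set(dam[dam >= 0])
        leaves = [r.id for i, r in enumerate(ped.records) if i not in parents]
        trimmed = trim_to_phenotyped(ped, leaves)
        # closure of all leaves contains every ancestor but not parentless
        # non-leaf dogs without descendants in the leaf set
        oracle = _ancestor_closure(ped, leaves)
        assert set(trimmed.ids) == oracle

    def test_single_founder(self, trio):
        trimmed = trim_to_phenotyped(trio, ["S"])
        assert trimmed.ids == ["S"]

    def test_chain_ancestor_closure(self):
        rows = [("G0", None, None)] + [(f"G{i}", f"G{i-1}", None) for i in range(1, 5)]
        ped = make_pedigree(rows)
        trimmed = trim_to_phenotyped(ped, ["G2"])
        assert trimmed.ids == ["G0", "G1", "G2"]

    def test_unknown_id_errors(self, trio):
        with pytest.raises(ValueError, match="nope"):
            trim_to_phenotyped(trio, ["nope"])

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx_closure_and_is_idempotent(self, seed):
        ped = random_pedigree(seed, size=100)
        rng = np.random.default_rng(seed)
        ids = list(rng.choice(ped.ids, size=15, replace=False))
        trimmed = trim_to_phenotyped(ped, ids)
        assert set(trimmed.ids) == _ancestor_closure(ped, ids)
        again = trim_to_phenotyped(trimmed, ids)
        assert again.ids == trimmed.ids
        # monotone: a larger id set keeps a superset
        bigger = trim_to_phenotyped(ped, ids + list(rng.choice(ped.ids, size=5)))
        assert set(trimmed.ids) <= set(bigger.ids)


def _ancestor_closure(ped, ids):
    g = nx.DiGraph()
    g.add_nodes_from(ped.ids)
    for r in ped.records:
        for pid in (r.sire_id, r.dam_id):
            if pid is not None and pid in ped:
                g.add_edge(pid, r.id)
    out = set(ids)
    for i in ids:
        out |= nx.ancestors(g, i)
    return out


class TestInbreeding:
    def test_founders_zero(self, trio):
        ped = compute_inbreeding(trio)
        assert ped["S"].f == 0.0 and ped["O"].f == 0.0

    def test_full_sib_mating_quarter(self, fullsib_mating):
        ped = compute_inbreeding(fullsib_mating)
        assert ped["X"].f == pytest.approx(0.25, abs=1e-14)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_tabular_oracle(self, seed):
        ped = random_pedigree(seed, size=200)
        A = tabular_relationship(ped)
        f = ped.inbreeding
        assert np.max(np.abs(f - (np.diag(A) - 1.0))) < 1e-12
        # f equals half the parents' tabular relationship
        sire, dam = ped._parent_positions()
        for i in range(len(ped)):
            if sire[i] >= 0 and dam[i] >= 0:
                assert f[i] == pytest.approx(0.5 * A[sire[i], dam[i]], abs=1e-12)

    def test_unordered_pedigree_errors(self):
        ped = Pedigree([PedigreeRecord("O", "S", None), PedigreeRecord("S", None, None)])
        with pytest.raises(ValueError, match="ordered"):
            compute_inbreeding(ped)


class TestTabularRelationship:
    def test_unrelated_founders_identity(self):
        ped = make_pedigree([("A", None, None), ("B", None, None)])
        assert np.allclose(tabular_relationship(ped), np.eye(2))

    def test_parent_offspring_half(self):
        ped = make_pedigree([("A", None, None), ("O", "A", None)])
        A = tabular_relationship(ped)
        assert A[0, 1] == 0.5 and A[1, 1] == 1.0

    def test_full_sibs_half(self):
        ped = make_pedigree(
            [("S", None, None), ("D", None, None), ("X", "S", "D"), ("Y", "S", "D")]
        )
        A = tabular_relationship(ped)
        assert A[2, 3] == 0.5 and A[2, 2] == 1.0

    def test_size_cap(self):
        ped = random_pedigree(0, size=60)
        with pytest.raises(ValueError, match="cholesky_factor"):
            tabular_relationship(ped, max_n=10)


class TestAInverseAndCholesky:
    def test_single_founder(self):
        ped = compute_inbreeding(make_pedigree([("A", None, None)]))
        assert np.allclose(build_a_inverse(ped).toarray(), [[1.0]])

    def test_noninbred_trio_rules(self, trio):
        ped = compute_inbreeding(trio)
        Ai = build_a_inverse(ped).toarray()
        assert np.allclose(np.diag(Ai), [1.5, 1.5, 2.0])
        assert Ai[0, 2] == pytest.approx(-1.0) and Ai[1, 2] == pytest.approx(-1.0)
        assert Ai[0, 1] == pytest.approx(0.5)

    def test_founders_only_cholesky_identity(self):
        ped = compute_inbreeding(make_pedigree([("A", None, None), ("B", None, None)]))
        assert np.allclose(cholesky_factor(ped).toarray(), np.eye(2))

    def test_single_known_parent_diagonal(self):
        ped = compute_inbreeding(make_pedigree([("A", None, None), ("O", "A", None)]))
        L = cholesky_factor(ped).toarray()
        assert L[1, 1] == pytest.approx(np.sqrt(0.75))

    @pytest.mark.parametrize("seed", range(6))
    def test_inverse_and_factor_match_tabular(self, seed):
        ped = random_pedigree(seed, size=150)
        A = tabular_relationship(ped)
        Ai = build_a_inverse(ped).toarray()
        assert np.max(np.abs(Ai @ A - np.eye(len(ped)))) < 1e-8
        L = cholesky_factor(ped).toarray()
        assert np.max(np.abs(L @ L.T - A)) < 1e-10
        # lower-triangular with positive diagonal
        assert np.allclose(L, np.tril(L))
        assert np.all(np.diag(L) > 0)

    def test_missing_f_errors(self, trio):
        with pytest.raises(ValueError, match="inbreeding"):
            build_a_inverse(trio)


class TestShowBreeding:
    def _ped(self, parent_sbn, gp_sbn):
        recs = []
        for i in range(4):
            recs.append(PedigreeRecord(f"GP{i}", None, None, has_sbn=gp_sbn))
        recs.append(PedigreeRecord("S", "GP0", "GP1", "male", has_sbn=parent_sbn))
        recs.append(PedigreeRecord("D", "GP2", "GP3", "female", has_sbn=parent_sbn))
        recs.append(PedigreeRecord("X", "S", "D"))
        return Pedigree(recs)

    def test_all_ancestors_with_sbn_scores_eight(self):
        assert show_breeding_score(self._ped(True, True), "X") == 8

    def test_no_ancestor_with_sbn_scores_zero(self):
        assert show_breeding_score(self._ped(False, False), "X") == 0

    def test_parents_only(self):
        assert show_breeding_score(self._ped(True, False), "X") == 4

    def test_unknown_ancestors_count_as_no_sbn(self, trio):
        assert show_breeding_score(trio, "O") == 0

    def test_unknown_id_errors(self, trio):
        with pytest.raises(KeyError):
            show_breeding_score(trio, "nope")
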