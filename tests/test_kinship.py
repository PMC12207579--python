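"""Relationship-matrix tests, anchored on a gene-dropping Monte-Carlo oracle."""

import numpy as np
import pandas as pd
import pytest

from diallelgp import kinship
from diallelgp.kinship import (PedigreeError, RelationshipMatrix,
                               adjust_G_scale, build_A_tetraploid, build_G_vanraden,
                               build_H, genomic_inbreeding, pedigree_inbreeding,
                               sort_pedigree)
from diallelgp.simdiallel import gene_drop_relationships


def ped_frame(rows):
    return pd.DataFrame(rows, columns=["clone_id", "sire_id", "dam_id"])


@pytest.fixture(scope="module")
def nested_pedigree():
    """Founders, an F1 cross, a selfing, a backcross and a second cross."""
    return ped_frame([
        ("P", "0", "0"), ("Q", "0", "0"), ("R", "0", "0"),
        ("F1", "P", "Q"), ("F1b", "P", "Q"),
        ("S1", "F1", "F1"),
        ("BC", "F1", "P"),
        ("X", "F1", "R"), ("HS", "Q", "R"),
    ])


class TestTetraploidA:
    def test_unrelated_founders_identity(self):
        A = build_A_tetraploid(ped_frame([("a", "0", "0"), ("b", "0", "0")]))
        assert np.allclose(A.values, np.eye(2))

    def test_parent_offspring_half(self):
        ped = ped_frame([("P", "0", "0"), ("Q", "0", "0"), ("O", "P", "Q")])
        A = build_A_tetraploid(ped, 0.0)
        df = A.to_frame()
        assert df.loc["O", "P"] == pytest.approx(0.5)
        assert df.loc["O", "O"] == pytest.approx(1.0)

    @pytest.mark.parametrize("w", [0.0, 0.1])
    def test_matches_gene_dropping_oracle(self, nested_pedigree, w):
        A = build_A_tetraploid(nested_pedigree, w).to_frame()
        oracle = gene_drop_relationships(nested_pedigree, w,
                                         n_rep=100_000, seed=2024)
        assert np.abs(A.values - oracle.values).max() < 0.01

    def test_selfed_diagonal_increases_with_double_reduction(self):
        ped = ped_frame([("P", "0", "0"), ("S", "P", "P")])
        diags = [build_A_tetraploid(ped, w).to_frame().loc["S", "S"]
                 for w in (0.0, 0.05, 0.1, 0.2)]
        assert np.all(np.diff(diags) > 0)
        # w = 0 selfing: F = 1/6, diagonal 1.5
        assert diags[0] == pytest.approx(1.5)

    def test_cycle_detected(self):
        ped = ped_frame([("a", "b", "0"), ("b", "a", "0")])
        with pytest.raises(PedigreeError):
            build_A_tetraploid(ped)

    def test_invalid_double_reduction(self):
        with pytest.raises(ValueError):
            build_A_tetraploid(ped_frame([("a", "0", "0")]), 1.5)

    def test_unsorted_input_handled(self, nested_pedigree):
        shuffled = nested_pedigree.sample(frac=1, random_state=1)
        A1 = build_A_tetraploid(nested_pedigree).to_frame()
        A2 = build_A_tetraploid(shuffled).to_frame()
        ids = list(A1.index)
        assert np.allclose(A1.values, A2.loc[ids, ids].values)

    def test_implicit_founders_prepended(self):
        ped = ped_frame([("O", "P", "Q")])
        A = build_A_tetraploid(ped)
        assert set(A.ids) == {"P", "Q", "O"}


class TestInbreeding:
    def test_identity_diagonal_zero(self):
        A = RelationshipMatrix(np.eye(3), ["a", "b", "c"], "A")
        assert pedigree_inbreeding(A).coefficient == pytest.approx(0.0)

    def test_formula_forced_value(self):
        A = RelationshipMatrix(np.diag([1.0006, 1.0006]), ["a", "b"], "A")
        assert pedigree_inbreeding(A).coefficient == pytest.approx(0.0002)

    def test_full_sib_mating_matches_gene_dropping(self):
        ped = ped_frame([
            ("P", "0", "0"), ("Q", "0", "0"),
            ("S1", "P", "Q"), ("S2", "P", "Q"),
            ("I", "S1", "S2"),
        ])
        A = build_A_tetraploid(ped, 0.0)
        F = (A.to_frame().loc["I", "I"] - 1.0) / 3.0
        oracle = gene_drop_relationships(ped, 0.0, n_rep=200_000, seed=7)
        F_mc = (oracle.loc["I", "I"] - 1.0) / 3.0
        assert F == pytest.approx(F_mc, abs=0.005)
        # tetrasomic full-sib mating: F = (2/3) * theta_sibs = (2/3)(1/8)
        assert F == pytest.approx(1.0 / 12.0, abs=1e-12)

    def test_genomic_inbreeding_formula(self):
        G = RelationshipMatrix(np.diag([1.099, 1.099]), ["a", "b"], "G")
        assert genomic_inbreeding(G).coefficient == pytest.approx(0.033)
        G0 = RelationshipMatrix(np.eye(2), ["a", "b"], "G")
        assert genomic_inbreeding(G0).coefficient == pytest.approx(0.0)


class TestVanRadenG:
    def test_hand_computed_entries(self):
        dos = pd.DataFrame([[0.0, 4.0], [2.0, 2.0], [4.0, 0.0]],
                           index=["a", "b", "c"], columns=["m1", "m2"])
        G = build_G_vanraden(dos)
        p = np.array([0.5, 0.5])
        Z = dos.to_numpy() - 4 * p
        expected = Z @ Z.T / (4 * np.sum(p * (1 - p)))
        assert np.allclose(G.values, expected)

    def test_identical_rows_give_equal_entries(self):
        dos = pd.DataFrame([[1.0, 3.0, 2.0]] * 2 + [[0.0, 4.0, 1.0]],
                           index=["a", "b", "c"])
        G = build_G_vanraden(dos)
        assert G.values[0, 0] == pytest.approx(G.values[1, 1])
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])

    def test_mean_diag_equals_one_plus_genomic_f(self):
        rng = np.random.default_rng(3)
        dos = pd.DataFrame(rng.binomial(4, 0.4, size=(40, 200)).astype(float))
        dos.index = [f"c{i}" for i in range(40)]
        G = build_G_vanraden(dos)
        f = genomic_inbreeding(G).coefficient
        assert np.mean(np.diag(G.values)) == pytest.approx(1 + 3 * f)

    def test_mean_imputation_of_missing(self):
        dos = pd.DataFrame([[0.0, 4.0], [np.nan, 0.0], [4.0, 2.0]],
                           index=["a", "b", "c"])
        G = build_G_vanraden(dos)
        # imputed entry equals the observed marker mean => contributes zero Z
        p = np.array([0.5, 0.5])
        M = np.array([[0, 4], [2.0, 0], [4, 2]])
        Z = M - 4 * p
        expected = Z @ Z.T / (4 * np.sum(p * (1 - p)))
        assert np.allclose(G.values, expected)

    def test_monomorphic_only_rejected(self):
        dos = pd.DataFrame([[4.0, 0.0], [4.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            build_G_vanraden(dos)

    def test_out_of_range_rejected(self):
        dos = pd.DataFrame([[5.0], [1.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            build_G_vanraden(dos)


class TestGScaling:
    def _pair(self, seed=0):
        rng = np.random.default_rng(seed)
        B = rng.standard_normal((5, 8))
        G = RelationshipMatrix(B @ B.T / 8 + np.eye(5) * 0.5,
                               [f"c{i}" for i in range(5)], "G")
        A22 = RelationshipMatrix(np.eye(5) * 1.045,
                                 [f"c{i}" for i in range(5)], "A22")
        return G, A22

    def test_scaling_matches_mean_diagonals(self):
        G, A22 = self._pair()
        G_adj = adjust_G_scale(G, A22)
        assert np.mean(np.diag(G_adj.values)) == pytest.approx(
            np.mean(np.diag(A22.values)))

    def test_idempotent(self):
        G, A22 = self._pair(1)
        once = adjust_G_scale(G, A22)
        twice = adjust_G_scale(once, A22)
        assert np.allclose(once.values, twice.values)

    def test_uniform_factor(self):
        G = RelationshipMatrix(np.diag([1.1, 1.1]), ["a", "b"], "G")
        A22 = RelationshipMatrix(np.diag([1.045, 1.045]), ["a", "b"], "A22")
        G_adj = adjust_G_scale(G, A22)
        assert np.allclose(G_adj.values, G.values * 0.95)

    def test_clone_mismatch_rejected(self):
        G = RelationshipMatrix(np.eye(2), ["a", "b"], "G")
        A22 = RelationshipMatrix(np.eye(2), ["a", "c"], "A22")
        with pytest.raises(IndexError):
            adjust_G_scale(G, A22)


class TestSingleStepH:
    @pytest.fixture()
    def setting(self, nested_pedigree):
        A = build_A_tetraploid(nested_pedigree)
        genotyped = ["F1", "S1", "X"]
        A22 = A.subset(genotyped)
        rng = np.random.default_rng(11)
        noise = rng.standard_normal((3, 3)) * 0.05
        G_adj = RelationshipMatrix(A22.values + (noise + noise.T) / 2,
                                   genotyped, "G_adj")
        return A, A22, G_adj, genotyped

    def test_equals_A_when_G_equals_A22(self, setting):
        A, A22, _, genotyped = setting
        G_same = RelationshipMatrix(A22.values.copy(), genotyped, "G_adj")
        H = build_H(A, G_same, genotyped)
        assert np.abs(H.values - A.values).max() < 1e-10

    def test_all_genotyped_gives_G(self, setting):
        A, _, _, _ = setting
        G_all = RelationshipMatrix(A.values + 0.01 * np.eye(len(A.ids)),
                                   list(A.ids), "G_adj")
        H = build_H(A, G_all, list(A.ids))
        assert np.allclose(H.values, G_all.values)

    def test_matches_block_formula(self, setting):
        A, A22, G_adj, genotyped = setting
        H = build_H(A, G_adj, genotyped)
        # brute-force block evaluation
        ids = list(A.ids)
        gi = [ids.index(c) for c in genotyped]
        pi = [i for i in range(len(ids)) if i not in gi]
        A22v = A.values[np.ix_(gi, gi)]
        A12 = A.values[np.ix_(pi, gi)]
        B = A12 @ np.linalg.inv(A22v)
        delta = G_adj.values - A22v
        expected = A.values.copy()
        expected[np.ix_(pi, pi)] += B @ delta @ B.T
        expected[np.ix_(pi, gi)] = B @ G_adj.values
        expected[np.ix_(gi, pi)] = (B @ G_adj.values).T
        expected[np.ix_(gi, gi)] = G_adj.values
        assert np.abs(H.values - expected).max() < 1e-9

    def test_martini_general_matches_direct_at_tau_omega_one(self, setting):
        A, _, G_adj, genotyped = setting
        H1 = build_H(A, G_adj, genotyped, tau=1.0, omega=1.0)
        H2 = build_H(A, G_adj, genotyped, tau=1.0, omega=1.0 - 1e-12)
        assert np.abs(H1.values - H2.values).max() < 1e-6

    def test_untouched_block_for_clones_unrelated_to_panel(self):
        ped = ped_frame([("a", "0", "0"), ("b", "0", "0"),
                         ("c", "0", "0"), ("o", "a", "b")])
        A = build_A_tetraploid(ped)
        G_adj = RelationshipMatrix(np.array([[1.05]]), ["c"], "G_adj")
        H = build_H(A, G_adj, ["c"])
        df_a, df_h = A.to_frame(), H.to_frame()
        for x in ("a", "b", "o"):
            for z in ("a", "b", "o"):
                assert df_h.loc[x, z] == pytest.approx(df_a.loc[x, z])
        assert df_h.loc["c", "c"] == pytest.approx(1.05)

    def test_symmetry_and_psd(self, setting):
        A, _, G_adj, genotyped = setting
        H = build_H(A, G_adj, genotyped)
        assert np.allclose(H.values, H.values.T)
        assert np.linalg.eigvalsh(H.values).min() > -1e-8


class TestSortPedigree:
    def test_parents_precede_offspring(self, nested_pedigree):
        out = sort_pedigree(nested_pedigree.sample(frac=1, random_state=3))
        seen = set()
        for r in out.itertuples(index=False):
            for par in (r.sire_id, r.dam_id):
                if par != "0":
                    assert par in seen
            seen.add(r.clone_id)

    def test_duplicate_ids_rejected(self):
        ped = ped_frame([("a", "0", "0"), ("a", "0", "0")])
        with pytest.raises(PedigreeError):
            sort_pedigree(ped)
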