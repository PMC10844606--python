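"""Relationship matrices, pedigree QC and kinship networks."""

import numpy as np
import pytest

import opbreed as ob
from opbreed.io import GenotypeMatrix, PedigreeTable, ValidationError


def recursive_A(ped: PedigreeTable) -> np.ndarray:
    """Independent oracle: numerator relationships straight from the
    recursive definition a(i,j) = (a(j,dam_i) + a(j,sire_i))/2."""
    idx = ped.index
    cache = {}

    def a(i, j):
        if idx[i] < idx[j]:
            i, j = j, i
        if (i, j) in cache:
            return cache[(i, j)]
        d, s = ped.parents_of(i)
        if i == j:
            val = 1.0 + 0.5 * (a(d, s) if d and s else 0.0)
        else:
            val = 0.5 * ((a(d, j) if d else 0.0) + (a(s, j) if s else 0.0))
        cache[(i, j)] = val
        return val

    n = len(ped)
    return np.array([[a(i, j) for j in ped.ids] for i in ped.ids])


def random_pedigree(rng, n):
    rows = []
    for k in range(n):
        parents = []
        for _ in range(2):
            if k and rng.random() < 0.6:
                parents.append(f"I{rng.integers(k)}")
            else:
                parents.append(None)
        rows.append((f"I{k}", parents[0], parents[1]))
    return PedigreeTable.from_records(rows)


class TestBuildA:
    def test_founders_only_identity(self):
        ped = PedigreeTable.from_records([(f"F{i}", None, None) for i in range(5)])
        np.testing.assert_array_equal(ob.build_A(ped).values, np.eye(5))

    def test_half_sibs(self):
        ped = PedigreeTable.from_records(
            [("D", None, None), ("O1", "D", None), ("O2", "D", None)]
        )
        A = ob.build_A(ped)
        assert A.loc("O1", "O2") == pytest.approx(0.25)
        assert A.loc("O1", "O1") == 1.0

    def test_selfing_inbreeding(self):
        ped = PedigreeTable.from_records([("F1", None, None), ("O1", "F1", "F1")])
        A = ob.build_A(ped)
        assert A.loc("O1", "O1") == pytest.approx(1.5)
        assert A.loc("F1", "O1") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_recursive_oracle(self, seed):
        ped = random_pedigree(np.random.default_rng(seed), 25)
        np.testing.assert_allclose(
            ob.build_A(ped).values, recursive_A(ped), atol=1e-12
        )


class TestImpute:
    def test_column_mean(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["s"], np.array([[0.0], [np.nan], [2.0]]))
        out = ob.impute_and_freq(gm)
        np.testing.assert_allclose(out.codes[:, 0], [0, 1.0, 2])

    def test_no_missing_identity(self, tiny_dataset):
        out = ob.impute_and_freq(tiny_dataset.genotypes)
        np.testing.assert_array_equal(out.codes, tiny_dataset.genotypes.codes)

    def test_two_missing(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"], ["s"], np.array([[1.0], [np.nan], [np.nan], [2.0]])
        )
        np.testing.assert_allclose(
            ob.impute_and_freq(gm).codes[:, 0], [1.0, 1.5, 1.5, 2.0]
        )

    def test_all_missing_errors(self):
        gm = GenotypeMatrix(["a", "b"], ["s"], np.array([[np.nan], [np.nan]]))
        with pytest.raises(ValidationError, match="all entries missing"):
            ob.impute_and_freq(gm)


class TestBuildGDE:
    def test_worked_single_snp_G(self, single_snp_genotypes):
        G = ob.build_G(single_snp_genotypes)
        np.testing.assert_allclose(
            G.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12
        )

    def test_worked_single_snp_D(self, single_snp_genotypes):
        D = ob.build_D(single_snp_genotypes)
        np.testing.assert_allclose(
            D.values, [[1, -1, 1], [-1, 1, -1], [1, -1, 1]], atol=1e-12
        )

    def test_epistatic_hadamard(self, single_snp_genotypes):
        G = ob.build_G(single_snp_genotypes)
        D = ob.build_D(single_snp_genotypes)
        E = ob.build_epistatic(G, D)
        np.testing.assert_allclose(
            E.values, [[2, 0, -2], [0, 0, 0], [-2, 0, 2]], atol=1e-12
        )
        np.testing.assert_allclose(
            E.values, ob.build_epistatic(D, G).values
        )

    def test_duplicated_columns_leave_G_unchanged(self, tiny_dataset):
        gm = tiny_dataset.genotypes
        dup = GenotypeMatrix(
            list(gm.ids),
            gm.snp_ids + [s + "_b" for s in gm.snp_ids],
            np.hstack([gm.codes, gm.codes]),
        )
        np.testing.assert_allclose(
            ob.build_G(dup).values, ob.build_G(gm).values, atol=1e-10
        )

    def test_G_invariant_to_code_flip(self, tiny_dataset):
        gm = tiny_dataset.genotypes
        flipped = GenotypeMatrix(list(gm.ids), list(gm.snp_ids), 2.0 - gm.codes)
        np.testing.assert_allclose(
            ob.build_G(flipped).values, ob.build_G(gm).values, atol=1e-10
        )

    def test_G_permutation_equivariance(self, tiny_dataset):
        gm = tiny_dataset.genotypes
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(gm.ids))
        G1 = ob.build_G(gm).submatrix(perm)
        G2 = ob.build_G(gm.subset_individuals(perm))
        np.testing.assert_allclose(G1.values, G2.values, atol=1e-10)

    def test_all_monomorphic_errors(self):
        gm = GenotypeMatrix(["a", "b"], ["s"], np.array([[2.0], [2.0]]))
        with pytest.raises(ValidationError, match="monomorphic"):
            ob.build_G(gm)

    def test_half_sib_G_expectations(self):
        # within-family mean genomic relationship -> 0.25, cross-family -> 0
        cfg = ob.SimConfig(
            n_families=30,
            offspring_per_family_per_site=10,
            n_sites=3,
            n_snps=5000,
            mating_proportions=(0.0, 0.0, 1.0),
            seed=21,
        )
        _, _, geno = ob.simulate_pedigree_genotypes(cfg)
        G = ob.build_G(geno).values
        fam = np.array([i.split("_")[0] for i in geno.ids])
        same = fam[:, None] == fam[None, :]
        off = ~np.eye(len(fam), dtype=bool)
        within = G[same & off]
        cross = G[~same]
        # observed-frequency centring deflates the pedigree expectation a
        # little (the sample itself is the allele-frequency base)
        assert abs(within.mean() - 0.25) < 0.03
        assert abs(cross.mean()) < 0.02


class TestVerifyPedigree:
    def test_clean_data_empty_report(self, tiny_dataset):
        G = ob.build_G(tiny_dataset.genotypes)
        rep = ob.verify_pedigree(G, tiny_dataset.pedigree_recorded)
        assert rep.is_clean()
        assert rep.final_ids == G.ids

    def test_recovers_injected_mislabels(self):
        cfg = ob.SimConfig(
            n_families=20,
            offspring_per_family_per_site=8,
            n_sites=3,
            n_snps=1200,
            seed=5,
        )
        ped_true, ped_rec, geno = ob.simulate_pedigree_genotypes(cfg)
        bad, altered = ob.inject_pedigree_errors(ped_rec, 0.05, seed=99)
        rep = ob.verify_pedigree(ob.build_G(geno), bad)
        flagged = {r[0] for r in rep.reassigned}
        assert len(flagged & set(altered)) >= 0.9 * len(altered)
        # reassignments point back at the true family (the dam of record)
        fam_true = {i: d for i, d in zip(ped_true.ids, ped_true.dam) if d}
        correct = sum(1 for i, _, new in rep.reassigned if fam_true.get(i) == new)
        assert correct >= 0.9 * len(rep.reassigned)

    def test_low_diagonal_removed(self, tiny_dataset):
        G = ob.build_G(tiny_dataset.genotypes)
        vals = G.values.copy()
        vals[0, 0] = 0.2  # a failed-genotyping individual
        G2 = ob.RelationshipMatrix("G", list(G.ids), vals)
        rep = ob.verify_pedigree(G2, tiny_dataset.pedigree_recorded)
        assert rep.removed_low_diagonal == [G.ids[0]]
        assert G.ids[0] not in rep.final_ids


class TestNetwork:
    def test_thresholds_edge_cases(self):
        K = ob.RelationshipMatrix("G", ["a", "b"], np.array([[1.0, 0.06], [0.06, 1.0]]))
        lo = ob.network_edges(K, 0.05)
        hi = ob.network_edges(K, 0.10)
        assert lo.n_edges == 1 and len(lo.components) == 1
        assert hi.n_edges == 0 and len(hi.components) == 2

    def test_threshold_above_max_gives_singletons(self, tiny_dataset):
        K = ob.build_G(tiny_dataset.genotypes)
        off = K.values[~np.eye(K.n, dtype=bool)]
        net = ob.network_edges(K, off.max() + 0.01)
        assert net.n_edges == 0 and len(net.components) == K.n

    def test_edge_count_non_increasing_in_threshold(self, tiny_dataset):
        K = ob.build_G(tiny_dataset.genotypes)
        counts = [ob.network_edges(K, t).n_edges for t in (0.0, 0.05, 0.1, 0.3, 0.6)]
        assert counts == sorted(counts, reverse=True)

    def test_half_sib_A_components_are_families(self):
        cfg = ob.SimConfig(
            n_families=5,
            offspring_per_family_per_site=4,
            n_sites=2,
            n_snps=50,
            n_qtl_per_trait=5,
            mating_proportions=(0, 0, 1),
            seed=2,
        )
        _, ped_rec, geno = ob.simulate_pedigree_genotypes(cfg)
        A = ob.build_A(ped_rec).submatrix(geno.ids)  # offspring only
        net = ob.network_edges(A, 0.05)
        fams = {i.split("_")[0] for i in geno.ids}
        assert len(net.components) == len(fams)
        for comp in net.components:
            assert len({i.split("_")[0] for i in comp}) == 1
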