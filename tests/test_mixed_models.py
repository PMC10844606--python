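"""REML variance components, MME/BLUP solutions, stage-1 adjustment."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import opbreed as ob
from opbreed.io import PhenotypeTable
from opbreed.mixed_models import (
    ModelSpec,
    VarianceComponents,
    _Problem,
    adjust_stage1,
    assemble_mme,
    fit_reml,
    predict_blup,
)


def half_sib_phenotypes(nfam, noff, sa2, se2, seed, mean=10.0):
    """Balanced single-site half-sib data simulated from the family model."""
    rng = np.random.default_rng(seed)
    fam_eff = rng.normal(0, np.sqrt(sa2 / 4), nfam)
    recs, ped_rows = [], []
    for f in range(nfam):
        dam = f"D{f}"
        ped_rows.append((dam, None, None))
        for o in range(noff):
            oid = f"D{f}_O{o}"
            ped_rows.append((oid, dam, None))
            recs.append(
                (oid, "S1", "R1", "HT",
                 mean + fam_eff[f] + rng.normal(0, np.sqrt(0.75 * sa2 + se2)))
            )
    phen = PhenotypeTable(
        pd.DataFrame(recs, columns=["id", "site", "rep", "trait", "value"]), ("HT",)
    )
    ped = ob.PedigreeTable.from_records(ped_rows)
    return phen, ped, np.array([r[4] for r in recs]).reshape(nfam, noff)


class TestFitREML:
    def test_matches_balanced_anova_oracle(self):
        """On a balanced half-sib design the individual-tree REML estimates
        map exactly onto the one-way ANOVA (Henderson III) estimator:
        sigma_a = 4 sigma_between, sigma_e = sigma_within - 3 sigma_between."""
        phen, ped, y = half_sib_phenotypes(15, 12, 0.5, 1.0, seed=7)
        A = ob.build_A(ped)
        vc = fit_reml(
            ModelSpec(["HT"], ["S1"], [("additive", A)], "ABLUP"),
            phen, tol=1e-14, max_iter=20000,
        )
        nfam, noff = y.shape
        msb = noff * y.mean(axis=1).var(ddof=1)
        msw = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum() / (nfam * (noff - 1))
        sb = (msb - msw) / noff
        assert vc.sigma["additive"][0, 0] == pytest.approx(4 * sb, abs=1e-4)
        assert vc.residual["S1"][1][0, 0] == pytest.approx(msw - 3 * sb, abs=1e-4)

    def test_loglik_trace_non_decreasing(self):
        phen, ped, _ = half_sib_phenotypes(8, 6, 0.5, 1.0, seed=3)
        vc = fit_reml(
            ModelSpec(["HT"], ["S1"], [("additive", ob.build_A(ped))], "ABLUP"),
            phen, tol=1e-8, max_iter=300,
        )
        t = np.array(vc.loglik_trace)
        assert np.all(np.diff(t) >= -1e-6 * (np.abs(t[:-1]) + 1))

    def test_null_genetic_variance_recovered(self):
        """Pure-noise phenotypes: the GBLUP heritability shrinks to the boundary."""
        cfg = ob.SimConfig(
            n_families=25, offspring_per_family_per_site=24, n_sites=1,
            n_snps=800, target_h2={"HT": 0.0}, genetic_correlations={}, seed=31,
        )
        ds = ob.simulate_dataset(cfg)
        G = ob.blend(ob.build_G(ds.genotypes), 0.01)
        vc = fit_reml(
            ModelSpec(["HT"], ["S1"], [("additive", G)], "GBLUP-A"),
            ds.phenotypes, tol=1e-7, max_iter=300,
        )
        h2 = ob.heritability(vc)["HT"][0]
        assert h2 <= 0.05

    def test_identity_A_equals_identity_G(self):
        """The engine only sees the relationship matrix, never its pedigree
        or genomic origin: identical K gives identical ABLUP/GBLUP output."""
        phen, ped, _ = half_sib_phenotypes(6, 5, 0.5, 1.0, seed=9)
        ids = sorted(phen.data["id"].unique())
        I = np.eye(len(ids))
        specA = ModelSpec(["HT"], ["S1"], [("additive", ob.RelationshipMatrix("A", ids, I))], "ABLUP")
        specG = ModelSpec(["HT"], ["S1"], [("additive", ob.RelationshipMatrix("G", ids, I))], "GBLUP-A")
        vcA = fit_reml(specA, phen, tol=1e-10, max_iter=500)
        vcG = fit_reml(specG, phen, tol=1e-10, max_iter=500)
        np.testing.assert_allclose(
            vcA.sigma["additive"], vcG.sigma["additive"], rtol=1e-8
        )
        bA = predict_blup(specA, phen, vcA).data["bv"].to_numpy()
        bG = predict_blup(specG, phen, vcG).data["bv"].to_numpy()
        np.testing.assert_allclose(bA, bG, atol=1e-8)


def small_multisite_fit(seed=5, n_sites=2):
    cfg = ob.SimConfig(
        n_families=8, offspring_per_family_per_site=6, n_sites=n_sites,
        n_snps=120, n_qtl_per_trait=12,
        target_h2={"HT": 0.4, "WD": 0.3},
        genetic_correlations={("HT", "WD"): -0.5}, seed=seed,
    )
    ds = ob.simulate_dataset(cfg)
    G = ob.blend(ob.build_G(ds.genotypes), 0.05)
    spec = ModelSpec(["HT", "WD"], ds.phenotypes.sites, [("additive", G)], "GBLUP-A")
    vc = fit_reml(spec, ds.phenotypes, tol=1e-8, max_iter=300)
    return ds, G, spec, vc


class TestMMEAndBLUP:
    def test_two_individual_closed_form_shrinkage(self):
        """Two unrelated individuals, one record each: the BLUP is the
        centred record shrunken by 1/(1+lambda)."""
        y = np.array([12.0, 8.0])
        sa2, se2 = 1.0, 2.0
        lam = se2 / sa2
        ids = ["a", "b"]
        phen = PhenotypeTable(
            pd.DataFrame(
                [("a", "S1", "R1", "HT", y[0]), ("b", "S1", "R1", "HT", y[1])],
                columns=["id", "site", "rep", "trait", "value"],
            ),
            ("HT",),
        )
        spec = ModelSpec(
            ["HT"], ["S1"], [("additive", ob.RelationshipMatrix("A", ids, np.eye(2)))]
        )
        vc = VarianceComponents(
            [("HT", "S1")], {"additive": np.array([[sa2]])},
            {"S1": (["HT"], np.array([[se2]]))},
        )
        bvs = predict_blup(spec, phen, vc)
        got = bvs.data.set_index("id")["bv"]
        mu = y.mean()  # GLS mean under equal variances
        for i, yi in zip(ids, y):
            assert got[i] == pytest.approx((yi - mu) / (1 + lam), abs=1e-10)

    def test_mme_coefficient_matrix_closed_form(self):
        """1 trait, 1 site, 2 individuals, A = I: the 3x3 Henderson system."""
        phen = PhenotypeTable(
            pd.DataFrame(
                [("a", "S1", "R1", "HT", 1.0), ("b", "S1", "R1", "HT", 2.0)],
                columns=["id", "site", "rep", "trait", "value"],
            ),
            ("HT",),
        )
        sa2, se2 = 2.0, 4.0
        spec = ModelSpec(
            ["HT"], ["S1"],
            [("additive", ob.RelationshipMatrix("A", ["a", "b"], np.eye(2)))],
        )
        vc = VarianceComponents(
            [("HT", "S1")], {"additive": np.array([[sa2]])},
            {"S1": (["HT"], np.array([[se2]]))},
        )
        mme = assemble_mme(spec, phen, vc)
        expected = np.array(
            [
                [2 / se2, 1 / se2, 1 / se2],
                [1 / se2, 1 / se2 + 1 / sa2, 0],
                [1 / se2, 0, 1 / se2 + 1 / sa2],
            ]
        )
        np.testing.assert_allclose(mme.coeff, expected, atol=1e-12)
        assert mme.coeff.shape == (3, 3)
        np.testing.assert_allclose(mme.coeff, mme.coeff.T)

    def test_multitrait_random_block_dimension(self):
        ds, G, spec, vc = small_multisite_fit()
        mme = assemble_mme(spec, ds.phenotypes, vc)
        q = len(spec.keys)
        assert mme.coeff.shape[0] == q + q * G.n
        np.testing.assert_allclose(mme.coeff, mme.coeff.T, atol=1e-9)

    def test_blup_matches_dense_gls_oracle(self):
        """MME solution == generalized-least-squares + conditional-expectation
        oracle computed by direct dense inversion."""
        ds, G, spec, vc = small_multisite_fit()
        bvs = predict_blup(spec, ds.phenotypes, vc)
        prob = _Problem(spec, ds.phenotypes)
        V, _ = prob.build_V(vc.sigma, vc.residual)
        X, y = prob.X, prob.y
        Vinv = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
        resid = y - X @ beta
        P = Vinv - Vinv @ X @ np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv)
        Sg = vc.sigma["additive"]
        pos = {i: k for k, i in enumerate(G.ids)}
        sub = [pos[i] for i in prob.individuals]
        Kcols = G.values[:, sub]
        for j, key in enumerate(spec.keys):
            C = Sg[j, prob.rec_key] * Kcols[:, prob.rec_lev]
            u = C @ (Vinv @ resid)
            got = (
                bvs.data[(bvs.data.trait == key[0]) & (bvs.data.site == key[1])]
                .set_index("id")["bv"]
                .reindex(G.ids)
                .to_numpy()
            )
            np.testing.assert_allclose(got, u, atol=1e-8)
            # PEV equals the oracle conditional variance diag
            pev_o = Sg[j, j] * np.diag(G.values) - np.einsum(
                "ij,jk,ik->i", C, P, C
            )
            got_pev = (
                bvs.data[(bvs.data.trait == key[0]) & (bvs.data.site == key[1])]
                .set_index("id")["pev"]
                .reindex(G.ids)
                .to_numpy()
            )
            np.testing.assert_allclose(got_pev, np.minimum(pev_o, Sg[j, j]), atol=1e-8)

    def test_zero_genetic_variance_gives_zero_bvs(self):
        phen, ped, _ = half_sib_phenotypes(4, 3, 0.5, 1.0, seed=2)
        A = ob.build_A(ped)
        vc = VarianceComponents(
            [("HT", "S1")], {"additive": np.array([[1e-10]])},
            {"S1": (["HT"], np.array([[1.0]]))},
        )
        bvs = predict_blup(
            ModelSpec(["HT"], ["S1"], [("additive", A)]), phen, vc
        )
        assert np.abs(bvs.data["bv"]).max() < 1e-6

    def test_bvs_sum_to_zero_per_key(self):
        ds, G, spec, vc = small_multisite_fit()
        bvs = predict_blup(spec, ds.phenotypes, vc)
        sums = bvs.data.groupby(["trait", "site"])["bv"].sum()
        scale = bvs.data["bv"].abs().max() + 1e-12
        assert (sums.abs() / scale < 1e-6).all()

    def test_prediction_accuracy_monotone_in_h2(self):
        cors = []
        for h2 in (0.1, 0.3, 0.5, 0.7):
            cfg = ob.SimConfig(
                n_families=15, offspring_per_family_per_site=10, n_sites=1,
                n_snps=500, n_qtl_per_trait=50, target_h2={"HT": h2},
                genetic_correlations={}, seed=77,
            )
            ds = ob.simulate_dataset(cfg)
            G = ob.blend(ob.build_G(ds.genotypes), 0.01)
            spec = ModelSpec(["HT"], ["S1"], [("additive", G)], "GBLUP-A")
            vc = fit_reml(spec, ds.phenotypes, tol=1e-6, max_iter=150)
            bvs = predict_blup(spec, ds.phenotypes, vc)
            truth = (
                ds.true_breeding_values.query("trait == 'HT' and site == 'S1'")
                .set_index("id")["bv"]
            )
            pred = bvs.site_averaged("HT")
            cors.append(np.corrcoef(truth.reindex(pred.index), pred)[0, 1])
        assert cors == sorted(cors)


class TestStage1Adjust:
    def test_no_rep_effect_is_near_identity(self):
        rng = np.random.default_rng(12)
        recs = [
            (f"I{i}", "S1", f"R{1 + i % 4}", "HT", 10 + rng.normal())
            for i in range(200)
        ]
        phen = PhenotypeTable(
            pd.DataFrame(recs, columns=["id", "site", "rep", "trait", "value"]), ("HT",)
        )
        ped = ob.PedigreeTable.from_records([(f"I{i}", None, None) for i in range(200)])
        adj = adjust_stage1(phen, ped)
        d = (adj.data["value"] - phen.data["value"]).abs()
        assert d.max() < 0.25  # shrunken rep predictions are ~0

    def test_single_replication_identity_with_warning(self):
        recs = [("a", "S1", "R1", "HT", 1.0), ("b", "S1", "R1", "HT", 2.0)]
        phen = PhenotypeTable(
            pd.DataFrame(recs, columns=["id", "site", "rep", "trait", "value"]), ("HT",)
        )
        ped = ob.PedigreeTable.from_records([("a", None, None), ("b", None, None)])
        with pytest.warns(UserWarning, match="single replication"):
            adj = adjust_stage1(phen, ped)
        pd.testing.assert_series_equal(adj.data["value"], phen.data["value"])

    def test_rep_blups_match_direct_gls_oracle(self):
        """12-record balanced toy, no genetic term: compare against an
        oracle that maximises the dense restricted likelihood numerically
        and computes u_rep = sigma_r^2 Z' P y directly."""
        rng = np.random.default_rng(5)
        reps = ["R1", "R2"]
        rep_eff = {"R1": 1.0, "R2": -1.0}
        recs = []
        for i in range(12):
            r = reps[i % 2]
            recs.append((f"I{i}", "S1", r, "HT", 5 + rep_eff[r] + rng.normal(0, 0.7)))
        phen = PhenotypeTable(
            pd.DataFrame(recs, columns=["id", "site", "rep", "trait", "value"]), ("HT",)
        )
        ped = ob.PedigreeTable.from_records([(f"I{i}", None, None) for i in range(12)])

        y = phen.data["value"].to_numpy()
        Zr = np.zeros((12, 2))
        Zr[np.arange(12), [i % 2 for i in range(12)]] = 1.0
        X = np.ones((12, 1))

        def negll(logtheta):
            sr, se = np.exp(logtheta)
            V = sr * Zr @ Zr.T + se * np.eye(12)
            Vinv = np.linalg.inv(V)
            VX = Vinv @ X
            P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
            _, ld = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(X.T @ VX)
            return 0.5 * (ld + ldx + y @ P @ y)

        res = scipy.optimize.minimize(negll, np.log([0.5, 0.5]), method="Nelder-Mead",
                                      options={"xatol": 1e-10, "fatol": 1e-12})
        sr, se = np.exp(res.x)
        V = sr * Zr @ Zr.T + se * np.eye(12)
        Vinv = np.linalg.inv(V)
        VX = Vinv @ X
        P = Vinv - VX @ np.linalg.solve(X.T @ VX, VX.T)
        u_oracle = sr * Zr.T @ (P @ y)

        adj = adjust_stage1(phen, ped, genetic_term=False, tol=1e-12, max_iter=5000)
        u_pkg = (phen.data["value"] - adj.data["value"]).to_numpy()
        u_pkg_by_rep = [u_pkg[0], u_pkg[1]]  # first two records cover R1, R2
        np.testing.assert_allclose(u_pkg_by_rep, u_oracle, atol=1e-4)
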