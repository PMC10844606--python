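"""Synthetic open-pollinated (OP) progeny-test generator.

Emulates the data structure the evaluation framework assumes: a set of OP
families (seed parents pollinated by a diffuse local pollen pool, so each
"half-sib" family is really a mixture of selfs, full-sibs and half-sibs),
offspring planted over several sites in randomised complete blocks, a few
correlated traits controlled by a shared set of QTL among the genotyped
SNPs, and a recorded pedigree that knows only the maternal side — and may
carry mislabelled dams.

Founder genotypes are drawn per SNP under Hardy–Weinberg equilibrium from a
uniform allele-frequency band; offspring genotypes arise by gene dropping
(one gamete from the dam, one from the sire drawn per the sibship mixture).
SNPs are unlinked.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PedigreeTable, PhenotypeTable, ValidationError

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_pedigree_genotypes",
    "simulate_phenotypes",
    "inject_pedigree_errors",
    "simulate_dataset",
]

#: genetic correlations among HT/DBH/WD; wood density trades off against
#: both growth traits (negative correlations), growth traits co-vary.
DEFAULT_TRAIT_CORR = {
    ("HT", "DBH"): 0.5,
    ("HT", "WD"): -0.53,
    ("DBH", "WD"): -0.72,
}

#: typical trait means for a mature spruce progeny test (m, cm, g/cm^3)
DEFAULT_TRAIT_MEANS = {"HT": 15.0, "DBH": 20.0, "WD": 0.45}


@dataclasses.dataclass
class SimConfig:
    n_families: int = 25
    offspring_per_family_per_site: int = 15
    n_sites: int = 3
    n_reps_per_site: int = 4
    n_snps: int = 3000
    founder_maf_distribution: tuple[float, float] = (0.05, 0.5)
    mating_proportions: tuple[float, float, float] = (0.05, 0.25, 0.70)  # self, FS, HS
    n_qtl_per_trait: int = 100
    target_h2: dict = dataclasses.field(
        default_factory=lambda: {"HT": 0.6, "DBH": 0.4, "WD": 0.5}
    )
    genetic_correlations: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAIT_CORR)
    )
    trait_means: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TRAIT_MEANS)
    )
    site_corr: float = 0.8  # genetic correlation of BVs across sites
    phenotypic_cv: float = 0.15  # phenotypic sd as a fraction of the trait mean
    site_effect_sd: float = 0.5  # site-mean shifts, in units of phenotypic sd
    rep_effect_sd: float = 0.25  # block effects, in units of phenotypic sd
    pedigree_error_rate: float = 0.0
    seed: int = 0

    @property
    def traits(self) -> list[str]:
        return list(self.target_h2)

    def validate(self) -> None:
        if abs(sum(self.mating_proportions) - 1.0) > 1e-12:
            raise ValidationError("mating proportions must sum to 1")
        if any(p < 0 for p in self.mating_proportions):
            raise ValidationError("mating proportions must be non-negative")
        if self.n_qtl_per_trait > self.n_snps:
            raise ValidationError("n_qtl_per_trait exceeds n_snps")
        for t, h2 in self.target_h2.items():
            if not (0.0 <= h2 < 1.0):
                raise ValidationError(f"target h2 for {t} must be in [0, 1)")
        C = self.trait_corr_matrix()
        if np.any(np.linalg.eigvalsh(C) <= 0):
            raise ValidationError("trait correlation matrix not positive definite")
        for f in ("n_families", "offspring_per_family_per_site", "n_sites",
                  "n_reps_per_site", "n_snps"):
            if getattr(self, f) < 1:
                raise ValidationError(f"{f} must be positive")

    def trait_corr_matrix(self) -> np.ndarray:
        t = self.traits
        C = np.eye(len(t))
        for (a, b), r in self.genetic_correlations.items():
            if a in t and b in t:
                ia, ib = t.index(a), t.index(b)
                C[ia, ib] = C[ib, ia] = r
        return C

    def site_corr_matrix(self) -> np.ndarray:
        S = np.full((self.n_sites, self.n_sites), self.site_corr)
        np.fill_diagonal(S, 1.0)
        return S


@dataclasses.dataclass
class SimulatedDataset:
    pedigree_true: PedigreeTable
    pedigree_recorded: PedigreeTable
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_breeding_values: pd.DataFrame  # columns id, trait, site, bv
    true_params: dict


# ---------------------------------------------------------------------------
# gene dropping


def _hwe_genotypes(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """n individuals × m SNPs as two haplotype arrays (returns (hap1, hap2))."""
    m = len(p)
    return (
        (rng.random((n, m)) < p).astype(np.int8),
        (rng.random((n, m)) < p).astype(np.int8),
    )


def _gamete(rng, hap1, hap2, rows):
    """One gamete per requested parent row; SNPs segregate independently."""
    pick = rng.random((len(rows), hap1.shape[1])) < 0.5
    return np.where(pick, hap1[rows], hap2[rows])


def simulate_pedigree_genotypes(
    config: SimConfig,
) -> tuple[PedigreeTable, PedigreeTable, GenotypeMatrix]:
    """Gene-drop offspring genotypes through the OP sibship mixture.

    Returns the true pedigree (sires known), the recorded pedigree (all
    sires unknown — what a breeder actually has for OP families), and the
    genotype matrix covering the offspring.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_snps
    lo, hi = config.founder_maf_distribution
    p = rng.uniform(lo, hi, size=m)

    n_fam = config.n_families
    n_off_fam = config.offspring_per_family_per_site * config.n_sites

    dam_ids = [f"DAM{k + 1:03d}" for k in range(n_fam)]
    dams = _hwe_genotypes(rng, p, n_fam)
    # one designated within-family full-sib father per family
    fs_fathers = _hwe_genotypes(rng, p, n_fam)

    p_self, p_fs, p_hs = config.mating_proportions
    true_rows: list[tuple[str, str | None, str | None]] = [
        (d, None, None) for d in dam_ids
    ]
    rec_rows: list[tuple[str, str | None, str | None]] = list(true_rows)

    off_ids: list[str] = []
    off_geno = np.empty((n_fam * n_off_fam, m), dtype=np.int8)
    hs_counter = 0
    k = 0
    snp_ids = [f"SNP{j + 1:05d}" for j in range(m)]
    for f in range(n_fam):
        kinds = rng.choice(3, size=n_off_fam, p=[p_self, p_fs, p_hs])
        dam_gam = _gamete(rng, *dams, np.full(n_off_fam, f))
        for o in range(n_off_fam):
            oid = f"F{f + 1:03d}_O{o + 1:03d}"
            off_ids.append(oid)
            kind = kinds[o]
            if kind == 0:  # selfing
                sire_gam = _gamete(rng, *dams, np.array([f]))[0]
                sire_id = dam_ids[f]
            elif kind == 1:  # shared within-family father
                sire_gam = _gamete(rng, *fs_fathers, np.array([f]))[0]
                sire_id = f"FSF{f + 1:03d}"
            else:  # fresh pollen-pool father, effectively infinite pool
                hs_counter += 1
                fh = _hwe_genotypes(rng, p, 1)
                sire_gam = _gamete(rng, *fh, np.array([0]))[0]
                sire_id = f"POLLEN{hs_counter:05d}"
            off_geno[k] = dam_gam[o] + sire_gam
            true_rows.append((oid, dam_ids[f], sire_id))
            rec_rows.append((oid, dam_ids[f], None))
            k += 1

    pedigree_true = PedigreeTable.from_records(true_rows)
    pedigree_recorded = PedigreeTable.from_records(rec_rows)
    genotypes = GenotypeMatrix(off_ids, snp_ids, off_geno.astype(float))
    return pedigree_true, pedigree_recorded, genotypes


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    config: SimConfig, genotypes: GenotypeMatrix
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Draw QTL effects and build phenotypes = site mean + rep + BV + residual.

    A common set of QTL drives all traits; per-QTL effects are multivariate
    normal across traits (covariance = the target genetic correlation
    matrix) and across sites (exchangeable correlation ``site_corr``), which
    makes site-specific breeding values correlated traits as the multi-site
    models assume.  Per trait, BVs are rescaled so that realised additive
    variance at site 1 over residual variance hits the target h²; residual
    variance is the same at every site and residuals are independent across
    traits.
    """
    config.validate()
    if genotypes.has_missing:
        raise ValidationError("genotypes must be complete before phenotype simulation")
    rng = np.random.default_rng(config.seed + 1)
    traits = config.traits
    T, S = len(traits), config.n_sites
    n = genotypes.n

    qtl = rng.choice(genotypes.m, size=config.n_qtl_per_trait, replace=False)
    cov = np.kron(config.trait_corr_matrix(), config.site_corr_matrix())
    effects = rng.multivariate_normal(
        np.zeros(T * S), cov, size=config.n_qtl_per_trait, method="cholesky"
    )  # (n_qtl, T*S)

    Wq = genotypes.codes[:, qtl] - genotypes.codes[:, qtl].mean(axis=0)
    bv = (Wq @ effects).reshape(n, T, S)

    # per-trait unit scale: phenotypic sd = cv x trait mean at site 1
    sigma_e = np.empty(T)
    phen_sd = np.empty(T)
    for t, trait in enumerate(traits):
        h2 = config.target_h2[trait]
        mean_t = abs(config.trait_means.get(trait, 10.0))
        phen_sd[t] = config.phenotypic_cv * (mean_t if mean_t > 0 else 1.0)
        if h2 == 0.0:
            bv[:, t, :] = 0.0
            sigma_e[t] = phen_sd[t]
            continue
        v1 = bv[:, t, 0].var()
        if v1 <= 0:
            raise ValidationError("degenerate additive variance; increase n_qtl or MAF")
        # realized additive variance at site 1 = h2 x phenotypic variance
        bv[:, t, :] *= phen_sd[t] * np.sqrt(h2 / v1)
        sigma_e[t] = phen_sd[t] * np.sqrt(1.0 - h2)

    site_ids = [f"S{s + 1}" for s in range(S)]
    rep_ids = [f"R{r + 1}" for r in range(config.n_reps_per_site)]
    site_means = {
        (trait, s): config.trait_means.get(trait, 10.0)
        + rng.normal(0.0, config.site_effect_sd * phen_sd[traits.index(trait)])
        for trait in traits
        for s in site_ids
    }
    rep_eff = {
        (s, r, trait): rng.normal(0.0, config.rep_effect_sd * phen_sd[t])
        for s in site_ids
        for r in rep_ids
        for t, trait in enumerate(traits)
    }

    # assign each individual to a site/replication: families split evenly
    # across sites, randomised blocks within site
    per_site = config.offspring_per_family_per_site
    rows = []
    bv_rows = []
    for i, oid in enumerate(genotypes.ids):
        within = i % (per_site * S)
        s = within // per_site
        site = site_ids[s]
        rep = rep_ids[rng.integers(len(rep_ids))]
        for t, trait in enumerate(traits):
            y = (
                site_means[(trait, site)]
                + rep_eff[(site, rep, trait)]
                + bv[i, t, s]
                + rng.normal(0.0, sigma_e[t])
            )
            rows.append((oid, site, rep, trait, y))
        for t, trait in enumerate(traits):
            for s2, site2 in enumerate(site_ids):
                bv_rows.append((oid, trait, site2, bv[i, t, s2]))

    phenotypes = PhenotypeTable(
        pd.DataFrame(rows, columns=["id", "site", "rep", "trait", "value"]),
        tuple(traits),
    )
    true_bv = pd.DataFrame(bv_rows, columns=["id", "trait", "site", "bv"])
    true_bv.attrs["qtl_snps"] = [genotypes.snp_ids[k] for k in qtl]
    return phenotypes, true_bv


def inject_pedigree_errors(
    pedigree: PedigreeTable, rate: float, seed: int
) -> tuple[PedigreeTable, list[str]]:
    """Mislabel a fraction ``rate`` of offspring with another family's dam.

    Returns the corrupted pedigree and the list of altered offspring ids.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValidationError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    dams = sorted({d for d in pedigree.dam if d is not None})
    rows = list(zip(pedigree.ids, pedigree.dam, pedigree.sire))
    altered: list[str] = []
    if len(dams) >= 2 and rate > 0:
        out_rows = []
        for i, d, s in rows:
            if d is not None and rng.random() < rate:
                choices = [x for x in dams if x != d]
                d = choices[rng.integers(len(choices))]
                altered.append(i)
            out_rows.append((i, d, s))
        rows = out_rows
    return PedigreeTable.from_records(rows), altered


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full simulated OP progeny test, deterministically from ``config.seed``."""
    ped_true, ped_rec, geno = simulate_pedigree_genotypes(config)
    phen, true_bv = simulate_phenotypes(config, geno)
    if config.pedigree_error_rate > 0:
        ped_rec, altered = inject_pedigree_errors(
            ped_rec, config.pedigree_error_rate, config.seed + 2
        )
    else:
        altered = []
    params = dataclasses.asdict(config)
    params["genetic_correlations"] = {
        f"{a}:{b}": v for (a, b), v in config.genetic_correlations.items()
    }
    params["mislabelled"] = altered
    params["qtl_snps"] = true_bv.attrs.get("qtl_snps", [])
    return SimulatedDataset(ped_true, ped_rec, geno, phen, true_bv, params)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, str]:
    """Write the standard tables plus truth.json; returns the path map."""
    from . import io as _io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": str(outdir / "pedigree.csv"),
        "pedigree_true": str(outdir / "pedigree_true.csv"),
        "genotypes": str(outdir / "genotypes.tsv"),
        "phenotypes": str(outdir / "phenotypes.csv"),
        "truth": str(outdir / "truth.json"),
    }
    _io.write_pedigree(ds.pedigree_recorded, paths["pedigree"])
    _io.write_pedigree(ds.pedigree_true, paths["pedigree_true"])
    _io.write_genotypes(ds.genotypes, paths["genotypes"])
    _io.write_phenotypes(ds.phenotypes, paths["phenotypes"])
    truth = {
        "params": ds.true_params,
        "breeding_values": ds.true_breeding_values.to_dict(orient="list"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
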