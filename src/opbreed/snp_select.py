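"""GWAS-effect SNP back-solution, ranking strategies and incremental subsets.

Because every analysed individual is genotyped after QC, the single-step
GWAS reduces to back-solving marker effects from the GBLUP solutions:

    û = W' G⁻¹ ĝ / (2 Σ_k p_k (1 − p_k)),

per site, with W the centred marker matrix used to build G.  SNPs are then
ranked by their cross-site mean absolute effect (largest first), by minor
allele frequency (rarest first) or by a seeded random shuffle, and grown
into nested incremental subsets for G-matrix re-construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, ValidationError
from .mixed_models import BreedingValueSet
from .relmat import RelationshipMatrix

__all__ = [
    "SnpEffectTable",
    "SnpRanking",
    "backsolve_snp_effects",
    "rank_snps",
    "make_increments",
    "combine_trait_top",
]


@dataclasses.dataclass
class SnpEffectTable:
    """Per-site back-solved SNP effects plus the cross-site mean |effect|."""

    effects: pd.DataFrame  # index snp_id, one column per site
    mean_abs: pd.Series  # index snp_id

    def __len__(self) -> int:
        return len(self.mean_abs)


@dataclasses.dataclass
class SnpRanking:
    strategy: str  # random | maf | gwas_effect
    snp_ids: list[str]
    scores: pd.Series | None = None
    seed: int | None = None

    def top(self, k: int) -> list[str]:
        return self.snp_ids[:k]


def backsolve_snp_effects(
    genotypes: GenotypeMatrix,
    G: RelationshipMatrix,
    gebv: BreedingValueSet,
    trait: str | None = None,
) -> SnpEffectTable:
    """Marker effects from per-site GEBVs of a multi-site GBLUP fit.

    ``G`` must have been built from these genotypes (same centring and
    denominator).  A pseudo-inverse is used so that rank-deficient
    (unblended) G is handled exactly: ĝ lies in the row space of W, where
    the back-solution is unique.
    """
    if genotypes.has_missing:
        raise ValidationError("genotypes must be imputed before back-solving effects")
    if genotypes.ids != G.ids:
        raise ValidationError("genotype and G-matrix individuals differ")
    keep = ~genotypes.monomorphic
    codes = genotypes.codes[:, keep]
    p = genotypes.p[keep]
    snp_ids = [s for s, k in zip(genotypes.snp_ids, keep) if k]
    W = codes - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))

    Ginv = np.linalg.pinv(G.values, hermitian=True)
    d = gebv.data
    if trait is not None:
        d = d[d["trait"] == trait]
    traits = d["trait"].unique()
    if len(traits) != 1:
        raise ValidationError("pass a single trait's GEBVs (or trait=...)")
    wide = d.pivot(index="id", columns="site", values="bv").loc[genotypes.ids]
    eff = W.T @ (Ginv @ wide.to_numpy()) / denom
    effects = pd.DataFrame(eff, index=snp_ids, columns=list(wide.columns))
    mean_abs = effects.abs().mean(axis=1)
    mean_abs.name = "mean_abs_effect"
    return SnpEffectTable(effects, mean_abs)


def rank_snps(
    source: SnpEffectTable | GenotypeMatrix,
    strategy: str,
    seed: int | None = None,
) -> SnpRanking:
    """Order SNPs by the requested strategy; ties break by ascending snp_id.

    * ``gwas_effect`` — descending cross-site mean absolute effect
      (needs a :class:`SnpEffectTable`);
    * ``maf`` — ascending minor allele frequency, rarest first
      (needs a :class:`GenotypeMatrix`);
    * ``random`` — seeded shuffle (needs any source with snp ids).
    """
    if strategy == "gwas_effect":
        if not isinstance(source, SnpEffectTable):
            raise ValidationError("gwas_effect ranking needs a SnpEffectTable")
        s = source.mean_abs
        order = sorted(s.index, key=lambda i: (-s[i], i))
        return SnpRanking(strategy, list(order), s)
    if strategy == "maf":
        if not isinstance(source, GenotypeMatrix):
            raise ValidationError("maf ranking needs a GenotypeMatrix")
        maf = pd.Series(source.maf, index=source.snp_ids)
        order = sorted(maf.index, key=lambda i: (maf[i], i))
        return SnpRanking(strategy, list(order), maf)
    if strategy == "random":
        ids = (
            list(source.mean_abs.index)
            if isinstance(source, SnpEffectTable)
            else list(source.snp_ids)
        )
        if seed is None:
            raise ValidationError("random ranking needs a seed")
        rng = np.random.default_rng(seed)
        ids = sorted(ids)
        rng.shuffle(ids)
        return SnpRanking(strategy, ids, None, seed)
    raise ValidationError(f"unknown ranking strategy {strategy!r}")


def make_increments(n_total: int, n_steps: int) -> list[int]:
    """Cumulative subset sizes round(j·n_total/n_steps), j = 1..n_steps."""
    if n_steps < 1 or n_total < n_steps:
        raise ValidationError("need n_steps >= 1 and n_total >= n_steps")
    sizes = [int(np.floor(j * n_total / n_steps + 0.5)) for j in range(1, n_steps + 1)]
    sizes[-1] = n_total
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValidationError("increment plan not strictly increasing")
    return sizes


def combine_trait_top(rankings: dict[str, SnpRanking], k: int) -> set[str]:
    """Union of each trait's top-k SNPs (the combined multi-trait G-matrix set)."""
    universes = [frozenset(r.snp_ids) for r in rankings.values()]
    if len(set(universes)) != 1:
        raise ValidationError("rankings cover different SNP universes")
    if k > len(universes[0]):
        raise ValidationError("k exceeds the SNP universe size")
    out: set[str] = set()
    for r in rankings.values():
        out.update(r.top(k))
    return out
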