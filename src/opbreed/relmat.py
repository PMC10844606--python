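"""Relationship matrices (A, G, D, epistatic), genomic pedigree QC, kinship networks.

The pedigree numerator relationship matrix **A** is built with the tabular
method (expected additive relatedness, founders unrelated).  The genomic
matrix **G** follows VanRaden's first method,

    G = W W' / (2 Σ_k p_k (1 − p_k)),

with W the per-SNP 2p-centred code matrix and p_k the observed
alternate-allele frequency.  The dominance matrix **D** uses Vitezica-style
heterozygosity covariates (−2p², 2pq, −2q² for codes 0/1/2) scaled by
Σ_k (2 p_k q_k)², and the additive×dominance epistatic matrix is the
Hadamard product G ∘ D.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import networkx as nx
import numpy as np

from .io import GenotypeMatrix, PedigreeTable, ValidationError

__all__ = [
    "RelationshipMatrix",
    "QCReport",
    "KinshipNetwork",
    "build_A",
    "impute_and_freq",
    "build_G",
    "build_D",
    "build_epistatic",
    "blend",
    "verify_pedigree",
    "network_edges",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class RelationshipMatrix:
    kind: str  # A | G | D | EPI
    ids: list[str]
    values: np.ndarray
    n_snps_used: int = 0
    blending_weight: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"{self.kind}-matrix shape {self.values.shape} != ({n},{n})")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValidationError(f"{self.kind}-matrix not symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids: Sequence[str]) -> "RelationshipMatrix":
        pos = {i: k for k, i in enumerate(self.ids)}
        idx = [pos[i] for i in ids]
        return RelationshipMatrix(
            self.kind, list(ids), self.values[np.ix_(idx, idx)].copy(),
            self.n_snps_used, self.blending_weight,
        )

    def loc(self, a: str, b: str) -> float:
        pos = {i: k for k, i in enumerate(self.ids)}
        return float(self.values[pos[a], pos[b]])


def build_A(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Founders are mutually unrelated and non-inbred; the diagonal is
    1 + F_i with F_i = half the parents' relationship.
    """
    n = len(pedigree)
    idx = pedigree.index
    A = np.zeros((n, n))
    for k, (i, d, s) in enumerate(zip(pedigree.ids, pedigree.dam, pedigree.sire)):
        di = idx[d] if d is not None else None
        si = idx[s] if s is not None else None
        # ids are in topological order, so parent rows are complete
        if di is not None and si is not None:
            A[k, :k] = 0.5 * (A[di, :k] + A[si, :k])
            A[k, k] = 1.0 + 0.5 * A[di, si]
        elif di is not None or si is not None:
            p = di if di is not None else si
            A[k, :k] = 0.5 * A[p, :k]
            A[k, k] = 1.0
        else:
            A[k, k] = 1.0
        A[:k, k] = A[k, :k]
    return RelationshipMatrix("A", list(pedigree.ids), A)


def impute_and_freq(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing codes per SNP (column mean of non-missing entries)."""
    codes = genotypes.codes.copy()
    all_missing = np.isnan(codes).all(axis=0)
    if all_missing.any():
        bad = [genotypes.snp_ids[k] for k in np.flatnonzero(all_missing)]
        raise ValidationError(f"SNPs with all entries missing: {bad[:10]}")
    col_mean = np.nanmean(codes, axis=0)
    miss = np.isnan(codes)
    codes[miss] = np.broadcast_to(col_mean, codes.shape)[miss]
    out = GenotypeMatrix(list(genotypes.ids), list(genotypes.snp_ids), codes)
    n_mono = int(out.monomorphic.sum())
    if n_mono:
        log.info("impute_and_freq: %d monomorphic SNPs flagged", n_mono)
    return out


def _polymorphic(genotypes: GenotypeMatrix):
    if genotypes.has_missing:
        raise ValidationError("genotypes must be imputed before building G/D")
    keep = ~genotypes.monomorphic
    if not keep.any():
        raise ValidationError("all SNPs monomorphic: zero denominator")
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("dropping %d monomorphic SNPs from relationship matrix", n_dropped)
    return genotypes.codes[:, keep], genotypes.p[keep]


def build_G(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix from observed allele frequencies."""
    codes, p = _polymorphic(genotypes)
    W = codes - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = W @ W.T / denom
    return RelationshipMatrix("G", list(genotypes.ids), G, n_snps_used=W.shape[1])


def build_D(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """Dominance relationship matrix (Vitezica parameterisation).

    Codes 0/1/2 map to covariates −2p², 2pq, −2q²; the scaling constant is
    Σ_k (2 p_k q_k)².
    """
    codes, p = _polymorphic(genotypes)
    q = 1.0 - p
    # linear-in-code form matching the three support points exactly for
    # integer codes; fractional (imputed) codes are interpolated
    w0, w1, w2 = -2.0 * p**2, 2.0 * p * q, -2.0 * q**2
    x = codes
    # quadratic interpolation through (0,w0),(1,w1),(2,w2)
    Wd = w0 * (x - 1) * (x - 2) / 2.0 - w1 * x * (x - 2) + w2 * x * (x - 1) / 2.0
    denom = np.sum((2.0 * p * q) ** 2)
    if denom <= 0:
        raise ValidationError("zero dominance denominator")
    D = Wd @ Wd.T / denom
    return RelationshipMatrix("D", list(genotypes.ids), D, n_snps_used=codes.shape[1])


def build_epistatic(G: RelationshipMatrix, D: RelationshipMatrix) -> RelationshipMatrix:
    """Additive×dominance epistatic relationship matrix: Hadamard product G ∘ D."""
    if G.ids != D.ids:
        raise ValidationError("G and D cover different individuals")
    return RelationshipMatrix(
        "EPI", list(G.ids), G.values * D.values, n_snps_used=G.n_snps_used
    )


def blend(K: RelationshipMatrix, weight: float = 0.01) -> RelationshipMatrix:
    """Shrink toward the identity, K ← (1−w) K + w I, so inverses exist.

    G is singular whenever n exceeds the rank of the marker matrix; a small
    identity blend is the standard remedy and is recorded in metadata.
    """
    out = RelationshipMatrix(
        K.kind,
        list(K.ids),
        (1.0 - weight) * K.values + weight * np.eye(K.n),
        K.n_snps_used,
        K.blending_weight + weight,
    )
    return out


# ---------------------------------------------------------------------------
# genomic pedigree verification


@dataclasses.dataclass
class QCReport:
    removed_low_diagonal: list[str]
    reassigned: list[tuple[str, str, str]]  # (id, old_family, new_family)
    new_families: list[tuple[str, list[str]]]
    unassigned: list[str]
    final_ids: list[str]

    def is_clean(self) -> bool:
        return not (
            self.removed_low_diagonal or self.reassigned or self.new_families or self.unassigned
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _family_of(pedigree: PedigreeTable) -> dict[str, str]:
    """Offspring → recorded dam (family label). Founders are skipped."""
    fam = {}
    for i, d, s in zip(pedigree.ids, pedigree.dam, pedigree.sire):
        if d is not None:
            fam[i] = d
    return fam


def verify_pedigree(
    G: RelationshipMatrix,
    pedigree_recorded: PedigreeTable,
    diag_low: float = 0.6,
    within_family_low: float = 0.1,
    cluster_min: float = 0.15,
) -> QCReport:
    """Genomic verification of a recorded (maternal) pedigree.

    1. drop individuals with G(i,i) < ``diag_low`` (failed genotyping);
    2. individuals whose mean genomic relationship to their recorded family
       falls below ``within_family_low`` are compared against every other
       family and reassigned to the best one whose mean is ≥ ``cluster_min``;
    3. leftovers that are mutually related (pairwise ≥ ``cluster_min``) are
       grouped into new families; the rest are reported unassigned.
    """
    fam = _family_of(pedigree_recorded)
    pos = {i: k for k, i in enumerate(G.ids)}
    offspring = [i for i in G.ids if i in fam]

    diag = np.diag(G.values)
    removed = [i for i in offspring if diag[pos[i]] < diag_low]
    kept = [i for i in offspring if i not in set(removed)]

    families: dict[str, list[str]] = {}
    for i in kept:
        families.setdefault(fam[i], []).append(i)

    def mean_rel(i: str, members: list[str]) -> float:
        others = [m for m in members if m != i]
        if not others:
            return np.nan
        r = [G.values[pos[i], pos[m]] for m in others]
        return float(np.mean(r))

    suspects = [
        i for i in kept
        if len(families[fam[i]]) > 1 and mean_rel(i, families[fam[i]]) < within_family_low
    ]

    reassigned: list[tuple[str, str, str]] = []
    leftovers: list[str] = []
    for i in suspects:
        best_fam, best_val = None, -np.inf
        for f, members in families.items():
            if f == fam[i]:
                continue
            v = mean_rel(i, members)
            if np.isfinite(v) and v > best_val:
                best_fam, best_val = f, v
        if best_fam is not None and best_val >= cluster_min:
            reassigned.append((i, fam[i], best_fam))
        else:
            leftovers.append(i)

    # cluster mutually related leftovers into new families
    g = nx.Graph()
    g.add_nodes_from(leftovers)
    for a in range(len(leftovers)):
        for b in range(a + 1, len(leftovers)):
            i, j = leftovers[a], leftovers[b]
            if G.values[pos[i], pos[j]] >= cluster_min:
                g.add_edge(i, j)
    new_families: list[tuple[str, list[str]]] = []
    unassigned: list[str] = []
    for k, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        members = sorted(comp)
        if len(members) >= 2:
            new_families.append((f"NEWFAM{k + 1}", members))
        else:
            unassigned.extend(members)

    final_ids = [i for i in G.ids if i not in set(removed)]
    return QCReport(removed, reassigned, new_families, sorted(unassigned), final_ids)


# ---------------------------------------------------------------------------
# kinship networks


@dataclasses.dataclass
class KinshipNetwork:
    threshold: float
    edges: list[tuple[str, str, float]]
    components: list[set[str]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def network_edges(K: RelationshipMatrix, threshold: float) -> KinshipNetwork:
    """Link every unordered pair with relationship strictly above ``threshold``."""
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    iu, ju = np.triu_indices(K.n, k=1)
    mask = K.values[iu, ju] > threshold
    edges = [
        (K.ids[a], K.ids[b], float(K.values[a, b]))
        for a, b in zip(iu[mask], ju[mask])
    ]
    g = nx.Graph()
    g.add_nodes_from(K.ids)
    g.add_edges_from((a, b) for a, b, _ in edges)
    components = [set(c) for c in nx.connected_components(g)]
    return KinshipNetwork(threshold, edges, components)
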