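"""Readers, writers and validated containers for the three standard tables.

All downstream analyses consume the three containers defined here:

* :class:`PedigreeTable` — contemporary genealogy (id, dam, sire), with
  unknown parents normalised to a single ``None`` sentinel.
* :class:`GenotypeMatrix` — individuals × SNPs coded as counts of the
  alternate allele (0/1/2), missing entries as NaN; observed allele
  frequencies are derived, never stored.
* :class:`PhenotypeTable` — long-format records (individual, site,
  replication, trait, value); each individual grows on exactly one site.

Files are UTF-8 CSV or TSV; the delimiter is sniffed from the header line.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PedigreeTable",
    "GenotypeMatrix",
    "PhenotypeTable",
    "ValidationError",
    "read_pedigree",
    "write_pedigree",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_matrix",
    "write_matrix",
    "read_vcf_genotypes",
]

#: tokens accepted as "parent unknown" in pedigree files
DEFAULT_UNKNOWN_TOKENS = ("NA", "0", "")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


@dataclasses.dataclass(frozen=True)
class PedigreeTable:
    """Validated pedigree: unique ids, acyclic, parents listed before use.

    ``dam``/``sire`` entries are individual ids or ``None`` (unknown).
    ``ids`` is stored in a topological order (parents before offspring).
    """

    ids: tuple[str, ...]
    dam: tuple[str | None, ...]
    sire: tuple[str | None, ...]

    def __post_init__(self):
        _validate_pedigree(self.ids, self.dam, self.sire)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def parents_of(self, individual: str) -> tuple[str | None, str | None]:
        k = self.index[individual]
        return self.dam[k], self.sire[k]

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(
            i for i, d, s in zip(self.ids, self.dam, self.sire) if d is None and s is None
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "dam": self.dam, "sire": self.sire})

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str | None, str | None]]
    ) -> "PedigreeTable":
        """Build from (id, dam, sire) rows; implicit parents are added as founders
        and rows are re-ordered topologically."""
        rows = [(str(i), d, s) for i, d, s in records]
        known = {r[0] for r in rows}
        implicit = []
        for _, d, s in rows:
            for p in (d, s):
                if p is not None and p not in known:
                    known.add(p)
                    implicit.append((p, None, None))
        rows = implicit + rows
        order = _toposort(rows)
        ids = tuple(r[0] for r in order)
        return cls(ids, tuple(r[1] for r in order), tuple(r[2] for r in order))


def _toposort(rows):
    g = nx.DiGraph()
    g.add_nodes_from(r[0] for r in rows)
    by_id = {r[0]: r for r in rows}
    for i, d, s in rows:
        for p in (d, s):
            if p is not None:
                if p == i:
                    raise ValidationError(f"individual {i!r} is its own parent")
                g.add_edge(p, i)
    if not nx.is_directed_acyclic_graph(g):
        cyc = nx.find_cycle(g)
        raise ValidationError(f"pedigree contains a cycle: {cyc}")
    # stable topological order: lexicographic tie-break for determinism
    return [by_id[i] for i in nx.lexicographical_topological_sort(g)]


def _validate_pedigree(ids, dam, sire):
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)
        dup = dup[dup.duplicated()].tolist()
        raise ValidationError(f"duplicate individual ids: {dup}")
    seen: set[str] = set()
    for i, d, s in zip(ids, dam, sire):
        for p in (d, s):
            if p is not None:
                if p == i:
                    raise ValidationError(f"individual {i!r} is its own parent")
                if p not in seen:
                    raise ValidationError(
                        f"parent {p!r} of {i!r} not listed before its offspring"
                    )
        seen.add(i)


def read_pedigree(
    path: str | Path, unknown_token: str | Sequence[str] = DEFAULT_UNKNOWN_TOKENS
) -> PedigreeTable:
    """Read a pedigree CSV/TSV with columns id, dam, sire.

    ``unknown_token`` may be one token or several; matching entries are
    normalised to the single internal sentinel ``None``. Parents that are
    referenced but have no row of their own are added as founders.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise ValidationError("pedigree file needs three columns: id, dam, sire")
    tokens = {unknown_token} if isinstance(unknown_token, str) else set(unknown_token)

    def norm(v: str) -> str | None:
        v = v.strip()
        return None if v in tokens else v

    rows = [
        (r[0].strip(), norm(r[1]), norm(r[2]))
        for r in df.iloc[:, :3].itertuples(index=False)
    ]
    return PedigreeTable.from_records(rows)


def write_pedigree(ped: PedigreeTable, path: str | Path, unknown_token: str = "NA") -> None:
    df = ped.to_frame().fillna(unknown_token)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes


@dataclasses.dataclass
class GenotypeMatrix:
    """n × m matrix of alternate-allele counts; missing entries are NaN.

    Allele frequencies ``p`` are computed over non-missing entries only.
    Coding is taken from the file as-is (no ref/alt flipping): the genomic
    relationship matrix is invariant to a consistent per-SNP coding choice.
    """

    ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray  # float array, NaN = missing

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.ids), len(self.snp_ids)):
            raise ValidationError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.ids)} ids x {len(self.snp_ids)} SNPs"
            )
        ok = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        # imputed matrices carry fractional codes in [0, 2]
        ok |= (self.codes >= 0) & (self.codes <= 2)
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype code out of range at individual {self.ids[bad[0]]!r}, "
                f"SNP {self.snp_ids[bad[1]]!r}: {self.codes[tuple(bad)]!r}"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate individual ids in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate SNP ids in genotype matrix")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def p(self) -> np.ndarray:
        """Observed alternate-allele frequency per SNP (non-missing entries only)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.codes, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.p
        return np.minimum(p, 1.0 - p)

    @property
    def monomorphic(self) -> np.ndarray:
        """Boolean mask of SNPs with no observed variation."""
        p = self.p
        return (p <= 0.0) | (p >= 1.0)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: k for k, s in enumerate(self.snp_ids)}
        cols = [idx[s] for s in snp_ids]
        return GenotypeMatrix(list(self.ids), list(snp_ids), self.codes[:, cols].copy())

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: k for k, s in enumerate(self.ids)}
        rows = [idx[s] for s in ids]
        return GenotypeMatrix(list(ids), list(self.snp_ids), self.codes[rows, :].copy())


def read_genotypes(
    path: str | Path,
    missing_token: str = "NA",
    max_missing: float = 0.5,
) -> GenotypeMatrix:
    """Read an id + one-column-per-SNP table of 0/1/2 codes.

    SNPs with a missing fraction above ``max_missing`` are dropped at read
    time (mean imputation degrades beyond that), with the dropped ids
    recorded on the returned object as ``dropped_snps``.
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep=_sniff_sep(path), dtype=str, keep_default_na=False, index_col=0
    )
    codes = np.full(df.shape, np.nan)
    vals = df.to_numpy()
    for tok, rep in ((missing_token, np.nan), ("0", 0.0), ("1", 1.0), ("2", 2.0)):
        codes[vals == tok] = rep
    unknown = ~(np.isin(vals, (missing_token, "0", "1", "2")))
    if unknown.any():
        r, c = np.argwhere(unknown)[0]
        raise ValidationError(
            f"invalid genotype code {vals[r, c]!r} for individual "
            f"{df.index[r]!r}, SNP {df.columns[c]!r} (expected 0/1/2/{missing_token})"
        )
    miss_frac = np.isnan(codes).mean(axis=0)
    keep = miss_frac <= max_missing
    gm = GenotypeMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns[keep]],
        codes[:, keep],
    )
    gm.dropped_snps = [str(c) for c in df.columns[~keep]]
    return gm


def write_genotypes(gm: GenotypeMatrix, path: str | Path, missing_token: str = "NA") -> None:
    df = pd.DataFrame(gm.codes, index=gm.ids, columns=gm.snp_ids)
    if not df.isna().to_numpy().any() and np.allclose(gm.codes, np.round(gm.codes)):
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="id", na_rep=missing_token)


def read_vcf_genotypes(path: str | Path) -> GenotypeMatrix:
    """Optional VCF ingestion: GT field converted to alternate-allele counts."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    snp_ids, rows = [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=float)  # 0=hom ref,1=het,2=unknown,3=hom alt
        row = np.where(gt == 3, 2.0, gt)
        row[gt == 2] = np.nan
        rows.append(row)
    return GenotypeMatrix(ids, snp_ids, np.column_stack(rows) if rows else np.empty((len(ids), 0)))


# ---------------------------------------------------------------------------
# phenotypes


@dataclasses.dataclass
class PhenotypeTable:
    """Long-format phenotypes with columns id, site, rep, trait, value."""

    data: pd.DataFrame
    traits: tuple[str, ...]

    REQUIRED = ("id", "site", "rep", "trait", "value")

    def __post_init__(self):
        df = self.data
        missing_cols = [c for c in self.REQUIRED if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"phenotype table lacks columns {missing_cols}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        for c in ("id", "site", "rep", "trait"):
            df[c] = df[c].astype(str)
        df["value"] = pd.to_numeric(df["value"])
        bad = ~df["trait"].isin(self.traits)
        if bad.any():
            rows = df.index[bad].tolist()
            raise ValidationError(
                f"traits outside declared list {self.traits} at rows {rows[:10]}"
            )
        dup = df.duplicated(subset=["id", "site", "trait"])
        if dup.any():
            raise ValidationError(
                f"duplicate (individual, site, trait) rows: {df.index[dup].tolist()[:10]}"
            )
        nsites = df.groupby("id")["site"].nunique()
        multi = nsites[nsites > 1]
        if len(multi):
            raise ValidationError(
                f"individuals recorded on more than one site: {multi.index.tolist()[:10]}"
            )
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].unique())

    @property
    def individuals(self) -> list[str]:
        return sorted(self.data["id"].unique())

    def site_of(self) -> dict[str, str]:
        return dict(self.data.drop_duplicates("id")[["id", "site"]].itertuples(index=False))


def read_phenotypes(path: str | Path, trait_list: Sequence[str]) -> PhenotypeTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    return PhenotypeTable(df, tuple(trait_list))


def write_phenotypes(pt: PhenotypeTable, path: str | Path) -> None:
    pt.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# relationship-matrix serialisation (TSV with id header row/column)


def write_matrix(ids: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", index_label="id"
    )


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(i) for i in df.index], df.to_numpy(dtype=float)
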