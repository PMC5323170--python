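"""Mutation-catalogue index and the 20/20 gene-role classifier.

The catalogue mimics a COSMIC-style export: one row per (gene, protein
change) with the number of tumor samples in which it was observed. Genes are
classified as tumor suppressor (TSG) or oncogene by the 20/20 rule: a gene
whose recorded mutations are >= 20% inactivating (nonsense, frameshift
indel, splice site) is a TSG; a gene with >= 20% of its mutations being
missense at recurrent residues — and almost no truncating burden — is an
oncogene. Genes with sparse catalogue evidence stay unclassified rather than
being noisily labelled.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import RowIssue, SomaticVariant, TableFormatError, VariantClass, _opt_int, _read_tsv


class Role(str, enum.Enum):
    TSG = "TSG"
    ONCOGENE = "oncogene"
    UNCLASSIFIED = "unclassified"


#: variant classes counted as inactivating for the 20/20 rule;
#: in-frame indels are deliberately not inactivating
INACTIVATING_CLASSES = frozenset(
    {VariantClass.NONSENSE, VariantClass.FRAMESHIFT_INDEL, VariantClass.SPLICE_SITE}
)


@dataclass(frozen=True)
class CatalogEntry:
    gene: str
    protein_pos: int | None
    mutation_class: VariantClass
    protein_change: str
    n_samples: int
    hematopoietic: bool

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.mutation_class is VariantClass.MISSENSE and self.protein_pos is None:
            raise ValueError("missense catalogue entries require a protein position")
        if self.protein_pos is not None and self.protein_pos < 1:
            raise ValueError(f"protein_pos must be >= 1, got {self.protein_pos}")


@dataclass(frozen=True)
class GeneRole:
    gene: str
    role: Role
    frac_inactivating: float
    frac_recurrent_missense: float
    n_catalog_mutations: int


@dataclass(frozen=True)
class RoleParams:
    """Thresholds of the 20/20 classifier (published 20% cut-offs)."""

    tsg_frac: float = 0.20
    onc_frac: float = 0.20
    onc_max_inact: float = 0.05
    recurrent_min: int = 3
    min_catalog_n: int = 10


class MutationCatalog:
    """Index over catalogue entries supporting gene and protein-change lookup.

    Duplicate (gene, protein_change) rows are aggregated by summing their
    sample counts, so classification is invariant under splitting an entry
    into parts.
    """

    def __init__(self, entries: Iterable[CatalogEntry]):
        self._by_gene: dict[str, list[CatalogEntry]] = defaultdict(list)
        merged: dict[tuple[str, str, VariantClass, int | None, bool], int] = defaultdict(int)
        for e in entries:
            merged[(e.gene, e.protein_change, e.mutation_class,
                    e.protein_pos, e.hematopoietic)] += e.n_samples
        for (gene, pc, mclass, ppos, hema), n in sorted(
            merged.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
        ):
            self._by_gene[gene].append(
                CatalogEntry(gene, ppos, mclass, pc, n, hema)
            )
        self._pc_counts: dict[tuple[str, str], int] = defaultdict(int)
        self._pc_counts_hema: dict[tuple[str, str], int] = defaultdict(int)
        for gene, ents in self._by_gene.items():
            for e in ents:
                self._pc_counts[(gene, e.protein_change)] += e.n_samples
                if e.hematopoietic:
                    self._pc_counts_hema[(gene, e.protein_change)] += e.n_samples

    @classmethod
    def from_tsv(cls, path: str | Path) -> tuple["MutationCatalog", list[RowIssue]]:
        df = _read_tsv(path)
        required = ["gene", "protein_pos", "mutation_class", "protein_change",
                    "n_samples", "hematopoietic"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
        entries: list[CatalogEntry] = []
        issues: list[RowIssue] = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                n = _opt_int(str(row.n_samples), "n_samples")
                if n is None:
                    raise ValueError("missing n_samples")
                entries.append(CatalogEntry(
                    gene=str(row.gene).strip(),
                    protein_pos=_opt_int(str(row.protein_pos), "protein_pos"),
                    mutation_class=VariantClass(str(row.mutation_class).strip()),
                    protein_change=str(row.protein_change).strip(),
                    n_samples=n,
                    hematopoietic=str(row.hematopoietic).strip().lower()
                    in ("y", "true", "1"),
                ))
            except ValueError as exc:
                issues.append(RowIssue(i, str(exc)))
        return cls(entries), issues

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "gene": e.gene,
                "protein_pos": "" if e.protein_pos is None else e.protein_pos,
                "mutation_class": e.mutation_class.value,
                "protein_change": e.protein_change,
                "n_samples": e.n_samples,
                "hematopoietic": "Y" if e.hematopoietic else "N",
            }
            for gene in sorted(self._by_gene)
            for e in self._by_gene[gene]
        ]
        pd.DataFrame(
            rows,
            columns=["gene", "protein_pos", "mutation_class", "protein_change",
                     "n_samples", "hematopoietic"],
        ).to_csv(path, sep="\t", index=False)

    @property
    def genes(self) -> list[str]:
        return sorted(self._by_gene)

    def entries_for(self, gene: str) -> list[CatalogEntry]:
        return list(self._by_gene.get(gene, []))

    def gene_total(self, gene: str) -> int:
        return sum(e.n_samples for e in self._by_gene.get(gene, []))

    def protein_change_count(
        self, gene: str, protein_change: str, *, hematopoietic_only: bool = False
    ) -> int:
        if hematopoietic_only:
            return self._pc_counts_hema.get((gene, protein_change), 0)
        return self._pc_counts.get((gene, protein_change), 0)


def classify_gene_role(
    gene: str,
    catalog: MutationCatalog,
    params: RoleParams = RoleParams(),
) -> GeneRole:
    """Apply the 20/20 rule to one gene's catalogue record.

    ``frac_inactivating`` is the sample-count fraction of truncating
    mutations; ``frac_recurrent_missense`` the fraction of missense samples
    at residues hit in >= ``recurrent_min`` samples. A gene absent from the
    catalogue, or with fewer than ``min_catalog_n`` recorded samples, is
    unclassified.
    """
    entries = catalog.entries_for(gene)
    total = sum(e.n_samples for e in entries)
    if total == 0:
        return GeneRole(gene, Role.UNCLASSIFIED, 0.0, 0.0, 0)
    inact = sum(e.n_samples for e in entries if e.mutation_class in INACTIVATING_CLASSES)
    residue_counts: dict[int, int] = defaultdict(int)
    for e in entries:
        if e.mutation_class is VariantClass.MISSENSE:
            residue_counts[e.protein_pos] += e.n_samples
    recurrent_missense = sum(
        n for n in residue_counts.values() if n >= params.recurrent_min
    )
    frac_inact = inact / total
    frac_rec = recurrent_missense / total
    if total < params.min_catalog_n:
        role = Role.UNCLASSIFIED
    elif frac_inact >= params.tsg_frac:
        role = Role.TSG
    elif frac_rec >= params.onc_frac and frac_inact < params.onc_max_inact:
        role = Role.ONCOGENE
    else:
        role = Role.UNCLASSIFIED
    return GeneRole(gene, role, frac_inact, frac_rec, total)


def is_recurrent(
    variant: SomaticVariant,
    catalog: MutationCatalog,
    min_count: int = 2,
    *,
    hematopoietic_only: bool = False,
) -> tuple[bool, int]:
    """Whether the identical (gene, protein change) is recurrent in the
    catalogue, i.e. recorded in >= ``min_count`` samples."""
    if not variant.protein_change:
        return (False, 0)
    n = catalog.protein_change_count(
        variant.gene, variant.protein_change, hematopoietic_only=hematopoietic_only
    )
    return (n >= min_count, n)


def is_novel(variant: SomaticVariant, catalog: MutationCatalog) -> bool:
    """Novel iff the (gene, protein change) is absent from the catalogue and
    the variant carries no catalogue cross-reference id. Novelty is
    independent of variant class."""
    if variant.catalog_id:
        return False
    return catalog.protein_change_count(variant.gene, variant.protein_change) == 0
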