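"""Cohort-level recurrence matrices and association statistics.

Builds the gene-by-patient recurrence ("oncoprint") matrix from driver
calls, aggregates it to pathways, derives 2x2 contingency tables from
clinical groupings, and runs the two-sided Fisher exact test on each named
table. Frequencies are patient-level: a patient with two hits in one gene
counts once for that gene.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .io import CnvDirection, CnvEvent, PatientRecord, SomaticVariant
from .rules import DriverCall
from .stats import ContingencyTable2x2, StatsUsageError, bh_adjust, fisher_exact_two_sided

UNASSIGNED_PATHWAY = "unassigned"


class EventClass(str, enum.Enum):
    SNV_INDEL = "snv_indel"
    CNV_LOSS = "cnv_loss"
    CNV_GAIN = "cnv_gain"


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Gene x patient grid of alteration classes.

    Genes are ordered by descending number of mutated patients, ties broken
    alphabetically; patients keep the clinical-table order. Cells map
    (gene, patient) to the set of event classes seen.
    """

    genes: tuple[str, ...]
    patients: tuple[str, ...]
    cells: Mapping[tuple[str, str], frozenset[EventClass]]

    def mutated_patients(self, gene: str) -> list[str]:
        return [p for p in self.patients if (gene, p) in self.cells]

    def to_frame(self) -> pd.DataFrame:
        """Genes as rows, patients as columns, cells as ';'-joined classes."""
        data = {
            p: [
                ";".join(sorted(c.value for c in self.cells.get((g, p), frozenset())))
                for g in self.genes
            ]
            for p in self.patients
        }
        return pd.DataFrame(data, index=list(self.genes))


@dataclass(frozen=True)
class PathwayMatrix:
    pathways: tuple[str, ...]  # ordered by member-gene count descending
    patients: tuple[str, ...]
    altered: Mapping[str, frozenset[str]]  # pathway -> altered patients
    member_genes: Mapping[str, tuple[str, ...]]

    def pathway_frequency(self, pathway: str) -> float:
        if pathway not in self.altered:
            raise KeyError(f"unknown pathway {pathway!r}")
        if not self.patients:
            return 0.0
        return len(self.altered[pathway]) / len(self.patients)


@dataclass(frozen=True)
class AssociationResult:
    name: str
    table: ContingencyTable2x2
    p: float
    test: str = "fisher_exact_two_sided"
    q: float | None = None


def _event_class(event: SomaticVariant | CnvEvent) -> EventClass:
    if isinstance(event, CnvEvent):
        if event.direction is CnvDirection.GAIN:
            return EventClass.CNV_GAIN
        return EventClass.CNV_LOSS
    return EventClass.SNV_INDEL


def build_matrix(
    calls: Sequence[DriverCall], patients: Sequence[PatientRecord]
) -> RecurrenceMatrix:
    """Deterministic recurrence matrix; zero-call patients keep their column."""
    patient_ids = tuple(p.patient_id for p in patients)
    known = set(patient_ids)
    cells: dict[tuple[str, str], set[EventClass]] = defaultdict(set)
    for c in calls:
        if c.patient_id not in known:
            raise KeyError(f"call references unknown patient {c.patient_id!r}")
        cells[(c.gene, c.patient_id)].add(_event_class(c.event))
    gene_counts: dict[str, int] = defaultdict(int)
    for gene, _pid in cells:
        gene_counts[gene] += 1
    genes = tuple(sorted(gene_counts, key=lambda g: (-gene_counts[g], g)))
    return RecurrenceMatrix(
        genes=genes,
        patients=patient_ids,
        cells={k: frozenset(v) for k, v in cells.items()},
    )


def gene_frequency(matrix: RecurrenceMatrix, gene: str) -> float:
    """Fraction of patients altered in ``gene`` (a patient counts once)."""
    if gene not in matrix.genes:
        raise KeyError(f"gene {gene!r} not in matrix")
    return len(matrix.mutated_patients(gene)) / len(matrix.patients)


def pathway_aggregate(
    matrix: RecurrenceMatrix, pathway_map: Mapping[str, str]
) -> PathwayMatrix:
    """Collapse genes to pathways; a patient is pathway-altered iff altered
    in any member gene. Genes without a mapping fall into "unassigned"."""
    members: dict[str, list[str]] = defaultdict(list)
    for g in matrix.genes:
        members[pathway_map.get(g, UNASSIGNED_PATHWAY)].append(g)
    if not matrix.genes:
        members[UNASSIGNED_PATHWAY] = []
    altered: dict[str, frozenset[str]] = {}
    for pw, genes in members.items():
        hit = {p for g in genes for p in matrix.mutated_patients(g)}
        altered[pw] = frozenset(hit)
    ordered = tuple(sorted(members, key=lambda pw: (-len(members[pw]), pw)))
    return PathwayMatrix(
        pathways=ordered,
        patients=matrix.patients,
        altered=altered,
        member_genes={pw: tuple(g) for pw, g in members.items()},
    )


def build_contingency(
    patients: Sequence[PatientRecord],
    group_fn: Callable[[PatientRecord], str | None],
    event_fn: Callable[[PatientRecord], bool],
    levels: tuple[str, str],
) -> tuple[ContingencyTable2x2, list[PatientRecord]]:
    """Cross-tabulate patients into a 2x2 table.

    ``group_fn`` maps a patient to one of ``levels`` (or anything else /
    ``None`` to exclude them); ``event_fn`` gives the column factor. Returns
    the table (a = level1 & event, b = level1 & not event, c/d likewise for
    level2) together with the excluded patients.
    """
    l1, l2 = levels
    a = b = c = d = 0
    excluded: list[PatientRecord] = []
    for p in patients:
        g = group_fn(p)
        if g == l1:
            if event_fn(p):
                a += 1
            else:
                b += 1
        elif g == l2:
            if event_fn(p):
                c += 1
            else:
                d += 1
        else:
            excluded.append(p)
    if a + b + c + d == 0:
        raise StatsUsageError("every patient was excluded from the contingency table")
    return ContingencyTable2x2(a, b, c, d), excluded


def association_report(
    named_tables: Sequence[tuple[str, ContingencyTable2x2]],
    *,
    adjust: bool = False,
) -> list[AssociationResult]:
    """One Fisher exact result per named table, in input order.

    No multiplicity adjustment by default; ``adjust=True`` attaches BH
    q-values as an extra column.
    """
    ps = [fisher_exact_two_sided(t) for _, t in named_tables]
    qs = bh_adjust(ps) if adjust and ps else [None] * len(ps)
    return [
        AssociationResult(name=name, table=t, p=p, q=q)
        for (name, t), p, q in zip(named_tables, ps, qs)
    ]


def association_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {
            "name": r.name,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "p": r.p, "test": r.test,
        }
        if r.q is not None:
            row["q"] = r.q
        rows.append(row)
    return pd.DataFrame(rows)
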