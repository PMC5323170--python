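"""Recurrence matrix, pathway aggregation and association tests."""

from __future__ import annotations

import pytest

from driverlens.cohort import (
    association_report,
    build_contingency,
    build_matrix,
    gene_frequency,
    pathway_aggregate,
)
from driverlens.io import (
    CnvDirection,
    CnvEvent,
    Group,
    PatientRecord,
    Sex,
    SomaticVariant,
    VariantClass,
)
from driverlens.rules import DriverCall, Evidence, Rule
from driverlens.stats import ContingencyTable2x2, StatsUsageError, fisher_exact_two_sided


def _call(pid, gene, kind="snv"):
    if kind == "snv":
        event = SomaticVariant(
            patient_id=pid, gene=gene, chrom="1", pos=abs(hash((pid, gene))) % 1000 + 1,
            ref="A", alt="T", variant_class=VariantClass.MISSENSE,
            alt_count=5, depth=10,
        )
    else:
        direction = CnvDirection.GAIN if kind == "gain" else CnvDirection.LOSS
        event = CnvEvent(pid, "9", 1, 100, direction, (gene,))
    return DriverCall(
        patient_id=pid, gene=gene, event=event, rule=Rule.I,
        rules_satisfied=(Rule.I,), evidence=frozenset({Evidence.CHASM_DRIVER}),
        novel=False,
    )


def _patients(n, prefix="P"):
    return [PatientRecord(f"{prefix}{i}", Sex.M, Group.MATURE, False)
            for i in range(n)]


class TestMatrix:
    def test_gene_ordering_by_mutated_patients_then_alpha(self):
        patients = _patients(3)
        calls = [
            _call("P0", "BBB"), _call("P1", "BBB"),
            _call("P0", "AAA"), _call("P2", "CCC"),
        ]
        m = build_matrix(calls, patients)
        assert m.genes == ("BBB", "AAA", "CCC")
        assert m.patients == ("P0", "P1", "P2")

    def test_zero_call_patient_keeps_column(self):
        m = build_matrix([_call("P0", "A")], _patients(3))
        assert m.patients == ("P0", "P1", "P2")

    def test_empty_calls_matrix_has_all_patients_no_genes(self):
        m = build_matrix([], _patients(2))
        assert m.genes == () and m.patients == ("P0", "P1")

    def test_orphan_patient_reference_is_error(self):
        with pytest.raises(KeyError):
            build_matrix([_call("ZZZ", "A")], _patients(2))

    def test_event_classes_accumulate_per_cell(self):
        m = build_matrix(
            [_call("P0", "A", "snv"), _call("P0", "A", "loss")], _patients(1)
        )
        cell = m.cells[("A", "P0")]
        assert {c.value for c in cell} == {"snv_indel", "cnv_loss"}

    def test_repeated_invocation_identical(self):
        calls = [_call("P0", "A"), _call("P1", "B")]
        patients = _patients(2)
        assert build_matrix(calls, patients) == build_matrix(calls, patients)


class TestFrequencies:
    def test_patient_level_frequency_half_cohort(self):
        patients = _patients(30)
        calls = [_call(f"P{i}", "NOTCH1") for i in range(15)]
        # second hit in the same patient must not change the frequency
        calls.append(_call("P0", "NOTCH1", "loss"))
        m = build_matrix(calls, patients)
        assert gene_frequency(m, "NOTCH1") == pytest.approx(0.50)

    def test_four_of_thirty(self):
        patients = _patients(30)
        m = build_matrix([_call(f"P{i}", "FBXW7") for i in range(4)], patients)
        assert gene_frequency(m, "FBXW7") == pytest.approx(0.1333, abs=5e-5)

    def test_all_patients_mutated(self):
        patients = _patients(5)
        m = build_matrix([_call(f"P{i}", "X") for i in range(5)], patients)
        assert gene_frequency(m, "X") == 1.0

    def test_unknown_gene_rejected(self):
        m = build_matrix([_call("P0", "A")], _patients(1))
        with pytest.raises(KeyError):
            gene_frequency(m, "NOPE")


class TestPathways:
    def test_patient_counted_once_per_pathway(self):
        patients = _patients(4)
        calls = [_call("P0", "A"), _call("P0", "B"), _call("P1", "A")]
        m = build_matrix(calls, patients)
        pw = pathway_aggregate(m, {"A": "notch", "B": "notch"})
        assert pw.altered["notch"] == {"P0", "P1"}
        assert pw.pathway_frequency("notch") == pytest.approx(0.5)

    def test_unmapped_genes_fall_into_unassigned(self):
        m = build_matrix([_call("P0", "A")], _patients(1))
        pw = pathway_aggregate(m, {})
        assert pw.pathways == ("unassigned",)
        assert pw.altered["unassigned"] == {"P0"}

    def test_ordering_by_member_gene_count(self):
        calls = [_call("P0", g) for g in ("A", "B", "C")]
        m = build_matrix(calls, _patients(1))
        pw = pathway_aggregate(m, {"A": "big", "B": "big", "C": "small"})
        assert pw.pathways == ("big", "small")

    def test_gene_frequency_never_exceeds_its_pathway_frequency(self):
        calls = [_call("P0", "A"), _call("P1", "B"), _call("P2", "A")]
        m = build_matrix(calls, _patients(4))
        pw = pathway_aggregate(m, {"A": "pw", "B": "pw"})
        for g in ("A", "B"):
            assert gene_frequency(m, g) <= pw.pathway_frequency("pw") + 1e-12


class TestContingency:
    def test_subtype_by_relapse_reproduces_published_table(self, table1_patients):
        table, excluded = build_contingency(
            table1_patients,
            lambda p: "immature" if p.immature_inclusive
            else ("mature" if p.group is Group.MATURE else None),
            lambda p: p.relapse,
            ("immature", "mature"),
        )
        assert table.as_tuple() == (5, 2, 1, 12)
        assert len(excluded) == 10  # unclassified patients leave subtype tests

    def test_sex_by_mutation_reproduces_published_table(self, table1_patients):
        mutated_males = {p.patient_id for p in table1_patients
                         if p.sex is Sex.M}  # pick 5 males + 3 females below
        males = sorted(mutated_males)[:5]
        females = sorted(p.patient_id for p in table1_patients
                         if p.sex is Sex.F)[:3]
        mutated = set(males) | set(females)
        table, excluded = build_contingency(
            table1_patients,
            lambda p: p.sex.value,
            lambda p: p.patient_id in mutated,
            ("M", "F"),
        )
        assert table.as_tuple() == (5, 15, 3, 7)
        assert excluded == []

    def test_cell_sums_equal_non_excluded_patients(self, table1_patients):
        table, excluded = build_contingency(
            table1_patients, lambda p: p.sex.value, lambda p: p.relapse, ("M", "F")
        )
        assert table.total + len(excluded) == len(table1_patients)

    def test_no_events_gives_empty_event_column(self):
        table, _ = build_contingency(
            _patients(6), lambda p: "g", lambda p: False, ("g", "h")
        )
        assert table.a == 0 and table.c == 0

    def test_all_excluded_is_usage_error(self):
        with pytest.raises(StatsUsageError):
            build_contingency(_patients(3), lambda p: None, lambda p: True,
                              ("x", "y"))


class TestAssociationReport:
    def test_published_association_pvalues(self):
        named = [
            ("cdkn2a_vs_relapse", ContingencyTable2x2(1, 15, 7, 7)),
            ("immature_vs_relapse", ContingencyTable2x2(5, 2, 1, 12)),
            ("phf6_vs_sex", ContingencyTable2x2(5, 15, 3, 7)),
        ]
        results = association_report(named)
        assert [r.name for r in results] == [n for n, _ in named]
        assert [round(r.p, 4) for r in results] == [0.0121, 0.0072, 1.0000]
        assert all(r.q is None for r in results)

    def test_matches_direct_fisher_calls(self):
        import numpy as np
        rng = np.random.default_rng(17)
        named = []
        for i in range(10):
            cells = [int(x) for x in rng.integers(0, 12, size=4)]
            if sum(cells) == 0:
                cells[0] = 1
            named.append((f"t{i}", ContingencyTable2x2(*cells)))
        for r, (_, t) in zip(association_report(named), named):
            assert r.p == fisher_exact_two_sided(t)

    def test_optional_bh_column(self):
        named = [("a", ContingencyTable2x2(8, 2, 1, 9)),
                 ("b", ContingencyTable2x2(5, 5, 5, 5))]
        results = association_report(named, adjust=True)
        assert results[0].q is not None
        assert results[0].q >= results[0].p
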