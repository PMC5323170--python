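"""Population prefilter and nomination-rule tests."""

from __future__ import annotations

import numpy as np
import pytest

from driverlens.catalog import GeneRole, MutationCatalog, Role, classify_gene_role
from driverlens.io import CnvDirection, CnvEvent, SomaticVariant, VariantClass
from driverlens.predictors import PredictorCalls, PolyphenCategory, chasm_calls
from driverlens.rules import (
    Evidence,
    Rule,
    RuleEngineError,
    nominate,
    prefilter_population,
    summarize_novelty,
)

from _oracles import driver_calls_as_records, nominate_oracle, random_rule_inputs


def _variant(gene="G1", vclass=VariantClass.MISSENSE, pid="P1", pos=100,
             protein_change="p.A10T", **kw):
    base = dict(
        patient_id=pid, gene=gene, chrom="1", pos=pos, ref="A", alt="T",
        variant_class=vclass, protein_change=protein_change,
        alt_count=5, depth=10,
    )
    base.update(kw)
    return SomaticVariant(**base)


def _role(gene, role):
    return GeneRole(gene, role, 0.0, 0.0, 50)


EMPTY_CATALOG = MutationCatalog([])


class TestPrefilter:
    def test_strictly_above_threshold_removed(self):
        kept, removed = prefilter_population([_variant(af_exac=0.02)])
        assert kept == [] and len(removed) == 1

    def test_exact_threshold_kept(self):
        kept, removed = prefilter_population([_variant(af_exac=0.01)])
        assert len(kept) == 1 and removed == []

    def test_missing_frequencies_keep_variant(self):
        kept, removed = prefilter_population([_variant()])
        assert len(kept) == 1 and removed == []

    def test_any_of_three_sources_can_remove(self):
        for field in ("af_1000g", "af_esp", "af_exac"):
            kept, removed = prefilter_population([_variant(**{field: 0.5})])
            assert kept == []


class TestNominate:
    def test_chasm_driver_alone_fires_rule_i(self):
        v = _variant()
        calls = [PredictorCalls(chasm_q=0.15, chasm_driver=True)]
        roles = {"G1": _role("G1", Role.UNCLASSIFIED)}
        (call,) = nominate([v], [], calls, roles, EMPTY_CATALOG, [])
        assert call.rule is Rule.I
        assert call.evidence == {Evidence.CHASM_DRIVER}
        assert call.novel  # absent from the empty catalogue

    def test_tsg_location_rescues_undamaging_nonsense(self):
        v = _variant(vclass=VariantClass.NONSENSE, sift=0.3)
        calls = [PredictorCalls(sift_damaging=False)]
        roles = {"G1": _role("G1", Role.TSG)}
        (call,) = nominate([v], [], calls, roles, EMPTY_CATALOG, [])
        assert call.rule is Rule.II
        assert call.evidence == {Evidence.IN_TSG}

    def test_recurrent_new_gene_emits_all_events_under_rule_iv(self):
        variants = [
            _variant(gene="U2AF1", pid=p, pos=44_514_000, protein_change="p.R35L")
            for p in ("P1", "P2", "P3")
        ]
        calls = [PredictorCalls()] * 3
        roles = {"U2AF1": _role("U2AF1", Role.UNCLASSIFIED)}
        out = nominate(variants, [], calls, roles, EMPTY_CATALOG, ["NOTCH1"])
        assert len(out) == 3
        assert all(c.rule is Rule.IV for c in out)
        assert all(Evidence.COHORT_RECURRENT_NEW_GENE in c.evidence for c in out)

    def test_gain_in_oncogene_fires_rule_iii(self):
        cnv = CnvEvent("P1", "14", 100, 200, CnvDirection.GAIN, ("JAG2",))
        roles = {"JAG2": _role("JAG2", Role.ONCOGENE)}
        (call,) = nominate([], [cnv], [], roles, EMPTY_CATALOG, ["JAG2"])
        assert call.rule is Rule.III
        assert call.evidence == {Evidence.GAIN_IN_ONCOGENE}

    def test_loss_in_tsg_fires_rule_iii_per_gene(self):
        cnv = CnvEvent("P1", "9", 100, 200, CnvDirection.BIALLELIC_LOSS,
                       ("CDKN2A", "CDKN2B", "MTAP"))
        roles = {
            "CDKN2A": _role("CDKN2A", Role.TSG),
            "CDKN2B": _role("CDKN2B", Role.TSG),
            "MTAP": _role("MTAP", Role.UNCLASSIFIED),
        }
        out = nominate([], [cnv], [], roles, EMPTY_CATALOG,
                       ["CDKN2A", "CDKN2B", "MTAP"])
        assert sorted(c.gene for c in out) == ["CDKN2A", "CDKN2B"]

    def test_synonymous_never_nominated_by_rules_i_to_iii(self):
        v = _variant(vclass=VariantClass.SYNONYMOUS)
        calls = [PredictorCalls(sift_damaging=True, chasm_driver=True,
                                mutationtaster_damaging=True,
                                polyphen_category=PolyphenCategory.DAMAGING)]
        roles = {"G1": _role("G1", Role.TSG)}
        out = nominate([v], [], calls, roles, EMPTY_CATALOG, ["G1"])
        assert out == []

    def test_lowest_rule_is_primary_when_several_fire(self):
        # recurrent missense hotspot in a new gene hit in two patients:
        # rule i (catalogue recurrence) and rule iv both fire
        from driverlens.catalog import CatalogEntry
        cat = MutationCatalog(
            [CatalogEntry("GX", 35, VariantClass.MISSENSE, "p.R35L", 5, True)]
        )
        variants = [_variant(gene="GX", pid=p, protein_change="p.R35L")
                    for p in ("P1", "P2")]
        calls = [PredictorCalls()] * 2
        roles = {"GX": _role("GX", Role.UNCLASSIFIED)}
        out = nominate(variants, [], calls, roles, cat, [])
        assert all(c.rule is Rule.I for c in out)
        assert all(c.rules_satisfied == (Rule.I, Rule.IV) for c in out)
        assert all(Evidence.COSMIC_RECURRENT in c.evidence for c in out)

    def test_missing_role_is_internal_error(self):
        with pytest.raises(RuleEngineError, match="GeneRole"):
            nominate([_variant()], [], [PredictorCalls()], {}, EMPTY_CATALOG, [])

    def test_deterministic_under_input_permutation(self):
        rng = np.random.default_rng(55)
        variants, cnvs, calls, roles, catalog, known = random_rule_inputs(rng, 200, 20)
        ref = nominate(variants, cnvs, calls, roles, catalog, known)
        order = rng.permutation(len(variants))
        shuffled_v = [variants[i] for i in order]
        shuffled_c = [calls[i] for i in order]
        got = nominate(shuffled_v, list(reversed(cnvs)), shuffled_c, roles,
                       catalog, known)
        assert got == ref

    def test_adding_damaging_evidence_never_removes_a_call(self):
        rng = np.random.default_rng(77)
        variants, cnvs, calls, roles, catalog, known = random_rule_inputs(rng, 300, 0)
        before = {r[:4] for r in driver_calls_as_records(
            nominate(variants, cnvs, calls, roles, catalog, known))}
        import dataclasses
        boosted = [
            dataclasses.replace(c, sift_damaging=True, chasm_driver=True,
                                mutationtaster_damaging=True,
                                polyphen_category=PolyphenCategory.DAMAGING)
            for c in calls
        ]
        after = {r[:4] for r in driver_calls_as_records(
            nominate(variants, cnvs, boosted, roles, catalog, known))}
        assert before <= after

    def test_agrees_with_straight_line_oracle(self):
        rng = np.random.default_rng(101)
        variants, cnvs, calls, roles, catalog, known = random_rule_inputs(rng, 400, 40)
        got = driver_calls_as_records(
            nominate(variants, cnvs, calls, roles, catalog, known))
        expected = nominate_oracle(variants, cnvs, calls, roles, catalog, known)
        assert got == expected


class TestNoveltySummary:
    def test_empty_input(self):
        counts = summarize_novelty([], EMPTY_CATALOG)
        assert counts == {"novel_calls": 0, "known_calls": 0,
                          "new_candidate_genes": 0}

    def test_catalog_id_marks_known(self):
        variants = [
            _variant(pid="P1", pos=1),
            _variant(pid="P2", pos=2, catalog_id="COSM99"),
        ]
        calls = [PredictorCalls(chasm_driver=True)] * 2
        roles = {"G1": _role("G1", Role.UNCLASSIFIED)}
        out = nominate(variants, [], calls, roles, EMPTY_CATALOG, ["G1"])
        counts = summarize_novelty(out, EMPTY_CATALOG)
        assert counts["novel_calls"] == 1
        assert counts["known_calls"] == 1

    def test_planted_novel_drivers_counted(self):
        from driverlens.simulate import generate, paper_like_preset

        cohort = generate(paper_like_preset(n_patients=60, seed=13))
        from driverlens.rules import prefilter_population
        kept, _ = prefilter_population(cohort.variants)
        calls = chasm_calls(kept)
        genes = {v.gene for v in kept} | {g for e in cohort.cnvs for g in e.genes}
        roles = {g: classify_gene_role(g, cohort.catalog) for g in genes}
        out = nominate(kept, cohort.cnvs, calls, roles, cohort.catalog,
                       cohort.known_genes)
        truth = cohort.truth.variant_truth
        planted_novel = {
            c.event.key for c in out
            if isinstance(c.event, SomaticVariant)
            and truth[c.event.key].is_driver and c.novel
        }
        # every nominated planted driver in a catalogue-free gene is novel
        novel_gene_drivers = {
            k for k, t in truth.items()
            if t.is_driver and t.gene in ("U2AF1", "MED12", "USP9X")
        }
        nominated_keys = {c.event.key for c in out
                          if isinstance(c.event, SomaticVariant)}
        assert novel_gene_drivers & nominated_keys <= planted_novel
        assert planted_novel
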