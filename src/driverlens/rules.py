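"""Population prefilter and the driver-nomination rule cascade.

After removing common polymorphisms (any population minor allele frequency
above 1%), somatic events are nominated as candidate drivers when they
satisfy at least one of four rules:

i.   missense mutations predicted driver by CHASM, or damaging by at least
     two of the other three predictors, or recurrent in the catalogue;
ii.  nonsense mutations damaging by SIFT, splice-site mutations damaging by
     MutationTaster, or either class located in a TSG, or recurrent in the
     catalogue;
iii. frameshift indels and copy-number losses located in a TSG, and
     copy-number gains located in an oncogene;
iv.  genes with more than one event in the cohort (across at least two
     patients by default) never previously associated with the disease —
     their events are nominated as hits in new candidate driver genes.

An event can satisfy several rules; it is emitted once with every evidence
tag it earned and the lowest-numbered rule as primary.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import GeneRole, MutationCatalog, Role, is_novel, is_recurrent
from .io import CnvDirection, CnvEvent, SomaticVariant, VariantClass
from .predictors import PredictorCalls

MAF_THRESHOLD_DEFAULT = 0.01


class RuleEngineError(RuntimeError):
    """Internal contract violation, e.g. a variant gene without a GeneRole."""


class Rule(str, enum.Enum):
    I = "i"
    II = "ii"
    III = "iii"
    IV = "iv"


_RULE_ORDER = {Rule.I: 1, Rule.II: 2, Rule.III: 3, Rule.IV: 4}


class Evidence(str, enum.Enum):
    CHASM_DRIVER = "chasm_driver"
    CONSENSUS_2OF3 = "consensus_2of3"
    COSMIC_RECURRENT = "cosmic_recurrent"
    MUTATIONTASTER_DAMAGING = "mutationtaster_damaging"
    SIFT_DAMAGING = "sift_damaging"
    IN_TSG = "in_TSG"
    GAIN_IN_ONCOGENE = "gain_in_oncogene"
    COHORT_RECURRENT_NEW_GENE = "cohort_recurrent_new_gene"


@dataclass(frozen=True)
class DriverCall:
    """A nominated event with the rule and evidence that fired."""

    patient_id: str
    gene: str
    event: SomaticVariant | CnvEvent
    rule: Rule  # primary (lowest-numbered) rule
    rules_satisfied: tuple[Rule, ...]
    evidence: frozenset[Evidence]
    novel: bool

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a driver call must carry evidence")


def prefilter_population(
    variants: Sequence[SomaticVariant],
    maf_threshold: float = MAF_THRESHOLD_DEFAULT,
) -> tuple[list[SomaticVariant], list[SomaticVariant]]:
    """Split variants into (kept, removed) by population allele frequency.

    A variant is removed iff any of its population frequencies is strictly
    above ``maf_threshold``; missing frequencies keep the variant.
    """
    kept: list[SomaticVariant] = []
    removed: list[SomaticVariant] = []
    for v in variants:
        afs = (v.af_1000g, v.af_esp, v.af_exac)
        if any(af is not None and af > maf_threshold for af in afs):
            removed.append(v)
        else:
            kept.append(v)
    return kept, removed


def _variant_sort_key(v: SomaticVariant) -> tuple:
    return (v.patient_id, v.gene, v.chrom, v.pos, v.ref, v.alt)


def _cnv_sort_key(e: CnvEvent, gene: str) -> tuple:
    return (e.patient_id, gene, e.chrom, e.start, e.end, e.direction.value)


def nominate(
    variants: Sequence[SomaticVariant],
    cnvs: Sequence[CnvEvent],
    calls: Sequence[PredictorCalls],
    roles: Mapping[str, GeneRole],
    catalog: MutationCatalog,
    known_genes: Iterable[str],
    *,
    polyphen_strict: bool = False,
    recurrent_min_count: int = 2,
    rule_iv_min_patients: int = 2,
    rule_iv_allow_same_patient: bool = False,
) -> list[DriverCall]:
    """Apply the nomination rules to prefiltered variants and CNV events.

    ``calls`` must be aligned with ``variants`` (as produced by
    :func:`driverlens.predictors.chasm_calls`); ``roles`` must cover every
    variant gene and every gene listed on a CNV event. ``known_genes`` is the
    explicit list of genes already associated with the disease; rule iv only
    fires for genes outside it. Output order is deterministic regardless of
    input order.
    """
    if len(calls) != len(variants):
        raise RuleEngineError("calls must be aligned with variants")
    known = set(known_genes)
    for v in variants:
        if v.gene not in roles:
            raise RuleEngineError(f"no GeneRole computed for gene {v.gene!r}")
    for e in cnvs:
        for g in e.genes:
            if g not in roles:
                raise RuleEngineError(f"no GeneRole computed for gene {g!r}")

    # rule iv bookkeeping: every SNV/indel and every CNV-gene hit is an event
    gene_patients: dict[str, set[str]] = defaultdict(set)
    gene_event_count: dict[str, int] = defaultdict(int)
    for v in variants:
        gene_patients[v.gene].add(v.patient_id)
        gene_event_count[v.gene] += 1
    for e in cnvs:
        for g in e.genes:
            gene_patients[g].add(e.patient_id)
            gene_event_count[g] += 1
    rule_iv_genes = {
        g
        for g, n in gene_event_count.items()
        if g not in known
        and n >= 2
        and (rule_iv_allow_same_patient or len(gene_patients[g]) >= rule_iv_min_patients)
    }

    out: list[DriverCall] = []

    order = sorted(range(len(variants)), key=lambda i: _variant_sort_key(variants[i]))
    for i in order:
        v = variants[i]
        pc = calls[i]
        evidence: set[Evidence] = set()
        rules: set[Rule] = set()
        role = roles[v.gene].role
        recurrent, _ = is_recurrent(v, catalog, min_count=recurrent_min_count)

        if v.variant_class is VariantClass.MISSENSE:
            if pc.chasm_driver:
                evidence.add(Evidence.CHASM_DRIVER)
            votes = [
                pc.sift_damaging,
                pc.polyphen_qualifies(strict=polyphen_strict),
                pc.mutationtaster_damaging,
            ]
            if sum(1 for b in votes if b) >= 2:  # missing counts as not-damaging
                evidence.add(Evidence.CONSENSUS_2OF3)
            if recurrent:
                evidence.add(Evidence.COSMIC_RECURRENT)
            if evidence:
                rules.add(Rule.I)
        elif v.variant_class is VariantClass.NONSENSE:
            if pc.sift_damaging:
                evidence.add(Evidence.SIFT_DAMAGING)
            if role is Role.TSG:
                evidence.add(Evidence.IN_TSG)
            if recurrent:
                evidence.add(Evidence.COSMIC_RECURRENT)
            if evidence:
                rules.add(Rule.II)
        elif v.variant_class is VariantClass.SPLICE_SITE:
            if pc.mutationtaster_damaging:
                evidence.add(Evidence.MUTATIONTASTER_DAMAGING)
            if role is Role.TSG:
                evidence.add(Evidence.IN_TSG)
            if recurrent:
                evidence.add(Evidence.COSMIC_RECURRENT)
            if evidence:
                rules.add(Rule.II)
        elif v.variant_class is VariantClass.FRAMESHIFT_INDEL:
            if role is Role.TSG:
                evidence.add(Evidence.IN_TSG)
                rules.add(Rule.III)

        if v.gene in rule_iv_genes:
            evidence.add(Evidence.COHORT_RECURRENT_NEW_GENE)
            rules.add(Rule.IV)

        if rules:
            primary = min(rules, key=_RULE_ORDER.get)
            out.append(DriverCall(
                patient_id=v.patient_id, gene=v.gene, event=v,
                rule=primary,
                rules_satisfied=tuple(sorted(rules, key=_RULE_ORDER.get)),
                evidence=frozenset(evidence),
                novel=is_novel(v, catalog),
            ))

    cnv_pairs = sorted(
        ((e, g) for e in cnvs for g in e.genes),
        key=lambda pair: _cnv_sort_key(pair[0], pair[1]),
    )
    for e, g in cnv_pairs:
        evidence = set()
        rules = set()
        role = roles[g].role
        if e.direction in (CnvDirection.LOSS, CnvDirection.BIALLELIC_LOSS):
            if role is Role.TSG:
                evidence.add(Evidence.IN_TSG)
                rules.add(Rule.III)
        else:  # gain
            if role is Role.ONCOGENE:
                evidence.add(Evidence.GAIN_IN_ONCOGENE)
                rules.add(Rule.III)
        if g in rule_iv_genes:
            evidence.add(Evidence.COHORT_RECURRENT_NEW_GENE)
            rules.add(Rule.IV)
        if rules:
            primary = min(rules, key=_RULE_ORDER.get)
            out.append(DriverCall(
                patient_id=e.patient_id, gene=g, event=e,
                rule=primary,
                rules_satisfied=tuple(sorted(rules, key=_RULE_ORDER.get)),
                evidence=frozenset(evidence),
                novel=False,  # novelty is defined at protein-change level
            ))
    return out


def summarize_novelty(
    calls: Sequence[DriverCall], catalog: MutationCatalog
) -> dict[str, int]:
    """Counts of novel vs catalogue-known calls and of new candidate genes
    (genes nominated through cohort recurrence)."""
    novel_calls = sum(1 for c in calls if c.novel)
    new_genes = {
        c.gene for c in calls if Evidence.COHORT_RECURRENT_NEW_GENE in c.evidence
    }
    return {
        "novel_calls": novel_calls,
        "known_calls": len(calls) - novel_calls,
        "new_candidate_genes": len(new_genes),
    }
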