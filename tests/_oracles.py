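"""Independent brute-force oracles used only by the test suite.

Each oracle is a deliberately naive, straight-line re-implementation that
shares no code with the package: exhaustive table enumeration for the Fisher
test, labeling enumeration for Mann-Whitney, literal step-up for BH, and an
if/else transcription of the nomination rules.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

from driverlens.catalog import Role
from driverlens.io import CnvDirection, CnvEvent, SomaticVariant, VariantClass
from driverlens.predictors import PolyphenCategory


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Sum of hypergeometric probabilities over all margin-consistent tables
    whose probability is <= the observed one (1e-7 relative tie slack)."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, r2, c1 = a + b, c + d, a + c

    def prob(k: int) -> float:
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def mwu_two_sided_enum(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating every group labeling of
    the pooled sample; U computed by direct pairwise comparison (ties 0.5)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)

    def u_stat(idx_x):
        idx_x = set(idx_x)
        xs = [pooled[i] for i in idx_x]
        ys = [pooled[i] for i in range(n) if i not in idx_x]
        u = 0.0
        for xi in xs:
            for yi in ys:
                if xi > yi:
                    u += 1.0
                elif xi == yi:
                    u += 0.5
        return u

    u_obs = u_stat(range(n1))
    n_le = n_ge = total = 0
    for idx in combinations(range(n), n1):
        u = u_stat(idx)
        total += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def bh_step_up(p_values) -> list[float]:
    """Literal Benjamini-Hochberg step-up: sort, scale by m/rank, then take
    the running minimum from the largest rank down."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    scaled = [p_values[i] * m / (rank + 1) for rank, i in enumerate(indexed)]
    running = 1.0
    q_sorted = [0.0] * m
    for rank in range(m - 1, -1, -1):
        running = min(running, scaled[rank])
        q_sorted[rank] = min(1.0, running)
    out = [0.0] * m
    for rank, i in enumerate(indexed):
        out[i] = q_sorted[rank]
    return out


def nominate_oracle(variants, cnvs, calls, roles, catalog, known_genes,
                    *, rule_iv_min_patients=2):
    """Straight-line transcription of nomination rules i-iv.

    Returns a set of records
    ``(kind, patient_id, gene, locus, primary_rule, evidence_frozenset)``.
    """
    known = set(known_genes)

    # gene-level recurrence for rule iv
    per_gene_events = {}
    per_gene_patients = {}
    for v in variants:
        per_gene_events[v.gene] = per_gene_events.get(v.gene, 0) + 1
        per_gene_patients.setdefault(v.gene, set()).add(v.patient_id)
    for e in cnvs:
        for g in e.genes:
            per_gene_events[g] = per_gene_events.get(g, 0) + 1
            per_gene_patients.setdefault(g, set()).add(e.patient_id)

    def gene_is_rule_iv(g):
        if g in known:
            return False
        if per_gene_events.get(g, 0) < 2:
            return False
        return len(per_gene_patients.get(g, set())) >= rule_iv_min_patients

    out = set()
    for v, pc in zip(variants, calls):
        evidence = []
        rule = None
        if v.variant_class == VariantClass.MISSENSE:
            if pc.chasm_driver is True:
                evidence.append("chasm_driver")
            n_damaging = 0
            if pc.sift_damaging is True:
                n_damaging += 1
            if pc.polyphen_category in (PolyphenCategory.POSSIBLY_DAMAGING,
                                        PolyphenCategory.DAMAGING):
                n_damaging += 1
            if pc.mutationtaster_damaging is True:
                n_damaging += 1
            if n_damaging >= 2:
                evidence.append("consensus_2of3")
            if v.protein_change and catalog.protein_change_count(
                    v.gene, v.protein_change) >= 2:
                evidence.append("cosmic_recurrent")
            if evidence:
                rule = "i"
        if v.variant_class == VariantClass.NONSENSE:
            if pc.sift_damaging is True:
                evidence.append("sift_damaging")
            if roles[v.gene].role == Role.TSG:
                evidence.append("in_TSG")
            if v.protein_change and catalog.protein_change_count(
                    v.gene, v.protein_change) >= 2:
                evidence.append("cosmic_recurrent")
            if evidence:
                rule = "ii"
        if v.variant_class == VariantClass.SPLICE_SITE:
            if pc.mutationtaster_damaging is True:
                evidence.append("mutationtaster_damaging")
            if roles[v.gene].role == Role.TSG:
                evidence.append("in_TSG")
            if v.protein_change and catalog.protein_change_count(
                    v.gene, v.protein_change) >= 2:
                evidence.append("cosmic_recurrent")
            if evidence:
                rule = "ii"
        if v.variant_class == VariantClass.FRAMESHIFT_INDEL:
            if roles[v.gene].role == Role.TSG:
                evidence.append("in_TSG")
                rule = "iii"
        if gene_is_rule_iv(v.gene):
            evidence.append("cohort_recurrent_new_gene")
            if rule is None:
                rule = "iv"
        if rule is not None:
            out.add(("snv", v.patient_id, v.gene,
                     (v.chrom, v.pos, v.ref, v.alt), rule, frozenset(evidence)))

    for e in cnvs:
        for g in e.genes:
            evidence = []
            rule = None
            if e.direction in (CnvDirection.LOSS, CnvDirection.BIALLELIC_LOSS):
                if roles[g].role == Role.TSG:
                    evidence.append("in_TSG")
                    rule = "iii"
            if e.direction == CnvDirection.GAIN:
                if roles[g].role == Role.ONCOGENE:
                    evidence.append("gain_in_oncogene")
                    rule = "iii"
            if gene_is_rule_iv(g):
                evidence.append("cohort_recurrent_new_gene")
                if rule is None:
                    rule = "iv"
            if rule is not None:
                out.add(("cnv", e.patient_id, g,
                         (e.chrom, e.start, e.end, e.direction.value),
                         rule, frozenset(evidence)))
    return out


def random_rule_inputs(rng, n_variants=1000, n_cnvs=60):
    """Randomized nomination inputs spanning all class x evidence combos.

    Returns (variants, cnvs, calls, roles, catalog, known_genes) with genes
    drawn from a small universe so cohort recurrence, catalogue recurrence,
    TSG/oncogene roles and known-gene membership all vary.
    """
    from driverlens.catalog import CatalogEntry, MutationCatalog, classify_gene_role
    from driverlens.predictors import PredictorCalls

    genes = [f"G{i}" for i in range(40)]
    catalog_entries = []
    for g in genes[:10]:  # TSG-like catalogue block
        catalog_entries.append(
            CatalogEntry(g, 10, VariantClass.NONSENSE, "p.R10*", 12, True))
    for g in genes[10:20]:  # oncogene-like block with a shared hotspot
        catalog_entries.append(
            CatalogEntry(g, 35, VariantClass.MISSENSE, "p.R35L", 20, True))
    catalog = MutationCatalog(catalog_entries)
    known = set(genes[::3])
    classes = list(VariantClass)
    protein_changes = ["", "p.R35L", "p.R10*", "p.A77T"]
    variants, calls = [], []
    for i in range(n_variants):
        vclass = classes[int(rng.integers(len(classes)))]
        variants.append(SomaticVariant(
            patient_id=f"P{int(rng.integers(12))}",
            gene=genes[int(rng.integers(len(genes)))],
            chrom=str(int(rng.integers(1, 23))), pos=i + 1,
            ref="A", alt="T", variant_class=vclass,
            protein_change=protein_changes[int(rng.integers(len(protein_changes)))],
            alt_count=5, depth=10,
        ))
        maybe = lambda v: None if rng.random() < 0.3 else v
        calls.append(PredictorCalls(
            sift_damaging=maybe(bool(rng.random() < 0.5)),
            polyphen_category=maybe(
                list(PolyphenCategory)[int(rng.integers(3))]),
            mutationtaster_damaging=maybe(bool(rng.random() < 0.5)),
            chasm_q=None,
            chasm_driver=maybe(bool(rng.random() < 0.4)),
        ))
    cnvs = []
    directions = list(CnvDirection)
    for i in range(n_cnvs):
        k = int(rng.integers(1, 4))
        picked = list(dict.fromkeys(
            genes[int(rng.integers(len(genes)))] for _ in range(k)))
        cnvs.append(CnvEvent(
            patient_id=f"P{int(rng.integers(12))}",
            chrom=str(int(rng.integers(1, 23))),
            start=1000 * (i + 1), end=1000 * (i + 1) + 500,
            direction=directions[int(rng.integers(len(directions)))],
            genes=tuple(picked),
        ))
    roles = {g: classify_gene_role(g, catalog) for g in genes}
    return variants, cnvs, calls, roles, catalog, known


def driver_calls_as_records(driver_calls):
    """Project package DriverCalls onto the oracle's record shape."""
    out = set()
    for c in driver_calls:
        ev = c.event
        if isinstance(ev, SomaticVariant):
            locus = (ev.chrom, ev.pos, ev.ref, ev.alt)
            kind = "snv"
        else:
            locus = (ev.chrom, ev.start, ev.end, ev.direction.value)
            kind = "cnv"
        out.add((kind, c.patient_id, c.gene, locus, c.rule.value,
                 frozenset(e.value for e in c.evidence)))
    return out
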