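"""One-call convenience wrapper chaining the nomination stages.

Prefilter -> predictor categorization + cohort CHASM FDR -> 20/20 roles ->
rule cascade. Each stage remains individually accessible in its own module;
this wrapper just wires the common path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .catalog import GeneRole, MutationCatalog, classify_gene_role
from .io import CnvEvent, SomaticVariant
from .predictors import CHASM_FDR_DEFAULT, PredictorCalls, chasm_calls
from .rules import MAF_THRESHOLD_DEFAULT, DriverCall, nominate, prefilter_population


@dataclass(frozen=True)
class NominationOutcome:
    kept: tuple[SomaticVariant, ...]
    removed: tuple[SomaticVariant, ...]
    predictor_calls: tuple[PredictorCalls, ...]
    roles: Mapping[str, GeneRole]
    driver_calls: tuple[DriverCall, ...]


def run_nomination(
    variants: Sequence[SomaticVariant],
    cnvs: Sequence[CnvEvent],
    catalog: MutationCatalog,
    known_genes: Iterable[str],
    *,
    maf_threshold: float = MAF_THRESHOLD_DEFAULT,
    chasm_fdr: float = CHASM_FDR_DEFAULT,
    polyphen_strict: bool = False,
) -> NominationOutcome:
    kept, removed = prefilter_population(variants, maf_threshold)
    calls = chasm_calls(kept, chasm_fdr)
    genes = {v.gene for v in kept} | {g for e in cnvs for g in e.genes}
    roles = {g: classify_gene_role(g, catalog) for g in genes}
    driver_calls = nominate(
        kept, cnvs, calls, roles, catalog, known_genes,
        polyphen_strict=polyphen_strict,
    )
    return NominationOutcome(
        kept=tuple(kept), removed=tuple(removed),
        predictor_calls=tuple(calls), roles=roles,
        driver_calls=tuple(driver_calls),
    )
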