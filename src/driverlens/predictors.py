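"""Categorical predictor calls from raw in-silico scores.

Thresholds (package defaults, configurable at the call sites):

* SIFT: damaging when score <= 0.05 (boundary inclusive);
* PolyPhen2: damaging when score > 0.909, possibly damaging in
  [0.447, 0.909], benign below;
* MutationTaster: damaging when score > 0.9 (strict);
* CHASM: driver when the Benjamini-Hochberg-adjusted p-value over the
  cohort's missense variants is <= 0.20.

A missing score always propagates as a missing call — it is never defaulted
to benign, and it never counts toward or against any consensus.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Sequence

from .io import SomaticVariant, VariantClass
from .stats import bh_adjust

SIFT_DAMAGING_MAX = 0.05
POLYPHEN_POSSIBLY_MIN = 0.447
POLYPHEN_DAMAGING_MIN = 0.909  # exclusive: > 0.909 is damaging
MUTATIONTASTER_DAMAGING_MIN = 0.9  # exclusive
CHASM_FDR_DEFAULT = 0.20


class PolyphenCategory(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    DAMAGING = "damaging"


@dataclass(frozen=True)
class PredictorCalls:
    sift_damaging: bool | None = None
    polyphen_category: PolyphenCategory | None = None
    mutationtaster_damaging: bool | None = None
    chasm_q: float | None = None
    chasm_driver: bool | None = None

    def polyphen_qualifies(self, *, strict: bool = False) -> bool | None:
        """Whether PolyPhen2 counts as a damaging vote.

        By default ``possibly_damaging`` qualifies (both categories are
        predictions of damage); ``strict=True`` demands the damaging
        category.
        """
        if self.polyphen_category is None:
            return None
        if strict:
            return self.polyphen_category is PolyphenCategory.DAMAGING
        return self.polyphen_category is not PolyphenCategory.BENIGN


def categorize(variant: SomaticVariant) -> PredictorCalls:
    """Convert a variant's raw SIFT/PolyPhen2/MutationTaster scores into
    categorical calls (CHASM is cohort-level; see :func:`chasm_calls`)."""
    sift = None if variant.sift is None else variant.sift <= SIFT_DAMAGING_MAX
    if variant.polyphen2 is None:
        poly = None
    elif variant.polyphen2 > POLYPHEN_DAMAGING_MIN:
        poly = PolyphenCategory.DAMAGING
    elif variant.polyphen2 >= POLYPHEN_POSSIBLY_MIN:
        poly = PolyphenCategory.POSSIBLY_DAMAGING
    else:
        poly = PolyphenCategory.BENIGN
    mt = (
        None if variant.mutationtaster is None
        else variant.mutationtaster > MUTATIONTASTER_DAMAGING_MIN
    )
    return PredictorCalls(sift_damaging=sift, polyphen_category=poly,
                          mutationtaster_damaging=mt)


def chasm_calls(
    variants: Sequence[SomaticVariant],
    fdr_threshold: float = CHASM_FDR_DEFAULT,
    *,
    scope: str = "cohort",
) -> list[PredictorCalls]:
    """Full predictor calls including the CHASM FDR decision.

    The BH adjustment runs over the missense variants that carry a CHASM
    p-value; ``scope="cohort"`` adjusts them jointly (the conservative
    default), ``scope="per_patient"`` adjusts within each patient. Variants
    without a CHASM p-value (or that are not missense) get missing CHASM
    calls. Returned list is aligned with the input.
    """
    if scope not in ("cohort", "per_patient"):
        raise ValueError(f"unknown adjustment scope {scope!r}")
    calls = [categorize(v) for v in variants]
    eligible = [
        i for i, v in enumerate(variants)
        if v.chasm_p is not None and v.variant_class is VariantClass.MISSENSE
    ]
    groups: dict[str, list[int]] = defaultdict(list)
    for i in eligible:
        key = variants[i].patient_id if scope == "per_patient" else ""
        groups[key].append(i)
    for idx_group in groups.values():
        qs = bh_adjust([variants[i].chasm_p for i in idx_group])
        for i, q in zip(idx_group, qs):
            calls[i] = replace(calls[i], chasm_q=q, chasm_driver=q <= fdr_threshold)
    return calls
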