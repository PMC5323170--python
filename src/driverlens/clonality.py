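"""VAF-based clonality analysis.

A mutation carried by every tumor cell ("clonal") has an expected variant
allele fraction set by the sample purity and the local copy state: with
purity ``p``, a heterozygous mutation on a diploid autosome is expected at
``p/2``, while a hemizygous mutation (male X, or a one-copy region) and a
homozygous mutation after loss of heterozygosity are both expected at ``p``.
The observed VAF divided by that expectation gives a purity-adjusted
fraction; events above a cutoff (default 0.7) are labelled clonal,
others subclonal.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .io import CnvDirection, PatientRecord, Sex, SomaticVariant
from .stats import MannWhitneyResult, StatsUsageError, mann_whitney_u

logger = logging.getLogger(__name__)

CLONAL_CUTOFF_DEFAULT = 0.7


class CopyState(str, enum.Enum):
    HET_DIPLOID = "het_diploid"
    HEMIZYGOUS = "hemizygous"
    HOMOZYGOUS_LOHED = "homozygous_lohed"


class ClonalityLabel(str, enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"


class ExpressionSupport(str, enum.Enum):
    EXPRESSED = "expressed"
    NOT_EXPRESSED = "not_expressed"
    NO_RNA_DATA = "no_rna_data"


@dataclass(frozen=True)
class ClonalityCall:
    variant: SomaticVariant
    expected_clonal_vaf: float
    adjusted_fraction: float
    label: ClonalityLabel


@dataclass(frozen=True)
class VafComparison:
    u_statistic: float
    p_two_sided: float
    method: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def expected_clonal_vaf(purity: float, copy_state: CopyState) -> float:
    """Expected VAF of a fully clonal mutation at the given purity.

    Het-diploid: one mutated of two tumor copies against two normal copies
    gives ``purity / 2``. Hemizygous and homozygous-after-LOH states both
    reduce to ``purity`` (every tumor copy carries the mutation).
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must lie in (0, 1], got {purity}")
    if copy_state is CopyState.HET_DIPLOID:
        return purity / 2.0
    return purity  # hemizygous and homozygous_lohed coincide algebraically


def infer_copy_state(
    sex: Sex,
    chrom: str,
    cnv_direction: CnvDirection | None = None,
) -> CopyState:
    """Default copy-state assignment: male chrX is hemizygous; an
    overlapping copy-number loss makes a site hemizygous; everything else is
    het-diploid. Female X-linked mutations at VAF near 1 (X-inactivation /
    LOH) should be passed explicitly as ``HOMOZYGOUS_LOHED``."""
    c = chrom.removeprefix("chr").upper()
    if sex is Sex.M and c == "X":
        return CopyState.HEMIZYGOUS
    if cnv_direction in (CnvDirection.LOSS, CnvDirection.BIALLELIC_LOSS):
        return CopyState.HEMIZYGOUS
    return CopyState.HET_DIPLOID


def label_clonality(
    variant: SomaticVariant,
    patient: PatientRecord,
    copy_state: CopyState | None = None,
    clonal_cutoff: float = CLONAL_CUTOFF_DEFAULT,
) -> ClonalityCall:
    """Label a variant clonal/subclonal from its purity-adjusted VAF.

    A missing purity defaults to 1.0 (logged), which makes the adjusted
    fraction a plain rescaled VAF.
    """
    purity = patient.purity
    if purity is None:
        logger.info(
            "patient %s has no purity estimate; assuming 1.0", patient.patient_id
        )
        purity = 1.0
    if copy_state is None:
        copy_state = infer_copy_state(patient.sex, variant.chrom)
    expected = expected_clonal_vaf(purity, copy_state)
    adjusted = variant.vaf / expected
    label = ClonalityLabel.CLONAL if adjusted >= clonal_cutoff else ClonalityLabel.SUBCLONAL
    return ClonalityCall(variant, expected, adjusted, label)


def compare_vaf_groups(a, b) -> VafComparison:
    """Mann-Whitney comparison of two VAF groups with summary moments."""
    a = [float(v) for v in a]
    b = [float(v) for v in b]
    if not a or not b:
        raise StatsUsageError("both VAF groups must be non-empty")
    res: MannWhitneyResult = mann_whitney_u(a, b)
    sd = lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return VafComparison(
        u_statistic=res.u_statistic,
        p_two_sided=res.p_two_sided,
        method=res.method,
        mean_a=float(np.mean(a)), sd_a=sd(a),
        mean_b=float(np.mean(b)), sd_b=sd(b),
    )


def expression_support(
    variant: SomaticVariant,
    min_rna_alt: int = 2,
    min_rna_vaf: float = 0.05,
) -> ExpressionSupport:
    """RNA-level support for the mutated allele as a count-threshold screen."""
    if variant.rna_alt_count is None or variant.rna_depth is None:
        return ExpressionSupport.NO_RNA_DATA
    if variant.rna_alt_count > variant.rna_depth:
        raise ValueError("rna_alt_count exceeds rna_depth")
    if variant.rna_depth == 0:
        return ExpressionSupport.NO_RNA_DATA
    rna_vaf = variant.rna_alt_count / variant.rna_depth
    if variant.rna_alt_count >= min_rna_alt and rna_vaf >= min_rna_vaf:
        return ExpressionSupport.EXPRESSED
    return ExpressionSupport.NOT_EXPRESSED
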