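"""Synthetic-cohort generator with ground truth for every planted feature.

Emulates a small childhood T-ALL-like cohort at the annotated-table level
(no reads, no alignment): clinical records with a 2:1 male:female ratio and
subtype-dependent relapse rates, clonal driver mutations whose VAF follows
the purity/copy-state expectation, subclonal Ras-like mutations at reduced
VAF, X-linked mutations near VAF 1 (hemizygous in males, LOH/X-inactivation
in females), passenger variants scattered over a large neutral gene pool,
predictor scores drawn from separated Beta families for drivers vs
passengers, and a mutation catalogue constructed so that each planted
TSG/oncogene satisfies the 20/20 thresholds.

All randomness flows from one seed through per-patient spawned streams, so
the output is fully deterministic and adding a patient does not perturb the
draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import CatalogEntry, MutationCatalog, Role
from .clonality import CopyState, expected_clonal_vaf
from .io import (
    CnvDirection,
    CnvEvent,
    Group,
    PatientRecord,
    Sex,
    SomaticVariant,
    VariantClass,
    write_clinical_table,
    write_cnv_table,
    write_variant_table,
)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class DriverSpec:
    """One planted driver: an SNV/indel class or a CNV direction per gene."""

    gene: str
    chrom: str
    patient_probability: float
    variant_class: VariantClass | None = None
    cnv_direction: CnvDirection | None = None
    clonal: bool = True
    role_truth: Role | None = None  # None for genes kept out of the catalogue
    novel: bool = False  # absent from the catalogue and the known-gene list
    protein_change: str = ""  # fixed hotspot change; empty -> per-event change

    def __post_init__(self) -> None:
        if (self.variant_class is None) == (self.cnv_direction is None):
            raise ConfigError(
                f"driver {self.gene}: exactly one of variant_class / "
                f"cnv_direction must be set"
            )
        if not 0.0 <= self.patient_probability <= 1.0:
            raise ConfigError(f"driver {self.gene}: bad patient_probability")
        if self.novel and self.role_truth is not None:
            raise ConfigError(
                f"driver {self.gene}: novel genes carry no catalogue role"
            )


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 30
    male_fraction: float = 2.0 / 3.0
    subtype_probs: Mapping[Group, float] = field(default_factory=lambda: {
        Group.IMMATURE: 5 / 30, Group.ETP: 2 / 30,
        Group.MATURE: 13 / 30, Group.UNCLASSIFIED: 10 / 30,
    })
    relapse_prob_by_group: Mapping[Group, float] = field(default_factory=lambda: {
        Group.IMMATURE: 5 / 7, Group.ETP: 5 / 7,
        Group.MATURE: 1 / 13, Group.UNCLASSIFIED: 0.2,
    })
    purity_range: tuple[float, float] = (0.80, 0.98)
    depth_mean: float = 150.0
    depth_dispersion: float = 10.0
    drivers: tuple[DriverSpec, ...] = ()
    passenger_rate: float = 27.0
    passenger_gene_pool: int = 18_000
    polymorphism_rate: float = 0.02  # passengers leaking through with MAF > 1%
    rna_patient_fraction: float = 0.4
    driver_expressed_prob: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if not 0.0 < self.male_fraction < 1.0:
            raise ConfigError("male_fraction must lie strictly between 0 and 1")
        for name, probs in (("subtype_probs", self.subtype_probs),):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} must be a probability vector summing to 1")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("purity_range must satisfy 0 < lo <= hi <= 1")


@dataclass(frozen=True)
class VariantTruth:
    is_driver: bool
    gene: str
    clonal: bool | None  # None when clonality truth is not defined (CNVs)
    copy_state: CopyState | None
    expected_vaf: float | None
    polymorphism: bool = False


@dataclass(frozen=True)
class GroundTruth:
    variant_truth: Mapping[tuple, VariantTruth]  # keyed by SomaticVariant.key
    gene_roles: Mapping[str, Role | None]
    patient_params: Mapping[str, Mapping[str, object]]


@dataclass(frozen=True)
class SyntheticCohort:
    config: CohortConfig
    patients: tuple[PatientRecord, ...]
    variants: tuple[SomaticVariant, ...]
    cnvs: tuple[CnvEvent, ...]
    catalog: MutationCatalog
    pathways: Mapping[str, str]
    known_genes: tuple[str, ...]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_clinical_table(self.patients, outdir / "clinical.tsv")
        write_variant_table(self.variants, outdir / "variants.tsv")
        write_cnv_table(self.cnvs, outdir / "cnvs.tsv")
        self.catalog.to_tsv(outdir / "catalog.tsv")
        pd.DataFrame(
            sorted(self.pathways.items()), columns=["gene", "pathway"]
        ).to_csv(outdir / "pathways.tsv", sep="\t", index=False)
        (outdir / "known_genes.txt").write_text(
            "\n".join(self.known_genes) + "\n"
        )
        rows = [
            {
                "patient_id": k[0], "chrom": k[1], "pos": k[2],
                "ref": k[3], "alt": k[4], "gene": t.gene,
                "is_driver": t.is_driver,
                "clonal": "" if t.clonal is None else t.clonal,
                "copy_state": "" if t.copy_state is None else t.copy_state.value,
                "expected_vaf": "" if t.expected_vaf is None else t.expected_vaf,
                "polymorphism": t.polymorphism,
            }
            for k, t in self.truth.variant_truth.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)


# synthetic genomic spans for the preset driver genes (1-based, arbitrary
# but fixed so CNV segments and variant positions are reproducible)
_GENE_SPANS: dict[str, tuple[str, int, int]] = {
    "NOTCH1": ("9", 139_388_896, 139_440_238),
    "CDKN2A": ("9", 21_967_752, 21_995_301),
    "CDKN2B": ("9", 22_002_903, 22_009_313),
    "PHF6": ("X", 133_507_342, 133_562_822),
    "FBXW7": ("4", 153_242_410, 153_456_185),
    "JAK3": ("19", 17_935_595, 17_958_880),
    "NRAS": ("1", 115_247_085, 115_259_515),
    "U2AF1": ("21", 44_513_066, 44_527_688),
    "MED12": ("X", 70_338_406, 70_362_303),
    "USP9X": ("X", 40_944_888, 41_095_371),
    "KDM6A": ("X", 44_732_423, 44_971_845),
    "JAG2": ("14", 105_635_943, 105_668_082),
}

_PATHWAYS: dict[str, str] = {
    "NOTCH1": "Notch signaling",
    "JAG2": "Notch signaling",
    "CDKN2A": "Regulation of cell cycle",
    "CDKN2B": "Regulation of cell cycle",
    "PHF6": "Chromatin modification/assembly",
    "KDM6A": "Chromatin modification/assembly",
    "MED12": "Post/Transcriptional regulation",
    "U2AF1": "Post/Transcriptional regulation",
    "USP9X": "Post/Transcriptional regulation",
    "FBXW7": "Hemopoiesis/T-cell differentiation",
    "JAK3": "Signaling/JAK-STAT",
    "NRAS": "Signaling/Ras",
}

# driver / passenger predictor-score Beta families (mirrored)
_DRIVER_BETAS = {"sift": (1, 20), "polyphen2": (20, 2),
                 "mutationtaster": (20, 2), "chasm_p": (1, 30)}
_PASSENGER_BETAS = {"sift": (20, 1), "polyphen2": (2, 20),
                    "mutationtaster": (2, 20), "chasm_p": (30, 1)}

_PASSENGER_CLASS_WEIGHTS: list[tuple[VariantClass, float]] = [
    (VariantClass.MISSENSE, 0.30),
    (VariantClass.SYNONYMOUS, 0.25),
    (VariantClass.OTHER, 0.30),
    (VariantClass.INFRAME_INDEL, 0.05),
    (VariantClass.FRAMESHIFT_INDEL, 0.04),
    (VariantClass.NONSENSE, 0.03),
    (VariantClass.SPLICE_SITE, 0.03),
]

_BASES = "ACGT"


def paper_like_preset(n_patients: int = 30, seed: int = 0) -> CohortConfig:
    """A configuration whose expectation matches the published cohort
    composition: 30 patients at a 2:1 male:female ratio, 7/30 immature
    (2 ETP) with a 5/7 relapse rate vs 1/13 for mature, and planted driver
    genes at the printed per-patient frequencies (NOTCH1 0.50, CDKN2A
    deletion 0.55, PHF6 0.267, FBXW7 0.133, JAK3 0.133, U2AF1 0.10,
    MED12 0.10, ...)."""
    drivers = (
        DriverSpec("NOTCH1", "9", 0.50, variant_class=VariantClass.MISSENSE,
                   clonal=True, role_truth=Role.ONCOGENE, protein_change="p.L1601P"),
        DriverSpec("CDKN2A", "9", 0.55, cnv_direction=CnvDirection.BIALLELIC_LOSS,
                   role_truth=Role.TSG),
        DriverSpec("PHF6", "X", 0.267, variant_class=VariantClass.NONSENSE,
                   clonal=True, role_truth=Role.TSG),
        DriverSpec("FBXW7", "4", 0.133, variant_class=VariantClass.MISSENSE,
                   clonal=True, role_truth=Role.ONCOGENE, protein_change="p.R465C"),
        DriverSpec("JAK3", "19", 0.133, variant_class=VariantClass.MISSENSE,
                   clonal=True, role_truth=Role.ONCOGENE, protein_change="p.M511I"),
        DriverSpec("NRAS", "1", 0.10, variant_class=VariantClass.MISSENSE,
                   clonal=False, role_truth=Role.ONCOGENE, protein_change="p.G12D"),
        DriverSpec("U2AF1", "21", 0.10, variant_class=VariantClass.MISSENSE,
                   clonal=False, novel=True, protein_change="p.R35L"),
        DriverSpec("MED12", "X", 0.10, variant_class=VariantClass.FRAMESHIFT_INDEL,
                   clonal=True, novel=True),
        DriverSpec("USP9X", "X", 0.067, variant_class=VariantClass.NONSENSE,
                   clonal=True, novel=True),
        DriverSpec("KDM6A", "X", 0.034, variant_class=VariantClass.NONSENSE,
                   clonal=True, role_truth=Role.TSG),
        DriverSpec("JAG2", "14", 0.067, cnv_direction=CnvDirection.GAIN,
                   role_truth=Role.ONCOGENE),
    )
    return CohortConfig(n_patients=n_patients, drivers=drivers, seed=seed)


def _negbin(rng: np.random.Generator, mean: float, dispersion: float,
            minimum: int = 1) -> int:
    p = dispersion / (dispersion + mean)
    return max(minimum, int(rng.negative_binomial(dispersion, p)))


def _protein_pos(change: str) -> int:
    digits = "".join(ch for ch in change if ch.isdigit())
    return int(digits) if digits else 1


def _build_catalog(config: CohortConfig) -> tuple[MutationCatalog, dict[str, Role | None]]:
    """Catalogue rows constructed so each role_truth gene satisfies (or
    deliberately violates) the 20/20 thresholds."""
    entries: list[CatalogEntry] = []
    roles: dict[str, Role | None] = {}
    genes = list(config.drivers) + [
        # an always-present TSG companion of the CDKN2A locus
        DriverSpec("CDKN2B", "9", 0.0, variant_class=VariantClass.NONSENSE,
                   role_truth=Role.TSG),
    ]
    for d in genes:
        roles[d.gene] = d.role_truth
        if d.novel or d.role_truth is None:
            continue
        if d.role_truth is Role.TSG:
            # 30/35 truncating samples -> frac_inactivating ~ 0.86
            for i, pos in enumerate((45, 116, 225)):
                entries.append(CatalogEntry(d.gene, pos, VariantClass.NONSENSE,
                                            f"p.R{pos}*", 8, True))
            entries.append(CatalogEntry(d.gene, 167, VariantClass.FRAMESHIFT_INDEL,
                                        "p.V167fs", 3, True))
            entries.append(CatalogEntry(d.gene, None, VariantClass.SPLICE_SITE,
                                        "c.1024+1G>A", 3, True))
            for pos in (12, 88, 140, 201, 260):
                entries.append(CatalogEntry(d.gene, pos, VariantClass.MISSENSE,
                                            f"p.A{pos}V", 1, False))
        else:  # oncogene: one dominant hotspot, scattered singletons
            hotspot = d.protein_change or "p.R100H"
            entries.append(CatalogEntry(d.gene, _protein_pos(hotspot),
                                        VariantClass.MISSENSE, hotspot, 24, True))
            for pos in (33, 77, 152, 310, 402, 515):
                entries.append(CatalogEntry(d.gene, pos, VariantClass.MISSENSE,
                                            f"p.G{pos}R", 1, False))
            entries.append(CatalogEntry(d.gene, 600, VariantClass.NONSENSE,
                                        "p.E600*", 1, False))
    return MutationCatalog(entries), roles


def _driver_copy_state(chrom: str, sex: Sex) -> CopyState:
    if chrom.removeprefix("chr").upper() == "X":
        # males are hemizygous; females reach VAF ~ 1 via LOH/X-inactivation
        return CopyState.HEMIZYGOUS if sex is Sex.M else CopyState.HOMOZYGOUS_LOHED
    return CopyState.HET_DIPLOID


def _draw_scores(rng: np.random.Generator, betas: Mapping[str, tuple[int, int]],
                 vclass: VariantClass) -> dict[str, float | None]:
    """Missense gets all four scores; other point classes get the two
    predictors that score them; indels and silent variants get none."""
    out: dict[str, float | None] = {k: None for k in betas}
    if vclass is VariantClass.MISSENSE:
        keys = ("sift", "polyphen2", "mutationtaster", "chasm_p")
    elif vclass in (VariantClass.NONSENSE, VariantClass.SPLICE_SITE):
        keys = ("sift", "mutationtaster")
    else:
        keys = ()
    for k in keys:
        a, b = betas[k]
        out[k] = float(rng.beta(a, b))
    return out


def generate(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort; deterministic given the seed."""
    ss = np.random.SeedSequence(config.seed)
    cohort_stream, *patient_streams = ss.spawn(config.n_patients + 1)
    rng0 = np.random.default_rng(cohort_stream)

    catalog, gene_roles = _build_catalog(config)
    pathways = {g: _PATHWAYS.get(g, "unassigned") for g in gene_roles}
    known = tuple(sorted(d.gene for d in config.drivers if not d.novel))

    group_names = list(config.subtype_probs)
    group_p = np.array([config.subtype_probs[g] for g in group_names], dtype=float)

    patients: list[PatientRecord] = []
    variants: list[SomaticVariant] = []
    cnvs: list[CnvEvent] = []
    truth: dict[tuple, VariantTruth] = {}
    patient_params: dict[str, dict[str, object]] = {}

    for i in range(config.n_patients):
        rng = np.random.default_rng(patient_streams[i])
        pid = f"P{i + 1:04d}"
        sex = Sex.M if rng.random() < config.male_fraction else Sex.F
        group = group_names[int(rng.choice(len(group_names), p=group_p))]
        relapse_p = config.relapse_prob_by_group.get(group, 0.0)
        relapse = bool(rng.random() < relapse_p)
        lo, hi = config.purity_range
        purity = float(rng.uniform(lo, hi))
        rna_available = bool(rng.random() < config.rna_patient_fraction)
        patients.append(PatientRecord(pid, sex, group, relapse, purity))
        patient_params[pid] = {
            "relapse_prob": relapse_p, "purity": purity,
            "rna_available": rna_available,
        }

        used_pos: set[tuple[str, int]] = set()

        def _unique_pos(chrom: str, lo_: int, hi_: int) -> int:
            while True:
                pos = int(rng.integers(lo_, hi_ + 1))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    return pos

        for d in config.drivers:
            if rng.random() >= d.patient_probability:
                continue
            span = _GENE_SPANS.get(d.gene)
            chrom, g_lo, g_hi = span if span else (d.chrom, 1_000_000, 2_000_000)
            if d.cnv_direction is not None:
                genes = (d.gene, "CDKN2B") if d.gene == "CDKN2A" else (d.gene,)
                event = CnvEvent(pid, chrom, g_lo - 5_000, g_hi + 5_000,
                                 d.cnv_direction, genes)
                cnvs.append(event)
                continue
            state = _driver_copy_state(chrom, sex)
            evaf_clonal = expected_clonal_vaf(purity, state)
            if d.clonal:
                evaf = evaf_clonal
            else:
                evaf = float(rng.uniform(0.1, 0.6)) * evaf_clonal
            depth = _negbin(rng, config.depth_mean, config.depth_dispersion)
            alt = int(rng.binomial(depth, evaf))
            pos = _unique_pos(chrom, g_lo, g_hi)
            ref, altb = rng.choice(list(_BASES), size=2, replace=False)
            if d.protein_change:
                pchange = d.protein_change
            elif d.variant_class is VariantClass.NONSENSE:
                pchange = f"p.Q{int(rng.integers(30, 900))}*"
            elif d.variant_class is VariantClass.FRAMESHIFT_INDEL:
                pchange = f"p.V{int(rng.integers(30, 900))}fs"
            elif d.variant_class is VariantClass.SPLICE_SITE:
                pchange = ""
            else:
                pchange = f"p.A{int(rng.integers(30, 900))}T"
            scores = _draw_scores(rng, _DRIVER_BETAS, d.variant_class)
            cosmic_n = catalog.protein_change_count(d.gene, pchange)
            rna_depth = rna_alt = None
            if rna_available:
                rna_depth = _negbin(rng, 60, 5)
                expressed = rng.random() < config.driver_expressed_prob
                vaf_now = alt / depth
                rna_alt = int(rng.binomial(rna_depth, vaf_now)) if expressed else 0
            v = SomaticVariant(
                patient_id=pid, gene=d.gene, chrom=chrom, pos=pos,
                ref=str(ref), alt=str(altb), variant_class=d.variant_class,
                protein_change=pchange, alt_count=alt, depth=depth,
                rna_alt_count=rna_alt, rna_depth=rna_depth,
                sift=scores["sift"], polyphen2=scores["polyphen2"],
                mutationtaster=scores["mutationtaster"], chasm_p=scores["chasm_p"],
                catalog_id=f"COSM{zlib.crc32(f'{d.gene}:{pchange}'.encode()) % 10**6}"
                if cosmic_n > 0 else "",
            )
            variants.append(v)
            truth[v.key] = VariantTruth(
                is_driver=True, gene=d.gene, clonal=d.clonal,
                copy_state=state, expected_vaf=evaf,
            )

        n_pass = int(rng.poisson(config.passenger_rate))
        classes, weights = zip(*_PASSENGER_CLASS_WEIGHTS)
        for _ in range(n_pass):
            gene = f"GENE{int(rng.integers(config.passenger_gene_pool)):05d}"
            vclass = classes[int(rng.choice(len(classes), p=np.array(weights)))]
            chrom = str(int(rng.integers(1, 23)))
            pos = _unique_pos(chrom, 1, 240_000_000)
            ref, altb = rng.choice(list(_BASES), size=2, replace=False)
            evaf_clonal = expected_clonal_vaf(purity, CopyState.HET_DIPLOID)
            clonal = bool(rng.random() < 0.5)
            evaf = evaf_clonal if clonal else float(rng.uniform(0.1, 0.6)) * evaf_clonal
            depth = _negbin(rng, config.depth_mean, config.depth_dispersion)
            alt = int(rng.binomial(depth, evaf))
            scores = _draw_scores(rng, _PASSENGER_BETAS, vclass)
            is_poly = bool(rng.random() < config.polymorphism_rate)
            af_exac = float(rng.uniform(0.011, 0.2)) if is_poly else None
            ppos = int(rng.integers(30, 900))
            if vclass is VariantClass.MISSENSE:
                pchange = f"p.A{ppos}T"
            elif vclass is VariantClass.NONSENSE:
                pchange = f"p.Q{ppos}*"
            elif vclass is VariantClass.FRAMESHIFT_INDEL:
                pchange = f"p.V{ppos}fs"
            elif vclass is VariantClass.INFRAME_INDEL:
                pchange = f"p.K{ppos}del"
            elif vclass is VariantClass.SYNONYMOUS:
                pchange = f"p.L{ppos}="
            else:
                pchange = ""
            rna_depth = rna_alt = None
            if rna_available:
                rna_depth = _negbin(rng, 60, 5)
                expressed = rng.random() < 0.5
                rna_alt = int(rng.binomial(rna_depth, alt / depth)) if expressed else 0
            v = SomaticVariant(
                patient_id=pid, gene=gene, chrom=chrom, pos=pos,
                ref=str(ref), alt=str(altb), variant_class=vclass,
                protein_change=pchange, alt_count=alt, depth=depth,
                rna_alt_count=rna_alt, rna_depth=rna_depth,
                sift=scores["sift"], polyphen2=scores["polyphen2"],
                mutationtaster=scores["mutationtaster"], chasm_p=scores["chasm_p"],
                af_exac=af_exac,
            )
            variants.append(v)
            truth[v.key] = VariantTruth(
                is_driver=False, gene=gene, clonal=clonal,
                copy_state=CopyState.HET_DIPLOID, expected_vaf=evaf,
                polymorphism=is_poly,
            )
            if gene not in gene_roles:
                gene_roles[gene] = None

    return SyntheticCohort(
        config=config,
        patients=tuple(patients),
        variants=tuple(variants),
        cnvs=tuple(cnvs),
        catalog=catalog,
        pathways=pathways,
        known_genes=known,
        truth=GroundTruth(truth, gene_roles, patient_params),
    )


def generate_pileup_pair(
    variant: SomaticVariant,
    somatic: bool,
    rng: np.random.Generator,
    *,
    normal_depth: int | None = None,
) -> tuple[str, str]:
    """Tumor/normal pileup lines for one variant site.

    The tumor line reflects the variant's alt/depth counts exactly. For a
    somatic truth the normal line carries 0-1 alt reads; for a germline
    truth the normal VAF matches the tumor VAF to within binomial noise.
    """
    def line(depth: int, alt_n: int) -> str:
        ref_n = depth - alt_n
        bases = "." * ref_n + variant.alt.upper() * alt_n
        return f"{variant.chrom}\t{variant.pos}\t{variant.ref.upper()}\t{depth}\t{bases}"

    nd = normal_depth if normal_depth is not None else max(
        1, int(rng.normal(variant.depth, variant.depth * 0.1))
    )
    tumor = line(variant.depth, variant.alt_count)
    if somatic:
        n_alt = int(rng.random() < 0.15)  # occasional stray read
    else:
        n_alt = int(rng.binomial(nd, variant.vaf))
    n_alt = min(n_alt, nd)
    normal = line(nd, n_alt)
    return tumor, normal
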