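"""Tabular input/output and pileup-level plumbing.

Reads and writes the four tab-separated inputs of the pipeline (somatic
variant table, CNV segment table, clinical table, and — in :mod:`.catalog` —
the mutation catalogue), parses SAMtools-pileup text, and confirms somatic
status of a targeted site from a tumor/normal pileup pair.

Conventions:

* all genomic coordinates are 1-based inclusive;
* missing optional values (predictor scores, population frequencies, RNA
  counts, purity) are represented as ``None`` and serialized as empty fields —
  never as 0, since 0 is a meaningful score for SIFT and CHASM;
* readers return ``(records, issues)`` where ``issues`` lists row-level
  diagnostics for rejected rows; structural problems (a missing required
  column, a duplicated patient id) raise :class:`TableFormatError`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class TableFormatError(ValueError):
    """A table-level structural problem (missing column, duplicate key)."""


class PileupParseError(ValueError):
    """A malformed pileup line; carries the offending column offset."""


class UsageError(ValueError):
    """API misuse, e.g. comparing pileups from different positions."""


@dataclass(frozen=True)
class RowIssue:
    """Diagnostic for one rejected input row."""

    line: int  # 1-based data-row index (header excluded)
    message: str


class VariantClass(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SPLICE_SITE = "splice_site"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class CnvDirection(str, enum.Enum):
    LOSS = "loss"
    BIALLELIC_LOSS = "biallelic_loss"
    GAIN = "gain"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


class Group(str, enum.Enum):
    IMMATURE = "immature"
    ETP = "ETP"  # early T-cell precursor; a sub-label of immature
    MATURE = "mature"
    UNCLASSIFIED = "unclassified"


class SomaticStatus(str, enum.Enum):
    CONFIRMED = "confirmed"
    ABSENT_IN_TUMOR = "absent_in_tumor"
    PRESENT_IN_NORMAL = "present_in_normal"


@dataclass(frozen=True)
class SomaticVariant:
    """One annotated somatic SNV/indel in one patient."""

    patient_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    protein_change: str = ""
    alt_count: int = 0
    depth: int = 1
    rna_alt_count: int | None = None
    rna_depth: int | None = None
    sift: float | None = None
    polyphen2: float | None = None
    mutationtaster: float | None = None
    chasm_p: float | None = None
    af_1000g: float | None = None
    af_esp: float | None = None
    af_exac: float | None = None
    catalog_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(
                f"alt_count must satisfy 0 <= alt_count <= depth, "
                f"got alt_count={self.alt_count}, depth={self.depth}"
            )
        if self.rna_alt_count is not None and self.rna_depth is not None:
            if self.rna_alt_count > self.rna_depth:
                raise ValueError("rna_alt_count exceeds rna_depth")
        for name in ("sift", "polyphen2", "mutationtaster", "chasm_p",
                     "af_1000g", "af_esp", "af_exac"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @property
    def vaf(self) -> float:
        """Variant allele fraction, computed lazily from read counts."""
        return self.alt_count / self.depth

    @property
    def rna_vaf(self) -> float | None:
        if self.rna_alt_count is None or not self.rna_depth:
            return None
        return self.rna_alt_count / self.rna_depth

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.patient_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class CnvEvent:
    """One somatic copy-number segment with the genes it affects."""

    patient_id: str
    chrom: str
    start: int
    end: int
    direction: CnvDirection
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start ({self.start}) > end ({self.end})")
        if not self.genes:
            raise ValueError("gene list must be non-empty")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: Sex
    group: Group
    relapse: bool
    purity: float | None = None

    def __post_init__(self) -> None:
        if self.purity is not None and not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity must lie in (0, 1], got {self.purity}")

    @property
    def immature_inclusive(self) -> bool:
        """True for immature patients including the ETP sub-label."""
        return self.group in (Group.IMMATURE, Group.ETP)


@dataclass(frozen=True)
class PileupSite:
    chrom: str
    pos: int
    ref_base: str
    base_counts: Mapping[str, int]
    depth: int

    def vaf(self, alt: str) -> float:
        if self.depth == 0:
            return 0.0
        return self.base_counts.get(alt.upper(), 0) / self.depth

    def count(self, alt: str) -> int:
        return self.base_counts.get(alt.upper(), 0)


# ---------------------------------------------------------------------------
# variant table

_VARIANT_COLUMNS = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
    "protein_change", "alt_count", "depth", "rna_alt_count", "rna_depth",
    "sift", "polyphen2", "mutationtaster", "chasm_p",
    "af_1000g", "af_esp", "af_exac", "catalog_id",
]
_VARIANT_REQUIRED = [
    "patient_id", "gene", "chrom", "pos", "ref", "alt", "variant_class",
    "alt_count", "depth",
]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _opt_float(raw: str, column: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValueError(f"non-numeric value {raw!r} in column {column!r}")


def _opt_int(raw: str, column: str) -> int | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return int(raw)
    except ValueError:
        raise ValueError(f"non-numeric count {raw!r} in column {column!r}")


def _req_int(raw: str, column: str) -> int:
    v = _opt_int(raw, column)
    if v is None:
        raise ValueError(f"missing required count in column {column!r}")
    return v


def read_variant_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[SomaticVariant], list[RowIssue]]:
    """Read a MAF-like tab-separated variant table.

    ``dialect`` optionally maps canonical column names to the file's actual
    header names. Rows violating record invariants are rejected and reported
    as :class:`RowIssue` entries; a missing required column raises
    :class:`TableFormatError`.
    """
    df = _read_tsv(path)
    rename = {v: k for k, v in (dialect or {}).items()}
    df = df.rename(columns=rename)
    missing = [c for c in _VARIANT_REQUIRED if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
    records: list[SomaticVariant] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        get = lambda col: getattr(row, col, "") if col in df.columns else ""
        try:
            records.append(SomaticVariant(
                patient_id=str(get("patient_id")).strip(),
                gene=str(get("gene")).strip(),
                chrom=str(get("chrom")).strip(),
                pos=_req_int(str(get("pos")), "pos"),
                ref=str(get("ref")).strip(),
                alt=str(get("alt")).strip(),
                variant_class=VariantClass(str(get("variant_class")).strip()),
                protein_change=str(get("protein_change")).strip(),
                alt_count=_req_int(str(get("alt_count")), "alt_count"),
                depth=_req_int(str(get("depth")), "depth"),
                rna_alt_count=_opt_int(str(get("rna_alt_count")), "rna_alt_count"),
                rna_depth=_opt_int(str(get("rna_depth")), "rna_depth"),
                sift=_opt_float(str(get("sift")), "sift"),
                polyphen2=_opt_float(str(get("polyphen2")), "polyphen2"),
                mutationtaster=_opt_float(str(get("mutationtaster")), "mutationtaster"),
                chasm_p=_opt_float(str(get("chasm_p")), "chasm_p"),
                af_1000g=_opt_float(str(get("af_1000g")), "af_1000g"),
                af_esp=_opt_float(str(get("af_esp")), "af_esp"),
                af_exac=_opt_float(str(get("af_exac")), "af_exac"),
                catalog_id=str(get("catalog_id")).strip(),
            ))
        except ValueError as exc:
            issues.append(RowIssue(i, str(exc)))
    return records, issues


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, enum.Enum):
        return v.value
    if isinstance(v, bool):
        return "Y" if v else "N"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_variant_table(variants: Iterable[SomaticVariant], path: str | Path) -> None:
    rows = [{c: _fmt(getattr(v, c)) for c in _VARIANT_COLUMNS} for v in variants]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNV table

_CNV_COLUMNS = ["patient_id", "chrom", "start", "end", "direction", "genes"]


def read_cnv_table(path: str | Path) -> tuple[list[CnvEvent], list[RowIssue]]:
    """Read a SEG-like CNV table (genes semicolon-separated, deduplicated)."""
    df = _read_tsv(path)
    missing = [c for c in _CNV_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
    events: list[CnvEvent] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            genes = []
            for g in str(row.genes).split(";"):
                g = g.strip()
                if g and g not in genes:  # dedup preserving order
                    genes.append(g)
            events.append(CnvEvent(
                patient_id=str(row.patient_id).strip(),
                chrom=str(row.chrom).strip(),
                start=_req_int(str(row.start), "start"),
                end=_req_int(str(row.end), "end"),
                direction=CnvDirection(str(row.direction).strip()),
                genes=tuple(genes),
            ))
        except ValueError as exc:
            issues.append(RowIssue(i, str(exc)))
    return events, issues


def write_cnv_table(events: Iterable[CnvEvent], path: str | Path) -> None:
    rows = [
        {
            "patient_id": e.patient_id, "chrom": e.chrom,
            "start": e.start, "end": e.end,
            "direction": e.direction.value, "genes": ";".join(e.genes),
        }
        for e in events
    ]
    pd.DataFrame(rows, columns=_CNV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical table

_CLINICAL_COLUMNS = ["patient_id", "sex", "group", "relapse", "purity"]

_TRUE_TOKENS = {"y", "true"}
_FALSE_TOKENS = {"n", "false"}


def _parse_relapse(raw: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE_TOKENS:
        return True
    if token in _FALSE_TOKENS:
        return False
    raise ValueError(f"unrecognized relapse token {raw!r} (expected Y/N/true/false)")


def read_clinical_table(path: str | Path) -> tuple[list[PatientRecord], list[RowIssue]]:
    df = _read_tsv(path)
    required = ["patient_id", "sex", "group", "relapse"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
    seen: set[str] = set()
    records: list[PatientRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        pid = str(row.patient_id).strip()
        if pid in seen:
            raise TableFormatError(f"duplicate patient_id {pid!r} at data row {i}")
        seen.add(pid)
        try:
            purity = (
                _opt_float(str(getattr(row, "purity", "")), "purity")
                if "purity" in df.columns else None
            )
            records.append(PatientRecord(
                patient_id=pid,
                sex=Sex(str(row.sex).strip()),
                group=Group(str(row.group).strip()),
                relapse=_parse_relapse(str(row.relapse)),
                purity=purity,
            ))
        except ValueError as exc:
            issues.append(RowIssue(i, str(exc)))
    return records, issues


def write_clinical_table(patients: Iterable[PatientRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": p.patient_id, "sex": p.sex.value,
            "group": p.group.value, "relapse": "Y" if p.relapse else "N",
            "purity": _fmt(p.purity),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# pileup

def parse_pileup_line(line: str) -> PileupSite:
    """Parse one line of SAMtools-pileup text into per-base counts.

    Handles ``.``/``,`` reference matches, ACGTN calls in either case,
    read start/end markers (``^`` + mapping-quality char, ``$``), deletion
    placeholders ``*``, and indel spans ``+n<seq>`` / ``-n<seq>`` (indels are
    tallied apart from the base counts, so counts still sum to the depth
    column).
    """
    fields = line.rstrip("\n").split()
    if len(fields) < 5:
        raise PileupParseError(f"expected >= 5 whitespace-separated fields, got {len(fields)}")
    chrom, pos_s, ref, depth_s, bases = fields[:5]
    try:
        pos = int(pos_s)
        depth = int(depth_s)
    except ValueError as exc:
        raise PileupParseError(str(exc))
    ref_base = ref.upper()
    counts: dict[str, int] = {}
    i = 0
    while i < len(bases):
        ch = bases[i]
        if ch in ".,":
            counts[ref_base] = counts.get(ref_base, 0) + 1
            i += 1
        elif ch.upper() in "ACGTN":
            b = ch.upper()
            counts[b] = counts.get(b, 0) + 1
            i += 1
        elif ch == "^":
            i += 2  # '^' is followed by a mapping-quality character
        elif ch == "$":
            i += 1
        elif ch == "*":
            counts["*"] = counts.get("*", 0) + 1
            i += 1
        elif ch in "+-":
            j = i + 1
            while j < len(bases) and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError(f"malformed indel length at column {i}")
            span = int(bases[i + 1:j])
            i = j + span  # indel sequence tallied separately from base counts
        elif ch in "<>":
            counts[ch] = counts.get(ch, 0) + 1
            i += 1
        else:
            raise PileupParseError(f"unexpected pileup symbol {ch!r} at column {i}")
    total = sum(counts.values())
    if total != depth:
        raise PileupParseError(
            f"base counts sum to {total} but depth column says {depth}"
        )
    return PileupSite(chrom=chrom, pos=pos, ref_base=ref_base,
                      base_counts=counts, depth=depth)


def confirm_somatic(
    tumor: PileupSite,
    normal: PileupSite,
    alt: str,
    *,
    t_min_vaf: float = 0.05,
    n_max_vaf: float = 0.01,
    n_max_alt: int = 1,
) -> SomaticStatus:
    """Classify a targeted site from its tumor/normal pileup pair.

    ``confirmed`` iff the tumor alt VAF is >= ``t_min_vaf`` while the normal
    sample shows at most ``n_max_alt`` alt reads and a VAF <= ``n_max_vaf``.
    The defaults are conventional screening thresholds for ultra-deep
    (~2,500X) targeted validation data and are configurable.
    """
    if (tumor.chrom, tumor.pos) != (normal.chrom, normal.pos):
        raise UsageError(
            f"tumor and normal pileups address different positions: "
            f"{tumor.chrom}:{tumor.pos} vs {normal.chrom}:{normal.pos}"
        )
    if tumor.vaf(alt) < t_min_vaf:
        return SomaticStatus.ABSENT_IN_TUMOR
    if normal.vaf(alt) > n_max_vaf or normal.count(alt) > n_max_alt:
        return SomaticStatus.PRESENT_IN_NORMAL
    return SomaticStatus.CONFIRMED
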