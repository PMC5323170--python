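from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from driverlens.catalog import CatalogEntry, MutationCatalog
from driverlens.io import Group, PatientRecord, Sex, VariantClass


@pytest.fixture
def toy_catalog() -> MutationCatalog:
    """Small catalogue: TSGX is a clear TSG, ONCY a clear hotspot oncogene,
    SPARSE has too little evidence to classify."""
    entries = [
        CatalogEntry("TSGX", 100, VariantClass.NONSENSE, "p.R100*", 6, True),
        CatalogEntry("TSGX", 50, VariantClass.FRAMESHIFT_INDEL, "p.V50fs", 3, True),
        CatalogEntry("TSGX", None, VariantClass.SPLICE_SITE, "c.100+1G>A", 2, False),
        CatalogEntry("TSGX", 20, VariantClass.MISSENSE, "p.A20V", 1, False),
        CatalogEntry("ONCY", 35, VariantClass.MISSENSE, "p.R35L", 20, True),
        CatalogEntry("ONCY", 70, VariantClass.MISSENSE, "p.G70R", 1, False),
        CatalogEntry("ONCY", 90, VariantClass.MISSENSE, "p.D90N", 1, False),
        CatalogEntry("SPARSE", 10, VariantClass.MISSENSE, "p.A10T", 2, False),
    ]
    return MutationCatalog(entries)


@pytest.fixture
def table1_patients() -> list[PatientRecord]:
    """A 30-patient clinical roster matching the published composition:
    7 immature (2 of them ETP) with 5 relapses, 13 mature with 1 relapse,
    10 unclassified with 2 relapses; 20 males, 10 females."""
    immature_ids = ["324", "432", "706", "716", "748"]
    etp_ids = ["791", "879"]
    mature_ids = ["340", "341", "437", "544", "547", "636", "647",
                  "693", "727", "743", "744", "759", "849"]
    unclassified_ids = [f"U{i:02d}" for i in range(1, 11)]
    relapsed = {"324", "432", "706", "716", "791", "849", "U01", "U02"}
    females = {"791", "879", "324", "437", "547", "U01", "U02", "U03", "U04", "U05"}
    patients = []
    for pid in immature_ids:
        patients.append(PatientRecord(pid, Sex.F if pid in females else Sex.M,
                                      Group.IMMATURE, pid in relapsed))
    for pid in etp_ids:
        patients.append(PatientRecord(pid, Sex.F if pid in females else Sex.M,
                                      Group.ETP, pid in relapsed))
    for pid in mature_ids:
        patients.append(PatientRecord(pid, Sex.F if pid in females else Sex.M,
                                      Group.MATURE, pid in relapsed))
    for pid in unclassified_ids:
        patients.append(PatientRecord(pid, Sex.F if pid in females else Sex.M,
                                      Group.UNCLASSIFIED, pid in relapsed))
    return patients
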