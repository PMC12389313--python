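import pytest

from grdc.io_model import AdmissionDrugSet, DrugGeneMap, RiskLevel, RiskTable


@pytest.fixture
def toy_admissions() -> list[AdmissionDrugSet]:
    """Five small admissions over a six-drug universe, built by hand."""
    sets = [
        ("s1", "h1", {"aspirin", "warfarin", "heparin"}),
        ("s1", "h2", {"aspirin", "warfarin"}),
        ("s2", "h3", {"aspirin", "warfarin", "prednisone"}),
        ("s3", "h4", {"aspirin", "warfarin"}),
        ("s4", "h5", {"gabapentin", "prednisone"}),
    ]
    return [
        AdmissionDrugSet(subject_id=s, hadm_id=h, drugs=frozenset(d))
        for s, h, d in sets
    ]


@pytest.fixture
def toy_genes() -> DrugGeneMap:
    return DrugGeneMap(
        {
            "aspirin": {"PTGS1", "PTGS2"},
            "warfarin": {"VKORC1", "CYP2C9"},
            "heparin": {"SERPINC1"},
            "prednisone": {"NR3C1", "PTGS2"},
            "gabapentin": {"CACNA2D1"},
        }
    )


@pytest.fixture
def toy_risks() -> RiskTable:
    t = RiskTable()
    t.set("aspirin", "warfarin", RiskLevel.HIGH)
    t.set("aspirin", "heparin", RiskLevel.MODERATE)
    t.set("warfarin", "heparin", RiskLevel.HIGH)
    t.set("aspirin", "prednisone", RiskLevel.LOW)
    return t
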