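"""Shared hand-built terminology fixtures for the unit tests."""

import pytest

from clingenmap.rrf_io import (
    ConceptAtom,
    CoOccurrence,
    ConceptRelation,
    SemanticTypeAssignment,
    build_kb,
)

# A tiny hand-written knowledge base:
#   C0000001 gene alpha      (T028)  -- related to c1 via MRREL, to d1/d2 via MRCOC
#   C0000002 gene beta       (T028)  -- shares the atom "shared term" with g1
#   C0000011 abdominal pain  (T184)  -- related to g1 (MRREL), d1 (MRREL)
#   C0000012 blood glucose   (T059)  -- related to d2 (MRCOC freq 1)
#   C0000021 colorectal carcinoma (T047, CRC-flagged by name)
#   C0000022 benign disorder (T047)
#   C0000031 compound x      (T109, no mapping role)
G1, G2 = "C0000001", "C0000002"
C1, C2 = "C0000011", "C0000012"
D1, D2 = "C0000021", "C0000022"
X1 = "C0000031"


def _atoms():
    return [
        ConceptAtom.make(G1, "gene alpha", source_code="101", preferred=True),
        ConceptAtom.make(G1, "Genes, alpha", source_vocabulary="MSH",
                         term_type="MH", source_code="D000101"),
        ConceptAtom.make(G1, "alpha gene synonym", source_vocabulary="MSH",
                         term_type="EN", source_code="D000101"),
        ConceptAtom.make(G1, "old alpha name", source_vocabulary="MSH",
                         term_type="EN", source_code="D000101", suppressed=True),
        ConceptAtom.make(G1, "shared term", source_code="109"),
        ConceptAtom.make(G2, "gene beta", source_code="102", preferred=True),
        ConceptAtom.make(G2, "shared term", source_code="110"),
        ConceptAtom.make(C1, "abdominal pain", source_code="201", preferred=True),
        ConceptAtom.make(C1, "Abdominal Pain", source_vocabulary="MSH",
                         term_type="MH", source_code="D000201", preferred=True),
        ConceptAtom.make(C2, "blood glucose", source_code="202", preferred=True),
        ConceptAtom.make(D1, "colorectal carcinoma", source_code="301",
                         preferred=True),
        ConceptAtom.make(D2, "benign disorder", source_code="302",
                         preferred=True),
        ConceptAtom.make(X1, "compound x", source_code="401", preferred=True),
    ]


def _relations():
    return [
        ConceptRelation.make(G1, "RO", C1),
        ConceptRelation.make(C1, "RO", D1),
        ConceptRelation.make(G1, "RO", G1),                 # self, ignored
        ConceptRelation.make(G2, "RO", C2, suppressed=True),  # suppressed
    ]


def _cooccurrences():
    return [
        CoOccurrence.make(G1, D1, 2),
        CoOccurrence.make(D2, G1, 1),
        CoOccurrence.make(C2, D2, 1),
        CoOccurrence.make(G1, X1, 4),
    ]


def _semantic_types():
    return [
        SemanticTypeAssignment.make(G1, "T028", semantic_type_name="Gene or Genome"),
        SemanticTypeAssignment.make(G2, "T028", semantic_type_name="Gene or Genome"),
        SemanticTypeAssignment.make(C1, "T184", semantic_type_name="Sign or Symptom"),
        SemanticTypeAssignment.make(C2, "T059", semantic_type_name="Laboratory Procedure"),
        SemanticTypeAssignment.make(D1, "T047", semantic_type_name="Disease or Syndrome"),
        SemanticTypeAssignment.make(D1, "T191", semantic_type_name="Neoplastic Process"),
        SemanticTypeAssignment.make(D2, "T047", semantic_type_name="Disease or Syndrome"),
        SemanticTypeAssignment.make(X1, "T109", semantic_type_name="Organic Chemical"),
    ]


@pytest.fixture(scope="session")
def tiny_tables():
    return {
        "mrconso": _atoms(),
        "mrrel": _relations(),
        "mrcoc": _cooccurrences(),
        "mrsty": _semantic_types(),
    }


@pytest.fixture(scope="session")
def tiny_kb(tiny_tables):
    return build_kb(**tiny_tables)
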