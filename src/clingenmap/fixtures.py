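"""Synthetic terminology, literature and OMIM fixtures with known ground truth.

The generator emits a miniature UMLS-like knowledge base — concept atoms in
a SNOMED-like and a MeSH-like source vocabulary, directed relations,
co-occurrence rows with frequencies, and semantic-type assignments for
gene-like, clinical-finding-like and disease-like concepts — together with
the exact relation sets the mapping pipeline should recover.  Ground truth
is computed by the generator's own bookkeeping (set intersection over the
links it sampled), never by calling the mapping engine, so pipeline-vs-
truth comparisons are a genuine oracle test.

Everything is deterministic per seed: the same :class:`FixtureSpec` yields
byte-identical files.

Also packaged here: the loader for the published table of representative
validated clinic-genomic relations for colorectal cancer (ten clinical
items with their gene lists), shipped as package data.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .keywords import matches_keyword_groups
from .omim import GeneLinkTable, OmimEntry
from .rrf_io import (
    ConceptAtom,
    CoOccurrence,
    ConceptRelation,
    SemanticTypeAssignment,
    write_rrf_table,
)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "FixtureBundle",
    "build_fixture",
    "generate_mini_umls",
    "generate_literature_index",
    "OmimFixture",
    "generate_omim_snapshot",
    "load_table1_relations",
    "table1_genes",
]

SNOMED_LIKE_SOURCE = "SNOMEDCT"
MESH_LIKE_SOURCE = "MSH"
CONTEXT_TERM = "Colorectal neoplasms"

GENE_TUI = "T028"      # Gene or Genome
CLINICAL_TUI = "T184"  # Sign or Symptom
DISEASE_TUI = "T047"   # Disease or Syndrome
OTHER_TUI = "T109"     # Organic Chemical (outside every mapping role)

_REL_LABELS = ("RO", "RQ")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture set.

    Defaults give a knowledge base of a few dozen concepts — the scale the
    mapping study runs at per concept pair — with sparse direct gene-to-
    finding links, denser disease neighbourhoods, half the diseases
    colorectal-cancer-related, and literature support for 60% of the true
    relations so the validation gate genuinely filters.
    """

    seed: int = 0
    n_genes: int = 10
    n_clinical: int = 10
    n_diseases: int = 8
    n_other: int = 10
    p_direct_link: float = 0.15
    p_disease_link: float = 0.30
    crc_fraction: float = 0.5
    literature_support_fraction: float = 0.6

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_clinical", "n_diseases", "n_other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("p_direct_link", "p_disease_link", "crc_fraction",
                     "literature_support_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """The relation sets the pipeline should recover, as CUI pairs."""

    direct_relations: frozenset[tuple[str, str]]
    indirect_relations: frozenset[tuple[str, str]]
    supported_pairs: frozenset[tuple[str, str]]

    @property
    def all_pairs(self) -> frozenset[tuple[str, str]]:
        return self.direct_relations | self.indirect_relations

    def to_json(self) -> dict:
        return {
            "direct_relations": sorted(map(list, self.direct_relations)),
            "indirect_relations": sorted(map(list, self.indirect_relations)),
            "supported_pairs": sorted(map(list, self.supported_pairs)),
        }

    @classmethod
    def from_json(cls, payload: dict) -> "GroundTruth":
        return cls(
            frozenset(map(tuple, payload["direct_relations"])),
            frozenset(map(tuple, payload["indirect_relations"])),
            frozenset(map(tuple, payload["supported_pairs"])),
        )


@dataclass(frozen=True)
class FixtureBundle:
    """In-memory fixture set: RRF rows, concept sets and ground truth."""

    spec: FixtureSpec
    mrconso: tuple[ConceptAtom, ...]
    mrrel: tuple[ConceptRelation, ...]
    mrcoc: tuple[CoOccurrence, ...]
    mrsty: tuple[SemanticTypeAssignment, ...]
    gene_cuis: tuple[str, ...]
    clinical_cuis: tuple[str, ...]
    disease_cuis: tuple[str, ...]
    other_cuis: tuple[str, ...]
    crc_disease_cuis: frozenset[str]
    mesh_terms: dict[str, str]  # CUI -> preferred MeSH-source term
    truth: GroundTruth

    @property
    def n_cuis(self) -> int:
        return (len(self.gene_cuis) + len(self.clinical_cuis)
                + len(self.disease_cuis) + len(self.other_cuis))


def _cui(index: int) -> str:
    return f"C{index:07d}"


def build_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate one fixture set in memory, deterministically per seed."""
    rng = random.Random(spec.seed)

    names: dict[str, str] = {}
    next_index = 1

    def allocate(count: int, namer) -> tuple[str, ...]:
        nonlocal next_index
        cuis = []
        for i in range(count):
            cui = _cui(next_index)
            next_index += 1
            names[cui] = namer(i)
            cuis.append(cui)
        return tuple(cuis)

    n_crc = round(spec.crc_fraction * spec.n_diseases)
    gene_cuis = allocate(spec.n_genes, lambda i: f"gene-{i:03d}")
    clinical_cuis = allocate(spec.n_clinical, lambda i: f"finding-{i:03d}")
    disease_cuis = allocate(
        spec.n_diseases,
        lambda i: (f"colorectal carcinoma type {i}" if i < n_crc
                   else f"benign disorder {i}"))
    other_cuis = allocate(spec.n_other, lambda i: f"compound-{i:03d}")
    crc_set = frozenset(disease_cuis[:n_crc])
    # the CRC flag must agree with the keyword semantics the mapper applies
    for cui in disease_cuis:
        assert matches_keyword_groups(names[cui]) == (cui in crc_set)

    mrconso: list[ConceptAtom] = []
    mesh_terms: dict[str, str] = {}
    for offset, cui in enumerate(gene_cuis + clinical_cuis
                                 + disease_cuis + other_cuis):
        name = names[cui]
        mrconso.append(ConceptAtom.make(
            cui, name, source_vocabulary=SNOMED_LIKE_SOURCE,
            source_code=str(400000 + offset), preferred=True))
        mesh_term = f"{name} mesh"
        mesh_terms[cui] = mesh_term
        mrconso.append(ConceptAtom.make(
            cui, mesh_term, source_vocabulary=MESH_LIKE_SOURCE,
            term_type="MH", source_code=f"D{offset:06d}"))
        if rng.random() < 0.3:  # occasional MeSH synonym, never preferred
            mrconso.append(ConceptAtom.make(
                cui, f"{name} mesh synonym",
                source_vocabulary=MESH_LIKE_SOURCE, term_type="EN",
                source_code=f"D{offset:06d}"))

    mrrel: list[ConceptRelation] = []
    mrcoc: list[CoOccurrence] = []

    def add_link(a: str, b: str) -> None:
        """One qualifying MRREL or MRCOC row, random kind and orientation."""
        if rng.random() < 0.5:
            a, b = b, a
        if rng.random() < 0.5:
            mrrel.append(ConceptRelation.make(a, rng.choice(_REL_LABELS), b))
        else:
            mrcoc.append(CoOccurrence.make(a, b, rng.randint(1, 5)))

    direct_pairs: set[tuple[str, str]] = set()
    for g in gene_cuis:
        for c in clinical_cuis:
            if rng.random() < spec.p_direct_link:
                direct_pairs.add((g, c))
                add_link(g, c)

    disease_links: dict[str, set[str]] = {}
    for cui in gene_cuis + clinical_cuis:
        linked: set[str] = set()
        for d in disease_cuis:
            if rng.random() < spec.p_disease_link:
                linked.add(d)
                add_link(cui, d)
        disease_links[cui] = linked

    # noise the semantic-type filter must reject
    for o in other_cuis:
        if gene_cuis and rng.random() < 0.3:
            add_link(o, rng.choice(gene_cuis))
        if clinical_cuis and rng.random() < 0.3:
            add_link(o, rng.choice(clinical_cuis))
    # degenerate and suppressed rows the traversal must ignore
    if gene_cuis:
        self_cui = rng.choice(gene_cuis)
        mrrel.append(ConceptRelation.make(self_cui, "RO", self_cui))
    if gene_cuis and clinical_cuis:
        g, c = rng.choice(gene_cuis), rng.choice(clinical_cuis)
        if (g, c) not in direct_pairs:
            mrrel.append(ConceptRelation.make(g, "RO", c, suppressed=True))

    # indirect truth: generator-side set intersection over sampled links
    indirect_pairs: set[tuple[str, str]] = set()
    for g in gene_cuis:
        for c in clinical_cuis:
            if disease_links[g] & disease_links[c] & crc_set:
                indirect_pairs.add((g, c))

    all_pairs = sorted(direct_pairs | indirect_pairs)
    supported = frozenset(
        pair for pair in all_pairs
        if rng.random() < spec.literature_support_fraction)

    mrsty: list[SemanticTypeAssignment] = []
    for cui in gene_cuis:
        mrsty.append(SemanticTypeAssignment.make(
            cui, GENE_TUI, semantic_type_name="Gene or Genome"))
    for cui in clinical_cuis:
        mrsty.append(SemanticTypeAssignment.make(
            cui, CLINICAL_TUI, semantic_type_name="Sign or Symptom"))
    for cui in disease_cuis:
        mrsty.append(SemanticTypeAssignment.make(
            cui, DISEASE_TUI, semantic_type_name="Disease or Syndrome"))
    for cui in other_cuis:
        mrsty.append(SemanticTypeAssignment.make(
            cui, OTHER_TUI, semantic_type_name="Organic Chemical"))

    truth = GroundTruth(frozenset(direct_pairs), frozenset(indirect_pairs),
                        supported)
    return FixtureBundle(
        spec=spec,
        mrconso=tuple(mrconso), mrrel=tuple(mrrel),
        mrcoc=tuple(mrcoc), mrsty=tuple(mrsty),
        gene_cuis=gene_cuis, clinical_cuis=clinical_cuis,
        disease_cuis=disease_cuis, other_cuis=other_cuis,
        crc_disease_cuis=crc_set, mesh_terms=mesh_terms, truth=truth)


def generate_mini_umls(spec: FixtureSpec, out_dir: str | Path
                       ) -> tuple[dict[str, Path], GroundTruth]:
    """Write a complete fixture set to ``out_dir``.

    Emits the four RRF files, the G and C concept-set files (explicit CUI
    references), the offline literature index, the fixture spec and the
    ground truth as JSON.  Returns the path map and the ground truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = build_fixture(spec)

    paths = {
        "mrconso": out_dir / "MRCONSO.RRF",
        "mrrel": out_dir / "MRREL.RRF",
        "mrcoc": out_dir / "MRCOC.RRF",
        "mrsty": out_dir / "MRSTY.RRF",
        "genes": out_dir / "genes.txt",
        "clinical": out_dir / "clinical.txt",
        "literature_index": out_dir / "literature_index.tsv",
        "ground_truth": out_dir / "ground_truth.json",
        "fixture_spec": out_dir / "fixture_spec.json",
    }
    write_rrf_table(bundle.mrconso, paths["mrconso"])
    write_rrf_table(bundle.mrrel, paths["mrrel"])
    write_rrf_table(bundle.mrcoc, paths["mrcoc"])
    write_rrf_table(bundle.mrsty, paths["mrsty"])

    for key, cuis in (("genes", bundle.gene_cuis),
                      ("clinical", bundle.clinical_cuis)):
        with open(paths[key], "w", encoding="utf-8") as handle:
            for cui in cuis:
                handle.write(f"CUI:{cui}\n")

    _write_index(bundle, paths["literature_index"])

    with open(paths["ground_truth"], "w", encoding="utf-8") as handle:
        json.dump(bundle.truth.to_json(), handle, indent=2, sort_keys=True)
        handle.write("\n")
    with open(paths["fixture_spec"], "w", encoding="utf-8") as handle:
        json.dump(vars(spec) | {}, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return paths, bundle.truth


def _write_index(bundle: FixtureBundle, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for i, (g, c) in enumerate(sorted(bundle.truth.supported_pairs)):
            terms = ";".join((bundle.mesh_terms[c], bundle.mesh_terms[g],
                              CONTEXT_TERM))
            handle.write(f"REC{i:04d}\t{terms}\n")


def generate_literature_index(truth: GroundTruth, spec: FixtureSpec,
                              path: str | Path) -> None:
    """Write the offline literature index for a fixture's supported pairs.

    One record per supported (genomic, clinical) pair, annotated with both
    concepts' MeSH terms plus the context heading.  The bundle is rebuilt
    from ``spec`` (deterministic) to recover the MeSH term strings.
    """
    bundle = build_fixture(spec)
    if truth != bundle.truth:
        raise ValueError("ground truth does not belong to this fixture spec")
    _write_index(bundle, Path(path))


# ---------------------------------------------------------------------------
# OMIM-style snapshot fixture

_POSITIVE_SITES = ("colon", "colorectal", "colonic", "rectal")
_POSITIVE_DISEASES = ("cancer", "carcinoma", "adenoma")
# decoys: each draws from at most one keyword group, so a negative entry can
# never combine a site word with a disease word across its fields
_NEGATIVE_SNIPPETS = (
    "semicolon cancer notation in text",
    "carcinoma of the stomach",
    "colonic polyposis without malignancy",
    "rectal examination normal",
    "unrelated cardiomyopathy phenotype",
    "hereditary deafness locus",
)
_NEGATIVE_SITE_FREE = _NEGATIVE_SNIPPETS[:2] + _NEGATIVE_SNIPPETS[4:]
_NEGATIVE_DISEASE_FREE = _NEGATIVE_SNIPPETS[2:]


@dataclass(frozen=True)
class OmimFixture:
    """Synthetic OMIM-style snapshot with link tables and expected outputs."""

    entries: tuple[OmimEntry, ...]
    mim_to_gene: GeneLinkTable
    gene_to_protein: GeneLinkTable
    gene_to_article: GeneLinkTable
    matching_mim_ids: frozenset[str]
    expected_genes: frozenset[str]
    expected_proteins: frozenset[str]
    expected_articles: frozenset[str]


def generate_omim_snapshot(seed: int = 0, n_entries: int = 100,
                           match_fraction: float = 0.3) -> OmimFixture:
    """Generate a snapshot whose matching entries are known by construction.

    Positive entries carry a "(site) (disease)" phrase in the title or an
    allelic-variant block; negative entries use decoy text drawn from a
    single keyword group only (including the "semicolon cancer" trap), so
    the expected match set is exact.
    """
    rng = random.Random(seed)
    entries: list[OmimEntry] = []
    matching: set[str] = set()
    mim_gene_rows: set[tuple[str, str]] = set()
    gene_protein_rows: set[tuple[str, str]] = set()
    gene_article_rows: set[tuple[str, str]] = set()

    def gene_for(index: int) -> str:
        return f"GENE{index:03d}"

    next_gene = 0
    for i in range(n_entries):
        mim_id = str(600000 + i)
        positive = rng.random() < match_fraction
        if positive:
            phrase = (f"familial {rng.choice(_POSITIVE_SITES)} "
                      f"{rng.choice(_POSITIVE_DISEASES)} susceptibility")
            if rng.random() < 0.5:
                title, variants = phrase, (f"variant {i}.0001 benign change",)
            else:
                title = f"gene locus {i}"
                variants = (f"variant {i}.0001 associated with {phrase}",)
            matching.add(mim_id)
        else:
            pool = (_NEGATIVE_SITE_FREE if rng.random() < 0.5
                    else _NEGATIVE_DISEASE_FREE)
            title = rng.choice(pool)
            variants = (rng.choice(pool),) if rng.random() < 0.5 else ()
        entries.append(OmimEntry(mim_id, title, variants))

        # every entry links to genes; only matched entries' genes count
        for _ in range(rng.randint(1, 2)):
            gene = gene_for(next_gene)
            next_gene += 1
            mim_gene_rows.add((mim_id, gene))
            for k in range(rng.randint(1, 2)):
                gene_protein_rows.add((gene, f"NP_{next_gene:05d}{k}"))
            for k in range(rng.randint(1, 3)):
                gene_article_rows.add((gene, str(10000000 + 10 * next_gene + k)))

    expected_genes = frozenset(
        gene for mim, gene in mim_gene_rows if mim in matching)
    expected_proteins = frozenset(
        p for g, p in gene_protein_rows if g in expected_genes)
    expected_articles = frozenset(
        a for g, a in gene_article_rows if g in expected_genes)

    return OmimFixture(
        entries=tuple(entries),
        mim_to_gene=GeneLinkTable("mim_to_gene", frozenset(mim_gene_rows)),
        gene_to_protein=GeneLinkTable("gene_to_protein",
                                      frozenset(gene_protein_rows)),
        gene_to_article=GeneLinkTable("gene_to_article",
                                      frozenset(gene_article_rows)),
        matching_mim_ids=frozenset(matching),
        expected_genes=expected_genes,
        expected_proteins=expected_proteins,
        expected_articles=expected_articles,
    )


# ---------------------------------------------------------------------------
# published representative relations (packaged dataset)

def load_table1_relations() -> dict[str, tuple[str, ...]]:
    """The published representative validated relations: ten clinical items
    mapped to their gene lists, in printed order."""
    ref = resources.files("clingenmap").joinpath("data/table1_relations.tsv")
    try:
        text = ref.read_text(encoding="utf-8")
    except FileNotFoundError as exc:
        raise FileNotFoundError("packaged relation table is missing") from exc
    relations: dict[str, tuple[str, ...]] = {}
    lines = [line for line in text.splitlines() if line.strip()]
    if not lines or lines[0].split("\t") != ["clinical_item", "genes"]:
        raise ValueError("packaged relation table is corrupt")
    for line in lines[1:]:
        item, _, genes = line.partition("\t")
        if not item or not genes:
            raise ValueError("packaged relation table is corrupt")
        relations[item] = tuple(genes.split(";"))
    return relations


def table1_genes(clinical_item: str) -> frozenset[str]:
    """Gene set for one clinical item; unknown items give an empty set."""
    return frozenset(load_table1_relations().get(clinical_item, ()))
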