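"""Direct and indirect clinic-genomic concept mapping over a terminology KB.

Two mapping methods relate a genomic concept set G (genes) with a clinical
concept set C (SNOMED-coded clinical items):

* **Direct mapping** — resolve a source concept to its CUI(s) in MRCONSO,
  collect the concepts one relation (MRREL) or co-occurrence (MRCOC) step
  away, keep those with the desired semantic type (MRSTY), and intersect
  with the opposite concept set.  Running it with G as sources gives
  genomic-to-clinic relations; with C as sources, clinic-to-genomic.

* **Indirect mapping via disease** — for a gene g collect its related
  disease concepts U1, for a clinical item c collect U2; if U1 and U2 share
  a disease concept that is itself colorectal-cancer-related, (g, c) is an
  (undirected) candidate relation, with the shared diseases as evidence.

All outputs are deterministic: sorted by (genomic CUI, clinical CUI,
method) with evidence tuples sorted internally.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .keywords import DISEASE_KEYWORDS, SITE_KEYWORDS, matches_keyword_groups
from .rrf_io import CUI_PATTERN, TerminologyKB

__all__ = [
    "DEFAULT_GENOMIC_TUIS",
    "DEFAULT_CLINICAL_TUIS",
    "DEFAULT_DISEASE_TUIS",
    "MappingConfig",
    "ConceptSet",
    "CandidateRelation",
    "resolve_cuis",
    "related_concepts",
    "filter_by_semantic_type",
    "direct_map",
    "diseases_for",
    "indirect_map",
    "combine_candidates",
    "write_relations_tsv",
    "write_relations_json",
    "read_relations_tsv",
]

logger = logging.getLogger(__name__)

# UMLS semantic types standardly used for these roles:
# T028 Gene or Genome; T047 Disease or Syndrome; T191 Neoplastic Process;
# T184 Sign or Symptom; T033 Finding; T059 Laboratory Procedure.
DEFAULT_GENOMIC_TUIS = frozenset({"T028"})
DEFAULT_DISEASE_TUIS = frozenset({"T047", "T191"})
DEFAULT_CLINICAL_TUIS = frozenset({"T184", "T033", "T047", "T191", "T059"})

GENOMIC_TO_CLINIC = "genomic_to_clinic"
CLINIC_TO_GENOMIC = "clinic_to_genomic"
UNDIRECTED = "undirected"


@dataclass
class MappingConfig:
    """Tunable parameters of the mapping traversal.

    Defaults take the most inclusive reading of "related": every
    non-suppressed MRREL row in both orientations plus every MRCOC row with
    frequency >= 1 counts, and all semantic-type sets are configurable.
    """

    genomic_tuis: frozenset[str] = DEFAULT_GENOMIC_TUIS
    clinical_tuis: frozenset[str] = DEFAULT_CLINICAL_TUIS
    disease_tuis: frozenset[str] = DEFAULT_DISEASE_TUIS
    #: MRREL REL labels that count as relatedness; empty = all labels.
    rel_whitelist: frozenset[str] = frozenset()
    min_cooccurrence_frequency: int = 1
    #: Explicit colorectal-cancer disease CUIs; None = keyword matching on
    #: the disease concept's preferred term.
    crc_disease_cuis: frozenset[str] | None = None
    crc_site_keywords: frozenset[str] = SITE_KEYWORDS
    crc_disease_keywords: frozenset[str] = DISEASE_KEYWORDS
    use_mrrel: bool = True
    use_mrcoc: bool = True
    treat_relations_as_bidirectional: bool = True
    include_suppressed: bool = False

    def __post_init__(self) -> None:
        if not (self.use_mrrel or self.use_mrcoc):
            raise ValueError("at least one of use_mrrel/use_mrcoc must be enabled")
        if self.min_cooccurrence_frequency < 1:
            raise ValueError("min_cooccurrence_frequency must be >= 1")
        for name in ("genomic_tuis", "clinical_tuis", "disease_tuis",
                     "rel_whitelist", "crc_site_keywords", "crc_disease_keywords"):
            setattr(self, name, frozenset(getattr(self, name)))
        if self.crc_disease_cuis is not None:
            self.crc_disease_cuis = frozenset(self.crc_disease_cuis)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MappingConfig":
        """Load a flat key:value YAML config; unknown keys are rejected."""
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


_CUI_REF_RE = re.compile(r"CUI:(C\d{7})")
_CODE_REF_RE = re.compile(r"(\S+):(\S.*)")


@dataclass(frozen=True)
class ConceptSet:
    """A named set of concept references.

    ``name`` is the set's role: ``G`` (genomic), ``C`` (clinical),
    ``disease`` or ``other``.  Members are raw term strings,
    ``SAB:CODE`` pairs, or explicit ``CUI:Cnnnnnnn`` references.
    """

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("concept set name must be non-empty")
        object.__setattr__(self, "members", tuple(self.members))

    @classmethod
    def from_file(cls, name: str, path: str | Path) -> "ConceptSet":
        """One concept per line; ``#`` starts a comment; blanks ignored."""
        members = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.split("#", 1)[0].strip()
                if line:
                    members.append(line)
        return cls(name, tuple(members))

    def resolve(self, kb: TerminologyKB, *, include_suppressed: bool = False
                ) -> dict[str, frozenset[str]]:
        """Per-member CUI resolution (possibly empty, possibly ambiguous)."""
        return {
            m: resolve_cuis(m, kb, include_suppressed=include_suppressed)
            for m in self.members
        }

    def resolved_cuis(self, kb: TerminologyKB, *,
                      include_suppressed: bool = False) -> frozenset[str]:
        out: set[str] = set()
        for member, cuis in self.resolve(kb, include_suppressed=include_suppressed).items():
            if not cuis:
                logger.warning("concept %r in set %s resolves to no CUI", member, self.name)
            out |= cuis
        return frozenset(out)


@dataclass(frozen=True)
class CandidateRelation:
    """A mapped (genomic CUI, clinical CUI) pair with method and evidence.

    ``evidence`` holds the qualifying MRREL/MRCOC rows for direct relations
    (compact ``MRREL:cui1:REL:cui2`` / ``MRCOC:cui1:cui2:freq`` descriptors)
    and the shared colorectal-cancer disease CUIs for indirect relations.
    """

    genomic_cui: str
    clinical_cui: str
    method: str      # "direct", "indirect" or "direct+indirect"
    direction: str   # genomic_to_clinic / clinic_to_genomic / undirected
    evidence: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.evidence:
            raise ValueError("a candidate relation must carry evidence")
        object.__setattr__(self, "evidence", tuple(self.evidence))

    @property
    def pair(self) -> tuple[str, str]:
        return (self.genomic_cui, self.clinical_cui)

    @property
    def methods(self) -> frozenset[str]:
        return frozenset(self.method.split("+"))

    def sort_key(self) -> tuple[str, str, str, str]:
        return (self.genomic_cui, self.clinical_cui, self.method, self.direction)


def resolve_cuis(concept: str, kb: TerminologyKB, *,
                 include_suppressed: bool = False) -> frozenset[str]:
    """Resolve one concept reference to a (possibly empty) set of CUIs.

    Ambiguity is returned, not resolved: a term that is an atom of several
    concepts yields all of them.  Suppressed atoms are skipped unless
    ``include_suppressed``.
    """
    ref = concept.strip()
    m = _CUI_REF_RE.fullmatch(ref)
    if m:
        cui = m.group(1)
        return frozenset({cui}) if kb.atoms_for_cui(cui) else frozenset()
    m = _CODE_REF_RE.fullmatch(ref)
    if m and m.group(1) in kb.source_vocabularies:
        atoms = kb.atoms_for_code(m.group(1), m.group(2))
    else:
        atoms = kb.atoms_for_term(ref)
    return frozenset(
        a.cui for a in atoms if include_suppressed or not a.suppressed
    )


def related_concepts(cui: str, kb: TerminologyKB, config: MappingConfig
                     ) -> frozenset[str]:
    """Concepts one MRREL/MRCOC step away from ``cui``.

    MRREL rows contribute their counterpart CUI when non-suppressed (unless
    configured otherwise) and, if a relation-label whitelist is set, when
    their REL label is whitelisted; both orientations are walked when
    relations are treated as bidirectional, otherwise only rows with
    ``cui`` on the cui1 side.  MRCOC rows contribute their counterpart when
    the co-occurrence frequency meets the configured minimum.  ``cui``
    itself is never returned (self-relations are ignored).
    """
    out: set[str] = set()
    if config.use_mrrel:
        whitelist = config.rel_whitelist
        for rel in kb.relations_from(cui):
            if rel.suppressed and not config.include_suppressed:
                continue
            if whitelist and rel.rel_label not in whitelist:
                continue
            out.add(rel.cui2)
        if config.treat_relations_as_bidirectional:
            for rel in kb.relations_to(cui):
                if rel.suppressed and not config.include_suppressed:
                    continue
                if whitelist and rel.rel_label not in whitelist:
                    continue
                out.add(rel.cui1)
    if config.use_mrcoc:
        for coc in kb.cooccurrences_of(cui):
            if coc.frequency >= config.min_cooccurrence_frequency:
                out.add(coc.cui2 if coc.cui1 == cui else coc.cui1)
    out.discard(cui)
    return frozenset(out)


def filter_by_semantic_type(cuis: Iterable[str], kb: TerminologyKB,
                            allowed_tuis: frozenset[str]) -> frozenset[str]:
    """Keep the CUIs carrying at least one semantic type in ``allowed_tuis``."""
    allowed = frozenset(allowed_tuis)
    return frozenset(c for c in cuis if kb.semantic_types(c) & allowed)


def _link_evidence(source: str, target: str, kb: TerminologyKB,
                   config: MappingConfig) -> set[str]:
    """Descriptors of the rows that make ``target`` related to ``source``."""
    evidence: set[str] = set()
    if config.use_mrrel:
        whitelist = config.rel_whitelist
        candidates = [r for r in kb.relations_from(source) if r.cui2 == target]
        if config.treat_relations_as_bidirectional:
            candidates += [r for r in kb.relations_to(source) if r.cui1 == target]
        for rel in candidates:
            if rel.suppressed and not config.include_suppressed:
                continue
            if whitelist and rel.rel_label not in whitelist:
                continue
            evidence.add(f"MRREL:{rel.cui1}:{rel.rel_label}:{rel.cui2}")
    if config.use_mrcoc:
        for coc in kb.cooccurrences_of(source):
            if {coc.cui1, coc.cui2} != {source, target}:
                continue
            if coc.frequency >= config.min_cooccurrence_frequency:
                evidence.add(f"MRCOC:{coc.cui1}:{coc.cui2}:{coc.frequency}")
    return evidence


def direct_map(sources: ConceptSet, targets: ConceptSet, kb: TerminologyKB,
               config: MappingConfig | None = None) -> list[CandidateRelation]:
    """Direct information mapping from ``sources`` into ``targets``.

    One of the two sets must be named ``G`` and the other ``C``; the
    direction of the emitted relations records which set supplied the
    sources.  For each source CUI the one-step related concepts are
    filtered to the target role's semantic types and intersected with the
    resolved target set; each hit becomes a candidate relation whose
    evidence is the qualifying MRREL/MRCOC rows.  Output is deduplicated on
    (genomic CUI, clinical CUI, direction) with merged evidence, sorted.
    """
    config = config or MappingConfig()
    roles = {sources.name, targets.name}
    if roles != {"G", "C"}:
        raise ValueError(
            f"direct_map needs one set named 'G' and one named 'C', got {roles}")
    src_is_genomic = sources.name == "G"
    target_tuis = config.clinical_tuis if src_is_genomic else config.genomic_tuis
    direction = GENOMIC_TO_CLINIC if src_is_genomic else CLINIC_TO_GENOMIC

    target_cuis = targets.resolved_cuis(kb, include_suppressed=config.include_suppressed)
    source_cuis = sources.resolved_cuis(kb, include_suppressed=config.include_suppressed)

    merged: dict[tuple[str, str], set[str]] = {}
    for s in sorted(source_cuis):
        related = related_concepts(s, kb, config)
        hits = filter_by_semantic_type(related, kb, target_tuis) & target_cuis
        for t in sorted(hits):
            g, c = (s, t) if src_is_genomic else (t, s)
            merged.setdefault((g, c), set()).update(_link_evidence(s, t, kb, config))
    return [
        CandidateRelation(g, c, "direct", direction, tuple(sorted(ev)))
        for (g, c), ev in sorted(merged.items())
    ]


def diseases_for(cui: str, kb: TerminologyKB, config: MappingConfig | None = None
                 ) -> frozenset[str]:
    """Disease concepts one step away from ``cui`` (direct mapping with the
    disease semantic types as the filter)."""
    config = config or MappingConfig()
    if not config.disease_tuis:
        raise ValueError("disease_tuis must be non-empty")
    return filter_by_semantic_type(related_concepts(cui, kb, config), kb,
                                   config.disease_tuis)


def is_crc_disease(cui: str, kb: TerminologyKB, config: MappingConfig) -> bool:
    """Is this disease concept colorectal-cancer-related?

    With an explicit CUI list configured, membership decides; otherwise the
    concept's preferred term must contain a whole word from each of the
    site and disease keyword groups (the same boolean combination used for
    the OMIM snapshot search).
    """
    if config.crc_disease_cuis is not None:
        return cui in config.crc_disease_cuis
    term = kb.preferred_term(cui)
    return bool(term) and matches_keyword_groups(
        term, config.crc_site_keywords, config.crc_disease_keywords)


def indirect_map(genomic: ConceptSet, clinical: ConceptSet, kb: TerminologyKB,
                 config: MappingConfig | None = None) -> list[CandidateRelation]:
    """Indirect information mapping via shared colorectal-cancer diseases.

    For every (g, c) pair of resolved genomic x clinical CUIs, the shared
    disease neighbourhood U1(g) ∩ U2(c) is restricted to colorectal-cancer
    diseases; a non-empty remainder yields one undirected candidate
    relation with those disease CUIs as evidence.
    """
    config = config or MappingConfig()
    g_cuis = sorted(genomic.resolved_cuis(kb, include_suppressed=config.include_suppressed))
    c_cuis = sorted(clinical.resolved_cuis(kb, include_suppressed=config.include_suppressed))
    u1 = {g: diseases_for(g, kb, config) for g in g_cuis}
    u2 = {c: diseases_for(c, kb, config) for c in c_cuis}
    crc_cache: dict[str, bool] = {}

    def crc(d: str) -> bool:
        if d not in crc_cache:
            crc_cache[d] = is_crc_disease(d, kb, config)
        return crc_cache[d]

    out: list[CandidateRelation] = []
    for g in g_cuis:
        for c in c_cuis:
            shared = {d for d in u1[g] & u2[c] if crc(d)}
            if shared:
                out.append(CandidateRelation(g, c, "indirect", UNDIRECTED,
                                             tuple(sorted(shared))))
    out.sort(key=CandidateRelation.sort_key)
    return out


def combine_candidates(direct: Sequence[CandidateRelation],
                       indirect: Sequence[CandidateRelation],
                       dedup: bool = False) -> list[CandidateRelation]:
    """Combine direct and indirect candidates.

    ``dedup=False`` simply concatenates (each pair may appear once per
    method/direction, matching a count that ignores method overlap).
    ``dedup=True`` merges to one relation per (genomic, clinical) pair with
    method tags joined by ``+``, evidence unioned, and direction collapsed
    to ``undirected`` when the merged relations disagree.
    """
    if not dedup:
        return list(direct) + list(indirect)
    merged: dict[tuple[str, str], tuple[set[str], set[str], set[str]]] = {}
    for rel in list(direct) + list(indirect):
        methods, directions, evidence = merged.setdefault(
            rel.pair, (set(), set(), set()))
        methods.update(rel.methods)
        directions.add(rel.direction)
        evidence.update(rel.evidence)
    out = []
    for (g, c), (methods, directions, evidence) in sorted(merged.items()):
        directed = directions - {UNDIRECTED}
        direction = directed.pop() if len(directed) == 1 else UNDIRECTED
        out.append(CandidateRelation(g, c, "+".join(sorted(methods)),
                                     direction, tuple(sorted(evidence))))
    out.sort(key=CandidateRelation.sort_key)
    return out


# ---------------------------------------------------------------------------
# serialization

_TSV_COLUMNS = ("genomic_cui", "genomic_label", "clinical_cui",
                "clinical_label", "method", "direction", "evidence")


def write_relations_tsv(relations: Sequence[CandidateRelation],
                        path: str | Path, kb: TerminologyKB | None = None,
                        provenance: Sequence[str] = ()) -> None:
    """Write relations as TSV with ``#`` provenance header lines."""
    with open(path, "w", encoding="utf-8") as handle:
        for line in provenance:
            handle.write(f"# {line}\n")
        handle.write("\t".join(_TSV_COLUMNS) + "\n")
        for rel in relations:
            g_label = (kb.preferred_term(rel.genomic_cui) or "") if kb else ""
            c_label = (kb.preferred_term(rel.clinical_cui) or "") if kb else ""
            handle.write("\t".join((
                rel.genomic_cui, g_label, rel.clinical_cui, c_label,
                rel.method, rel.direction, ";".join(rel.evidence))) + "\n")


def read_relations_tsv(path: str | Path) -> list[CandidateRelation]:
    """Read a relation TSV written by :func:`write_relations_tsv`."""
    relations = []
    with open(path, encoding="utf-8") as handle:
        header: list[str] | None = None
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                if tuple(header) != _TSV_COLUMNS:
                    raise ValueError(f"{path}: unexpected relation TSV header")
                continue
            parts = line.split("\t")
            row = dict(zip(header, parts))
            relations.append(CandidateRelation(
                row["genomic_cui"], row["clinical_cui"], row["method"],
                row["direction"],
                tuple(row["evidence"].split(";")) if row["evidence"] else ()))
    return relations


def write_relations_json(relations: Sequence[CandidateRelation],
                         path: str | Path, kb: TerminologyKB | None = None) -> None:
    payload = [
        {
            "genomic_cui": rel.genomic_cui,
            "genomic_label": (kb.preferred_term(rel.genomic_cui) or "") if kb else "",
            "clinical_cui": rel.clinical_cui,
            "clinical_label": (kb.preferred_term(rel.clinical_cui) or "") if kb else "",
            "method": rel.method,
            "direction": rel.direction,
            "evidence": list(rel.evidence),
        }
        for rel in relations
    ]
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
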