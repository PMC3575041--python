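"""Literature co-occurrence validation of candidate relations.

A candidate clinic-genomic relation (X, Y) passes validation when at least
one indexed article is annotated with a MeSH term of X, a MeSH term of Y
and the context heading "Colorectal neoplasms".  The MeSH terms of a
concept are its atoms from the MeSH-like source vocabulary in MRCONSO; the
search itself runs against either a bundled offline index (one record per
line: id, tab, ";"-joined MeSH annotations) or the live PubMed esearch
endpoint of NCBI's E-utilities.

The rendered query is the exact template
``{X}[MeSH Terms] AND {Y}[MeSH Terms] AND {context}[MeSH Terms]`` — the
live endpoint's behaviour depends on this string, so it is regression-
tested bit-exactly.
"""

from __future__ import annotations

import itertools
import logging
import time
import urllib.error
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence

from .concept_mapping import CandidateRelation
from .rrf_io import TerminologyKB

__all__ = [
    "DEFAULT_CONTEXT_TERM",
    "DEFAULT_MESH_SOURCE",
    "MeshTermSet",
    "ValidationQuery",
    "ValidatedRelation",
    "LiteratureBackendError",
    "TransientBackendError",
    "MalformedResponseError",
    "ValidationAborted",
    "OfflineLiteratureIndex",
    "EntrezLiteratureBackend",
    "mesh_terms_for",
    "build_query",
    "count_hits",
    "validate_relations",
    "write_validation_report",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTEXT_TERM = "Colorectal neoplasms"
DEFAULT_MESH_SOURCE = "MSH"

QUERY_TEMPLATE = "{x}[MeSH Terms] AND {y}[MeSH Terms] AND {context}[MeSH Terms]"


@dataclass(frozen=True)
class MeshTermSet:
    """The MeSH vocabulary terms of one concept, preferred term first."""

    cui: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for term in self.terms:
            key = term.casefold()
            if key not in seen:
                seen.add(key)
                deduped.append(term)
        object.__setattr__(self, "terms", tuple(deduped))

    def __bool__(self) -> bool:
        return bool(self.terms)


@dataclass(frozen=True)
class ValidationQuery:
    """One rendered three-term MeSH query."""

    x_term: str
    y_term: str
    context_term: str

    @property
    def rendered(self) -> str:
        return QUERY_TEMPLATE.format(x=self.x_term, y=self.y_term,
                                     context=self.context_term)

    @property
    def terms(self) -> tuple[str, str, str]:
        return (self.x_term, self.y_term, self.context_term)


@dataclass(frozen=True)
class ValidatedRelation:
    """A candidate relation plus its literature-validation outcome."""

    relation: CandidateRelation
    queries: tuple[ValidationQuery, ...]
    hit_count: int

    @property
    def passed(self) -> bool:
        return self.hit_count >= 1


class LiteratureBackendError(RuntimeError):
    """The literature backend failed; never reported as a zero hit count."""


class TransientBackendError(LiteratureBackendError):
    """Network-level failure that persisted through the bounded retries."""


class MalformedResponseError(LiteratureBackendError):
    """The backend answered but the result count could not be parsed."""


class ValidationAborted(RuntimeError):
    """A batch validation stopped on a backend error.

    ``validated`` holds the completed prefix so the batch can resume after
    the already-processed candidates.
    """

    def __init__(self, message: str, validated: tuple[ValidatedRelation, ...]):
        super().__init__(message)
        self.validated = validated


class LiteratureBackend(Protocol):
    def count(self, query: ValidationQuery) -> int: ...


def mesh_terms_for(cui: str, kb: TerminologyKB,
                   mesh_source: str = DEFAULT_MESH_SOURCE) -> MeshTermSet:
    """MeSH-source atom strings of ``cui``, non-suppressed, preferred first.

    An empty set is a valid outcome; the relation will then fail validation
    with zero hits (logged, not raised).
    """
    atoms = [a for a in kb.atoms_for_cui(cui)
             if a.source_vocabulary == mesh_source and not a.suppressed]
    # preferred atoms first, then main headings (MH) before entry terms
    atoms.sort(key=lambda a: (not a.is_preferred, a.term_type != "MH",
                              a.term_type, a.term_string))
    return MeshTermSet(cui, tuple(a.term_string for a in atoms))


def build_query(x_term: str, y_term: str,
                context_term: str = DEFAULT_CONTEXT_TERM) -> ValidationQuery:
    """Render the three-term MeSH query; all terms must be non-empty."""
    for name, value in (("x_term", x_term), ("y_term", y_term),
                        ("context_term", context_term)):
        if not value:
            raise ValueError(f"{name} must be non-empty")
    return ValidationQuery(x_term, y_term, context_term)


def count_hits(query: ValidationQuery, backend: LiteratureBackend) -> int:
    """Article count for ``query`` from the given backend (offline or live)."""
    return backend.count(query)


class OfflineLiteratureIndex:
    """Line-oriented offline literature index.

    File format: one record per line, ``record_id<TAB>term;term;...``;
    ``#`` lines and blanks are skipped.  A record counts as a hit for a
    query when its annotation set contains all three query terms,
    case-insensitively.
    """

    def __init__(self, records: Sequence[tuple[str, Sequence[str]]] = ()) -> None:
        self._records: list[tuple[str, tuple[str, ...], frozenset[str]]] = []
        for record_id, terms in records:
            self.add(record_id, terms)

    def add(self, record_id: str, terms: Sequence[str]) -> None:
        terms = tuple(terms)
        self._records.append(
            (record_id, terms, frozenset(t.casefold() for t in terms)))

    @classmethod
    def from_file(cls, path: str | Path) -> "OfflineLiteratureIndex":
        index = cls()
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                record_id, _, annotation = line.partition("\t")
                terms = [t for t in annotation.split(";") if t]
                index.add(record_id, terms)
        return index

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for record_id, terms, _ in self._records:
                handle.write(f"{record_id}\t{';'.join(terms)}\n")

    def count(self, query: ValidationQuery) -> int:
        wanted = frozenset(t.casefold() for t in query.terms)
        return sum(1 for _, _, annotation in self._records if wanted <= annotation)

    def __len__(self) -> int:
        return len(self._records)


class EntrezLiteratureBackend:
    """Live article counts from the E-utilities esearch endpoint.

    Reads only the ``Count`` field of ``db=pubmed`` searches.  Requests are
    rate-limited (default ≤3/s) and retried up to ``max_retries`` times
    with exponential backoff on network errors; a response without a
    parseable count raises :class:`MalformedResponseError` immediately.
    The base URL is configurable so tests can target a local stub server.
    """

    DEFAULT_BASE_URL = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/esearch.fcgi"

    def __init__(self, base_url: str = DEFAULT_BASE_URL, *,
                 email: str = "", api_key: str = "", max_retries: int = 3,
                 min_interval: float = 0.34, backoff: float = 1.0,
                 timeout: float = 30.0) -> None:
        self.base_url = base_url
        self.email = email
        self.api_key = api_key
        self.max_retries = max_retries
        self.min_interval = min_interval
        self.backoff = backoff
        self.timeout = timeout
        self._last_request = 0.0

    def _throttle(self) -> None:
        wait = self._last_request + self.min_interval - time.monotonic()
        if wait > 0:
            time.sleep(wait)
        self._last_request = time.monotonic()

    def _url(self, query: ValidationQuery) -> str:
        params = {"db": "pubmed", "term": query.rendered, "retmax": "0"}
        if self.email:
            params["email"] = self.email
        if self.api_key:
            params["api_key"] = self.api_key
        return f"{self.base_url}?{urllib.parse.urlencode(params)}"

    def count(self, query: ValidationQuery) -> int:
        url = self._url(query)
        last_error: Exception | None = None
        for attempt in range(self.max_retries):
            self._throttle()
            try:
                with urllib.request.urlopen(url, timeout=self.timeout) as response:
                    body = response.read()
                break
            except (urllib.error.URLError, TimeoutError, OSError) as exc:
                last_error = exc
                logger.warning("esearch attempt %d failed: %s", attempt + 1, exc)
                time.sleep(self.backoff * 2 ** attempt)
        else:
            raise TransientBackendError(
                f"esearch failed after {self.max_retries} attempts: {last_error}"
            ) from last_error
        try:
            root = ET.fromstring(body)
            count_text = root.findtext("Count")
            if count_text is None:
                raise ValueError("no Count element in esearch result")
            return int(count_text)
        except (ET.ParseError, ValueError) as exc:
            raise MalformedResponseError(
                f"could not parse esearch response: {exc}") from exc


def validate_relations(candidates: Sequence[CandidateRelation],
                       kb: TerminologyKB,
                       backend: LiteratureBackend,
                       context_term: str = DEFAULT_CONTEXT_TERM,
                       mesh_source: str = DEFAULT_MESH_SOURCE,
                       ) -> list[ValidatedRelation]:
    """Validate each candidate by MeSH co-occurrence search.

    For a candidate the X terms are the clinical concept's MeSH terms and
    the Y terms the genomic concept's; (x, y) combinations are tried in
    order — preferred terms first — until the first query with at least one
    hit, whose count is recorded.  A candidate with an empty MeSH term set
    on either side fails with zero hits.  A backend error aborts the batch
    with :class:`ValidationAborted` carrying the validated prefix.
    """
    validated: list[ValidatedRelation] = []
    mesh_cache: dict[str, MeshTermSet] = {}

    def mesh(cui: str) -> MeshTermSet:
        if cui not in mesh_cache:
            mesh_cache[cui] = mesh_terms_for(cui, kb, mesh_source)
        return mesh_cache[cui]

    for candidate in candidates:
        x_set = mesh(candidate.clinical_cui)
        y_set = mesh(candidate.genomic_cui)
        if not x_set or not y_set:
            side = candidate.clinical_cui if not x_set else candidate.genomic_cui
            logger.info("relation %s-%s: no MeSH terms for %s; fails validation",
                        candidate.genomic_cui, candidate.clinical_cui, side)
            validated.append(ValidatedRelation(candidate, (), 0))
            continue
        queries: list[ValidationQuery] = []
        hit_count = 0
        for x_term, y_term in itertools.product(x_set.terms, y_set.terms):
            query = build_query(x_term, y_term, context_term)
            queries.append(query)
            try:
                hits = backend.count(query)
            except LiteratureBackendError as exc:
                raise ValidationAborted(
                    f"backend failed at relation {candidate.genomic_cui}-"
                    f"{candidate.clinical_cui}: {exc}", tuple(validated)
                ) from exc
            if hits >= 1:
                hit_count = hits
                break
        validated.append(ValidatedRelation(candidate, tuple(queries), hit_count))
    return validated


def write_validation_report(validated: Sequence[ValidatedRelation],
                            path: str | Path,
                            kb: TerminologyKB | None = None,
                            provenance: Sequence[str] = ()) -> None:
    """Validation report TSV: candidate columns plus hit_count and passed."""
    columns = ("genomic_cui", "genomic_label", "clinical_cui", "clinical_label",
               "method", "direction", "evidence", "queries_tried",
               "hit_count", "passed")
    with open(path, "w", encoding="utf-8") as handle:
        for line in provenance:
            handle.write(f"# {line}\n")
        handle.write("\t".join(columns) + "\n")
        for item in validated:
            rel = item.relation
            g_label = (kb.preferred_term(rel.genomic_cui) or "") if kb else ""
            c_label = (kb.preferred_term(rel.clinical_cui) or "") if kb else ""
            handle.write("\t".join((
                rel.genomic_cui, g_label, rel.clinical_cui, c_label,
                rel.method, rel.direction, ";".join(rel.evidence),
                str(len(item.queries)), str(item.hit_count),
                "true" if item.passed else "false")) + "\n")
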