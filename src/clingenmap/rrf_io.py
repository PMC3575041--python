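"""Reading, writing and indexing of UMLS Rich Release Format (RRF) tables.

A local UMLS installation produces pipe-delimited flat files; the four this
package consumes are MRCONSO (concept atoms), MRREL (concept-to-concept
relations), MRCOC (concept co-occurrences) and MRSTY (semantic type
assignments).  Each line is a sequence of ``|``-separated fields with a
trailing ``|``.  Only the columns the mapping pipeline interprets are given
typed accessors; every other column is carried verbatim so a read/write
round trip is lossless, which also absorbs release-to-release column drift.

Column positions follow the published RRF layouts:

====== ======================================================================
table  columns (0-based positions of the interpreted fields)
====== ======================================================================
MRCONSO 18 cols; CUI=0, LAT=1, TS=2, ISPREF=6, SAB=11, TTY=12, CODE=13,
        STR=14, SUPPRESS=16
MRREL   16 cols; CUI1=0, REL=3, CUI2=4, RELA=7, SAB=10, SUPPRESS=14
MRCOC    9 cols; CUI1=0, CUI2=2, SAB=4, COT=5, COF=6
MRSTY    6 cols; CUI=0, TUI=1, STY=3
====== ======================================================================
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "CUI_PATTERN",
    "TUI_PATTERN",
    "RrfFormatError",
    "ConceptAtom",
    "ConceptRelation",
    "CoOccurrence",
    "SemanticTypeAssignment",
    "TerminologyKB",
    "read_rrf_table",
    "write_rrf_table",
    "build_kb",
]

CUI_PATTERN = re.compile(r"C\d{7}")
TUI_PATTERN = re.compile(r"T\d{3}")

#: SUPPRESS flag values that mark a row as suppressed (obsolete/editor/source).
_SUPPRESSED_FLAGS = frozenset({"O", "E", "Y"})


class RrfFormatError(ValueError):
    """A line of an RRF file cannot be parsed into the required columns."""


def _is_cui(value: str) -> bool:
    return CUI_PATTERN.fullmatch(value) is not None


@dataclass(frozen=True)
class _RrfRow:
    """Base class: one RRF line as an opaque field tuple plus typed views."""

    fields: tuple[str, ...]

    #: total columns in the published layout (used when building rows).
    NCOLS = 0
    #: minimum columns a parsed line must supply for the typed accessors.
    MIN_FIELDS = 0

    def _get(self, index: int) -> str:
        return self.fields[index] if index < len(self.fields) else ""

    def validate(self) -> None:
        """Raise ``ValueError`` if the row violates its type invariants."""

    def to_line(self) -> str:
        return "|".join(self.fields) + "|"


@dataclass(frozen=True)
class ConceptAtom(_RrfRow):
    """One MRCONSO row: a (CUI, source vocabulary, code, string) atom."""

    NCOLS = 18
    MIN_FIELDS = 17

    @property
    def cui(self) -> str:
        return self._get(0)

    @property
    def language(self) -> str:
        return self._get(1)

    @property
    def is_preferred(self) -> bool:
        """Preferred atom of its concept (TS=P and ISPREF=Y)."""
        return self._get(2) == "P" and self._get(6) == "Y"

    @property
    def source_vocabulary(self) -> str:
        return self._get(11)

    @property
    def term_type(self) -> str:
        return self._get(12)

    @property
    def source_code(self) -> str:
        return self._get(13)

    @property
    def term_string(self) -> str:
        return self._get(14)

    @property
    def suppressed(self) -> bool:
        return self._get(16) in _SUPPRESSED_FLAGS

    @classmethod
    def make(
        cls,
        cui: str,
        term_string: str,
        *,
        language: str = "ENG",
        source_vocabulary: str = "SNOMEDCT",
        term_type: str = "PT",
        source_code: str = "",
        preferred: bool = False,
        suppressed: bool = False,
    ) -> "ConceptAtom":
        fields = [""] * cls.NCOLS
        fields[0] = cui
        fields[1] = language
        fields[2] = "P" if preferred else "S"
        fields[6] = "Y" if preferred else "N"
        fields[11] = source_vocabulary
        fields[12] = term_type
        fields[13] = source_code
        fields[14] = term_string
        fields[16] = "O" if suppressed else "N"
        atom = cls(tuple(fields))
        atom.validate()
        return atom

    def validate(self) -> None:
        if not _is_cui(self.cui):
            raise ValueError(f"invalid CUI {self.cui!r} in MRCONSO row")
        if not self.term_string:
            raise ValueError(f"empty term string for CUI {self.cui}")


@dataclass(frozen=True)
class ConceptRelation(_RrfRow):
    """One MRREL row: a directed relation between two concepts."""

    NCOLS = 16
    MIN_FIELDS = 15

    @property
    def cui1(self) -> str:
        return self._get(0)

    @property
    def rel_label(self) -> str:
        return self._get(3)

    @property
    def cui2(self) -> str:
        return self._get(4)

    @property
    def rela_label(self) -> str:
        return self._get(7)

    @property
    def source_vocabulary(self) -> str:
        return self._get(10)

    @property
    def suppressed(self) -> bool:
        return self._get(14) in _SUPPRESSED_FLAGS

    @classmethod
    def make(
        cls,
        cui1: str,
        rel_label: str,
        cui2: str,
        *,
        rela_label: str = "",
        source_vocabulary: str = "SNOMEDCT",
        suppressed: bool = False,
    ) -> "ConceptRelation":
        fields = [""] * cls.NCOLS
        fields[0] = cui1
        fields[3] = rel_label
        fields[4] = cui2
        fields[7] = rela_label
        fields[10] = source_vocabulary
        fields[14] = "O" if suppressed else "N"
        row = cls(tuple(fields))
        row.validate()
        return row

    def validate(self) -> None:
        for cui in (self.cui1, self.cui2):
            if not _is_cui(cui):
                raise ValueError(f"invalid CUI {cui!r} in MRREL row")


@dataclass(frozen=True)
class CoOccurrence(_RrfRow):
    """One MRCOC row: two concepts co-occurring with a frequency count."""

    NCOLS = 9
    MIN_FIELDS = 7

    @property
    def cui1(self) -> str:
        return self._get(0)

    @property
    def cui2(self) -> str:
        return self._get(2)

    @property
    def source_vocabulary(self) -> str:
        return self._get(4)

    @property
    def cooccurrence_type(self) -> str:
        return self._get(5)

    @property
    def frequency(self) -> int:
        raw = self._get(6)
        return int(raw) if raw else 0

    @classmethod
    def make(
        cls,
        cui1: str,
        cui2: str,
        frequency: int,
        *,
        cooccurrence_type: str = "L",
        source_vocabulary: str = "MED",
    ) -> "CoOccurrence":
        fields = [""] * cls.NCOLS
        fields[0] = cui1
        fields[2] = cui2
        fields[4] = source_vocabulary
        fields[5] = cooccurrence_type
        fields[6] = str(int(frequency))
        row = cls(tuple(fields))
        row.validate()
        return row

    def validate(self) -> None:
        for cui in (self.cui1, self.cui2):
            if not _is_cui(cui):
                raise ValueError(f"invalid CUI {cui!r} in MRCOC row")
        raw = self._get(6)
        if raw:
            try:
                value = int(raw)
            except ValueError as exc:
                raise ValueError(f"non-integer frequency {raw!r}") from exc
            if value < 0:
                raise ValueError(f"negative co-occurrence frequency {value}")


@dataclass(frozen=True)
class SemanticTypeAssignment(_RrfRow):
    """One MRSTY row: a semantic type (TUI) assigned to a concept."""

    NCOLS = 6
    MIN_FIELDS = 4

    @property
    def cui(self) -> str:
        return self._get(0)

    @property
    def tui(self) -> str:
        return self._get(1)

    @property
    def semantic_type_name(self) -> str:
        return self._get(3)

    @classmethod
    def make(
        cls, cui: str, tui: str, *, semantic_type_name: str = ""
    ) -> "SemanticTypeAssignment":
        fields = [""] * cls.NCOLS
        fields[0] = cui
        fields[1] = tui
        fields[3] = semantic_type_name
        row = cls(tuple(fields))
        row.validate()
        return row

    def validate(self) -> None:
        if not _is_cui(self.cui):
            raise ValueError(f"invalid CUI {self.cui!r} in MRSTY row")
        if not TUI_PATTERN.fullmatch(self.tui):
            raise ValueError(f"invalid TUI {self.tui!r} in MRSTY row")


_TABLE_CLASSES = {
    "MRCONSO": ConceptAtom,
    "MRREL": ConceptRelation,
    "MRCOC": CoOccurrence,
    "MRSTY": SemanticTypeAssignment,
}

RrfRow = Union[ConceptAtom, ConceptRelation, CoOccurrence, SemanticTypeAssignment]


def read_rrf_table(path: str | Path, table_kind: str) -> list[RrfRow]:
    """Parse one RRF file into typed rows.

    Parameters
    ----------
    path
        File to read (UTF-8).
    table_kind
        One of ``MRCONSO``, ``MRREL``, ``MRCOC``, ``MRSTY``.

    Returns
    -------
    list
        One typed row per non-empty line, in file order.  No line is ever
        silently dropped: a line with fewer columns than the typed accessors
        need raises :class:`RrfFormatError` naming the line number.
    """
    try:
        cls = _TABLE_CLASSES[table_kind]
    except KeyError:
        raise ValueError(f"unknown RRF table kind {table_kind!r}") from None
    rows: list[RrfRow] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("|")
            if line.endswith("|"):
                parts.pop()  # trailing delimiter, per RRF convention
            if len(parts) < cls.MIN_FIELDS:
                raise RrfFormatError(
                    f"{path}: line {lineno}: {table_kind} row has "
                    f"{len(parts)} fields, need at least {cls.MIN_FIELDS}"
                )
            rows.append(cls(tuple(parts)))
    return rows


def write_rrf_table(rows: Sequence[RrfRow], path: str | Path) -> None:
    """Write typed rows back to pipe-delimited RRF.

    All rows are validated against their type invariants before the first
    byte is written; files produced here round-trip byte-identically through
    :func:`read_rrf_table`.
    """
    for row in rows:
        row.validate()
    with open(path, "w", encoding="utf-8") as handle:
        for row in rows:
            handle.write(row.to_line() + "\n")


class TerminologyKB:
    """In-memory indexed union of the four RRF tables.

    Atoms are indexed by CUI, by lower-cased term string and by
    (source vocabulary, source code); relations by either CUI;
    co-occurrences by either CUI; semantic types as CUI -> set of TUIs.
    Suppressed atoms and relations are stored and indexed (their flag is
    queried by consumers), so the KB itself is a faithful view of the files.
    """

    def __init__(
        self,
        atoms: Iterable[ConceptAtom] = (),
        relations: Iterable[ConceptRelation] = (),
        cooccurrences: Iterable[CoOccurrence] = (),
        semantic_types: Iterable[SemanticTypeAssignment] = (),
    ) -> None:
        self.atoms: list[ConceptAtom] = list(atoms)
        self.relations: list[ConceptRelation] = list(relations)
        self.cooccurrences: list[CoOccurrence] = list(cooccurrences)
        self.semantic_type_rows: list[SemanticTypeAssignment] = list(semantic_types)

        self._atoms_by_cui: dict[str, list[ConceptAtom]] = defaultdict(list)
        self._atoms_by_term: dict[str, list[ConceptAtom]] = defaultdict(list)
        self._atoms_by_code: dict[tuple[str, str], list[ConceptAtom]] = defaultdict(list)
        for atom in self.atoms:
            self._atoms_by_cui[atom.cui].append(atom)
            self._atoms_by_term[atom.term_string.casefold()].append(atom)
            self._atoms_by_code[(atom.source_vocabulary, atom.source_code)].append(atom)

        self._rel_by_cui1: dict[str, list[ConceptRelation]] = defaultdict(list)
        self._rel_by_cui2: dict[str, list[ConceptRelation]] = defaultdict(list)
        for rel in self.relations:
            self._rel_by_cui1[rel.cui1].append(rel)
            self._rel_by_cui2[rel.cui2].append(rel)

        self._coc_by_cui: dict[str, list[CoOccurrence]] = defaultdict(list)
        for coc in self.cooccurrences:
            self._coc_by_cui[coc.cui1].append(coc)
            if coc.cui2 != coc.cui1:
                self._coc_by_cui[coc.cui2].append(coc)

        self._sty_by_cui: dict[str, set[str]] = defaultdict(set)
        for sty in self.semantic_type_rows:
            self._sty_by_cui[sty.cui].add(sty.tui)

        self._sabs = frozenset(a.source_vocabulary for a in self.atoms)

    # -- atom lookups ----------------------------------------------------
    def atoms_for_cui(self, cui: str) -> list[ConceptAtom]:
        return list(self._atoms_by_cui.get(cui, ()))

    def atoms_for_term(self, term: str) -> list[ConceptAtom]:
        """All atoms whose term string equals ``term`` case-insensitively."""
        return list(self._atoms_by_term.get(term.casefold(), ()))

    def atoms_for_code(self, source_vocabulary: str, code: str) -> list[ConceptAtom]:
        return list(self._atoms_by_code.get((source_vocabulary, code), ()))

    @property
    def source_vocabularies(self) -> frozenset[str]:
        return self._sabs

    def preferred_term(self, cui: str) -> str | None:
        """Best display name for a concept.

        Preference order: non-suppressed preferred atoms, then any
        non-suppressed atom, then any atom; ties broken by sorted
        (vocabulary, term type, string) so the choice is deterministic.
        """
        atoms = self._atoms_by_cui.get(cui)
        if not atoms:
            return None
        def key(a: ConceptAtom) -> tuple:
            return (a.suppressed, not a.is_preferred,
                    a.source_vocabulary, a.term_type, a.term_string)
        return min(atoms, key=key).term_string

    # -- relation / co-occurrence lookups --------------------------------
    def relations_from(self, cui: str) -> list[ConceptRelation]:
        return list(self._rel_by_cui1.get(cui, ()))

    def relations_to(self, cui: str) -> list[ConceptRelation]:
        return list(self._rel_by_cui2.get(cui, ()))

    def cooccurrences_of(self, cui: str) -> list[CoOccurrence]:
        return list(self._coc_by_cui.get(cui, ()))

    def semantic_types(self, cui: str) -> frozenset[str]:
        return frozenset(self._sty_by_cui.get(cui, ()))

    @property
    def cuis(self) -> frozenset[str]:
        return frozenset(self._atoms_by_cui)


def build_kb(
    mrconso: Iterable[ConceptAtom] = (),
    mrrel: Iterable[ConceptRelation] = (),
    mrcoc: Iterable[CoOccurrence] = (),
    mrsty: Iterable[SemanticTypeAssignment] = (),
) -> TerminologyKB:
    """Assemble parsed RRF rows into an indexed :class:`TerminologyKB`."""
    return TerminologyKB(mrconso, mrrel, mrcoc, mrsty)


def load_kb_from_files(
    mrconso_path: str | Path,
    mrrel_path: str | Path,
    mrcoc_path: str | Path,
    mrsty_path: str | Path,
) -> TerminologyKB:
    """Read the four RRF files and build the knowledge base in one step."""
    return build_kb(
        read_rrf_table(mrconso_path, "MRCONSO"),
        read_rrf_table(mrrel_path, "MRREL"),
        read_rrf_table(mrcoc_path, "MRCOC"),
        read_rrf_table(mrsty_path, "MRSTY"),
    )
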