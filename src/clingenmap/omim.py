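"""Colorectal-cancer gene extraction from OMIM-style snapshots.

Three steps: (1) field-restricted boolean keyword search over gene/
phenotype entries — (colon OR colorectal OR colonic OR rectal) AND
(cancer OR carcinoma OR adenoma), whole-word, case-insensitive, limited by
default to the title and allelic-variant fields; (2) a join from matched
entry IDs to gene IDs; (3) joins from gene IDs to protein accessions and
article IDs through NCBI-style two-column association tables.

Snapshots are JSON-lines files (one entry per line with ``mim_id``,
``title``, ``allelic_variants`` and optional ``other_text``); association
tables are tab-separated with ``#`` header lines skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .keywords import DISEASE_KEYWORDS, SITE_KEYWORDS, word_set

__all__ = [
    "OmimEntry",
    "KeywordQuery",
    "GeneLinkTable",
    "load_snapshot",
    "write_snapshot",
    "search_entries",
    "genes_from_entries",
    "link_targets",
    "extraction_summary",
]

logger = logging.getLogger(__name__)

SEARCHABLE_FIELDS = frozenset({"title", "allelic_variants", "other_text"})
LINK_KINDS = frozenset({"gene_to_protein", "gene_to_article", "mim_to_gene"})


@dataclass(frozen=True)
class OmimEntry:
    """One OMIM-style entry: id, title and allelic-variant text blocks."""

    mim_id: str
    title: str
    allelic_variants: tuple[str, ...] = ()
    other_text: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "allelic_variants", tuple(self.allelic_variants))

    def field_text(self, fields: Iterable[str]) -> str:
        parts = []
        for name in fields:
            if name == "title":
                parts.append(self.title)
            elif name == "allelic_variants":
                parts.extend(self.allelic_variants)
            elif name == "other_text":
                parts.append(self.other_text)
            else:
                raise ValueError(f"unknown searchable field {name!r}")
        return " ".join(parts)


@dataclass(frozen=True)
class KeywordQuery:
    """Boolean keyword combination restricted to selected entry fields.

    Semantics: (any site keyword) AND (any disease keyword), each keyword
    matched as a whole word, case-insensitively, against the concatenation
    of the selected fields — so the two groups may match in different
    fields.
    """

    site_group: frozenset[str] = SITE_KEYWORDS
    disease_group: frozenset[str] = DISEASE_KEYWORDS
    fields: frozenset[str] = frozenset({"title", "allelic_variants"})

    def __post_init__(self) -> None:
        site = frozenset(k.casefold() for k in self.site_group)
        disease = frozenset(k.casefold() for k in self.disease_group)
        if not site or not disease:
            raise ValueError("both keyword groups must be non-empty")
        unknown = frozenset(self.fields) - SEARCHABLE_FIELDS
        if unknown:
            raise ValueError(f"unknown search fields {sorted(unknown)}")
        object.__setattr__(self, "site_group", site)
        object.__setattr__(self, "disease_group", disease)
        object.__setattr__(self, "fields", frozenset(self.fields))

    def matches(self, entry: OmimEntry) -> bool:
        words = word_set(entry.field_text(self.fields))
        return bool(words & self.site_group) and bool(words & self.disease_group)


@dataclass(frozen=True)
class GeneLinkTable:
    """Deduplicated (source ID, target ID) pairs from an association file."""

    kind: str
    rows: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.kind not in LINK_KINDS:
            raise ValueError(f"unknown link table kind {self.kind!r}")
        for source, target in self.rows:
            if not source or not target:
                raise ValueError("association IDs must be non-empty")
        object.__setattr__(self, "rows", frozenset(self.rows))

    @classmethod
    def from_file(cls, path: str | Path, kind: str, *,
                  source_column: int = 0, target_column: int = 1,
                  taxon_column: int | None = None,
                  taxon: str | None = None) -> "GeneLinkTable":
        """Load a tab-separated association file.

        ``#`` header/comment lines are skipped.  ``source_column`` /
        ``target_column`` select the two ID columns, so the full NCBI
        gene2accession/gene2pubmed layouts load directly (e.g. tax_id,
        GeneID, accession...); give ``taxon_column`` and ``taxon`` to
        restrict to a single organism.
        """
        rows: set[tuple[str, str]] = set()
        needed = max(source_column, target_column,
                     -1 if taxon_column is None else taxon_column) + 1
        with open(path, encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < needed:
                    raise ValueError(
                        f"{path}: line {lineno}: expected >= {needed} columns")
                if taxon_column is not None and parts[taxon_column] != taxon:
                    continue
                source, target = parts[source_column], parts[target_column]
                if source and target and target != "-":
                    rows.add((source, target))
        return cls(kind, frozenset(rows))

    def targets_of(self, source: str) -> frozenset[str]:
        return frozenset(t for s, t in self.rows if s == source)


def load_snapshot(path: str | Path) -> list[OmimEntry]:
    """Read a JSON-lines snapshot; entry IDs must be unique."""
    entries: list[OmimEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            record = json.loads(line)
            entry = OmimEntry(
                mim_id=str(record["mim_id"]),
                title=record.get("title", ""),
                allelic_variants=tuple(record.get("allelic_variants", ())),
                other_text=record.get("other_text", ""),
            )
            if entry.mim_id in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate mim_id "
                                 f"{entry.mim_id}")
            seen.add(entry.mim_id)
            entries.append(entry)
    return entries


def write_snapshot(entries: Sequence[OmimEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for entry in entries:
            handle.write(json.dumps({
                "mim_id": entry.mim_id,
                "title": entry.title,
                "allelic_variants": list(entry.allelic_variants),
                "other_text": entry.other_text,
            }, sort_keys=True) + "\n")


def search_entries(snapshot: Sequence[OmimEntry],
                   query: KeywordQuery | None = None) -> list[OmimEntry]:
    """Entries matching the keyword query, in stable input order."""
    query = query or KeywordQuery()
    return [entry for entry in snapshot if query.matches(entry)]


def genes_from_entries(entries: Sequence[OmimEntry],
                       mim_to_gene: GeneLinkTable) -> list[str]:
    """Gene IDs linked to any matched entry, sorted, duplicates collapsed."""
    if mim_to_gene.kind != "mim_to_gene":
        raise ValueError(f"expected a mim_to_gene table, got {mim_to_gene.kind}")
    genes: set[str] = set()
    for entry in entries:
        linked = mim_to_gene.targets_of(entry.mim_id)
        if not linked:
            logger.warning("mim_id %s has no linked genes", entry.mim_id)
        genes |= linked
    return sorted(genes)


def link_targets(gene_ids: Iterable[str], table: GeneLinkTable) -> list[str]:
    """Target IDs (protein accessions or article IDs) of the genes, sorted."""
    if table.kind not in ("gene_to_protein", "gene_to_article"):
        raise ValueError(f"expected a gene-target table, got {table.kind}")
    targets: set[str] = set()
    for gene in gene_ids:
        targets |= table.targets_of(gene)
    return sorted(targets)


def extraction_summary(genes: Sequence[str], proteins: Sequence[str],
                       articles: Sequence[str]) -> dict[str, int]:
    return {"genes": len(genes), "proteins": len(proteins),
            "articles": len(articles)}
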