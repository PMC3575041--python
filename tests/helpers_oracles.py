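"""Independent brute-force oracles for the mapping engine tests.

These enumerators work straight off the raw RRF field tuples (positional
access, no knowledge base, no index structures) so they share nothing with
the implementation they check beyond the row dataclasses' storage.
"""

from __future__ import annotations

import re

_SUPPRESSED = {"O", "E", "Y"}


def sty_map(mrsty) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for row in mrsty:
        out.setdefault(row.fields[0], set()).add(row.fields[1])
    return out


def neighbors(cui, mrrel, mrcoc, *, min_freq: int = 1,
              bidirectional: bool = True) -> set[str]:
    """All concepts linked to ``cui`` by a qualifying MRREL/MRCOC row."""
    out: set[str] = set()
    for row in mrrel:
        if row.fields[14] in _SUPPRESSED:
            continue
        if row.fields[0] == cui and row.fields[4] != cui:
            out.add(row.fields[4])
        if bidirectional and row.fields[4] == cui and row.fields[0] != cui:
            out.add(row.fields[0])
    for row in mrcoc:
        freq = int(row.fields[6] or 0)
        if freq < min_freq:
            continue
        if row.fields[0] == cui and row.fields[2] != cui:
            out.add(row.fields[2])
        if row.fields[2] == cui and row.fields[0] != cui:
            out.add(row.fields[0])
    return out


def oracle_direct_pairs(g_cuis, c_cuis, mrrel, mrcoc, mrsty, *,
                        genomic_tuis=frozenset({"T028"}),
                        clinical_tuis=frozenset({"T184", "T033", "T047",
                                                 "T191", "T059"}),
                        min_freq: int = 1):
    """(pair, direction) tuples a naive pairwise enumeration finds."""
    sty = sty_map(mrsty)
    found: set[tuple[str, str, str]] = set()
    for g in g_cuis:
        linked = neighbors(g, mrrel, mrcoc, min_freq=min_freq)
        for c in c_cuis:
            if c in linked and sty.get(c, set()) & clinical_tuis:
                found.add((g, c, "genomic_to_clinic"))
    for c in c_cuis:
        linked = neighbors(c, mrrel, mrcoc, min_freq=min_freq)
        for g in g_cuis:
            if g in linked and sty.get(g, set()) & genomic_tuis:
                found.add((g, c, "clinic_to_genomic"))
    return found


_CRC_RE_SITE = re.compile(r"\b(colon|colorectal|colonic|rectal)\b", re.I)
_CRC_RE_DISEASE = re.compile(r"\b(cancer|carcinoma|adenoma)\b", re.I)


def preferred_terms(mrconso) -> dict[str, str]:
    """CUI -> preferred atom string (TS=P, ISPREF=Y, non-suppressed)."""
    out: dict[str, str] = {}
    for row in mrconso:
        if (row.fields[2] == "P" and row.fields[6] == "Y"
                and row.fields[16] not in _SUPPRESSED):
            out.setdefault(row.fields[0], row.fields[14])
    return out


def oracle_indirect_pairs(g_cuis, c_cuis, mrconso, mrrel, mrcoc, mrsty, *,
                          disease_tuis=frozenset({"T047", "T191"}),
                          min_freq: int = 1):
    """(g, c) -> shared CRC-disease evidence, by exhaustive triple scan."""
    sty = sty_map(mrsty)
    terms = preferred_terms(mrconso)

    def crc_diseases(cui: str) -> set[str]:
        out = set()
        for d in neighbors(cui, mrrel, mrcoc, min_freq=min_freq):
            if not sty.get(d, set()) & disease_tuis:
                continue
            term = terms.get(d, "")
            if _CRC_RE_SITE.search(term) and _CRC_RE_DISEASE.search(term):
                out.add(d)
        return out

    found: dict[tuple[str, str], frozenset[str]] = {}
    for g in g_cuis:
        dg = crc_diseases(g)
        for c in c_cuis:
            shared = dg & crc_diseases(c)
            if shared:
                found[(g, c)] = frozenset(shared)
    return found


_OMIM_SITE_RE = re.compile(r"\b(colon|colorectal|colonic|rectal)\b", re.I)
_OMIM_DISEASE_RE = re.compile(r"\b(cancer|carcinoma|adenoma)\b", re.I)


def oracle_omim_matches(entries) -> set[str]:
    """mim_ids matched by a regex scan of title + allelic variants."""
    matched = set()
    for entry in entries:
        text = " ".join([entry.title, *entry.allelic_variants])
        if _OMIM_SITE_RE.search(text) and _OMIM_DISEASE_RE.search(text):
            matched.add(entry.mim_id)
    return matched
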