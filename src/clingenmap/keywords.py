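"""Shared keyword matching for colorectal-cancer concept filters.

The same boolean keyword combination — (colon OR colorectal OR colonic OR
rectal) AND (cancer OR carcinoma OR adenoma) — is used both to pull
colorectal-cancer gene entries out of an OMIM-style snapshot and to decide
whether a disease concept counts as colorectal-cancer-related during
indirect mapping.  Keywords match as whole words: the keyword list contains
both "colon" and "colonic" as separate forms, so "colon" must not fire
inside "colonic" (or "semicolon").
"""

from __future__ import annotations

import re

__all__ = ["SITE_KEYWORDS", "DISEASE_KEYWORDS", "word_set", "matches_keyword_groups"]

SITE_KEYWORDS: frozenset[str] = frozenset({"colon", "colorectal", "colonic", "rectal"})
DISEASE_KEYWORDS: frozenset[str] = frozenset({"cancer", "carcinoma", "adenoma"})

_WORD_RE = re.compile(r"[a-z]+")


def word_set(text: str) -> frozenset[str]:
    """Lower-cased alphabetic words of ``text`` (non-letters delimit)."""
    return frozenset(_WORD_RE.findall(text.casefold()))


def matches_keyword_groups(
    text: str,
    site_keywords: frozenset[str] = SITE_KEYWORDS,
    disease_keywords: frozenset[str] = DISEASE_KEYWORDS,
) -> bool:
    """True iff ``text`` contains a whole word from each keyword group."""
    words = word_set(text)
    return bool(words & site_keywords) and bool(words & disease_keywords)
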