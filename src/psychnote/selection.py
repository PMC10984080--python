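"""Keyword matching and sentence-level note pre-selection.

Long admission notes carry much text that is irrelevant to psychosis. Before
classification, each note can be reduced to only the sentences containing a
lexicon keyword, yielding three dataset variants:

* ``full``  — the note untouched;
* ``broad`` — sentences containing any keyword from the full tiered list
  (base + strict + broad);
* ``base``  — sentences containing a base (psychiatrist seed) keyword.

Matching is case-insensitive contiguous-substring matching, because the
lexicon entries are stems ("psychosi", "disorganis"). This is deliberately
blunt — it fires inside negations ("no signs of psychosis") and across word
boundaries — and is the dominant false-positive source of the rule-based arm.

:func:`truncate_tokens` implements the fixed token budget used when feeding
length-limited encoders: keep the first ``max_tokens`` whitespace tokens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Literal

from .lexicon import KeywordLexicon, load_packaged_lexicon
from .textprep import Note, segment_sentences

__all__ = ["SelectedNote", "match_keywords", "select_sentences", "truncate_tokens"]

SelectionTier = Literal["full", "broad", "base"]

#: lexicon tier backing each dataset variant
_VARIANT_LEXICON = {"broad": "all", "base": "base"}


@dataclass
class SelectedNote:
    """A note after sentence-level keyword pre-selection.

    ``text`` is the selected sentences joined by single spaces in original
    order (the full note text when ``tier='full'``); ``matched_terms`` maps
    each matched lexicon term to its total hit count across the kept text.
    An empty selection is valid: ``text == ""`` with no matches.
    """

    note_id: str
    tier: SelectionTier
    text: str
    matched_terms: dict[str, int] = field(default_factory=dict)
    label: str | None = None


def match_keywords(sentence: str, lexicon: KeywordLexicon) -> dict[str, int]:
    """Count case-insensitive substring hits of every lexicon term.

    Overlapping hits of *distinct* terms are all reported; occurrences of one
    term are counted non-overlapping (``str.count`` semantics). Terms with
    zero hits are omitted.
    """
    low = sentence.lower()
    out: dict[str, int] = {}
    for term in lexicon.terms:
        c = low.count(term)
        if c:
            out[term] = c
    return out


def select_sentences(
    note: Note,
    tier: SelectionTier = "base",
    lexicon: KeywordLexicon | None = None,
) -> SelectedNote:
    """Build one dataset-variant record for ``note``.

    ``tier='full'`` copies the note text verbatim (matched terms are still
    reported, against the all-keyword lexicon unless one is given). Otherwise
    only sentences with at least one lexicon hit are kept, in original order.
    A note with no keyword sentence yields empty text — downstream models
    receive it as-is rather than erroring.
    """
    if tier not in ("full", "broad", "base"):
        raise ValueError(f"unknown tier {tier!r}; expected full, broad or base")
    if lexicon is None:
        lexicon = load_packaged_lexicon(_VARIANT_LEXICON.get(tier, "all"))
    counts: Counter[str] = Counter()
    if tier == "full":
        counts.update(match_keywords(note.text, lexicon))
        return SelectedNote(note.note_id, tier, note.text, dict(counts), note.label)
    kept: list[str] = []
    for a, b in segment_sentences(note.text):
        hits = match_keywords(note.text[a:b], lexicon)
        if hits:
            kept.append(note.text[a:b])
            counts.update(hits)
    return SelectedNote(note.note_id, tier, " ".join(kept), dict(counts), note.label)


def truncate_tokens(text: str, max_tokens: int = 512) -> str:
    """Keep the first ``max_tokens`` whitespace-delimited tokens of ``text``."""
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    tokens = text.split()
    if len(tokens) <= max_tokens:
        return text
    return " ".join(tokens[:max_tokens])
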