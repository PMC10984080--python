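"""Tiered psychosis keyword lexicons.

The rule-based arm of the pipeline rests on three nested keyword lists:

* **base** — seed terms chosen by psychiatrists for symptoms and descriptors of
  psychosis (e.g. ``hallucination``, ``psychosi``, ``thought disorder``);
* **strict** — terms from an upstream candidate list that *both* annotators
  rated Relevant (RT);
* **broad** — terms with partial annotator support: exactly one RT rating, or
  both annotators agreeing on Potentially Relevant (PT).

Entries are lowercase stems ("psychosi", "disorganis"), so matching semantics
throughout the package are case-insensitive contiguous-substring matching; see
:mod:`psychnote.selection`.

The packaged lists ship as ``data/keywords.tsv``; :func:`build_tier`,
:func:`normalize_terms` and :func:`reduce_to_unique_substrings` implement the
construction rules so users can re-derive lexicons from their own dual-annotator
rating tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Sequence

__all__ = [
    "RATINGS",
    "TIERS",
    "TermRating",
    "KeywordLexicon",
    "build_tier",
    "normalize_terms",
    "reduce_to_unique_substrings",
    "load_packaged_lexicon",
    "read_ratings_tsv",
    "read_lexicon_tsv",
    "write_lexicon_tsv",
]

RATINGS = ("RT", "PT", "NT")
TIERS = ("base", "strict", "broad", "all")

Rating = Literal["RT", "PT", "NT"]
Tier = Literal["base", "strict", "broad", "all"]


class LexiconConfigError(RuntimeError):
    """Raised when packaged lexicon data is missing or malformed."""


@dataclass(frozen=True)
class TermRating:
    """A candidate term with two independent annotator ratings (RT/PT/NT)."""

    term: str
    rating_a: Rating
    rating_b: Rating

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise ValueError("TermRating.term must be non-empty")
        for r in (self.rating_a, self.rating_b):
            if r not in RATINGS:
                raise ValueError(
                    f"unknown rating {r!r} for term {self.term!r}; expected one of {RATINGS}"
                )


@dataclass(frozen=True)
class KeywordLexicon:
    """A tier-labelled ordered set of lowercase surface terms.

    ``terms`` preserves insertion order and contains no duplicates or empty
    strings. Matching is case-insensitive substring matching (the packaged
    entries are stems).
    """

    tier: Tier
    terms: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}; expected one of {TIERS}")
        seen = set()
        for t in self.terms:
            if not t:
                raise ValueError("lexicon terms must be non-empty")
            if t in seen:
                raise ValueError(f"duplicate lexicon term {t!r}")
            seen.add(t)

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms


def build_tier(ratings: Iterable[TermRating], rule: Literal["strict", "broad"]) -> list[str]:
    """Select terms from a dual-annotator rating table under one tier rule.

    ``strict``: both annotators rated the term RT. ``broad``: exactly one
    annotator rated it RT (the other PT or NT), or both rated it PT. The two
    rules partition disjoint subsets of any input, and both are symmetric in
    the annotators.
    """
    if rule not in ("strict", "broad"):
        raise ValueError(f"unknown rule {rule!r}; expected 'strict' or 'broad'")
    out: list[str] = []
    for r in ratings:
        if not isinstance(r, TermRating):
            r = TermRating(*r)
        pair = {r.rating_a, r.rating_b}
        n_rt = (r.rating_a == "RT") + (r.rating_b == "RT")
        if rule == "strict":
            hit = n_rt == 2
        else:
            hit = n_rt == 1 or pair == {"PT"}
        if hit:
            out.append(r.term)
    return out


def normalize_terms(terms: Sequence[str]) -> list[str]:
    """Normalize raw candidate terms.

    Underscores become single spaces, text is lowercased and stripped, a
    trailing plural ``s`` is dropped (blunt stemming: ``delusions`` ->
    ``delusion``, ``commentaries``-style forms lose only the final ``s``;
    ``-ss`` endings are left alone), and duplicates collapse keeping
    first-seen order.
    """
    out: list[str] = []
    seen: set[str] = set()
    for raw in terms:
        t = " ".join(raw.replace("_", " ").lower().split())
        if len(t) > 2 and t.endswith("s") and not t.endswith("ss"):
            t = t[:-1]
        if t and t not in seen:
            seen.add(t)
            out.append(t)
    return out


def reduce_to_unique_substrings(terms: Sequence[str]) -> list[str]:
    """Drop every term that contains another retained term as a substring.

    Because matching is substring-based, a term subsumed by a shorter retained
    term is redundant: any text it flags is already flagged by the shorter one.
    The reduced set therefore matches exactly the same texts as the input set,
    and the operation is idempotent. Output keeps the input's relative order.
    """
    kept_sorted: list[str] = []
    kept: set[str] = set()
    for t in sorted(dict.fromkeys(terms), key=len):
        if not any(s in t for s in kept_sorted):
            kept_sorted.append(t)
            kept.add(t)
    return [t for t in dict.fromkeys(terms) if t in kept]


def _read_packaged_rows() -> list[tuple[str, str]]:
    try:
        path = resources.files("psychnote.data").joinpath("keywords.tsv")
        text = path.read_text(encoding="utf-8")
    except (FileNotFoundError, ModuleNotFoundError) as exc:  # pragma: no cover
        raise LexiconConfigError("packaged keyword file data/keywords.tsv is missing") from exc
    rows: list[tuple[str, str]] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise LexiconConfigError(f"malformed keyword line: {line!r}")
        rows.append((parts[0], parts[1]))
    return rows


def load_packaged_lexicon(tier: Tier = "all") -> KeywordLexicon:
    """Load the packaged tiered keyword lists.

    Tiers are cumulative: ``base`` returns the 19 seed terms; ``strict``
    returns base plus the strictly-relevant column; ``broad`` and ``all`` both
    return the union of all three columns. Duplicated entries in the source
    table collapse on load.

    The packaged lists are shipped exactly as curated — including cross-tier
    substring redundancy (e.g. broad ``halluc`` subsumes strict spelling
    variants). :func:`reduce_to_unique_substrings` is only applied when a user
    re-derives lexicons from ratings.
    """
    if tier not in TIERS:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    include = {"base": ("base",), "strict": ("base", "strict")}.get(
        tier, ("base", "strict", "broad")
    )
    terms = [t for t, col in _read_packaged_rows() if col in include]
    return KeywordLexicon(tier=tier, terms=tuple(dict.fromkeys(terms)))


def read_ratings_tsv(path) -> list[TermRating]:
    """Read a three-column (term, rating_a, rating_b) TSV of annotator ratings."""
    out = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 3:
                raise ValueError(f"expected 3 tab-separated columns, got {row!r}")
            out.append(TermRating(row[0].strip(), row[1].strip(), row[2].strip()))
    return out


def read_lexicon_tsv(path, tier: Tier = "all") -> KeywordLexicon:
    """Read a two-column (term, tier) TSV; keeps terms whose tier is included by ``tier``."""
    include = {"base": ("base",), "strict": ("base", "strict")}.get(
        tier, ("base", "strict", "broad")
    )
    terms = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) != 2:
                raise ValueError(f"expected 2 tab-separated columns, got {row!r}")
            if row[1].strip() in include:
                terms.append(row[0].strip())
    return KeywordLexicon(tier=tier, terms=tuple(dict.fromkeys(terms)))


def write_lexicon_tsv(lexicon: KeywordLexicon, path, tier_label: str | None = None) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        for t in lexicon.terms:
            w.writerow([t, tier_label or lexicon.tier])
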