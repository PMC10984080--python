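"""Note preparation: de-identification, template removal, segmentation, cohort screens.

Psychiatric admission notes arrive as free text organised into sections
(history of present illness, past psychiatric history, family history,
formulation, ...). Before any modelling the pipeline

1. masks protected health information with regex patterns — dates ->
   ``[date]``, titled clinician names -> ``[doctor]``, hospital names ->
   ``[hospital]``, street addresses -> ``[address]``, and any number longer
   than three digits -> ``[number]``;
2. removes boilerplate: lines shared verbatim by a large fraction of the
   corpus (template text) and blocks repeated inside a single note;
3. segments text into sentences (abbreviation-safe regex splitting), the unit
   used by keyword pre-selection;
4. applies cohort text-mining screens for *first hospitalization* and *past
   psychosis/mania*. Screens return a three-way verdict
   (include / exclude / review) with the matched evidence, never silently
   resolving conflicting phrases — mirroring a workflow in which conflicting
   hits go to manual review.

All patterns here are regex-level heuristics, not a certified de-identification
system; the defaults are configurable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Literal, Sequence

__all__ = [
    "Note",
    "ScreenResult",
    "deidentify",
    "drop_template_and_duplicates",
    "segment_sentences",
    "screen_first_hospitalization",
    "screen_past_psychosis",
]


@dataclass
class Note:
    """One admission note.

    ``sections`` optionally maps section name -> text; ``icd_codes`` are
    discharge diagnosis codes; ``label`` is the gold standard ("case" for
    psychosis, "control" otherwise) when known.
    """

    note_id: str
    text: str
    sections: dict[str, str] | None = None
    icd_codes: list[str] | None = None
    label: Literal["case", "control"] | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError(f"note {self.note_id!r} has empty text")
        if self.label is not None and self.label not in ("case", "control"):
            raise ValueError(f"note {self.note_id!r}: label must be 'case' or 'control'")


@dataclass(frozen=True)
class ScreenResult:
    """Three-way screening verdict with the evidence that produced it.

    ``evidence`` lists ``(matched_phrase, (start, end))`` character spans in
    the screened text. ``include``/``exclude`` are only returned when the
    evidence is one-sided; any conflict (or absence) of evidence yields
    ``review`` so a human resolves it.
    """

    flag: Literal["include", "exclude", "review"]
    evidence: tuple[tuple[str, tuple[int, int]], ...] = ()


# --- de-identification -------------------------------------------------------

_MONTHS = (
    "Jan(?:uary)?|Feb(?:ruary)?|Mar(?:ch)?|Apr(?:il)?|May|Jun(?:e)?|Jul(?:y)?|"
    "Aug(?:ust)?|Sep(?:t(?:ember)?)?|Oct(?:ober)?|Nov(?:ember)?|Dec(?:ember)?"
)

DEID_PATTERNS: tuple[tuple[re.Pattern, str], ...] = (
    (re.compile(r"\b\d{1,2}[/-]\d{1,2}[/-]\d{2,4}\b"), "[date]"),
    (re.compile(r"\b\d{4}-\d{2}-\d{2}\b"), "[date]"),
    (re.compile(rf"\b(?:{_MONTHS})\.?\s+\d{{1,2}}(?:,?\s+\d{{4}})?\b"), "[date]"),
    (
        re.compile(
            r"\b\d{1,5}\s+[A-Z][a-z]+(?:\s+[A-Z][a-z]+)?\s+"
            r"(?:Street|St\.|Avenue|Ave\.?|Road|Rd\.?|Lane|Drive|Boulevard|Blvd\.?)\b"
        ),
        "[address]",
    ),
    (
        re.compile(
            r"\b(?:[A-Z][a-z]+\s+){1,3}(?:Hospital|Medical\s+Center|Clinic|Health\s+Center)\b"
        ),
        "[hospital]",
    ),
    (re.compile(r"\b(?:Dr|Drs|Mr|Mrs|Ms)\.?\s+[A-Z][a-z]+(?:\s+[A-Z][a-z]+)?\b"), "[doctor]"),
    (re.compile(r"\d{4,}"), "[number]"),
)


def deidentify(text: str, patterns: Sequence[tuple[re.Pattern, str]] = DEID_PATTERNS) -> str:
    """Mask PHI-like spans in ``text``.

    Patterns apply in order (dates and addresses before the bare long-number
    rule, so a 4-digit year inside a date becomes part of ``[date]`` rather
    than ``[number]``). The operation is idempotent: mask tokens contain no
    digits or titled-name shapes, so a second pass is a no-op.
    """
    for pat, token in patterns:
        text = pat.sub(token, text)
    return text


# --- template & duplicate removal --------------------------------------------


def _dedup_paragraphs(text: str) -> str:
    """Collapse exact repeated blank-line-separated blocks to one occurrence."""
    paras = re.split(r"\n\s*\n", text)
    seen: set[str] = set()
    kept = []
    for p in paras:
        key = p.strip()
        if key and key in seen:
            continue
        if key:
            seen.add(key)
        kept.append(p)
    return "\n\n".join(kept)


def drop_template_and_duplicates(
    notes: Sequence[Note], template_threshold: float = 0.5
) -> list[Note]:
    """Remove corpus-wide template lines and within-note repeated blocks.

    A line (stripped, compared verbatim) occurring in more than
    ``template_threshold`` of the notes is treated as template boilerplate and
    removed everywhere; this requires a corpus of at least two notes. Within
    each note, a paragraph pasted more than once is kept once. Notes left with
    no text after removal keep a single space so the record survives.
    """
    if not 0 < template_threshold <= 1:
        raise ValueError("template_threshold must lie in (0, 1]")
    presence: dict[str, int] = {}
    for n in notes:
        for line in {ln.strip() for ln in n.text.splitlines() if ln.strip()}:
            presence[line] = presence.get(line, 0) + 1
    n_notes = len(notes)
    template = (
        {ln for ln, c in presence.items() if c / n_notes > template_threshold}
        if n_notes > 1
        else set()
    )
    out = []
    for n in notes:
        lines = [ln for ln in n.text.splitlines() if ln.strip() not in template]
        text = _dedup_paragraphs("\n".join(lines))
        out.append(replace(n, text=text if text.strip() else " "))
    return out


# --- sentence segmentation ---------------------------------------------------

# Trailing-word abbreviations that do not end a sentence.
ABBREVIATIONS = frozenset(
    {"dr", "drs", "mr", "mrs", "ms", "st", "vs", "etc", "approx", "pt", "e.g", "i.e", "p.r.n"}
)

_TERMINATOR = re.compile(r"[.!?]+(?=\s|$)|\n")


def segment_sentences(
    text: str, abbreviations: frozenset[str] = ABBREVIATIONS
) -> list[tuple[int, int]]:
    """Split ``text`` into sentence character spans.

    Boundaries are runs of ``.!?`` followed by whitespace (or end of text) and
    newlines; a terminator preceded by a known abbreviation ("Dr.", "e.g.")
    does not split. Spans are non-overlapping, ordered, trimmed of surrounding
    whitespace, and jointly cover every non-whitespace character.
    """
    spans: list[tuple[int, int]] = []
    start = 0

    def _flush(end: int) -> None:
        seg = text[start:end]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((start + lstrip, end - rstrip))

    for m in _TERMINATOR.finditer(text):
        if m.group() != "\n":
            word = text[: m.start()].rsplit(None, 1)
            prev = word[-1].lower().rstrip(".") if word else ""
            if prev in abbreviations or re.fullmatch(r"[a-z]", prev):
                continue
        _flush(m.end())
        start = m.end()
    _flush(len(text))
    return spans


def sentences(text: str, **kw) -> list[str]:
    """Convenience: the sentence texts themselves."""
    return [text[a:b] for a, b in segment_sentences(text, **kw)]


# --- cohort screening --------------------------------------------------------

_NEGATORS = ("no", "not", "without", "denies", "denied", "never", "zero", "nor")

_HOSP_TRIGGER = re.compile(
    r"\b(?:prior|previous|past)\s+(?:\w+\s+){0,2}?(?:hospitalizations?|hospitalisations?|admissions?)\b"
    r"|\bhospitalized\s+(?:before|previously|in the past)\b",
    re.IGNORECASE,
)
_HOSP_FIRST = re.compile(
    r"\bfirst\s+(?:\w+\s+){0,2}?(?:hospitalization|hospitalisation|admission)\b",
    re.IGNORECASE,
)

_PSYCH_PAST = re.compile(
    r"\b(?:past\s+)?history\s+of\s+(?:\w+\s+){0,2}?"
    r"(?:psychosis|psychotic|schizophrenia|schizoaffective|mania|manic|bipolar)\b"
    r"|\bknown\s+(?:psychosis|schizophrenia|mania)\b"
    r"|\bprior\s+(?:psychotic|manic)\s+episodes?\b",
    re.IGNORECASE,
)
_PSYCH_NEW = re.compile(
    r"\bfirst\s+break\b|\bfirst\s+episode\b|\bnew[\s-]onset\b|\bfirst\s+psychotic\s+episode\b",
    re.IGNORECASE,
)


def _negated(text: str, start: int, window: int = 5) -> bool:
    """True when a negator appears within ``window`` tokens before ``start``."""
    left = re.findall(r"[\w'-]+", text[:start])
    return any(tok.lower() in _NEGATORS for tok in left[-window:])


def _screen(
    text: str,
    exclude_pat: re.Pattern,
    include_pat: re.Pattern,
    negation_window: int = 5,
) -> ScreenResult:
    include_ev: list[tuple[str, tuple[int, int]]] = []
    exclude_ev: list[tuple[str, tuple[int, int]]] = []
    for m in exclude_pat.finditer(text):
        ev = (m.group(), (m.start(), m.end()))
        # a negated "prior ..." / "history of ..." phrase argues for inclusion
        (include_ev if _negated(text, m.start(), negation_window) else exclude_ev).append(ev)
    for m in include_pat.finditer(text):
        ev = (m.group(), (m.start(), m.end()))
        (exclude_ev if _negated(text, m.start(), negation_window) else include_ev).append(ev)
    evidence = tuple(sorted(include_ev + exclude_ev, key=lambda e: e[1]))
    if include_ev and not exclude_ev:
        return ScreenResult("include", evidence)
    if exclude_ev and not include_ev:
        return ScreenResult("exclude", evidence)
    return ScreenResult("review", evidence)


def screen_first_hospitalization(text: str, negation_window: int = 5) -> ScreenResult:
    """Screen for incident (first) psychiatric hospitalization.

    Phrases asserting prior hospitalization ("multiple prior hospitalizations")
    vote *exclude*; negated-prior phrases ("no prior psych hospitalizations")
    and explicit first-admission phrases vote *include*; conflicting or absent
    evidence yields *review*.
    """
    return _screen(text, _HOSP_TRIGGER, _HOSP_FIRST, negation_window)


def screen_past_psychosis(text: str, negation_window: int = 5) -> ScreenResult:
    """Screen for past history of psychosis or mania versus new onset.

    Past-history phrases ("patient with past history of schizophrenia") vote
    *exclude*; new-onset phrases ("first break") vote *include*; otherwise
    *review*.
    """
    return _screen(text, _PSYCH_PAST, _PSYCH_NEW, negation_window)
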