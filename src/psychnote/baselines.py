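"""Non-ML comparators: keyword-presence rules and the exact-match ICD baseline.

The keyword rule flags a note as psychosis whenever any lexicon term matches
anywhere in its text. Under the paper-like data regime — every admission note
contains at least one base keyword — this rule attains perfect recall with
precision equal to the cohort prevalence, which is exactly why it serves as a
pre-selection step rather than a classifier.

The ICD baseline consumes structured discharge diagnosis codes only: a patient
is flagged when any code matches a configurable psychosis code set, either
exactly or by family prefix ("F20" covering "F20.9"). The shipped set is
``data/icd_psychosis_codes.txt`` (editable, ``#``-comments allowed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal

from .lexicon import KeywordLexicon
from .textprep import Note

__all__ = [
    "ICDCodeSet",
    "classify_by_keywords",
    "classify_by_icd",
    "load_packaged_icd_codes",
]

# ICD-10 (letter + digits, optional subcode) or ICD-9 (3 digits / V / E codes)
_ICD_SHAPE = re.compile(
    r"^[A-Z]\d{2}(?:\.\d{1,4}[A-Z]?)?$"  # ICD-10
    r"|^\d{3}(?:\.\d{1,2})?$"  # ICD-9
    r"|^[VE]\d{2,3}(?:\.\d{1,2})?$"  # ICD-9 V/E codes
)


def _validate_code(code: str) -> str:
    c = code.strip().upper()
    if not _ICD_SHAPE.match(c):
        raise ValueError(f"malformed ICD code {code!r}")
    return c


@dataclass(frozen=True)
class ICDCodeSet:
    """A set of psychosis diagnosis codes with its matching semantics.

    ``match_mode='exact'`` requires literal code equality; ``'prefix'`` treats
    each entry as a family stem, so "F20" also covers "F20.9" (and "295"
    covers "295.30"). Whether the original exact-match baseline used full
    codes or family stems for subcoded families is not knowable from the code
    list alone, so both modes are exposed; prefix is the default because the
    shipped set mixes stems and full subcodes.
    """

    codes: frozenset[str]
    match_mode: Literal["exact", "prefix"] = "prefix"

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", frozenset(_validate_code(c) for c in self.codes))
        if self.match_mode not in ("exact", "prefix"):
            raise ValueError(f"unknown match_mode {self.match_mode!r}")

    def matches(self, code: str) -> bool:
        c = _validate_code(code)
        if c in self.codes:
            return True
        if self.match_mode == "prefix":
            return any(c.startswith(stem + ".") or c.startswith(stem) for stem in self.codes)
        return False


def load_packaged_icd_codes(match_mode: Literal["exact", "prefix"] = "prefix") -> ICDCodeSet:
    """Load the shipped psychosis code set (one code per line, ``#`` comments)."""
    text = resources.files("psychnote.data").joinpath("icd_psychosis_codes.txt").read_text()
    codes = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            codes.append(line)
    return ICDCodeSet(frozenset(codes), match_mode)


def read_icd_codes(path, match_mode: Literal["exact", "prefix"] = "prefix") -> ICDCodeSet:
    """Read a user code-set file (same format as the packaged one)."""
    codes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                codes.append(line)
    return ICDCodeSet(frozenset(codes), match_mode)


def classify_by_keywords(note: Note | str, lexicon: KeywordLexicon) -> bool:
    """Flag a note as psychosis iff any lexicon term matches its text.

    Monotone in the lexicon: enlarging the term set can only turn negatives
    positive, never the reverse.
    """
    text = note.text if isinstance(note, Note) else note
    low = text.lower()
    return any(term in low for term in lexicon.terms)


def classify_by_icd(codes: Iterable[str] | None, code_set: ICDCodeSet) -> bool:
    """Flag a patient as psychosis iff any discharge code matches ``code_set``."""
    if codes is None:
        return False
    return any(code_set.matches(c) for c in codes)
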