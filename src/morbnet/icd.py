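"""ICD-10 chapter labels (Roman numerals) and the default chapter restriction.

Multimorbidity analyses of coded EHR data conventionally restrict comorbid
conditions to ICD-10 Chapters I-XIV, which capture well-defined diseases and
exclude chapters dominated by symptoms/signs, injuries and external causes.
"""

from __future__ import annotations

ROMAN_CHAPTERS: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XII", "XIII", "XIV", "XV", "XVI", "XVII", "XVIII", "XIX", "XX", "XXI", "XXII",
)

_CHAPTER_INDEX = {c: i + 1 for i, c in enumerate(ROMAN_CHAPTERS)}

#: Chapters I-XIV: infectious through genitourinary diseases.
DEFAULT_CHAPTER_WHITELIST: frozenset[str] = frozenset(ROMAN_CHAPTERS[:14])


def chapter_number(chapter: str) -> int:
    """Return the 1-based ordinal of a Roman-numeral ICD-10 chapter."""
    try:
        return _CHAPTER_INDEX[chapter]
    except KeyError:
        raise ValueError(f"unknown ICD-10 chapter {chapter!r}") from None


def is_valid_chapter(chapter: str) -> bool:
    return chapter in _CHAPTER_INDEX
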