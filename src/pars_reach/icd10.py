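"""ICD-10-CM code normalization and wildcard ("truncated code") matching.

EHR extracts print diagnosis codes in two dialects: dotted (``J45.40``) and
undotted (``J4540``), with inconsistent case. Everything downstream works on
a single normalized form — uppercase, dot removed — so matching is
dialect-insensitive.

Criteria are expressed as *code patterns*: either an exact code or a
truncated code ending in a single trailing asterisk, which matches every
code sharing the prefix (e.g. ``J45.4*`` covers J45.40, J45.41, J45.42).
A bare stem of equal length also matches its own wildcard (``J45.4*``
matches a non-billable header record ``J45.4``), so header codes present in
an extract are not silently dropped.

Validity is a shape check only (letter + 2 alphanumerics + up to 4 more);
no embedded table of the >65,000 real ICD-10-CM codes is consulted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "DxCode",
    "CodePattern",
    "MalformedCodeError",
    "PatternSyntaxError",
    "normalize_code",
    "parse_pattern",
    "matches",
    "expand_pattern",
]

# letter, then 2 alphanumerics, then 0-4 alphanumerics (3-7 chars total,
# after the decimal point is removed)
_VALID_SHAPE = re.compile(r"^[A-Z][A-Z0-9]{2}[A-Z0-9]{0,4}$")


class MalformedCodeError(ValueError):
    """Raised for empty / whitespace-only diagnosis code input."""


class PatternSyntaxError(ValueError):
    """Raised for a code pattern with a misplaced or bare wildcard."""


@dataclass(frozen=True)
class DxCode:
    """A diagnosis code as found in source data plus its normalized form."""

    raw: str
    normalized: str
    valid: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.normalized


@dataclass(frozen=True)
class CodePattern:
    """An exact code or trailing-wildcard prefix pattern."""

    raw: str
    stem: str
    wildcard: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.stem + ("*" if self.wildcard else "")


def _normalize_text(raw: str) -> str:
    return raw.strip().upper().replace(".", "")


def normalize_code(raw: str) -> DxCode:
    """Normalize a raw diagnosis code string.

    Uppercases and removes the single decimal point; the ``valid`` flag is a
    shape check (letter + 2 alphanumerics + 0-4 alphanumerics). Odd shapes
    never raise — they come back with ``valid=False`` so that a stray junk
    code in an extract degrades to a non-match instead of aborting a run.

    Raises
    ------
    MalformedCodeError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise MalformedCodeError(f"empty or whitespace-only diagnosis code: {raw!r}")
    normalized = _normalize_text(raw)
    return DxCode(raw=raw, normalized=normalized, valid=bool(_VALID_SHAPE.match(normalized)))


def parse_pattern(raw: str) -> CodePattern:
    """Parse an exact or truncated (trailing ``*``) code pattern.

    Raises
    ------
    PatternSyntaxError
        For a bare ``*``, a ``*`` anywhere but the trailing position, more
        than one ``*``, a wildcard stem shorter than 3 characters, or an
        exact pattern that is not itself a valid normalized code.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise PatternSyntaxError(f"empty pattern: {raw!r}")
    text = raw.strip()
    n_stars = text.count("*")
    if n_stars > 1 or (n_stars == 1 and not text.endswith("*")):
        raise PatternSyntaxError(f"wildcard '*' only allowed once, in trailing position: {raw!r}")
    wildcard = text.endswith("*")
    stem = _normalize_text(text[:-1] if wildcard else text)
    if wildcard:
        if len(stem) < 3:
            raise PatternSyntaxError(f"wildcard stem must be at least 3 characters: {raw!r}")
    else:
        if not _VALID_SHAPE.match(stem):
            raise PatternSyntaxError(f"exact pattern is not a valid ICD-10-CM shape: {raw!r}")
    return CodePattern(raw=raw, stem=stem, wildcard=wildcard)


def matches(pattern: CodePattern, code: DxCode) -> bool:
    """True iff ``code`` falls under ``pattern``.

    Wildcard patterns match on prefix, the stem itself included; exact
    patterns require equality of normalized forms.
    """
    if pattern.wildcard:
        return code.normalized.startswith(pattern.stem)
    return code.normalized == pattern.stem


def expand_pattern(pattern: CodePattern, universe: set[DxCode] | frozenset[DxCode]) -> set[DxCode]:
    """All members of ``universe`` that ``pattern`` matches."""
    return {c for c in universe if matches(pattern, c)}
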