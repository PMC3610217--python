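"""Conversion of NLSdb and PROSITE pattern dialects to standard regular
expressions, matching, and per-class coverage.

NLSdb patterns are regex-like with a lowercase ``x`` wildcard:
``KKPx{6,9}Kx{1,3}RK`` becomes ``KKP.{6,9}K.{1,3}RK``.  PROSITE patterns use
dash-separated elements: ``G-S-x(2)-M-x-{RS}-K-x-N`` becomes
``GS.{2}M.[^RS]K.N``; ``[..]`` classes pass through, ``{..}`` becomes a
negated class, ``<``/``>`` anchor to the termini and ``(a)``/``(a,b)``
repeats become ``{a}``/``{a,b}``.  Conversion is deterministic; matching is
case-sensitive uppercase.

In masked sequences 'X' is an ordinary literal to the regex engine, so a
``.`` wildcard can fall in a masked gap; set ``wildcard_matches_mask=False``
to turn each ``.`` into ``[^X]`` instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Sequence

from .errors import DataError, PatternError


class Dialect(str, Enum):
    NLSDB = "nlsdb"
    PROSITE = "prosite"
    REGEX = "regex"


@dataclass(frozen=True)
class PatternSpec:
    raw: str
    dialect: Dialect
    converted: str


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    spans: tuple[tuple[int, int], ...]  # 1-based inclusive


_REPEAT_RE = re.compile(r"\{\d+(,\d+)?\}")
_PROSITE_ELEMENT_RE = re.compile(
    r"^(?P<base>[A-Z]|x|\[[A-Z]+\]|\{[A-Z]+\})(\((?P<lo>\d+)(,(?P<hi>\d+))?\))?$"
)


def _convert_nlsdb(raw: str) -> str:
    out: list[str] = []
    i = 0
    n = len(raw)
    while i < n:
        ch = raw[i]
        if ch == "x":
            out.append(".")
            i += 1
        elif ch.isalpha() and ch.isupper():
            out.append(ch)
            i += 1
        elif ch == "[":
            j = raw.find("]", i)
            if j == -1 or not raw[i + 1 : j].isupper():
                raise PatternError(
                    f"unparseable token {raw[i:]!r} at offset {i} in NLSdb pattern"
                )
            out.append(raw[i : j + 1])
            i = j + 1
        else:
            raise PatternError(
                f"unparseable token {ch!r} at offset {i} in NLSdb pattern"
            )
        if i < n and raw[i] == "{":
            j = raw.find("}", i)
            repeat = raw[i : j + 1] if j != -1 else raw[i:]
            if j == -1 or not _REPEAT_RE.fullmatch(repeat):
                raise PatternError(
                    f"unparseable repeat {repeat!r} at offset {i} in NLSdb pattern"
                )
            out.append(repeat)
            i = j + 1
    return "".join(out)


def _convert_prosite(raw: str) -> str:
    body = raw.strip().rstrip(".")
    prefix = suffix = ""
    if body.startswith("<"):
        prefix = "^"
        body = body[1:]
    if body.endswith(">"):
        suffix = "$"
        body = body[:-1]
    out: list[str] = [prefix]
    offset = 0
    for element in body.split("-"):
        m = _PROSITE_ELEMENT_RE.match(element)
        if m is None:
            raise PatternError(
                f"unparseable element {element!r} at offset {offset} "
                "in PROSITE pattern"
            )
        base = m.group("base")
        if base == "x":
            out.append(".")
        elif base.startswith("{"):
            out.append("[^" + base[1:-1] + "]")
        else:
            out.append(base)
        lo, hi = m.group("lo"), m.group("hi")
        if lo is not None:
            out.append("{" + lo + ("," + hi if hi else "") + "}")
        offset += len(element) + 1
    out.append(suffix)
    return "".join(out)


def convert_pattern(raw: str, dialect: Dialect | str) -> PatternSpec:
    """Convert a native pattern to the standard regex dialect."""
    if not raw:
        raise PatternError("empty pattern")
    dialect = Dialect(dialect)
    if dialect is Dialect.NLSDB:
        converted = _convert_nlsdb(raw)
    elif dialect is Dialect.PROSITE:
        converted = _convert_prosite(raw)
    else:
        converted = raw
    try:
        re.compile(converted)
    except re.error as exc:
        raise PatternError(f"converted pattern {converted!r} does not compile: {exc}")
    return PatternSpec(raw=raw, dialect=dialect, converted=converted)


@lru_cache(maxsize=4096)
def _compiled(converted: str, wildcard_matches_mask: bool) -> "re.Pattern[str]":
    if not wildcard_matches_mask:
        converted = re.sub(r"(?<!\\)\.", "[^X]", converted)
    return re.compile(converted)


def match_pattern(
    spec: PatternSpec, subject: str, wildcard_matches_mask: bool = True
) -> MatchResult:
    """Unanchored search of the converted pattern in ``subject``.

    Spans are 1-based inclusive, one per non-overlapping match.
    """
    pat = _compiled(spec.converted, wildcard_matches_mask)
    spans = tuple(
        (m.start() + 1, m.end()) for m in pat.finditer(subject) if m.end() > m.start()
    )
    return MatchResult(matched=pat.search(subject) is not None, spans=spans)


def coverage(
    specs: Sequence[PatternSpec],
    subjects: Sequence[str],
    wildcard_matches_mask: bool = True,
) -> float:
    """Fraction of subjects matched by at least one pattern (any-match)."""
    if not subjects:
        raise DataError("coverage needs at least one subject")
    if not specs:
        return 0.0
    pats = [_compiled(s.converted, wildcard_matches_mask) for s in specs]
    hit = sum(1 for subj in subjects if any(p.search(subj) for p in pats))
    return hit / len(subjects)


def per_pattern_counts(
    specs: Sequence[PatternSpec],
    subjects: Sequence[str],
    wildcard_matches_mask: bool = True,
) -> dict[str, int]:
    """Number of subjects matched by each pattern individually."""
    out: dict[str, int] = {}
    for spec in specs:
        pat = _compiled(spec.converted, wildcard_matches_mask)
        out[spec.raw] = sum(1 for subj in subjects if pat.search(subj))
    return out
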