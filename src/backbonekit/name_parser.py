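"""Decompose verbatim scientific-name strings into canonical parts.

Occurrence records arrive with a free-text name ("Vicia faba var. equina
Pers.").  Matching needs the canonical components — genus, epithets, an
infraspecific rank marker — separated from the authorship.  The heuristic
here: the genus is the leading capitalised token, epithets are the
following lower-case tokens, recognised rank markers (subsp., var., f.)
are lifted out of the epithet stream, and everything from the first token
that starts with an uppercase letter or "(" onward is authorship.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional


class RankMarker(str, enum.Enum):
    SUBSP = "subsp"
    VAR = "var"
    F = "f"

    @property
    def text(self) -> str:
        return f"{self.value}."


class ImpliedRank(str, enum.Enum):
    GENUS = "genus"
    SPECIES = "species"
    INFRASPECIFIC = "infraspecific"


_MARKER_TOKENS = {
    "subsp": RankMarker.SUBSP,
    "subsp.": RankMarker.SUBSP,
    "ssp": RankMarker.SUBSP,
    "ssp.": RankMarker.SUBSP,
    "var": RankMarker.VAR,
    "var.": RankMarker.VAR,
    "f": RankMarker.F,
    "f.": RankMarker.F,
}


class NameParseError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class ParsedName:
    genus: str
    specific_epithet: Optional[str] = None
    infraspecific_epithet: Optional[str] = None
    rank_marker: Optional[RankMarker] = None
    authorship: Optional[str] = None
    is_hybrid: bool = False

    @property
    def canonical(self) -> str:
        """Genus [+ epithet [+ marker + infraspecific epithet]]; epithets
        lower-cased, genus capitalised, no authorship."""
        parts = [self.genus]
        if self.specific_epithet:
            parts.append(self.specific_epithet)
        if self.infraspecific_epithet:
            marker = self.rank_marker.text if self.rank_marker else ""
            if marker:
                parts.append(marker)
            parts.append(self.infraspecific_epithet)
        return " ".join(parts)

    @property
    def implied_rank(self) -> ImpliedRank:
        if self.infraspecific_epithet:
            return ImpliedRank.INFRASPECIFIC
        if self.specific_epithet:
            return ImpliedRank.SPECIES
        return ImpliedRank.GENUS


_WS = re.compile(r"\s+")


def normalize_authorship(authorship: str) -> str:
    """Canonical whitespace for an authorship string.

    Collapses internal whitespace runs, removes space after "(" and before
    ")", and trims; case is preserved.  Total on any string.
    """
    s = _WS.sub(" ", authorship).strip()
    s = s.replace("( ", "(").replace(" )", ")")
    return s


def _is_author_start(token: str) -> bool:
    return token[:1] == "(" or token[:1].isupper()


def parse_name(verbatim: str) -> ParsedName:
    """Parse a verbatim name into :class:`ParsedName`.

    Raises :class:`NameParseError` when no alphabetic genus token exists.
    """
    s = _WS.sub(" ", verbatim).strip()
    is_hybrid = False
    if s.startswith("×"):
        is_hybrid = True
        s = s[1:].lstrip()
    elif s[:2] in ("x ", "X "):
        is_hybrid = True
        s = s[2:]
    s = s.replace("×", "").strip()
    tokens = s.split(" ")
    if not tokens or not tokens[0] or not tokens[0][0].isalpha():
        raise NameParseError(f"no alphabetic genus token in {verbatim!r}")

    genus = tokens[0][0].upper() + tokens[0][1:].lower()
    i = 1
    specific: Optional[str] = None
    infraspecific: Optional[str] = None
    marker: Optional[RankMarker] = None

    while i < len(tokens):
        tok = tokens[i]
        low = tok.lower()
        if low in _MARKER_TOKENS:
            # "f." is the forma marker only after an epithet; before one it
            # is far more likely "filius" inside an authorship.
            if _MARKER_TOKENS[low] is RankMarker.F and specific is None:
                break
            if i + 1 < len(tokens) and tokens[i + 1][:1].islower():
                marker = _MARKER_TOKENS[low]
                infraspecific = tokens[i + 1].lower()
                i += 2
                continue
            break
        if tok[:1].islower() and tok.replace("-", "").isalpha():
            if specific is None:
                specific = low
            elif infraspecific is None and marker is None:
                # an un-markered third epithet: keep it as infraspecific
                # with no marker rather than inventing one
                infraspecific = low
            i += 1
            continue
        if _is_author_start(tok):
            break
        break

    authorship = normalize_authorship(" ".join(tokens[i:])) if i < len(tokens) else None
    if authorship == "":
        authorship = None
    return ParsedName(
        genus=genus,
        specific_epithet=specific,
        infraspecific_epithet=infraspecific,
        rank_marker=marker,
        authorship=authorship,
        is_hybrid=is_hybrid,
    )
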