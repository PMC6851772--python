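"""Scheme identifiers, N/S/U bins, and label canonicalization.

Four structure-based mode-of-action (MOA) classification schemes are
supported: the modified Verhaar framework, ASTER, TEST, and OASIS.  Each
scheme emits free-text MOA labels; downstream they are collapsed into one of
three concordance bins — narcotic (N), specifically acting (S), or
unclassified (U).  The scheme ordering TEST < ASTER < OASIS < VERHAAR is
significant: it fixes the letter positions of the 4-letter concordance code.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass


class SchemeId(enum.Enum):
    """The four MOA classification schemes, in code-letter order."""

    TEST = "test"
    ASTER = "aster"
    OASIS = "oasis"
    VERHAAR = "verhaar"

    def __lt__(self, other: "SchemeId") -> bool:
        if not isinstance(other, SchemeId):
            return NotImplemented
        return SCHEME_ORDER.index(self) < SCHEME_ORDER.index(other)


#: Code-letter positions: codes read TEST, ASTER, OASIS, VERHAAR.
SCHEME_ORDER: tuple[SchemeId, ...] = (
    SchemeId.TEST,
    SchemeId.ASTER,
    SchemeId.OASIS,
    SchemeId.VERHAAR,
)


class Bin(enum.Enum):
    """Concordance bin: narcotic, specifically acting, or unclassified."""

    N = "N"
    S = "S"
    U = "U"


#: Canonical "no prediction / out of domain" key per scheme.  A scheme that
#: returns nothing is treated as out-of-domain, which every scheme bins as U.
UNKNOWN_LABELS: dict[SchemeId, str] = {
    SchemeId.TEST: "unknown or out of domain",
    SchemeId.ASTER: "unknown mode of action or out of domain",
    SchemeId.OASIS: "unknown or out of domain",
    SchemeId.VERHAAR: "class 5 (not classifiable)",
}

# Unicode hyphen/dash variants collapsed to ASCII '-' so labels copied from
# typeset sources match tool output.
_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")
_WS_RE = re.compile(r"\s+")


def canonical_key(raw: str) -> str:
    """Deterministic canonical form of a raw label (no scheme semantics)."""
    text = unicodedata.normalize("NFKC", raw).translate(_DASHES)
    text = _WS_RE.sub(" ", text).strip().casefold()
    # tighten spacing around punctuation that tools render inconsistently
    text = re.sub(r"\s*([/:,\-])\s*", r"\1", text)
    return text


@dataclass(frozen=True)
class SchemeLabel:
    """A raw scheme output together with its canonical lookup key."""

    scheme: SchemeId
    raw: str
    canonical: str

    @property
    def is_unknown_input(self) -> bool:
        return not self.raw.strip()


def canonicalize_label(scheme: SchemeId, raw: str | None) -> SchemeLabel:
    """Canonicalize a raw scheme label.

    Never raises: empty or missing input canonicalizes to the scheme's
    out-of-domain key (tools that return no prediction indicate the chemical
    is outside their applicability domain).
    """
    raw = "" if raw is None else str(raw)
    if not raw.strip():
        return SchemeLabel(scheme, raw, canonical_key(UNKNOWN_LABELS[scheme]))
    return SchemeLabel(scheme, raw, canonical_key(raw))
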