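"""Heavy-metal detection from SMILES and dummy-ion grouping.

The toxicity of many metal salts is driven by the freely dissolved metal
ion rather than by the parent compound, and metals are generally outside the
applicability domain of structure-based MOA schemes.  Compounds containing a
heavy metal — a metallic element with density above 5 g/cm³ — are therefore
flagged from their SMILES and collapsed into per-metal "dummy ion" groups;
grouped compounds carry no scheme classifications into the consensus engine.

Element extraction uses a lightweight SMILES tokenizer that understands
bracket atoms (``[Cd+2]``, ``[nH]``), the two-letter organic-subset halogens
(``Cl``, ``Br``), the single-letter organic subset and its aromatic
lowercase forms.  Bonds, branches, ring-closure digits, charges and
stereo markers are ignored: only element identity matters here.  An
RDKit-based validator can be layered on top where available, but element
counting itself needs no chemistry engine.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

DEFAULT_POLICY_RESOURCE = "heavy_metals_v1.txt"

# Organic-subset elements that never count as heavy metals.
ORGANIC_SUBSET = {"H", "B", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}

_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
}

_BRACKET_ATOM = re.compile(r"\[(\d*)([A-Za-z][a-z]?|\*)")
_TOKEN = re.compile(
    r"""
    \[[^\]]*\]          # bracket atom
  | Cl | Br             # two-letter organic subset
  | [BCNOSPFI]          # one-letter organic subset
  | [bcnops]            # aromatic organic subset
  | %\d{2} | \d         # ring closures
  | [-=\#$:/\\.()+*~]   # bonds, branches, dot-disconnect, wildcard
    """,
    re.VERBOSE,
)

_AROMATIC = {"b": "B", "c": "C", "n": "N", "o": "O", "p": "P", "s": "S",
             "se": "Se", "as": "As"}


class SmilesParseError(ValueError):
    """Raised on a SMILES token the element scanner cannot interpret."""


def parse_elements(smiles: str) -> Counter:
    """Element multiset of a SMILES string.

    >>> dict(parse_elements("[Cd+2].[Cl-].[Cl-]"))
    {'Cd': 1, 'Cl': 2}
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES")
    smiles = smiles.strip()
    counts: Counter = Counter()
    pos = 0
    while pos < len(smiles):
        m = _TOKEN.match(smiles, pos)
        if m is None:
            raise SmilesParseError(
                f"unparseable SMILES token at position {pos}: {smiles[pos:pos + 8]!r}"
            )
        tok = m.group(0)
        if tok.startswith("["):
            am = _BRACKET_ATOM.match(tok)
            sym = am.group(2) if am else ""
            if sym in _AROMATIC:
                sym = _AROMATIC[sym]
            if sym == "*":
                pass  # wildcard atom: no element
            elif sym in _ELEMENTS:
                counts[sym] += 1
            else:
                raise SmilesParseError(
                    f"unknown element {sym!r} in bracket atom {tok} at position {pos}"
                )
        elif tok in ("Cl", "Br") or (len(tok) == 1 and tok in "BCNOSPFI"):
            counts[tok] += 1
        elif tok in _AROMATIC:
            counts[_AROMATIC[tok]] += 1
        # ring closures, bonds, branches, dots: structural only
        pos = m.end()
    return counts


@dataclass(frozen=True)
class HeavyMetalPolicy:
    """Versioned set of heavy-metal element symbols (density > 5 g/cm³)."""

    elements: frozenset[str]
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if not self.elements:
            raise ValueError("heavy-metal policy is empty")
        clash = self.elements & ORGANIC_SUBSET
        if clash:
            raise ValueError(f"policy contains organic-subset elements: {sorted(clash)}")


def load_policy(path: str | Path | None = None) -> HeavyMetalPolicy:
    """Load the packaged heavy-metal element list, or an override file."""
    if path is None:
        ref = resources.files("moaconsensus.data") / DEFAULT_POLICY_RESOURCE
        text = ref.read_text(encoding="utf-8")
        version = DEFAULT_POLICY_RESOURCE.rsplit(".", 1)[0]
    else:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        version = path.stem
    elements = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if line not in _ELEMENTS:
            raise ValueError(f"heavy-metal policy: unknown element symbol {line!r}")
        elements.add(line)
    return HeavyMetalPolicy(elements=frozenset(elements), version=version)


def contains_heavy_metal(
    smiles: str, policy: HeavyMetalPolicy
) -> tuple[bool, frozenset[str]]:
    """Whether a SMILES contains any policy element, and which.

    Mixture SMILES (dot-disconnected) are covered component-wise by
    construction: the element multiset spans all components.
    """
    found = frozenset(parse_elements(smiles)) & policy.elements
    return bool(found), found


def collapse_to_dummy_ion(
    chemicals: pd.DataFrame, policy: HeavyMetalPolicy
) -> pd.DataFrame:
    """Flag heavy-metal compounds and assign dummy metal-ion groups.

    Adds/overwrites columns ``metal_flag``, ``metal_elements`` (sorted,
    '+'-joined) and ``dummy_group``.  The group key is the sorted set of
    heavy-metal elements present, so e.g. all cadmium salts collapse into
    one "Cd" dummy ion.  Non-metal chemicals are untouched.  Flagged
    chemicals have their scheme labels cleared: these compounds have no
    modeled MOA data, so the consensus engine sees them as UUUU.
    """
    out = chemicals.copy()
    flags, elems, groups = [], [], []
    for smiles in out["smiles"]:
        if pd.isna(smiles) or not str(smiles).strip():
            flags.append(False)
            elems.append("")
            groups.append("")
            continue
        flag, found = contains_heavy_metal(str(smiles), policy)
        flags.append(flag)
        key = "+".join(sorted(found))
        elems.append(key)
        groups.append(key if flag else "")
    out["metal_flag"] = flags
    out["metal_elements"] = elems
    out["dummy_group"] = groups
    label_cols = [c for c in out.columns if c.endswith("_label")]
    if label_cols:
        out.loc[out["metal_flag"], label_cols] = ""
    return out
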