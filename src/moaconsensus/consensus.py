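"""Consensus MOA assignment from 4-letter concordance codes.

Each chemical carries a 4-letter code over {N, S, U} giving the collapsed
bin reported by TEST, ASTER, OASIS and Verhaar, in that order.  The consensus
rules score the degree of agreement:

* all four letters identical → that bin, confidence 3;
* exactly three identical → the majority bin, confidence 2;
* two identical non-U letters with the other two both U → the non-U bin,
  confidence 1;
* anything else → U, confidence 0.

The ``conservative`` mode implements the precautionary variant: a 2-vs-2
split between N and S is reassigned to S (reactive unspecified) with
confidence 1 rather than left unclassified, on the grounds that treating a
possibly specifically acting chemical as narcotic understates its hazard.
All 3^4 = 81 codes are classifiable; the rules partition them with no ties.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .binmap import BinMap, bin_chemical
from .schemes import SCHEME_ORDER, Bin, SchemeId

Mode = Literal["default", "conservative"]

LETTERS = ("N", "S", "U")


@dataclass(frozen=True)
class ConsensusResult:
    """Consensus MOA and confidence for one 4-letter code."""

    code: str
    consensus_moa: Bin
    confidence: int
    mode: Mode

    def __post_init__(self) -> None:
        if len(self.code) != 4 or any(c not in LETTERS for c in self.code):
            raise ValueError(f"invalid 4-letter code {self.code!r}")
        if self.confidence not in (0, 1, 2, 3):
            raise ValueError(f"confidence must be 0..3, got {self.confidence}")


def code_of(bins: Sequence[Bin]) -> str:
    """Concatenate a (TEST, ASTER, OASIS, VERHAAR) bin vector into a code."""
    if len(bins) != 4:
        raise ValueError(f"expected 4 bins, got {len(bins)}")
    return "".join(b.value for b in bins)


def consensus(bins: Sequence[Bin] | str, mode: Mode = "default") -> ConsensusResult:
    """Apply the consensus rules to a bin vector or 4-letter code."""
    if isinstance(bins, str):
        code = bins.upper()
        if len(code) != 4 or any(c not in LETTERS for c in code):
            raise ValueError(f"invalid 4-letter code {bins!r}")
    else:
        code = code_of(bins)
    counts = Counter(code)
    top_letter, top = counts.most_common(1)[0]
    if top == 4:
        moa, score = Bin(top_letter), 3
    elif top == 3:
        moa, score = Bin(top_letter), 2
    elif top == 2 and counts.get("U") == 2 and len(counts) == 2:
        # a non-U pair plus two U letters
        moa, score = Bin(top_letter if top_letter != "U" else code.replace("U", "")[0]), 1
    elif mode == "conservative" and counts.get("N") == 2 and counts.get("S") == 2:
        moa, score = Bin.S, 1
    else:
        moa, score = Bin.U, 0
    return ConsensusResult(code=code, consensus_moa=moa, confidence=score, mode=mode)


def enumerate_all_codes(mode: Mode = "default") -> pd.DataFrame:
    """Classify all 81 possible codes; columns code, consensus_moa, confidence."""
    rows = []
    for letters in itertools.product(LETTERS, repeat=4):
        res = consensus("".join(letters), mode=mode)
        rows.append(
            {"code": res.code, "consensus_moa": res.consensus_moa.value, "confidence": res.confidence}
        )
    return pd.DataFrame(rows)


def classify_chemicals(
    chemicals: pd.DataFrame,
    binmap: BinMap,
    mode: Mode = "default",
    *,
    strict: bool = False,
) -> pd.DataFrame:
    """Classify a chemical table into consensus MOA assignments.

    ``chemicals`` must have columns ``id`` plus the four label columns
    ``test_label``, ``aster_label``, ``oasis_label``, ``verhaar_label``
    (empty cells mean the scheme returned no prediction).  Chemicals with
    ``metal_flag`` set are forced to UUUU: metal-containing compounds carry
    no modeled MOA data.

    Returns one row per chemical: id, code, consensus_moa, confidence.
    """
    dup = chemicals["id"][chemicals["id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"duplicate chemical ids: {', '.join(map(str, dup))}")
    label_cols = {s: f"{s.value}_label" for s in SCHEME_ORDER}
    out = []
    for row in chemicals.itertuples(index=False):
        rowd = row._asdict()
        if bool(rowd.get("metal_flag", False)):
            bins: tuple[Bin, ...] = (Bin.U, Bin.U, Bin.U, Bin.U)
        else:
            raw = {s: rowd.get(col) for s, col in label_cols.items()}
            raw = {s: (None if pd.isna(v) else v) for s, v in raw.items()}
            bins = bin_chemical(raw, binmap, strict=strict)
        res = consensus(bins, mode=mode)
        out.append(
            {
                "id": rowd["id"],
                "code": res.code,
                "consensus_moa": res.consensus_moa.value,
                "confidence": res.confidence,
            }
        )
    return pd.DataFrame(out, columns=["id", "code", "consensus_moa", "confidence"])


def summarize_assignments(
    results: pd.DataFrame, studies: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-(consensus MOA, confidence) chemical counts and percentages.

    Mirrors the shape of the published assignment summary: one row per
    occupied (consensus_moa, confidence) cell with the member codes listed.
    If a study table (with column ``id``) is given, per-cell study counts
    and percentages are added.
    """
    if results.empty:
        cols = ["consensus_moa", "confidence", "n_chemicals", "pct_chemicals", "codes"]
        if studies is not None:
            cols += ["n_studies", "pct_studies"]
        return pd.DataFrame(columns=cols)
    grp = results.groupby(["consensus_moa", "confidence"], sort=True)
    summary = grp.agg(
        n_chemicals=("id", "size"),
        codes=("code", lambda c: ",".join(sorted(c.unique()))),
    ).reset_index()
    summary["pct_chemicals"] = 100.0 * summary["n_chemicals"] / len(results)
    if studies is not None:
        joined = studies.merge(results[["id", "consensus_moa", "confidence"]], on="id", how="inner")
        sc = (
            joined.groupby(["consensus_moa", "confidence"])
            .size()
            .rename("n_studies")
            .reset_index()
        )
        summary = summary.merge(sc, on=["consensus_moa", "confidence"], how="left")
        summary["n_studies"] = summary["n_studies"].fillna(0).astype(int)
        total = summary["n_studies"].sum()
        summary["pct_studies"] = 100.0 * summary["n_studies"] / total if total else 0.0
    order = ["consensus_moa", "confidence", "n_chemicals", "pct_chemicals"]
    if studies is not None:
        order += ["n_studies", "pct_studies"]
    order += ["codes"]
    summary = summary[order].sort_values(
        ["consensus_moa", "confidence"], ascending=[True, False]
    )
    return summary.reset_index(drop=True)


def scheme_bin_distribution(chemicals: pd.DataFrame, binmap: BinMap) -> pd.DataFrame:
    """Fraction of chemicals each scheme places in N, S and U.

    Returns a tidy frame with columns scheme, bin, fraction; fractions for
    one scheme sum to 1.
    """
    label_cols = {s: f"{s.value}_label" for s in SCHEME_ORDER}
    rows = []
    n = len(chemicals)
    per_scheme: dict[SchemeId, Counter] = {s: Counter() for s in SCHEME_ORDER}
    for row in chemicals.itertuples(index=False):
        rowd = row._asdict()
        if bool(rowd.get("metal_flag", False)):
            bins: Iterable[Bin] = (Bin.U,) * 4
        else:
            raw = {s: rowd.get(col) for s, col in label_cols.items()}
            raw = {s: (None if pd.isna(v) else v) for s, v in raw.items()}
            bins = bin_chemical(raw, binmap)
        for s, b in zip(SCHEME_ORDER, bins):
            per_scheme[s][b.value] += 1
    for s in SCHEME_ORDER:
        for letter in LETTERS:
            rows.append(
                {
                    "scheme": s.value,
                    "bin": letter,
                    "fraction": per_scheme[s][letter] / n if n else 0.0,
                }
            )
    return pd.DataFrame(rows)
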