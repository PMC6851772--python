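"""The label → bin concordance map.

The map collapsing each scheme's MOA labels into N/S/U ships as a versioned
CSV under ``moaconsensus/data`` so curators can extend it without touching
code.  Lookup is by canonical key: case-insensitive with whitespace and
punctuation normalization, never by substring heuristics.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .schemes import (
    SCHEME_ORDER,
    UNKNOWN_LABELS,
    Bin,
    SchemeId,
    SchemeLabel,
    canonical_key,
    canonicalize_label,
)

logger = logging.getLogger(__name__)

DEFAULT_BINMAP_RESOURCE = "binmap_v1.csv"


class UnmatchedLabelError(KeyError):
    """Raised in strict mode when a raw label has no bin-map entry."""


@dataclass(frozen=True)
class BinMap:
    """Mapping (scheme, canonical label) → Bin, with a version tag."""

    entries: dict[tuple[SchemeId, str], Bin]
    version: str = "unversioned"
    labels_raw: dict[tuple[SchemeId, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for scheme in SCHEME_ORDER:
            bins = {b for (s, _), b in self.entries.items() if s is scheme}
            missing = set(Bin) - bins
            if missing:
                raise ValueError(
                    f"bin map {self.version!r}: scheme {scheme.name} has no "
                    f"label mapped to {sorted(b.value for b in missing)}"
                )

    def lookup(self, label: SchemeLabel) -> Bin | None:
        return self.entries.get((label.scheme, label.canonical))

    def labels_for(self, scheme: SchemeId, bin_: Bin) -> list[str]:
        """Raw (printable) labels of one scheme mapped to one bin."""
        return [
            self.labels_raw.get((s, key), key)
            for (s, key), b in self.entries.items()
            if s is scheme and b is bin_
        ]


def load_binmap(path: str | Path | None = None) -> BinMap:
    """Load the packaged bin map, or a user-supplied override CSV.

    The CSV must have columns ``scheme`` (test/aster/oasis/verhaar),
    ``label`` and ``bin`` (N/S/U).
    """
    if path is None:
        ref = resources.files("moaconsensus.data") / DEFAULT_BINMAP_RESOURCE
        with resources.as_file(ref) as p:
            return _parse_binmap(p, version=DEFAULT_BINMAP_RESOURCE.replace(".csv", ""))
    path = Path(path)
    return _parse_binmap(path, version=path.stem)


def _parse_binmap(path: Path, version: str) -> BinMap:
    entries: dict[tuple[SchemeId, str], Bin] = {}
    raws: dict[tuple[SchemeId, str], str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"scheme", "label", "bin"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"bin map {path}: expected columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            scheme = SchemeId(row["scheme"].strip().lower())
            key = canonical_key(row["label"])
            bin_ = Bin(row["bin"].strip().upper())
            if (scheme, key) in entries and entries[(scheme, key)] is not bin_:
                raise ValueError(
                    f"bin map {path} line {i}: conflicting bins for "
                    f"{scheme.name} label {row['label']!r}"
                )
            entries[(scheme, key)] = bin_
            raws[(scheme, key)] = row["label"].strip()
    return BinMap(entries=entries, version=version, labels_raw=raws)


def bin_label(label: SchemeLabel, binmap: BinMap, *, strict: bool = False) -> Bin:
    """Collapse one scheme label into its N/S/U bin.

    Unmatched labels default to U with a warning — the schemes themselves
    report "unknown", "not classifiable" or "out of domain" for chemicals
    they cannot place, so an unrecognized label is treated the same way.
    With ``strict=True`` an unmatched label raises instead (curation mode).
    """
    bin_ = binmap.lookup(label)
    if bin_ is not None:
        return bin_
    if strict:
        raise UnmatchedLabelError(
            f"{label.scheme.name}: no bin-map entry for label {label.raw!r}"
        )
    logger.warning(
        "unmatched label defaulted to U: scheme=%s raw=%r canonical=%r",
        label.scheme.name,
        label.raw,
        label.canonical,
    )
    return Bin.U


def bin_chemical(
    labels: dict[SchemeId, str | None] | list[SchemeLabel],
    binmap: BinMap,
    *,
    strict: bool = False,
) -> tuple[Bin, Bin, Bin, Bin]:
    """Bin one chemical's four scheme labels into a (TEST, ASTER, OASIS,
    VERHAAR) bin vector.

    Accepts either a scheme→raw-text mapping (missing schemes filled with
    the scheme's out-of-domain label) or a list of SchemeLabels covering
    each scheme at most once.
    """
    if isinstance(labels, dict):
        slabels = {s: canonicalize_label(s, labels.get(s)) for s in SCHEME_ORDER}
    else:
        slabels = {}
        for lab in labels:
            if lab.scheme in slabels:
                raise ValueError(f"duplicate label for scheme {lab.scheme.name}")
            slabels[lab.scheme] = lab
        for s in SCHEME_ORDER:
            slabels.setdefault(s, canonicalize_label(s, None))
    return tuple(bin_label(slabels[s], binmap, strict=strict) for s in SCHEME_ORDER)  # type: ignore[return-value]
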