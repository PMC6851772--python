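"""CSV readers/writers and run metadata.

Interchange format is UTF-8, comma-delimited CSV with a header row.  Readers
validate the column contract up front and fail with the offending column or
row named; writers emit deterministic column and row order so identical
inputs and configuration produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .toxicity import TROPHIC_LEVELS

logger = logging.getLogger(__name__)

CHEMICAL_COLUMNS = [
    "id",
    "smiles",
    "test_label",
    "aster_label",
    "oasis_label",
    "verhaar_label",
]
STUDY_COLUMNS = ["id", "species", "trophic_level", "endpoint", "duration_h", "effect_mg_L"]


def read_chemicals(path: str | Path) -> pd.DataFrame:
    """Read a chemical table (id, SMILES, four raw scheme labels).

    Empty label cells are preserved as empty strings, meaning the scheme
    returned no prediction.  Duplicate ids are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CHEMICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    dup = df["id"][df["id"].duplicated()].unique()
    if len(dup):
        raise ValueError(f"{path}: duplicate chemical id(s): {', '.join(dup)}")
    if (df["id"].str.strip() == "").any():
        raise ValueError(f"{path}: empty chemical id")
    return df


def read_studies(path: str | Path) -> pd.DataFrame:
    """Read a study table; effects must parse as positive decimals."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    for col in ("duration_h", "effect_mg_L"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col} is not numeric: {exc}") from None
        bad = df.index[~(df[col] > 0)]
        if len(bad):
            # +2: header line plus 1-based numbering
            lines = ", ".join(str(i + 2) for i in bad[:10])
            raise ValueError(f"{path}: non-positive {col} at line(s) {lines}")
    df["trophic_level"] = df["trophic_level"].str.strip().str.lower()
    unknown = sorted(set(df["trophic_level"]) - set(TROPHIC_LEVELS))
    if unknown:
        raise ValueError(f"{path}: unknown trophic level(s): {', '.join(unknown)}")
    df["endpoint"] = df["endpoint"].str.strip().str.upper()
    return df


def write_table(df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a CSV deterministically (sorted rows, fixed column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if sort_by:
        df = df.sort_values(sort_by, kind="mergesort")
    df.to_csv(path, index=False)
    logger.info("wrote %d row(s) to %s", len(df), path)


def write_run_metadata(path: str | Path, **meta: object) -> None:
    """Record the run's configuration (mode, versions, seed, paths)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__

    payload = {"package_version": __version__, **meta}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
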