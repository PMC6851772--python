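"""Synthetic chemical and study tables with known ground truth.

The generator emulates the statistical structure the consensus analysis
assumes, so every pipeline stage is testable without external data:

* each chemical has a latent true MOA (N or S); each of the four schemes
  reports a label from the latent bin's label set with probability
  ``agreement``, from the opposite bin otherwise, and is out-of-domain
  (→ U) with a per-scheme ``p_unknown`` — scheme errors are independent by
  default, with an optional shared-error correlation knob;
* study-level log10 effect concentrations are Normal with MOA- and
  trophic-level-specific location/scale.  Defaults put the fish medians at
  10 mg/L (narcotic) and 1 mg/L (specifically acting), separate the
  invertebrate medians by nearly three orders of magnitude, and let the
  algal N and S distributions overlap — the potency structure the consensus
  classification is validated against;
* a small fraction of chemicals are heavy-metal salts drawn from a pool of
  metal elements; they carry no scheme labels.

Everything is reproducible given a seed, and a latent-truth table is
returned alongside each generated table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binmap import BinMap, load_binmap
from .schemes import SCHEME_ORDER, UNKNOWN_LABELS, Bin, SchemeId

ORGANIC_SMILES_POOL = (
    "CCO",
    "c1ccccc1",
    "CC(=O)OCC",
    "CCCCCCCCO",
    "Oc1ccccc1",
    "CC(=O)C",
    "ClCCCl",
    "c1ccc2ccccc2c1",
    "CC(C)O",
    "O=Cc1ccccc1",
)

METAL_ELEMENT_POOL = (
    "Cd", "Cu", "Zn", "Pb", "Hg", "Ni", "Co", "Cr", "Mn", "Fe", "Ag", "Sn",
    "Sb", "Mo", "V", "W", "Tl", "Bi", "U", "Zr", "Ga", "In", "Pd", "Pt",
)

#: Acute in-window duration choices per trophic level (hours) and the
#: qualifying endpoint drawn for generated records.
_TROPHIC_DURATIONS = {
    "fish": (24.0, 48.0, 72.0, 96.0),
    "invertebrate": (24.0, 48.0, 96.0),
    "algae": (48.0, 72.0, 96.0),
}
_TROPHIC_ENDPOINT = {"fish": "LC50", "invertebrate": "EC50", "algae": "EC50"}
_OFFWINDOW_DURATION = 120.0


def _default_p_unknown() -> dict[str, float]:
    # per-scheme out-of-domain rates, roughly the relative ordering seen in
    # practice: Verhaar unclassifiable far more often than OASIS
    return {"test": 0.21, "aster": 0.22, "oasis": 0.08, "verhaar": 0.44}


def _default_effect_mu() -> dict[str, dict[str, float]]:
    # log10 mg/L medians per trophic level and latent MOA
    return {
        "fish": {"N": 1.0, "S": 0.0},
        "invertebrate": {"N": 1.5, "S": -1.3},
        "algae": {"N": 0.5, "S": 0.7},
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic chemical/study generator."""

    n_chemicals: int = 500
    p_specific: float = 0.3
    agreement: float = 0.8
    p_unknown: dict[str, float] = field(default_factory=_default_p_unknown)
    rho: float = 0.0
    effect_mu: dict[str, dict[str, float]] = field(default_factory=_default_effect_mu)
    effect_sigma: float = 0.8
    studies_per_chemical: float = 2.0
    p_offwindow: float = 0.1
    metal_fraction: float = 0.035
    metal_elements: tuple[str, ...] = METAL_ELEMENT_POOL

    def __post_init__(self) -> None:
        if isinstance(self.p_unknown, (int, float)):
            # scalar convenience: same out-of-domain rate for all schemes
            self.p_unknown = {s.value: float(self.p_unknown) for s in SCHEME_ORDER}

    def validate(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        probs = [self.p_specific, self.agreement, self.rho, self.p_offwindow,
                 self.metal_fraction, *self.p_unknown.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.effect_sigma < 0:
            raise ValueError("effect_sigma must be >= 0")
        if self.studies_per_chemical < 0:
            raise ValueError("studies_per_chemical must be >= 0")


def _draw_label(rng: np.random.Generator, binmap: BinMap, scheme: SchemeId, bin_: Bin) -> str:
    labels = sorted(binmap.labels_for(scheme, bin_))
    return labels[rng.integers(len(labels))]


def generate_chemicals(
    cfg: GeneratorConfig, seed: int, binmap: BinMap | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a chemical table and its latent-truth table.

    Returns ``(chemicals, truth)``: chemicals has columns id, smiles and the
    four scheme-label columns; truth has id, true_moa and is_metal.
    """
    cfg.validate()
    binmap = binmap or load_binmap()
    rng = np.random.default_rng(seed)
    n = cfg.n_chemicals
    ids = [f"SYN-{i:05d}" for i in range(n)]
    latent = np.where(rng.random(n) < cfg.p_specific, "S", "N")
    is_metal = rng.random(n) < cfg.metal_fraction

    chem_rows = []
    for i in range(n):
        if is_metal[i]:
            el = cfg.metal_elements[rng.integers(len(cfg.metal_elements))]
            anion = (".[Cl-].[Cl-]", ".[O-]S(=O)(=O)[O-]")[rng.integers(2)]
            row = {
                "id": ids[i],
                "smiles": f"[{el}+2]{anion}",
                **{f"{s.value}_label": "" for s in SCHEME_ORDER},
            }
        else:
            smiles = ORGANIC_SMILES_POOL[rng.integers(len(ORGANIC_SMILES_POOL))]
            true_bin = Bin(latent[i])
            opposite = Bin.S if true_bin is Bin.N else Bin.N
            shared = rng.random() < cfg.rho
            shared_agrees = rng.random() < cfg.agreement
            labels = {}
            for s in SCHEME_ORDER:
                if rng.random() < cfg.p_unknown[s.value]:
                    labels[f"{s.value}_label"] = UNKNOWN_LABELS[s]
                    continue
                agrees = shared_agrees if shared else rng.random() < cfg.agreement
                labels[f"{s.value}_label"] = _draw_label(
                    rng, binmap, s, true_bin if agrees else opposite
                )
            row = {"id": ids[i], "smiles": smiles, **labels}
        chem_rows.append(row)

    chemicals = pd.DataFrame(chem_rows)
    truth = pd.DataFrame({"id": ids, "true_moa": latent, "is_metal": is_metal})
    return chemicals, truth


def generate_studies(
    truth: pd.DataFrame, cfg: GeneratorConfig, seed: int
) -> pd.DataFrame:
    """Generate a study table for generated chemicals.

    Per chemical × trophic level, Poisson(``studies_per_chemical``) records;
    each is in the acute window with probability 1 − ``p_offwindow``
    (off-window records get a 120-h duration).  log10 effect is Normal with
    the configured (MOA, trophic level) location and common scale.
    """
    cfg.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for rec in truth.itertuples(index=False):
        for level in _TROPHIC_DURATIONS:
            k = rng.poisson(cfg.studies_per_chemical)
            mu = cfg.effect_mu[level][rec.true_moa]
            for _ in range(k):
                if rng.random() < cfg.p_offwindow:
                    duration = _OFFWINDOW_DURATION
                else:
                    durs = _TROPHIC_DURATIONS[level]
                    duration = durs[rng.integers(len(durs))]
                log_effect = rng.normal(mu, cfg.effect_sigma)
                rows.append(
                    {
                        "id": rec.id,
                        "species": f"{level}_sp{rng.integers(5)}",
                        "trophic_level": level,
                        "endpoint": _TROPHIC_ENDPOINT[level],
                        "duration_h": duration,
                        "effect_mg_L": 10.0 ** log_effect,
                    }
                )
    cols = ["id", "species", "trophic_level", "endpoint", "duration_h", "effect_mg_L"]
    return pd.DataFrame(rows, columns=cols)


def code_probabilities(cfg: GeneratorConfig) -> dict[str, float]:
    """Exact 4-letter-code distribution implied by the generator (rho = 0).

    Closed form by enumeration: per scheme, the reported letter is U with
    ``p_unknown``, the latent letter with (1 − p_unknown)·agreement, and the
    opposite non-U letter otherwise; schemes independent, latents mixed with
    ``p_specific``.  Metal chemicals (all-U codes) are included.
    """
    cfg.validate()
    if cfg.rho != 0.0:
        raise ValueError("closed form assumes independent scheme errors (rho = 0)")
    out: dict[str, float] = {c: 0.0 for c in map("".join, itertools.product("NSU", repeat=4))}
    for latent, p_lat in (("N", 1 - cfg.p_specific), ("S", cfg.p_specific)):
        opposite = "S" if latent == "N" else "N"
        per_scheme = []
        for s in SCHEME_ORDER:
            pu = cfg.p_unknown[s.value]
            per_scheme.append(
                {
                    latent: (1 - pu) * cfg.agreement,
                    opposite: (1 - pu) * (1 - cfg.agreement),
                    "U": pu,
                }
            )
        for letters in itertools.product("NSU", repeat=4):
            p = np.prod([per_scheme[i][c] for i, c in enumerate(letters)])
            out["".join(letters)] += (1 - cfg.metal_fraction) * p_lat * float(p)
    out["UUUU"] += cfg.metal_fraction
    return out
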