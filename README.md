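# moaconsensus

Consensus mode-of-action (MOA) classification for aquatic ecotoxicology.

Several structure-based schemes assign an aquatic MOA to a chemical — the
modified Verhaar framework, ASTER, TEST and OASIS — but their category
systems differ and they frequently disagree. `moaconsensus` is for
ecotoxicologists and risk assessors who have the raw outputs of those four
schemes for a set of chemicals and want a single, transparent consensus
call per chemical with an explicit measure of how much the schemes agreed.

## The method

Each scheme's label is first collapsed into one of three bins:

* **N** — narcotic (non-specific, baseline toxicity),
* **S** — specifically acting (reactive chemistry or a specific target,
  e.g. AChE inhibition, uncoupling of oxidative phosphorylation),
* **U** — unclassified (out of the scheme's applicability domain, or no
  prediction).

The four bins are concatenated into a 4-letter code in the fixed order
TEST, ASTER, OASIS, Verhaar, and scored:

| pattern | consensus MOA | confidence |
|---|---|---|
| all four letters equal (NNNN, SSSS, UUUU) | that bin | 3 |
| exactly three equal (e.g. NNNS) | majority bin | 2 |
| one non-U pair plus two U (e.g. NNUU, SUSU) | the non-U bin | 1 |
| anything else (e.g. NUNS) | U | 0 |

An opt-in *conservative* mode additionally reassigns the six 2-N/2-S split
codes (e.g. NNSS) to S with confidence 1, on the precautionary argument
that a chemical which half the schemes call specifically acting should not
be left unclassified.

Around the rule engine the package provides: heavy-metal flagging from
SMILES (metallic elements with density > 5 g/cm³; metal compounds are
collapsed into per-element "dummy ion" groups and carry no scheme
classifications), acute-toxicity filtering (24–96-h fish LC50 and
analogous windows for invertebrates and algae), quartile summaries of
log10 effect concentrations by consensus MOA and trophic level, and a
synthetic-data generator with known ground truth for end-to-end testing.

## Worked example

```python
import pandas as pd
import moaconsensus as moa

chems = pd.DataFrame([
    {"id": "71-43-2", "smiles": "c1ccccc1",
     "test_label": "Narcosis", "aster_label": "Nonpolar narcosis",
     "oasis_label": "Base surface narcotics",
     "verhaar_label": "Class 1 (narcosis or baseline toxicity)"},
    {"id": "121-75-5", "smiles": "CCOC(=O)CC(SP(=S)(OC)OC)C(=O)OCC",
     "test_label": "AChE inhibition",
     "aster_label": "Organophosphate-mediated AChE inhibition",
     "oasis_label": "Esters",
     "verhaar_label": "Class 4 (compounds and groups of compounds acting by a specific mechanism)"},
    {"id": "7646-85-7", "smiles": "[Zn+2].[Cl-].[Cl-]",
     "test_label": "", "aster_label": "", "oasis_label": "", "verhaar_label": ""},
])
chems = moa.collapse_to_dummy_ion(chems, moa.load_policy())
results = moa.classify_chemicals(chems, moa.load_binmap())
print(results.to_string(index=False))
```

prints

```
       id code consensus_moa  confidence
  71-43-2 NNNN             N           3
 121-75-5 SSNS             S           2
7646-85-7 UUUU             U           3
```

Benzene is called narcotic by all four schemes — consensus N at the highest
confidence. Malathion is specifically acting for TEST, ASTER and Verhaar
but OASIS files it under its ester *structure* (an N bin), so the consensus
is S with confidence 2: the code makes the disagreement visible instead of
hiding it. Zinc chloride is flagged as a heavy-metal salt (dummy group
"Zn"), its scheme labels are dropped, and it lands in UUUU — metals are
outside the applicability domain of all four schemes.

The same pipeline is available from the shell:

```sh
moaconsensus classify --chemicals chemicals.csv --out results.csv --out-summary summary.csv
moaconsensus summarize --studies studies.csv --results results.csv \
    --by-trophic-level --out-distribution dist.csv --out-coverage cov.csv
moaconsensus enumerate --out codes.csv          # all 81 codes and their scores
moaconsensus flag-metals --chemicals chemicals.csv --out flagged.csv
moaconsensus simulate --n 1000 --seed 1 --outdir sim/
```

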