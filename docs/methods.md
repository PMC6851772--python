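# Methods

## Scope and model

`moaconsensus` post-processes the outputs of four structure-based aquatic
mode-of-action (MOA) classification schemes — TEST, ASTER, OASIS and the
modified Verhaar framework — into a consensus MOA per chemical. It does
not predict MOA from structure itself: the upstream tools are run
elsewhere, and their free-text labels are this package's input.

The classification pipeline has four stages:

1. **Binning.** Each scheme label is collapsed to N (narcotic), S
   (specifically acting) or U (unclassified) through a packaged lookup
   table (`src/moaconsensus/data/binmap_v1.csv`, 51 labels). Matching is
   by canonical key — NFKC normalization, Unicode-dash folding, whitespace
   collapsing, case folding, and tightened spacing around `/ : , -` — and
   deliberately not by substring heuristics, which would confuse e.g.
   "ester narcosis" (N) with ASTER's diester/acrylate reactivity classes
   (S). A label with no table entry defaults to U with a logged warning; a
   strict flag turns this into an error for curation work. A missing or
   empty label is treated as the scheme's own "unknown / out of domain"
   answer, which every scheme bins as U.
2. **Concordance code.** The four bins are concatenated in the fixed
   order TEST, ASTER, OASIS, Verhaar. The order is not configurable:
   keeping letter positions fixed is what makes codes comparable across
   datasets.
3. **Consensus scoring.** 4 alike → that bin, confidence 3; exactly 3
   alike → majority bin, confidence 2; a non-U pair plus two U → the non-U
   bin, confidence 1; everything else → U, confidence 0. The four cases
   are mutually exclusive and exhaustive over all 81 codes, so no
   tie-break is ever needed; the test suite asserts this by enumeration
   against two independent oracles (a sorted-multiset case analysis and a
   position-pair count) rather than assuming it. Of the 81 codes, 3 score
   3, 24 score 2, 12 score 1 and 42 score 0.
4. **Conservative option.** Off by default. It reassigns only the six
   codes with two N and two S to (S, confidence 1). The default leaves
   them (U, 0); the conservative reading prefers to treat an even
   narcotic/specific split as specifically acting ("reactive
   unspecified") because under-calling potency is the costlier error in
   prioritization. Everywhere else the two modes are identical (asserted
   by enumeration).

In the default mode the score depends only on the multiset of letters,
never their order (property-tested); the conservative mode preserves this.

## Heavy-metal flagging

Compounds containing a heavy metal — defined as a metallic element with
density above 5 g/cm³ — are identified from SMILES and collapsed into
"dummy ion" groups keyed by the sorted set of heavy-metal elements present
(all cadmium salts → group "Cd"). The rationale is that the toxicity of
such compounds is often driven by the freely dissolved metal ion, and
metals are outside the structural domain of all four schemes; flagged
compounds therefore have their scheme labels cleared and classify as UUUU.

The element list ships as a versioned text file
(`data/heavy_metals_v1.txt`): the d-block metals from V/Cr through the
post-transition metals to Bi, plus the lanthanides and the actinides
through Cm. The density criterion, not a fixed published list, is the
definition, so the file is the single editable source of truth; it
includes vanadium (6.1 g/cm³) and excludes metalloids lighter than 5
(and Te, kept out as a non-metal). Whether an organometallic should be
distinguished from a dissociable salt is not decidable from SMILES alone;
the policy treats any occurrence of a listed element as a flag, and
mixture SMILES are covered component-wise because element extraction spans
dot-disconnected components.

Element extraction uses a purpose-built SMILES tokenizer (bracket atoms,
two-letter halogens, the organic subset and its aromatic lowercase forms;
bonds, ring closures, branches, charges and stereo markers are skipped).
Element identity is all that is needed here, so a full cheminformatics
parse would add dependencies without adding information; the tokenizer
raises with position and token on anything it cannot read, rather than
guessing.

## Toxicity summaries

Study records (chemical, species, trophic level, endpoint, duration,
effect concentration in mg/L) are joined to consensus assignments and
summarized as min/Q1/median/Q3/max of log10(effect).

* **Acute windows.** Fish: LC50, 24–96 h inclusive — the anchor
  definition. Invertebrates: LC50 or EC50, 24–96 h; algae: LC50 or EC50,
  48–96 h. The lower-trophic windows are package defaults chosen to match
  standard acute guideline designs (48-h daphnid immobilization, 72-h
  algal growth inhibition) and are configurable per run.
* **All entries, not per-chemical medians.** Distributions are computed
  over every study record, reflecting the data as they stand; a
  `per_chemical_median` option collapses each chemical to its median
  first, as a sensitivity check on data-rich chemicals dominating a group.
* **Quartile convention.** Linear interpolation between order statistics
  (the "type 7" convention, numpy's default), fixed and tested against a
  brute-force sort-based oracle.
* Effects must be strictly positive (rejected at ingest with the line
  number); groups with zero records are omitted rather than emitted as
  NaN rows. The "complete acute" subset is the chemicals with at least
  one qualifying record in each of the three trophic levels.

## Synthetic data generator

The generator produces chemical and study tables with known latent truth
so every stage — binning, consensus, metal collapsing, filtering,
summarization — can be tested end to end without external data.

* Each chemical draws a latent MOA: S with probability `p_specific`
  (default 0.3, near the classified S share in large curated aquatic
  datasets), else N.
* Each scheme independently reports U with a per-scheme `p_unknown`
  (defaults 0.21 / 0.22 / 0.08 / 0.44 for TEST / ASTER / OASIS / Verhaar,
  mirroring the very different out-of-domain rates of the real tools),
  otherwise a label drawn from the latent bin's label set with
  probability `agreement` (default 0.8) and from the opposite non-U bin
  otherwise. A correlation knob `rho` makes the four schemes share one
  agreement draw with that probability, to stress the confidence score
  under correlated errors; the default is independence.
* log10 effect concentrations are Normal with (MOA × trophic level)
  means: fish 1.0 (N) and 0.0 (S) log10 mg/L — medians of 10 and 1 mg/L;
  invertebrates 1.5 and −1.3, a separation of nearly three orders of
  magnitude; algae 0.5 (N) and 0.7 (S), overlapping with N slightly more
  toxic, because structure-based MOA schemes are built on fish data and
  do not transfer to algae. Common σ = 0.8 log10 units. Study counts per
  chemical × trophic level are Poisson (mean 2 by default), and a
  configurable fraction (default 0.1) of records falls outside the acute
  window (120-h duration) to exercise the filter.
* A configurable fraction of chemicals (default 0.035) are heavy-metal
  salts drawn from a 24-element pool; they carry no scheme labels.

What the generator does not emulate: real chemical-space structure
(SMILES come from a small template pool), inter-scheme error correlation
beyond the single shared-error knob, species-level sensitivity differences
within a trophic level, and censored or qualified effect values. Passing
recovery tests therefore demonstrates the pipeline's correctness and the
statistical identifiability of the group medians — not the real-world
accuracy of the four upstream schemes.

## Problem sizes and numerical choices

The end-to-end recovery test uses 2 000 chemicals with ~6 studies per
chemical per trophic level (≈2 000–12 000 studies per consensus-MOA ×
trophic group after filtering), at which the group-median standard error
(≈1.25·σ/√n ≈ 0.02 log10 units) makes the 0.1-log10 recovery tolerance
comfortable. The closed-form code distribution used to cross-check the
generator is exact (enumeration over 81 codes with per-scheme letter
probabilities), not simulated. All randomness flows through
`numpy.random.default_rng` seeds; identical inputs, configuration and
seeds give byte-identical output files (sorted rows, fixed column order).

## Known limitations

* The bin map covers the published label vocabulary of the four schemes;
  tool versions with new label spellings will fall back to U (with a
  warning) until the versioned CSV is extended.
* Consensus treats the four schemes as exchangeable votes. TEST and ASTER
  share lineage, so their agreement is weaker evidence than agreement
  between unrelated schemes; the confidence score does not model this.
* OASIS bins mix structural families with MOA (e.g. all esters → N), so
  a nitro-phenol uncoupler can lose a confidence point to a structural
  classification; the score reports the disagreement but cannot resolve
  it.
* Heavy-metal flagging is element-based: it does not model speciation,
  bioavailability, or the difference between a dissociable salt and a
  covalent organometallic.
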