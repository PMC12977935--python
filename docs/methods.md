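# Methods

This note documents the model and the numerical choices behind dmckit: what
each stage computes, which parameters matter, what the synthetic generator
does and does not emulate, and where the design was genuinely open.

## Problem setting

Given a multiple sequence alignment of nucleotide barcodes whose sequence
ids encode taxon membership, and a list of query taxa, the task is to find
for each query a diagnostic molecular combination (DMC): an ordered set of
(1-based alignment column, nucleotide state) pairs such that every
*background* sequence — everything not assigned to the query — differs from
the combination at a required minimum number of sites.  That minimum, the
**exclusivity** of the DMC, plays the role Bremer support plays for tree
nodes: the number of character-state changes that would have to appear in a
future background sequence before the diagnosis breaks.

Taxon membership is resolved by delimited-prefix matching on sequence ids
(`Diachlorus_curvipes_ACC01` belongs to `Diachlorus_curvipes`, and also
would to a genus-level query `Diachlorus`), with the longest matching query
winning and everything unmatched pooled as background.  The id convention
is a deliberate artifact decision: barcode libraries rarely ship a separate
metadata table, and label-in-id is the de-facto convention of curated FASTA
exports.  The separator set (`_`, `|`) is configurable.

## Search

**Eligibility.** A column can host a DMC site only if all non-missing query
states there are one unambiguous nucleotide.  `N` and `?` are always
missing; gaps are missing by default.  Under the gaps-as-state option a gap
is instead an ordinary fifth character — it then breaks eligibility when it
appears among the query states, and counts as a differing, informative
state in the background.  A gap itself is never emitted as a DMC state: a
printed diagnosis names nucleotides.

**Weights.** The default site weight is the fraction of informative
background sequences whose state differs from the query state.  This is
the "sequence-count" reading of a Jaccard-style uniqueness score; the
alternative "state-set" reading (one minus the Jaccard similarity of the
observed state sets) is implemented behind `weight_method="state_jaccard"`
for comparison.  Both map ineligible or uninformative columns to 0.
Ambiguity codes in the background count as differing unless they equal the
query state exactly — an `R` cannot demonstrate an `A`.

**Sampling.** Candidates are built by weighted random sampling without
replacement: sites join one at a time with probability proportional to
weight among the remaining positive-weight columns.  Sampling from the full
weight table with rejection of already-drawn sites is used internally; it
is distribution-identical to renormalizing after each draw and much
cheaper.  Growth stops at the first length `≥ max(MnLen, exclusive)` whose
exclusivity reaches the `exclusive` bar, and a candidate is rejected
outright at `max_len` (default 15) — a stopping rule the algorithm needs
but that is otherwise unconstrained; the cap prevents runaway growth on
recalcitrant taxa.  Exclusivity is maintained incrementally as a running
per-background difference count, so each added site costs one vector add.

**Missing data and exclusivity.** A missing background state never counts
as differing (a state we cannot observe cannot demonstrate a difference).
This conservative rule can underestimate exclusivity in gappy libraries;
the lenient alternative (count missing as differing) is available as
`missing_breaks=True` but is not the default.

**Refinement.** The refinement strength in [0, 1] controls how intensively
sub-combinations of each optimal candidate are tested for shorter
qualifying DMCs.  Zero disables refinement.  For candidates with `2^L ≤
4096` every proper subset of allowed size is enumerated outright (exact and
cheap); larger candidates get `max(1, round(strength × L))` randomized
backward-elimination passes, each shuffling site order and keeping any
single-site deletion that preserves qualification.  Refinement is applied
to the retained optimal candidates (the top `top_k`), not to every sampled
candidate — sub-combinations of dominated candidates are dominated.

**Ranking and consensus.** Candidates are ranked by exclusivity
(descending), then length (ascending), then lexicographic position order —
a total order that makes seeded runs fully deterministic.  The top `top_k`
(default 100) form the optimal pool.  The consensus starts from the sites
present in at least half of the pool (`majority_threshold = 0.5`) and
greedily adds next-most-frequent sites, lower column first on ties, until
the combination re-qualifies; if it cannot, the rank-1 candidate stands in
(recorded as a fallback).  The alternative DMC is the best-ranked candidate
distinct from the consensus.  Pool size and majority cut-off are free
parameters of the method; the defaults were fixed once and exposed in
`SearchParams`.

**Reproducibility.** One root seed; each taxon draws from an independent
stream keyed by a CRC-32 hash of its label, so adding or removing a query
leaves every other taxon's result bit-identical.  Both output DMCs are
re-verified against the alignment (length floor and exclusivity bar,
recomputed by the public scorer) before a row is written.

### Parameters

| name | default | meaning |
|---|---|---|
| `n_iter` | 50 000 | candidate DMCs sampled per taxon |
| `min_len` | 2 | minimum DMC length (sites); floored at `exclusive` |
| `exclusive` | 2 | minimum exclusivity (differing sites vs. any background sequence) |
| `ref_strength` | 0.33 | refinement intensity in [0, 1] |
| `max_len` | 15 | growth cap during sampling |
| `gaps_new` | off | treat `-` as a fifth state instead of missing |
| `top_k` | 100 | optimal candidates retained for consensus |
| `majority_threshold` | 0.5 | site frequency defining the consensus core |

Raising `exclusive` floors the DMC length automatically (a DMC with *k*
exclusive states cannot have fewer than *k* sites).  Longer minima
(`min_len` 6–10) buy precision and specificity at the cost of recall; the
recommended starting point for real libraries is `exclusive=4`,
`min_len=10`, relaxed or tightened per dataset.

## Verification

Three modes cover the ways test data arrive:

- **aligned** — test sequences share the training coordinate system; states
  are read off directly.
- **global** — each unaligned test sequence is pairwise-aligned to the
  degapped designated reference of the DMC's taxon (the first query
  sequence, recorded in the DMC table) and DMC columns are projected
  through the reference's gap pattern.  The aligner is Biopython's
  `PairwiseAligner` in semi-global mode (end gaps free on both sequences;
  match +2, mismatch −1, gap open −10, extend −0.5).  Free end gaps are
  essential because test barcodes range from short fragments to sequences
  several times the reference length; the stiff gap-open cost keeps the map
  rigid so that indels outside the DMC footprint cannot shift sites inside
  it.  Aligning to a single reference rather than a profile keeps the
  position map well-defined and cheap; the choice is a design decision, not
  forced.
- **sliding** — alignment-free: the DMC's sites, rigidly spaced as in the
  degapped reference, are scanned over every start position; the window
  with the fewest mismatches wins (leftmost on ties).  Indels *inside* the
  footprint are not absorbed — a known limitation of the rigid scan; such
  sequences fall through to the global mode.

A sequence matches a DMC when its non-missing mismatches are at most the
tolerance (0 or 1 in practice) *and* at least one site is informative: an
all-missing profile is uninformative, never a match.  IUPAC ambiguity codes
in test sequences count as matches when their expansion contains the DMC
state (configurable); `N`, `?` and gaps count as missing and are tallied
for the evaluation stage.  Missing sites are deliberately never mismatches:
a fragment that simply does not cover a site should be excluded, not
penalized.

Short DMCs make the sliding mode promiscuous: a 2-site motif will match
*somewhere* along almost any sequence, so window-based and positional modes
only agree when the footprint is specific enough (≈10 sites at tolerance
0).  This mirrors the general observation that short diagnoses lack
specificity; it is a property of alignment-free matching, not an
implementation artifact.

## Evaluation

Per DMC (species) *s*, each test sequence with any undetermined state at
*s*'s sites is excluded from *s*'s confusion matrix — exclusion is per-DMC,
so one sequence can be excluded for one species and counted for another
(the sites, and hence the evidence, are species-specific).  Among the rest:
conspecific matches are TP, conspecific non-matches FN, heterospecific
matches FP, heterospecific non-matches TN, and
`TP+FP+TN+FN+n_excluded = n` holds per taxon by construction.

Metrics follow the standard definitions, with one deliberate deviation:
**accuracy here is the balanced form `(recall + specificity)/2`**, not
`(TP+TN)/n`.  In barcode testing the heterospecific class dwarfs the
conspecific one, and raw accuracy saturates near 1 regardless of DMC
quality; the balanced form at least weights both error types, and F1 is the
headline metric precisely because it ignores the TN flood.  Undefined
metrics (no conspecific test sequences, or an empty precision denominator)
are serialized as `NA`, never coerced to 0, to avoid silently deflating
averages; taxa with no conspecific test sequences report specificity only.

## Synthetic libraries

The generator emulates the statistical structure the search relies on,
with exact ground truth:

1. a uniform-random ancestral sequence (default 313 bp, a typical
   mini-barcode length);
2. per-species consensus sequences via independent per-site substitutions
   at `background_divergence` (default 0.2);
3. per-species *planted* diagnostic sites — disjoint columns where the
   species is fixed for a state every other species avoids;
4. optionally (default on), chance diagnostics outside the planted columns
   are scrubbed: a consensus state carried by exactly one species is folded
   into the column majority, so the planted sites are provably the only
   fully exclusive columns and brute-force minimal DMC length is known by
   construction;
5. individuals per species with within-species substitutions
   (`intraspecific_rate`, default 0.005), undetermined cells
   (`missing_rate`), and column-coherent gap events shared by whole
   species (`gap_rate`);
6. unaligned test sets as degapped copies with seeded truncations,
   substitutions and indels, ids carrying the true label.

What this does **not** emulate: phylogenetic correlation among species
(substitutions are independent, not tree-shaped), codon structure,
alignment error, or real-world label noise.  Passing tests on these
libraries therefore demonstrate algorithmic correctness — weights,
exclusivity, search completeness, projection geometry, metric algebra —
not performance on empirical barcode libraries, where intraspecific
variability and barcode-gap width dominate outcomes.

## Verified properties and problem sizes

The acceptance suite checks, on libraries of up to 8 species × 5 sequences
× 40–80 columns (sizes chosen so exhaustive enumeration stays exact):
reported exclusivities equal an independent brute-force recount; wherever
enumeration proves a qualifying DMC of ≤ 4 sites exists, a 50 000-iteration
full-refinement search reports one of minimal length in ≥ 95% of 20 seeded
runs; a noise-free library yields F1 = specificity = 1.0 for every species
in all three verification modes; the metric identities hold to machine
precision on randomized counts; the exclusion ledger always balances;
clone test sets give identical decisions across modes and monotone match
sets in the tolerance; `exclusive = 4` floors reported lengths at 4; and
repeated seeded runs serialize byte-identically.
`scripts/acceptance.py --seed N --out results/acceptance.json` recomputes
all of these from scratch.

## Known limitations

- The sliding window is rigid; indels inside a footprint defeat it.
- Exclusivity under heavy missing data is conservative and can forgo
  otherwise valid diagnoses.
- The consensus can overshoot the minimal length when more than the
  necessary sites clear the majority threshold; the alternative DMC, being
  the top-ranked candidate, is typically the minimal-length one.
- Protein alphabets, multi-locus DMCs and tree-aware analyses are out of
  scope.
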