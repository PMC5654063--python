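# Methods

## The barbell model

The package operationalizes a structural model of efficient site-selective
A-to-I editing: an edited adenosine sits in a comparatively short duplex
(the *edited stem*), and editing efficiency depends on a second, longer and
highly base-paired duplex nearby — the *editing inducer element* (EIE) —
that is structurally separate from the edited stem. Separation is provided
by a large internal loop which the editing enzyme treats as a helix end.
The two stems joined by the loop form a "barbell". The package does not
predict editing percentages (they are experimental inputs throughout); it
detects and measures the structural elements the model is about and tests
their association with measured efficiency.

## Structure representation and folding

A structure is a 1-based pair table over a single sense-strand transcript:
a partial involution with no crossing pairs (no pseudoknots) and at least
three unpaired nucleotides inside every pair. Dot-bracket and CT files are
first-class inputs — real substrates are expected to arrive with structures
predicted by thermodynamic tools — and round-trip losslessly through the
internal representation.

The built-in folder is a Nussinov-style dynamic program maximizing
`pairs + stacking_bonus × stacked pairs` over canonical pairs (A-U, G-C,
and G-U when `allow_gu`, the default). It exists so that designed and toy
substrates can be folded deterministically with no external tool; it is not
a thermodynamic model and makes no free-energy claims. Defaults:
`min_hairpin = 3` (steric minimum), `stacking_bonus = 0.5` (prefers
contiguous helices among equal-pair-count optima), `allow_gu = true`
(wobble pairs occur in real editing substrates). The traceback is
deterministic: stacking is extended first, otherwise a position pairs with
its smallest admissible partner. Correctness is checked against exhaustive
enumeration of all valid pairings for short sequences, and the test suite
optionally cross-checks designed substrates against ViennaRNA's MFE folder
when its python bindings are installed.

## Segmentation and the helix-end rule

Maximal stacked runs (helices) are merged into stems across small
interruptions and split at large internal loops:

* an interruption with unpaired nucleotides on **both** strands merges when
  its total is ≤ `merge_tolerance` (default 4 nt) and terminates the stem
  when larger; totals of 5–6 nt (between the merge tolerance and the
  `helix_end_threshold` of 6) are conservatively treated as helix ends —
  the boundary policy is configurable in code but not split into a third
  behaviour;
* a **one-sided bulge never terminates a stem** by default
  (`merge_bulges = true`). This is deliberate: the helix-end rule that
  motivates the thresholds was established for internal loops, and the
  canonical 43-bp EIE contains an 8-nt bulge yet is one 102-nt stem
  (43×2 + 4 mismatches × 2 + 8 = 102). Setting `merge_bulges = false`
  applies the total-size rule to bulges as well.

Loop sizes always count unpaired nucleotides on both strands (a 20+15 loop
is 35 nt). A stem's `length_nt` likewise counts both strands including
merged interruptions — the only convention under which a 43-bp stem with
four mismatches and an 8-nt bulge measures 102 nt — and its paired fraction
is `2·bp / length_nt`.

## EIE detection and the screen

Given an edit site, the containing stem is identified (an edit site in a
loop or exterior region is an error: the structure cannot support the
model). Every other stem with ≥ `min_bp` pairs (default 20, the duplex
length sufficient for the deaminase domain to engage) separated from the
edit site by at least one loop-region nucleotide is a candidate, reported
with side (5′/3′ by its nearest nucleotide), `length_nt`, `bp_count`, and
`distance_nt` — the count of nucleotides strictly between the edit site and
the nearest EIE nucleotide along the transcript. Stability additionally
requires a paired fraction ≥ 0.6. Efficiency classes follow the published
convention: high ≥ 50%, low ≤ 45%, the 45–50% gap deliberately
unclassified. Conservation is assessed separately and never gates
detection, mirroring the separate "conserved" and "stable" columns of the
published survey.

The screen summary counts substrates per efficiency class and how many in
each class carry a conserved *and* stable adjacent stem. Count identities
(`n = n_high + n_low + n_unclassified`, with-stem ≤ class size) are
asserted in the constructor, not only in tests.

The packaged survey transcription (`data/conserved_editing_survey.tsv`)
carries per-substrate editing percentages, conserved/stable calls and EIE
metrics as *inputs*; the screen recomputes classes and counts from them.
Its 5′/3′ side marks are typographically unreliable in the source and are
flagged `ambiguous_side`; no computed quantity depends on them.

## Conservation

Orthologs are aligned globally (Needleman–Wunsch, linear gaps, defaults
+1/−1/−2, via Biopython's PairwiseAligner; optimality is verified against
exhaustive enumeration for short pairs). Each substituted column is
classified from the two residues, the partner residues and the paired
status of the reference position only: `loop_located` (unpaired),
`compensatory` (both partners changed, canonical pairing retained),
`wobble_preserving` (single change retaining a canonical pair),
`disruptive` (canonical pairing holds in exactly one species — a
definition symmetric under swapping the species), `indel` (gap columns;
counted against identity, and as disruptive only when a paired position is
deleted). The published survey gives no quantitative criterion for its
"conserved" calls, so the verdict is explicitly parameterized: conserved
iff identity ≥ `min_identity` (0.85) and disruptive calls ≤
`max_disruptive_fraction` (0.05) of paired columns; both thresholds are
reported in every verdict. Note the two criteria interact: heavy but purely
compensatory divergence can fail the identity criterion alone — "conserved"
here means *recognizably the same element*, not merely *same secondary
structure*.

## Editing quantification and construct operations

Percent editing is 100·G/(A+G) from peak heights (scale-invariant;
A+G = 0 is an error, not 0%). Replicates are summarized as mean and sample
(n−1) standard deviation; a single replicate reports sd 0 with n = 1. No
correction is applied for overlapping peaks at heterozygous-looking
positions — none is published.

Construct coordinates are relative (edit site = 0, downstream positive),
with inclusive deletion ranges: deleting +24..+44 and +276..+291 removes
21 + 16 = 37 nt. Deletions must not cover the edit site; relocations excise
an inclusive range and reinsert it with a requested number of nucleotides
between segment and edit site on a chosen side, preserving length and
residue content. Both return old→new coordinate maps; `remap_structure`
carries a pair table through a map, dropping pairs that lose an endpoint or
whose enclosed loop was removed.

## Synthetic data

`make_barbell_sequence` realizes a design exactly: the dot-bracket template
is assembled from the spec (stem pair counts with interruptions distributed
evenly, loop/hairpin/linker sizes, edit-site placement solved from the
requested distance and side), pairs are filled ~70% G-C / 20% A-U / 10%
G-U, and loops with A/C only (which cannot pair canonically with each
other). GC-bias guarantees the internal folder finds at least the designed
pair count — the designed structure is itself a valid candidate for the
maximizer. Infeasible geometries (hairpin < 3 nt, separating loop ≤ 6 nt,
an edit site that would land outside the stem or in an interruption) raise
errors rather than being silently adjusted.

Peak noise is multiplicative truncated Gaussian:
`A = H(1−f)(1+ε)`, `G = Hf(1+ε′)`, ε ~ N(0, σ²) clipped at −0.9 — a
documented stand-in, since no noise model for chromatogram peak heights is
published; σ defaults to 0.05. The mean of the ratio estimator then
converges to 100·f (checked at n = 200 within 3σ·100/√n).

Cohorts plant an EIE-by-efficiency contingency exactly (defaults: 11 high
of which 10 with an EIE, 12 low of which 1, matching the published survey);
editing percentages are drawn uniformly within each class range, with-EIE
substrates get a conserved ortholog (compensatory 3% per pair, loop 5% per
position), and about half of the no-EIE substrates carry a decoy flanking
stem of 5–11 bp, below the 20-bp threshold. Sensitivity 1 and specificity 1
on such cohorts are exact by construction — planted stems always exceed the
threshold and decoys never do — so these tests validate bookkeeping and
detection logic, not discrimination power on marginal real substrates.

What the generator does **not** emulate: thermodynamic stability (stems are
pair-count constructs), tertiary or pseudoknotted structure, sequence
context preferences of the enzymes (nearest-neighbour preferences around
the edited adenosine), hyper-editing of the EIE itself, alignment-ambiguous
ortholog divergence (indel-rich regions), or chromatogram artefacts beyond
peak-height noise. Passing round-trip and cohort tests therefore
demonstrates internal consistency of the analysis, not performance on
predicted structures of real transcripts, where stem boundaries are fuzzy
and thresholds matter.

## Numerical and design choices

* Coordinates 1-based inclusive everywhere; relative coordinates only in
  construct specs and peak tables.
* Folding scores are floats; traceback comparisons use a 1e-6 tolerance
  (scores are sums of 1 and the stacking bonus, so exact ties are the only
  subtlety).
* Alignment tie-breaking follows PairwiseAligner's deterministic first
  traceback; any optimal alignment satisfies the package's contracts.
* Problem sizes in tests and the acceptance script — 500 enumerable
  sequences of ≤ 12 nt for the folding oracle, 100 random barbell designs
  for the round trip, 200 replicates for the estimator, 20 ortholog pairs
  for conservation calls — were chosen as the smallest sizes at which the
  checked properties are stable, keeping the whole suite in seconds.
* The survey screen and the default synthetic cohort are deliberately the
  same shape (23 substrates, 11/12 split) so the two routes through the
  pipeline are directly comparable.

## Known limitations

* The internal folder maximizes pairs and will happily pair loop regions of
  arbitrary real sequences; segmentation of its output on non-designed
  sequences is meaningful only as a stress test (the property tests use it
  exactly that way).
* `distance_nt` is transcript distance, blind to spatial proximity through
  the loop.
* Multibranch junctions are recorded as loop segments but their topology is
  not analysed; coaxial stacking is ignored.
* A substrate whose EIE encloses the edited stem (rather than nesting
  inside it) is reported with the side of its nearest arm.
* Conservation verdicts depend on the supplied reference structure; a wrong
  structure converts compensatory calls into loop/disruptive ones.
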