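# Methods

This note documents the models, conventions and parameter choices behind
`biletree`, in the order a reader would meet them in the pipeline.

## Spectrum model and normalization

A spectrum is a scan identifier, a precursor m/z (charge and retention time
optional) and a peak list. On construction, zero-intensity peaks are dropped,
peaks with exactly equal m/z are merged by summing their intensities, and the
list is sorted ascending in m/z. Merging before sorting makes every window
lookup deterministic: a query can never see two candidate peaks at the same
coordinate.

Relative intensity is defined against the spectrum's own base peak (the most
intense peak = 100 %). All predicates operate on this within-spectrum scale,
so absolute instrument response cancels out; nothing in the pipeline compares
raw intensities across spectra except the TIC ordering used in clustering.

MGF is the native exchange format. The reader (pyteomics underneath) accepts
the dialect variation seen in GNPS/MZmine exports: `PEPMASS` with an optional
intensity second field, `CHARGE` with trailing sign, unknown headers. The
scan key is `SCANS` when present, else `TITLE`, else the 1-based block index
— the last two are package conventions, chosen because files without `SCANS`
exist in the wild and a stable key is required for label joining. A malformed
block fails loudly with its block index rather than being skipped. The writer
uses fixed 6-decimal formatting so that generated fixtures are
byte-reproducible; 6 decimals bounds round-trip error at 5·10⁻⁷ Th, an order
below the tightest window used anywhere. mzML input is supported for MS2
scans with a selected precursor only.

## Predicates and the query engine

Three predicate types cover the filtering vocabulary:

* **IonPresence(target_mz, tol_mz, min_rel_intensity)** — true when some peak
  within ±tol of the target reaches the floor. The floor defaults to 0 (any
  *detected* peak counts; an empty window always fails), because diagnostic
  ions are characteristically weak and per-node floors belong in the tree
  configuration.
* **IonAbsence(target_mz, tol_mz, max_rel_intensity)** — true when no
  in-window peak reaches the ceiling. Needed to express exclusive branches
  (e.g. "not a ketone").
* **IntensityRatio(numerator_mz, denominator_mz, comparator, threshold,
  tol_mz)** — compares max-in-window(num)/max-in-window(den) against a
  threshold with one of `<, <=, >, >=`.

Numerical conventions: window aggregation is the **maximum**, not the sum —
robust to shoulder peaks and independent of peak splitting; a ratio with an
empty denominator window is **false for every comparator** — a missing marker
ion must never positively route a spectrum into a bin (this is the
conservative side of the known false-negative trade-off of low-intensity
markers). The default window is ±0.01 Th: marker ions are quoted to three
decimals on Orbitrap-class data and no published tolerance exists, so the
window is set per predicate in the configs (±0.05 Th for the class ions,
which are quoted to two decimals).

A query is the conjunction of its predicates; evaluation short-circuits but
is order-independent (verified by an exhaustive-permutation test and a
property test).

## Filtering trees and classification semantics

A tree is a rooted hierarchy of named queries; leaves carry isomer bin
labels. Classification uses intersection semantics: a leaf is matched iff the
spectrum satisfies the query of every node on the root-to-leaf path. The
traversal therefore never descends past a failed node. Outcomes:

* exactly one matched leaf → unambiguous assignment (bin = leaf);
* several matched leaves → an ambiguity record listing all matched bins —
  ambiguity is surfaced, never tie-broken or dropped, because no principled
  priority order among sibling bins exists and downstream users need the
  flag;
* none, root satisfied → a dead-end record carrying the deepest satisfied
  node (the spectrum passed the class filter but lacks isomer markers);
* root failed → the spectrum is outside this tree's class and produces no
  record in `classify_dataset`.

There is deliberately no option to skip the sequential intersection — it is
the mechanism that suppresses false hits.

The shipped `dihydroxy` tree encodes the described branch structure: class
ions 321.26/339.27 → ketone split on 161.132 → 201.163/211.147 ratio split
(threshold 2.0) → leaf bins 3,12α / 7,12α (high-ratio side) and 3,7 / 3,6
(low-ratio side), each confirmed by one leaf-specific marker ion. The ratio
threshold and the leaf marker m/z values are placeholders calibrated on the
synthetic fixtures: the published numeric thresholds live in external
supplementary material, and users are expected to substitute their own
calibrations. The `monohydroxy` and `trihydroxy` configs are skeletal
templates (class ions shifted by ∓/± one hydroxyl, 15.995 Da; ketone split
only).

A known behaviour, reproduced intentionally: a monohydroxy core carrying one
ketone produces the same core fragment ions as two hydroxyls, so such
spectra enter the dihydroxy tree (2 Da lighter precursor notwithstanding)
and land in its ketone bin. The simulator's ketone profile models exactly
this.

## Theoretical core enumeration

`count_cores`/`enumerate_cores` enumerate hydroxylation patterns over the
eleven reported positions with up to three hydroxyls, two stereo options per
occupied site and two C5 ring-fusion configurations:
Σ C(11,k)·2ᵏ·2 = 44 + 440 + 2640 = 3124. Side-chain positions C22/C23 get
the same two stereo options as ring positions — the only uniform convention
consistent with that total. The count is treated as exact under these
assumptions; alternates (e.g. collapsing stereo) are reachable through
`EnumParams`. Chemical-feasibility filtering and conjugate combinatorics are
out of scope.

## Mass arithmetic

Element monoisotopic masses are a fixed five-element table (C 12 exactly,
H 1.0078250, N 14.0030740, O 15.9949146, S 31.9720707 Da), cross-checked
against pyteomics in the tests. Water is 18.0105646 Da.

The modification-ion convention: the protonated fragment m/z is computed as
formula mass + **hydrogen-atom** mass (1.0078250 Da), not the bare proton
(1.0072765 Da). For C6H7NO this gives 109.0528 + 1.0078 = 110.0606, matching
the printed value to four decimals, whereas the proton mass gives 110.0600;
the electron mass is the discrepancy, and both constants are exported so the
choice is explicit. The companion identity — modification ion − 2·water − H
= 73.0316 ≈ the observed +73.03 precursor shift — is asserted in the tests.

`annotate_delta` explains an observed precursor shift by searching a
user-supplied formula list (a built-in list ships with aminophenol and
common amine conjugates; no online database is queried) under six
interpretations: intact formula, amide condensation (−1 H₂O), condensation
plus in-source dehydration (−2 H₂O), each with/without hydrogen gain.
Matches within a ppm tolerance (default 10 ppm, Orbitrap-class accuracy) are
ranked by |error|. The tolerance is relative to the observed delta, so a
zero delta matches nothing.

## FDR evaluation

Each terminal bin is scored as a retrieval query on a labelled reference
set: retrieved = references whose classification includes the bin among its
matched bins (ambiguous spectra count for every matched bin — conservative,
penalising promiscuous queries); a `label_map` declares which true labels a
bin legitimately covers (a bin may span several stereoisomers). Then
FDR = FP/(TP+FP) and specificity = TN/(TN+FP); the specificity formula is a
package convention, stated here because no published formula exists. A bin
that retrieves nothing reports FDR as undefined (NaN + flag), never as 0.
Evaluation ignores the conjugate field entirely: queries built on taurine
amidates are expected to capture the same cores under other amines.

## Clustering

`cosine_score` matches peak pairs within the fragment tolerance greedily in
descending order of intensity product, one-to-one, ties broken by smaller
m/z difference; the score is the matched-product sum over the product of the
spectrum norms, using raw intensities (no square-root weighting — the
simplest defensible convention, isolated behind one function). The greedy
matcher agrees with matchms' independent implementation in the tests.

`cluster_spectra` is a deterministic single-pass procedure: spectra are
processed in descending TIC order; each joins the first existing cluster
whose representative is within the precursor tolerance (0.02 Th) and reaches
cosine ≥ 0.7 with ≥ 6 matched peaks (0.05 Th fragment tolerance), else seeds
a new cluster; the max-TIC member represents each cluster. The four
thresholds are the library-generation settings. This is a deterministic
greedy procedure, not a reimplementation of MS-Cluster; shifted-peak
(modified-cosine) matching is not implemented.

## Synthetic spectra: what they emulate and what they do not

`IsomerProfile` describes the ions a bin's spectra must carry: class ions
(fixed 50 % mean intensity), diagnostic ions with per-ion means, and ratio
constraints that pin a numerator's mean to ratio × denominator's mean — so
every ratio holds exactly in the noise-free limit and in expectation on the
log scale under noise. `NoiseModel` applies, in order: multiplicative
log-normal intensity scatter (mean-preserving, CV parameterised), Gaussian
m/z jitter, per-peak Bernoulli dropout with probability
p(I) = p_max·exp(−I/scale) (monotone non-increasing in intensity —
emulating the unreliable detection of weak diagnostic ions), and uniform
chemical-noise peaks. All randomness flows from one `numpy` Generator; MGF
output is byte-identical for identical inputs and seed.

Defaults: CV 0.25, 15 noise peaks in 150–500 Th at ≤5 % intensity, dropout
p_max 0.2 with scale 10 %, jitter SD 0.002 Th — plausible for
Orbitrap-quality MS2 of mid-abundance analytes, but **arbitrary**: the true
intensity distributions of bile acid diagnostic ions are unpublished. The
five shipped profiles mirror the dihydroxy tree's terminal bins (including
the mono-OH+ketone aliasing profile) with taurine-amidate-like precursors
(~500.30; the ketone profile 2.016 Da lower). Consequently, passing tests
demonstrate internal consistency — that the tree recovers exactly the
structure the generator plants, that FDR behaves correctly, that dropout
degrades recall monotonically — and say nothing about classification
accuracy on real instrument data, which depends on thresholds calibrated
against authentic standards.

## Problem sizes in tests and the acceptance script

The shipped verification runs use 5 profiles × 20 noise-free spectra for the
benchmark, 300–1000 noisy spectra for the path-subset property, 20 seeds ×
3 dropout levels (0 / 0.4 / 0.8) × 50 spectra for the dropout-sensitivity
trend, and an 8-duplicate set for the clustering check — sizes at which
every result is stable across seeds while the whole suite stays fast.

## Known limitations

* Shipped tree thresholds are fixture calibrations, not instrument
  calibrations; mono-/tri-hydroxy trees are templates.
* Greedy clustering depends on processing order (mitigated, not removed, by
  the deterministic TIC ordering); it is not MS-Cluster.
* No MassQL string parsing, neutral-loss or MS1 predicates, adducts beyond
  hydrogen gain/water loss, isotope patterns, or multiply charged species.
* Thresholds are not learned from data; with a large labelled corpus a
  trained classifier would be the natural extension.
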