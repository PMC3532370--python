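# Methods

## The classification model

ngloc predicts the subcellular localization of a protein from its
sequence alone, using a naive Bayes model over overlapping fixed-length
peptides (n-grams).  For a localization class L with training gram
counts c(g, L), gram total C(L) = Σ_g c(g, L), and prior P(L), a query
sequence S with gram bag {g₁ … g_B} is scored

    log score(L) = log P(L) + Σ_i log[ (c(g_i, L) + α) / (C(L) + α·V) ]

and the class posterior p(L|S) follows from a log-sum-exp normalization
over all classes.  Accumulation runs in a canonical (sorted) class order
so the posteriors are bit-identical under any permutation of the class
list.  The naive-Bayes independence assumption is knowingly wrong for
overlapping windows — adjacent grams share n−1 residues — but it is what
makes the model trainable from modest corpora and is the standard
trade-off for this model family.

Parameters:

* **n** — gram length.  Defaults: 7 for the animal profile, 6 for plant
  and both bacterial profiles.  Larger n gives sharper class signatures
  but sparser counts; the right value grows with training-set size.
* **α** (default 1.0) — Lidstone smoothing constant; the pseudo-count
  added to every gram.  Values ≤ 0 are rejected.
* **V** — smoothing vocabulary size, set to the number of distinct grams
  observed in the whole training corpus plus one.  The full combinatorial
  space 20ⁿ is deliberately not used: at n = 7 it is ≈ 1.28 × 10⁹ and the
  smoothing mass α·V would swamp every real count.  The +1 reserves mass
  for never-seen grams.
* **priors** — empirical (class sequence-count share) by default,
  switchable to uniform.

Windows containing a non-canonical residue (B, Z, X, U, O, J, gaps,
stops) are skipped rather than remapped — skipping never fabricates
counts — and the number of skipped windows is reported with every
prediction.

Multi-labelled training sequences contribute their full gram counts to
every class in their label set and increment each class's sequence count
for the prior; no fractional weighting is applied.

## Confidence scores and dual-location calls

Two scores on a 0–100 scale accompany every prediction, with p₁ ≥ p₂ the
two largest posteriors:

* **CS** = 100·p₁, the confidence of the top call;
* **MLCS** = 100·(p₁+p₂)·(p₂/p₁), the multi-localization confidence
  score.  It is 100 exactly when the top two classes split the mass
  evenly (p₁ = p₂ = 0.5), decays as the margin widens, and is 0 for a
  single-class model.  When MLCS ≥ 60.0 (configurable) the call is
  reported as the dual location "TOP1/TOP2" — e.g. a nucleocytoplasmic
  shuttling protein as "CYT/NUC".

Ranking ties are broken by class-code lexicographic order so output is
deterministic across platforms.

## Dataset preparation

Two filters run before training, mirroring standard corpus curation:
sequences shorter than 10 residues are dropped, and exact duplicate
sequences are dropped keeping the first occurrence in input order.
Similarity-threshold redundancy reduction (CD-HIT-style clustering) is
deliberately out of scope; "redundant" here means string-identical.
Annotation-evidence filtering and manual curation require metadata and a
curator and are likewise out of scope.

## Leave-one-out validation

`loo_validate` trains one model, then for each record subtracts its
counts and sequence-count contribution from its labelled classes
(priors follow automatically), scores it, and restores the counts — an
exact, order-stable inverse.  V is held fixed across the loop, so the
decrement trick is provably identical to retraining on the remaining
records with V frozen; the test suite checks bit-identical reports
against that retrain-per-fold oracle.

Per-class performance is one-vs-rest over top-1 calls of single-labelled
records: precision, sensitivity, specificity and the Matthews
correlation coefficient, with every 0/0 defined as 0 (this matters for
classes with a handful of members).  Multi-labelled records are excluded
from the one-vs-rest tallies (their confusion assignment would be
ambiguous) but count toward overall accuracy under the any-match rule: a
prediction is correct if any true class appears in the call, including
the second class of a dual call.  A switch
(`include_multilabel_per_class`) admits them to the per-class tallies
for sensitivity analyses.

### A known leave-one-out artifact at small corpus size

Removing the held-out record lowers its own class's gram total C(L),
which *raises* the smoothed likelihood α/(C(L)+α·V) of every unseen
query gram for exactly that class.  The size of this push is roughly
B̄/(C+αV) per query gram (B̄ = mean grams per sequence), while the
between-class spread of totals scales as √N·σ_len/(C+αV).  At desk scale
(tens of sequences per class) the two are comparable, so on a corpus
with no class signal at all, leave-one-out accuracy does not sit at the
naive chance level 1/K: it lands anywhere between chance (when one class
happens to have the distinctly smallest total and attracts everything)
and well above it (when totals are near-tied and the decrement tips each
held-out sequence toward its own class).  At realistic training scale
(thousands of sequences per class, queries sharing grams with homologs)
the artifact is negligible.  The acceptance suite states the
exchangeability expectation for the zero-signal corpus regardless, and
that check documents this limitation by failing honestly at small scale.

## Confidence-score calibration

`benchmark_cs` bins predictions into CS deciles [0,10), …, [90,100]
(last bin closed) and tabulates per-bin and cumulative ("CS ≥ edge")
data share and accuracy.  The renderer prints the published layout:
column labels run 0–90, a bin's per-decile statistics appear under its
upper-edge column, and the cumulative column c covers CS ≥ c−10, so the
cumulative entry at column 0 repeats the whole-dataset accuracy —
which equals the overall leave-one-out accuracy exactly, by
construction.  Empty bins render as "-".

## Synthetic corpora

The generator produces labelled corpora whose class structure is exactly
what an n-gram count model can represent: each class owns m signature
motifs (length ℓ, globally disjoint, drawn uniformly from the canonical
alphabet), and each sequence is an i.i.d.-background string with
Poisson(density) motif copies written in at uniform positions.  Later
insertions may clip earlier ones; the overlap is treated as noise.
Defaults, chosen once as a plausible desk-scale stand-in for real
compartment datasets: length range 60–120 residues, m = 3, ℓ = 8 (≥ the
largest default n, so signatures are detectable), density 3, uniform
background, single pseudo-random source seeded per corpus.

Multi-labelled sequences draw the motif count once and insert that many
copies of *each* label's motifs, so a dual-resident sequence carries
both signatures at equal strength — the balanced-evidence situation the
MLCS is designed to detect.  With independent per-label draws the
evidence is almost never balanced and dual calls almost never fire;
the shared draw is also the more faithful model of a protein genuinely
resident in two compartments.

What the generator does *not* emulate: homology structure, substitution
processes, compositional bias, length–compartment correlations, or
signal peptides with positional preference.  Passing tests on synthetic
corpora therefore demonstrate that the estimator recovers the structure
this generator plants — not that real-data accuracies are reproduced
(those depend on curated corpora not shipped here).

Ready-made fixtures: `tiny2` (the two-sequence hand corpus of the worked
example) and `animal_like` / `plant_like` / `gramneg_like`, which keep
the real class sets with class sizes scaled to ~1% while preserving
their rank order (secreted proteins dominate the animal set, chloroplast
the plant set).

## Problem sizes used by tests and the acceptance script

Scale was chosen so the full pipeline runs comfortably on a laptop:
tiny hand corpora for exact-arithmetic oracle checks (≤ 4 classes,
≤ 10 sequences, n ≤ 3, over a 4-letter alphabet to force gram
collisions); 30 sequences for the decrement-vs-retrain equivalence;
4 × 50 sequences for signature recovery; and a 2,000-sequence
graded-density mixture (densities 0, 0.5, 1, 2, 5) for calibration.

## Numerical choices

* All scoring in log space; normalization by log-sum-exp after
  subtracting the maximum log score; no overflow for realistic inputs.
* Posterior sums are asserted to 1 within 1e−9; oracle agreement is
  checked to 1e−10; decrement-vs-retrain posteriors match to 1e−12
  (in practice bit-identically, since both paths perform the same
  float operations on the same integer counts).
* A class with prior 0 (possible only for a profile class absent from
  the training data) scores −∞ and gets posterior 0.
* Model files store integer counts and `repr` floats, so
  save → load → save is byte-identical.

## Known limitations

* The leave-one-out small-sample artifact described above.
* Exact-duplicate redundancy filtering only; no similarity clustering.
* The n-gram model has no notion of position, so N-terminal targeting
  signals are weighted no differently from any other subsequence.
* CS is the raw top posterior scaled to 0–100, not a recalibrated
  probability; its decile reliability should be read from the
  calibration table, not taken as a calibrated frequency.
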