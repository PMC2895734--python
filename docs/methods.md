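# Methods

`deidgold` implements the full working cycle behind a de-identification
gold standard for clinical free text: multiple annotators mark Protected
Health Information (PHI) spans, their disagreements are resolved into
consensus reference sets, and a sequence labeler is trained and evaluated
on the result. Because real record corpora of this kind are confidential,
the package also ships a synthetic corpus generator and an annotator error
model, so every stage runs — and is tested — end to end on data it can
legally contain.

## Data model

Annotations are flat, labeled character spans (`0`-based, half-open)
attached to plain-text documents; nesting is not modeled. Tokenization is
deterministic: whitespace splitting followed by punctuation splitting,
except inside numeric runs (`3/5`, `08-123`), hyphen/colon-joined words
(`34-årig`, `S:t`) and listed abbreviations with trailing periods
(`Univ.`). The abbreviation list is data, not code. Because the refined
annotation guidelines forbid sub-tokenized spans, any span not aligned to
token boundaries is snapped *outward* to whole tokens at BIO-encoding and
exact-evaluation time.

The label catalog covers a generic working set (`Age`, `First_Name`,
`Last_Name`, `Date_Part`, `Full_Date`, `Location`, `Health_Care_Unit`,
`Phone_Number`, `E-mail_Address`, `Social_Security_Number`) plus the
pre-refinement refinements (clinician/patient/relative name subclasses,
`Age_Over_89`, the five location subclasses) and the two classes the
refined guidelines abandon (`Relation`, `Ethnicity`) — 24 labels. The
original study corpus used a larger historical inventory whose exact
membership is not published; this catalog is the package's own inventory,
sufficient for every rule and scheme the pipeline defines.

## Automatic consensus

All annotators' spans are pooled per document and clustered into
*instances*: maximal connected components under character overlap
(transitive closure; a minimum-overlap fraction is configurable, default
any overlap, which is the recall-maximizing choice appropriate for
de-identification). Each cluster resolves to one annotation:

* **span** — the longest member span, ties to the smallest start;
* **label** — one vote per annotator (its longest member's label).
  A strict plurality wins; otherwise, if all voted labels lie on one
  chain of the refinement order, the most specific label wins
  (`First_Name` vs `Clinician_First_Name` → `Clinician_First_Name`);
  otherwise a fixed, documented label order breaks the tie;
* single-annotator instances are kept by default (recall over precision).

One caveat worth knowing: for a transitively *chained* cluster (spans
A–B–C where A and C do not touch), the longest-member span cannot cover
the whole chain, so a chain's far members are represented by the cluster
but not necessarily overlapped by its resolved span. Chains are rare in
practice (they require three-way boundary disagreement) and the
longest-member rule is retained because it is the stated resolution rule;
the test suite verifies the builder against an independent brute-force
implementation of exactly these rules.

## Guideline-refined (manual-style) consensus

The refined guidelines are executable as an ordered rule engine, applied
here to the automatic consensus (the engine accepts any annotation set):

1. snap sub-tokenized spans outward to whole tokens;
2. merge `Street_Address`/`Town`/`Municipality`/`Country`/`Organization`
   into `Location`;
3. strip weekday tokens from date-span edges (delete a span that was
   only a weekday); the `Date_Part`/`Full_Date` split is preserved;
4. merge adjacent same-label `Location`/`Health_Care_Unit` spans whose
   gap is only whitespace/punctuation (largest-possible-span rule for
   addresses and unit names);
5. delete a `Health_Care_Unit` whose surface is entirely generic terms
   (`Geriatriken`); what is "generic" is a configurable lexicon, since
   the underlying guideline deliberately leaves it to judgment;
6. delete `Relation` and `Ethnicity` outright.

Boundary fixes run before label logic and deletions run last. Every
change is logged; `|output| = |input| − deletions` (absorbed merge
members count as deletions) holds by construction, and the engine is
idempotent. Rule sets round-trip through YAML.

## Agreement statistics

Pairwise inter-annotator agreement is the F-score of one annotator
evaluated against another with the same matcher used for system
evaluation; it is symmetric because P(a,b) = R(b,a) and the matcher is
order-independent. The headline number is the micro-average over
instances; per-class macro views come from the same reports. The
agreement table has one row per overlap cluster (the same clustering code
path as the consensus builder, so row count always equals cluster count)
and one column per class counting judgments. Chance-corrected
coefficients are deliberately out of scope: span annotation without a
fixed item universe has no natural chance baseline.

## Evaluation

Two modes: **exact** (same token-aligned span, same label) and
**partial** (same label, character overlap; minimum overlap fraction
configurable, default any). Matching is one-to-one per (document, label):
predictions in span order take the earliest-ending unmatched gold they
match. On non-overlapping interval sets this greedy rule attains the
maximum matching, which the tests confirm against Hopcroft–Karp on
random inputs; the one-to-one constraint stops a single long prediction
from absorbing several gold spans. Reports carry the
Annotated/Retrieved/Relevant triple per class with micro and macro
P/R/F; by construction partial ≥ exact throughout, and merging classes
(a non-deleting scheme applied to both sides) never decreases the
relevant count. The false-positive audit lists every exactly-unmatched
prediction with ±40 characters of context — the mechanism by which
system-found PHI the annotators missed gets re-adjudicated.

## Class schemes

A scheme is a total mapping from source labels to coarser labels or
deletion; schemes compose, and `apply` conserves count minus deletions.
The registered series runs from the identity through name, age and
location merges down to a single `PHI` class, mirroring a
progressive-coarsening experiment design; `manual_gs` is the refined
working set (generic first/last names, one `Age`, both date classes,
`Location`, `Health_Care_Unit`, `Phone_Number`, identifiers) with the
abandoned classes deleted. The intermediate memberships are defaults
built from the stated merging principles, not canonical reproductions,
and can be replaced by YAML mapping files.

## The CRF de-identifier

A first-order linear-chain CRF over IOB2 tags, written in-package:
sparse indicator features, L2-regularized conditional log-likelihood,
L-BFGS from zero initialization (hence deterministic), batched
log-domain forward–backward with per-step max shifts for stability, and
Viterbi decoding with orphan-`I` repair. Features per token: lowercased
identity, word shape (raw and run-squeezed), capitalization and digit
flags, prefix/suffix character n-grams up to order six, and the
identity/shape of neighbors in a ±1 window. Defaults: `l2 = 0.1`,
`max_iter = 80`, n-gram order 6. The engine sits behind a plain
train/predict contract so another linear-chain implementation can be
substituted without touching the pipeline.

Cross-validation splits by document — never by annotation — so no
textual context leaks between train and test; fold sizes differ by at
most one and the assignment is fixed by a seed.

## Synthetic corpus and annotator model

Documents are short pseudo-Swedish clinical sentences assembled from a
filler vocabulary, with PHI surfaces inserted between tokens and their
offsets recorded as gold. All lexicon entries (names, towns, care units)
are fictional. Defaults, chosen once as this package's study conditions:
100 documents of ~200 tokens; insertion probability 0.075 per sentence
position (~13 instances per document — a density at which every major
class has enough instances to learn from at desk scale);
`Health_Care_Unit` strictly the most frequent class (weight 0.26),
followed by dates and names, with identifiers rare; one generic-unit
distractor per document inserted *without* annotation; 30% of date
insertions preceded by a weekday token outside the gold span. The last
two exist specifically so the guideline rules have real work to do.

The annotator error model drops each gold span with `miss_rate`,
relabels survivors through a confusion row concentrated on genuinely
confusable classes (refinement siblings, the town/care-unit ambiguity,
the two date classes), jitters kept boundaries by one token with
probability `boundary_jitter`, and adds spurious spans (never
overlapping gold — that keeps oracle bookkeeping exact). The default
annotator trio uses miss rates 0.08/0.15/0.25, jitter 0.08, confusion
diagonal 0.95 and 0.15 spurious spans per document; the asymmetric miss
rates make annotator totals differ by roughly 15% of the gold count, and
the combination places the mean pairwise exact-match agreement in the
mid-0.6 band — the regime where consensus building is genuinely needed.
A miss-only model admits closed-form/Monte-Carlo expectations (kept
counts binomial, pairwise F ≈ (1−m) for equal rates), which the tests
exploit for parameter recovery.

What the generator does *not* emulate: real clinical syntax and
discourse, systematic (rather than independent) annotator bias,
document-level entity coreference, and surface ambiguity between
classes beyond the injected confusions. Passing tests therefore
demonstrate the correctness and internal consistency of the pipeline
under controlled noise — not performance on real records, where lexical
memorization would be far less effective.

## Numerical and degenerate-input conventions

Precision with zero retrieved (and recall with zero annotated) is
reported as 0 with an explicit undefined flag; agreement between two
empty sets is NaN with a warning. Equal-length consensus span ties break
to the smallest start; incomparable label ties to lexicographic order
unless a policy order is given. Empty text tokenizes to an empty list;
an empty rule set is the identity. All randomness flows from explicit
integer seeds through `numpy`'s `default_rng`.

## Problem sizes used in the shipped checks

The end-to-end rehearsal runs 200 documents (~40,000 tokens, ~2,600 gold
instances) through agreement, both consensus builds, and 4-fold plus
10-fold CRF cross-validation; oracle-equivalence and monotonicity checks
use exhaustive small configurations and 1,000-case random sweeps. These
sizes were chosen as the smallest at which class counts, agreement bands
and learning curves are stable.
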