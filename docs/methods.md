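# Methods

This note documents the model implemented by `snowball2`, the choices made
where the design was genuinely open, and what the synthetic studies do and
do not show.

## Phrase model

A sentence arrives pre-tokenized with labeled candidate entities; no
tokenization, POS tagging or chemical NER happens here. A *property
model* names a property and the slot kinds a complete record requires
(specifier, value, unit), optionally with nested sub-models; a complete
record over `n` models carries `3n + 1` entities (one shared compound).
Choosing one tagged entity per required slot, spans pairwise disjoint,
gives a relation; decomposing the sentence around the relation's
span-ordered entities gives a phrase whose non-entity token runs form the
elements:

- **prefix** — at most `max_prefix_len` tokens adjacent to the first
  entity (default 3),
- **middles** — one element per gap between consecutive entities (a
  `pooled_middles` flag concatenates all gaps into a single element for
  users who prefer the joint reading),
- **suffix** — at most `max_suffix_len` tokens after the last entity
  (default 3).

Element importance weights default to 0.1 (prefix), 0.8 shared equally
among the middles, 0.1 (suffix), normalized to sum one. Token comparison
is case-insensitive throughout the vector space; original surfaces are
preserved for output records. Phrases curated during supervised training
carry confidence 1.0 — they are ground truth.

Nested property models are treated as optional at candidate enumeration:
a nested model participates only when the sentence tags every one of its
required slots (and its parent participates). Without this, a schema with
a nested model could never parse a sentence that mentions only the root
property.

## Similarity

Each element becomes a within-element term-frequency vector scaled to
unit L2 norm; an empty element is the zero vector. The similarity of two
layout-compatible phrases is the weight-summed element-wise dot product,
which lies in [0, 1] by Cauchy–Schwarz. There is no inverse-document
component: plain term frequency is the simplest model that makes
identical phrases score exactly 1.

Two corresponding *empty* elements contribute 0, not 1: absence of
context is not treated as evidence of agreement. The practical
consequence is a similarity ceiling for phrases with empty gaps — a
sentence whose value and unit are adjacent (the common case) has one
empty middle of three, capping its self-similarity at
0.1 + 0.8·(2/3) + 0.1 ≈ 0.733 at default weights. Under the default
τ_sim_h = 0.75 such phrases therefore live in singleton clusters and are
matched through the soft band; phrases with all-non-empty elements (and
phrases built with `pooled_middles`) can still reach similarity 1 and the
hard band. We keep the convention because the alternative (counting
mutual absence as a perfect match) rewards short phrases and inflates
similarities between unrelated sentences that merely share a layout.

## Clustering

First level: phrases are grouped by a layout key recording, per property
model in schema preorder, the index positions of the model's entities in
the span-ordered entity list and their slot-kind order, plus the compound
position. Property *names* are deliberately absent, so a model trained on
one property parses any property with the same layout; this also allows
labeled phrases to be exported from one model and imported into another.

Second level, within a key group: single-pass assignment (SPCA). A phrase
joins an existing cluster when its similarity to the cluster's extraction
pattern reaches τ_sim_h, else it seeds a new cluster. By default a phrase
joins only the best-matching cluster (`single_best`), so each phrase
belongs to exactly one cluster; the redundant all-matches mode is kept as
an option. Patterns refresh after every insertion.

The extraction pattern is the modal element per slot across members
(case-insensitive), ties broken toward the most recently added member, so
the pattern always tracks the newest information. Its confidence is
`C(P) = Σ_i v_i · C_i`, where `C_i` is the confidence of the members
contributing element `i` — when several members share the chosen
sequence, the best-attested (maximum) confidence among them. This
contributor rule is the one reading consistent with both the
newest-information tie-break and the weighted-contributor arithmetic
(contributors 1.0/0.5/0.0 at weights 0.1/0.8/0.1 give 0.5).

Plain SPCA depends on presentation order (three phrases with pairwise
similarities 0.91/0.89/0.80 at τ_sim_h = 0.85 form one cluster in order
A,B,C but two in order A,C,B). The order-invariant entry point therefore
processes a *similarity triangle*: the strict upper triangle of the
pairwise similarity matrix, consumed minimum-first — take the least
similar remaining pair, push both phrases through SPCA, delete their row
and column, repeat until the triangle is cleared (a final unpaired phrase
is pushed through alone). Splitting the least similar pairs first
maximizes the cluster count and fixes the partition. Two determinism
choices: inputs are first sorted by a content-based canonical key (so
duplicate similarity values cannot reintroduce order dependence), and
minimum ties resolve to the lowest index pair after that sort.

Clustering runs after training, not during it, and every cluster
recomputes its pattern from its current members on insertion or removal —
so re-clustering under new thresholds is cheap and exactly reversible.

## Training annotation

Candidate relations are the cross product of per-slot entity pools with
overlap violations discarded, in lexicographic span order. Annotation is
relationship-based (confirm candidates from the list) until the candidate
count exceeds a threshold — default 100, user-adjustable; the spec of the
switch is a count, not a property of the sentence — after which the
session switches to entity-based mode: relations are assembled slot by
slot in schema order (compound first, then each model's required slots),
one single-choice question per slot, cycling until all relations are
built. Each compound may carry at most one relation per sentence.

## Extraction

For a new sentence, candidates are enumerated exactly as in training and
scored against the clusters of their layout key:

- **hard band** (max similarity ≥ τ_sim_h): exclusive — only the single
  best cluster is considered, and the candidate's confidence is computed
  against that cluster's internal member phrases;
- **soft band** (otherwise, max similarity ≥ τ_sim_l): inclusive — all
  clusters at or above τ_sim_l contribute their patterns;
- below τ_sim_l: confidence 0, rejected.

Confidence combines the band's terms `t_i = C_i · sim_i` as
`1 − [Π (1 − t_i)]^(1/n)`. The `1/n` geometric normalization keeps scores
comparable when the cluster count changes with τ_sim_h. Two variants are
preserved: `normalization="none"` drops the exponent (the earlier
Snowball product form; the `emulation_10` flag pins this together with
τ_c = 1 so no new clusters are seeded), and `"single_term"` keeps only
the best term. The learning rate of the predecessor algorithm is fixed at
1: patterns and confidences update immediately on insertion, with no
delayed-update machinery.

Per compound, the highest-confidence accepted candidate wins (ties to the
earliest spans). A hard-band winner is absorbed into its cluster. A
soft-band winner is emitted, and additionally seeds a new single-member
cluster when its confidence reaches τ_c — the bootstrap. Soft-band
winners below τ_c are emitted without learning; the six-region
accept/reject picture distinguishes confidence above/below τ_c in the
other bands too, but no behavioral difference is attached there, so τ_c
gates only cluster seeding. Records below `min_record_confidence` are
dropped from the output (0 disables the filter).

Defaults: τ_sim_h = 0.75, τ_sim_l = 0.6 (sensible band 0.4–0.8),
τ_c = 0.8, geometric normalization.

## Synthetic corpus

The generator emulates the statistical structure of sentences reporting a
scalar material property: six default skeletons in varying entity orders
(plus a held-out paraphrase set for generalization studies), a closed
pool of 16 compound names, four multi-token specifier variants, two
units, band-gap-like values drawn uniformly from 0.1–10 at one decimal,
nested-model sentences adding a temperature-like specifier/value/unit
triple (integer 4–1000 K), two-compound sentences sharing a specifier,
and untagged numeric distractor insertions. Rates for distractors,
multi-relation and nested sentences default to 0 and are switched on per
study. Generation is bit-reproducible per seed; the corpus splits 5:1
into train and test by interleaving.

What passing tests on this corpus do **not** show: the generator's
entities are correct by construction (there is no NER noise analogue),
vocabulary is closed, and phrasing variation is template-bounded, so
absolute precision/recall values here say nothing about performance on
real literature sentences — they validate the mechanics (exact recovery
when test phrasings are known, threshold monotonicity, order invariance,
lossless serialization), not real-world accuracy.

## Evaluation protocol

A record is a true positive only when every slot — sentence id, compound,
property name, specifier, value, unit — matches a gold record exactly;
partial matches count as a false positive plus a false negative.
Precision, recall and F (harmonic mean) use the convention 0/0 = 0.
Nested relations flatten to one record per property model, each scored
separately.

The study harnesses train one model per τ_sim_h and score frozen copies
per τ_sim_l (sweeps reflect thresholds, not accumulated bootstrapping);
the training-size study resamples training subsets at fixed sizes and
reports mean/std over repeats. Default study sizes in the shipped tests
and acceptance script (corpora of 180–300 sentences, 6×8 threshold grids,
50 permutations) were chosen to exercise every code path at desk scale.

## Numerical notes

- Similarity accumulates in double precision; the dense-basis oracle
  agreement is tested to 1e-12 over 1000 random pairs.
- Element weights must sum to 1 within 1e-9; serialization round-trips
  floats via their decimal repr, so save/load reproduces partitions and
  pattern confidences exactly.
- Degenerate inputs: an empty phrase list clusters to nothing; a single
  phrase forms one cluster; a sentence without entities extracts nothing;
  a required slot with no tagged entity yields zero candidates (not an
  error).

## Known limitations

- Interval or range values, unit conversion and cross-sentence
  coreference are out of scope; one record per compound per sentence.
- The empty-element convention caps similarity for phrases with adjacent
  entities (see above); users who want identical sentences to score 1
  regardless can enable `pooled_middles`.
- `predict` mutates the fitted model by design (bootstrapping); this
  departs from sklearn convention and is documented on the estimator.
  Pass `learn=False` for frozen-model scoring.
- Confidence scores are heuristic match qualities, not calibrated
  probabilities.
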