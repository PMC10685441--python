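# snowball2

Semisupervised, bootstrapping extraction of chemical property records from
pre-tagged sentences in the scientific literature.

Materials-science text mining pipelines tag sentences with candidate
entities — compound names, property specifiers, numeric values, units — and
then need a sentence parser that decides which entities belong together in
a record such as `{TiO2, band gap, 3.2, eV}`, with a confidence estimate
attached to every record. `snowball2` implements a Snowball-style parser
for that step: it is trained once from a modest set of annotated sentences,
generalizes across properties (a model trained on one property can parse
another with the same sentence layout), and keeps learning from its own
high-confidence extractions.

## Method

A labeled sentence is decomposed into a **phrase**: its entities in span
order, interleaved with token *elements* — a prefix, one middle per gap
between entities, and a suffix — each carrying an importance weight
`v_i` (defaults 0.1 / 0.8 split over middles / 0.1). Elements become
term-frequency vectors of unit L2 norm, and two layout-compatible phrases
`p, q` are compared with

    sim(p, q) = Σ_i v_i · (p_i · q_i)   ∈ [0, 1].

Training phrases are clustered in two levels. First, phrases are keyed by
the count and positional ordering of their entities per property model
(never by property name — that is what makes the model generic). Second,
within a key group a single-pass assignment attaches each phrase to the
cluster whose synthesized **extraction pattern** it matches at or above
the high threshold `τ_sim_h`, seeding a new cluster otherwise; pairs are
processed minimum-similarity-first off a precomputed *similarity triangle*,
which makes the partition independent of training order. A cluster's
pattern is built from the modal element across members (ties favor the
newest member) and carries the confidence `C(P) = Σ_i v_i · C_i`.

At extraction time, every candidate relation of a new sentence is scored
against the patterns of its layout group. Matches at or above `τ_sim_h`
form an exclusive *hard* band (only the best cluster counts, and the
candidate is compared with that cluster's internal phrases); otherwise
all clusters at or above the lower threshold `τ_sim_l` form an inclusive
*soft* band. The record confidence is

    C(r_c) = 1 − [ Π_i (1 − C_i · sim_i) ]^(1/n),

the product running over the band's n terms; dropping the `1/n`
normalization (and pinning `τ_c = 1`) reproduces the earlier Snowball
behavior, available as an emulation mode. Per compound the best accepted
candidate wins. Hard-band phrases are absorbed into their cluster
immediately; soft-band phrases whose confidence reaches `τ_c` seed new
clusters — the bootstrap by which coverage of novel phrasings grows.

No corpus is bundled: a seeded synthetic-corpus generator
(`snowball2.synth`) produces annotated property sentences with known gold
relations, nested property models, two-compound sentences and untagged
numeric distractors.

## Worked example

```python
import snowball2 as sb

corpus = sb.generate(sb.SynthConfig(n_sentences=300, seed=42,
                                    nested_rate=0.2, distractor_rate=0.2))
train, test = sb.train_test_split(corpus, ratio=5)

est = sb.SnowballExtractor(schema=sb.default_schema(), tau_h=0.75, tau_l=0.4)
est.fit(train)
print(f"trained on {est.n_phrases_} phrases in {est.n_clusters_} clusters")

records = [r for recs in est.predict(test, learn=False) for r in recs]
print(f"extracted {len(records)} records from {len(test)} sentences")
r = records[0]
print(f"{r.sentence_id}: {r.compound} {r.property_name} = {r.value} {r.unit} "
      f"(specifier '{r.specifier}', confidence {r.confidence:.3f})")

result = est.evaluate(test, learn=False)
print(f"precision {result.precision:.3f}  recall {result.recall:.3f}  "
      f"F {result.f_score:.3f}")
```

prints

```
trained on 250 phrases in 250 clusters
extracted 60 records from 50 sentences
s00005: Si band_gap = 3.3 meV (specifier 'optical gap', confidence 0.716)
precision 1.000  recall 1.000  F 1.000
```

The test split repeats the training skeletons with fresh compounds and
values, so every record is recovered exactly; the per-record confidence
reflects how closely each sentence matches the learned patterns. It stays
below 1 here because the adjacent value–unit pair leaves an empty middle
element, which counts as a non-match under the zero-vector convention and
caps the attainable similarity (0.733 at the default weights), and because
weaker matches from other templates enter the soft-band average. Records
count one row
per property model, so nested sentences contribute both a `band_gap` and a
`temperature` row. `SnowballExtractor` follows the scikit-learn estimator
protocol (`get_params`/`set_params`/`clone`); note that `predict` lets the
model bootstrap by default — pass `learn=False` to score against a frozen
model.

The same workflow is available from a shell:

```sh
snowball synth -n 300 --seed 42 -o corpus.jsonl --schema-out schema.json
snowball train -i corpus.jsonl -s schema.json -o model.json --tau-l 0.4
snowball extract -m model.json -i corpus.jsonl -o records.csv --no-learn
snowball eval -m model.json -i corpus.jsonl --no-learn
```

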