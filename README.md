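# dtmtox

Dynamic topic models for time-series toxicogenomics.

Repeated-dose toxicogenomics studies profile many compounds against matched
controls at several ordered time points.  `dtmtox` treats each
compound–time condition as a *document* whose *words* are its
differentially expressed genes split by direction (`Acot1_up`,
`Stac3_down`), with word counts `round(100 × fold change)`, and fits a
**dynamic topic model (DTM)**: topics are probability distributions over
gene-words that evolve across time slices through a Gaussian random walk on
their natural parameters,

    β_{t,k} | β_{t−1,k} ~ N(β_{t−1,k}, σ² I),      π_{t,k} = softmax(β_{t,k}),
    θ_d ~ Dirichlet(α),   w_n | z_n = k ~ Mult(π_{t(d),k}),

fitted by variational EM with a Kalman-filter/smoother treatment of the
topic chains.  The fit yields two objects: **P(T|D)**, the topic signature
of every compound–time condition (used to group compounds by shared mode of
action), and **P(W|T)_t**, per-time-point gene rankings for every topic
(used to follow a process's gene content over time and to run Fisher's-exact
gene-set enrichment of the top-ranked genes).

The package is for computational toxicologists and anyone clustering
time-resolved differential-expression profiles: it contains the corpus
encoder, the model (a scikit-learn-style estimator), interpretation and
enrichment utilities, fully ground-truthed synthetic-data generators, and a
CLI chaining the stages.  See `docs/methods.md` for the model and the
numerical choices.

## Worked example

Simulate a study with four planted mode-of-action groups (24 compounds × 4
time points × 2 doses × 3 replicates), encode it, fit a four-topic model
and assign conditions to topics:

```python
from dtmtox import (CorpusBuilder, DynamicTopicModel, StudySimSpec,
                    generate_expression_study, rank_genes, top_n)
from dtmtox.interpret import assign_topics

study, truth = generate_expression_study(StudySimSpec.recovery_default())
corpus = CorpusBuilder(deg_threshold=1.0).build(study)
model = DynamicTopicModel(n_topics=4, alpha=0.01, em_rel_tol=1e-6,
                          em_max_iter=100, random_state=0).fit(corpus)
print(f"corpus: {len(corpus)} documents over {corpus.n_slices} slices, "
      f"{corpus.n_words} words, {corpus.total_tokens()} tokens")
print(f"converged={model.converged_} after {model.n_iter_} iterations")
assignments = assign_topics(model)
print(assignments.head(3).to_string(index=False))
print(top_n(rank_genes(model, int(assignments.loc[0, 'topic']), 0), 5))
```

prints

```
corpus: 96 documents over 4 slices, 4000 words, 1468526 tokens
converged=True after 51 iterations
doc_id  topic  probability   margin
c000@4      0     0.999998 0.999998
c001@4      0     0.999998 0.999998
c002@4      0     0.999998 0.999998
['g00186_up', 'g01728_up', 'g00751_up', 'g00898_up', 'g00498_up']
```

Compounds `c000`–`c005` share a planted module and all land on topic 0 with
probability ≈ 1: the argmax assignment recovers the planted groups exactly
(adjusted Rand index 1.0 on this benchmark), and the topic's top-ranked
words are the planted module's genes, up-regulated.  The same flow works
from the shell:

```sh
dtmtox simulate-study --compounds 24 --seed 11 --out study/
dtmtox build-corpus --matrix study/expression.tsv --meta study/samples.tsv --out corpus/
dtmtox fit --corpus corpus/ --topics 4 --seed 0 --out model/
dtmtox interpret --model model/ --top-n 300 --out results/
dtmtox enrich --model model/ --gmt pathways.gmt --out results/
```

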