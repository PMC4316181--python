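# miscore

Merging and confidence scoring of molecular-interaction evidences in the
PSI-MI MITAB format.

## The problem

The same physical interaction between two molecules is typically reported
many times: by different experiments, in different publications, and —
because interaction databases import from one another — by different
databases under different identifiers. Anyone integrating interaction data
therefore needs two operations:

* **merge** — recognize that a group of evidences describes the same
  molecule pair and collapse them into one non-redundant binary
  interaction, while keeping every piece of the original annotation;
* **score** — turn the merged annotation into a single normalized
  confidence value, so interactions supported by many independent,
  specific, trustworthy observations rank above those seen once with a
  vague method.

The package implements both over standard PSI-MI inputs: MITAB 2.5/2.6/2.7
files and the MI controlled vocabulary (OBO). It is aimed at
bioinformaticians building non-redundant interactomes from multiple
databases and at bench scientists who want to rank the evidence behind
their pairs of interest.

## The algorithms

**Merging** matches interactor molecules through a configurable set of
accepted identifier namespaces (UniProtKB, RefSeq, ROGID, ChEBI by
default), drawn from all three MITAB identifier fields (unique identifier,
alternative identifiers, aliases). Interactor occurrences connected
through shared identifiers form clusters (transitive closure via
union-find); evidences collapse into one merged interaction per canonical
unordered cluster pair. The merged record keeps the distinct publication
set and the per-term occurrence counts of detection methods and
interaction types.

**Scoring** combines three sub-scores, each in [0, 1]:

```
S_MI = (Kp·Sp + Km·Sm + Kt·St) / (Kp + Km + Kt)

Sp = log_(b+1)(n + 1)          n  = distinct publications, b = 7 by default
Sm = log_(B+1)(a + 1)          a  = Σ scv_i · n_i  over reported method terms
                               B  = a + Σ max(Gscv)  over the score groups
St = same as Sm over the interaction-type score table
```

`scv` is the normalized score of a controlled-vocabulary term; a term
without a direct assignment inherits the score of its nearest scored
ancestor in the MI ontology (so *two hybrid* scores as *protein
complementation assay*, 0.66, and *coimmunoprecipitation* as
*biochemical*, 1.00). `Gscv` groups related assignments; the sum of group
maxima normalizes the sub-score so it saturates as annotation diversity
grows. All weights, `b`, and the scv tables are configurable; the defaults
are the HUPO PSI-MI consensus values.

The composite measures *how well annotated* an interaction is, not the
quality of any single experiment.

## Worked example

`python examples/score_worked_example.py` scores the evidence for the
interaction between AKT-interacting protein (AKTIP) and hook
microtubule-tethering protein 2 (HOOK2) as reported by individual
databases and by their union:

```
configuration                ev pub     Sp     Sm     St   S_MI
virhostnet                    1   1  0.333  0.321  0.449   0.37
spike                         1   1  0.333  0.421  0.562   0.44
apid                          1   1  0.333  0.321  0.281   0.31
spike+intact+virhostnet       4   2  0.528  0.701  0.818   0.68
```

One two-hybrid observation of a physical association scores 0.37; one
coimmunoprecipitation of a direct interaction scores higher (0.44) because
both its method and its type carry higher scv values. Merging four
evidences from three databases — two distinct publications, four distinct
methods, a direct-interaction annotation — lifts the composite to 0.68,
in the range databases treat as high confidence (IntAct, for instance,
regards > 0.6 as high and 0.45–0.6 as medium confidence).

The same operations are available from a shell:

```
miscore merge  input1.mitab input2.mitab --out merged     # + redundancy %
miscore score  merged.mitab --out scored                  # miscore:<value>
miscore dist   scored.scores.tsv                          # decile histogram
miscore eval   labeled.tsv                                # MCC cutoff, AUC
miscore fixture --out fx --seed 7 --n 20                  # synthetic data
```

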