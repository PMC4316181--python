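# Methods

## Evidence model

One MITAB row is one *evidence*: a pair of interactors, one interaction
detection method, one interaction type, a source database, and zero or
more publications. Every evidence contributes exactly one method term and
one type term to its merged interaction; an empty or label-only column
maps to the `unknown` sentinel (this keeps the occurrence counts `n_i`
well defined — their sums always equal the evidence count). Predicted
rows may legitimately carry no publication and then contribute nothing to
the publication count.

The parser is lossless: the original columns of each row are retained, so
read → write round-trips are byte-identical, including for the wider
2.6/2.7 layouts (writing a wide record to a 2.5 target drops the extra
columns with a warning; the reverse pads with `-`). Dialects are told
apart by column count alone (15/36/42); any other count is an error, not
a guess. Database namespace tokens are lowercased on parse because
namespace matching must be case-insensitive; accessions keep their case
(ROGID values are case-sensitive). Quoted segments may contain `:`, `|`
and parentheses, as required by the CV-term grammar.

## Merging

Matching namespaces default to UniProtKB, RefSeq, ROGID (with
`irefindex` treated as a spelling of the same namespace) and ChEBI;
the set is configurable. Keys are drawn from all three identifier
fields. Gene-symbol aliases are not matched by default — symbols collide
across species and paralogs, and a false join is worse than a missed one.
RefSeq version suffixes (`.2`) are stripped since versions denote the
same molecule; UniProt isoform suffixes (`P12345-1`) are kept distinct by
default because isoforms can have different interaction partners
(`collapse_isoforms=True` collapses them).

Clustering is union-find over interactor occurrences sharing a key, i.e.
the transitive closure of pairwise identifier overlap; occurrences with
no accepted identifier remain singletons (this is why databases that
publish only Entrez gene ids cannot merge with UniProt-keyed data).
Merged interactions are keyed by the unordered cluster pair;
self-interactions are legal, and a row whose second interactor is absent
(intra-molecular) is treated as a self-pair and flagged. Publications are
counted as distinct identifiers across the whole cluster. Row order never
affects the result: cluster ids are assigned in first-occurrence order
but the grouping, counts and publication sets are order-invariant, which
the suite checks by shuffling.

## Score resolution in the ontology

"Nearest scored ancestor" is implemented as breadth-first ascent through
`is_a` parents: the first depth at which any assigned term appears wins.
Where several scored ancestors sit at the same minimal depth (a diamond),
the maximum scv is taken — the ontology does not dictate a choice here,
and preferring the stronger reading is deterministic and errs on the side
of the more informative annotation. The `unknown` score (0.05 by default)
applies to the sentinel, to terms missing from the ontology and to terms
whose ancestry reaches the root unscored; it participates in `a` but
belongs to no group, so it never inflates the group-maxima sum. Rows that
carry only a term label are resolved through a name → accession lookup
built from the loaded ontology.

The bundled ontology is a slim of the public MI vocabulary: the 11 terms
with default scv assignments plus the ancestry paths of the terms
appearing in the worked example and test fixtures (26 terms in all). It
exists so resolution and the default tables work offline; any full OBO
file can be substituted at run time.

## Scoring parameters

* `Kp, Km, Kt` — sub-score weights, each in [0, 1], default 1. Equal
  weights make the composite the plain mean of the three sub-scores and
  reproduce the published worked-example values; they are the package
  default.
* `b_pub` — distinct-publication count at which `Sp` saturates,
  default 7. The raw logarithm exceeds 1 beyond saturation, so `Sp` is
  explicitly clamped to 1: the score contract is [0, 1].
* scv tables — per-accession overrides overlay the consensus defaults;
  an overridden grouped term keeps its group (moving the group maximum
  with it), a newly scored term forms a singleton group.

`n_i` in the method/type sub-scores counts evidence occurrences of a
term, not distinct publications — the four-evidence worked-example row
(physical association reported three times) only reproduces under this
reading. Because `B − a` is the constant group-maxima sum,
`log_(a+C+1)(a+1)` is strictly increasing in `a`, giving the monotonicity
the property tests assert: more occurrences, more publications or
higher-scv terms never lower a sub-score. Scores are carried at full
floating precision; only display and serialization round to two decimals.

Two rows of the published worked example are deliberately not asserted
anywhere: one prints a value the stated formulas cannot produce under any
reading of its counts (a likely typo), and the meta-database rows do not
print per-term counts at all, so they are under-determined. The four
asserted configurations are exactly those whose printed inputs determine
the output.

## Evaluation machinery

A score equal to the cutoff predicts positive (this makes "0.45–0.6 as
medium confidence" inclusive at its lower edge). Candidate cutoffs for
the MCC scan are the midpoints of adjacent distinct scores plus {0, 1} —
every achievable confusion table is visited exactly once, so the optimum
is exact, and ties resolve to the smallest cutoff. MCC with a zero factor
in its denominator is reported as 0; undefined precision (no predicted
positives) is reported as 0 with a flag. ROC points are the standard
descending-score staircase (tied scores move in one step), AUC by
trapezoid. Score histograms use the left-open bins (0, 0.1], …, (0.9, 1];
an exact zero fits no left-open bin and is counted in a separate
underflow bucket so totals are conserved.

## Synthetic data

The generator emulates the redundancy structure that merging exists to
remove: `n` true interactions between synthetic proteins, each reported
once by a primary database and re-reported by each further database with
probability `overlap_fraction`; a re-report uses a RefSeq-style primary
identifier whose alias field carries the UniProt-style one with
probability `alias_probability`, forcing merges through the alias path.
Defaults (20 interactions, 3 databases, overlap 0.5, alias 0.3, one fresh
publication per evidence) describe a small multi-database integration
with moderate redundancy; method and type terms are drawn from weighted
pools of commonly curated assays. Accessions live in reserved prefixes
(`UPTEST`/`RSTEST`) so collisions with real identifiers are impossible,
and RefSeq ids carry a version suffix on purpose to exercise stripping.
Output is deterministic per seed.

What the generator does **not** emulate: realistic interactome topology
(degree distributions are irrelevant to merge/score correctness), dirty
provider quirks beyond label-only CV columns, or conflicting identifier
mappings. Passing tests therefore demonstrate algorithmic correctness of
merging and scoring, not robustness to every real-world file.

Test problem sizes — 200 random instances of up to 50 evidences checked
against a naive transitive-closure oracle, 1000 randomized merged
interactions for score bounds and monotonicity, exhaustive cutoff scans
on sets of up to 12 — were chosen as the smallest scales at which the
properties quantify over all structural corners (alias bridges,
unmatchable namespaces, empty counts, ties).

## Known limitations

* Only `is_a` ontology links are traversed; other relationship types are
  ignored, and OWL is not supported.
* Spoke-expanded complex rows merge exactly like true binary rows; the
  expansion column is carried through but not interpreted.
* Live PSICQUIC federation, web services and third-party export rule
  sets are out of scope; input is files (or in-memory records) only.
* The large-scale redundancy figures reported for public databases
  depend on their snapshots and are not reproduced here; only the
  reporting arithmetic is.
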