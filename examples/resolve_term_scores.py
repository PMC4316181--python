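"""Resolve controlled-vocabulary terms to their scv scores.

Detection-method and interaction-type terms are scored through a small
consensus table; a term without a direct assignment inherits the score of
its nearest scored ancestor in the MI ontology (e.g. 'two hybrid' inherits
0.66 from 'protein complementation assay'; 'coimmunoprecipitation'
inherits 1.00 from 'biochemical').  Unresolvable terms fall back to 0.05.
"""

from miscore import (
    CvTermRef,
    bundled_ontology,
    default_method_scores,
    default_type_scores,
    resolve_score,
)

ontology = bundled_ontology()
methods = default_method_scores()
types = default_type_scores()

for accession in ("MI:0013", "MI:0018", "MI:0019", "MI:0398", "unknown"):
    name = ontology.terms[accession].name if accession in ontology else accession
    scv, group = resolve_score(CvTermRef(accession), ontology, methods)
    print(f"method {accession:<8} {name:<32} scv={scv:.2f} group={group}")

for accession in ("MI:0407", "MI:0915", "MI:0914", "MI:0403"):
    name = ontology.terms[accession].name
    scv, group = resolve_score(CvTermRef(accession), ontology, types)
    print(f"type   {accession:<8} {name:<32} scv={scv:.2f} group={group}")
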