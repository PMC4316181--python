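"""Merge a synthetic three-database dataset and report redundancy.

Generates 20 true interactions re-reported by three pseudo databases with
80% overlap (30% of re-reports use a RefSeq-style identifier whose alias
carries the UniProt-style one, so merging must look at aliases), merges
the evidences and checks the result against the generator's ground truth.
The redundancy percentage is the share of input rows that were re-reports
of an interaction already seen.
"""

from miscore import FixtureSpec, generate, merge, read_mitab, redundancy_percent

spec = FixtureSpec(
    n_true_interactions=20,
    n_databases=3,
    overlap_fraction=0.8,
    alias_probability=0.3,
    seed=7,
)
text, truth = generate(spec)
evidences = read_mitab(text)
merged, clusters, synonyms = merge(evidences)

print(f"input evidences : {len(evidences)}")
print(f"merged pairs    : {len(merged)} (ground truth {truth.expected_merged})")
print(f"interactors     : {len(clusters)}")
print(f"synonym rows    : {len(synonyms)}")
print(f"redundancy      : {redundancy_percent(len(evidences), len(merged)):.2f}%")
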