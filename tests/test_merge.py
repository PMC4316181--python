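"""Evidence clustering: identifier matching, union-find merge, invariants."""

import random
from collections import Counter

import pytest

from helpers import (
    brute_force_clusters,
    grouping_signature,
    make_evidence,
    make_interactor,
    random_instance,
)
from miscore import (
    IdentifierKey,
    cluster_interactors,
    identifier_keys,
    merge,
    redundancy_percent,
)
from miscore.merge import DEFAULT_ACCEPTED_NAMESPACES, expand, merged_to_row
from miscore.mitab import InteractorRecord

ACCEPTED = DEFAULT_ACCEPTED_NAMESPACES


class TestIdentifierKeys:
    def test_unique_id_yields_one_key(self):
        rec = make_interactor(("uniprotkb", "Q9H8T0"))
        assert identifier_keys(rec) == {IdentifierKey("uniprotkb", "Q9H8T0")}

    def test_non_accepted_namespace_yields_empty_set(self):
        rec = make_interactor(("entrezgene", "12345"))
        assert identifier_keys(rec) == frozenset()

    def test_union_over_all_three_fields(self):
        rec = make_interactor(("refseq", "NP_001"), alias=("uniprotkb", "P1"))
        assert identifier_keys(rec) == {
            IdentifierKey("refseq", "NP_001"),
            IdentifierKey("uniprotkb", "P1"),
        }

    def test_refseq_version_suffix_is_stripped(self):
        rec = make_interactor(("refseq", "NP_001.2"))
        assert identifier_keys(rec) == {IdentifierKey("refseq", "NP_001")}

    def test_irefindex_normalizes_to_rogid(self):
        rec = make_interactor(("irefindex", "AbCdEf=="))
        assert identifier_keys(rec) == {IdentifierKey("rogid", "AbCdEf==")}

    def test_uniprot_isoforms_distinct_unless_collapsed(self):
        rec = make_interactor(("uniprotkb", "P12345-2"))
        assert identifier_keys(rec) == {IdentifierKey("uniprotkb", "P12345-2")}
        assert identifier_keys(rec, collapse_isoforms=True) == {
            IdentifierKey("uniprotkb", "P12345")
        }


class TestClusterInteractors:
    def test_shared_primary_id_joins_occurrences(self):
        evs = [
            make_evidence(make_interactor(("uniprotkb", "P1")), make_interactor(("uniprotkb", "P2"))),
            make_evidence(make_interactor(("uniprotkb", "P1")), make_interactor(("uniprotkb", "P3"))),
        ]
        assignment = cluster_interactors(evs)
        assert assignment[(0, "A")] == assignment[(1, "A")]
        assert assignment[(0, "B")] != assignment[(1, "B")]

    def test_alias_bridges_transitively(self):
        # A(uniprot P1), B(refseq R1 + alias uniprot P1), C(refseq R1)
        evs = [
            make_evidence(make_interactor(("uniprotkb", "P1")), make_interactor(("uniprotkb", "PX"))),
            make_evidence(
                make_interactor(("refseq", "R1"), alias=("uniprotkb", "P1")),
                make_interactor(("uniprotkb", "PY")),
            ),
            make_evidence(make_interactor(("refseq", "R1")), make_interactor(("uniprotkb", "PZ"))),
        ]
        assignment = cluster_interactors(evs)
        assert assignment[(0, "A")] == assignment[(1, "A")] == assignment[(2, "A")]

    def test_unrelated_ids_stay_apart(self):
        evs = [
            make_evidence(make_interactor(("uniprotkb", "P1")), make_interactor(("uniprotkb", "P2")))
        ]
        assignment = cluster_interactors(evs)
        assert assignment[(0, "A")] != assignment[(0, "B")]

    def test_keyless_occurrences_form_singletons(self):
        evs = [
            make_evidence(
                make_interactor(("entrezgene", "1")), make_interactor(("entrezgene", "1"))
            )
        ]
        assignment = cluster_interactors(evs)
        # same unmatchable id on both sides: no key, two singleton clusters
        assert assignment[(0, "A")] != assignment[(0, "B")]

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = random.Random(seed)
        evs = random_instance(rng, max_evidences=30)
        ours = cluster_interactors(evs, ACCEPTED)
        oracle = brute_force_clusters(evs, ACCEPTED)
        assert grouping_signature(ours, evs) == grouping_signature(oracle, evs)


class TestMerge:
    def fig1_scenario(self):
        m1 = make_interactor(("uniprotkb", "M1"))
        m2 = make_interactor(("uniprotkb", "M2"))
        m3 = make_interactor(("uniprotkb", "M3"))
        return [
            make_evidence(m1, m2, method="MI:0018", itype="MI:0915", pubs=("P1",)),
            make_evidence(m1, m2, method="MI:0019", itype="MI:0915", pubs=("P2",)),
            make_evidence(m1, m3, method="MI:0004", itype="MI:0407", pubs=("P3",)),
        ]

    def test_three_evidences_two_molecule_pairs(self):
        merged, clusters, synonyms = merge(self.fig1_scenario())
        assert len(merged) == 2
        assert len(clusters) == 3
        pair12 = next(m for m in merged if m.n_evidences == 2)
        assert pair12.n_publications == 2
        assert len(pair12.method_counts) == 2
        assert list(pair12.type_counts.values()) == [2]

    def test_duplicate_row_collapses_publications(self):
        ev = self.fig1_scenario()[0]
        merged, _, _ = merge([ev, ev])
        assert len(merged) == 1
        assert merged[0].n_evidences == 2
        assert merged[0].n_publications == 1

    def test_evidence_conservation(self):
        evs = self.fig1_scenario()
        merged, _, _ = merge(evs)
        assert sum(m.n_evidences for m in merged) == len(evs)

    def test_term_counts_total_evidence_count(self):
        evs = random_instance(random.Random(5), max_evidences=40)
        merged, _, _ = merge(evs)
        for m in merged:
            assert sum(m.method_counts.values()) == m.n_evidences
            assert sum(m.type_counts.values()) == m.n_evidences

    def test_idempotence_on_re_expanded_output(self):
        evs = random_instance(random.Random(11), max_evidences=40)
        merged, _, _ = merge(evs)
        again, _, _ = merge(expand(merged))
        assert self._content(again) == self._content(merged)

    def test_order_invariance(self):
        evs = random_instance(random.Random(3), max_evidences=40)
        merged, _, _ = merge(evs)
        shuffled = list(evs)
        random.Random(99).shuffle(shuffled)
        merged2, _, _ = merge(shuffled)
        assert self._content(merged) == self._content(merged2)

    def test_pair_symmetry(self):
        evs = self.fig1_scenario()
        swapped = [
            make_evidence(e.interactor_b, e.interactor_a,
                          method=e.detection_method.accession,
                          itype=e.interaction_type.accession,
                          pubs=tuple(p.accession for p in e.publications))
            for e in evs
        ]
        assert self._content(merge(evs)[0]) == self._content(merge(swapped)[0])

    def test_absent_interactor_becomes_flagged_self_pair(self):
        intra = make_evidence(
            make_interactor(("uniprotkb", "P1")), make_interactor(("uniprotkb", "P9"))
        )
        intra.interactor_b = InteractorRecord(None)
        merged, _, _ = merge([intra])
        assert len(merged) == 1
        assert merged[0].intra_molecular
        assert merged[0].pair[0] == merged[0].pair[1]

    def test_synonym_table_lists_every_identifier(self):
        evs = [
            make_evidence(
                make_interactor(("refseq", "R1"), alias=("uniprotkb", "P1")),
                make_interactor(("uniprotkb", "P2")),
            )
        ]
        _, _, synonyms = merge(evs)
        pairs = {(db, acc) for _, db, acc in synonyms}
        assert ("refseq", "R1") in pairs and ("uniprotkb", "P1") in pairs

    def test_merged_row_pipe_concatenates_multivalued_fields(self):
        merged, clusters, _ = merge(self.fig1_scenario())
        by_id = {c.cluster_id: c for c in clusters}
        row = merged_to_row(next(m for m in merged if m.n_evidences == 2), by_id)
        assert len(row) == 15
        assert row[8] == "pubmed:P1|pubmed:P2"
        assert row[6].count("|") == 1  # two distinct method terms

    @staticmethod
    def _content(merged):
        out = Counter()
        for m in merged:
            keys = frozenset(
                frozenset(identifier_keys(rec))
                for ev in m.evidences
                for rec in (ev.interactor_a, ev.interactor_b)
                if not rec.is_absent
            )
            out[(keys, m.n_evidences, m.publications,
                 frozenset(m.method_counts.items()),
                 frozenset(m.type_counts.items()))] += 1
        return out


@pytest.mark.parametrize(
    "n_input,n_merged,expected",
    [(1291743, 865642, 32.99), (10, 10, 0.0), (10, 5, 50.0)],
)
def test_redundancy_percent(n_input, n_merged, expected):
    assert redundancy_percent(n_input, n_merged) == pytest.approx(expected, abs=0.005)


def test_redundancy_percent_rejects_bad_counts():
    with pytest.raises(ValueError):
        redundancy_percent(0, 0)
    with pytest.raises(ValueError):
        redundancy_percent(5, 6)
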