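"""Shared test utilities: independent oracles and random-instance builders.

The oracles here deliberately avoid the library's own union-find and
log-score code paths: clustering is re-derived by naive repeated-pass
transitive closure over pairwise key sharing, so agreement with the
implementation is a genuine cross-check.
"""

from __future__ import annotations

import random
from collections import Counter

from miscore import (
    CrossReference,
    CvTermRef,
    InteractionEvidence,
    InteractorRecord,
    MergedInteraction,
    identifier_keys,
)


def make_interactor(*xrefs: tuple[str, str], alias: tuple[str, str] | None = None):
    """Interactor with a unique id, optional extra alt ids and one alias."""
    ids = [CrossReference(db, acc) for db, acc in xrefs]
    aliases = (CrossReference(*alias),) if alias else ()
    return InteractorRecord(ids[0], tuple(ids[1:]), aliases)


def make_evidence(
    a: InteractorRecord,
    b: InteractorRecord,
    method: str = "MI:0018",
    itype: str = "MI:0915",
    pubs: tuple[str, ...] = ("1",),
    source: str = "testdb",
) -> InteractionEvidence:
    return InteractionEvidence(
        interactor_a=a,
        interactor_b=b,
        detection_method=CvTermRef(method),
        interaction_type=CvTermRef(itype),
        publications=tuple(CrossReference("pubmed", p) for p in pubs),
        source_db=CvTermRef("unknown", source),
    )


def brute_force_clusters(evidences, accepted) -> dict[tuple[int, str], int]:
    """Transitive closure over shared identifier keys, by repeated passes.

    O(n^2) per pass and no union-find: an independent re-derivation of the
    clustering contract.  Occurrences with empty key sets stay singletons.
    """
    occs = []
    keysets = []
    for idx, ev in enumerate(evidences):
        for side, rec in (("A", ev.interactor_a), ("B", ev.interactor_b)):
            if rec.is_absent:
                continue
            occs.append((idx, side))
            keysets.append(set(identifier_keys(rec, accepted)))
    labels = list(range(len(occs)))
    changed = True
    while changed:
        changed = False
        for i in range(len(occs)):
            for j in range(i + 1, len(occs)):
                if labels[i] != labels[j] and keysets[i] & keysets[j]:
                    winner = min(labels[i], labels[j])
                    loser = max(labels[i], labels[j])
                    for k, lab in enumerate(labels):
                        if lab == loser:
                            labels[k] = winner
                            changed = True
    return {occ: labels[i] for i, occ in enumerate(occs)}


def grouping_signature(assignment, evidences) -> Counter:
    """Multiset of merged-group sizes keyed by unordered cluster pair.

    Cluster ids are arbitrary, so the signature maps each evidence to its
    unordered pair of cluster labels and counts group sizes; two clusterings
    agree iff the signatures (as partitions of the evidence list) agree.
    """
    pair_of = {}
    for idx in range(len(evidences)):
        ca = assignment.get((idx, "A"))
        cb = assignment.get((idx, "B"))
        if ca is None:
            ca = cb
        if cb is None:
            cb = ca
        pair_of[idx] = frozenset((ca, cb))
    groups = {}
    for idx, pair in pair_of.items():
        groups.setdefault(pair, []).append(idx)
    return Counter(frozenset(g) for g in groups.values())


def random_instance(rng: random.Random, max_evidences: int = 50):
    """A random evidence list with overlapping ids and alias bridges."""
    n = rng.randint(1, max_evidences)
    n_proteins = rng.randint(2, max(2, n))
    evidences = []
    for _ in range(n):
        i, j = rng.randrange(n_proteins), rng.randrange(n_proteins)
        sides = []
        for prot in (i, j):
            style = rng.random()
            if style < 0.6:
                rec = make_interactor(("uniprotkb", f"P{prot:04d}"))
            elif style < 0.85:
                rec = make_interactor(
                    ("refseq", f"NP_{prot:04d}"), alias=("uniprotkb", f"P{prot:04d}")
                )
            else:
                # unmatchable namespace: must stay a singleton
                rec = make_interactor(("entrezgene", f"G{rng.randrange(10_000)}"))
            sides.append(rec)
        evidences.append(
            make_evidence(sides[0], sides[1], pubs=(str(rng.randrange(100)),))
        )
    return evidences


def make_merged(
    n_pubs: int,
    method_counts: dict[str, int],
    type_counts: dict[str, int],
) -> MergedInteraction:
    """Merged interaction built directly from count structure (no file I/O)."""
    n_ev = max(1, sum(method_counts.values()), sum(type_counts.values()))
    a = make_interactor(("uniprotkb", "PAAAA1"))
    b = make_interactor(("uniprotkb", "PBBBB2"))
    evidences = [make_evidence(a, b) for _ in range(n_ev)]
    from miscore.merge import IdentifierKey

    return MergedInteraction(
        pair=(0, 1),
        evidences=evidences,
        publications=frozenset(
            IdentifierKey("pubmed", str(100 + k)) for k in range(n_pubs)
        ),
        method_counts=Counter({CvTermRef(acc): n for acc, n in method_counts.items()}),
        type_counts=Counter({CvTermRef(acc): n for acc, n in type_counts.items()}),
        source_dbs=frozenset({"testdb"}),
    )


SCORABLE_METHODS = ["MI:0013", "MI:0090", "MI:0018", "MI:0019", "MI:0398",
                    "MI:0399", "MI:0004", "MI:0254", "MI:0428", "MI:0063"]
SCORABLE_TYPES = ["MI:0208", "MI:0403", "MI:0914", "MI:0915", "MI:0407"]


def random_merged(rng: random.Random) -> MergedInteraction:
    methods = {
        acc: rng.randint(1, 4)
        for acc in rng.sample(SCORABLE_METHODS, rng.randint(0, 3))
    }
    types = {
        acc: rng.randint(1, 4)
        for acc in rng.sample(SCORABLE_TYPES, rng.randint(0, 2))
    }
    return make_merged(rng.randint(0, 12), methods, types)
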