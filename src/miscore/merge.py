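"""Evidence clustering: group MITAB rows that describe the same molecule pair.

Interaction databases report the same physical interaction many times —
re-curated from the same publication, imported from each other, or observed
with different methods.  Merging matches the two interactor columns of every
evidence through a configurable set of *accepted* identifier namespaces
(UniProtKB, RefSeq, ROGID and ChEBI by default) drawn from the unique
identifier, alternative identifier and alias fields.  Two interactor
occurrences belong to the same interactor cluster when they are connected
through shared identifiers (transitive closure via union-find); evidences
collapse into one merged interaction per canonical unordered pair of
interactor clusters.

The merged record keeps everything scoring needs: the distinct publication
set, and how many evidences reported each detection-method and
interaction-type term.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .mitab import (
    UNKNOWN_TERM,
    CrossReference,
    CvTermRef,
    InteractionEvidence,
    InteractorRecord,
)

#: identifier namespaces used for matching unless the caller overrides them
DEFAULT_ACCEPTED_NAMESPACES = ("uniprotkb", "refseq", "rogid", "irefindex", "chebi")

# alternate spellings of the same namespace seen in provider MITAB output
_NAMESPACE_SYNONYMS = {
    "irefindex": "rogid",
    "uniprot": "uniprotkb",
    "uniprot knowledge base": "uniprotkb",
    "uniprotkb/swiss-prot": "uniprotkb",
}

_REFSEQ_VERSION_RE = re.compile(r"\.\d+$")
_UNIPROT_ISOFORM_RE = re.compile(r"-\d+$")


@dataclass(frozen=True)
class IdentifierKey:
    """A normalized (namespace, accession) pair usable for matching."""

    namespace: str
    value: str


@dataclass
class MergedInteraction:
    """All evidences for one canonical unordered pair of interactor clusters."""

    pair: tuple[int, int]
    evidences: list[InteractionEvidence]
    publications: frozenset[IdentifierKey]
    method_counts: Counter  # CvTermRef -> number of evidences reporting it
    type_counts: Counter
    source_dbs: frozenset[str]
    intra_molecular: bool = False

    @property
    def n_evidences(self) -> int:
        return len(self.evidences)

    @property
    def n_publications(self) -> int:
        return len(self.publications)


@dataclass
class InteractorCluster:
    """A connected component of interactor occurrences."""

    cluster_id: int
    member_keys: frozenset[IdentifierKey]
    synonyms: frozenset[CrossReference]
    interaction_refs: set[int] = field(default_factory=set)

    def preferred_label(self) -> str:
        for key in sorted(self.member_keys, key=lambda k: (k.namespace, k.value)):
            return f"{key.namespace}:{key.value}"
        for syn in sorted(self.synonyms, key=lambda s: (s.database, s.accession)):
            return f"{syn.database}:{syn.accession}"
        return f"cluster:{self.cluster_id}"


def normalize_namespace(namespace: str) -> str:
    ns = namespace.strip().lower()
    return _NAMESPACE_SYNONYMS.get(ns, ns)


def _normalize_value(namespace: str, value: str, collapse_isoforms: bool) -> str:
    if namespace == "refseq":
        # version suffixes (NP_001234.2) denote revisions of one molecule
        return _REFSEQ_VERSION_RE.sub("", value)
    if namespace == "uniprotkb" and collapse_isoforms:
        return _UNIPROT_ISOFORM_RE.sub("", value)
    return value


def identifier_keys(
    interactor: InteractorRecord,
    accepted: Sequence[str] = DEFAULT_ACCEPTED_NAMESPACES,
    collapse_isoforms: bool = False,
) -> frozenset[IdentifierKey]:
    """Matching keys from all three identifier fields of an interactor.

    Only cross-references whose (normalized) namespace appears in
    ``accepted`` participate; an interactor annotated solely with other
    namespaces (e.g. entrez gene ids) yields an empty set and will form a
    singleton cluster.
    """
    accepted_norm = {normalize_namespace(ns) for ns in accepted}
    keys = set()
    for xref in interactor.all_xrefs():
        ns = normalize_namespace(xref.database)
        if ns in accepted_norm:
            keys.add(IdentifierKey(ns, _normalize_value(ns, xref.accession, collapse_isoforms)))
    return frozenset(keys)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_interactors(
    evidences: Sequence[InteractionEvidence],
    accepted: Sequence[str] = DEFAULT_ACCEPTED_NAMESPACES,
    collapse_isoforms: bool = False,
) -> dict[tuple[int, str], Optional[int]]:
    """Assign every interactor occurrence to an interactor cluster.

    Occurrences are addressed as ``(evidence index, side)`` with side in
    ``{"A", "B"}``; absent interactors (intra-molecular rows) map to None.
    Cluster ids are contiguous integers in first-occurrence order, so the
    mapping is deterministic for a given evidence order.
    """
    occurrences: list[tuple[int, str]] = []
    keysets: list[frozenset[IdentifierKey]] = []
    for idx, ev in enumerate(evidences):
        for side, rec in (("A", ev.interactor_a), ("B", ev.interactor_b)):
            if rec.is_absent:
                continue
            occurrences.append((idx, side))
            keysets.append(identifier_keys(rec, accepted, collapse_isoforms))

    uf = _UnionFind(len(occurrences))
    first_seen: dict[IdentifierKey, int] = {}
    for occ_idx, keys in enumerate(keysets):
        for key in keys:
            if key in first_seen:
                uf.union(first_seen[key], occ_idx)
            else:
                first_seen[key] = occ_idx

    root_to_cluster: dict[int, int] = {}
    assignment: dict[tuple[int, str], Optional[int]] = {}
    for idx, ev in enumerate(evidences):
        for side, rec in (("A", ev.interactor_a), ("B", ev.interactor_b)):
            if rec.is_absent:
                assignment[(idx, side)] = None
    for occ_idx, occ in enumerate(occurrences):
        root = uf.find(occ_idx)
        if root not in root_to_cluster:
            root_to_cluster[root] = len(root_to_cluster)
        assignment[occ] = root_to_cluster[root]
    return assignment


def publication_keys(ev: InteractionEvidence) -> frozenset[IdentifierKey]:
    """Distinct publication identifiers of one evidence (may be empty)."""
    return frozenset(
        IdentifierKey(normalize_namespace(p.database), p.accession) for p in ev.publications
    )


def merge(
    evidences: Sequence[InteractionEvidence],
    accepted: Sequence[str] = DEFAULT_ACCEPTED_NAMESPACES,
    collapse_isoforms: bool = False,
) -> tuple[list[MergedInteraction], list[InteractorCluster], list[tuple[str, str, str]]]:
    """Merge evidences into non-redundant interactions.

    Returns the three outputs of the merge step: the merged interactions,
    the interactor clusters, and a synonym table of
    ``(cluster label, database, accession)`` rows listing every identifier
    seen for each cluster.  Every input evidence lands in exactly one merged
    interaction; each evidence contributes exactly one detection-method term
    and one interaction-type term (the ``unknown`` sentinel when the column
    is empty), so term counts total the evidence count.  Rows with one
    absent interactor are treated as self-pairs of the present one and
    flagged intra-molecular.
    """
    assignment = cluster_interactors(evidences, accepted, collapse_isoforms)

    cluster_keys: dict[int, set[IdentifierKey]] = defaultdict(set)
    cluster_syns: dict[int, set[CrossReference]] = defaultdict(set)
    groups: dict[tuple[int, int], list[int]] = defaultdict(list)
    intra: set[tuple[int, int]] = set()

    for idx, ev in enumerate(evidences):
        ca = assignment[(idx, "A")]
        cb = assignment[(idx, "B")]
        for side, cid, rec in (("A", ca, ev.interactor_a), ("B", cb, ev.interactor_b)):
            if cid is None:
                continue
            cluster_keys[cid].update(identifier_keys(rec, accepted, collapse_isoforms))
            cluster_syns[cid].update(rec.all_xrefs())
        if ca is None and cb is None:
            raise ValueError(f"evidence {idx}: both interactors absent")
        if ca is None or cb is None:
            present = ca if ca is not None else cb
            pair = (present, present)
            intra.add(pair)
        else:
            pair = (min(ca, cb), max(ca, cb))
            if ca == cb:
                intra.add(pair)
        groups[pair].append(idx)

    merged: list[MergedInteraction] = []
    for pair in sorted(groups):
        idxs = groups[pair]
        pubs: set[IdentifierKey] = set()
        methods: Counter = Counter()
        types: Counter = Counter()
        sources: set[str] = set()
        for idx in idxs:
            ev = evidences[idx]
            pubs.update(publication_keys(ev))
            methods[_term_key(ev.detection_method)] += 1
            types[_term_key(ev.interaction_type)] += 1
            src = ev.source_db
            if not src.is_unknown or src.label:
                sources.add(src.label or src.accession)
        merged.append(
            MergedInteraction(
                pair=pair,
                evidences=[evidences[i] for i in idxs],
                publications=frozenset(pubs),
                method_counts=methods,
                type_counts=types,
                source_dbs=frozenset(sources),
                intra_molecular=pair in intra,
            )
        )

    clusters = [
        InteractorCluster(
            cluster_id=cid,
            member_keys=frozenset(cluster_keys[cid]),
            synonyms=frozenset(cluster_syns[cid]),
        )
        for cid in sorted(cluster_keys)
    ]
    by_id = {c.cluster_id: c for c in clusters}
    for midx, m in enumerate(merged):
        for cid in set(m.pair):
            if cid in by_id:
                by_id[cid].interaction_refs.add(midx)

    synonym_table = [
        (cluster.preferred_label(), syn.database, syn.accession)
        for cluster in clusters
        for syn in sorted(cluster.synonyms, key=lambda s: (s.database, s.accession))
    ]
    return merged, clusters, synonym_table


def _term_key(term: CvTermRef) -> CvTermRef:
    """Counting key for a CV term: accession when known, else the label."""
    if term.is_unknown and term.label is None:
        return UNKNOWN_TERM
    return term


def merged_to_row(
    m: MergedInteraction,
    clusters_by_id: dict[int, InteractorCluster],
    confidence: str = "-",
) -> list[str]:
    """Serialize one merged interaction as 15 MITAB 2.5 columns.

    Multi-valued fields (publications, methods, types, source databases)
    are pipe-concatenated and sorted for deterministic output.
    """

    def cluster_columns(cid: int) -> tuple[str, str, str]:
        cluster = clusters_by_id.get(cid)
        if cluster is None:
            return "-", "-", "-"
        keys = sorted(cluster.member_keys, key=lambda k: (k.namespace, k.value))
        uid = f"{keys[0].namespace}:{keys[0].value}" if keys else cluster.preferred_label()
        alts = "|".join(f"{k.namespace}:{k.value}" for k in keys[1:]) or "-"
        other = sorted(
            (s for s in cluster.synonyms), key=lambda s: (s.database, s.accession)
        )
        aliases = "|".join(s.to_mitab() for s in other) or "-"
        return uid, alts, aliases

    ida, alta, aliasa = cluster_columns(m.pair[0])
    idb, altb, aliasb = cluster_columns(m.pair[1])
    pubs = "|".join(
        f"{p.namespace}:{p.value}"
        for p in sorted(m.publications, key=lambda p: (p.namespace, p.value))
    ) or "-"
    methods = "|".join(
        t.to_mitab() for t in sorted(m.method_counts, key=_term_sort_key)
    ) or "-"
    types = "|".join(
        t.to_mitab() for t in sorted(m.type_counts, key=_term_sort_key)
    ) or "-"
    sources = "|".join(
        CvTermRef(s, None).to_mitab() if re.match(r"^MI:\d{4}$", s)
        else CvTermRef("unknown", s).to_mitab()
        for s in sorted(m.source_dbs)
    ) or "-"
    return [
        ida, idb, alta, altb, aliasa, aliasb,
        methods, "-", pubs, "-", "-", types, sources, "-", confidence,
    ]


def _term_sort_key(term: CvTermRef) -> tuple[str, str]:
    return (term.accession, term.label or "")


def redundancy_percent(n_input: int, n_merged: int) -> float:
    """Percentage of input evidences that were redundant re-reports."""
    if n_input <= 0:
        raise ValueError("n_input must be positive")
    if n_merged > n_input:
        raise ValueError("merged count cannot exceed input count")
    return 100.0 * (n_input - n_merged) / n_input


def expand(merged: Iterable[MergedInteraction]) -> list[InteractionEvidence]:
    """Flatten merged interactions back into their original evidences."""
    return [ev for m in merged for ev in m.evidences]
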