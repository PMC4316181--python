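"""PSI-MI controlled-vocabulary handling and per-term score resolution.

The MIscore method and type sub-scores rate each controlled-vocabulary (CV)
term through a small table of normalized scores (*scv*, each in [0, 1])
assigned to a handful of high-level terms.  A term without a direct
assignment inherits the score of its nearest scored ancestor in the MI
ontology; a term that cannot be resolved at all falls back to a low
``unknown`` score.  Assigned terms belong to named groups whose maxima
(*Gscv*) normalize the sub-score denominators.

A slim of the PSI-MI ontology covering both scored branches ships with the
package so that resolution works without downloading the full OBO file; any
OBO 1.2 file (e.g. the complete ``mi.obo``) can be loaded instead.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import obonet

from .mitab import MI_ACCESSION_RE, UNKNOWN_TERM_ACCESSION, CvTermRef

logger = logging.getLogger(__name__)

DEFAULT_UNKNOWN_SCORE = 0.05


@dataclass
class CvTerm:
    """One ontology term: MI accession, display name and is_a parents."""

    accession: str
    name: str = ""
    parents: tuple[str, ...] = ()
    obsolete: bool = False


@dataclass
class CvOntology:
    """The MI term DAG with name lookup and dangling-parent bookkeeping."""

    terms: dict[str, CvTerm] = field(default_factory=dict)
    dangling: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.by_name: dict[str, str] = {
            term.name.lower(): acc for acc, term in self.terms.items() if term.name
        }
        for term in self.terms.values():
            for parent in term.parents:
                if parent not in self.terms:
                    self.dangling.add(parent)

    def __contains__(self, accession: str) -> bool:
        return accession in self.terms

    def parents_of(self, accession: str) -> tuple[str, ...]:
        term = self.terms.get(accession)
        return term.parents if term else ()

    def accession_for_name(self, name: str) -> Optional[str]:
        return self.by_name.get(name.strip().lower())


@dataclass
class ScoreMap:
    """Per-term score assignments plus group structure.

    ``assignments`` maps MI accessions to scv values; ``groups`` maps a
    group id to the set of assigned accessions it covers.  The group
    maximum Gscv is derived from the members, so the invariant "Gscv equals
    the max scv of its members" holds by construction.  ``unknown_score``
    is used for terms that resolve nowhere; it belongs to no group.
    """

    assignments: dict[str, float]
    groups: dict[str, frozenset[str]]
    unknown_score: float = DEFAULT_UNKNOWN_SCORE

    def __post_init__(self) -> None:
        for acc, scv in self.assignments.items():
            if not 0.0 <= scv <= 1.0:
                raise ValueError(f"scv for {acc} outside [0,1]: {scv}")
        if not 0.0 <= self.unknown_score <= 1.0:
            raise ValueError(f"unknown_score outside [0,1]: {self.unknown_score}")
        self._group_of: dict[str, str] = {}
        for gid, members in self.groups.items():
            for acc in members:
                if acc not in self.assignments:
                    raise ValueError(f"group {gid} member {acc} has no assignment")
                self._group_of[acc] = gid

    def group_of(self, accession: str) -> Optional[str]:
        return self._group_of.get(accession)

    def group_max(self, gid: str) -> float:
        return max(self.assignments[a] for a in self.groups[gid])

    def group_max_sum(self) -> float:
        """Sum of group maxima, the constant part of the sub-score base."""
        return sum(self.group_max(g) for g in self.groups)


def default_method_scores() -> ScoreMap:
    """The HUPO PSI-MI consensus scores for detection-method branches.

    Six branch roots are scored (biophysical and biochemical highest,
    interference methods lowest); each forms its own group, so the group
    maxima sum to 3.19.
    """
    return ScoreMap(
        assignments={
            "MI:0013": 1.00,  # biophysical
            "MI:0090": 0.66,  # protein complementation assay
            "MI:0254": 0.10,  # genetic interference
            "MI:0255": 0.10,  # post transcriptional interference
            "MI:0401": 1.00,  # biochemical
            "MI:0428": 0.33,  # imaging technique
        },
        groups={
            "Gscv1": frozenset({"MI:0013"}),
            "Gscv2": frozenset({"MI:0090"}),
            "Gscv3": frozenset({"MI:0254"}),
            "Gscv4": frozenset({"MI:0255"}),
            "Gscv5": frozenset({"MI:0401"}),
            "Gscv6": frozenset({"MI:0428"}),
        },
    )


def default_type_scores() -> ScoreMap:
    """The HUPO PSI-MI consensus scores for interaction types.

    Association, physical association and direct interaction share one
    group (a single lineage of increasing specificity), so the group
    maxima sum to 0.10 + 0.33 + 1.00 = 1.43.
    """
    return ScoreMap(
        assignments={
            "MI:0208": 0.10,  # genetic interaction
            "MI:0403": 0.33,  # colocalization
            "MI:0914": 0.33,  # association
            "MI:0915": 0.66,  # physical association
            "MI:0407": 1.00,  # direct interaction
        },
        groups={
            "Gscv1": frozenset({"MI:0208"}),
            "Gscv2": frozenset({"MI:0403"}),
            "Gscv3": frozenset({"MI:0914", "MI:0915", "MI:0407"}),
        },
    )


def resolve_score(
    term: CvTermRef, ontology: CvOntology, scores: ScoreMap
) -> tuple[float, Optional[str]]:
    """Resolve a CV term to its scv and score group.

    Directly assigned terms return their own assignment.  Otherwise the
    ontology is ascended breadth-first through is_a parents and the first
    assigned ancestor at minimal depth wins; if several scored ancestors sit
    at the same minimal depth the maximum scv is taken (ties broken to the
    lexicographically smallest accession among the maxima, for determinism).
    Terms absent from the ontology, the ``unknown`` sentinel, and terms with
    no scored ancestor all yield ``(unknown_score, None)``.
    """
    accession = term.accession
    if accession == UNKNOWN_TERM_ACCESSION or not MI_ACCESSION_RE.match(accession):
        # name-based fallback for rows that only carry a label
        mapped = ontology.accession_for_name(term.label) if term.label else None
        if mapped is None:
            return scores.unknown_score, None
        accession = mapped
    if accession in scores.assignments:
        return scores.assignments[accession], scores.group_of(accession)
    if accession not in ontology:
        logger.warning("term %s not in ontology; scored as unknown", accession)
        return scores.unknown_score, None
    frontier = deque([accession])
    seen = {accession}
    while frontier:
        hits: list[str] = []
        next_frontier: list[str] = []
        for acc in frontier:
            for parent in ontology.parents_of(acc):
                if parent in seen:
                    continue
                seen.add(parent)
                if parent in scores.assignments:
                    hits.append(parent)
                else:
                    next_frontier.append(parent)
        if hits:
            best = min(hits, key=lambda a: (-scores.assignments[a], a))
            return scores.assignments[best], scores.group_of(best)
        frontier = deque(next_frontier)
    return scores.unknown_score, None


def load_obo(source) -> CvOntology:
    """Load an OBO 1.2 controlled vocabulary into a :class:`CvOntology`.

    ``source`` is a path or open text handle.  Only is_a relationships are
    kept; obsolete terms are flagged and parent accessions that are never
    defined are recorded as dangling rather than raising.
    """
    graph = obonet.read_obo(source, ignore_obsolete=False)
    terms: dict[str, CvTerm] = {}
    # nodes that only appear as edge targets carry no stanza data: dangling
    defined = {acc for acc, data in graph.nodes(data=True) if "name" in data}
    for acc in defined:
        data = graph.nodes[acc]
        parents = tuple(
            sorted(
                target
                for _, target, rel in graph.out_edges(acc, keys=True)
                if rel == "is_a"
            )
        )
        terms[acc] = CvTerm(
            accession=acc,
            name=data.get("name", ""),
            parents=parents,
            obsolete=data.get("is_obsolete", "false") == "true",
        )
    return CvOntology(terms=terms)


def bundled_ontology() -> CvOntology:
    """The packaged PSI-MI slim covering the scored branches."""
    ref = resources.files("miscore.data") / "psi-mi-slim.obo"
    with ref.open("r", encoding="utf-8") as handle:
        return load_obo(handle)
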