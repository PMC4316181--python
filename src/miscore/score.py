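"""MIscore: an annotation-based confidence score for merged interactions.

The composite score is the weighted, normalized mean of three sub-scores,
each in [0, 1]:

* publication sub-score ``Sp = log_{b+1}(n + 1)`` where ``n`` is the number
  of distinct publications reporting the interaction and ``b`` (default 7)
  is the publication count at which the sub-score saturates at 1;
* detection-method sub-score ``Sm = log_{B+1}(a + 1)`` with
  ``a = sum(scv_i * n_i)`` over the reported method terms and
  ``B = a + sum(max Gscv)``, the same quantity plus the sum of the score
  groups' maxima;
* interaction-type sub-score ``St``, computed as ``Sm`` but over the type
  score table.

``S_MI = (Kp*Sp + Km*Sm + Kt*St) / (Kp + Km + Kt)`` with all weights 1 by
default.  ``n_i`` counts evidence occurrences of a term, not distinct
publications; a term with no direct scv assignment inherits from its
nearest scored ancestor in the MI ontology (see :mod:`miscore.ontology`).

The score measures how well an interaction is annotated — more distinct
publications, more diverse and more trustworthy methods, and more specific
interaction types all increase it — not the physical quality of any single
experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .merge import MergedInteraction
from .mitab import CvTermRef
from .ontology import (
    CvOntology,
    ScoreMap,
    default_method_scores,
    default_type_scores,
    resolve_score,
)

DEFAULT_B_PUB = 7


@dataclass
class ScoreConfig:
    """Weights and score tables controlling the composite score.

    k_p, k_m, k_t
        Relative weights of the publication, method and type sub-scores.
        Equal weights make the composite the plain mean of the three.
    b_pub
        Number of distinct publications at which Sp saturates at 1.
    method_scores / type_scores
        Per-term scv tables with group structure; default to the HUPO
        PSI-MI consensus values.
    """

    k_p: float = 1.0
    k_m: float = 1.0
    k_t: float = 1.0
    b_pub: int = DEFAULT_B_PUB
    method_scores: ScoreMap = field(default_factory=default_method_scores)
    type_scores: ScoreMap = field(default_factory=default_type_scores)

    def __post_init__(self) -> None:
        for name, k in (("k_p", self.k_p), ("k_m", self.k_m), ("k_t", self.k_t)):
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {k}")
        if self.k_p + self.k_m + self.k_t <= 0:
            raise ValueError("at least one weight must be positive")
        if self.b_pub < 1:
            raise ValueError("b_pub must be >= 1")

    @classmethod
    def from_yaml(cls, source) -> "ScoreConfig":
        """Load weights / b_pub / scv overrides from a YAML mapping.

        Recognized keys: ``weights: {publication, method, type}``,
        ``b_pub``, ``method_scores`` and ``type_scores`` (each a mapping of
        MI accession to scv, overlaid on the defaults; overridden terms keep
        their default group, new terms form singleton groups).
        """
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source, "r", encoding="utf-8") as handle:
                data = yaml.safe_load(handle)
        data = data or {}
        weights = data.get("weights", {})
        method = _overlay(default_method_scores(), data.get("method_scores", {}))
        types = _overlay(default_type_scores(), data.get("type_scores", {}))
        return cls(
            k_p=float(weights.get("publication", 1.0)),
            k_m=float(weights.get("method", 1.0)),
            k_t=float(weights.get("type", 1.0)),
            b_pub=int(data.get("b_pub", DEFAULT_B_PUB)),
            method_scores=method,
            type_scores=types,
        )


def _overlay(base: ScoreMap, overrides: Mapping[str, float]) -> ScoreMap:
    assignments = dict(base.assignments)
    groups = {gid: set(members) for gid, members in base.groups.items()}
    for acc, scv in overrides.items():
        assignments[acc] = float(scv)
        if base.group_of(acc) is None:
            groups[f"Gscv_{acc}"] = {acc}
    return ScoreMap(
        assignments=assignments,
        groups={gid: frozenset(m) for gid, m in groups.items()},
        unknown_score=base.unknown_score,
    )


@dataclass
class SubScores:
    """The three sub-scores, the composite, and the log-base intermediates."""

    s_p: float
    s_m: float
    s_t: float
    s_mi: float
    a_m: float = 0.0
    b_m: float = 0.0
    a_t: float = 0.0
    b_t: float = 0.0

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float, float]:
        return (
            round(self.s_p, ndigits),
            round(self.s_m, ndigits),
            round(self.s_t, ndigits),
            round(self.s_mi, ndigits),
        )


def publication_score(n: int, b_pub: int = DEFAULT_B_PUB) -> float:
    """Saturating log of the distinct publication count.

    ``log_{b+1}(n+1)``, clamped to 1 for n beyond the saturation count b
    (the raw formula would exceed 1 there, but the score contract is [0,1]).
    """
    if n < 0:
        raise ValueError("publication count must be >= 0")
    if b_pub < 1:
        raise ValueError("b_pub must be >= 1")
    return min(1.0, math.log(n + 1) / math.log(b_pub + 1))


def cv_score(
    term_counts: Mapping[CvTermRef, int],
    ontology: CvOntology,
    scores: ScoreMap,
) -> tuple[float, float, float]:
    """Sub-score for one CV dimension (methods or types) of an interaction.

    Returns ``(score, a, B)`` where ``a = sum(scv_i * n_i)`` over the
    resolved terms and ``B = a + sum(max Gscv)`` over all score groups.
    Empty counts give score 0 (no annotation, no evidence of diversity).
    The score is strictly increasing in every ``n_i``: B - a is the constant
    group-maxima sum C, and ``log_{a+C+1}(a+1)`` grows with a.
    """
    if not term_counts:
        return 0.0, 0.0, scores.group_max_sum()
    a = 0.0
    for term, n in term_counts.items():
        if n < 0:
            raise ValueError(f"negative count for {term}")
        scv, _ = resolve_score(term, ontology, scores)
        a += scv * n
    big_b = a + scores.group_max_sum()
    if big_b <= 0:
        return 0.0, a, big_b
    return math.log(a + 1) / math.log(big_b + 1), a, big_b


def score_interaction(
    merged: MergedInteraction,
    config: Optional[ScoreConfig] = None,
    ontology: Optional[CvOntology] = None,
) -> SubScores:
    """Compute the composite confidence score of one merged interaction."""
    from .ontology import bundled_ontology

    config = config or ScoreConfig()
    ontology = ontology or bundled_ontology()
    s_p = publication_score(merged.n_publications, config.b_pub)
    s_m, a_m, b_m = cv_score(merged.method_counts, ontology, config.method_scores)
    s_t, a_t, b_t = cv_score(merged.type_counts, ontology, config.type_scores)
    total_k = config.k_p + config.k_m + config.k_t
    s_mi = (config.k_p * s_p + config.k_m * s_m + config.k_t * s_t) / total_k
    return SubScores(s_p=s_p, s_m=s_m, s_t=s_t, s_mi=s_mi, a_m=a_m, b_m=b_m, a_t=a_t, b_t=b_t)


def score_dataset(
    merged: Sequence[MergedInteraction],
    config: Optional[ScoreConfig] = None,
    ontology: Optional[CvOntology] = None,
) -> list[SubScores]:
    """Element-wise :func:`score_interaction`, preserving input order."""
    from .ontology import bundled_ontology

    config = config or ScoreConfig()
    ontology = ontology or bundled_ontology()
    return [score_interaction(m, config, ontology) for m in merged]


def confidence_field(sub: SubScores, ndigits: int = 2) -> str:
    """MITAB confidence-column entry for a scored interaction."""
    return f"miscore:{round(sub.s_mi, ndigits)}"
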