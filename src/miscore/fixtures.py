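"""Synthetic multi-database MITAB generation with known ground truth.

Real merge behaviour is hard to validate against live databases, so this
module fabricates what those databases would report: a set of *true*
interactions between synthetic proteins, re-reported by several pseudo
databases with a configurable overlap, sometimes under an alternative
identifier namespace (a RefSeq-style primary id whose alias field carries
the UniProt-style id), with fresh pubmed-style publication ids and CV terms
sampled from weighted pools.  The generator returns both the MITAB text and
a :class:`FixtureTruth` describing exactly which rows belong to which true
interaction, so merge output can be checked for exact recovery.

Synthetic accessions live in reserved prefixes (``UPTEST``/``RSTEST``) so
they cannot collide with real identifiers or with each other.
"""

from __future__ import annotations

import io
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .merge import MergedInteraction, merge
from .mitab import (
    CrossReference,
    CvTermRef,
    InteractionEvidence,
    InteractorRecord,
    build_columns,
    read_mitab,
    write_mitab,
)

#: (MI accession, label, sampling weight) pools mirroring commonly reported
#: assays and types in curated protein-interaction data
DEFAULT_METHOD_POOL = (
    ("MI:0018", "two hybrid", 3.0),
    ("MI:0398", "two hybrid pooling approach", 2.0),
    ("MI:0399", "two hybrid fragment pooling approach", 1.0),
    ("MI:0019", "coimmunoprecipitation", 2.0),
    ("MI:0004", "affinity chromatography technology", 1.0),
)
DEFAULT_TYPE_POOL = (
    ("MI:0915", "physical association", 3.0),
    ("MI:0407", "direct interaction", 1.0),
    ("MI:0914", "association", 1.0),
)


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_true_interactions: int = 20
    n_databases: int = 3
    overlap_fraction: float = 0.5
    alias_probability: float = 0.3
    method_pool: tuple[tuple[str, str, float], ...] = DEFAULT_METHOD_POOL
    type_pool: tuple[tuple[str, str, float], ...] = DEFAULT_TYPE_POOL
    pubs_per_evidence: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_interactions < 1 or self.n_databases < 1:
            raise ValueError("counts must be >= 1")
        for name, p in (
            ("overlap_fraction", self.overlap_fraction),
            ("alias_probability", self.alias_probability),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {p}")


@dataclass
class FixtureTruth:
    """Ground truth the merge step must recover."""

    expected_merged: int
    row_to_interaction: list[int]
    per_interaction: dict[int, dict] = field(default_factory=dict)


def _uniprot(j: int) -> CrossReference:
    return CrossReference("uniprotkb", f"UPTEST{j:05d}")


def _refseq(j: int) -> CrossReference:
    # carries a version suffix on purpose: merging must strip it
    return CrossReference("refseq", f"RSTEST{j:05d}.1")


def _interactor(j: int, use_alias: bool) -> InteractorRecord:
    if use_alias:
        return InteractorRecord(unique_id=_refseq(j), aliases=(_uniprot(j),))
    return InteractorRecord(unique_id=_uniprot(j))


def _weighted_choice(rng: random.Random, pool) -> tuple[str, str]:
    total = sum(w for _, _, w in pool)
    x = rng.random() * total
    for acc, label, w in pool:
        x -= w
        if x <= 0:
            return acc, label
    return pool[-1][0], pool[-1][1]


def generate(spec: FixtureSpec) -> tuple[str, FixtureTruth]:
    """Emit a MITAB 2.5 dataset and its ground truth.

    Database 0 reports every true interaction once; each further database
    re-reports it with probability ``overlap_fraction``, using the
    alternative-namespace identifiers with probability
    ``alias_probability``.  Deterministic for a fixed seed.
    """
    rng = random.Random(spec.seed)
    rows: list[InteractionEvidence] = []
    truth = FixtureTruth(
        expected_merged=spec.n_true_interactions, row_to_interaction=[]
    )
    next_pub = 10_000_000
    for i in range(spec.n_true_interactions):
        a, b = 2 * i, 2 * i + 1
        pubs: set[str] = set()
        methods: Counter = Counter()
        types: Counter = Counter()
        n_ev = 0
        for db in range(spec.n_databases):
            if db > 0 and rng.random() >= spec.overlap_fraction:
                continue
            use_alias = db > 0 and rng.random() < spec.alias_probability
            method_acc, method_label = _weighted_choice(rng, spec.method_pool)
            type_acc, type_label = _weighted_choice(rng, spec.type_pool)
            ev_pubs = []
            for _ in range(spec.pubs_per_evidence):
                ev_pubs.append(CrossReference("pubmed", str(next_pub)))
                pubs.add(str(next_pub))
                next_pub += 1
            ev = InteractionEvidence(
                interactor_a=_interactor(a, use_alias),
                interactor_b=_interactor(b, use_alias),
                detection_method=CvTermRef(method_acc, method_label),
                interaction_type=CvTermRef(type_acc, type_label),
                publications=tuple(ev_pubs),
                source_db=CvTermRef("unknown", f"testdb{db}"),
            )
            ev.raw_columns = build_columns(ev)
            rows.append(ev)
            truth.row_to_interaction.append(i)
            methods[method_acc] += 1
            types[type_acc] += 1
            n_ev += 1
        truth.per_interaction[i] = {
            "n_evidences": n_ev,
            "publications": len(pubs),
            "method_counts": dict(methods),
            "type_counts": dict(types),
        }
    buffer = io.StringIO()
    write_mitab(rows, buffer, dialect="2.5")
    return buffer.getvalue(), truth


# ---------------------------------------------------------------------------
# The AKTIP_HUMAN / HOOK2_HUMAN worked example
# ---------------------------------------------------------------------------

_AKTIP = "Q9H8T0"
_HOOK2 = "Q96ED9"
# placeholder pubmed-style ids standing in for the two underlying articles
_PUB1 = "90000001"
_PUB2 = "90000002"


def _example_row(
    source: str, method: tuple[str, str], itype: tuple[str, str], pub: str
) -> str:
    ev = InteractionEvidence(
        interactor_a=InteractorRecord(CrossReference("uniprotkb", _AKTIP)),
        interactor_b=InteractorRecord(CrossReference("uniprotkb", _HOOK2)),
        detection_method=CvTermRef(method[0], method[1]),
        interaction_type=CvTermRef(itype[0], itype[1]),
        publications=(CrossReference("pubmed", pub),),
        source_db=CvTermRef("unknown", source),
    )
    return "\t".join(build_columns(ev))

_TWO_HYBRID = ("MI:0018", "two hybrid")
_COIP = ("MI:0019", "coimmunoprecipitation")
_2H_POOL = ("MI:0398", "two hybrid pooling approach")
_2H_FRAG = ("MI:0399", "two hybrid fragment pooling approach")
_PHYS = ("MI:0915", "physical association")
_DIRECT = ("MI:0407", "direct interaction")
_ASSOC = ("MI:0914", "association")


def table1_mitab() -> dict[str, str]:
    """MITAB 2.5 text per evidence configuration of the worked example.

    Four configurations of the AKTIP–HOOK2 interaction as reported by
    individual databases and by their union: VirHostNet (two hybrid /
    physical association), Spike (coimmunoprecipitation / direct
    interaction), APID (two hybrid pooling / association) and the
    Spike+IntAct+VirHostNet union (4 evidences, 2 distinct publications).
    Publication identifiers are synthetic placeholders; the evidence
    structure (counts of publications, methods and types) is what matters.
    """
    virhostnet = _example_row("virhostnet", _TWO_HYBRID, _PHYS, _PUB1)
    spike = _example_row("spike", _COIP, _DIRECT, _PUB2)
    intact_1 = _example_row("intact", _2H_POOL, _PHYS, _PUB1)
    intact_2 = _example_row("intact", _2H_FRAG, _PHYS, _PUB2)
    apid = _example_row("apid", _2H_POOL, _ASSOC, _PUB1)
    return {
        "virhostnet": virhostnet + "\n",
        "spike": spike + "\n",
        "apid": apid + "\n",
        "spike+intact+virhostnet": "\n".join([spike, intact_1, intact_2, virhostnet]) + "\n",
    }


def table1_fixture() -> dict[str, MergedInteraction]:
    """The four verifiable worked-example configurations, merged.

    Each value is the single merged interaction obtained by running the
    merge step over that configuration's MITAB rows.
    """
    out: dict[str, MergedInteraction] = {}
    for name, text in table1_mitab().items():
        merged, _, _ = merge(read_mitab(text))
        if len(merged) != 1:
            raise AssertionError(f"{name}: expected one merged interaction")
        out[name] = merged[0]
    return out
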