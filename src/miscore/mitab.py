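"""Reading, writing and field grammar for PSI-MI MITAB files.

MITAB is the tab-delimited interchange format of the HUPO Proteomics
Standards Initiative for molecular interactions.  One line is one binary
interaction *evidence*: a pair of interactors plus the publication,
interaction detection method, interaction type and source database that
reported it.  Three column layouts are in circulation:

========  =======  =============================================
version   columns  extra content
========  =======  =============================================
2.5       15       core evidence
2.6       36       roles, xrefs, annotations, parameters
2.7       42       2.6 plus feature/stoichiometry/method columns
========  =======  =============================================

Multi-valued fields are pipe-separated lists of ``database:accession(text)``
items; accessions containing reserved characters (``:`` ``|`` ``(``) are
double-quoted, e.g. ``psi-mi:"MI:0407"(direct interaction)``.  The single
character ``-`` is the empty-field placeholder.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: column counts per MITAB dialect
DIALECT_COLUMNS = {"2.5": 15, "2.6": 36, "2.7": 42}
COLUMNS_DIALECT = {v: k for k, v in DIALECT_COLUMNS.items()}

MI_ACCESSION_RE = re.compile(r"^MI:\d{4}$")

# column indices shared by all dialects (2.6/2.7 append, never reorder)
COL_ID_A, COL_ID_B = 0, 1
COL_ALT_A, COL_ALT_B = 2, 3
COL_ALIAS_A, COL_ALIAS_B = 4, 5
COL_METHOD = 6
COL_AUTHOR = 7
COL_PUBLICATION = 8
COL_TAX_A, COL_TAX_B = 9, 10
COL_TYPE = 11
COL_SOURCE_DB = 12
COL_INTERACTION_ID = 13
COL_CONFIDENCE = 14


@dataclass(frozen=True)
class CrossReference:
    """A ``database:accession(text)`` item from a MITAB column."""

    database: str
    accession: str
    text: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.database or any(c.isspace() for c in self.database):
            raise ValueError(f"invalid database namespace: {self.database!r}")
        if not self.accession:
            raise ValueError("empty accession")

    def to_mitab(self) -> str:
        acc = self.accession
        if any(c in acc for c in ':|("'):
            acc = f'"{acc}"'
        out = f"{self.database}:{acc}"
        if self.text is not None:
            text = self.text
            if any(c in text for c in ':|("'):
                text = f'"{text}"'
            out += f"({text})"
        return out


@dataclass(frozen=True)
class CvTermRef:
    """Reference to a PSI-MI controlled-vocabulary term.

    ``accession`` is either an ``MI:NNNN`` accession or the sentinel
    ``"unknown"`` used when a row does not annotate the field (or only
    carries a free-text label, kept in ``label`` for name-based fallback).
    """

    accession: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.accession != UNKNOWN_TERM_ACCESSION and not MI_ACCESSION_RE.match(self.accession):
            raise ValueError(f"not an MI accession: {self.accession!r}")

    @property
    def is_unknown(self) -> bool:
        return self.accession == UNKNOWN_TERM_ACCESSION

    def to_mitab(self) -> str:
        if self.is_unknown and self.label is None:
            return "-"
        acc = self.accession if not self.is_unknown else "unknown"
        item = CrossReference("psi-mi", acc, self.text_label())
        return item.to_mitab()

    def text_label(self) -> Optional[str]:
        return self.label


UNKNOWN_TERM_ACCESSION = "unknown"
UNKNOWN_TERM = CvTermRef(UNKNOWN_TERM_ACCESSION)


@dataclass(frozen=True)
class InteractorRecord:
    """The three MITAB identifier fields of one interactor.

    ``unique_id`` is None only for the absent side of an intra-molecular
    interaction, in which case the other two lists are empty as well.
    """

    unique_id: Optional[CrossReference]
    alternative_ids: tuple[CrossReference, ...] = ()
    aliases: tuple[CrossReference, ...] = ()

    @property
    def is_absent(self) -> bool:
        return self.unique_id is None

    def all_xrefs(self) -> tuple[CrossReference, ...]:
        head = (self.unique_id,) if self.unique_id is not None else ()
        return head + self.alternative_ids + self.aliases


@dataclass
class InteractionEvidence:
    """One MITAB row: a single reported observation of an interaction."""

    interactor_a: InteractorRecord
    interactor_b: InteractorRecord
    detection_method: CvTermRef
    interaction_type: CvTermRef
    publications: tuple[CrossReference, ...]
    source_db: CvTermRef
    raw_columns: list[str] = field(default_factory=list)
    dialect: str = "2.5"

    def __post_init__(self) -> None:
        if self.raw_columns and len(self.raw_columns) != DIALECT_COLUMNS[self.dialect]:
            raise ValueError(
                f"raw_columns length {len(self.raw_columns)} inconsistent with "
                f"dialect {self.dialect}"
            )


class MitabFormatError(ValueError):
    """Raised for structurally invalid MITAB input."""


def _split_outside_quotes(text: str, sep: str) -> list[str]:
    parts: list[str] = []
    buf: list[str] = []
    in_quotes = False
    for ch in text:
        if ch == '"':
            in_quotes = not in_quotes
            buf.append(ch)
        elif ch == sep and not in_quotes:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def _find_outside_quotes(text: str, target: str) -> int:
    in_quotes = False
    for i, ch in enumerate(text):
        if ch == '"':
            in_quotes = not in_quotes
        elif ch == target and not in_quotes:
            return i
    return -1


def _dequote(text: str) -> str:
    if len(text) >= 2 and text[0] == '"' and text[-1] == '"':
        return text[1:-1]
    return text


def parse_xref_field(field_text: str) -> list[CrossReference]:
    """Parse one MITAB multi-value column into cross-references.

    Items are pipe-separated; quotes protect ``|`` ``:`` and parentheses
    inside accessions and free-text labels.  The placeholder ``-`` (or an
    empty string) yields an empty list.  An item without a ``:`` separator
    cannot be assigned a namespace and is recorded under the ``unknown``
    namespace with a warning, so parsing never fails on dirty provider data.
    """
    field_text = field_text.strip()
    if field_text in ("", "-"):
        return []
    out: list[CrossReference] = []
    for item in _split_outside_quotes(field_text, "|"):
        item = item.strip()
        if item in ("", "-"):
            continue
        colon = _find_outside_quotes(item, ":")
        if colon <= 0:
            logger.warning("malformed cross-reference item %r: no namespace", item)
            out.append(CrossReference("unknown", _dequote(item) or item))
            continue
        database = item[:colon].strip().lower()
        rest = item[colon + 1 :]
        text: Optional[str] = None
        paren = _find_outside_quotes(rest, "(")
        if paren != -1 and rest.rstrip().endswith(")"):
            text = _dequote(rest.rstrip()[paren + 1 : -1])
            rest = rest[:paren]
        accession = _dequote(rest.strip())
        if not accession:
            logger.warning("malformed cross-reference item %r: empty accession", item)
            continue
        out.append(CrossReference(database, accession, text))
    return out


def parse_cv_field(field_text: str) -> CvTermRef:
    """Extract the first controlled-vocabulary term from a MITAB column.

    Rows that carry only a free-text label (no MI accession) yield the
    ``unknown`` sentinel with the label preserved for name-based resolution.
    """
    for xref in parse_xref_field(field_text):
        if MI_ACCESSION_RE.match(xref.accession):
            return CvTermRef(xref.accession, xref.text)
        label = xref.text or (xref.accession if xref.accession.lower() != "unknown" else None)
        return CvTermRef(UNKNOWN_TERM_ACCESSION, label)
    return UNKNOWN_TERM


def _parse_interactor(id_field: str, alt_field: str, alias_field: str) -> InteractorRecord:
    ids = parse_xref_field(id_field)
    alts = tuple(parse_xref_field(alt_field))
    aliases = tuple(parse_xref_field(alias_field))
    if not ids:
        return InteractorRecord(None, alts, aliases)
    return InteractorRecord(ids[0], tuple(ids[1:]) + alts, aliases)


def parse_row(columns: Sequence[str], dialect: str) -> InteractionEvidence:
    """Build an :class:`InteractionEvidence` from one split MITAB line."""
    return InteractionEvidence(
        interactor_a=_parse_interactor(
            columns[COL_ID_A], columns[COL_ALT_A], columns[COL_ALIAS_A]
        ),
        interactor_b=_parse_interactor(
            columns[COL_ID_B], columns[COL_ALT_B], columns[COL_ALIAS_B]
        ),
        detection_method=parse_cv_field(columns[COL_METHOD]),
        interaction_type=parse_cv_field(columns[COL_TYPE]),
        publications=tuple(parse_xref_field(columns[COL_PUBLICATION])),
        source_db=parse_cv_field(columns[COL_SOURCE_DB]),
        raw_columns=list(columns),
        dialect=dialect,
    )


def read_mitab(stream: IO[str] | str, dialect: Optional[str] = None) -> list[InteractionEvidence]:
    """Read a MITAB file (or text) into evidence records.

    The dialect is auto-detected from the column count of the first data
    line when not given; lines whose column count matches none of the three
    published layouts raise :class:`MitabFormatError` naming the line.
    Header lines starting with ``#`` are skipped.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    evidences: list[InteractionEvidence] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        columns = line.split("\t")
        ncol = len(columns)
        if ncol not in COLUMNS_DIALECT:
            raise MitabFormatError(
                f"line {lineno}: {ncol} columns; expected one of "
                f"{sorted(COLUMNS_DIALECT)} (MITAB 2.5/2.6/2.7)"
            )
        line_dialect = COLUMNS_DIALECT[ncol]
        if dialect is None:
            dialect = line_dialect
        elif line_dialect != dialect:
            raise MitabFormatError(
                f"line {lineno}: dialect {line_dialect} conflicts with {dialect}"
            )
        evidences.append(parse_row(columns, line_dialect))
    return evidences


DEFAULT_HEADER_25 = (
    "#ID(s) interactor A\tID(s) interactor B\tAlt. ID(s) interactor A\t"
    "Alt. ID(s) interactor B\tAlias(es) interactor A\tAlias(es) interactor B\t"
    "Interaction detection method(s)\tPublication 1st author(s)\t"
    "Publication Identifier(s)\tTaxid interactor A\tTaxid interactor B\t"
    "Interaction type(s)\tSource database(s)\tInteraction identifier(s)\t"
    "Confidence value(s)"
)


def write_mitab(
    evidences: Iterable[InteractionEvidence],
    stream: IO[str],
    dialect: Optional[str] = None,
    header: Optional[str] = None,
) -> None:
    """Write evidences as MITAB rows.

    When ``dialect`` is narrower than a record's own (e.g. 2.7 source to a
    2.5 target) the trailing columns are dropped with a warning; a wider
    target pads with ``-``.  ``header`` is emitted verbatim as a first line
    when given.
    """
    if header is not None:
        stream.write(header.rstrip("\n") + "\n")
    warned = False
    for ev in evidences:
        target = dialect or ev.dialect
        want = DIALECT_COLUMNS[target]
        columns = list(ev.raw_columns) if ev.raw_columns else build_columns(ev)
        if len(columns) > want:
            if not warned:
                logger.warning(
                    "narrowing MITAB %s records to %s: extra columns dropped",
                    ev.dialect,
                    target,
                )
                warned = True
            columns = columns[:want]
        elif len(columns) < want:
            columns = columns + ["-"] * (want - len(columns))
        stream.write("\t".join(columns) + "\n")


def _interactor_columns(rec: InteractorRecord) -> tuple[str, str, str]:
    if rec.is_absent:
        return "-", "-", "-"
    uid = rec.unique_id.to_mitab()
    alts = "|".join(x.to_mitab() for x in rec.alternative_ids) or "-"
    aliases = "|".join(x.to_mitab() for x in rec.aliases) or "-"
    return uid, alts, aliases


def build_columns(ev: InteractionEvidence, confidence: str = "-") -> list[str]:
    """Serialize an evidence built in memory into 15 MITAB 2.5 columns."""
    ida, alta, aliasa = _interactor_columns(ev.interactor_a)
    idb, altb, aliasb = _interactor_columns(ev.interactor_b)
    pubs = "|".join(x.to_mitab() for x in ev.publications) or "-"
    return [
        ida,
        idb,
        alta,
        altb,
        aliasa,
        aliasb,
        ev.detection_method.to_mitab(),
        "-",
        pubs,
        "-",
        "-",
        ev.interaction_type.to_mitab(),
        ev.source_db.to_mitab(),
        "-",
        confidence,
    ]
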