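"""Reading, validating and filtering cognate-coded wordlists.

The canonical in-memory object is :class:`CognateMatrix`: for every
(language, semantic concept) cell it records the set of cognate-set ids
attested there.  A cell with no row at all in the source wordlist is
*unattested* (missing data); a cell whose entries were all removed as
loans stays *attested but empty*.  The event counter treats the two very
differently — an unattested concept is skipped, an attested-empty cell
can witness a word loss.

Cognate-set ids are plain strings matched only within the same concept:
two languages are cognate for a meaning when they hold a word from the
same cognate set *at that meaning*.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

#: default column mapping for ABVD-style exports
DEFAULT_SCHEMA: Mapping[str, str] = {
    "language_id": "language",
    "concept_id": "concept",
    "form": "form",
    "cognate_set_id": "cognate_set",
    "is_loan": "loan",
}

_TRUTHY = {"1", "true", "t", "yes", "y", "loan", "l"}
_FALSY = {"", "0", "false", "f", "no", "n", "nan", "none"}


@dataclass(frozen=True, order=True)
class WordForm:
    """One row of a cognate-coded wordlist."""

    language_id: str
    concept_id: str
    form: str
    cognate_set_id: str
    is_loan: bool = False


@dataclass
class CognateMatrix:
    """Languages x concepts presence structure over cognate sets.

    ``attested_cells`` lists every (language, concept) cell that had at
    least one row in the source data, independently of later filtering.
    """

    languages: tuple[str, ...]
    concepts: tuple[str, ...]
    entries: frozenset[WordForm]
    attested_cells: frozenset[tuple[str, str]]
    _presence: dict[tuple[str, str], frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        index: dict[tuple[str, str], set[str]] = {}
        lang_set, conc_set = set(self.languages), set(self.concepts)
        for e in self.entries:
            if e.language_id not in lang_set:
                raise DataError(f"entry references unknown language {e.language_id!r}")
            if e.concept_id not in conc_set:
                raise DataError(f"entry references unknown concept {e.concept_id!r}")
            index.setdefault((e.language_id, e.concept_id), set()).add(e.cognate_set_id)
        self._presence = {cell: frozenset(ids) for cell, ids in index.items()}

    # -- queries ---------------------------------------------------------
    def presence(self, language_id: str, concept_id: str) -> frozenset[str]:
        """Cognate-set ids attested for a cell (empty set if none)."""
        return self._presence.get((language_id, concept_id), frozenset())

    def attested(self, language_id: str, concept_id: str) -> bool:
        return (language_id, concept_id) in self.attested_cells

    @property
    def n_entries(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CognateMatrix):
            return NotImplemented
        return (
            self.languages == other.languages
            and self.concepts == other.concepts
            and self.entries == other.entries
            and self.attested_cells == other.attested_cells
        )

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[WordForm],
        *,
        attested_cells: Iterable[tuple[str, str]] | None = None,
        languages: Iterable[str] | None = None,
        concepts: Iterable[str] | None = None,
    ) -> "CognateMatrix":
        """Build a matrix from rows; ids are ordered lexicographically."""
        entry_set = frozenset(entries)
        cells = set(attested_cells) if attested_cells is not None else set()
        cells.update((e.language_id, e.concept_id) for e in entry_set)
        langs = set(languages) if languages is not None else set()
        langs.update(c[0] for c in cells)
        concs = set(concepts) if concepts is not None else set()
        concs.update(c[1] for c in cells)
        return cls(
            languages=tuple(sorted(langs)),
            concepts=tuple(sorted(concs)),
            entries=entry_set,
            attested_cells=frozenset(cells),
        )


def read_wordlists(
    source: str | io.TextIOBase,
    schema: Mapping[str, str] | None = None,
) -> CognateMatrix:
    """Read a delimited wordlist (comma or tab, auto-detected) into a matrix.

    Duplicate rows collapse (set semantics).  Rows with an empty
    cognate-set id are a validation error and reported together.
    """
    schema = dict(DEFAULT_SCHEMA if schema is None else schema)
    missing_fields = set(DEFAULT_SCHEMA) - set(schema)
    if missing_fields:
        raise SchemaError(f"schema is missing field mappings: {sorted(missing_fields)}")
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = [col for col in schema.values() if col not in df.columns]
    if missing:
        raise SchemaError(
            f"wordlist is missing mapped column(s) {missing}; found {list(df.columns)}"
        )

    bad_rows = [
        i + 2  # 1-based, plus header line
        for i, v in enumerate(df[schema["cognate_set_id"]])
        if str(v).strip() == ""
    ]
    if bad_rows:
        raise DataError(f"empty cognate_set_id on file line(s) {bad_rows}")

    entries = []
    for _, row in df.iterrows():
        entries.append(
            WordForm(
                language_id=str(row[schema["language_id"]]).strip(),
                concept_id=str(row[schema["concept_id"]]).strip(),
                form=str(row[schema["form"]]),
                cognate_set_id=str(row[schema["cognate_set_id"]]).strip(),
                is_loan=_parse_loan(row[schema["is_loan"]]),
            )
        )
    matrix = CognateMatrix.from_entries(entries)
    logger.info(
        "read %d rows -> %d unique entries, %d languages, %d concepts",
        len(df), matrix.n_entries, len(matrix.languages), len(matrix.concepts),
    )
    return matrix


def _parse_loan(value: object) -> bool:
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise DataError(f"unrecognised loan flag {value!r}")


def write_wordlists(matrix: CognateMatrix, target: str | io.TextIOBase) -> None:
    """Canonical writer (sorted rows) for fixtures; inverse of the reader.

    Attested-but-empty cells (possible only after loan filtering) have no
    row representation and cannot round-trip; write pre-filter matrices.
    """
    rows = [
        {
            "language": e.language_id,
            "concept": e.concept_id,
            "form": e.form,
            "cognate_set": e.cognate_set_id,
            "loan": int(e.is_loan),
        }
        for e in sorted(matrix.entries)
    ]
    pd.DataFrame(rows, columns=["language", "concept", "form", "cognate_set", "loan"]).to_csv(
        target, index=False
    )


def filter_loans(matrix: CognateMatrix) -> CognateMatrix:
    """Drop every loan-flagged entry; attestation flags are unchanged.

    A cell whose only entries were loans becomes attested-but-empty: the
    language demonstrably had data collected for the concept, so absence
    of an inherited cognate there is informative.
    """
    kept = frozenset(e for e in matrix.entries if not e.is_loan)
    removed = len(matrix.entries) - len(kept)
    if removed:
        logger.info("filter_loans: removed %d loan-flagged entries", removed)
    return CognateMatrix(
        languages=matrix.languages,
        concepts=matrix.concepts,
        entries=kept,
        attested_cells=matrix.attested_cells,
    )


def restrict_to_languages(matrix: CognateMatrix, keep: Iterable[str]) -> CognateMatrix:
    """Project the matrix onto a language subset; concepts unchanged."""
    keep_set = set(keep)
    unknown = keep_set - set(matrix.languages)
    if unknown:
        raise DataError(f"unknown language id(s) in keep set: {sorted(unknown)}")
    return CognateMatrix(
        languages=tuple(l for l in matrix.languages if l in keep_set),
        concepts=matrix.concepts,
        entries=frozenset(e for e in matrix.entries if e.language_id in keep_set),
        attested_cells=frozenset(c for c in matrix.attested_cells if c[0] in keep_set),
    )
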