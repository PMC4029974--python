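"""Readers and writers for the PINV tab-separated dataset formats.

A dataset is a pair of TSV files — interactions and features — plus an
optional third file of numeric expression values:

* interactions: two protein accessions, an aggregate confidence score,
  and optional per-source evidence scores in columns 4+;
* features: accession, organism, and arbitrary annotation columns;
* expression: accession followed by one numeric column per condition.

Files are UTF-8, tab-separated; lines starting with ``#`` and trailing
blank lines are ignored.  A first interaction line whose third field is
not numeric is treated as a header naming the evidence columns; the
features and expression files are recognised as having a header when the
first cell is one of ``accession``/``id``/``protein``/``protein_id``
(case-insensitive).

Parsing is total: every input line either yields a record, a warning, or
a located :class:`~pinetviz.errors.ParseError` — never silent loss.
"""

from __future__ import annotations

import csv
import hashlib
import io as _io
import math
from dataclasses import dataclass, field

from .errors import ParseError

__all__ = [
    "ProteinRecord",
    "InteractionRecord",
    "Dataset",
    "parse_interactions",
    "parse_features",
    "parse_expression",
    "build_dataset",
    "load_dataset",
    "write_interactions_tsv",
    "write_features_tsv",
    "write_table_csv",
    "content_hash",
]

_ID_HEADER_CELLS = {"accession", "id", "protein", "protein_id", "acc"}


@dataclass
class ProteinRecord:
    """One protein: accession, organism, annotations, optional expression."""

    accession: str
    organism: str
    features: dict[str, str] = field(default_factory=dict)
    expression: dict[str, float] | None = None

    def __post_init__(self):
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.organism:
            raise ValueError("organism must be non-empty")


@dataclass
class InteractionRecord:
    """Undirected scored edge; endpoints are kept in lexicographic order.

    ``evidence`` holds only the sources whose cell was non-empty in the
    file; an absent key means the evidence value was missing.
    """

    endpoint_a: str
    endpoint_b: str
    score: float
    evidence: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.endpoint_b < self.endpoint_a:
            self.endpoint_a, self.endpoint_b = self.endpoint_b, self.endpoint_a
        if not math.isfinite(self.score):
            raise ValueError("interaction score must be finite")
        for name, value in self.evidence.items():
            if not math.isfinite(value):
                raise ValueError(f"evidence {name!r} must be finite")

    @property
    def key(self) -> tuple[str, str]:
        """Canonical unordered-pair key."""
        return (self.endpoint_a, self.endpoint_b)

    @property
    def is_self_loop(self) -> bool:
        return self.endpoint_a == self.endpoint_b

    def touches(self, accession: str) -> bool:
        return accession in (self.endpoint_a, self.endpoint_b)


@dataclass
class Dataset:
    """A fully loaded network: proteins, interactions, column metadata."""

    proteins: dict[str, ProteinRecord]
    interactions: list[InteractionRecord]
    evidence_columns: list[str]
    feature_columns: list[str]
    warnings: list[str] = field(default_factory=list)

    @property
    def expression_columns(self) -> list[str]:
        cols: list[str] = []
        for p in self.proteins.values():
            if p.expression:
                for c in p.expression:
                    if c not in cols:
                        cols.append(c)
        return cols

    def interaction_by_key(self, key: tuple[str, str]) -> InteractionRecord | None:
        for rec in self.interactions:
            if rec.key == key:
                return rec
        return None


def _data_lines(text: str):
    """Yield (1-based line number, stripped line) skipping blanks/comments."""
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield i, line


def _is_number(cell: str) -> bool:
    try:
        float(cell)
    except ValueError:
        return False
    return True


def parse_interactions(
    text: str, evidence_names: list[str] | None = None
) -> tuple[list[InteractionRecord], list[str], list[str]]:
    """Parse an interactions TSV into records.

    Returns ``(records, evidence_columns, warnings)``.  Evidence column
    names are, in order of precedence: the ``evidence_names`` argument, a
    header line (first line whose third field is non-numeric), or
    auto-generated ``evidence1``, ``evidence2``, ...

    Duplicate unordered pairs are *not* merged here; `build_dataset`
    resolves them (keep-max) so the repair is applied exactly once.
    """
    records: list[InteractionRecord] = []
    warnings: list[str] = []
    columns: list[str] = list(evidence_names) if evidence_names else []
    header_seen = False
    first_data = True
    for lineno, line in _data_lines(text):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"interaction line needs >= 3 tab-separated fields, got {len(fields)}",
                line=lineno,
            )
        if first_data:
            first_data = False
            if not _is_number(fields[2]):
                header_seen = True
                if evidence_names is None:
                    columns = [c.strip() for c in fields[3:]]
                continue
        if not _is_number(fields[2]):
            raise ParseError(f"score {fields[2]!r} is not numeric", line=lineno)
        score = float(fields[2])
        if not math.isfinite(score):
            raise ParseError(f"score {fields[2]!r} is not finite", line=lineno)
        a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ParseError("empty accession field", line=lineno)
        evidence: dict[str, float] = {}
        for j, cell in enumerate(fields[3:]):
            cell = cell.strip()
            while j >= len(columns):
                columns.append(f"evidence{len(columns) + 1}")
            if cell == "":
                continue
            if not _is_number(cell):
                raise ParseError(
                    f"evidence value {cell!r} is not numeric",
                    line=lineno,
                    column=columns[j],
                )
            value = float(cell)
            if not math.isfinite(value):
                raise ParseError(
                    f"evidence value {cell!r} is not finite", line=lineno, column=columns[j]
                )
            evidence[columns[j]] = value
        records.append(InteractionRecord(a, b, score, evidence))
    if header_seen and evidence_names is not None:
        warnings.append("interactions header ignored: evidence_names supplied explicitly")
    return records, columns, warnings


def parse_features(
    text: str, feature_names: list[str] | None = None
) -> tuple[list[ProteinRecord], list[str], list[str]]:
    """Parse a features TSV (accession, organism, annotations...).

    Returns ``(records, feature_columns, warnings)``.  Duplicate
    accessions resolve last-wins with a warning.
    """
    records: dict[str, ProteinRecord] = {}
    warnings: list[str] = []
    columns: list[str] = list(feature_names) if feature_names else []
    first_data = True
    for lineno, line in _data_lines(text):
        fields = line.split("\t")
        if first_data:
            first_data = False
            if fields[0].strip().lower() in _ID_HEADER_CELLS:
                if feature_names is None:
                    columns = [c.strip() for c in fields[2:]]
                continue
        if len(fields) < 2:
            raise ParseError(
                "feature line needs >= 2 fields (accession, organism)", line=lineno
            )
        acc, organism = fields[0].strip(), fields[1].strip()
        if not acc:
            raise ParseError("empty accession field", line=lineno)
        if not organism:
            raise ParseError("missing organism (second column is required)", line=lineno)
        feats: dict[str, str] = {}
        for j, cell in enumerate(fields[2:]):
            while j >= len(columns):
                columns.append(f"feature{len(columns) + 1}")
            cell = cell.strip()
            if cell:
                feats[columns[j]] = cell
        if acc in records:
            warnings.append(f"duplicate accession {acc!r}: keeping the last occurrence")
        records[acc] = ProteinRecord(acc, organism, feats)
    return list(records.values()), columns, warnings


def parse_expression(text: str) -> dict[str, dict[str, float]]:
    """Parse an expression TSV into ``{accession: {condition: value}}``.

    The first row names the conditions; remaining cells must be numeric.
    Empty input yields an empty map.
    """
    result: dict[str, dict[str, float]] = {}
    conditions: list[str] | None = None
    for lineno, line in _data_lines(text):
        fields = line.split("\t")
        if conditions is None:
            conditions = [c.strip() for c in fields[1:]]
            continue
        acc = fields[0].strip()
        if not acc:
            raise ParseError("empty accession field", line=lineno)
        values: dict[str, float] = {}
        for j, cell in enumerate(fields[1:]):
            name = conditions[j] if j < len(conditions) else f"condition{j + 1}"
            cell = cell.strip()
            if cell == "":
                continue
            if not _is_number(cell):
                raise ParseError(
                    f"expression value {cell!r} is not numeric", line=lineno, column=name
                )
            values[name] = float(cell)
        result[acc] = values
    return result


def build_dataset(
    interactions: list[InteractionRecord],
    proteins: list[ProteinRecord],
    evidence_columns: list[str] | None = None,
    feature_columns: list[str] | None = None,
    expression: dict[str, dict[str, float]] | None = None,
    warnings: list[str] | None = None,
) -> Dataset:
    """Assemble a validated :class:`Dataset`, repairing rather than failing.

    Repairs (each recorded in ``Dataset.warnings``):

    * duplicate unordered pairs keep the record with the highest score;
    * self-interactions are kept but flagged;
    * interaction endpoints missing from the feature records get a stub
      protein with organism ``"unspecified"``;
    * expression rows for unknown accessions are dropped.
    """
    warns: list[str] = list(warnings) if warnings else []
    prot_map: dict[str, ProteinRecord] = {}
    for p in proteins:
        if p.accession in prot_map:
            warns.append(f"duplicate accession {p.accession!r}: keeping the last occurrence")
        prot_map[p.accession] = p

    by_key: dict[tuple[str, str], InteractionRecord] = {}
    order: list[tuple[str, str]] = []
    ev_cols: list[str] = list(evidence_columns) if evidence_columns else []
    for rec in interactions:
        for name in rec.evidence:
            if name not in ev_cols:
                ev_cols.append(name)
        if rec.is_self_loop:
            warns.append(f"self-interaction {rec.endpoint_a!r} kept (skipped by layouts)")
        if rec.key in by_key:
            kept = by_key[rec.key]
            winner = rec if rec.score > kept.score else kept
            warns.append(
                f"duplicate interaction {rec.key[0]}-{rec.key[1]}: keeping score {winner.score:g}"
            )
            by_key[rec.key] = winner
        else:
            by_key[rec.key] = rec
            order.append(rec.key)

    for key in order:
        for acc in key:
            if acc not in prot_map:
                prot_map[acc] = ProteinRecord(acc, "unspecified")
                warns.append(f"protein {acc!r} missing from features: stub with organism 'unspecified'")

    if expression:
        for acc, values in expression.items():
            if acc not in prot_map:
                warns.append(f"expression row for unknown accession {acc!r} ignored")
                continue
            prot_map[acc].expression = dict(values)

    return Dataset(
        proteins=prot_map,
        interactions=[by_key[k] for k in order],
        evidence_columns=ev_cols,
        feature_columns=list(feature_columns) if feature_columns else [],
        warnings=warns,
    )


def load_dataset(
    interactions_text: str,
    features_text: str = "",
    expression_text: str | None = None,
    evidence_names: list[str] | None = None,
    feature_names: list[str] | None = None,
) -> Dataset:
    """One-call loader: parse all files and assemble the Dataset."""
    inter, ev_cols, w1 = parse_interactions(interactions_text, evidence_names)
    prots, feat_cols, w2 = parse_features(features_text, feature_names) if features_text else ([], [], [])
    expr = parse_expression(expression_text) if expression_text else None
    return build_dataset(inter, prots, ev_cols, feat_cols, expr, warnings=w1 + w2)


def _fmt(value: float) -> str:
    """Shortest round-tripping decimal text for a float."""
    return repr(value)


def write_interactions_tsv(dataset: Dataset) -> str:
    """Serialize interactions (with header) back to PINV TSV."""
    lines = ["\t".join(["protein_a", "protein_b", "score"] + dataset.evidence_columns)]
    for rec in dataset.interactions:
        cells = [rec.endpoint_a, rec.endpoint_b, _fmt(rec.score)]
        for col in dataset.evidence_columns:
            cells.append(_fmt(rec.evidence[col]) if col in rec.evidence else "")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_features_tsv(dataset: Dataset) -> str:
    """Serialize protein features (with header) back to PINV TSV."""
    lines = ["\t".join(["accession", "organism"] + dataset.feature_columns)]
    for p in dataset.proteins.values():
        cells = [p.accession, p.organism]
        for col in dataset.feature_columns:
            cells.append(p.features.get(col, ""))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def write_table_csv(rows: list[dict], columns: list[str]) -> str:
    """Render rows as RFC 4180 CSV text (header first, CRLF line endings)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n", quoting=csv.QUOTE_MINIMAL)
    writer.writerow(columns)
    for row in rows:
        writer.writerow(["" if row.get(c) is None else row.get(c) for c in columns])
    return buf.getvalue()


def content_hash(dataset: Dataset) -> str:
    """SHA-256 over a canonical serialization; detects dataset mismatch on share."""
    h = hashlib.sha256()
    for acc in sorted(dataset.proteins):
        p = dataset.proteins[acc]
        h.update(f"P\t{p.accession}\t{p.organism}\t{sorted(p.features.items())}\n".encode())
        if p.expression:
            h.update(f"X\t{acc}\t{sorted(p.expression.items())}\n".encode())
    for rec in sorted(dataset.interactions, key=lambda r: r.key):
        h.update(
            f"I\t{rec.endpoint_a}\t{rec.endpoint_b}\t{rec.score!r}\t{sorted(rec.evidence.items())}\n".encode()
        )
    return h.hexdigest()
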