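"""Namespace validation and the batch rename audit.

Renaming an established corpus is scripted and retrospective: every record
gets either a CV name or an exemption code, previous names are retained as
aliases, and the run is idempotent.  Duplicated names (the documented
failure mode is cleavage of peptides with uncertain coordinates) are
reported for manual naming, never silently suffixed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .assembly_naming import name_entity
from .event_naming import classify_reaction, name_reaction, regulation_sentence
from .model import (
    Assembly,
    CvError,
    CvName,
    Document,
    ExemptionError,
    PeptideEntity,
    brackets_balanced,
)
from .peptide_naming import check_exemption
from .tables import Tables


@dataclass
class NamespaceReport:
    """Duplicate name groups, bracket failures and exempted entities."""

    duplicates: list[tuple[str, list[object]]] = field(default_factory=list)
    unbalanced: list[CvName] = field(default_factory=list)
    exempt: list[tuple[object, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.duplicates

    def summary(self) -> str:
        lines = [
            f"names checked with {len(self.duplicates)} duplicate group(s), "
            f"{len(self.unbalanced)} bracket failure(s), "
            f"{len(self.exempt)} exempt entit(ies)"
        ]
        for text, sources in self.duplicates:
            lines.append(f"  duplicate ({len(sources)} records): {text}")
        for name in self.unbalanced:
            lines.append(f"  unbalanced brackets: {name.text}")
        for _, code in self.exempt:
            lines.append(f"  exempt: {code}")
        return "\n".join(lines)


def validate_namespace(
    names: list[CvName],
    exempt: list[tuple[object, str]] | None = None,
) -> NamespaceReport:
    """Check a name collection for duplicates and bracket balance.

    ``exempt`` lists (entity, exemption code) pairs that were excluded from
    naming; they are carried into the report.  The collection fails (ok is
    False) only on duplicates among the named, non-exempt records.
    """
    report = NamespaceReport(exempt=list(exempt or []))
    by_text: dict[str, list[object]] = {}
    for name in names:
        by_text.setdefault(name.text, []).append(name.source)
        if not brackets_balanced(name.text):
            report.unbalanced.append(name)
    for text, sources in by_text.items():
        if len(sources) > 1:
            report.duplicates.append((text, sources))
    return report


AUDIT_COLUMNS = (
    "record_id", "record_type", "old_name", "new_name",
    "exemption_code", "category", "error",
)


@dataclass
class AuditRow:
    record_id: str
    record_type: str  # peptide | molecule | assembly | reaction
    old_name: str = ""
    new_name: str = ""
    exemption_code: str = ""
    category: str = ""
    error: str = ""


def rename_batch(doc: Document, tables: Tables) -> list[AuditRow]:
    """Apply CV naming to every record of a document.

    Deterministic and total: per-record failures land in the row's
    error/exemption column and never abort the batch.  Reactions also get
    their event category, and the regulation statement is appended to the
    reaction name when a regulator is present.
    """
    rows: list[AuditRow] = []
    for eid, entity in doc.entities.items():
        row = AuditRow(
            record_id=eid,
            record_type=(
                "peptide" if isinstance(entity, PeptideEntity)
                else "assembly" if isinstance(entity, Assembly)
                else "molecule"
            ),
            old_name=doc.aliases.get(eid, ""),
        )
        try:
            row.new_name = name_entity(entity, tables).text
        except ExemptionError as exc:
            row.exemption_code = exc.code
        except CvError as exc:
            row.error = str(exc)
        rows.append(row)

    for rid, rxn in doc.reactions.items():
        row = AuditRow(record_id=rid, record_type="reaction")
        try:
            category = classify_reaction(rxn, tables)
            row.category = category
            text = name_reaction(rxn, category, tables).text
            regulation = regulation_sentence(rxn, text, tables)
            row.new_name = text if regulation is None else f"{text}; {regulation}"
        except CvError as exc:
            row.error = str(exc)
        rows.append(row)
    return rows


def write_audit(rows: list[AuditRow], path: str | Path) -> None:
    """Write the audit as TSV (one header row, UTF-8)."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(AUDIT_COLUMNS)
        for row in rows:
            writer.writerow([getattr(row, col) for col in AUDIT_COLUMNS])


def exemption_code_for(entity: object) -> str | None:
    """The exemption code an entity would be reported under, if any."""
    if isinstance(entity, PeptideEntity):
        return check_exemption(entity)
    return None
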