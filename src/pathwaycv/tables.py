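"""Lookup tables behind the CV: PSI-MOD prefixes, small-molecule
abbreviations and GO-molecular-function verbs.

Three TSV files (one header row, UTF-8) seed the tables; each is an
extensible seed covering the prefixes, abbreviations and verbs the CV
defines, and users may point the loader at a directory with extended
copies.  An optional PSI-MOD OBO file can bootstrap extra prefix rows
(infrequent modification types use the unabbreviated ontology term as
their prefix).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .model import CvError, LookupMissError

#: event-name templates a GOMF verb can select
TEMPLATES = ("catalyzes", "transfers", "transports", "exchanges", "cotransports")

#: GOMF substrings that all denote hydrolysis reactions (fallback rule when
#: a term has no exact row in the verb table)
HYDROLYSIS_SUBSTRINGS = (
    "phosphodiesterase", "esterase", "lipase", "fumarylacetoacetase", "gtpase",
)


class TableError(CvError):
    """A lookup table file is malformed."""


@dataclass(frozen=True)
class ModPrefix:
    """One PSI-MOD id -> prefix row.

    ``includes_coordinate`` marks the modification classes whose residue
    coordinate is printed in the name (di/tri-lysine and arginine
    methylation, lysine acetylation, ubiquitination, phosphorylation);
    ``phospho`` marks the phosphorylation class, which renders as a single
    trailing "p-" block with subtype letters.
    """

    psimod_id: str
    prefix: str
    includes_coordinate: bool
    phospho: bool


def normalize_molecule_name(name: str) -> str:
    """Case-insensitive, whitespace-normalized key for abbreviation lookup."""
    return " ".join(name.split()).casefold()


@dataclass
class Tables:
    """The three lookup tables plus derived indexes."""

    mod_prefixes: dict[str, ModPrefix] = field(default_factory=dict)
    molecule_abbrev: dict[str, str] = field(default_factory=dict)  # norm name -> abbrev
    gomf_verbs: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        self.prefix_rows: dict[str, ModPrefix] = {}
        for row in self.mod_prefixes.values():
            # first row wins for a shared prefix (reverse lookup for parsing)
            self.prefix_rows.setdefault(row.prefix, row)
        self.abbreviations: set[str] = set(self.molecule_abbrev.values())
        for abbrev in self.abbreviations:
            if normalize_molecule_name(abbrev) in self.molecule_abbrev:
                raise TableError(
                    f"abbreviation {abbrev!r} also appears as a full-name key; "
                    "abbreviation lookup must be idempotent"
                )

    # -- lookups ----------------------------------------------------------

    def mod_prefix(self, psimod_id: str) -> ModPrefix:
        try:
            return self.mod_prefixes[psimod_id]
        except KeyError:
            raise LookupMissError(psimod_id, "mod_prefixes") from None

    def abbreviation_for(self, full_name: str) -> str | None:
        return self.molecule_abbrev.get(normalize_molecule_name(full_name))

    def phospho_psimod_id(self) -> str:
        for row in self.mod_prefixes.values():
            if row.phospho:
                return row.psimod_id
        raise TableError("mod_prefixes has no phosphorylation row")


def _read_tsv(path: Path, columns: tuple[str, ...]) -> list[dict]:
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != columns:
            raise TableError(
                f"{path.name}: expected columns {columns}, got {reader.fieldnames}"
            )
        rows = []
        for i, row in enumerate(reader, start=2):
            if any(v is None or v == "" for v in row.values()):
                raise TableError(f"{path.name}:{i}: empty field")
            rows.append(row)
        return rows


def _parse_bool(value: str, where: str) -> bool:
    if value.lower() in ("true", "1", "yes"):
        return True
    if value.lower() in ("false", "0", "no"):
        return False
    raise TableError(f"{where}: expected a boolean, got {value!r}")


def load_tables(directory: str | Path | None = None) -> Tables:
    """Load the three TSV tables, defaulting to the shipped seed tables."""
    if directory is None:
        directory = Path(str(resources.files("pathwaycv") / "data"))
    directory = Path(directory)

    mods: dict[str, ModPrefix] = {}
    for row in _read_tsv(directory / "mod_prefixes.tsv",
                         ("psimod_id", "prefix", "includes_coordinate", "phospho")):
        mid = row["psimod_id"]
        if mid in mods:
            raise TableError(f"mod_prefixes.tsv: duplicate psimod_id {mid!r}")
        mods[mid] = ModPrefix(
            psimod_id=mid,
            prefix=row["prefix"],
            includes_coordinate=_parse_bool(
                row["includes_coordinate"], f"mod_prefixes.tsv {mid}"),
            phospho=_parse_bool(row["phospho"], f"mod_prefixes.tsv {mid}"),
        )

    abbrev: dict[str, str] = {}
    for row in _read_tsv(directory / "molecule_abbrev.tsv",
                         ("full_name", "abbreviation")):
        key = normalize_molecule_name(row["full_name"])
        if key in abbrev:
            raise TableError(
                f"molecule_abbrev.tsv: duplicate full_name {row['full_name']!r}")
        abbrev[key] = row["abbreviation"]

    verbs: dict[str, tuple[str, str]] = {}
    for row in _read_tsv(directory / "gomf_verbs.tsv",
                         ("gomf_term", "verb", "template")):
        if row["template"] not in TEMPLATES:
            raise TableError(
                f"gomf_verbs.tsv: template {row['template']!r} not in {TEMPLATES}")
        verbs[row["gomf_term"].strip().casefold()] = (row["verb"], row["template"])

    return Tables(mod_prefixes=mods, molecule_abbrev=abbrev, gomf_verbs=verbs)


def mod_prefixes_from_obo(path: str | Path) -> dict[str, ModPrefix]:
    """Bootstrap extra prefix rows from a PSI-MOD OBO file.

    Terms absent from the curated seed get their unabbreviated ontology name
    as the prefix, with no coordinate and non-phospho class — the treatment
    given to infrequently used modification types.  Requires obonet.
    """
    import obonet  # optional path; never required for normal operation

    graph = obonet.read_obo(str(path))
    rows: dict[str, ModPrefix] = {}
    for node, data in graph.nodes(data=True):
        name = data.get("name")
        if not name:
            continue
        rows[node] = ModPrefix(
            psimod_id=node, prefix=name,
            includes_coordinate=False, phospho=False,
        )
    return rows


def merge_tables(base: Tables, extra_mods: dict[str, ModPrefix]) -> Tables:
    """Return a Tables with extra prefix rows merged in (seed rows win)."""
    merged = dict(extra_mods)
    merged.update(base.mod_prefixes)
    return Tables(
        mod_prefixes=merged,
        molecule_abbrev=dict(base.molecule_abbrev),
        gomf_verbs=dict(base.gomf_verbs),
    )
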