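"""Domain model for pathway-entity controlled-vocabulary (CV) naming.

The model mirrors the objects a pathway database names: cleaved/modified
peptides anchored on an HGNC gene symbol, ChEBI-style small molecules, and
recursive assemblies (complexes, defined sets, candidate sets), plus the
reactions (events) they participate in.

Coordinates are 1-based and inclusive and always refer to the reference
peptide chain; an unknown coordinate is ``None`` in memory and ``"?"`` in the
JSON document format.  All entity types are frozen dataclasses, so entity
trees are hashable, structurally comparable and cycle-free by construction.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Union

UNKNOWN = None  # readable alias for an unknown 1-based coordinate

PHOSPHO_SUBTYPES = ("S", "T", "Y")

COMPLEX = "complex"
DEFINED_SET = "defined_set"
CANDIDATE_SET = "candidate_set"
ASSEMBLY_KINDS = (COMPLEX, DEFINED_SET, CANDIDATE_SET)
SET_KINDS = (DEFINED_SET, CANDIDATE_SET)

POLYMERIZATION = "POLYMERIZATION"
DEPOLYMERIZATION = "DEPOLYMERIZATION"
EXPLICIT_CLASSES = (POLYMERIZATION, DEPOLYMERIZATION)


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class CvError(Exception):
    """Base class for all controlled-vocabulary errors."""


class ValidationError(CvError):
    """A domain invariant is violated."""


class LookupMissError(CvError):
    """An identifier is absent from a lookup table (carries the identifier)."""

    def __init__(self, identifier: str, table: str):
        self.identifier = identifier
        self.table = table
        super().__init__(f"{identifier!r} not found in table {table!r}")


class ExemptionError(CvError):
    """A peptide is exempt from CV naming (carries the exemption code)."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        super().__init__(message or f"peptide exempt from CV naming: {code}")


class StructureError(CvError):
    """The entity graph is malformed (e.g. a cycle)."""


class ParseError(CvError):
    """A CV name string is rejected (carries the character offset)."""

    def __init__(self, message: str, position: int):
        self.position = position
        super().__init__(f"{message} (at position {position})")


class DocumentError(CvError):
    """An entity document fails schema validation (names the offending field)."""


# ---------------------------------------------------------------------------
# Entity types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ptm:
    """One post-translational modification on a peptide.

    ``subtype`` is the phosphorylation residue letter (S/T/Y) and is only
    meaningful for the phosphorylation prefix.  ``multiplicity`` > 1 encodes
    the "nx" form and is only legal when the residue coordinate is unknown.
    """

    psimod_id: str
    prefix: str
    subtype: str | None = None
    coordinate: int | None = None
    multiplicity: int = 1

    def __post_init__(self):
        if self.subtype is not None and self.subtype not in PHOSPHO_SUBTYPES:
            raise ValidationError(
                f"Ptm.subtype must be one of {PHOSPHO_SUBTYPES} or None, "
                f"got {self.subtype!r}"
            )
        if self.multiplicity < 1:
            raise ValidationError("Ptm.multiplicity must be a positive integer")
        if self.multiplicity > 1 and self.coordinate is not None:
            raise ValidationError(
                "Ptm.multiplicity > 1 requires an unknown coordinate "
                "(the 'nx' form never carries a position)"
            )
        if self.coordinate is not None and self.coordinate < 1:
            raise ValidationError("Ptm.coordinate is 1-based and must be >= 1")


@dataclass(frozen=True)
class PeptideEntity:
    """A translated or cleaved peptide, named around its HGNC gene symbol.

    ``start``/``end`` are the peptide's coordinates on the reference
    sequence; ``chain_start``/``chain_end`` are the reference chain feature
    delimiting the default mature peptide, and ``chain_count`` the number of
    chain features on the reference record (coordinates are only suppressed
    when there is exactly one chain and the peptide coincides with it).
    """

    gene_symbol: str
    start: int | None = None
    end: int | None = None
    chain_start: int | None = None
    chain_end: int | None = None
    chain_count: int = 1
    ptms: tuple[Ptm, ...] = ()
    isoform_variant: int = 1
    active_flag: bool = False
    disease_mutation_flag: bool = False
    cross_link_flag: bool = False
    hla_flag: bool = False

    def __post_init__(self):
        object.__setattr__(self, "ptms", tuple(self.ptms))
        if not self.gene_symbol:
            raise ValidationError("PeptideEntity.gene_symbol must be non-empty")
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValidationError(
                f"PeptideEntity.start ({self.start}) > end ({self.end})"
            )
        for coord in (self.start, self.end, self.chain_start, self.chain_end):
            if coord is not None and coord < 1:
                raise ValidationError("peptide coordinates are 1-based (>= 1)")
        if self.chain_count < 0:
            raise ValidationError("PeptideEntity.chain_count must be >= 0")
        if self.isoform_variant < 1:
            raise ValidationError("PeptideEntity.isoform_variant must be >= 1")


@dataclass(frozen=True)
class SmallMolecule:
    """A small molecule, identified by its reference (ChEBI-style) name."""

    reference_name: str
    chebi_id: str | None = None

    def __post_init__(self):
        if not self.reference_name:
            raise ValidationError("SmallMolecule.reference_name must be non-empty")


@dataclass(frozen=True)
class Part:
    """One slot of an assembly: a member with stoichiometry and candidate flag."""

    member: "Entity"
    stoichiometry: int = 1
    is_candidate: bool = False

    def __post_init__(self):
        if self.stoichiometry < 1:
            raise ValidationError("Part.stoichiometry must be a positive integer")


@dataclass(frozen=True)
class Assembly:
    """A complex, defined set or candidate set with ordered parts.

    The structure is a tree: a shared sub-complex appearing twice is simply
    the same (structurally equal) value in two slots, and is named
    identically at each occurrence.
    """

    kind: str
    parts: tuple[Part, ...] = ()
    functional_label: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "parts", tuple(self.parts))
        if self.kind not in ASSEMBLY_KINDS:
            raise ValidationError(
                f"Assembly.kind must be one of {ASSEMBLY_KINDS}, got {self.kind!r}"
            )
        if not self.parts:
            raise ValidationError("Assembly.parts must be non-empty")
        n_cand = sum(1 for p in self.parts if p.is_candidate)
        if self.kind != CANDIDATE_SET and n_cand:
            raise ValidationError(
                "is_candidate parts are only legal in a candidate_set"
            )
        if self.kind == CANDIDATE_SET and (n_cand == 0 or n_cand == len(self.parts)):
            raise ValidationError(
                "a candidate_set needs at least one member and one candidate"
            )


Entity = Union[PeptideEntity, SmallMolecule, Assembly]


@dataclass(frozen=True)
class CvName:
    """A generated CV name together with the tree it was derived from."""

    text: str
    source: object = None
    namespace: str = "default"

    def __post_init__(self):
        if not self.text:
            raise ValidationError("CvName.text must be non-empty")
        if not brackets_balanced(self.text):
            raise ValidationError(f"CvName has unbalanced brackets: {self.text!r}")


def brackets_balanced(text: str) -> bool:
    """True iff round and square brackets in ``text`` are balanced and nested."""
    stack = []
    pairs = {")": "(", "]": "["}
    for ch in text:
        if ch in "([":
            stack.append(ch)
        elif ch in ")]":
            if not stack or stack.pop() != pairs[ch]:
                return False
    return not stack


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Participant:
    """One reaction participant with its compartment, count and cell type."""

    entity: Entity
    compartment: str | None = None
    count: int = 1
    cell_type: str | None = None

    def __post_init__(self):
        if self.count < 1:
            raise ValidationError("Participant.count must be a positive integer")


@dataclass(frozen=True)
class Reaction:
    """A pathway event: inputs, outputs, optional catalyst and regulator.

    ``catalyst_gomf`` is the GO molecular function label attached to the
    catalyst; it drives the verb used in the event name.  The transfer_*
    fields carry the transferase roles (transferred group, acceptor and
    optional product) which are not recoverable from flat input/output
    lists.  ``omit_product`` suppresses the optional product clause in the
    rendered name (a curator choice; the templates mark it optional).
    """

    inputs: tuple[Participant, ...] = ()
    outputs: tuple[Participant, ...] = ()
    catalyst: Entity | None = None
    catalyst_gomf: str | None = None
    regulator: Entity | None = None
    regulator_sign: str | None = None  # "positive" | "negative"
    explicit_class: str | None = None  # POLYMERIZATION | DEPOLYMERIZATION
    membrane: str | None = None        # e.g. "late endosome", for antiport
    transfer_group: Entity | None = None
    transfer_acceptor: Entity | None = None
    transfer_product: Entity | None = None
    omit_product: bool = False

    def __post_init__(self):
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(self, "outputs", tuple(self.outputs))
        if self.explicit_class is not None and self.explicit_class not in EXPLICIT_CLASSES:
            raise ValidationError(
                f"Reaction.explicit_class must be one of {EXPLICIT_CLASSES}"
            )
        if self.explicit_class is None and (not self.inputs or not self.outputs):
            raise ValidationError(
                "Reaction.inputs and outputs must be non-empty unless an "
                "explicit class is set"
            )
        if self.regulator is not None and self.regulator_sign not in ("positive", "negative"):
            raise ValidationError(
                "Reaction.regulator_sign must be 'positive' or 'negative' "
                "when a regulator is present"
            )


# ---------------------------------------------------------------------------
# Entity documents (JSON)
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


@dataclass
class Document:
    """A flat entity/reaction document: ids map to objects, roots list the
    top-level entities, aliases retain previous free-text names."""

    entities: dict[str, Entity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    aliases: dict[str, str] = field(default_factory=dict)
    roots: list[str] = field(default_factory=list)

    def root_entities(self) -> list[Entity]:
        return [self.entities[i] for i in self.roots]


def document_from_entities(
    entities: Iterable[Entity],
    reactions: Iterable[Reaction] = (),
    aliases: dict[int, str] | None = None,
) -> Document:
    """Build a Document, registering every distinct subtree under a local id.

    Structurally equal subtrees share one id, which is what lets a shared
    sub-complex be serialized once.  ``aliases`` maps root positions (0-based)
    to retained previous names.
    """
    doc = Document()
    ids: dict[Entity, str] = {}

    def register(ent: Entity) -> str:
        if ent in ids:
            return ids[ent]
        if isinstance(ent, Assembly):
            for part in ent.parts:
                register(part.member)
        eid = f"e{len(ids) + 1}"
        ids[ent] = eid
        doc.entities[eid] = ent
        return eid

    for pos, ent in enumerate(entities):
        eid = register(ent)
        doc.roots.append(eid)
        if aliases and pos in aliases:
            doc.aliases[eid] = aliases[pos]
    for i, rxn in enumerate(reactions, start=1):
        for p in (*rxn.inputs, *rxn.outputs):
            register(p.entity)
        for ent in (rxn.catalyst, rxn.regulator, rxn.transfer_group,
                    rxn.transfer_acceptor, rxn.transfer_product):
            if ent is not None:
                register(ent)
        doc.reactions[f"r{i}"] = rxn
    return doc


def _coord_out(value: int | None):
    return "?" if value is None else value


def _coord_in(value, where: str) -> int | None:
    if value == "?" or value is None:
        return None
    if isinstance(value, bool) or not isinstance(value, int):
        raise DocumentError(f"{where}: expected an integer or '?', got {value!r}")
    return value


def _entity_to_json(ent: Entity, ids: dict[Entity, str]) -> dict:
    if isinstance(ent, PeptideEntity):
        out = {
            "type": "peptide",
            "gene_symbol": ent.gene_symbol,
            "start": _coord_out(ent.start),
            "end": _coord_out(ent.end),
            "chain_count": ent.chain_count,
        }
        if ent.chain_start is not None:
            out["chain_start"] = ent.chain_start
        if ent.chain_end is not None:
            out["chain_end"] = ent.chain_end
        if ent.ptms:
            out["ptms"] = [
                {
                    "psimod_id": m.psimod_id,
                    "prefix": m.prefix,
                    "subtype": m.subtype,
                    "coordinate": _coord_out(m.coordinate),
                    "multiplicity": m.multiplicity,
                }
                for m in ent.ptms
            ]
        if ent.isoform_variant != 1:
            out["isoform_variant"] = ent.isoform_variant
        for key, val in (
            ("active", ent.active_flag),
            ("disease_mutation", ent.disease_mutation_flag),
            ("cross_link", ent.cross_link_flag),
            ("hla", ent.hla_flag),
        ):
            if val:
                out[key] = True
        return out
    if isinstance(ent, SmallMolecule):
        out = {"type": "molecule", "reference_name": ent.reference_name}
        if ent.chebi_id is not None:
            out["chebi_id"] = ent.chebi_id
        return out
    if isinstance(ent, Assembly):
        out = {
            "type": "assembly",
            "kind": ent.kind,
            "parts": [
                {
                    "ref": ids[p.member],
                    **({"stoichiometry": p.stoichiometry} if p.stoichiometry != 1 else {}),
                    **({"candidate": True} if p.is_candidate else {}),
                }
                for p in ent.parts
            ],
        }
        if ent.functional_label is not None:
            out["functional_label"] = ent.functional_label
        return out
    raise DocumentError(f"unserializable entity type: {type(ent).__name__}")


def _participant_to_json(p: Participant, ids: dict[Entity, str]) -> dict:
    out: dict = {"ref": ids[p.entity]}
    if p.compartment is not None:
        out["compartment"] = p.compartment
    if p.count != 1:
        out["count"] = p.count
    if p.cell_type is not None:
        out["cell_type"] = p.cell_type
    return out


def write_entity_document(doc: Document, path: str | Path) -> None:
    """Serialize a Document to the package JSON schema."""
    ids = {ent: eid for eid, ent in doc.entities.items()}
    entities_json = []
    for eid, ent in doc.entities.items():
        rec = {"id": eid, **_entity_to_json(ent, ids)}
        if eid in doc.aliases:
            rec["name"] = doc.aliases[eid]
        entities_json.append(rec)
    reactions_json = []
    for rid, rxn in doc.reactions.items():
        rec: dict = {
            "id": rid,
            "inputs": [_participant_to_json(p, ids) for p in rxn.inputs],
            "outputs": [_participant_to_json(p, ids) for p in rxn.outputs],
        }
        if rxn.catalyst is not None:
            rec["catalyst"] = ids[rxn.catalyst]
        if rxn.catalyst_gomf is not None:
            rec["catalyst_gomf"] = rxn.catalyst_gomf
        if rxn.regulator is not None:
            rec["regulator"] = {"ref": ids[rxn.regulator], "sign": rxn.regulator_sign}
        if rxn.explicit_class is not None:
            rec["explicit_class"] = rxn.explicit_class
        if rxn.membrane is not None:
            rec["membrane"] = rxn.membrane
        if rxn.transfer_group is not None:
            rec["transfer"] = {
                "group": ids[rxn.transfer_group],
                "acceptor": ids[rxn.transfer_acceptor] if rxn.transfer_acceptor else None,
            }
            if rxn.transfer_product is not None:
                rec["transfer"]["product"] = ids[rxn.transfer_product]
        if rxn.omit_product:
            rec["omit_product"] = True
        reactions_json.append(rec)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "entities": entities_json,
        "reactions": reactions_json,
        "roots": list(doc.roots),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n", encoding="utf-8")


def _require(record: dict, key: str, types, where: str):
    if key not in record:
        raise DocumentError(f"{where}.{key}: required field is missing")
    value = record[key]
    if types is not None and not isinstance(value, types):
        raise DocumentError(
            f"{where}.{key}: expected {types}, got {type(value).__name__}"
        )
    return value


def _entity_from_json(rec: dict, where: str,
                      resolve) -> Entity:
    etype = _require(rec, "type", str, where)
    try:
        if etype == "peptide":
            ptms = []
            for j, m in enumerate(rec.get("ptms", [])):
                pw = f"{where}.ptms[{j}]"
                ptms.append(Ptm(
                    psimod_id=_require(m, "psimod_id", str, pw),
                    prefix=_require(m, "prefix", str, pw),
                    subtype=m.get("subtype"),
                    coordinate=_coord_in(m.get("coordinate"), f"{pw}.coordinate"),
                    multiplicity=m.get("multiplicity", 1),
                ))
            return PeptideEntity(
                gene_symbol=_require(rec, "gene_symbol", str, where),
                start=_coord_in(rec.get("start", "?"), f"{where}.start"),
                end=_coord_in(rec.get("end", "?"), f"{where}.end"),
                chain_start=rec.get("chain_start"),
                chain_end=rec.get("chain_end"),
                chain_count=rec.get("chain_count", 1),
                ptms=tuple(ptms),
                isoform_variant=rec.get("isoform_variant", 1),
                active_flag=rec.get("active", False),
                disease_mutation_flag=rec.get("disease_mutation", False),
                cross_link_flag=rec.get("cross_link", False),
                hla_flag=rec.get("hla", False),
            )
        if etype == "molecule":
            return SmallMolecule(
                reference_name=_require(rec, "reference_name", str, where),
                chebi_id=rec.get("chebi_id"),
            )
        if etype == "assembly":
            parts = []
            for j, p in enumerate(_require(rec, "parts", list, where)):
                pw = f"{where}.parts[{j}]"
                member = resolve(_require(p, "ref", str, pw), pw)
                parts.append(Part(
                    member=member,
                    stoichiometry=p.get("stoichiometry", 1),
                    is_candidate=p.get("candidate", False),
                ))
            return Assembly(
                kind=_require(rec, "kind", str, where),
                parts=tuple(parts),
                functional_label=rec.get("functional_label"),
            )
    except ValidationError as exc:
        raise DocumentError(f"{where}: {exc}") from exc
    raise DocumentError(f"{where}.type: unknown entity type {etype!r}")


def read_entity_document(path: str | Path) -> Document:
    """Read and validate a JSON entity document.

    Raises DocumentError naming the offending field on schema violations,
    unknown references or cyclic assembly definitions.
    """
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DocumentError(f"not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise DocumentError("document root: expected a JSON object")
    records: dict[str, dict] = {}
    order: list[str] = []
    for i, rec in enumerate(_require(payload, "entities", list, "document")):
        where = f"entities[{i}]"
        if not isinstance(rec, dict):
            raise DocumentError(f"{where}: expected an object")
        eid = _require(rec, "id", str, where)
        if eid in records:
            raise DocumentError(f"{where}.id: duplicate id {eid!r}")
        records[eid] = rec
        order.append(eid)

    built: dict[str, Entity] = {}
    in_progress: set[str] = set()

    def resolve(eid: str, where: str) -> Entity:
        if eid in built:
            return built[eid]
        if eid not in records:
            raise DocumentError(f"{where}.ref: unknown entity id {eid!r}")
        if eid in in_progress:
            raise DocumentError(
                f"{where}.ref: cyclic assembly definition through {eid!r}"
            )
        in_progress.add(eid)
        idx = order.index(eid)
        ent = _entity_from_json(records[eid], f"entities[{idx}]", resolve)
        in_progress.discard(eid)
        built[eid] = ent
        return ent

    doc = Document()
    for eid in order:
        doc.entities[eid] = resolve(eid, f"entities[{order.index(eid)}]")
        if "name" in records[eid]:
            doc.aliases[eid] = records[eid]["name"]

    def participant(p: dict, where: str) -> Participant:
        ref = _require(p, "ref", str, where)
        if ref not in doc.entities:
            raise DocumentError(f"{where}.ref: unknown entity id {ref!r}")
        try:
            return Participant(
                entity=doc.entities[ref],
                compartment=p.get("compartment"),
                count=p.get("count", 1),
                cell_type=p.get("cell_type"),
            )
        except ValidationError as exc:
            raise DocumentError(f"{where}: {exc}") from exc

    def entity_ref(rec: dict, key: str, where: str) -> Entity | None:
        if key not in rec or rec[key] is None:
            return None
        ref = rec[key]
        if ref not in doc.entities:
            raise DocumentError(f"{where}.{key}: unknown entity id {ref!r}")
        return doc.entities[ref]

    for i, rec in enumerate(payload.get("reactions", [])):
        where = f"reactions[{i}]"
        rid = _require(rec, "id", str, where)
        transfer = rec.get("transfer", {})
        regulator = rec.get("regulator")
        try:
            doc.reactions[rid] = Reaction(
                inputs=tuple(participant(p, f"{where}.inputs[{j}]")
                             for j, p in enumerate(rec.get("inputs", []))),
                outputs=tuple(participant(p, f"{where}.outputs[{j}]")
                              for j, p in enumerate(rec.get("outputs", []))),
                catalyst=entity_ref(rec, "catalyst", where),
                catalyst_gomf=rec.get("catalyst_gomf"),
                regulator=entity_ref(regulator or {}, "ref", f"{where}.regulator")
                if regulator else None,
                regulator_sign=(regulator or {}).get("sign"),
                explicit_class=rec.get("explicit_class"),
                membrane=rec.get("membrane"),
                transfer_group=entity_ref(transfer, "group", f"{where}.transfer"),
                transfer_acceptor=entity_ref(transfer, "acceptor", f"{where}.transfer"),
                transfer_product=entity_ref(transfer, "product", f"{where}.transfer"),
                omit_product=rec.get("omit_product", False),
            )
        except ValidationError as exc:
            raise DocumentError(f"{where}: {exc}") from exc

    for i, eid in enumerate(payload.get("roots", order)):
        if eid not in doc.entities:
            raise DocumentError(f"roots[{i}]: unknown entity id {eid!r}")
        doc.roots.append(eid)
    return doc


# ---------------------------------------------------------------------------
# Synthetic fixture generation
# ---------------------------------------------------------------------------

def _base26(i: int, width: int = 4) -> str:
    letters = []
    for _ in range(width):
        letters.append(chr(ord("A") + i % 26))
        i //= 26
    return "".join(reversed(letters))


# Canonical molecule names the generator draws from (abbreviations already in
# canonical form, so a generated tree survives a parse round-trip).
_MOLECULE_POOL = (
    "GDP", "FAD", "ATP", "ADP", "GABA", "Na+", "H+", "Cl-", "Man",
    "I(1,3,4,5,6)P5", "4-Di-2-ASP", "Neu5Ac",
)

_PHOSPHO_ID = "MOD:00696"


class _FixtureFactory:
    """Deterministic entity factory exercising every grammar branch.

    Peptides are emitted in canonical, name-recoverable form: either bare
    (one chain, all coordinates unknown) or with explicit coordinates and no
    chain feature, so that generation followed by parsing is the identity.
    """

    def __init__(self, rng: random.Random):
        self.rng = rng
        self.counter = 0

    def symbol(self) -> str:
        self.counter += 1
        return _base26(self.counter) + str(self.rng.randint(1, 9))

    def bare_peptide(self, ptms: tuple[Ptm, ...] = ()) -> PeptideEntity:
        return PeptideEntity(gene_symbol=self.symbol(), ptms=ptms, chain_count=1)

    def coord_peptide(self, ptms: tuple[Ptm, ...] = ()) -> PeptideEntity:
        start = self.rng.randint(1, 400)
        end = None if self.rng.random() < 0.25 else start + self.rng.randint(1, 800)
        return PeptideEntity(
            gene_symbol=self.symbol(), start=start, end=end,
            chain_count=0, ptms=ptms,
        )

    # -- PTM recipes (listed in canonical rendering order) ------------------

    def _phospho(self, subtype, coordinate) -> Ptm:
        return Ptm(_PHOSPHO_ID, "p", subtype=subtype, coordinate=coordinate)

    def ptm_recipe(self, which: int) -> tuple[Ptm, ...]:
        rng = self.rng
        coords = sorted(rng.sample(range(1, 900), 3))
        if which == 0:  # single phospho, known site
            return (self._phospho(rng.choice(PHOSPHO_SUBTYPES), coords[0]),)
        if which == 1:  # multi-site phospho, ascending coordinates
            return tuple(
                self._phospho(rng.choice(PHOSPHO_SUBTYPES), c) for c in coords
            )
        if which == 2:  # phospho, subtype known, position unknown
            return (self._phospho(rng.choice(PHOSPHO_SUBTYPES), None),)
        if which == 3:  # phospho, nothing known
            return (self._phospho(None, None),)
        if which == 4:  # lipidation with multiplicity (no coordinate)
            return (Ptm("MOD:00440", "PalmC", multiplicity=rng.randint(2, 3)),)
        if which == 5:  # coordinate-bearing prefixes, descending coordinate
            return (Ptm("MOD:01148", "Ub", coordinate=coords[2]),
                    Ptm("MOD:00064", "AcK", coordinate=coords[0]))
        if which == 6:  # combination: lipidations then phospho last
            return (Ptm("MOD:00440", "PalmC", multiplicity=2),
                    Ptm("MOD:00068", "MyrG"),
                    self._phospho("S", coords[1]))
        return (Ptm("MOD:00068", "MyrG"),)

    def molecule(self) -> SmallMolecule:
        self.counter += 1
        if self.rng.random() < 0.6:
            # distinct via chebi id only; names repeat across the corpus
            return SmallMolecule(self.rng.choice(_MOLECULE_POOL))
        return SmallMolecule(f"metabolite-{self.counter}")

    def leaf(self, which: int | None = None) -> Entity:
        rng = self.rng
        if which is None:
            which = rng.randrange(6)
        if which == 0:
            return self.bare_peptide()
        if which == 1:
            return self.coord_peptide()
        if which == 2:
            return self.bare_peptide(self.ptm_recipe(rng.randrange(8)))
        if which == 3:
            return self.coord_peptide(self.ptm_recipe(rng.randrange(8)))
        if which == 4:
            pep = self.bare_peptide()
            return PeptideEntity(
                gene_symbol=pep.gene_symbol, chain_count=1, active_flag=True
            )
        return self.molecule()

    def _part(self, depth: int, allow_stoich: bool) -> Part:
        member = self.tree(depth)
        stoich = 1
        if allow_stoich and self.rng.random() < 0.25 and self._stoich_safe(member):
            stoich = self.rng.randint(2, 3)
        return Part(member, stoichiometry=stoich)

    @staticmethod
    def _stoich_safe(member: Entity) -> bool:
        # An "nx" count directly before a non-phospho PTM prefix reads as PTM
        # multiplicity; never put stoichiometry on such members.
        if isinstance(member, PeptideEntity) and member.ptms:
            first = member.ptms[0]
            return first.prefix == "p"
        return True

    def assembly(self, depth: int, kind: str | None = None) -> Assembly:
        rng = self.rng
        if kind is None:
            kind = rng.choice(ASSEMBLY_KINDS)
        if kind == COMPLEX:
            nparts = rng.randint(2, 4)
            parts = tuple(self._part(depth - 1, True) for _ in range(nparts))
            return Assembly(COMPLEX, parts)
        if kind == DEFINED_SET:
            nparts = rng.randint(2, 4)
            parts = tuple(self._part(depth - 1, False) for _ in range(nparts))
            return Assembly(DEFINED_SET, parts)
        members = [self._part(depth - 1, False) for _ in range(rng.randint(1, 3))]
        candidates = [
            Part(self.tree(depth - 1), is_candidate=True)
            for _ in range(rng.randint(1, 2))
        ]
        return Assembly(CANDIDATE_SET, tuple(members + candidates))

    def tree(self, depth: int) -> Entity:
        if depth > 0 and self.rng.random() < 0.45:
            return self.assembly(depth)
        return self.leaf()


# One entity per schedule slot guarantees branch coverage at modest n.
_SCHEDULE = (
    "bare", "coords", "phospho", "phospho_multi", "phospho_unknown",
    "nonphospho", "combo", "active", "molecule",
    "complex", "defined_set", "candidate_set", "nested",
)


def generate_fixture_entities(
    seed: int, n: int, max_depth: int = 2
) -> list[Entity]:
    """Generate ``n`` deterministic synthetic entities for a given seed.

    The corpus cycles through a schedule covering every grammar branch (bare
    peptides, coordinate suffixes, each PTM prefix class, assemblies of each
    kind, stoichiometry > 1, nesting up to ``max_depth``), so all branches
    are exercised whenever ``n`` is at least the schedule length.  All
    emitted peptides are non-exempt and in canonical name-recoverable form.
    """
    if n <= 0:
        raise ValidationError("generate_fixture_entities: n must be > 0")
    if max_depth < 0:
        raise ValidationError("generate_fixture_entities: max_depth must be >= 0")
    rng = random.Random(seed)
    factory = _FixtureFactory(rng)
    out: list[Entity] = []
    for i in range(n):
        slot = _SCHEDULE[i % len(_SCHEDULE)]
        if max_depth == 0 and slot in (COMPLEX, DEFINED_SET, CANDIDATE_SET, "nested"):
            slot = ("bare", "coords", "phospho", "molecule")[i % 4]
        if slot == "bare":
            out.append(factory.bare_peptide())
        elif slot == "coords":
            out.append(factory.coord_peptide())
        elif slot == "phospho":
            out.append(factory.bare_peptide(factory.ptm_recipe(0)))
        elif slot == "phospho_multi":
            out.append(factory.bare_peptide(factory.ptm_recipe(1)))
        elif slot == "phospho_unknown":
            out.append(factory.bare_peptide(factory.ptm_recipe(rng.choice((2, 3)))))
        elif slot == "nonphospho":
            out.append(factory.coord_peptide(factory.ptm_recipe(rng.choice((4, 5, 7)))))
        elif slot == "combo":
            out.append(factory.bare_peptide(factory.ptm_recipe(6)))
        elif slot == "active":
            out.append(factory.leaf(4))
        elif slot == "molecule":
            out.append(factory.molecule())
        elif slot == "nested":
            out.append(factory.assembly(max(max_depth, 1)))
        else:
            out.append(factory.assembly(1, kind=slot))
    return out


# ---------------------------------------------------------------------------
# Exhaustive small-tree enumeration (round-trip oracle input)
# ---------------------------------------------------------------------------

def default_enumeration_leaves() -> tuple[Entity, ...]:
    """The four structurally distinct leaves used for exhaustive enumeration."""
    return (
        PeptideEntity(gene_symbol="ENTA", chain_count=1),
        PeptideEntity(gene_symbol="ENTB", start=2, end=30, chain_count=0),
        PeptideEntity(
            gene_symbol="ENTC", chain_count=1,
            ptms=(Ptm(_PHOSPHO_ID, "p", subtype="Y", coordinate=12),),
        ),
        SmallMolecule("GDP"),
    )


def enumerate_fixture_trees(
    max_leaves: int = 4,
    max_depth: int = 2,
    leaves: tuple[Entity, ...] | None = None,
) -> list[Entity]:
    """Enumerate every assembly tree with at most ``max_leaves`` leaves and
    depth at most ``max_depth`` over the default leaf pool.

    Stoichiometry 2 is tried on the first slot of complexes (on members it is
    legal for), and candidate sets place a single candidate in the trailing
    slot — the shapes the grammar distinguishes.
    """
    pool = leaves if leaves is not None else default_enumeration_leaves()
    memo: dict[tuple[int, int], list[tuple[Entity, int]]] = {}

    def subtrees(depth: int, budget: int) -> list[tuple[Entity, int]]:
        key = (depth, budget)
        if key in memo:
            return memo[key]
        out: list[tuple[Entity, int]] = [(leaf, 1) for leaf in pool]
        if depth == 0 or budget < 2:
            memo[key] = out
            return out
        for nparts in range(2, min(4, budget) + 1):
            for combo in _compositions(budget, nparts):
                for members in _choices(
                    [subtrees(depth - 1, b) for b in combo]
                ):
                    ents = [m for m, _ in members]
                    used = sum(u for _, u in members)
                    parts = tuple(Part(e) for e in ents)
                    out.append((Assembly(COMPLEX, parts), used))
                    out.append((Assembly(DEFINED_SET, parts), used))
                    # candidate set: last slot is the candidate
                    cparts = parts[:-1] + (Part(ents[-1], is_candidate=True),)
                    out.append((Assembly(CANDIDATE_SET, cparts), used))
                    if _FixtureFactory._stoich_safe(ents[0]):
                        sparts = (Part(ents[0], stoichiometry=2),) + parts[1:]
                        out.append((Assembly(COMPLEX, sparts), used))
        memo[key] = out
        return out

    seen: set[Entity] = set()
    result: list[Entity] = []
    for tree, _ in subtrees(max_depth, max_leaves):
        if tree not in seen:
            seen.add(tree)
            result.append(tree)
    return result


def _compositions(total: int, nparts: int):
    """All orderings of ``nparts`` positive integers with sum <= total and
    at least 1 each (budget split among assembly slots)."""
    if nparts == 1:
        for v in range(1, total + 1):
            yield (v,)
        return
    for first in range(1, total - nparts + 2):
        for rest in _compositions(total - first, nparts - 1):
            yield (first,) + rest


def _choices(options: list[list]):
    """Cartesian product over per-slot option lists."""
    if not options:
        yield ()
        return
    for head in options[0]:
        for tail in _choices(options[1:]):
            yield (head,) + tail
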