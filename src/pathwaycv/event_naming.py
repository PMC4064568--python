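"""Classification of reactions into event categories and rendering of the
corresponding CV name templates.

A small set of event categories covers pathway reactions: transformation
(the default), binding, dissociation, polymerization/depolymerization,
catalysis and its specializations (group transfer, transport, antiport,
cotransport), catalyst-free translocation, conformational activation, and
additive regulation.  The categories overlap on raw attributes (a
transporter reaction also has a catalyst), so classification applies a
fixed precedence in which the most specific, attribute-gated classes win.

Verbs come from a GO-molecular-function lookup: an exact-match table plus a
substring fallback for the hydrolase family.  Verbs are rendered lower-case
(the CV term is case-insensitive) and pluralized when the catalyst is a set
("NMT1,2 transfer").
"""

from __future__ import annotations

import logging
from collections import Counter

from .assembly_naming import name_entity, shorten_label
from .model import (
    Assembly,
    CvName,
    DEPOLYMERIZATION,
    Entity,
    POLYMERIZATION,
    Participant,
    Reaction,
    SET_KINDS,
    ValidationError,
)
from .tables import HYDROLYSIS_SUBSTRINGS, Tables

logger = logging.getLogger("pathwaycv.events")

# Event categories.
TRANSFORMATION = "TRANSFORMATION"
BINDING = "BINDING"
DISSOCIATION = "DISSOCIATION"
CATALYSIS = "CATALYSIS"
TRANSFER = "TRANSFER"
TRANSLOCATION = "TRANSLOCATION"
TRANSPORT = "TRANSPORT"
EXCHANGE = "EXCHANGE"
COTRANSPORT = "COTRANSPORT"
ACTIVATION = "ACTIVATION"
REGULATION = "REGULATION"  # attaches to a reaction, additively

EVENT_CATEGORIES = (
    TRANSFORMATION, BINDING, DISSOCIATION, POLYMERIZATION, DEPOLYMERIZATION,
    CATALYSIS, TRANSFER, TRANSLOCATION, TRANSPORT, EXCHANGE, COTRANSPORT,
    ACTIVATION,
)


def verb_for_gomf(term: str | None, tables: Tables) -> tuple[str | None, str]:
    """Map a GO molecular function label to (verb, template).

    Exact table match first; then the hydrolase substring rule; a miss
    returns ``(None, "catalyzes")``, selecting the generic template.
    """
    if term:
        key = term.strip().casefold()
        if key in tables.gomf_verbs:
            return tables.gomf_verbs[key]
        if any(sub in key for sub in HYDROLYSIS_SUBSTRINGS):
            return ("hydrolyses", "catalyzes")
    return (None, "catalyzes")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _entity_key(entity: Entity, tables: Tables) -> str:
    # names depend only on composition, so the CV name is the identity key
    return name_entity(entity, tables, override=True).text


def _component_names(entity: Entity, tables: Tables) -> set[str]:
    """CV names of every proper constituent of ``entity`` (recursively)."""
    names: set[str] = set()
    if isinstance(entity, Assembly):
        for part in entity.parts:
            names.add(_entity_key(part.member, tables))
            names |= _component_names(part.member, tables)
    return names


def _count(participants: tuple[Participant, ...]) -> int:
    return sum(p.count for p in participants)


def classify_reaction(rxn: Reaction, tables: Tables) -> str:
    """Assign exactly one event category by fixed precedence.

    Precedence: explicit (de)polymerization class; catalyst whose GOMF
    template is exchange/cotransport/transport; catalyst-free movement of
    unchanged entities between compartments (translocation); any other
    catalyst (transfer vs generic catalysis by template); binding (more
    inputs than outputs, and an input is a component of an output — the
    same containment test that verifies stoichiometric balance);
    dissociation (the mirror image); unchanged entities in unchanged
    compartments (activation); otherwise transformation.
    """
    if rxn.explicit_class is not None:
        logger.debug("explicit class %s", rxn.explicit_class)
        return rxn.explicit_class
    if not rxn.inputs or not rxn.outputs:
        raise ValidationError(
            "reaction must have inputs and outputs unless an explicit "
            "class is set"
        )

    in_names = Counter()
    out_names = Counter()
    in_located = Counter()
    out_located = Counter()
    for p in rxn.inputs:
        key = _entity_key(p.entity, tables)
        in_names[key] += p.count
        in_located[(key, p.compartment, p.cell_type)] += p.count
    for p in rxn.outputs:
        key = _entity_key(p.entity, tables)
        out_names[key] += p.count
        out_located[(key, p.compartment, p.cell_type)] += p.count

    if rxn.catalyst is not None:
        _, template = verb_for_gomf(rxn.catalyst_gomf, tables)
        if template == "exchanges":
            return EXCHANGE
        if template == "cotransports":
            return COTRANSPORT
        if template == "transports":
            return TRANSPORT
        if template == "transfers":
            return TRANSFER
    elif in_names == out_names and in_located != out_located:
        return TRANSLOCATION

    if rxn.catalyst is not None:
        return CATALYSIS

    n_in, n_out = _count(rxn.inputs), _count(rxn.outputs)
    if n_in > n_out and any(
        in_name in _component_names(p.entity, tables)
        for in_name in in_names
        for p in rxn.outputs
    ):
        return BINDING
    if n_out > n_in and any(
        out_name in _component_names(p.entity, tables)
        for out_name in out_names
        for p in rxn.inputs
    ):
        return DISSOCIATION
    if in_located == out_located:
        return ACTIVATION
    return TRANSFORMATION


# ---------------------------------------------------------------------------
# Name rendering
# ---------------------------------------------------------------------------

def _series(items: list[str]) -> str:
    """Join as "a", "a and b", "a, b and c"."""
    if not items:
        return ""
    if len(items) == 1:
        return items[0]
    return ", ".join(items[:-1]) + " and " + items[-1]


def _participant_text(p: Participant, tables: Tables, *, tight_count=False) -> str:
    name = _entity_key(p.entity, tables)
    if p.count > 1:
        return f"{p.count}{name}" if tight_count else f"{p.count}x{name}"
    return name


def _plist(participants, tables, *, tight_count=False) -> str:
    return _series(
        [_participant_text(p, tables, tight_count=tight_count)
         for p in participants]
    )


def _catalyst_text(rxn: Reaction, tables: Tables) -> tuple[str, bool]:
    """Catalyst display name (diagram short label for sets) and set-ness."""
    cat = rxn.catalyst
    if cat is None:
        raise ValidationError("this event category requires a catalyst")
    if isinstance(cat, Assembly) and cat.kind in SET_KINDS:
        return shorten_label(cat, tables), True
    return _entity_key(cat, tables), False


def _pluralize(verb: str, plural: bool) -> str:
    return verb[:-1] if plural and verb.endswith("s") else verb


def _compartment(p: Participant) -> str | None:
    if p.compartment is None:
        return None
    if p.cell_type is not None:
        return f"{p.compartment} of {p.cell_type}"
    return p.compartment


def name_reaction(rxn: Reaction, category: str, tables: Tables) -> CvName:
    """Fill the category's CV template with entity names.

    ``category`` must be the classification of ``rxn``.  Verbs are
    lower-case; entity lists join as "a, b and c"; optional clauses
    (compartments, the "to form" product) appear when the data carries
    them.
    """
    inputs, outputs = rxn.inputs, rxn.outputs

    if category == TRANSFORMATION:
        text = f"{_plist(inputs, tables)} transforms to {_plist(outputs, tables)}"
    elif category == BINDING:
        head = _participant_text(inputs[0], tables)
        rest = _plist(inputs[1:], tables)
        text = f"{head} binds {rest} forming {_plist(outputs, tables)}"
    elif category == DISSOCIATION:
        text = f"{_plist(inputs, tables)} dissociates to {_plist(outputs, tables)}"
    elif category == POLYMERIZATION:
        text = f"{_plist(inputs, tables)} polymerize to {_plist(outputs, tables)}"
    elif category == DEPOLYMERIZATION:
        text = f"{_plist(inputs, tables)} depolymerizes to {_plist(outputs, tables)}"
    elif category in (CATALYSIS, TRANSFER, TRANSPORT, EXCHANGE, COTRANSPORT):
        text = _catalyzed_text(rxn, category, tables)
    elif category == TRANSLOCATION:
        here, there = _compartment(inputs[0]), _compartment(outputs[0])
        text = (
            f"{_participant_text(inputs[0], tables)} translocates "
            f"from [{here}] to [{there}]"
        )
    elif category == ACTIVATION:
        copula = "is" if len(inputs) == 1 and inputs[0].count == 1 else "are"
        text = f"{_plist(inputs, tables)} {copula} activated"
    else:
        raise ValidationError(f"unknown event category {category!r}")

    return CvName(text=text, source=rxn)


def _catalyzed_text(rxn: Reaction, category: str, tables: Tables) -> str:
    catalyst, is_set = _catalyst_text(rxn, tables)
    verb, _template = verb_for_gomf(rxn.catalyst_gomf, tables)

    if category == CATALYSIS:
        verb = _pluralize(verb or "catalyzes", is_set)
        text = f"{catalyst} {verb} {_plist(rxn.inputs, tables)}"
        if not rxn.omit_product:
            text += f" to {_plist(rxn.outputs, tables)}"
        return text

    if category == TRANSFER:
        if rxn.transfer_group is None or rxn.transfer_acceptor is None:
            raise ValidationError(
                "a transfer event needs transfer_group and transfer_acceptor"
            )
        verb = _pluralize(verb or "transfers", is_set)
        text = (
            f"{catalyst} {verb} "
            f"{_entity_key(rxn.transfer_group, tables)} to "
            f"{_entity_key(rxn.transfer_acceptor, tables)}"
        )
        if rxn.transfer_product is not None and not rxn.omit_product:
            text += f" (to form {_entity_key(rxn.transfer_product, tables)})"
        return text

    if category == TRANSPORT:
        verb = _pluralize(verb or "transports", is_set)
        text = f"{catalyst} {verb} {_plist(rxn.inputs, tables)}"
        here, there = _compartment(rxn.inputs[0]), _compartment(rxn.outputs[0])
        if here is not None and there is not None and here != there:
            text += f" (from {here} to {there})"
        return text

    if category == EXCHANGE:
        if len(rxn.inputs) < 2:
            raise ValidationError("an exchange event needs two input entities")
        verb = _pluralize(verb or "exchanges", is_set)
        a = _participant_text(rxn.inputs[0], tables, tight_count=True)
        b = _participant_text(rxn.inputs[1], tables, tight_count=True)
        text = f"{catalyst} {verb} {a} for {b}"
        if rxn.membrane is not None:
            text += f" (across the {rxn.membrane} membrane)"
        return text

    # COTRANSPORT: first input is the cargo, the rest move with it
    if len(rxn.inputs) < 2:
        raise ValidationError("a cotransport event needs at least two inputs")
    verb = _pluralize(verb or "cotransports", is_set)
    cargo = _participant_text(rxn.inputs[0], tables, tight_count=True)
    with_ = _plist(rxn.inputs[1:], tables, tight_count=True)
    return f"{catalyst} {verb} {cargo} with {with_}"


def regulation_sentence(rxn: Reaction, event_text: str, tables: Tables) -> str | None:
    """The additive "a positively/negatively regulates x" statement, or None."""
    if rxn.regulator is None:
        return None
    sign = "positively" if rxn.regulator_sign == "positive" else "negatively"
    return f"{_entity_key(rxn.regulator, tables)} {sign} regulates {event_text}"
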