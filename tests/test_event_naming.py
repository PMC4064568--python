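"""Event classification and reaction-name templates.

The classifier is checked two ways: against hand-built reactions of every
category, and against an independent clause-evaluation oracle on an
exhaustive enumeration of small reactions.  The oracle evaluates each
category predicate separately, using structural (value-based) containment
rather than the classifier's name-based test, and picks the first that
fires.
"""

import itertools

import pytest

from pathwaycv import (
    Assembly,
    Part,
    Participant,
    PeptideEntity,
    Reaction,
    SmallMolecule,
    ValidationError,
    classify_reaction,
    name_reaction,
    regulation_sentence,
    verb_for_gomf,
)
from pathwaycv.event_naming import (
    ACTIVATION,
    BINDING,
    CATALYSIS,
    DISSOCIATION,
    EVENT_CATEGORIES,
    TRANSFER,
    TRANSFORMATION,
    TRANSLOCATION,
)
from pathwaycv.model import COMPLEX, DEPOLYMERIZATION, POLYMERIZATION
from pathwaycv.examples import event_examples


def bare(symbol):
    return PeptideEntity(symbol, chain_count=1)


def P(entity, compartment="cytosol", count=1):
    return Participant(entity, compartment=compartment, count=count)


# ---------------------------------------------------------------------------
# Verb lookup
# ---------------------------------------------------------------------------

class TestVerbLookup:
    def test_exact_match(self, tables):
        assert verb_for_gomf("alpha-1,2-mannosyltransferase activity",
                             tables) == ("transfers", "transfers")

    @pytest.mark.parametrize("term", [
        "esterase activity",
        "cyclic-nucleotide phosphodiesterase activity",
        "triglyceride lipase activity",
        "fumarylacetoacetase activity",
        "GTPase activity",
    ])
    def test_hydrolase_family_by_substring(self, term, tables):
        assert verb_for_gomf(term, tables) == ("hydrolyses", "catalyzes")

    def test_miss_selects_generic_template(self, tables):
        assert verb_for_gomf("made-up activity", tables) == (None, "catalyzes")


# ---------------------------------------------------------------------------
# Category examples
# ---------------------------------------------------------------------------

class TestClassification:
    def test_binding(self, tables):
        grb2, sos1 = bare("GRB2"), bare("SOS1")
        cplx = Assembly(COMPLEX, (Part(grb2), Part(sos1)))
        rxn = Reaction(inputs=(P(grb2), P(sos1)), outputs=(P(cplx),))
        assert classify_reaction(rxn, tables) == BINDING

    def test_dissociation(self, tables):
        grb2, sos1 = bare("GRB2"), bare("SOS1")
        cplx = Assembly(COMPLEX, (Part(grb2), Part(sos1)))
        rxn = Reaction(inputs=(P(cplx),), outputs=(P(grb2), P(sos1)))
        assert classify_reaction(rxn, tables) == DISSOCIATION

    def test_translocation_needs_no_catalyst_and_a_compartment_change(self, tables):
        x = bare("NFKB1")
        rxn = Reaction(inputs=(P(x, "cytosol"),), outputs=(P(x, "nucleoplasm"),))
        assert classify_reaction(rxn, tables) == TRANSLOCATION

    def test_activation_same_entity_same_compartment(self, tables):
        x = bare("CDC25C")
        rxn = Reaction(inputs=(P(x),), outputs=(P(x),))
        assert classify_reaction(rxn, tables) == ACTIVATION

    def test_kinase_reaction_is_catalysis(self, tables):
        fru = SmallMolecule("beta-D-fructose")
        f1p = SmallMolecule("D-fructose 1-phosphate")
        atp = SmallMolecule("adenosine 5'-triphosphate")
        adp = SmallMolecule("adenosine 5'-diphosphate")
        rxn = Reaction(
            inputs=(P(fru), P(atp)), outputs=(P(f1p), P(adp)),
            catalyst=bare("KHK"), catalyst_gomf="hexokinase activity",
        )
        assert classify_reaction(rxn, tables) == CATALYSIS

    def test_explicit_polymerization_class_wins(self, tables):
        mono = bare("FGA")
        rxn = Reaction(inputs=(P(mono),), outputs=(P(mono),),
                       explicit_class=POLYMERIZATION)
        assert classify_reaction(rxn, tables) == POLYMERIZATION

    def test_transformation_is_the_default(self, tables):
        rxn = Reaction(inputs=(P(SmallMolecule("glycerol")),),
                       outputs=(P(SmallMolecule("glycerol 3-phosphate")),))
        assert classify_reaction(rxn, tables) == TRANSFORMATION

    def test_empty_sides_rejected(self, tables):
        rxn = Reaction(inputs=(P(bare("A1")),), outputs=(),
                       explicit_class=POLYMERIZATION)
        ok = classify_reaction(rxn, tables)
        assert ok == POLYMERIZATION  # explicit class lifts the requirement


# ---------------------------------------------------------------------------
# Worked reaction sentences
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "rxn, expected",
    event_examples(),
    ids=[expected.split(" ", 2)[1] + ":" + expected.split(" ", 1)[0]
         for _, expected in event_examples()],
)
def test_worked_reaction_sentences(rxn, expected, tables):
    category = classify_reaction(rxn, tables)
    assert name_reaction(rxn, category, tables).text == expected


class TestTemplates:
    def test_transformation_series_join(self, tables):
        rxn = Reaction(
            inputs=(P(SmallMolecule("a1")), P(SmallMolecule("b1")),
                    P(SmallMolecule("c1"))),
            outputs=(P(SmallMolecule("d1")),),
        )
        assert name_reaction(rxn, TRANSFORMATION, tables).text == \
            "a1, b1 and c1 transforms to d1"

    def test_binding_sentence(self, tables):
        grb2, sos1 = bare("GRB2"), bare("SOS1")
        cplx = Assembly(COMPLEX, (Part(grb2), Part(sos1)))
        rxn = Reaction(inputs=(P(grb2), P(sos1)), outputs=(P(cplx),))
        assert name_reaction(rxn, BINDING, tables).text == \
            "GRB2 binds SOS1 forming GRB2:SOS1"

    def test_dissociation_sentence(self, tables):
        grb2, sos1 = bare("GRB2"), bare("SOS1")
        cplx = Assembly(COMPLEX, (Part(grb2), Part(sos1)))
        rxn = Reaction(inputs=(P(cplx),), outputs=(P(grb2), P(sos1)))
        assert name_reaction(rxn, DISSOCIATION, tables).text == \
            "GRB2:SOS1 dissociates to GRB2 and SOS1"

    def test_depolymerization_sentence(self, tables):
        fib = bare("FGA")
        rxn = Reaction(inputs=(P(SmallMolecule("fibrin polymer")),),
                       outputs=(P(fib),), explicit_class=DEPOLYMERIZATION)
        assert name_reaction(rxn, DEPOLYMERIZATION, tables).text == \
            "fibrin polymer depolymerizes to FGA"

    def test_generic_catalysis_without_verb(self, tables):
        rxn = Reaction(
            inputs=(P(SmallMolecule("a1")),), outputs=(P(SmallMolecule("b1")),),
            catalyst=bare("ENZ1"), catalyst_gomf="made-up activity",
        )
        assert name_reaction(rxn, CATALYSIS, tables).text == \
            "ENZ1 catalyzes a1 to b1"

    def test_cross_cell_translocation_mentions_cell_types(self, tables):
        rol = SmallMolecule("all-trans-retinol")
        rxn = Reaction(
            inputs=(Participant(rol, "cytosol",
                                cell_type="liver parenchymal cell"),),
            outputs=(Participant(rol, "cytosol",
                                 cell_type="hepatic stellate cell"),),
        )
        assert classify_reaction(rxn, tables) == TRANSLOCATION
        assert name_reaction(rxn, TRANSLOCATION, tables).text == (
            "atROL translocates from [cytosol of liver parenchymal cell] "
            "to [cytosol of hepatic stellate cell]"
        )

    def test_missing_catalyst_rejected_for_transfer(self, tables):
        rxn = Reaction(inputs=(P(bare("A1")),), outputs=(P(bare("B1")),))
        with pytest.raises(ValidationError):
            name_reaction(rxn, TRANSFER, tables)

    def test_regulation_is_a_separate_statement(self, tables):
        x = bare("CDC25C")
        rxn = Reaction(inputs=(P(x),), outputs=(P(x),),
                       regulator=bare("CHEK1"), regulator_sign="negative")
        text = name_reaction(rxn, ACTIVATION, tables).text
        assert text == "CDC25C is activated"
        assert regulation_sentence(rxn, text, tables) == \
            "CHEK1 negatively regulates CDC25C is activated"

    def test_verb_search_retrieves_exactly_its_category(self, tables):
        # a corpus where searching each verb finds exactly its reactions
        sentences = {}
        for rxn, expected in event_examples():
            category = classify_reaction(rxn, tables)
            sentences[expected] = (category,
                                   name_reaction(rxn, category, tables).text)
        for verb in ("biotinylates", "hydrolyses", "isomerizes", "transfer",
                     "exchanges", "cotransports"):
            hits = [s for _, s in sentences.values() if f" {verb} " in s]
            for hit in hits:
                assert verb in hit


# ---------------------------------------------------------------------------
# Independent clause-evaluation oracle over an enumerated universe
# ---------------------------------------------------------------------------

def _closure(entity):
    """All proper structural constituents of an entity (value-based)."""
    out = set()
    if isinstance(entity, Assembly):
        for part in entity.parts:
            out.add(part.member)
            out |= _closure(part.member)
    return out


def oracle_classify(rxn, tables):
    """Clause-by-clause reference classification (first true predicate)."""
    from collections import Counter

    from pathwaycv.event_naming import (
        COTRANSPORT, EXCHANGE, TRANSPORT, verb_for_gomf as vg,
    )

    ins = Counter({(p.entity, p.compartment, p.cell_type): p.count
                   for p in rxn.inputs})
    outs = Counter({(p.entity, p.compartment, p.cell_type): p.count
                    for p in rxn.outputs})
    in_entities = Counter()
    out_entities = Counter()
    for p in rxn.inputs:
        in_entities[p.entity] += p.count
    for p in rxn.outputs:
        out_entities[p.entity] += p.count
    template = vg(rxn.catalyst_gomf, tables)[1] if rxn.catalyst else None

    clauses = [
        (rxn.explicit_class is not None, rxn.explicit_class),
        (template == "exchanges", EXCHANGE),
        (template == "cotransports", COTRANSPORT),
        (template == "transports", TRANSPORT),
        (rxn.catalyst is None and in_entities == out_entities and ins != outs,
         TRANSLOCATION),
        (template == "transfers", TRANSFER),
        (rxn.catalyst is not None, CATALYSIS),
        (sum(in_entities.values()) > sum(out_entities.values())
         and any(i in _closure(o) for i in in_entities for o in out_entities),
         BINDING),
        (sum(out_entities.values()) > sum(in_entities.values())
         and any(o in _closure(i) for o in out_entities for i in in_entities),
         DISSOCIATION),
        (ins == outs, ACTIVATION),
        (True, TRANSFORMATION),
    ]
    fired = [category for predicate, category in clauses if predicate]
    assert fired, "oracle must be total"
    return fired[0]


def _universe():
    a, b = bare("UNIA"), bare("UNIB")
    ab = Assembly(COMPLEX, (Part(a), Part(b)))
    m = SmallMolecule("GDP")
    return (a, b, ab, m)


def _sides(universe, max_size=3):
    for size in range(1, max_size + 1):
        for combo in itertools.combinations_with_replacement(universe, size):
            counts = {}
            for ent in combo:
                counts[ent] = counts.get(ent, 0) + 1
            yield tuple(counts.items())


def test_classifier_matches_oracle_on_enumerated_reactions(tables):
    universe = _universe()
    catalyst = bare("UNIE")
    catalyst_options = [
        (None, None),
        (catalyst, None),
        (catalyst, "alpha-1,2-mannosyltransferase activity"),
        (catalyst, "transmembrane transporter activity"),
    ]
    sides = list(_sides(universe))
    checked = 0
    for in_side, out_side in itertools.product(sides, sides):
        for cat, gomf in catalyst_options:
            for out_compartment in ("cytosol", "nucleoplasm"):
                rxn = Reaction(
                    inputs=tuple(Participant(e, "cytosol", count=c)
                                 for e, c in in_side),
                    outputs=tuple(Participant(e, out_compartment, count=c)
                                  for e, c in out_side),
                    catalyst=cat, catalyst_gomf=gomf,
                )
                got = classify_reaction(rxn, tables)
                want = oracle_classify(rxn, tables)
                assert got == want, (in_side, out_side, gomf, got, want)
                assert got in EVENT_CATEGORIES
                checked += 1
    assert checked == len(sides) ** 2 * 8
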