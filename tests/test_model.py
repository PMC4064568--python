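"""Domain types, document round-trip and the synthetic fixture generator."""

import json

import pytest

from pathwaycv import (
    Assembly,
    DocumentError,
    Part,
    Participant,
    PeptideEntity,
    Ptm,
    Reaction,
    SmallMolecule,
    ValidationError,
    document_from_entities,
    generate_fixture_entities,
    read_entity_document,
    write_entity_document,
)
from pathwaycv.model import CANDIDATE_SET, COMPLEX, DEFINED_SET


class TestInvariants:
    def test_start_after_end_rejected(self):
        with pytest.raises(ValidationError):
            PeptideEntity("CASP9", start=316, end=315)

    def test_multiplicity_requires_unknown_coordinate(self):
        with pytest.raises(ValidationError):
            Ptm("MOD:00440", "PalmC", coordinate=15, multiplicity=2)

    def test_subtype_letters_restricted(self):
        with pytest.raises(ValidationError):
            Ptm("MOD:00696", "p", subtype="Q")

    def test_candidate_set_needs_both_member_kinds(self):
        pep = PeptideEntity("HRH2")
        with pytest.raises(ValidationError):
            Assembly(CANDIDATE_SET, (Part(pep, is_candidate=True),))
        with pytest.raises(ValidationError):
            Assembly(CANDIDATE_SET, (Part(pep),))

    def test_candidates_only_in_candidate_sets(self):
        pep = PeptideEntity("HRH2")
        with pytest.raises(ValidationError):
            Assembly(DEFINED_SET, (Part(pep, is_candidate=True),))

    def test_reaction_needs_both_sides_without_explicit_class(self):
        with pytest.raises(ValidationError):
            Reaction(inputs=(Participant(PeptideEntity("A1")),), outputs=())
        # but an explicit polymerization class lifts the requirement
        Reaction(inputs=(Participant(PeptideEntity("A1")),), outputs=(),
                 explicit_class="POLYMERIZATION")


class TestFixtureGenerator:
    def test_deterministic_for_fixed_seed(self):
        a = generate_fixture_entities(seed=1, n=50, max_depth=2)
        b = generate_fixture_entities(seed=1, n=50, max_depth=2)
        assert a == b

    def test_depth_zero_forces_leaves(self):
        for ent in generate_fixture_entities(seed=1, n=10, max_depth=0):
            assert not isinstance(ent, Assembly)

    def test_different_seeds_differ(self):
        assert generate_fixture_entities(2, 30) != generate_fixture_entities(3, 30)

    def test_every_grammar_branch_is_exercised(self):
        corpus = generate_fixture_entities(seed=2, n=200, max_depth=3)

        def walk(ent):
            yield ent
            if isinstance(ent, Assembly):
                for part in ent.parts:
                    yield part
                    yield from walk(part.member)

        nodes = [n for ent in corpus for n in walk(ent)]
        assert any(isinstance(n, Assembly) and n.kind == CANDIDATE_SET
                   for n in nodes)
        assert any(isinstance(n, Part) and n.stoichiometry > 1 for n in nodes)
        assert any(
            isinstance(n, PeptideEntity) and any(m.prefix == "p" for m in n.ptms)
            for n in nodes
        )
        assert any(isinstance(n, SmallMolecule) for n in nodes)
        assert any(isinstance(n, Assembly) and n.kind == COMPLEX for n in nodes)
        # nesting actually occurs
        assert any(
            isinstance(n, Assembly)
            and any(isinstance(p.member, Assembly) for p in n.parts)
            for n in nodes
        )


class TestDocumentRoundTrip:
    def test_empty_document(self, tmp_path):
        path = tmp_path / "empty.json"
        write_entity_document(document_from_entities([]), path)
        doc = read_entity_document(path)
        assert doc.entities == {} and doc.reactions == {}

    def test_fixture_corpus_roundtrips(self, tmp_path):
        entities = generate_fixture_entities(seed=1, n=50, max_depth=2)
        doc = document_from_entities(entities, aliases={0: "old name"})
        path = tmp_path / "corpus.json"
        write_entity_document(doc, path)
        back = read_entity_document(path)
        assert back.root_entities() == entities
        assert back.aliases == doc.aliases
        assert back.entities == doc.entities

    def test_reactions_roundtrip(self, tmp_path):
        a, b = PeptideEntity("GRB2"), PeptideEntity("SOS1")
        cplx = Assembly(COMPLEX, (Part(a), Part(b)))
        rxn = Reaction(
            inputs=(Participant(a, "cytosol"), Participant(b, "cytosol")),
            outputs=(Participant(cplx, "cytosol"),),
            regulator=PeptideEntity("CBL1"), regulator_sign="negative",
        )
        doc = document_from_entities([a, b, cplx], [rxn])
        path = tmp_path / "rxn.json"
        write_entity_document(doc, path)
        assert read_entity_document(path).reactions == doc.reactions

    def test_shared_subcomplex_serialized_once(self, tmp_path):
        sub = Assembly(COMPLEX, (Part(PeptideEntity("ABC1")),
                                 Part(PeptideEntity("ABC2"))))
        outer = Assembly(COMPLEX, (Part(sub), Part(sub)))
        doc = document_from_entities([outer])
        assert sum(1 for e in doc.entities.values() if e == sub) == 1

    def test_invalid_coordinates_rejected_with_field_name(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({
            "schema_version": 1,
            "entities": [{"id": "e1", "type": "peptide",
                          "gene_symbol": "CASP9", "start": 316, "end": 315}],
        }))
        with pytest.raises(DocumentError, match="entities\\[0\\]"):
            read_entity_document(path)

    def test_unknown_reference_rejected(self, tmp_path):
        path = tmp_path / "badref.json"
        path.write_text(json.dumps({
            "schema_version": 1,
            "entities": [{"id": "e1", "type": "assembly", "kind": "complex",
                          "parts": [{"ref": "nope"}]}],
        }))
        with pytest.raises(DocumentError, match="nope"):
            read_entity_document(path)

    def test_cyclic_assembly_rejected(self, tmp_path):
        path = tmp_path / "cycle.json"
        path.write_text(json.dumps({
            "schema_version": 1,
            "entities": [
                {"id": "e1", "type": "assembly", "kind": "complex",
                 "parts": [{"ref": "e2"}]},
                {"id": "e2", "type": "assembly", "kind": "complex",
                 "parts": [{"ref": "e1"}]},
            ],
        }))
        with pytest.raises(DocumentError, match="cyclic"):
            read_entity_document(path)
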