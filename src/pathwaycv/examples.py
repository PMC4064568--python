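"""Worked examples of the controlled vocabulary, as structured fixtures.

Each function pairs an entity (or reaction) built from the domain model
with the CV name it must render to, byte for byte.  The corpus doubles as
executable documentation of the naming rules and as a regression suite:
caspase-9 cleavage products, multi-site phosphorylations, the doubly
palmitoylated/myristoylated NOS3 fragment, nested complex bracketing,
candidate sets, family diagram labels, and one reaction per event template
(biotinylation, hydrolysis, isomerization, two group transfers, antiport
and two cotransports).
"""

from __future__ import annotations

from .model import (
    Assembly,
    CANDIDATE_SET,
    COMPLEX,
    DEFINED_SET,
    Entity,
    Part,
    Participant,
    PeptideEntity,
    Ptm,
    Reaction,
    SmallMolecule,
)

_P = "MOD:00696"  # phosphorylated residue


def _bare(symbol: str, **kw) -> PeptideEntity:
    return PeptideEntity(gene_symbol=symbol, chain_count=1, **kw)


def _phos(subtype: str | None, coord: int | None) -> Ptm:
    return Ptm(_P, "p", subtype=subtype, coordinate=coord)


def peptide_examples() -> list[tuple[PeptideEntity, str]]:
    """Peptide fixtures and their expected CV names."""
    return [
        # the precursor coincides with the single chain: no suffix
        (PeptideEntity("CASP9", start=1, end=416, chain_start=1,
                       chain_end=416, chain_count=1), "CASP9"),
        # cleavage products keep chain-frame coordinates
        (PeptideEntity("CASP9", start=1, end=315, chain_start=1,
                       chain_end=416, chain_count=1), "CASP9(1-315)"),
        (PeptideEntity("CASP9", start=316, end=416, chain_start=1,
                       chain_end=416, chain_count=1), "CASP9(316-416)"),
        # second cleavage at an unknown site
        (PeptideEntity("ACAN", start=17, end=None, chain_start=17,
                       chain_end=2415, chain_count=1), "ACAN(17-?)"),
        (_bare("DAPP1", ptms=(_phos("Y", 139),)), "p-Y139-DAPP1"),
        # ordering is by coordinate, not grouped by subtype (input scrambled)
        (_bare("WASF2", ptms=(_phos("S", 343), _phos("Y", 150),
                              _phos("T", 346))), "p-Y150,S343,T346-WASF2"),
        (_bare("SPRY2", ptms=(_phos("S", 112), _phos("Y", 227),
                              _phos("Y", 55), _phos("S", 121))),
         "p-Y55,S112,S121,Y227-SPRY2"),
        (_bare("GAB2", ptms=(_phos("Y", None),)), "p-Y-GAB2"),
        (_bare("GLI3", ptms=(_phos(None, None),)), "p-GLI3"),
        # lipidations first, phosphorylation after everything else
        (PeptideEntity(
            "NOS3", start=2, end=1203, chain_start=1, chain_end=1203,
            chain_count=1,
            ptms=(Ptm("MOD:00440", "PalmC", multiplicity=2),
                  Ptm("MOD:00068", "MyrG"),
                  _phos("S", 1177))),
         "2xPalmC-MyrG-p-S1177-NOS3(2-1203)"),
    ]


def _complex(*members: Entity | Part) -> Assembly:
    parts = tuple(m if isinstance(m, Part) else Part(m) for m in members)
    return Assembly(COMPLEX, parts)


def assembly_examples() -> list[tuple[Assembly, str]]:
    """Complex/set fixtures and their expected CV names."""
    grb2, sos1 = _bare("GRB2"), _bare("SOS1")
    ab12 = _complex(_bare("ABC1"), _bare("ABC2"))
    ab34 = _complex(_bare("ABC3"), _bare("ABC4"))
    nested = _complex(ab12, ab34)
    with_xyz = _complex(nested, _bare("XYZ1"))
    with_mno = _complex(with_xyz, _bare("MNO1"))
    hrh_one_candidate = Assembly(CANDIDATE_SET, (
        Part(_bare("HRH2")), Part(_bare("HRH3")),
        Part(_bare("HRH6"), is_candidate=True),
    ))
    return [
        (_complex(grb2, sos1), "GRB2:SOS1"),
        (_complex(_bare("IL3"), _bare("IL3RA"), _bare("IL3RB"), _bare("JAK2")),
         "IL3:IL3RA:IL3RB:JAK2"),
        (_complex(Part(_bare("PPOX"), stoichiometry=2),
                  SmallMolecule("flavin adenine dinucleotide")),
         "2xPPOX:FAD"),
        (Assembly(DEFINED_SET, tuple(Part(_bare(s)) for s in
                                     ("IL3", "IL3RA", "CSF2RB"))),
         "IL3,IL3RA,CSF2RB"),
        (Assembly(CANDIDATE_SET, (
            Part(_bare("HRH2")), Part(_bare("HRH3")),
            Part(_bare("HRH6"), is_candidate=True),
            Part(_bare("HRH8"), is_candidate=True),
        )), "HRH2,HRH3,(HRH6,HRH8)"),
        (nested, "[ABC1:ABC2]:[ABC3:ABC4]"),
        (with_xyz, "[[ABC1:ABC2]:[ABC3:ABC4]]:XYZ1"),
        (with_mno, "[[[ABC1:ABC2]:[ABC3:ABC4]]:XYZ1]:MNO1"),
        (_complex(with_mno, hrh_one_candidate),
         "[[[[ABC1:ABC2]:[ABC3:ABC4]]:XYZ1]:MNO1]:[HRH2,HRH3,(HRH6)]"),
    ]


def label_examples() -> list[tuple[Assembly, bool, str]]:
    """(set, complete_family flag, expected diagram label)."""

    def family(*symbols: str) -> Assembly:
        return Assembly(DEFINED_SET, tuple(Part(_bare(s)) for s in symbols))

    return [
        (family("VAV1", "VAV2", "VAV3"), True, "VAVs"),
        (family("CCR1", "CCR2", "CCR3", "CCR4", "CCR5"), False, "CCR1-5"),
        (family("CCR1", "CCR3", "CCR4", "CCR5"), False, "CCR1,3-5"),
    ]


def _mol(name: str) -> SmallMolecule:
    return SmallMolecule(name)


def _pp(entity: Entity, compartment: str | None = None, count: int = 1):
    return Participant(entity, compartment=compartment, count=count)


def event_examples() -> list[tuple[Reaction, str]]:
    """Reaction fixtures and their expected event CV names."""
    examples: list[tuple[Reaction, str]] = []

    acaca = _bare("ACACA")
    examples.append((
        Reaction(
            inputs=(_pp(acaca),),
            outputs=(_pp(_mol("biotinyl-ACACA")),),
            catalyst=_bare("HLCS"),
            catalyst_gomf="biotin-protein ligase activity",
            omit_product=True,
        ),
        "HLCS biotinylates ACACA",
    ))

    examples.append((
        Reaction(
            inputs=(_pp(_mol("retinyl palmitate")),),
            outputs=(_pp(_mol("all-trans-retinol")),),
            catalyst=_bare("PLB1"),
            catalyst_gomf="lysophospholipase activity",  # hydrolase family
        ),
        "PLB1 hydrolyses RPALM to atROL",
    ))

    examples.append((
        Reaction(
            inputs=(_pp(_mol("prostaglandin H2")),),
            outputs=(_pp(_mol("prostaglandin D2")),),
            catalyst=_bare("PTGDS"),
            catalyst_gomf="prostaglandin-D synthase activity",
        ),
        "PTGDS isomerizes PGH2 to PGD2",
    ))

    glycan6 = _mol("(GlcNAc)2 (Man)6 (PP-Dol)1")
    glycan7 = _mol("(GlcNAc)2 (Man)7 (PP-Dol)1")
    examples.append((
        Reaction(
            inputs=(_pp(_mol("dolichyl phosphate D-mannose")), _pp(glycan6)),
            outputs=(_pp(glycan7),),
            catalyst=_bare("ALG9"),
            catalyst_gomf="alpha-1,2-mannosyltransferase activity",
            transfer_group=_mol("alpha-D-mannose"),
            transfer_acceptor=glycan6,
            transfer_product=glycan7,
        ),
        "ALG9 transfers Man to (GlcNAc)2 (Man)6 (PP-Dol)1 "
        "(to form (GlcNAc)2 (Man)7 (PP-Dol)1)",
    ))

    gnat1 = _bare("GNAT1")
    myristoylated = _mol("N-(C14:0)-GNAT1")
    examples.append((
        Reaction(
            inputs=(_pp(_mol("myristoyl-CoA")), _pp(gnat1)),
            outputs=(_pp(myristoylated),),
            catalyst=Assembly(DEFINED_SET, (Part(_bare("NMT1")),
                                            Part(_bare("NMT2")))),
            catalyst_gomf="glycylpeptide N-tetradecanoyltransferase activity",
            transfer_group=_mol("tetradecanoic acid"),
            transfer_acceptor=gnat1,
            transfer_product=myristoylated,
        ),
        "NMT1,2 transfer MYS to GNAT1 (to form N-(C14:0)-GNAT1)",
    ))

    sodium, proton = _mol("sodium(1+)"), _mol("hydron")
    examples.append((
        Reaction(
            inputs=(_pp(sodium, "late endosome lumen"), _pp(proton, "cytosol")),
            outputs=(_pp(sodium, "cytosol"), _pp(proton, "late endosome lumen")),
            catalyst=_bare("SLC9A9"),
            catalyst_gomf="sodium:proton antiporter activity",
            membrane="late endosome",
        ),
        "SLC9A9 exchanges Na+ for H+ (across the late endosome membrane)",
    ))

    neu5ac = _mol("N-acetylneuraminic acid")
    examples.append((
        Reaction(
            inputs=(_pp(neu5ac, "lysosomal lumen"), _pp(proton, "lysosomal lumen")),
            outputs=(_pp(neu5ac, "cytosol"), _pp(proton, "cytosol")),
            catalyst=_bare("SLC17A5"),
            catalyst_gomf="sialic acid:proton symporter activity",
        ),
        "SLC17A5 cotransports Neu5Ac with H+",
    ))

    gaba, chlorine = _mol("4-aminobutanoic acid"), _mol("chloride")
    examples.append((
        Reaction(
            inputs=(_pp(gaba, "extracellular region"),
                    _pp(sodium, "extracellular region", count=3),
                    _pp(chlorine, "extracellular region", count=2)),
            outputs=(_pp(gaba, "cytosol"), _pp(sodium, "cytosol", count=3),
                     _pp(chlorine, "cytosol", count=2)),
            catalyst=_bare("SLC6A12"),
            catalyst_gomf=(
                "gamma-aminobutyric acid:sodium:chloride symporter activity"),
        ),
        "SLC6A12 cotransports GABA with 3Na+ and 2Cl-",
    ))

    return examples
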