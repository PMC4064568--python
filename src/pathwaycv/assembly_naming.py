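"""Recursive CV names for complexes and sets.

Composition is concatenation: ``:`` separates complex components, ``,``
separates set members, candidates sit in one trailing round-bracket group,
and a member that is itself a multi-part assembly is wrapped in square
brackets so that assembly history stays unambiguous
(``[ABC1:ABC2]:[ABC3:ABC4]`` is not ``[ABC1:ABC2:ABC3]:ABC4``).

Also provides the diagram-label shortener (stem plurals and integer-range
compression for protein-family sets).
"""

from __future__ import annotations

import re

from .model import (
    Assembly,
    CANDIDATE_SET,
    COMPLEX,
    CvName,
    Entity,
    PeptideEntity,
    SmallMolecule,
    StructureError,
)
from .molecule_naming import name_molecule
from .peptide_naming import name_peptide
from .tables import Tables


def name_entity(entity: Entity, tables: Tables, *, override: bool = False) -> CvName:
    """Dispatch to the peptide, molecule or assembly namer."""
    if isinstance(entity, PeptideEntity):
        return name_peptide(entity, tables, override=override)
    if isinstance(entity, SmallMolecule):
        return name_molecule(entity, tables)
    if isinstance(entity, Assembly):
        return name_assembly(entity, tables, override=override)
    raise TypeError(f"cannot name object of type {type(entity).__name__}")


def name_assembly(
    node: Assembly, tables: Tables, *, override: bool = False
) -> CvName:
    """Generate the recursive CV name of a complex or set.

    Part order is preserved as given (names reflect curator order, not a
    sort); stoichiometry n > 1 renders as an ``nx`` count; output contains
    no spaces after separators.
    """
    text = _render(node, tables, override, on_path=set())
    return CvName(text=text, source=node)


def _render(node: Assembly, tables: Tables, override: bool, on_path: set) -> str:
    if id(node) in on_path:
        raise StructureError("cycle detected in assembly structure")
    on_path = on_path | {id(node)}

    def part_text(part) -> str:
        member = part.member
        if isinstance(member, Assembly):
            inner = _render(member, tables, override, on_path)
            if len(member.parts) >= 2:
                inner = f"[{inner}]"
        else:
            inner = name_entity(member, tables, override=override).text
        if part.stoichiometry > 1:
            inner = f"{part.stoichiometry}x{inner}"
        return inner

    if node.kind == COMPLEX:
        return ":".join(part_text(p) for p in node.parts)
    members = [part_text(p) for p in node.parts if not p.is_candidate]
    candidates = [part_text(p) for p in node.parts if p.is_candidate]
    if node.kind == CANDIDATE_SET:
        return ",".join(members) + ",(" + ",".join(candidates) + ")"
    return ",".join(members)


# ---------------------------------------------------------------------------
# Diagram labels
# ---------------------------------------------------------------------------

_STEM_RE = re.compile(r"^([A-Z][A-Z0-9]*?)(\d+)$")


def _family_split(node: Assembly) -> tuple[str, list[int]] | None:
    """Common stem + integer suffixes of leaf-peptide members, if they exist."""
    stems, numbers = set(), []
    for part in node.parts:
        if not isinstance(part.member, PeptideEntity) or part.stoichiometry != 1:
            return None
        match = _STEM_RE.match(part.member.gene_symbol)
        if not match:
            return None
        stems.add(match.group(1))
        numbers.append(int(match.group(2)))
    if len(stems) != 1 or len(set(numbers)) != len(numbers):
        return None
    return stems.pop(), sorted(numbers)


def _compress_ranges(numbers: list[int]) -> str:
    """1,3,4,5 -> "1,3-5"; runs shorter than three are listed out."""
    groups: list[list[int]] = [[numbers[0]]]
    for value in numbers[1:]:
        if value == groups[-1][-1] + 1:
            groups[-1].append(value)
        else:
            groups.append([value])
    pieces = []
    for group in groups:
        if len(group) >= 3:
            pieces.append(f"{group[0]}-{group[-1]}")
        else:
            pieces.extend(str(v) for v in group)
    return ",".join(pieces)


def shorten_label(
    node: Assembly,
    tables: Tables,
    *,
    complete_family: bool = False,
) -> str:
    """A short plural label for a set, for use in pathway diagrams.

    Priority: a curator-supplied functional label; the pluralized family
    stem (``VAVs``) when ``complete_family`` asserts the set covers the
    whole family and the member numbers run unbroken from the minimum;
    stem plus compressed integer ranges (``CCR1-5``, ``CCR1,3-5``);
    otherwise the full CV name.  Whether a set is the complete family and
    not expected to grow is a curation judgement, hence the explicit flag.
    """
    if node.functional_label is not None:
        return node.functional_label
    family = _family_split(node)
    if family is not None:
        stem, numbers = family
        consecutive = numbers == list(range(numbers[0], numbers[0] + len(numbers)))
        if complete_family and consecutive:
            return f"{stem}s"
        return stem + _compress_ranges(numbers)
    return name_assembly(node, tables).text
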