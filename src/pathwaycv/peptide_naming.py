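"""CV names for peptides: gene-symbol core, coordinate suffix, PTM
prefixes, and exemption detection.

A peptide name reads ``[Active ]<ptm prefixes><GENE SYMBOL>[(start-end)]``.
Coordinates are suppressed only when the peptide coincides with the single
reference chain; unknown coordinates print as ``?``.  Modification prefixes
are hyphen-terminated; phosphorylations collapse into a single trailing
``p-`` block whose subtype-letter+coordinate tokens sort by coordinate.
"""

from __future__ import annotations

from .model import CvName, ExemptionError, PeptideEntity, Ptm, ValidationError
from .tables import Tables

# Exemption codes, in detection order.
DISEASE_MUTATION = "DISEASE_MUTATION"
NONCANONICAL_ISOFORM = "NONCANONICAL_ISOFORM"
COMPLEX_MODIFICATION = "COMPLEX_MODIFICATION"
MULTI_OR_NO_CHAIN = "MULTI_OR_NO_CHAIN"
HLA = "HLA"

#: codes that block automatic naming; MULTI_OR_NO_CHAIN only signals that the
#: reference chain had to be chosen manually, the name itself is still formed
BLOCKING_EXEMPTIONS = frozenset(
    {DISEASE_MUTATION, NONCANONICAL_ISOFORM, COMPLEX_MODIFICATION, HLA}
)


def coordinate_suffix(peptide: PeptideEntity) -> str:
    """The ``(start-end)`` suffix, or ``""`` when coordinates are redundant.

    Redundant means: the reference record has exactly one chain feature and
    the peptide's coordinates agree with it.  With no chain or several
    chains the suffix is always emitted.
    """
    if (
        peptide.chain_count == 1
        and peptide.start == peptide.chain_start
        and peptide.end == peptide.chain_end
    ):
        return ""
    start = "?" if peptide.start is None else str(peptide.start)
    end = "?" if peptide.end is None else str(peptide.end)
    return f"({start}-{end})"


def _check_duplicates(ptms: tuple[Ptm, ...]) -> None:
    seen = set()
    for ptm in ptms:
        key = (ptm.prefix, ptm.subtype, ptm.coordinate)
        if key in seen:
            raise ValidationError(
                f"modification listed twice: prefix {ptm.prefix!r} at "
                f"coordinate {ptm.coordinate}"
            )
        seen.add(key)


def _nonphospho_sort(ptms: list[tuple[Ptm, bool]]) -> list[tuple[Ptm, bool]]:
    # Descending coordinate of the first modified residue, unknown positions
    # last; ties among unknowns broken by prefix, high-to-low, which keeps
    # palmitoyl sites (numerically above the myristoyl glycine) first.
    ordered = sorted(ptms, key=lambda t: t[0].prefix, reverse=True)
    return sorted(
        ordered,
        key=lambda t: (t[0].coordinate is None, -(t[0].coordinate or 0)),
    )


def ptm_prefix(ptms: tuple[Ptm, ...] | list[Ptm], tables: Tables) -> str:
    """Render the hyphen-terminated modification prefix string.

    Non-phospho prefixes come first (each ``[nx]Prefix[coord]-``), then at
    most one phospho block ``p-[tokens-]`` with subtype-letter+coordinate
    tokens in ascending coordinate order.  The result is canonical: it does
    not depend on the order modifications are listed in.
    """
    ptms = tuple(ptms)
    if not ptms:
        return ""
    _check_duplicates(ptms)

    nonphospho: list[tuple[Ptm, bool]] = []
    phospho: list[Ptm] = []
    for ptm in ptms:
        row = tables.mod_prefix(ptm.psimod_id)
        if row.phospho:
            phospho.append(ptm)
        else:
            nonphospho.append((ptm, row.includes_coordinate))

    pieces: list[str] = []
    for ptm, with_coord in _nonphospho_sort(nonphospho):
        count = f"{ptm.multiplicity}x" if ptm.multiplicity > 1 else ""
        coord = (
            str(ptm.coordinate)
            if with_coord and ptm.coordinate is not None
            else ""
        )
        pieces.append(f"{count}{ptm.prefix}{coord}-")

    if phospho:
        tokens = []
        for ptm in sorted(
            phospho,
            key=lambda m: (
                m.coordinate is None,
                m.coordinate or 0,
                m.subtype or "",
            ),
        ):
            if ptm.multiplicity > 1 and ptm.subtype is None and ptm.coordinate is None:
                raise ValidationError(
                    "a multiple phosphorylation with unknown subtype and "
                    "position has no printable form"
                )
            count = f"{ptm.multiplicity}x" if ptm.multiplicity > 1 else ""
            token = f"{count}{ptm.subtype or ''}" \
                    f"{ptm.coordinate if ptm.coordinate is not None else ''}"
            if token:
                tokens.append(token)
        pieces.append("p-" + (",".join(tokens) + "-" if tokens else ""))

    return "".join(pieces)


def check_exemption(peptide: PeptideEntity) -> str | None:
    """First matching exemption code in fixed order, or None.

    MULTI_OR_NO_CHAIN means "a curator must pick the reference chain", not
    "unnameable": the name is still generated, with coordinates forced on.
    """
    if peptide.disease_mutation_flag:
        return DISEASE_MUTATION
    if peptide.isoform_variant > 1:
        return NONCANONICAL_ISOFORM
    if peptide.cross_link_flag:
        return COMPLEX_MODIFICATION
    if peptide.chain_count != 1:
        return MULTI_OR_NO_CHAIN
    if peptide.hla_flag:
        return HLA
    return None


def name_peptide(
    peptide: PeptideEntity, tables: Tables, *, override: bool = False
) -> CvName:
    """Generate the peptide CV name.

    Raises ExemptionError (carrying the code) for blocked exemptions unless
    ``override`` is given; raises LookupMissError for a PSI-MOD id absent
    from the prefix table.
    """
    code = check_exemption(peptide)
    if code in BLOCKING_EXEMPTIONS and not override:
        raise ExemptionError(code)
    text = (
        ("Active " if peptide.active_flag else "")
        + ptm_prefix(peptide.ptms, tables)
        + peptide.gene_symbol
        + coordinate_suffix(peptide)
    )
    return CvName(text=text, source=peptide)
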