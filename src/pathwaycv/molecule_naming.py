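"""CV names for small molecules.

A short familiar abbreviation is preferred over the full reference
(ChEBI-style) name whenever the abbreviation table has one; otherwise the
reference name is used verbatim.  Abbreviations never appear as table keys,
so naming is idempotent: an already-abbreviated name passes through
unchanged.
"""

from __future__ import annotations

from .model import CvName, SmallMolecule, ValidationError
from .tables import Tables


def name_molecule(mol: SmallMolecule, tables: Tables) -> CvName:
    """Resolve the molecule's CV name via the abbreviation table.

    The lookup is case-insensitive and whitespace-normalized; a miss falls
    back to the reference name unchanged.
    """
    if not mol.reference_name.strip():
        raise ValidationError("small molecule has an empty reference name")
    abbrev = tables.abbreviation_for(mol.reference_name)
    return CvName(text=abbrev if abbrev is not None else mol.reference_name,
                  source=mol)
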