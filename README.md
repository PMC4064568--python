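# pathwaycv

Controlled-vocabulary (CV) names for pathway entities and events.

Pathway databases must name objects that the literature never names:
cleaved peptide fragments, multiply phosphorylated forms, transient
complexes, curated sets of functional equivalents, and the reactions they
take part in. Free-text names drift, collide and defeat text search — a
query for "phosphorylates" misses most phosphorylation events when each
curator phrased the reaction differently. `pathwaycv` implements a
deterministic naming scheme for these objects, a parser that maps CV names
back to structured entity trees (the operational test of "unambiguous"),
and a rule-based classifier that assigns every reaction one event category
and renders its name from a template.

## The naming scheme

**Peptides** are named around the HGNC gene symbol:

```
[Active ]<ptm prefixes><SYMBOL>[(start-end)]
```

Coordinates are 1-based on the reference chain and suppressed only when
the peptide coincides with the record's single chain feature; `?` marks an
unknown coordinate (`ACAN(17-?)`). Each modification adds a
hyphen-terminated prefix chosen by PSI-MOD id from a lookup table;
phosphorylations collapse into one trailing `p-` block whose
subtype-letter+coordinate tokens sort by coordinate, and a modification
occurring *n* times with no recorded position takes an `nx` count:
`2xPalmC-MyrG-p-S1177-NOS3(2-1203)`. Peptides with disease mutations,
non-canonical isoforms, cross-links or HLA alleles are exempt and reported
by code rather than misnamed.

**Small molecules** use a short familiar abbreviation (`FAD`, `Na+`,
`I(1,3,4,5,6)P5`) when the table has one for the full ChEBI-style name,
otherwise the reference name verbatim.

**Complexes and sets** concatenate member names — `:` inside complexes,
`,` inside sets, candidates of a candidate set in one trailing `(...)`
group, stoichiometry as `nx`. Members that are themselves multimeric are
wrapped in square brackets, so assembly history stays distinguishable:
`[ABC1:ABC2]:[ABC3:ABC4]` is a different object from
`[ABC1:ABC2:ABC3]:ABC4`. Family sets get short plural diagram labels
(`VAVs`, `CCR1-5`, `CCR1,3-5`).

**Events** are classified by fixed precedence into transformation,
binding, dissociation, (de)polymerization, catalysis, group transfer,
translocation, transport, antiport (exchange), cotransport or activation,
with regulation as an additive statement, and named from per-category
templates. Catalyst verbs derive from the GO molecular function term via a
lookup table (`PTGDS isomerizes PGH2 to PGD2`,
`SLC6A12 cotransports GABA with 3Na+ and 2Cl-`), with plural agreement
for set catalysts (`NMT1,2 transfer MYS to GNAT1 (to form
N-(C14:0)-GNAT1)`).

## Worked example

```python
import pathwaycv as pc

tables = pc.load_tables()

nos3 = pc.PeptideEntity(
    "NOS3", start=2, end=1203, chain_start=1, chain_end=1203, chain_count=1,
    ptms=(
        pc.Ptm("MOD:00440", "PalmC", multiplicity=2),   # 2 palmitoyl Cys
        pc.Ptm("MOD:00068", "MyrG"),                    # myristoyl Gly
        pc.Ptm("MOD:00696", "p", subtype="S", coordinate=1177),
    ),
)
print(pc.name_peptide(nos3, tables).text)
# 2xPalmC-MyrG-p-S1177-NOS3(2-1203)

tree = pc.parse_entity_name("[ABC1:ABC2]:[ABC3:ABC4]", tables)
print(type(tree).__name__, tree.kind, len(tree.parts))
# Assembly complex 2
```

The name says: the NOS3 fragment spanning residues 2–1203 (printed because
it differs from the full chain 1–1203), doubly palmitoylated,
myristoylated, and phosphorylated on serine-1177 — and the parsed complex
is the pairing of two pre-existing dimers, not a trimer plus a monomer.

From the shell:

```
$ pathwaycv fixtures --seed 1 --n 5 --out demo.json
$ pathwaycv name-entity demo.json
e1      AAAB3
e2      AAAC2(292-1075)
e3      p-T121-AAAD8
e4      p-S389,S668,T808-AAAE1
e5      p-AAAF1
```

Other subcommands: `classify`, `name-reaction`, `parse`, `validate`
(duplicate/bracket report, nonzero exit on duplicates) and `rename`
(batch audit TSV with old names retained as aliases).

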