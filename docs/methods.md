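# Methods

This note records the model behind `pathwaycv`, the design choices taken
where the scheme left room, the synthetic data the tests run on, and the
limits of what those tests show.

## The naming model

A CV name is a deterministic function of an entity's composition. The
entity model is a tree: peptides and small molecules at the leaves,
complexes/defined sets/candidate sets as interior nodes with ordered
parts, each part carrying a stoichiometry and (in candidate sets) a
candidate flag. Trees are immutable values; structurally equal subtrees
get identical names wherever they occur, which is what makes the name a
faithful composition fingerprint. A shared sub-complex is therefore
serialized once in the JSON document format (flat entity list, local-id
references) but named identically at each occurrence; no attempt is made
to name an entity differently by provenance.

### Peptides

`[Active ]<ptm prefixes><SYMBOL>[(start-end)]`, with these rules:

- Coordinates are 1-based, inclusive, and always in the frame of the
  reference chain, even where literature convention renumbers after
  signal-peptide removal. The suffix is suppressed exactly when the record
  has one chain feature and the peptide's coordinates equal it; with zero
  or multiple chains the suffix is always printed (and the entity is
  reported under the `MULTI_OR_NO_CHAIN` code, which means "a curator
  chose the chain", not "unnameable").
- Unknown coordinates print as `?`. Cleavage of peptides with unknown
  coordinates is the one documented route to duplicate names; duplicates
  are *reported* by the namespace validator for manual naming, never
  auto-suffixed, because an automatic index would encode record order
  rather than biology.
- PTM prefixes are table-driven (`mod_prefixes.tsv`): PSI-MOD id → prefix,
  plus two flags — whether the residue coordinate is printed (true for
  di-/tri-lysine and arginine methylation, lysine acetylation,
  ubiquitination, phosphorylation) and whether the row is the
  phosphorylation class. All phosphorylations merge into one trailing
  `p-` block; its tokens (subtype letter + coordinate, e.g. `Y150`) sort
  ascending by coordinate, unknown positions last, because site order is
  the property a reader scans for.
- Non-phospho prefixes sort by descending first-residue coordinate with
  unknown positions last. Ties among unknown-position prefixes break by
  prefix string, high to low: this is the one genuinely open ordering
  decision, and it is fixed by the doubly palmitoylated, myristoylated
  NOS3 form, where the palmitoyl cysteines sit numerically above the
  myristoyl glycine and the canonical name reads `2xPalmC-MyrG-…`. Only
  that single printed form constrains the order; the tie-break is
  documented here precisely because it is conventional, not derivable.
- A multiplicity *n* > 1 is only representable when the position is
  unknown (the `nx` form); a "multiple phosphorylation, nothing known"
  combination has no printable form and is rejected rather than guessed.
- Exemption codes, checked in fixed order: `DISEASE_MUTATION`,
  `NONCANONICAL_ISOFORM`, `COMPLEX_MODIFICATION` (cross-links and other
  non-residue modifications), `MULTI_OR_NO_CHAIN`, `HLA` (an established
  allele nomenclature already exists). The first four of these minus
  `MULTI_OR_NO_CHAIN` block naming unless explicitly overridden.

### Small molecules and assemblies

Molecule naming is a normalized (case- and whitespace-insensitive) lookup
of the full reference name in `molecule_abbrev.tsv`, falling back to the
reference name verbatim. Abbreviations are forbidden as table keys, which
the loader enforces, making naming idempotent. The shipped table seeds
only the abbreviations the CV itself defines; it is meant to be extended.

Assembly names preserve curator part order (sorting would change the
meaning of printed names, and order can carry assembly semantics).
Canonical output has no spaces after separators; the parser tolerates
them. Square brackets wrap any member that is itself an assembly of ≥ 2
parts; single-part wrappers are transparent (a complex containing only
`2xPPOX` prints `2xPPOX`). Candidate members always render grouped in one
trailing round-bracket group regardless of their input position, since
interleaving has no printed form. Homomer words (`dimer`, `tetramer`) are
accepted by the parser as input aliases only; generation always uses the
machine-friendly `nx` form.

Diagram labels (`shorten_label`) are a separate, lossy operation:
functional label verbatim, else family stem handling. Integer runs
compress only at length ≥ 3 (`CCR1-5`, `CCR1,3-5` but `NMT1,2`), matching
the printed catalyst-set label. The stem-plural form (`VAVs`) requires the
caller to assert `complete_family=True`: whether a set covers the whole
family and is not expected to grow is a curation judgement that cannot be
inferred from membership (a complete CCR1–CCR5 set and the complete VAV
family are both unbroken runs from 1).

### Events

Classification is a fixed precedence over reaction attributes:

1. explicit (de)polymerization class;
2. catalyst whose GOMF template is exchange / cotransport / transport;
3. no catalyst, entity multiset unchanged, compartment (or cell type)
   changed → translocation;
4. any other catalyst → transfer if the template is `transfers`, else
   generic catalysis;
5. more inputs than outputs and an input is a constituent of an output →
   binding (the containment test doubles as a stoichiometric-balance
   check);
6. the mirror condition → dissociation;
7. inputs equal outputs in place → activation;
8. otherwise transformation.

The precedence is a design choice — the categories themselves overlap on
raw attributes (every transporter reaction also has a catalyst) — and is
ordered so the most specific, attribute-gated class wins. Decisions are
logged per reaction at debug level for audit.

Verb lookup is exact-match on `gomf_verbs.tsv` plus a substring fallback
mapping the hydrolase family (phosphodiesterase, esterase, lipase,
fumarylacetoacetase, GTPase) to `hydrolyses`; a miss selects the generic
`catalyzes` template. Verbs render lower-case (the CV term is
case-insensitive) and drop the final `s` when the catalyst is a set, whose
display name is its diagram label (`NMT1,2 transfer …`).

Template details that are not derivable from flat input/output lists live
on the reaction object: the transferred group, acceptor and optional
product for transferases; the membrane for antiport; the convention that
the first input of a cotransport is the cargo and the rest the co-ions
(rendered with tight count prefixes, `3Na+`); and an `omit_product` flag,
because the product clause of catalyzed templates is optional and some
canonical names omit it (`HLCS biotinylates ACACA`). Cross-cell
translocation renders compartments as `[compartment of cell type]`.
Regulation is rendered as a separate statement appended to the event name
("X negatively regulates …") rather than woven into the event's own
template, keeping the event name a pure function of its mechanism.

## The parser

The parser is a hand-written recursive-descent implementation of the name
grammar; the grammar is small enough that a generator would obscure the
two disambiguation rules that carry the design:

- **Phospho-comma binding.** `p-Y150,S343,T346-WASF2` must be one peptide,
  not a three-member set. Before separator scanning, maximal munch binds
  any maximal `p-tok(,tok)*-` span to its phospho block and masks the
  commas inside it. The residual pathological case — a set whose member is
  literally named like a phospho token — is resolved in favor of the
  peptide reading; the fixture generator never emits such names.
- **`nx` binding.** `2xPPOX` is stoichiometry; `2xPalmC-…` is PTM
  multiplicity. The count binds to the modification exactly when a known
  non-phospho prefix (+ optional digits + hyphen) follows; the generator
  never puts stoichiometry > 1 directly on a member whose name begins
  with such a prefix, so generation and parsing agree.

One separator kind is allowed per bracket level (mixing `:` and `,`
is an error with a character offset, as are unbalanced brackets and empty
items). Unknown leaf tokens parse as opaque molecule-like leaves instead
of failing, since real corpora contain abbreviations outside any shipped
table. Input tolerances: en dash for hyphen, spaces after commas, homomer
words. Flat names of multiply-assembled complexes are genuinely
ambiguous by construction; they parse as flat, and only the bracketed
forms round-trip the assembly history — that is the point of the
brackets.

Round-trip identity holds on *canonical* trees: a parsed peptide carries
only name-recoverable state (printed coordinates imply `chain_count = 0`;
a bare symbol implies one chain with matching coordinates), and the
fixture generator emits peptides in exactly that form. Chain annotations
beyond this are preserved by the JSON document format, not by names.

## Synthetic data

`generate_fixture_entities(seed, n, max_depth)` is a pure function of its
arguments. It cycles a 13-slot schedule (bare peptide, coordinate suffix,
single/multi/unknown phospho, coordinate-bearing and multiplicity
prefixes, combined lipidation+phospho, active form, molecule, complex,
defined set, candidate set, nested assembly), so every grammar branch
appears whenever n ≥ 13; parameters within a slot are drawn from the
seeded generator. Gene symbols are unique by construction (base-26
counter), so leaf names never collide and name uniqueness over the corpus
probes the scheme rather than the symbol supply. Molecules draw from the
abbreviation table's canonical forms plus opaque lower-case names.

What the generator does *not* emulate: real HGNC symbol shapes beyond
`[A-Z][A-Z0-9]*`, realistic PTM co-occurrence frequencies, shared
sub-complexes across records, exempt peptides (constructed directly in
tests instead), and reaction corpora (reaction fixtures are hand-built
per category). Passing tests therefore demonstrate grammatical coverage
and determinism, not fidelity to any particular database's content
distribution.

The exhaustive enumeration (`enumerate_fixture_trees`) generates every
assembly tree over a fixed four-leaf pool with ≤ 4 leaves and depth ≤ 2
(~40 000 trees after deduplication), with stoichiometry and candidate
variants at the positions the grammar distinguishes. The classifier
cross-check enumerates all input/output multisets of size ≤ 3 over a
four-entity universe (monomers, their complex, a molecule), with and
without a catalyst under each template-selecting GOMF, with and without a
compartment change (~14 000 reactions), and compares against an
independent clause-evaluation oracle that uses value-based containment
instead of the classifier's name-based test.

Problem sizes used by the acceptance script — 1000 seeded trees plus the
full enumeration for round-trip, the full reaction enumeration, and a
10 000-entity corpus for uniqueness — run in a few seconds and are sized
to be exhaustive where enumeration is defined and comfortably larger than
the schedule period where sampling is.

## Numerical and degenerate-input choices

- Coordinates serialize as integers with `"?"` for unknown, mirroring the
  printed `(17-?)` convention.
- The ASCII hyphen is canonical in coordinate ranges; the en dash is
  accepted on input only.
- Duplicate (prefix, subtype, coordinate) modification entries are
  validation errors (the same modification listed twice), as are empty
  molecule names, empty assemblies, candidate flags outside candidate
  sets, and reactions with an empty side and no explicit class.
- Document reading resolves assembly references with cycle detection;
  errors name the offending field (`entities[3].parts[0].ref: …`).
- Exit codes of the CLI: 0 success, 1 validation/duplicate failure,
  2 input/schema error.

## Known limitations

- The shipped tables are seeds: ten PTM prefixes, eighteen molecule
  abbreviations, fifteen GOMF→verb rows. Production use requires the full
  curated tables; the loader accepts a replacement directory and an
  optional PSI-MOD OBO file for prefix bootstrapping.
- A single PSI-MOD id represents the phosphorylation class; subtype
  letters live on the modification object, so subtype-specific ontology
  ids are not recovered by parsing.
- Event *sentences* are not parsed back into reactions (entity names
  only).
- The disease-mutation extension of the CV and automatic selection among
  multiple reference chains are out of scope; affected peptides surface
  as exemption codes.
- `REGULATION` composes textually as a separate appended statement; no
  printed form pins this down and the choice is recorded here.
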