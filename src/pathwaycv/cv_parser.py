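"""Parse CV entity names back into entity trees.

This operationalizes the "unambiguous" claim of the naming scheme: any
canonically generated entity name parses back to the tree it came from.
The grammar, informally::

    assembly := item ((":" | ",") item)*     # one separator kind per level
    item     := "[" assembly "]" | stoich? leaf | leaf " " homomer-word
    leaf     := "Active "? ptm-prefix* SYMBOL coords?

Phosphorylation lists reuse the set separator (``p-Y150,S343,T346-``), so
commas are bound to a phospho block by maximal munch before separators are
scanned.  An ``nx`` count binds to the modification when a non-phospho PTM
prefix follows (``2xPalmC-…`` is a doubly palmitoylated peptide), and to
stoichiometry otherwise (``2xPPOX``).  The parser additionally tolerates
the en dash, spaces after commas, and dimer/trimer/tetramer homomer words;
unknown tokens become opaque small-molecule-like leaves rather than
failures.  Rejected strings always report a character offset.

Parsed peptides are in canonical form: printed coordinates imply no chain
feature (the suffix always regenerates), a bare symbol implies one chain
with matching coordinates (the suffix stays suppressed).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import (
    Assembly,
    CANDIDATE_SET,
    COMPLEX,
    CvError,
    DEFINED_SET,
    Entity,
    ParseError,
    Part,
    PeptideEntity,
    Ptm,
    SmallMolecule,
)
from .tables import Tables, normalize_molecule_name

HOMOMER_WORDS = {"dimer": 2, "trimer": 3, "tetramer": 4}

_PHOSPHO_TOKEN = r"(?:\d+x)?(?:[STY]\d*|\d+)"
_PHOSPHO_BLOCK = rf"p-(?:({_PHOSPHO_TOKEN}(?:,{_PHOSPHO_TOKEN})*)-)?"
_PHOSPHO_BLOCK_RE = re.compile(_PHOSPHO_BLOCK)
_PHOSPHO_SCAN_RE = re.compile(r"(?<![A-Za-z0-9])(?:\d+x)?" + _PHOSPHO_BLOCK)
_PHOSPHO_TOKEN_RE = re.compile(r"^(?:(\d+)x)?([STY])?(\d+)?$")
_SYMBOL_RE = re.compile(r"^[A-Z][A-Z0-9]*$")
_COORDS_RE = re.compile(r"\((\d+|\?)-(\d+|\?)\)$")
_STOICH_RE = re.compile(r"^(\d+)x(.+)$", re.DOTALL)


@dataclass
class _Ctx:
    tables: Tables
    nonphospho_re: re.Pattern
    phospho_id: str


def _build_ctx(tables: Tables) -> _Ctx:
    prefixes = sorted(
        (row.prefix for row in tables.prefix_rows.values() if not row.phospho),
        key=len,
        reverse=True,
    )
    alternation = "|".join(re.escape(p) for p in prefixes) or r"(?!x)x"
    pattern = re.compile(rf"(?:(\d+)x)?({alternation})(\d+)?-")
    return _Ctx(tables, pattern, tables.phospho_psimod_id())


def parse_entity_name(text: str, tables: Tables) -> Entity:
    """Parse a CV entity name into a PeptideEntity, SmallMolecule or Assembly."""
    if not text or not text.strip():
        raise ParseError("empty name", 0)
    s = text.replace("–", "-")  # the en dash prints both ways
    _check_balance(s)
    ctx = _build_ctx(tables)
    return _parse_span(s, 0, ctx)


def _check_balance(s: str) -> None:
    stack: list[tuple[str, int]] = []
    pairs = {")": "(", "]": "["}
    for i, ch in enumerate(s):
        if ch in "([":
            stack.append((ch, i))
        elif ch in ")]":
            if not stack or stack[-1][0] != pairs[ch]:
                raise ParseError(f"unbalanced {ch!r}", i)
            stack.pop()
    if stack:
        raise ParseError(f"unclosed {stack[-1][0]!r}", stack[-1][1])


def _masked_commas(s: str) -> set[int]:
    """Offsets of commas bound inside phospho blocks (maximal munch)."""
    bound: set[int] = set()
    for match in _PHOSPHO_SCAN_RE.finditer(s):
        for i in range(match.start(), match.end()):
            if s[i] == ",":
                bound.add(i)
    return bound


def _split_level(s: str, base: int) -> tuple[str | None, list[tuple[str, int]]]:
    """Split a span on its uniform top-level separator.

    Returns (separator or None, [(item, absolute offset), ...]).  Mixing
    ":" and "," at one level is an error.
    """
    bound = _masked_commas(s)
    depth = 0
    sep: str | None = None
    cuts: list[int] = []
    for i, ch in enumerate(s):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
        elif depth == 0 and (ch == ":" or (ch == "," and i not in bound)):
            if sep is None:
                sep = ch
            elif ch != sep:
                raise ParseError(
                    f"mixed separators {sep!r} and {ch!r} at one level",
                    base + i,
                )
            cuts.append(i)
    items: list[tuple[str, int]] = []
    prev = 0
    for cut in cuts + [len(s)]:
        piece = s[prev:cut]
        stripped = piece.strip()
        offset = base + prev + piece.index(stripped) if stripped else base + prev
        if not stripped:
            raise ParseError("empty item", base + prev)
        items.append((stripped, offset))
        prev = cut + 1
    return sep, items


def _parse_span(s: str, base: int, ctx: _Ctx) -> Entity:
    sep, items = _split_level(s, base)
    if sep is None:
        part = _parse_item(*items[0], ctx)
        if part.is_candidate:
            raise ParseError(
                "a candidate group needs preceding set members", items[0][1]
            )
        if part.stoichiometry > 1:
            return Assembly(COMPLEX, (part,))
        return part.member

    parts: list[Part] = []
    for idx, (item, offset) in enumerate(items):
        part = _parse_item(item, offset, ctx)
        if part.is_candidate:
            if sep == ":":
                raise ParseError("candidate group inside a complex", offset)
            if idx != len(items) - 1:
                raise ParseError(
                    "candidate group must be the trailing item", offset
                )
        parts.append(part)

    if sep == ":":
        return Assembly(COMPLEX, tuple(parts))
    if parts[-1].is_candidate:
        candidates = _expand_candidates(items[-1], ctx)
        return Assembly(CANDIDATE_SET, tuple(parts[:-1]) + candidates)
    return Assembly(DEFINED_SET, tuple(parts))


def _expand_candidates(item: tuple[str, int], ctx: _Ctx) -> tuple[Part, ...]:
    text, offset = item
    inner = text[1:-1]
    sep, members = _split_level(inner, offset + 1)
    if sep == ":":
        raise ParseError("candidate group may not contain a complex level", offset)
    out = []
    for member, moffset in members:
        part = _parse_item(member, moffset, ctx)
        if part.is_candidate:
            raise ParseError("nested candidate group", moffset)
        out.append(Part(part.member, part.stoichiometry, is_candidate=True))
    return tuple(out)


def _fully_wrapped(s: str, open_ch: str, close_ch: str) -> bool:
    if not (s.startswith(open_ch) and s.endswith(close_ch)):
        return False
    depth = 0
    for i, ch in enumerate(s):
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth -= 1
            if depth == 0:
                return i == len(s) - 1
    return False


def _parse_item(s: str, base: int, ctx: _Ctx) -> Part:
    if _fully_wrapped(s, "[", "]"):
        return Part(_parse_span(s[1:-1], base + 1, ctx))
    if _fully_wrapped(s, "(", ")") and s not in ctx.tables.abbreviations:
        # trailing candidate group; expanded by the caller
        return Part(SmallMolecule("candidate-group"), is_candidate=True)

    for word, count in HOMOMER_WORDS.items():
        if s.endswith(" " + word):
            inner = _parse_item(s[: -len(word) - 1].rstrip(), base, ctx)
            if inner.stoichiometry != 1:
                raise ParseError(f"conflicting counts before {word!r}", base)
            return Part(inner.member, stoichiometry=count)

    stoich = _STOICH_RE.match(s)
    if stoich is not None:
        rest = stoich.group(2)
        # "2xPalmC-…" is PTM multiplicity, "2xPPOX" is stoichiometry
        if not ctx.nonphospho_re.match(rest):
            if rest.startswith("["):
                if not _fully_wrapped(rest, "[", "]"):
                    raise ParseError("count must precede a whole item", base)
                return Part(
                    _parse_span(rest[1:-1], base + len(stoich.group(1)) + 2, ctx),
                    stoichiometry=int(stoich.group(1)),
                )
            member = _parse_leaf(rest, base + len(stoich.group(1)) + 1, ctx)
            return Part(member, stoichiometry=int(stoich.group(1)))

    return Part(_parse_leaf(s, base, ctx))


def _parse_leaf(s: str, base: int, ctx: _Ctx) -> Entity:
    tables = ctx.tables
    if s in tables.abbreviations or normalize_molecule_name(s) in tables.molecule_abbrev:
        return SmallMolecule(s)
    active = s.startswith("Active ")
    body = s[len("Active "):] if active else s
    peptide = _parse_peptide(body, ctx, active)
    if peptide is not None:
        return peptide
    # unknown token: an opaque small-molecule-like leaf
    return SmallMolecule(s)


def _parse_peptide(s: str, ctx: _Ctx, active: bool) -> PeptideEntity | None:
    try:
        return _parse_peptide_inner(s, ctx, active)
    except CvError:
        return None


def _parse_peptide_inner(s: str, ctx: _Ctx, active: bool) -> PeptideEntity | None:
    start = end = None
    has_coords = False
    coords = _COORDS_RE.search(s)
    if coords is not None:
        has_coords = True
        start = None if coords.group(1) == "?" else int(coords.group(1))
        end = None if coords.group(2) == "?" else int(coords.group(2))
        s = s[: coords.start()]

    ptms: list[Ptm] = []
    pos = 0
    while True:
        m = ctx.nonphospho_re.match(s, pos)
        if m is not None:
            ptms.append(Ptm(
                psimod_id=ctx.tables.prefix_rows[m.group(2)].psimod_id,
                prefix=m.group(2),
                coordinate=int(m.group(3)) if m.group(3) else None,
                multiplicity=int(m.group(1)) if m.group(1) else 1,
            ))
            pos = m.end()
            continue
        m = _PHOSPHO_BLOCK_RE.match(s, pos)
        if m is not None:
            tokens = m.group(1).split(",") if m.group(1) else [""]
            for token in tokens:
                tm = _PHOSPHO_TOKEN_RE.match(token)
                if tm is None:
                    return None
                ptms.append(Ptm(
                    psimod_id=ctx.phospho_id,
                    prefix="p",
                    subtype=tm.group(2),
                    coordinate=int(tm.group(3)) if tm.group(3) else None,
                    multiplicity=int(tm.group(1)) if tm.group(1) else 1,
                ))
            pos = m.end()
            continue
        break

    symbol = s[pos:]
    if not _SYMBOL_RE.match(symbol):
        return None
    try:
        if has_coords:
            return PeptideEntity(
                gene_symbol=symbol, start=start, end=end,
                chain_count=0, ptms=tuple(ptms), active_flag=active,
            )
        return PeptideEntity(
            gene_symbol=symbol, chain_count=1, ptms=tuple(ptms),
            active_flag=active,
        )
    except Exception:
        return None
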