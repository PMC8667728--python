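"""Domain types and notation for rank-free phylogenetic clade definitions.

Phylogenetic nomenclature anchors a clade name to explicit *specifier*
species rather than to a rank.  Two kinds of definition are supported:

* **minimum-clade** ("node-based"): the smallest clade containing every
  internal specifier;
* **maximum-clade** ("branch-based"/"stem-based"): the largest clade
  containing the internal specifier(s) but not the external specifier(s).

Definitions are written in a compact notation::

    max ∇ (Ankylosaurus magniventris ~ Stegosaurus stenops)
    min ∇ ∈ Ornithopoda (Edmontosaurus regalis & Hypsilophodon foxii)
    min ∇ (Lambeosaurus lambei & Saurolophus osborni | ~ Hadrosaurus foulkii)

with the conventions ``max`` = the largest, ``min`` = the smallest,
``∇`` = clade, ``()`` = containing, ``&`` = and, ``∨`` = or, ``~`` = but
not (or, after ``|``, a qualifying "provided that it does not include"
clause), ``|`` = on the condition that, and the set symbols ``∈`` / ``∉``
restricting the name's use to topologies where the clade lies within /
outside another named clade.

Every glyph has an ASCII alias for keyboards and config files:
``max-clade`` / ``min-clade`` (for ``max ∇`` / ``min ∇``), ``and``, ``or``,
``not`` (for ``~``), ``provided-not`` (for ``| ~``), ``in`` / ``not-in``
(for ``∈`` / ``∉``).

This module owns the data model (:class:`TaxonName`,
:class:`ContextConstraint`, :class:`CladeDefinition`), the parser
(:func:`parse_definition`), the canonical serializer
(:func:`serialize_definition`) and structural validation
(:func:`validate_definition`).  Applying a definition to a tree lives in
:mod:`cladedef.resolver`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "Connective",
    "Polarity",
    "DefinitionKind",
    "TaxonName",
    "ContextConstraint",
    "CladeDefinition",
    "DefinitionSyntaxError",
    "DefinitionValidationError",
    "parse_definition",
    "serialize_definition",
    "validate_definition",
    "normalize_label",
    "normalize_binomial",
]


# ---------------------------------------------------------------------------
# normalization

_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Normalize a tip/taxon label: strip surrounding quotes, map
    underscores to spaces, collapse internal whitespace."""
    s = label.strip()
    if len(s) >= 2 and s[0] == s[-1] and s[0] in ("'", '"'):
        s = s[1:-1]
    s = s.replace("_", " ")
    return _WS.sub(" ", s).strip()


def normalize_binomial(name: str) -> str:
    """Identity key for a taxon name.

    The genus token is case-sensitive (case-preserving); every further
    token (the species epithet) is compared case-insensitively, so
    ``Dryosaurus Altus`` and ``Dryosaurus_altus`` collide while
    ``dryosaurus altus`` does not.
    """
    tokens = normalize_label(name).split(" ")
    if not tokens:
        return ""
    return " ".join([tokens[0]] + [t.lower() for t in tokens[1:]])


# ---------------------------------------------------------------------------
# enums

class Connective(str, Enum):
    """How the members of a specifier/context list are joined."""

    AND = "and"
    OR = "or"
    NONE = "none"


class Polarity(str, Enum):
    """Direction of a context constraint: ``∈`` (within) or ``∉`` (outside)."""

    WITHIN = "within"
    OUTSIDE = "outside"


class DefinitionKind(str, Enum):
    MINIMUM = "minimum"
    MAXIMUM = "maximum"


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class TaxonName:
    """A taxon used as a specifier or as a context reference.

    ``binomial`` is the name proper ("Genus epithet" for species-level
    names, a single token for supraspecific clade-name references).
    ``authority`` keeps any trailing author/citation material verbatim;
    it never participates in identity.
    """

    binomial: str
    authority: Optional[str] = None
    is_supraspecific: bool = False

    @property
    def key(self) -> str:
        return normalize_binomial(self.binomial)

    def __eq__(self, other: object) -> bool:  # identity on normalized binomial
        if not isinstance(other, TaxonName):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __str__(self) -> str:
        return self.binomial


@dataclass(frozen=True)
class ContextConstraint:
    """Restricts a name's applicability relative to other named clades.

    ``polarity`` is :attr:`Polarity.WITHIN` for ``∈`` ("the smallest clade
    *within* Ornithopoda containing ...") or :attr:`Polarity.OUTSIDE` for
    ``∉`` ("the largest clade *outside* Hypsilophodontidae or
    Thescelosauridae containing ...").  ``contexts`` are clade-name
    references, left symbolic at parse time and resolved against a corpus
    only when the definition is applied to a tree.
    """

    polarity: Polarity
    contexts: tuple[TaxonName, ...]
    connective: Connective = Connective.NONE


@dataclass(frozen=True)
class CladeDefinition:
    """One named phylogenetic definition.

    ``internal`` specifiers must end up inside the named clade; for
    maximum-clade definitions ``external`` specifiers must end up outside.
    ``qualifying_excluded`` holds the taxa of a "provided that it does not
    include ..." clause: their inclusion voids the name on that topology
    rather than re-anchoring it.  Connectives are recorded exactly as
    printed; their exclusion semantics are decided by the resolver.
    """

    clade_name: str
    kind: DefinitionKind
    internal: tuple[TaxonName, ...]
    external: tuple[TaxonName, ...] = ()
    external_connective: Connective = Connective.NONE
    qualifying_excluded: tuple[TaxonName, ...] = ()
    qualifying_connective: Connective = Connective.NONE
    context: Optional[ContextConstraint] = None
    registration_number: Optional[int] = None
    authorship: str = ""
    status: str = "converted"  # "converted" | "new"

    def strip_authorities(self) -> "CladeDefinition":
        """Copy of this definition with all authority text dropped."""
        bare = lambda ts: tuple(
            TaxonName(t.binomial, None, t.is_supraspecific) for t in ts
        )
        ctx = self.context
        if ctx is not None:
            ctx = ContextConstraint(ctx.polarity, bare(ctx.contexts), ctx.connective)
        return CladeDefinition(
            clade_name=self.clade_name,
            kind=self.kind,
            internal=bare(self.internal),
            external=bare(self.external),
            external_connective=self.external_connective,
            qualifying_excluded=bare(self.qualifying_excluded),
            qualifying_connective=self.qualifying_connective,
            context=ctx,
            registration_number=self.registration_number,
            authorship=self.authorship,
            status=self.status,
        )


# ---------------------------------------------------------------------------
# errors

class DefinitionSyntaxError(ValueError):
    """Malformed abbreviated-definition text; carries the offending position."""

    def __init__(self, message: str, position: int, text: str):
        self.position = position
        self.text = text
        super().__init__(f"{message} (at position {position}: ...{text[position:position + 25]!r})")


class DefinitionValidationError(ValueError):
    """A parsed definition violates a structural invariant."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("; ".join(violations))


# ---------------------------------------------------------------------------
# tokenizer

_SYMBOLS = {
    "(": "LPAREN",
    ")": "RPAREN",
    "&": "AMP",
    "∨": "VEE",
    "~": "TILDE",
    "|": "PIPE",
    "∈": "IN",
    "∉": "NOTIN",
    "∇": "NABLA",
}

_WORD_ALIASES = {
    "and": "AMP",
    "or": "VEE",
    "not": "TILDE",
    "in": "IN",
    "not-in": "NOTIN",
    "nabla": "NABLA",
}

_WORD_RE = re.compile(r"[^\s()&∨~|∈∉∇\[\]]+")


@dataclass
class _Token:
    kind: str
    text: str
    start: int
    end: int


def _tokenize(raw: str) -> tuple[list[_Token], str]:
    # Markdown emphasis markers are transcription noise; blank them so
    # offsets into the original string stay valid.
    text = raw.replace("*", " ")
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c == "[":  # bracketed citation -> authority material
            depth, j = 1, i + 1
            while j < n and depth:
                depth += {"[": 1, "]": -1}.get(text[j], 0)
                j += 1
            if depth:
                raise DefinitionSyntaxError("unterminated '['", i, text)
            tokens.append(_Token("AUTH", text[i:j], i, j))
            i = j
            continue
        if c == "(":
            # "([...])" is a parenthesized citation, not a grammar paren
            j = i + 1
            while j < n and text[j].isspace():
                j += 1
            if j < n and text[j] == "[":
                depth, k = 1, i + 1
                while k < n and depth:
                    depth += {"(": 1, ")": -1}.get(text[k], 0)
                    k += 1
                if depth:
                    raise DefinitionSyntaxError("unterminated '('", i, text)
                tokens.append(_Token("AUTH", text[i:k], i, k))
                i = k
                continue
        if c in _SYMBOLS:
            tokens.append(_Token(_SYMBOLS[c], c, i, i + 1))
            i += 1
            continue
        m = _WORD_RE.match(text, i)
        if not m:
            raise DefinitionSyntaxError(f"unexpected character {c!r}", i, text)
        word = m.group(0)
        if word == "provided-not":  # alias for the "| ~" pair
            tokens.append(_Token("PIPE", word, m.start(), m.end()))
            tokens.append(_Token("TILDE", word, m.start(), m.end()))
        else:
            tokens.append(_Token(_WORD_ALIASES.get(word, "WORD"), word, m.start(), m.end()))
        i = m.end()
    return tokens, text


# ---------------------------------------------------------------------------
# parser

_CONNECTIVE_OF = {"AMP": Connective.AND, "VEE": Connective.OR}


class _Parser:
    def __init__(self, tokens: list[_Token], text: str):
        self.tokens = tokens
        self.text = text
        self.pos = 0

    # -- token plumbing -----------------------------------------------------
    def peek(self, offset: int = 0) -> Optional[_Token]:
        i = self.pos + offset
        return self.tokens[i] if i < len(self.tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise DefinitionSyntaxError("unexpected end of input", len(self.text), self.text)
        self.pos += 1
        return tok

    def expect(self, kind: str, what: str) -> _Token:
        tok = self.peek()
        if tok is None or tok.kind != kind:
            at = tok.start if tok else len(self.text)
            raise DefinitionSyntaxError(f"expected {what}", at, self.text)
        return self.next()

    def error(self, message: str) -> DefinitionSyntaxError:
        tok = self.peek()
        at = tok.start if tok else len(self.text)
        return DefinitionSyntaxError(message, at, self.text)

    # -- grammar ------------------------------------------------------------
    def parse(self) -> CladeDefinition:
        kind = self._kind()
        context = self._context()
        self.expect("LPAREN", "'('")
        internal = self._taxon_list(allow_or=False)[0]
        external: tuple[TaxonName, ...] = ()
        external_conn = Connective.NONE
        qualifying: tuple[TaxonName, ...] = ()
        qualifying_conn = Connective.NONE
        tok = self.peek()
        if tok is not None and tok.kind == "TILDE":
            self.next()
            external, external_conn = self._taxon_list(allow_or=True)
            tok = self.peek()
        if tok is not None and tok.kind == "PIPE":
            self.next()
            self.expect("TILDE", "'~' after '|'")
            qualifying, qualifying_conn = self._taxon_list(allow_or=True)
        self.expect("RPAREN", "')'")
        if self.peek() is not None:
            raise self.error("trailing material after definition")
        return CladeDefinition(
            clade_name="",
            kind=kind,
            internal=internal,
            external=external,
            external_connective=external_conn,
            qualifying_excluded=qualifying,
            qualifying_connective=qualifying_conn,
            context=context,
        )

    def _kind(self) -> DefinitionKind:
        tok = self.expect("WORD", "'max' or 'min'")
        word = tok.text
        if word in ("max-clade", "min-clade"):
            return DefinitionKind.MAXIMUM if word.startswith("max") else DefinitionKind.MINIMUM
        if word in ("max", "min"):
            self.expect("NABLA", "'∇' (clade symbol)")
            return DefinitionKind.MAXIMUM if word == "max" else DefinitionKind.MINIMUM
        raise DefinitionSyntaxError("expected 'max' or 'min'", tok.start, self.text)

    def _context(self) -> Optional[ContextConstraint]:
        tok = self.peek()
        if tok is None or tok.kind not in ("IN", "NOTIN"):
            return None
        polarity = Polarity.WITHIN if tok.kind == "IN" else Polarity.OUTSIDE
        self.next()
        names = [self._clade_ref()]
        connective = Connective.NONE
        while True:
            tok = self.peek()
            if tok is None or tok.kind not in _CONNECTIVE_OF:
                break
            conn = _CONNECTIVE_OF[tok.kind]
            if connective is Connective.NONE:
                connective = conn
            elif connective is not conn:
                raise self.error("mixed '&'/'∨' within one context list")
            self.next()
            names.append(self._clade_ref())
        return ContextConstraint(polarity, tuple(names), connective)

    def _clade_ref(self) -> TaxonName:
        tok = self.expect("WORD", "clade name")
        if not tok.text[0].isupper():
            raise DefinitionSyntaxError("clade name must be capitalized", tok.start, self.text)
        authority = self._authority(citations_only=True)
        return TaxonName(tok.text, authority, is_supraspecific=True)

    def _taxon_list(self, allow_or: bool) -> tuple[tuple[TaxonName, ...], Connective]:
        taxa = [self._taxon()]
        connective = Connective.NONE
        while True:
            tok = self.peek()
            if tok is None or tok.kind not in _CONNECTIVE_OF:
                break
            conn = _CONNECTIVE_OF[tok.kind]
            if conn is Connective.OR and not allow_or:
                raise self.error("internal specifiers must be joined by '&'")
            if connective is Connective.NONE:
                connective = conn
            elif connective is not conn:
                raise self.error("mixed '&'/'∨' within one specifier list")
            self.next()
            taxa.append(self._taxon())
        return tuple(taxa), connective

    def _taxon(self) -> TaxonName:
        genus = self.expect("WORD", "taxon name")
        nxt = self.peek()
        if nxt is not None and nxt.kind == "WORD" and nxt.text[0].islower():
            epithet = self.next()
            binomial = f"{genus.text} {epithet.text}"
            supra = False
        else:
            binomial = genus.text
            supra = True
        authority = self._authority()
        return TaxonName(binomial, authority, is_supraspecific=supra)

    def _authority(self, citations_only: bool = False) -> Optional[str]:
        """Trailing citation/author material after a name, verbatim.

        Anything up to the next structural token (connective, '~', '|',
        ')') belongs to the authority: bracketed keys, parenthesized
        citations, and loose words such as ``Owen in`` (the ``in``/
        ``not-in`` alias words are demoted to plain text here — they only
        act as glyph aliases in context position).  With
        ``citations_only`` (used for context clade references, which sit
        directly before the definition body) only bracketed/citation
        tokens are consumed.
        """
        start = end = None
        while True:
            tok = self.peek()
            if tok is None or tok.kind in ("AMP", "VEE", "TILDE", "PIPE", "RPAREN", "NABLA"):
                break
            if citations_only and tok.kind != "AUTH":
                break
            if tok.kind == "LPAREN":  # e.g. "(Marsh, 1885)"
                depth = 0
                first = tok
                while True:
                    t = self.next()
                    depth += {"LPAREN": 1, "RPAREN": -1}.get(t.kind, 0)
                    if depth == 0:
                        break
                    if self.peek() is None:
                        raise DefinitionSyntaxError("unbalanced '(' in authority", first.start, self.text)
                end_tok = t
                start = first.start if start is None else start
                end = end_tok.end
                continue
            self.next()
            start = tok.start if start is None else start
            end = tok.end
        if start is None:
            return None
        return _WS.sub(" ", self.text[start:end]).strip()


def parse_definition(text: str, *, validate: bool = True, **meta) -> CladeDefinition:
    """Parse one abbreviated-notation definition string.

    Accepts either Unicode glyphs or their ASCII aliases (mixing is
    allowed).  Markdown emphasis markers and bracketed citation keys are
    tolerated: emphasis is discarded and citations are captured into each
    name's ``authority``.  Keyword arguments (``clade_name``,
    ``registration_number``, ``authorship``, ``status``) attach corpus
    metadata to the parsed structure.

    Raises :class:`DefinitionSyntaxError` with a character position for
    malformed input, and (unless ``validate=False``)
    :class:`DefinitionValidationError` when the parsed structure violates
    an invariant, e.g. a minimum-clade definition with a single internal
    specifier.
    """
    tokens, prepared = _tokenize(text)
    parsed = _Parser(tokens, prepared).parse()
    if meta:
        parsed = CladeDefinition(
            clade_name=meta.get("clade_name", parsed.clade_name),
            kind=parsed.kind,
            internal=parsed.internal,
            external=parsed.external,
            external_connective=parsed.external_connective,
            qualifying_excluded=parsed.qualifying_excluded,
            qualifying_connective=parsed.qualifying_connective,
            context=parsed.context,
            registration_number=meta.get("registration_number"),
            authorship=meta.get("authorship", ""),
            status=meta.get("status", "converted"),
        )
    if validate:
        violations = validate_definition(parsed)
        if violations:
            raise DefinitionValidationError(violations)
    return parsed


# ---------------------------------------------------------------------------
# serializer

def _fmt(taxon: TaxonName, include_authority: bool) -> str:
    if include_authority and taxon.authority:
        return f"{taxon.binomial} {taxon.authority}"
    return taxon.binomial


def _join(taxa: Sequence[TaxonName], connective: Connective, include_authority: bool) -> str:
    glyph = " ∨ " if connective is Connective.OR else " & "
    return glyph.join(_fmt(t, include_authority) for t in taxa)


def serialize_definition(d: CladeDefinition, *, include_authority: bool = False) -> str:
    """Emit the canonical abbreviated form (single spaces, Unicode glyphs).

    ``parse_definition(serialize_definition(d))`` equals ``d`` up to
    authority stripping and corpus metadata.
    """
    parts = ["max" if d.kind is DefinitionKind.MAXIMUM else "min", "∇"]
    if d.context is not None:
        parts.append("∈" if d.context.polarity is Polarity.WITHIN else "∉")
        parts.append(_join(d.context.contexts, d.context.connective, include_authority))
    body = _join(d.internal, Connective.AND, include_authority)
    if d.external:
        body += " ~ " + _join(d.external, d.external_connective, include_authority)
    if d.qualifying_excluded:
        body += " | ~ " + _join(d.qualifying_excluded, d.qualifying_connective, include_authority)
    parts.append(f"({body})")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# validation

def _duplicates(taxa: Iterable[TaxonName]) -> list[str]:
    seen, dups = set(), []
    for t in taxa:
        if t.key in seen and t.key not in dups:
            dups.append(t.key)
        seen.add(t.key)
    return dups


def validate_definition(d: CladeDefinition) -> list[str]:
    """Check every structural invariant; violations come back as data.

    An empty list means the definition is well-formed.  Corpus-level rules
    (registration-number uniqueness) are checked in
    :func:`cladedef.corpus.load_corpus`, not here.
    """
    v: list[str] = []
    if d.kind is DefinitionKind.MINIMUM and len(d.internal) < 2:
        v.append("minimum definition requires ≥2 internal specifiers")
    if d.kind is DefinitionKind.MAXIMUM:
        if len(d.internal) < 1:
            v.append("maximum definition requires ≥1 internal specifier")
        if len(d.external) < 1:
            v.append("maximum definition requires ≥1 external specifier")
    for label, taxa in (
        ("internal", d.internal),
        ("external", d.external),
        ("qualifying_excluded", d.qualifying_excluded),
    ):
        for dup in _duplicates(taxa):
            v.append(f"{label}: duplicate specifier {dup!r} after normalization")
    internal_keys = {t.key for t in d.internal}
    overlap = internal_keys & {t.key for t in d.external}
    if overlap:
        v.append(f"internal and external specifiers overlap: {sorted(overlap)}")
    overlap = internal_keys & {t.key for t in d.qualifying_excluded}
    if overlap:
        v.append(f"internal and qualifying specifiers overlap: {sorted(overlap)}")
    for label, taxa, conn in (
        ("external", d.external, d.external_connective),
        ("qualifying_excluded", d.qualifying_excluded, d.qualifying_connective),
    ):
        if len(taxa) <= 1 and conn is not Connective.NONE:
            v.append(f"{label}: connective must be 'none' for ≤1 member")
        if len(taxa) > 1 and conn is Connective.NONE:
            v.append(f"{label}: connective required for >1 member")
    for t in (*d.internal, *d.external, *d.qualifying_excluded):
        tokens = t.binomial.split()
        if not tokens:
            v.append("empty taxon name")
            continue
        if not tokens[0][0].isupper():
            v.append(f"taxon name {t.binomial!r}: genus must be capitalized")
        if not t.is_supraspecific and len(tokens) != 2:
            v.append(f"species-level name {t.binomial!r} must have exactly two tokens")
    if d.context is not None:
        if not d.context.contexts:
            v.append("context constraint requires ≥1 clade reference")
        if len(d.context.contexts) == 1 and d.context.connective is not Connective.NONE:
            v.append("context: connective must be 'none' for a single clade reference")
        if len(d.context.contexts) > 1 and d.context.connective is Connective.NONE:
            v.append("context: connective required for >1 clade reference")
    if d.registration_number is not None and d.registration_number <= 0:
        v.append("registration_number must be a positive integer")
    if d.status not in ("converted", "new"):
        v.append(f"status must be 'converted' or 'new', got {d.status!r}")
    return v
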