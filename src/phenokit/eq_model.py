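"""Entity-quality (EQ) logical definitions of phenotype terms.

A phenotype class is defined by the equivalent-class expression

    has part some (Q and characteristic_of[_part_of] some E
                   and has modifier some M [and towards some T])

where Q is a quality (PATO-style), E the bearer entity (anatomy, process,
cell, chemical; optionally located via ``occurs in`` when the bearer is a
process, or carrying a chemical role via ``has role``), M the
abnormal/normal modifier, and T the second entity of a relational quality
(e.g. "fused with").  ``EQDefinition`` is the normal form of that expression;
two definitions are logically identical iff their normal forms are equal
field by field.

The textual rendering follows OWL Manchester syntax for this fragment, with
multi-word class labels single-quoted.  The parser is deliberately tolerant:
relation keywords may be quoted, conjuncts and atoms may carry redundant
parentheses, and ``qualifier`` is accepted as an alias of ``has modifier``
(both occur in the wild; ``has modifier`` is the canonical relation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .errors import ParseError, UnknownTermError, ValidationError
from .ontology_io import (
    CHARACTERISTIC_OF,
    CHARACTERISTIC_OF_PART_OF,
    IS_A,
    Curie,
    as_curie,
)
from .references import References

__all__ = [
    "EntityExpression",
    "EQDefinition",
    "normalize",
    "validate_eq",
    "render_manchester",
    "parse_manchester",
]

BEARER_MODES = (CHARACTERISTIC_OF, CHARACTERISTIC_OF_PART_OF)


def _opt_curie(value: str | Curie | None) -> Curie | None:
    return None if value is None else as_curie(value)


@dataclass(frozen=True)
class EntityExpression:
    """The bearer expression of an EQ definition.

    ``entity`` is mandatory.  ``occurs_in`` localizes a process bearer to an
    anatomical entity; ``towards`` names the second entity of a relational
    quality; ``role`` gives a chemical-role context.
    """

    entity: Curie
    occurs_in: Curie | None = None
    towards: Curie | None = None
    role: Curie | None = None

    def __post_init__(self):
        object.__setattr__(self, "entity", as_curie(self.entity))
        object.__setattr__(self, "occurs_in", _opt_curie(self.occurs_in))
        object.__setattr__(self, "towards", _opt_curie(self.towards))
        object.__setattr__(self, "role", _opt_curie(self.role))


@dataclass(frozen=True)
class EQDefinition:
    """Normalized EQ logical definition of one phenotype term."""

    quality: Curie
    bearer: EntityExpression
    bearer_mode: str = CHARACTERISTIC_OF_PART_OF
    modifier: Curie = Curie("PATO", "0000460")  # "abnormal"

    def __post_init__(self):
        object.__setattr__(self, "quality", as_curie(self.quality))
        if isinstance(self.bearer, (str, Curie)):
            object.__setattr__(self, "bearer", EntityExpression(as_curie(self.bearer)))
        object.__setattr__(self, "modifier", as_curie(self.modifier))
        if self.bearer_mode not in BEARER_MODES:
            raise ValidationError(f"invalid bearer_mode: {self.bearer_mode!r}")

    def atoms(self) -> list[Curie]:
        """All CURIEs referenced by the definition, in canonical field order."""
        out = [self.quality, self.bearer.entity]
        for c in (self.bearer.occurs_in, self.bearer.towards, self.bearer.role):
            if c is not None:
                out.append(c)
        out.append(self.modifier)
        return out


def validate_eq(eq: EQDefinition, refs: References, strict: bool = False) -> None:
    """Check every CURIE resolves and structural constraints hold.

    Unresolvable CURIEs raise one error listing every unresolved id.  With
    ``strict`` the quality must descend from the designated quality root and
    ``occurs_in`` is only allowed on process-type bearers.
    """
    unresolved = [str(c) for c in eq.atoms() if c not in refs]
    if unresolved:
        raise UnknownTermError("unresolved ids: " + ", ".join(sorted(set(unresolved))))
    if strict:
        if refs.quality_root is not None:
            anc = refs.quality.closure(eq.quality, [IS_A], reflexive=True)
            if refs.quality_root not in anc:
                raise ValidationError(
                    f"quality {eq.quality} is not a descendant of the quality root "
                    f"{refs.quality_root}"
                )
        if eq.bearer.occurs_in is not None and refs.process_root is not None:
            entity_graph = refs.merged_entity_graph()
            anc = entity_graph.closure(eq.bearer.entity, [IS_A], reflexive=True)
            if refs.process_root not in anc:
                raise ValidationError(
                    f"occurs_in is only meaningful for process bearers; "
                    f"{eq.bearer.entity} is not a process"
                )


def normalize(eq: EQDefinition, refs: References, strict: bool = False) -> EQDefinition:
    """Validate and return the canonical form of a definition.

    The dataclass representation already fixes field order and uses ``None``
    as the explicit empty marker for absent optional fields, so
    normalization is idempotent and normal-form equality is plain dataclass
    equality.
    """
    validate_eq(eq, refs, strict=strict)
    return replace(eq, bearer=replace(eq.bearer))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_BARE_LABEL_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.\-]*$")

_MODE_KEYWORD = {
    CHARACTERISTIC_OF: "characteristic of",
    CHARACTERISTIC_OF_PART_OF: "characteristic of part of",
}
_KEYWORD_MODE = {v: k for k, v in _MODE_KEYWORD.items()}


def _render_label(curie: Curie, labels) -> str:
    label = labels.get(curie) if hasattr(labels, "get") else None
    if label is None or label == "":
        raise UnknownTermError(f"no label available for {curie}")
    if _BARE_LABEL_RE.match(label) and label.lower() not in ("and", "some"):
        return label
    return f"'{label}'"


def render_manchester(eq: EQDefinition, labels: dict[Curie, str]) -> str:
    """Render the definition deterministically in the fragment's Manchester
    grammar, e.g. ``has part some (morphology and characteristic of part of
    some heart and has modifier some abnormal)``."""
    q = _render_label(eq.quality, labels)
    mode = _MODE_KEYWORD[eq.bearer_mode]
    b = eq.bearer
    bearer = _render_label(b.entity, labels)
    inner = []
    if b.occurs_in is not None:
        inner.append(f"occurs in some {_render_label(b.occurs_in, labels)}")
    if b.role is not None:
        inner.append(f"has role some {_render_label(b.role, labels)}")
    if inner:
        bearer = "(" + " and ".join([bearer] + inner) + ")"
    parts = [q, f"{mode} some {bearer}", f"has modifier some {_render_label(eq.modifier, labels)}"]
    if b.towards is not None:
        parts.append(f"towards some {_render_label(b.towards, labels)}")
    return "has part some (" + " and ".join(parts) + ")"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""\s*(?:
        (?P<quoted>'(?:[^'\\]|\\.)*'|‘[^’]*’)   # single-quoted label (ASCII or curly)
      | (?P<lparen>\()
      | (?P<rparen>\))
      | (?P<word>[^\s()']+)
    )""",
    re.VERBOSE,
)

# Relation keywords of the fragment, longest first so greedy matching works.
_RELATIONS = [
    "characteristic of part of",
    "inheres in part of",  # historical synonym of characteristic of part of
    "characteristic of",
    "inheres in",
    "has modifier",
    "has part",
    "occurs in",
    "has role",
    "qualifier",
    "towards",
]


@dataclass(frozen=True)
class _Token:
    kind: str  # 'word' | 'quoted' | 'lparen' | 'rparen'
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise ParseError("unexpected character", position=pos)
            break
        if m.lastgroup == "quoted":
            raw = m.group("quoted")
            tokens.append(_Token("quoted", raw[1:-1].replace("\\'", "'"), m.start()))
        elif m.lastgroup == "lparen":
            tokens.append(_Token("lparen", "(", m.start()))
        elif m.lastgroup == "rparen":
            tokens.append(_Token("rparen", ")", m.start()))
        else:
            tokens.append(_Token("word", m.group("word"), m.start()))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[_Token], text: str):
        self.tokens = tokens
        self.text = text
        self.i = 0

    def _pos(self) -> int:
        return self.tokens[self.i].pos if self.i < len(self.tokens) else len(self.text)

    def peek(self, offset: int = 0) -> _Token | None:
        j = self.i + offset
        return self.tokens[j] if j < len(self.tokens) else None

    def at_relation(self) -> str | None:
        """Return the relation keyword starting at the cursor, if any."""
        tok = self.peek()
        if tok is None:
            return None
        if tok.kind == "quoted":
            return tok.text if tok.text in _RELATIONS else None
        if tok.kind != "word":
            return None
        for rel in _RELATIONS:
            words = rel.split()
            if all(
                (t := self.peek(k)) is not None and t.kind == "word" and t.text == w
                for k, w in enumerate(words)
            ):
                return rel
        return None

    def eat_relation(self, expected: str | None = None) -> str:
        rel = self.at_relation()
        if rel is None or (expected is not None and rel != expected):
            raise ParseError(
                f"expected relation keyword{' ' + repr(expected) if expected else ''}",
                position=self._pos(),
            )
        tok = self.peek()
        self.i += 1 if tok.kind == "quoted" else len(rel.split())
        return rel

    def eat_keyword(self, word: str) -> None:
        tok = self.peek()
        if tok is None or tok.kind not in ("word", "quoted") or tok.text != word:
            raise ParseError(f"expected {word!r}", position=self._pos())
        self.i += 1

    def eat(self, kind: str) -> _Token:
        tok = self.peek()
        if tok is None or tok.kind != kind:
            raise ParseError(f"expected {kind}", position=self._pos())
        self.i += 1
        return tok

    def parse_label(self) -> str:
        """A quoted label, or greedy bare words up to 'and' / ')' / end."""
        tok = self.peek()
        if tok is None:
            raise ParseError("expected a class label", position=self._pos())
        if tok.kind == "quoted":
            self.i += 1
            return tok.text
        if tok.kind == "lparen":
            self.i += 1
            label = self.parse_label()
            self.eat("rparen")
            return label
        words = []
        while (t := self.peek()) is not None and t.kind == "word" and t.text != "and":
            words.append(t.text)
            self.i += 1
        if not words:
            raise ParseError("expected a class label", position=self._pos())
        return " ".join(words)


def parse_manchester(text: str, label_to_id: dict[str, Curie]) -> EQDefinition:
    """Parse the rendered grammar back into an ``EQDefinition``.

    Inverse of :func:`render_manchester` on its image.  Labels are looked up
    case-sensitively in ``label_to_id``; unknown labels and malformed nesting
    raise :class:`ParseError` with a character position.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise ParseError("empty class expression", position=0)
    p = _Parser(tokens, text)
    # Optional outer parentheses around the whole expression.
    outer = 0
    while (t := p.peek()) is not None and t.kind == "lparen":
        nxt = p.peek(1)
        if nxt is not None and (nxt.kind in ("quoted", "word")) and p_is_has_part(p):
            p.i += 1
            outer += 1
        else:
            break
    p.eat_relation("has part")
    p.eat_keyword("some")
    p.eat("lparen")

    def resolve(label: str, pos: int) -> Curie:
        if label not in label_to_id:
            raise ParseError(f"unknown class label: {label!r}", position=pos)
        return as_curie(label_to_id[label])

    quality: Curie | None = None
    entity: Curie | None = None
    mode: str | None = None
    modifier: Curie | None = None
    occurs_in: Curie | None = None
    towards: Curie | None = None
    role: Curie | None = None

    def parse_bearer_filler() -> None:
        nonlocal entity, occurs_in, role, towards
        tok = p.peek()
        if tok is not None and tok.kind == "lparen":
            # Could be a parenthesized atom or a bearer group with clauses.
            p.i += 1
            pos = p._pos()
            if p.at_relation() is None:
                entity = resolve(p.parse_label(), pos)
            while (t := p.peek()) is not None and t.kind == "word" and t.text == "and":
                p.i += 1
                parse_bearer_clause()
            p.eat("rparen")
        else:
            pos = p._pos()
            entity = resolve(p.parse_label(), pos)

    def parse_bearer_clause() -> None:
        nonlocal occurs_in, role, towards
        wrapped = False
        if (t := p.peek()) is not None and t.kind == "lparen":
            p.i += 1
            wrapped = True
        rel = p.eat_relation()
        p.eat_keyword("some")
        pos = p._pos()
        filler = resolve(p.parse_label(), pos)
        if rel == "occurs in":
            set_once("occurs in", filler, pos)
        elif rel == "has role":
            set_once("has role", filler, pos)
        elif rel == "towards":
            set_once("towards", filler, pos)
        else:
            raise ParseError(f"unexpected relation {rel!r} in bearer expression", position=pos)
        if wrapped:
            p.eat("rparen")

    def set_once(name: str, value, pos: int) -> None:
        nonlocal quality, entity, mode, modifier, occurs_in, towards, role
        slots = {
            "occurs in": "occurs_in",
            "has role": "role",
            "towards": "towards",
            "modifier": "modifier",
        }
        key = slots[name]
        current = {"occurs_in": occurs_in, "role": role, "towards": towards, "modifier": modifier}[key]
        if current is not None:
            raise ParseError(f"duplicate {name!r} clause", position=pos)
        if key == "occurs_in":
            occurs_in = value
        elif key == "role":
            role = value
        elif key == "towards":
            towards = value
        else:
            modifier = value

    while True:
        wrapped = False
        if (t := p.peek()) is not None and t.kind == "lparen":
            p.i += 1
            wrapped = True
        rel = p.at_relation()
        pos = p._pos()
        if rel in (_KEYWORD_MODE | {"inheres in": CHARACTERISTIC_OF, "inheres in part of": CHARACTERISTIC_OF_PART_OF}):
            p.eat_relation(rel)
            p.eat_keyword("some")
            if mode is not None:
                raise ParseError("duplicate bearer clause", position=pos)
            mode = {
                "characteristic of": CHARACTERISTIC_OF,
                "inheres in": CHARACTERISTIC_OF,
                "characteristic of part of": CHARACTERISTIC_OF_PART_OF,
                "inheres in part of": CHARACTERISTIC_OF_PART_OF,
            }[rel]
            parse_bearer_filler()
        elif rel in ("has modifier", "qualifier"):
            p.eat_relation(rel)
            p.eat_keyword("some")
            set_once("modifier", resolve(p.parse_label(), p._pos()), pos)
        elif rel in ("occurs in", "has role", "towards"):
            p.eat_relation(rel)
            p.eat_keyword("some")
            set_once(rel, resolve(p.parse_label(), p._pos()), pos)
        elif rel is not None:
            raise ParseError(f"unexpected relation {rel!r}", position=pos)
        else:
            if quality is not None:
                raise ParseError("more than one quality conjunct", position=pos)
            quality = resolve(p.parse_label(), pos)
        if wrapped:
            p.eat("rparen")
        t = p.peek()
        if t is not None and t.kind == "word" and t.text == "and":
            p.i += 1
            continue
        break

    p.eat("rparen")
    for _ in range(outer):
        p.eat("rparen")
    if p.peek() is not None:
        raise ParseError("trailing content after class expression", position=p._pos())
    if quality is None:
        raise ParseError("missing quality conjunct", position=len(text))
    if entity is None or mode is None:
        raise ParseError("missing bearer clause", position=len(text))
    if modifier is None:
        raise ParseError("missing has-modifier clause", position=len(text))
    return EQDefinition(
        quality=quality,
        bearer=EntityExpression(entity, occurs_in=occurs_in, towards=towards, role=role),
        bearer_mode=mode,
        modifier=modifier,
    )


def p_is_has_part(p: _Parser) -> bool:
    """Look ahead (past the current lparen) for a 'has part' keyword."""
    saved = p.i
    p.i += 1
    rel = p.at_relation()
    p.i = saved
    return rel == "has part"
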