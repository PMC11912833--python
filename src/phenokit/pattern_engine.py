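"""Design-pattern templates and filler tables: mass production of phenotype terms.

A pattern template is a YAML document (a DOSDP subset) with variable slots:
text templates for the label, definition and synonyms (printf ``%s`` slots
substituted positionally, in the order of each field's ``vars`` list), and a
Manchester-style ``equivalentTo`` template whose substitution is parsed into
an :class:`~phenokit.eq_model.EQDefinition`.  Filler tables are TSV files
whose header names the template variables; each accepted row mints one fully
annotated phenotype term.

Minted identifiers are numeric local ids assigned from a configurable range
by a stable hash of ``(pattern_id, sorted binding)``; collisions are resolved
by linear probing and recorded in a ledger that can be persisted beside the
generated fragment, so regeneration is reproducible term for term.
"""

from __future__ import annotations

import csv
import hashlib
import io
import json
import re
from dataclasses import dataclass, field

import yaml

from .errors import ParseError, UnknownTermError, ValidationError
from .eq_model import EQDefinition, parse_manchester
from .ontology_io import IS_A, Curie, OntologyGraph, OntologyTerm, as_curie
from .references import References

__all__ = [
    "PatternTemplate",
    "TextTemplate",
    "FillerTable",
    "GeneratedTerm",
    "IdMinter",
    "Binding",
    "load_template",
    "load_template_file",
    "dump_template",
    "bind",
    "instantiate",
    "instantiate_all",
    "InstantiationResult",
]

_SLOT_RE = re.compile(r"%s")


@dataclass(frozen=True)
class TextTemplate:
    """A text field with positional ``%s`` slots filled from named vars."""

    text: str
    vars: tuple[str, ...] = ()

    def fill(self, values: dict[str, str]) -> str:
        labels = tuple(values[v] for v in self.vars)
        n_slots = len(_SLOT_RE.findall(self.text))
        if n_slots != len(labels):
            raise ValidationError(
                f"template text {self.text!r} has {n_slots} slots for {len(labels)} vars"
            )
        return self.text % labels


@dataclass(frozen=True)
class PatternTemplate:
    pattern_id: str
    description: str = ""
    contributors: tuple[str, ...] = ()
    vars: dict[str, Curie] = field(default_factory=dict)  # var name -> range class
    name_template: TextTemplate | None = None
    def_template: TextTemplate | None = None
    synonym_templates: tuple[TextTemplate, ...] = ()
    equivalent_to_template: TextTemplate | None = None
    declared_classes: dict[str, Curie] = field(default_factory=dict)  # label -> id
    declared_relations: dict[str, Curie] = field(default_factory=dict)

    @property
    def var_names(self) -> tuple[str, ...]:
        return tuple(self.vars)


Binding = dict  # var name -> Curie


@dataclass
class FillerTable:
    rows: list[Binding]
    columns: tuple[str, ...]
    source: str = ""

    @classmethod
    def from_tsv(cls, text: str, source: str = "") -> "FillerTable":
        reader = csv.reader(io.StringIO(text), delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"empty filler table {source!r}") from None
        header = tuple(h.strip() for h in header)
        rows: list[Binding] = []
        seen: set[tuple] = set()
        for lineno, raw in enumerate(reader, start=2):
            if not raw or all(not c.strip() for c in raw):
                continue
            if len(raw) != len(header):
                raise ParseError(f"{source}: row {lineno} has {len(raw)} cells, expected {len(header)}")
            binding = {h: as_curie(c.strip()) for h, c in zip(header, raw)}
            key = tuple(sorted((k, str(v)) for k, v in binding.items()))
            if key in seen:
                raise ValidationError(f"{source}: duplicate binding row at line {lineno}")
            seen.add(key)
            rows.append(binding)
        return cls(rows=rows, columns=header, source=source)

    def to_tsv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
        writer.writerow(self.columns)
        for row in self.rows:
            writer.writerow([str(row[c]) for c in self.columns])
        return buf.getvalue()


@dataclass(frozen=True)
class GeneratedTerm:
    id: Curie
    label: str
    text_definition: str
    synonyms: tuple[str, ...]
    eq: EQDefinition
    pattern_id: str
    binding: tuple[tuple[str, str], ...]  # (var, filler id), sorted by var
    contributors: tuple[str, ...]

    def to_ontology_term(self) -> OntologyTerm:
        provenance = [
            ("property_value", f"generated_by_pattern {self.pattern_id}"),
            (
                "property_value",
                "pattern_binding " + json.dumps(dict(self.binding), sort_keys=True),
            ),
        ]
        provenance += [("created_by", orcid) for orcid in self.contributors]
        return OntologyTerm(
            id=self.id,
            label=self.label,
            text_definition=self.text_definition or None,
            synonyms=tuple((s, "EXACT") for s in self.synonyms),
            annotations=tuple(provenance),
        )


# ---------------------------------------------------------------------------
# Template YAML
# ---------------------------------------------------------------------------


def _text_template(raw, field_name: str) -> TextTemplate:
    if isinstance(raw, str):
        return TextTemplate(text=raw, vars=())
    if isinstance(raw, dict) and "text" in raw:
        return TextTemplate(text=str(raw["text"]), vars=tuple(raw.get("vars", ())))
    raise ParseError(f"template field {field_name!r} must be a string or a text/vars mapping")


def load_template(yaml_text: str) -> PatternTemplate:
    """Parse and validate a pattern template from YAML text.

    Every var referenced by a text template must be declared under ``vars``;
    every var range must resolve to a declared class.  Contributor ORCIDs are
    preserved verbatim.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise ParseError(f"invalid template YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError("template YAML must be a mapping")
    pattern_id = doc.get("pattern_iri") or doc.get("pattern_name")
    if not pattern_id:
        raise ParseError("template must declare pattern_iri or pattern_name")

    declared_classes = {
        str(label): as_curie(cid) for label, cid in (doc.get("classes") or {}).items()
    }
    declared_relations = {
        str(label): as_curie(cid) for label, cid in (doc.get("relations") or {}).items()
    }

    vars_decl: dict[str, Curie] = {}
    for name, rng in (doc.get("vars") or {}).items():
        rng = str(rng)
        stripped = rng.strip("'\"")
        if stripped in declared_classes:
            vars_decl[str(name)] = declared_classes[stripped]
        else:
            try:
                vars_decl[str(name)] = as_curie(stripped)
            except ParseError:
                raise ValidationError(
                    f"var {name!r} range {rng!r} is neither a declared class nor a CURIE"
                ) from None

    def checked(field_name: str) -> TextTemplate | None:
        raw = doc.get(field_name)
        if raw is None:
            return None
        tt = _text_template(raw, field_name)
        for v in tt.vars:
            if v not in vars_decl:
                raise ValidationError(
                    f"template field {field_name!r} uses undeclared slot {v!r}"
                )
        n_slots = len(_SLOT_RE.findall(tt.text))
        if n_slots != len(tt.vars):
            raise ValidationError(
                f"template field {field_name!r} has {n_slots} %s slots but {len(tt.vars)} vars"
            )
        return tt

    synonyms = []
    for raw in doc.get("synonyms") or []:
        tt = _text_template(raw, "synonyms")
        for v in tt.vars:
            if v not in vars_decl:
                raise ValidationError(f"synonym template uses undeclared slot {v!r}")
        synonyms.append(tt)

    return PatternTemplate(
        pattern_id=str(pattern_id),
        description=str(doc.get("description", "")),
        contributors=tuple(doc.get("contributors") or ()),
        vars=vars_decl,
        name_template=checked("name"),
        def_template=checked("def"),
        synonym_templates=tuple(synonyms),
        equivalent_to_template=checked("equivalentTo"),
        declared_classes=declared_classes,
        declared_relations=declared_relations,
    )


def load_template_file(path: str) -> PatternTemplate:
    with open(path, encoding="utf-8") as fh:
        return load_template(fh.read())


def dump_template(template: PatternTemplate) -> str:
    """Serialize a template back to YAML (load ∘ dump ∘ load is a fixed point)."""
    doc: dict = {"pattern_iri": template.pattern_id}
    if template.description:
        doc["description"] = template.description
    if template.contributors:
        doc["contributors"] = list(template.contributors)
    if template.declared_classes:
        doc["classes"] = {k: str(v) for k, v in template.declared_classes.items()}
    if template.declared_relations:
        doc["relations"] = {k: str(v) for k, v in template.declared_relations.items()}
    if template.vars:
        doc["vars"] = {k: str(v) for k, v in template.vars.items()}
    for field_name, tt in (
        ("name", template.name_template),
        ("def", template.def_template),
        ("equivalentTo", template.equivalent_to_template),
    ):
        if tt is not None:
            doc[field_name] = {"text": tt.text, "vars": list(tt.vars)}
    if template.synonym_templates:
        doc["synonyms"] = [
            {"text": tt.text, "vars": list(tt.vars)} for tt in template.synonym_templates
        ]
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# Binding validation
# ---------------------------------------------------------------------------


@dataclass
class BindResult:
    accepted: list[Binding]
    rejected: list[tuple[Binding, str]]


def bind(template: PatternTemplate, table: FillerTable, refs: References) -> BindResult:
    """Validate each filler row against the template's var ranges.

    A filler is in range when it lies in the reflexive is_a closure of the
    declared range class.  Violating rows are rejected with a reason;
    accepted rows keep table order.
    """
    if set(table.columns) != set(template.var_names):
        raise ValidationError(
            f"filler table columns {table.columns} do not match template vars "
            f"{template.var_names}"
        )
    accepted: list[Binding] = []
    rejected: list[tuple[Binding, str]] = []
    for row in table.rows:
        reason = None
        for var, filler in row.items():
            rng = template.vars[var]
            if filler not in refs:
                reason = f"filler {filler} for var {var!r} is unresolvable"
                break
            graph = _graph_containing(refs, filler)
            if rng not in graph:
                reason = (
                    f"filler {filler} for var {var!r} is outside the range "
                    f"hierarchy of {rng}"
                )
                break
            if rng not in graph.closure(filler, [IS_A], reflexive=True):
                reason = f"filler {filler} for var {var!r} violates range {rng}"
                break
        if reason is None:
            accepted.append(row)
        else:
            rejected.append((row, reason))
    return BindResult(accepted=accepted, rejected=rejected)


def _graph_containing(refs: References, curie: Curie) -> OntologyGraph:
    for g in refs.all_graphs():
        if curie in g:
            return g
    raise UnknownTermError(f"unknown term id: {curie}")


# ---------------------------------------------------------------------------
# Id minting
# ---------------------------------------------------------------------------


class IdMinter:
    """Deterministic numeric id assignment with a collision ledger.

    The local id is ``base + (sha256(pattern_id | sorted binding) % span)``,
    linearly probed past ids already taken by other keys.  ``overrides`` pin
    specific (pattern, binding) pairs to externally fixed ids.  The ledger
    (key -> id) can be persisted and reloaded so that later runs mint
    identically even when new rows change probing order.
    """

    def __init__(
        self,
        prefix: str = "EX",
        base: int = 1_000_000,
        span: int = 1_000_000,
        pad: int = 7,
        overrides: dict[str, str | Curie] | None = None,
        ledger: dict[str, str] | None = None,
    ):
        self.prefix = prefix
        self.base = base
        self.span = span
        self.pad = pad
        self.overrides = {k: as_curie(v) for k, v in (overrides or {}).items()}
        self.ledger: dict[str, Curie] = {k: as_curie(v) for k, v in (ledger or {}).items()}
        self._taken: set[Curie] = set(self.ledger.values()) | set(self.overrides.values())

    @staticmethod
    def key(pattern_id: str, binding: Binding) -> str:
        canonical = ",".join(f"{k}={binding[k]}" for k in sorted(binding))
        return f"{pattern_id}|{canonical}"

    def mint(self, pattern_id: str, binding: Binding) -> Curie:
        key = self.key(pattern_id, binding)
        if key in self.ledger:
            return self.ledger[key]
        if key in self.overrides:
            curie = self.overrides[key]
            self.ledger[key] = curie
            self._taken.add(curie)
            return curie
        digest = hashlib.sha256(key.encode("utf-8")).digest()
        offset = int.from_bytes(digest[:8], "big") % self.span
        for probe in range(self.span):
            local = self.base + (offset + probe) % self.span
            curie = Curie(self.prefix, str(local).zfill(self.pad))
            if curie not in self._taken:
                self.ledger[key] = curie
                self._taken.add(curie)
                return curie
        raise ValidationError(f"id range exhausted (span={self.span})")

    def ledger_json(self) -> str:
        return json.dumps({k: str(v) for k, v in sorted(self.ledger.items())}, indent=2)

    @classmethod
    def from_ledger_json(cls, text: str, **kwargs) -> "IdMinter":
        return cls(ledger=json.loads(text), **kwargs)


# ---------------------------------------------------------------------------
# Instantiation
# ---------------------------------------------------------------------------


def _filler_labels(binding: Binding, refs: References) -> dict[str, str]:
    labels = {}
    for var, filler in binding.items():
        term = refs.resolve(filler)  # raises UnknownTermError if missing
        if not term.label:
            raise ValidationError(f"filler {filler} has no primary label")
        labels[var] = term.label
    return labels


def instantiate(
    template: PatternTemplate,
    binding: Binding,
    refs: References,
    minter: IdMinter,
) -> GeneratedTerm:
    """Mint one fully annotated term from a validated binding.

    The label, definition and synonyms come from slot substitution with the
    fillers' primary labels; the EQ comes from substituting filler labels
    into the equivalentTo template and parsing it with the EQ grammar.
    Minting is deterministic for (pattern_id, binding).
    """
    if template.equivalent_to_template is None:
        raise ValidationError(f"pattern {template.pattern_id} has no equivalentTo template")
    if template.name_template is None:
        raise ValidationError(f"pattern {template.pattern_id} has no name template")
    labels = _filler_labels(binding, refs)

    label = template.name_template.fill(labels)
    definition = template.def_template.fill(labels) if template.def_template else ""
    synonyms = tuple(tt.fill(labels) for tt in template.synonym_templates)

    # Substitute quoted filler labels into the logical template, then parse.
    quoted = {v: f"'{lbl}'" if not re.fullmatch(r"[A-Za-z0-9_.\-]+", lbl) else lbl for v, lbl in labels.items()}
    eq_text = template.equivalent_to_template.fill(quoted)
    label_to_id: dict[str, Curie] = {}
    for ref_label, curie in template.declared_classes.items():
        label_to_id[ref_label] = curie
    for var, filler in binding.items():
        label_to_id[labels[var]] = filler
    try:
        eq = parse_manchester(eq_text, label_to_id)
    except ParseError as exc:
        raise ValidationError(
            f"pattern {template.pattern_id}: equivalentTo did not parse after "
            f"substitution: {eq_text!r} ({exc})"
        ) from exc

    term_id = minter.mint(template.pattern_id, binding)
    return GeneratedTerm(
        id=term_id,
        label=label,
        text_definition=definition,
        synonyms=synonyms,
        eq=eq,
        pattern_id=template.pattern_id,
        binding=tuple(sorted((k, str(v)) for k, v in binding.items())),
        contributors=template.contributors,
    )


@dataclass
class InstantiationResult:
    terms: list[GeneratedTerm]
    eqs: dict[Curie, EQDefinition]
    rejected: list[tuple[Binding, str]]

    def fragment(self, ontology_id: str = "generated") -> OntologyGraph:
        graph = OntologyGraph(ontology_id)
        for t in self.terms:
            graph.add_term(t.to_ontology_term())
        return graph


def instantiate_all(
    template: PatternTemplate,
    table: FillerTable,
    refs: References,
    minter: IdMinter,
    strict: bool = False,
) -> InstantiationResult:
    """Apply :func:`instantiate` to every accepted row of the table, in table
    order.  With ``strict`` any rejected row is a hard error; otherwise row
    errors are aggregated and partial success is allowed."""
    result = bind(template, table, refs)
    if strict and result.rejected:
        reasons = "; ".join(reason for _, reason in result.rejected)
        raise ValidationError(f"pattern {template.pattern_id}: rejected rows: {reasons}")
    terms: list[GeneratedTerm] = []
    eqs: dict[Curie, EQDefinition] = {}
    for binding in result.accepted:
        term = instantiate(template, binding, refs, minter)
        terms.append(term)
        eqs[term.id] = term.eq
    return InstantiationResult(terms=terms, eqs=eqs, rejected=result.rejected)
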