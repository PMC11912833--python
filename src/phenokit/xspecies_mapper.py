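"""Cross-species phenotype mappings, exchanged as SSSOM TSV.

Two phenotype terms from different species ontologies map to each other
logically when their normalized EQ definitions — after rewriting
species-specific anatomy fillers to species-neutral ids through a bridge
table — are identical field for field (e.g. a mouse "abnormal forelimb
zeugopod morphology" and a human "Abnormal forearm morphology" defined on
the same forelimb-zeugopod anatomy class).  Lexical matching compares
normalized labels and synonyms.  Each emitted row records its predicate,
semapv-style justification and a confidence, one justification per row.

The SSSOM serialization is the standard layout: a commented YAML metadata
header (curie_map, mapping_set_id, license) followed by a TSV body with a
canonical column order.  ``read_sssom(write_sssom(m)) == m`` including
confidence at full precision.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace

import yaml

from .errors import ParseError, ValidationError
from .eq_model import EntityExpression, EQDefinition
from .ontology_io import Curie, as_curie

__all__ = [
    "BridgeTable",
    "Mapping",
    "EXACT_MATCH",
    "BROAD_MATCH",
    "NARROW_MATCH",
    "LOGICAL_MATCHING",
    "LEXICAL_MATCHING",
    "MANUAL_CURATION",
    "apply_bridges",
    "logical_matches",
    "lexical_matches",
    "merge_manual",
    "write_sssom",
    "read_sssom",
]

EXACT_MATCH = "semapv:crossSpeciesExactMatch"
BROAD_MATCH = "semapv:crossSpeciesBroadMatch"
NARROW_MATCH = "semapv:crossSpeciesNarrowMatch"
LOGICAL_MATCHING = "semapv:LogicalMatching"
LEXICAL_MATCHING = "semapv:LexicalMatching"
MANUAL_CURATION = "semapv:ManualMappingCuration"

SSSOM_COLUMNS = (
    "subject_id",
    "subject_label",
    "predicate_id",
    "object_id",
    "object_label",
    "mapping_justification",
    "confidence",
    "mapping_tool",
)

MAPPING_TOOL = "phenokit"


@dataclass
class BridgeTable:
    """Functional map from species-specific anatomy ids to species-neutral ids."""

    rows: dict[Curie, Curie]

    @classmethod
    def from_pairs(cls, pairs) -> "BridgeTable":
        rows: dict[Curie, Curie] = {}
        for species_id, neutral_id in pairs:
            species_id, neutral_id = as_curie(species_id), as_curie(neutral_id)
            if species_id in rows and rows[species_id] != neutral_id:
                raise ValidationError(
                    f"bridge table not functional: {species_id} maps to both "
                    f"{rows[species_id]} and {neutral_id}"
                )
            rows[species_id] = neutral_id
        return cls(rows=rows)

    @classmethod
    def from_tsv(cls, text: str) -> "BridgeTable":
        pairs = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if lineno == 1 and not _looks_like_curie(cells[0]):
                continue  # header row
            if len(cells) < 2:
                raise ParseError(f"bridge table line {lineno}: expected 2 columns")
            pairs.append((cells[0], cells[1]))
        return cls.from_pairs(pairs)

    def to_tsv(self) -> str:
        lines = ["species_anatomy_id\tneutral_anatomy_id"]
        for k in sorted(self.rows):
            lines.append(f"{k}\t{self.rows[k]}")
        return "\n".join(lines) + "\n"

    def rewrite(self, curie: Curie | None) -> Curie | None:
        if curie is None:
            return None
        return self.rows.get(curie, curie)


def _looks_like_curie(text: str) -> bool:
    try:
        as_curie(text)
        return True
    except ParseError:
        return False


def apply_bridges(eq: EQDefinition, bridges: BridgeTable | None) -> EQDefinition:
    """Rewrite species-specific fillers to species-neutral ids."""
    if bridges is None:
        return eq
    b = eq.bearer
    return replace(
        eq,
        bearer=EntityExpression(
            entity=bridges.rewrite(b.entity),
            occurs_in=bridges.rewrite(b.occurs_in),
            towards=bridges.rewrite(b.towards),
            role=bridges.rewrite(b.role),
        ),
    )


@dataclass(frozen=True)
class Mapping:
    subject_id: Curie
    subject_label: str
    predicate_id: str
    object_id: Curie
    object_label: str
    mapping_justification: str
    confidence: float
    mapping_tool: str = MAPPING_TOOL
    extensions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "subject_id", as_curie(self.subject_id))
        object.__setattr__(self, "object_id", as_curie(self.object_id))
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence out of [0,1]: {self.confidence}")


def _mapping_sort_key(m: Mapping):
    return (str(m.subject_id), str(m.object_id), m.predicate_id, m.mapping_justification)


def logical_matches(
    eqs_a: dict[Curie, EQDefinition],
    eqs_b: dict[Curie, EQDefinition],
    bridges_a: BridgeTable | None = None,
    bridges_b: BridgeTable | None = None,
    labels: dict[Curie, str] | None = None,
    include_near: bool = False,
    idx=None,
) -> list[Mapping]:
    """Exact logical cross-species matches between two EQ-defined term sets.

    A mapping is emitted iff the normalized, bridge-rewritten EQs are
    field-identical (predicate cross-species exact match, justification
    logical matching, confidence 1.0).  With ``include_near`` (requires a
    :class:`~phenokit.eq_reasoner.SubsumptionIndex`), pairs identical except
    for qualities in strict ancestor relation are additionally emitted as
    broad/narrow matches at confidence 0.8.  Output sorted by
    (subject, object).
    """
    labels = labels or {}
    bridged_a = {c: apply_bridges(eq, bridges_a) for c, eq in eqs_a.items()}
    bridged_b = {c: apply_bridges(eq, bridges_b) for c, eq in eqs_b.items()}
    by_eq_b: dict[EQDefinition, list[Curie]] = {}
    for c, eq in bridged_b.items():
        by_eq_b.setdefault(eq, []).append(c)

    out: list[Mapping] = []
    for ca, eq_a in bridged_a.items():
        for cb in by_eq_b.get(eq_a, ()):
            out.append(
                Mapping(
                    subject_id=ca,
                    subject_label=labels.get(ca, ""),
                    predicate_id=EXACT_MATCH,
                    object_id=cb,
                    object_label=labels.get(cb, ""),
                    mapping_justification=LOGICAL_MATCHING,
                    confidence=1.0,
                )
            )
    if include_near:
        if idx is None:
            raise ValidationError("include_near requires a SubsumptionIndex")
        for ca, eq_a in bridged_a.items():
            for cb, eq_b in bridged_b.items():
                if eq_a == eq_b:
                    continue
                if replace(eq_a, quality=eq_b.quality) != eq_b:
                    continue  # differ in more than the quality
                a_anc = idx.quality_ancestors(eq_a.quality)
                b_anc = idx.quality_ancestors(eq_b.quality)
                if eq_b.quality in a_anc:
                    predicate = BROAD_MATCH  # subject narrower than object
                elif eq_a.quality in b_anc:
                    predicate = NARROW_MATCH
                else:
                    continue
                out.append(
                    Mapping(
                        subject_id=ca,
                        subject_label=labels.get(ca, ""),
                        predicate_id=predicate,
                        object_id=cb,
                        object_label=labels.get(cb, ""),
                        mapping_justification=LOGICAL_MATCHING,
                        confidence=0.8,
                    )
                )
    return sorted(out, key=_mapping_sort_key)


# ---------------------------------------------------------------------------
# Lexical matching
# ---------------------------------------------------------------------------

import re as _re

_PUNCT_RE = _re.compile(r"[^\w\s]", _re.UNICODE)
_WS_RE = _re.compile(r"\s+")


def normalize_label(text: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", text.casefold())).strip()


def lexical_matches(
    terms_a: dict[Curie, tuple[str, tuple[str, ...]]],
    terms_b: dict[Curie, tuple[str, tuple[str, ...]]],
    label_confidence: float = 0.9,
    synonym_confidence: float = 0.7,
) -> list[Mapping]:
    """Matches on normalized label/synonym string equality.

    ``terms_a`` / ``terms_b`` map term id to (label, synonyms).  Label-label
    matches score ``label_confidence``; any synonym-involved match scores
    ``synonym_confidence``.  Deterministic output sorted by (subject, object).
    """

    def strings(entry: tuple[str, tuple[str, ...]]):
        label, synonyms = entry
        out = []
        if label:
            out.append((normalize_label(label), True))
        for s in synonyms:
            if s:
                out.append((normalize_label(s), False))
        return out

    index_b: dict[str, list[tuple[Curie, bool]]] = {}
    for cb, entry in terms_b.items():
        for norm, is_label in strings(entry):
            index_b.setdefault(norm, []).append((cb, is_label))

    best: dict[tuple[Curie, Curie], float] = {}
    labels_out: dict[Curie, str] = {}
    for ca, entry in terms_a.items():
        labels_out[ca] = entry[0]
        for norm, a_is_label in strings(entry):
            for cb, b_is_label in index_b.get(norm, ()):
                conf = label_confidence if (a_is_label and b_is_label) else synonym_confidence
                key = (ca, cb)
                if conf > best.get(key, -1.0):
                    best[key] = conf
    for cb, entry in terms_b.items():
        labels_out[cb] = entry[0]

    out = [
        Mapping(
            subject_id=ca,
            subject_label=labels_out.get(ca, ""),
            predicate_id=EXACT_MATCH,
            object_id=cb,
            object_label=labels_out.get(cb, ""),
            mapping_justification=LEXICAL_MATCHING,
            confidence=conf,
        )
        for (ca, cb), conf in best.items()
    ]
    return sorted(out, key=_mapping_sort_key)


def merge_manual(derived: list[Mapping], manual: list[Mapping]) -> list[Mapping]:
    """Merge manually curated mappings with derived ones; on a (subject,
    object) conflict the manual row wins."""
    manual_pairs = {(m.subject_id, m.object_id) for m in manual}
    kept = [m for m in derived if (m.subject_id, m.object_id) not in manual_pairs]
    return sorted(kept + list(manual), key=_mapping_sort_key)


# ---------------------------------------------------------------------------
# SSSOM TSV
# ---------------------------------------------------------------------------


def _format_confidence(value: float) -> str:
    return repr(float(value))


def write_sssom(
    mappings: list[Mapping],
    curie_map: dict[str, str],
    metadata: dict | None = None,
) -> str:
    """Serialize mappings with a commented YAML metadata header.

    Every CURIE prefix appearing in the rows must be covered by
    ``curie_map``; a missing prefix is a hard error.
    """
    metadata = dict(metadata or {})
    prefixes = set()
    for m in mappings:
        prefixes.add(m.subject_id.prefix)
        prefixes.add(m.object_id.prefix)
        for text in (m.predicate_id, m.mapping_justification):
            if ":" in text and not text.startswith(("http:", "https:")):
                prefixes.add(text.split(":", 1)[0])
    missing = sorted(p for p in prefixes if p not in curie_map)
    if missing:
        raise ValidationError(f"curie_map lacks prefixes: {', '.join(missing)}")

    header_doc = {
        "curie_map": {k: curie_map[k] for k in sorted(curie_map)},
        "mapping_set_id": metadata.get("mapping_set_id", "https://example.org/mappings/default"),
        "license": metadata.get("license", "https://creativecommons.org/publicdomain/zero/1.0/"),
    }
    for key in sorted(metadata):
        if key not in header_doc:
            header_doc[key] = metadata[key]
    header_yaml = yaml.safe_dump(header_doc, sort_keys=False, allow_unicode=True)
    lines = ["# " + line for line in header_yaml.rstrip("\n").split("\n")]

    extension_cols: list[str] = []
    for m in mappings:
        for key, _ in m.extensions:
            if key not in extension_cols:
                extension_cols.append(key)
    columns = list(SSSOM_COLUMNS) + extension_cols

    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(columns)
    for m in sorted(mappings, key=_mapping_sort_key):
        ext = dict(m.extensions)
        writer.writerow(
            [
                str(m.subject_id),
                m.subject_label,
                m.predicate_id,
                str(m.object_id),
                m.object_label,
                m.mapping_justification,
                _format_confidence(m.confidence),
                m.mapping_tool,
            ]
            + [ext.get(c, "") for c in extension_cols]
        )
    return "\n".join(lines) + "\n" + buf.getvalue()


def read_sssom(text: str) -> tuple[list[Mapping], dict]:
    """Parse an SSSOM TSV document back into mappings plus its metadata.

    Unknown columns trigger a warning and are preserved per row as
    extensions.
    """
    header_lines: list[str] = []
    body_lines: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            header_lines.append(line[1:].lstrip())
        elif line.strip():
            body_lines.append(line)
    metadata = yaml.safe_load("\n".join(header_lines)) or {} if header_lines else {}
    if not body_lines:
        return [], metadata
    reader = csv.reader(io.StringIO("\n".join(body_lines)), delimiter="\t")
    columns = next(reader)
    unknown = [c for c in columns if c not in SSSOM_COLUMNS]
    if unknown:
        warnings.warn(f"unknown SSSOM columns preserved as extensions: {unknown}")
    mappings: list[Mapping] = []
    for row in reader:
        if not row:
            continue
        record = dict(zip(columns, row))
        missing = [c for c in ("subject_id", "predicate_id", "object_id", "mapping_justification") if c not in record]
        if missing:
            raise ParseError(f"SSSOM row lacks required columns: {missing}")
        extensions = tuple((c, record[c]) for c in unknown if record.get(c, "") != "")
        mappings.append(
            Mapping(
                subject_id=record["subject_id"],
                subject_label=record.get("subject_label", ""),
                predicate_id=record["predicate_id"],
                object_id=record["object_id"],
                object_label=record.get("object_label", ""),
                mapping_justification=record["mapping_justification"],
                confidence=float(record.get("confidence", 1.0) or 1.0),
                mapping_tool=record.get("mapping_tool", ""),
                extensions=extensions,
            )
        )
    return mappings, metadata
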