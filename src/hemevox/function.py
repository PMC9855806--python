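"""Function-label assignment for heme-binding sites.

Labels come from a fixed cascade over annotation sources attached to the
chains carrying the heme's axial ligand(s):

1. EC numbers on the axial-ligand chain(s): the first EC digit decides
   (class 1 -> oxidoreductase; any other digit maps to ``other`` and is
   excluded from modelling);
2. otherwise the first matching GO concept, in priority order
   oxygen-binding > oxidoreductase activity > electron transfer activity >
   transcription > heme transport;
3. otherwise the first matching entry keyword, in priority order
   hemophore > electron transfer > oxygen-binding > oxidoreductase >
   heme extraction > signaling protein > nitrophorin (NO transport) >
   heme transport;
4. otherwise a description naming cytochrome P460 -> oxidoreductase;
5. otherwise, or with no axial ligand at all -> unclassified.

Two manual overrides reflect curated biochemistry: dehaloperoxidases, and
myoglobin variants with oxidoreductase activity, are dual-function
(oxygen-binding and oxidoreductase, class OB-OR).

Class encodings are bit vectors with one position per function, ordered
(oxidoreductase, oxygen-binding[, electron-transfer]): OB = (0,1),
OR = (1,0), OB-OR = (1,1); in the three-label scheme OB = (0,1,0),
OR = (1,0,0), OB-OR = (1,1,0), ET = (0,0,1).  The all-zero vector decodes
to the catch-all outcome ``Others``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

# function identifiers
OXYGEN_BINDING = "oxygen-binding"
OXIDOREDUCTASE = "oxidoreductase"
ELECTRON_TRANSFER = "electron-transfer"
TRANSCRIPTION = "transcription"
HEME_TRANSPORT = "heme-transport"
HEMOPHORE = "hemophore"
HEME_EXTRACTION = "heme-extraction"
SIGNALING = "signaling"
NO_TRANSPORT = "NO-transport"
UNCLASSIFIED = "unclassified"
OTHER = "other"

OTHERS = "Others"  # decoded all-zero prediction outcome

_EC_PATTERN = re.compile(r"^\d+(\.\d+)*")

# EC first digit -> function of interest; everything except class 1 is
# outside the modelled label set.
_EC_CLASS1 = OXIDOREDUCTASE

# concept -> case-insensitive synonyms (matched as substrings of the
# normalized annotation strings)
_SYNONYMS: dict[str, tuple[str, ...]] = {
    OXYGEN_BINDING: ("oxygen binding", "oxygen carrier", "oxygen transport", "oxygen storage"),
    OXIDOREDUCTASE: ("oxidoreductase",),
    ELECTRON_TRANSFER: ("electron transfer", "electron transport", "electron carrier"),
    TRANSCRIPTION: ("transcription",),
    HEME_TRANSPORT: ("heme transport", "haem transport"),
    HEMOPHORE: ("hemophore", "haemophore"),
    HEME_EXTRACTION: ("heme extraction", "haem extraction"),
    SIGNALING: ("signaling protein", "signalling protein"),
    NO_TRANSPORT: ("nitrophorin", "no transport", "nitric oxide transport"),
}

_GO_PRIORITY = (
    OXYGEN_BINDING,
    OXIDOREDUCTASE,
    ELECTRON_TRANSFER,
    TRANSCRIPTION,
    HEME_TRANSPORT,
)

_KEYWORD_PRIORITY = (
    HEMOPHORE,
    ELECTRON_TRANSFER,
    OXYGEN_BINDING,
    OXIDOREDUCTASE,
    HEME_EXTRACTION,
    SIGNALING,
    NO_TRANSPORT,
    HEME_TRANSPORT,
)

TWO_LABEL_ENCODING: dict[str, tuple[int, ...]] = {
    "OB": (0, 1),
    "OR": (1, 0),
    "OB-OR": (1, 1),
}
THREE_LABEL_ENCODING: dict[str, tuple[int, ...]] = {
    "OB": (0, 1, 0),
    "OR": (1, 0, 0),
    "OB-OR": (1, 1, 0),
    "ET": (0, 0, 1),
}
_SCHEMES = {"two-label": TWO_LABEL_ENCODING, "three-label": THREE_LABEL_ENCODING}


def _normalize(text: str) -> str:
    return re.sub(r"[-_/]", " ", text.lower()).strip()


def _matches(concept: str, texts: Iterable[str]) -> bool:
    synonyms = _SYNONYMS[concept]
    for text in texts:
        norm = _normalize(text)
        if any(s in norm for s in synonyms):
            return True
    return False


@dataclass(frozen=True)
class AnnotationRecord:
    """Offline annotation row for one (entry, chain)."""

    entry_id: str
    chain_id: str
    ec_numbers: tuple[str, ...] = ()
    go_terms: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    description: str = ""


@dataclass(frozen=True)
class FunctionLabel:
    """Assigned function set and the derived classification class."""

    functions: frozenset[str]

    @property
    def class_name(self) -> str:
        f = self.functions
        if not f or f == {UNCLASSIFIED}:
            return UNCLASSIFIED
        if {OXYGEN_BINDING, OXIDOREDUCTASE} <= f:
            return "OB-OR"
        if f == {OXYGEN_BINDING}:
            return "OB"
        if f == {OXIDOREDUCTASE}:
            return "OR"
        if f == {ELECTRON_TRANSFER}:
            return "ET"
        return OTHER

    def encoding(self, scheme: str) -> tuple[int, ...]:
        return encode_labels(self, scheme)


def make_label(*functions: str) -> FunctionLabel:
    return FunctionLabel(frozenset(functions))


def assign_function(
    annotations: AnnotationRecord | Sequence[AnnotationRecord],
    axial_chains: Sequence[str],
) -> FunctionLabel:
    """Run the annotation cascade for one site.

    ``annotations`` may be a single record or one record per chain of the
    entry; EC numbers and GO terms are read from the chains listed in
    ``axial_chains``, keywords and descriptions from the whole entry.
    A site without axial ligands is unclassified.
    """
    if isinstance(annotations, AnnotationRecord):
        annotations = [annotations]
    if not axial_chains or not annotations:
        return make_label(UNCLASSIFIED)
    axial_set = set(axial_chains)
    axial_records = [r for r in annotations if r.chain_id in axial_set]

    # case 1: EC number on an axial-ligand chain
    ec_numbers = [ec for r in axial_records for ec in r.ec_numbers if ec]
    if ec_numbers:
        funcs = set()
        for ec in ec_numbers:
            m = _EC_PATTERN.match(ec.strip())
            digit = m.group(0).split(".")[0] if m else ""
            funcs.add(_EC_CLASS1 if digit == "1" else OTHER)
        return FunctionLabel(frozenset(funcs))

    # case 2: GO terms of the axial-ligand chains, fixed priority order
    go_terms = [t for r in axial_records for t in r.go_terms if t]
    for concept in _GO_PRIORITY:
        if _matches(concept, go_terms):
            return make_label(concept)

    # case 3: entry-level keywords, fixed priority order
    keywords = [k for r in annotations for k in r.keywords if k]
    for concept in _KEYWORD_PRIORITY:
        if _matches(concept, keywords):
            return make_label(concept)

    # case 4: cytochrome P460 by description
    descriptions = [r.description for r in annotations if r.description]
    if any("cytochrome p460" in _normalize(d) for d in descriptions):
        return make_label(OXIDOREDUCTASE)

    # case 5
    return make_label(UNCLASSIFIED)


def apply_manual_overrides(label: FunctionLabel, protein_name: str) -> FunctionLabel:
    """Curated dual-function corrections.

    Dehaloperoxidase entries, and myoglobin entries whose cascade result
    includes oxidoreductase activity, become OB-OR.  Everything else passes
    through unchanged.
    """
    name = _normalize(protein_name or "")
    if "dehaloperoxidase" in name:
        return FunctionLabel(frozenset({OXYGEN_BINDING, OXIDOREDUCTASE}))
    if "myoglobin" in name and OXIDOREDUCTASE in label.functions:
        return FunctionLabel(label.functions | {OXYGEN_BINDING})
    return label


def encode_labels(label: FunctionLabel | str, scheme: str) -> tuple[int, ...]:
    """Encode a class as its 0/1 label vector under the given scheme."""
    table = _SCHEMES.get(scheme)
    if table is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    name = label if isinstance(label, str) else label.class_name
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"class {name!r} is not encodable under {scheme}") from None


def decode_labels(vector: Sequence[int], scheme: str) -> str:
    """Decode a 0/1 vector to a class name; non-class vectors -> Others."""
    table = _SCHEMES.get(scheme)
    if table is None:
        raise ValueError(f"unknown scheme {scheme!r}")
    vec = tuple(int(v) for v in vector)
    if len(vec) != len(next(iter(table.values()))):
        raise ValueError(f"vector length {len(vec)} does not match {scheme}")
    for name, enc in table.items():
        if enc == vec:
            return name
    return OTHERS


def scheme_classes(scheme: str) -> list[str]:
    """Ordered class list of a scheme (excluding the Others outcome)."""
    if scheme == "two-label":
        return ["OB", "OR", "OB-OR"]
    if scheme == "three-label":
        return ["OB", "OR", "OB-OR", "ET"]
    raise ValueError(f"unknown scheme {scheme!r}")
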