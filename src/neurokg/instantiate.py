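"""Knowledge-graph instantiation of harmonized subject records.

Each subject becomes a small, fixed instance pattern: a ``Homo sapiens``
instance carrying a study-subject role and denoted by exactly one
pseudonymous identifier; an anatomy skeleton (brain, left/right hippocampus)
attached by parthood; cognitive assays the subject participated in, each with
a measurement-datum → value-specification → literal-score chain; and volume
feature-extraction processes whose output measurement data are *about* the
subject's hippocampus instances.

Instance IRIs are deterministic suffixes of the subject IRI, so re-ingestion
is idempotent and serializations are reproducible. Every emitted triple
carries per-row provenance; ontology triples merged later are background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF, RDFS, XSD
from rdflib import Namespace

from .mapping import PseudonymPolicy, mint_subject_iri
from .vocab import APP_TERMS, NKG, OBO, TERMS

__all__ = [
    "InstanceGraph",
    "PatternReport",
    "InstantiationError",
    "instantiate_subject",
    "instantiate_assessment",
    "instantiate_feature_extraction",
    "instantiate_icv_extraction",
    "validate_patterns",
    "build_instance_graph",
    "export_shacl_shapes",
]

SH = Namespace("http://www.w3.org/ns/shacl#")

_HUMAN = TERMS["Homo sapiens"]
_DENOTES = TERMS["denotes"]
_HAS_PARTICIPANT = TERMS["has participant"]
_HAS_OUTPUT = TERMS["has specified output"]
_HAS_INPUT = TERMS["has specified input"]
_HAS_VS = TERMS["has value specification"]
_HAS_VALUE = TERMS["has specified value"]
_INHERES = TERMS["inheres in"]
_PART_OF = TERMS["part of"]
_IS_ABOUT = TERMS["is about"]
_ROLE_CLASS = TERMS["study subject role"]
_DATUM = TERMS["measurement datum"]
_VALUE_SPEC = TERMS["value specification"]
_IMAGE = TERMS["image"]
_MOCA = TERMS["Montreal cognitive assessment assay"]

_GROUP_CLASSES = {
    "PD": APP_TERMS["study subject with Parkinson disease"],
    "HC": APP_TERMS["healthy control study subject"],
}
_SIDE_CLASSES = {
    "left": (
        APP_TERMS["left hippocampus"],
        APP_TERMS[
            "left hippocampal volume feature extraction using the FIRST "
            "segmentation utility from FSL on a T1 MRI image"
        ],
        APP_TERMS["left hippocampal volume measurement datum"],
    ),
    "right": (
        APP_TERMS["right hippocampus"],
        APP_TERMS[
            "right hippocampal volume feature extraction using the FIRST "
            "segmentation utility from FSL on a T1 MRI image"
        ],
        APP_TERMS["right hippocampal volume measurement datum"],
    ),
}

#: Default subtest → measured-cognitive-function table (configurable; the
#: pattern does not hard-code which function each subtest measures).
DEFAULT_FUNCTION_MAP: dict[str, URIRef] = {
    "moca_category_fluency": APP_TERMS["semantic category fluency function"],
}
_SUBTEST_CLASSES: dict[str, URIRef] = {
    "moca_category_fluency": APP_TERMS["MoCA category fluency subtest"],
}


class InstantiationError(ValueError):
    """Instance pattern cannot be built for the given inputs."""


@dataclass
class InstanceGraph:
    """Instance triples plus per-triple provenance (source name, row index)."""

    graph: Graph = field(default_factory=Graph)
    provenance: dict[tuple, tuple[str, int]] = field(default_factory=dict)
    skips: list[tuple[str, int, str]] = field(default_factory=list)  # (source, row, reason)

    def __post_init__(self) -> None:
        self.graph.bind("obo", OBO)
        self.graph.bind("nkg", NKG)

    def add(self, triple: tuple, prov: tuple[str, int] | None = None) -> None:
        self.graph.add(triple)
        if prov is not None:
            self.provenance[triple] = prov

    def __len__(self) -> int:
        return len(self.graph)


@dataclass
class PatternReport:
    """Named conformance-rule violations; empty ⇔ the graph fits the pattern."""

    violations: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rule, _, _ in self.violations:
            out[rule] = out.get(rule, 0) + 1
        return out

    @property
    def ok(self) -> bool:
        return not self.violations


def _suffix(subject_iri: URIRef, *parts: str) -> URIRef:
    return URIRef(str(subject_iri) + "/" + "/".join(parts))


def instantiate_subject(
    ig: InstanceGraph,
    subject_iri: URIRef,
    id_label: str,
    group: str,
    source_name: str | None = None,
    prov: tuple[str, int] | None = None,
) -> URIRef:
    """Add the subject pattern: typed human + role + identifier + anatomy."""
    if group not in _GROUP_CLASSES:
        raise InstantiationError(f"unknown group {group!r}; expected PD or HC")
    if (subject_iri, RDF.type, _HUMAN) in ig.graph:
        raise InstantiationError(f"duplicate subject IRI: {subject_iri}")

    ig.add((subject_iri, RDF.type, _HUMAN), prov)
    ig.add((subject_iri, RDF.type, _GROUP_CLASSES[group]), prov)

    role = _suffix(subject_iri, "role")
    ig.add((role, RDF.type, _ROLE_CLASS), prov)
    ig.add((role, _INHERES, subject_iri), prov)

    identifier = _suffix(subject_iri, "id")
    ig.add((identifier, RDF.type, APP_TERMS["pseudonymous subject identifier"]), prov)
    ig.add((identifier, _DENOTES, subject_iri), prov)
    ig.add((identifier, RDFS.label, Literal(id_label)), prov)

    brain = _suffix(subject_iri, "brain")
    ig.add((brain, RDF.type, APP_TERMS["brain"]), prov)
    ig.add((brain, _PART_OF, subject_iri), prov)
    for side in ("left", "right"):
        hippo = _suffix(subject_iri, f"hippocampus-{side}")
        ig.add((hippo, RDF.type, _SIDE_CLASSES[side][0]), prov)
        ig.add((hippo, _PART_OF, brain), prov)

    if source_name is not None:
        ig.add((subject_iri, APP_TERMS["source dataset name"], Literal(source_name)), prov)
    return subject_iri


def instantiate_assessment(
    ig: InstanceGraph,
    subject_iri: URIRef,
    assay_class: URIRef,
    score: int | float | None,
    part_scores: dict[str, int | float] | None = None,
    function_map: dict[str, URIRef] | None = None,
    prov: tuple[str, int] | None = None,
) -> URIRef | None:
    """Add one assay with its output chain; subtests become assay parts.

    A missing total score yields no fragment (the skip is logged on the
    instance graph); subtest scores without a parent assay are skipped too.
    """
    if score is None or (isinstance(score, float) and pd.isna(score)):
        ig.skips.append((prov[0] if prov else "?", prov[1] if prov else -1, "missing score"))
        return None
    function_map = function_map if function_map is not None else DEFAULT_FUNCTION_MAP

    assay = _suffix(subject_iri, "assay", "moca")
    ig.add((assay, RDF.type, assay_class), prov)
    ig.add((assay, _HAS_PARTICIPANT, subject_iri), prov)
    _add_output_chain(ig, assay, int(score), XSD.integer, prov)

    for key, part_score in (part_scores or {}).items():
        if part_score is None or (isinstance(part_score, float) and pd.isna(part_score)):
            continue
        subtest_class = _SUBTEST_CLASSES.get(key)
        if subtest_class is None:
            ig.skips.append(
                (prov[0] if prov else "?", prov[1] if prov else -1, f"unknown subtest {key}")
            )
            continue
        subtest = _suffix(subject_iri, "assay", "moca", key)
        ig.add((subtest, RDF.type, subtest_class), prov)
        ig.add((subtest, _PART_OF, assay), prov)
        ig.add((subtest, _HAS_PARTICIPANT, subject_iri), prov)
        datum = _add_output_chain(ig, subtest, int(part_score), XSD.integer, prov)
        function_class = function_map.get(key)
        if function_class is not None:
            function = _suffix(subject_iri, "function", key)
            ig.add((function, RDF.type, function_class), prov)
            ig.add((function, _INHERES, _suffix(subject_iri, "brain")), prov)
            ig.add((datum, _IS_ABOUT, function), prov)
    return assay


def _add_output_chain(
    ig: InstanceGraph, process: URIRef, value, datatype, prov
) -> URIRef:
    """process →has_specified_output→ datum →has_value_spec→ vs →value→ literal."""
    datum = URIRef(str(process) + "/datum")
    vs = URIRef(str(process) + "/vs")
    ig.add((datum, RDF.type, _DATUM), prov)
    ig.add((process, _HAS_OUTPUT, datum), prov)
    ig.add((vs, RDF.type, _VALUE_SPEC), prov)
    ig.add((datum, _HAS_VS, vs), prov)
    ig.add((vs, _HAS_VALUE, Literal(value, datatype=datatype)), prov)
    return datum


def instantiate_feature_extraction(
    ig: InstanceGraph,
    subject_iri: URIRef,
    volume_mm3: float,
    side: str,
    prov: tuple[str, int] | None = None,
) -> URIRef:
    """Add a hippocampal-volume feature-extraction process for one side.

    The process has exactly one specified input (the subject's image) and one
    specified output: a volume measurement datum about the side's hippocampus
    instance, carrying the volume in mm³.
    """
    if side not in _SIDE_CLASSES:
        raise InstantiationError(f"side must be 'left' or 'right', got {side!r}")
    hippo = _suffix(subject_iri, f"hippocampus-{side}")
    if (hippo, None, None) not in ig.graph:
        raise InstantiationError(
            f"no {side} hippocampus instance for subject {subject_iri}; "
            "instantiate the subject first"
        )
    _, process_class, datum_class = _SIDE_CLASSES[side]

    image = _suffix(subject_iri, "image")
    ig.add((image, RDF.type, _IMAGE), prov)

    process = _suffix(subject_iri, "featx", side)
    ig.add((process, RDF.type, process_class), prov)
    ig.add((process, _HAS_INPUT, image), prov)

    datum = URIRef(str(process) + "/datum")
    vs = URIRef(str(process) + "/vs")
    ig.add((datum, RDF.type, datum_class), prov)
    ig.add((datum, RDF.type, _DATUM), prov)
    ig.add((process, _HAS_OUTPUT, datum), prov)
    ig.add((datum, _IS_ABOUT, hippo), prov)
    ig.add((vs, RDF.type, _VALUE_SPEC), prov)
    ig.add((datum, _HAS_VS, vs), prov)
    ig.add((vs, _HAS_VALUE, Literal(round(float(volume_mm3), 4), datatype=XSD.decimal)), prov)
    return process


def instantiate_icv_extraction(
    ig: InstanceGraph,
    subject_iri: URIRef,
    icv_mm3: float,
    prov: tuple[str, int] | None = None,
) -> URIRef:
    """Add an intracranial-volume extraction whose output is about the brain."""
    brain = _suffix(subject_iri, "brain")
    if (brain, None, None) not in ig.graph:
        raise InstantiationError(f"no brain instance for subject {subject_iri}")
    image = _suffix(subject_iri, "image")
    ig.add((image, RDF.type, _IMAGE), prov)
    process = _suffix(subject_iri, "featx", "icv")
    ig.add((process, RDF.type, APP_TERMS["intracranial volume feature extraction"]), prov)
    ig.add((process, _HAS_INPUT, image), prov)
    datum = URIRef(str(process) + "/datum")
    vs = URIRef(str(process) + "/vs")
    ig.add((datum, RDF.type, APP_TERMS["intracranial volume measurement datum"]), prov)
    ig.add((datum, RDF.type, _DATUM), prov)
    ig.add((process, _HAS_OUTPUT, datum), prov)
    ig.add((datum, _IS_ABOUT, brain), prov)
    ig.add((vs, RDF.type, _VALUE_SPEC), prov)
    ig.add((datum, _HAS_VS, vs), prov)
    ig.add((vs, _HAS_VALUE, Literal(round(float(icv_mm3), 4), datatype=XSD.decimal)), prov)
    return process


# ---------------------------------------------------------------------------
# conformance validation

_ASSAY_INSTANCE_CLASSES = (_MOCA,) + tuple(_SUBTEST_CLASSES.values())
_PROCESS_CLASSES = (
    _SIDE_CLASSES["left"][1],
    _SIDE_CLASSES["right"][1],
    APP_TERMS["intracranial volume feature extraction"],
)


def _instances_of(graph: Graph, cls: URIRef):
    return sorted(graph.subjects(RDF.type, cls))


def validate_patterns(graph: Graph | InstanceGraph) -> PatternReport:
    """Check every instance-pattern invariant as a named rule.

    Rules: each subject has exactly one identifier and one inhering role;
    each assay instance has ≥1 participant and exactly one specified output;
    each feature-extraction process has exactly one input and one output;
    each measurement datum has exactly one value specification, each value
    specification exactly one specified value. Report ordering is
    deterministic (sorted by rule, then focus node).
    """
    g = graph.graph if isinstance(graph, InstanceGraph) else graph
    report = PatternReport()

    def check_count(rule, focus, actual, expected_lo, expected_hi, what):
        if not expected_lo <= actual <= (expected_hi if expected_hi is not None else actual):
            report.violations.append(
                (rule, str(focus), f"expected {what}, found {actual}")
            )

    for subject in _instances_of(g, _HUMAN):
        n_ids = len(list(g.subjects(_DENOTES, subject)))
        check_count("subject-has-identifier", subject, n_ids, 1, 1, "exactly 1 identifier")
        roles = [
            r for r in g.subjects(_INHERES, subject)
            if (r, RDF.type, _ROLE_CLASS) in g
        ]
        check_count("subject-has-role", subject, len(roles), 1, 1, "exactly 1 subject role")

    for cls in _ASSAY_INSTANCE_CLASSES:
        for assay in _instances_of(g, cls):
            n_part = len(list(g.objects(assay, _HAS_PARTICIPANT)))
            check_count("assay-has-participant", assay, n_part, 1, None, ">=1 participant")
            n_out = len(list(g.objects(assay, _HAS_OUTPUT)))
            check_count("assay-single-output", assay, n_out, 1, 1, "exactly 1 specified output")

    for cls in _PROCESS_CLASSES:
        for process in _instances_of(g, cls):
            n_in = len(list(g.objects(process, _HAS_INPUT)))
            check_count("process-single-input", process, n_in, 1, 1, "exactly 1 specified input")
            n_out = len(list(g.objects(process, _HAS_OUTPUT)))
            check_count("process-single-output", process, n_out, 1, 1, "exactly 1 specified output")

    for datum in _instances_of(g, _DATUM):
        n_vs = len(list(g.objects(datum, _HAS_VS)))
        check_count("single-value-spec", datum, n_vs, 1, 1, "exactly 1 value specification")

    for vs in _instances_of(g, _VALUE_SPEC):
        n_val = len(list(g.objects(vs, _HAS_VALUE)))
        check_count("single-specified-value", vs, n_val, 1, 1, "exactly 1 specified value")

    report.violations.sort()
    return report


def export_shacl_shapes() -> Graph:
    """Export the conformance rules as SHACL node shapes (interoperability aid)."""
    g = Graph()
    g.bind("sh", SH)
    g.bind("obo", OBO)
    g.bind("nkg", NKG)

    def shape(name, target_class, path, min_c, max_c):
        node = NKG[f"shape-{name}"]
        g.add((node, RDF.type, SH.NodeShape))
        g.add((node, SH.targetClass, target_class))
        prop = NKG[f"shape-{name}-prop"]
        g.add((node, SH.property, prop))
        g.add((prop, SH.path, path))
        if min_c is not None:
            g.add((prop, SH.minCount, Literal(min_c)))
        if max_c is not None:
            g.add((prop, SH.maxCount, Literal(max_c)))

    shape("subject-role", _HUMAN, URIRef(str(_INHERES) + ""), None, None)
    shape("assay-participant", _MOCA, _HAS_PARTICIPANT, 1, None)
    shape("assay-output", _MOCA, _HAS_OUTPUT, 1, 1)
    shape("datum-value-spec", _DATUM, _HAS_VS, 1, 1)
    shape("value-spec-value", _VALUE_SPEC, _HAS_VALUE, 1, 1)
    return g


# ---------------------------------------------------------------------------
# batch construction from a harmonized frame

def build_instance_graph(
    harmonized: pd.DataFrame,
    policy: PseudonymPolicy,
    function_map: dict[str, URIRef] | None = None,
) -> tuple[InstanceGraph, dict[str, URIRef]]:
    """Instantiate every harmonized row; returns the graph and the
    (source, subject_id) → subject IRI index used for oracle checks."""
    ig = InstanceGraph()
    index: dict[tuple[str, str], URIRef] = {}
    for _, row in harmonized.iterrows():
        source = row["source"]
        prov = (source, int(row["row_index"]))
        group = row.get("group_label")
        subject_id = row.get("subject_id")
        if not isinstance(subject_id, str) or group not in _GROUP_CLASSES:
            ig.skips.append((source, int(row["row_index"]), "missing subject id or group"))
            continue
        subject_iri = mint_subject_iri(source, subject_id, policy)
        instantiate_subject(
            ig, subject_iri, id_label=str(subject_iri).rsplit("/", 1)[-1],
            group=group, source_name=source, prov=prov,
        )
        index[(source, subject_id)] = subject_iri

        part_scores = {}
        if "moca_category_fluency" in row and pd.notna(row.get("moca_category_fluency")):
            part_scores["moca_category_fluency"] = row["moca_category_fluency"]
        instantiate_assessment(
            ig, subject_iri, _MOCA, row.get("moca_total"),
            part_scores=part_scores, function_map=function_map, prov=prov,
        )

        for side, key in (("left", "volume_left_hippocampus"),
                          ("right", "volume_right_hippocampus")):
            value = row.get(key)
            if value is not None and pd.notna(value):
                instantiate_feature_extraction(ig, subject_iri, float(value), side, prov=prov)
        icv = row.get("icv")
        if icv is not None and pd.notna(icv):
            instantiate_icv_extraction(ig, subject_iri, float(icv), prov=prov)
    return ig, index
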