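"""SPARQL execution, cohort selection, and rule-based defined-class membership.

The merged graph (ontology modules + instance data) is held in an rdflib
graph, which doubles as the queryable store: :func:`run_sparql` executes
SPARQL 1.1 against it, :func:`select_cohort_by_score` instantiates the
bundled cohort-selection template (subject → role → identifier → assay →
measurement datum → value specification → score, with a comparator filter),
and :func:`materialize_defined_class` turns a score rule into explicit
``rdf:type`` assertions for a defined cohort class — the SPARQL-definable
analogue of reasoner-derived class membership.
"""

from __future__ import annotations

import csv
import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from string import Template

import pandas as pd
from rdflib import Graph, URIRef
from rdflib.namespace import RDF

__all__ = [
    "BindingSet",
    "DefinedClassRule",
    "QueryError",
    "run_sparql",
    "cohort_query",
    "select_cohort_by_score",
    "materialize_defined_class",
    "cohort_counts_by_source",
]

_COMPARATORS = {"lt": "<", "le": "<=", "ge": ">=", "gt": ">"}
_SOURCE_PROP = URIRef("https://w3id.org/neurokg/onto/NKG_0000080")


class QueryError(ValueError):
    """SPARQL parse/execution failure, with the engine's position message."""


@dataclass
class BindingSet:
    """SELECT result: variable names plus one dict per result row."""

    variables: list[str]
    rows: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def column(self, name: str) -> list:
        return [row.get(name) for row in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.variables)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle, lineterminator="\n")
            writer.writerow(self.variables)
            for row in self.rows:
                writer.writerow([row.get(v, "") for v in self.variables])
        return path

    def to_sparql_json(self) -> str:
        bindings = []
        for row in self.rows:
            entry = {}
            for var in self.variables:
                value = row.get(var)
                if value is None:
                    continue
                if isinstance(value, URIRef):
                    entry[var] = {"type": "uri", "value": str(value)}
                else:
                    entry[var] = {"type": "literal", "value": str(value)}
            bindings.append(entry)
        return json.dumps(
            {"head": {"vars": self.variables}, "results": {"bindings": bindings}},
            indent=2,
        )


@dataclass
class DefinedClassRule:
    """Membership rule for a defined cohort class (e.g. MoCA total < 26)."""

    class_iri: URIRef
    assay_class: URIRef
    comparator: str
    threshold: float
    valid_range: tuple[float, float] = (0, 30)

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
        lo, hi = self.valid_range
        if not lo <= self.threshold <= hi:
            raise ValueError(
                f"threshold {self.threshold} outside the instrument range [{lo}, {hi}]"
            )


def run_sparql(graph: Graph, query: str) -> BindingSet:
    """Execute a SPARQL 1.1 SELECT/ASK/CONSTRUCT query; SELECTs return bindings.

    Literal values are converted to Python natives; unbound variables are
    absent from the row dict. Row order follows the query's ORDER BY when
    present (otherwise engine order).
    """
    try:
        result = graph.query(query)
    except Exception as exc:  # rdflib raises pyparsing/Exception subclasses
        raise QueryError(f"SPARQL query failed: {exc}") from exc
    if result.type == "ASK":
        return BindingSet(variables=["ask"], rows=[{"ask": bool(result.askAnswer)}])
    if result.type == "CONSTRUCT":
        return BindingSet(variables=["triples"], rows=[{"triples": set(result.graph)}])
    variables = [str(v) for v in result.vars]
    rows = []
    for binding in result:
        row = {}
        for var, value in zip(variables, binding):
            if value is None:
                continue
            row[var] = value.toPython() if hasattr(value, "toPython") else value
            if isinstance(value, URIRef):
                row[var] = value
        rows.append(row)
    return BindingSet(variables=variables, rows=rows)


def _template_text() -> str:
    ref = importlib.resources.files("neurokg.queries").joinpath("cohort_by_score.rq")
    return ref.read_text(encoding="utf-8")


def cohort_query(
    assay_class: URIRef | str, comparator: str = "lt", threshold: float = 26
) -> str:
    """Render the cohort-selection SPARQL template for a class/comparator/threshold."""
    if comparator not in _COMPARATORS:
        raise ValueError(f"comparator must be one of {sorted(_COMPARATORS)}")
    return Template(_template_text()).substitute(
        assay_class=str(assay_class),
        cmp=_COMPARATORS[comparator],
        threshold=threshold,
    )


def select_cohort_by_score(
    graph: Graph,
    assay_class: URIRef | str,
    comparator: str = "lt",
    threshold: float = 26,
) -> BindingSet:
    """Subjects whose score on ``assay_class`` satisfies the comparator.

    Returns one row per qualifying (subject, assay) with the subject node,
    its pseudonymous identifier label, and the score. An assay class with no
    instances in the graph yields an empty result with a warning.
    """
    assay_class = URIRef(str(assay_class))
    if next(graph.subjects(RDF.type, assay_class), None) is None:
        warnings.warn(f"no instances of assay class {assay_class} in graph", stacklevel=2)
    return run_sparql(graph, cohort_query(assay_class, comparator, threshold))


def materialize_defined_class(graph: Graph, rule: DefinedClassRule) -> Graph:
    """Assert ``rdf:type rule.class_iri`` for every subject the rule selects.

    Membership is exactly the subject set of :func:`select_cohort_by_score`
    with the rule's comparator and threshold. The assertions are added to
    ``graph``; the returned graph holds only the *newly* inferred triples,
    so re-running yields an empty graph (idempotence).
    """
    bindings = select_cohort_by_score(
        graph, rule.assay_class, rule.comparator, rule.threshold
    )
    inferred = Graph()
    for subject in {row["s"] for row in bindings.rows}:
        triple = (URIRef(str(subject)), RDF.type, rule.class_iri)
        if triple not in graph:
            graph.add(triple)
            inferred.add(triple)
    return inferred


def cohort_counts_by_source(graph: Graph, bindings: BindingSet) -> dict[str, int]:
    """Per-source tally of a cohort result, via the source-dataset annotation."""
    counts: dict[str, int] = {}
    for row in bindings.rows:
        subject = row.get("s")
        source = graph.value(URIRef(str(subject)), _SOURCE_PROP)
        key = str(source) if source is not None else "unknown"
        counts[key] = counts.get(key, 0) + 1
    return counts
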