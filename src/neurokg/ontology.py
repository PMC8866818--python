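"""Application-ontology construction and ontology-module operations.

Three operations cover the ontology side of the integration workflow:

* :func:`define_term` builds application-ontology class definitions using the
  axiom pattern shared by the process terms (named parents plus existential
  ``some`` restrictions over registered properties);
* :func:`extract_module` produces a minimal module of an ontology — the seed
  terms plus, recursively, every term referenced by a member's axioms;
* :func:`merge_graphs` combines ontology modules with instance data under RDF
  set semantics.

Module extraction implements plain recursive reference closure; it is not a
syntactic-locality extractor and performs no reasoning.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS
from rdflib.compare import to_canonical_graph

from .vocab import APP_TERMS, NKG, OBO, TermRegistry, RegistryError, core_registry

__all__ = [
    "TermDefinition",
    "OntologyModule",
    "DefinitionError",
    "define_term",
    "extract_module",
    "merge_graphs",
    "build_app_ontology",
    "canonical_nt",
]

_BUILTIN_PREFIXES = (str(RDF), str(RDFS), str(OWL), "http://www.w3.org/2001/XMLSchema#")


class DefinitionError(ValueError):
    """Raised for structurally invalid term definitions."""


@dataclass
class TermDefinition:
    """An application-ontology class: named parents + existential restrictions."""

    iri: URIRef
    label: str
    parent_iris: list[URIRef]
    restrictions: list[tuple[URIRef, str, URIRef]] = field(default_factory=list)
    annotations: dict[URIRef, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.parent_iris:
            raise DefinitionError(f"term {self.label!r} must have at least one parent")
        for _, quantifier, _ in self.restrictions:
            if quantifier != "some":
                raise DefinitionError(
                    f"unsupported quantifier {quantifier!r}; only existential "
                    "('some') restrictions are supported"
                )

    def to_graph(self, graph: Graph | None = None) -> Graph:
        """Serialize: one subclass axiom per parent, one existential axiom per restriction."""
        g = graph if graph is not None else Graph()
        g.add((self.iri, RDF.type, OWL.Class))
        g.add((self.iri, RDFS.label, Literal(self.label)))
        for parent in self.parent_iris:
            g.add((self.iri, RDFS.subClassOf, parent))
        for prop, _, filler in self.restrictions:
            node = BNode()
            g.add((node, RDF.type, OWL.Restriction))
            g.add((node, OWL.onProperty, prop))
            g.add((node, OWL.someValuesFrom, filler))
            g.add((self.iri, RDFS.subClassOf, node))
        for prop, value in self.annotations.items():
            g.add((self.iri, prop, Literal(value)))
        return g

    @property
    def parent_axiom_count(self) -> int:
        return len(self.parent_iris)

    @property
    def restriction_axiom_count(self) -> int:
        return len(self.restrictions)


def _mint_iri(label: str) -> URIRef:
    """Stable application-namespace IRI for a label without a registered IRI."""
    digest = hashlib.blake2s(label.encode("utf-8"), digest_size=4).hexdigest()
    return NKG[f"NKG_X{digest}"]


def _resolve(registry: TermRegistry, key: str | URIRef) -> URIRef:
    if isinstance(key, URIRef) and key == OWL.Thing:
        return key
    if str(key) == str(OWL.Thing):
        return OWL.Thing
    return registry.resolve(str(key))


def define_term(
    label: str,
    parents: Sequence[str | URIRef],
    restrictions: Sequence[tuple[str | URIRef, str, str | URIRef]] = (),
    registry: TermRegistry | None = None,
    iri: URIRef | None = None,
) -> TermDefinition:
    """Build a :class:`TermDefinition`, resolving every referenced term.

    Parameters
    ----------
    label:
        Human-readable class label; must be non-empty.
    parents:
        Labels/CURIEs/IRIs of the named superclasses (at least one).
    restrictions:
        ``(property, quantifier, filler)`` triples; only the existential
        quantifier ``"some"`` is supported.
    registry:
        Term registry used to resolve references; defaults to the core
        registry. Unresolvable references raise :class:`RegistryError`
        naming the offending key.
    iri:
        Explicit IRI for the new class; defaults to the registered
        application-term IRI for ``label``, or a stable minted IRI.
    """
    if not label:
        raise DefinitionError("term label must be non-empty")
    registry = registry if registry is not None else core_registry()
    if not parents:
        raise DefinitionError(f"term {label!r} must have at least one parent")

    parent_iris = [_resolve(registry, p) for p in parents]
    resolved_restrictions = []
    for prop, quantifier, filler in restrictions:
        resolved_restrictions.append(
            (_resolve(registry, prop), quantifier, _resolve(registry, filler))
        )
    if iri is None:
        iri = APP_TERMS.get(label) or (
            registry.entries.get(label) or _mint_iri(label)
        )
    return TermDefinition(
        iri=URIRef(str(iri)),
        label=label,
        parent_iris=parent_iris,
        restrictions=resolved_restrictions,
    )


# ---------------------------------------------------------------------------
# module extraction

@dataclass
class OntologyModule:
    """A minimal ontology module: seed terms plus recursive axiom closure."""

    graph: Graph
    seed_iris: set[URIRef]

    @property
    def members(self) -> set[URIRef]:
        return _entity_iris(self.graph)

    def __len__(self) -> int:
        return len(self.graph)


def _is_builtin(iri: URIRef) -> bool:
    text = str(iri)
    return any(text.startswith(prefix) for prefix in _BUILTIN_PREFIXES)


def _entity_iris(graph: Graph) -> set[URIRef]:
    """Named entities (classes/properties) declared or used as subjects."""
    return {
        s for s in graph.subjects()
        if isinstance(s, URIRef) and not _is_builtin(s)
    }


def _referenced_iris(graph: Graph, node) -> set[URIRef]:
    """IRIs appearing in the axioms of ``node``, walking restriction bnodes."""
    refs: set[URIRef] = set()
    for _, obj in graph.predicate_objects(node):
        if isinstance(obj, URIRef) and not _is_builtin(obj):
            refs.add(obj)
        elif isinstance(obj, BNode):
            refs |= _referenced_iris(graph, obj)
    return refs


def _node_triples(graph: Graph, node) -> set[tuple]:
    """Triples rooted at ``node``, following blank-node objects."""
    triples: set[tuple] = set()
    for pred, obj in graph.predicate_objects(node):
        triples.add((node, pred, obj))
        if isinstance(obj, BNode):
            triples |= _node_triples(graph, obj)
    return triples


def extract_module(ontology: Graph, seeds: Iterable[URIRef | str]) -> OntologyModule:
    """Extract the minimal module of ``ontology`` containing ``seeds``.

    Starting from the seeds, every IRI referenced by a member's axioms is
    recursively added, and the module keeps all triples rooted at member
    IRIs (including restriction blank nodes). Seeds absent from the ontology
    are retained as bare class declarations with a warning.
    """
    seed_set = {URIRef(str(s)) for s in seeds}
    if not seed_set:
        raise ValueError("seeds must be non-empty")

    module = Graph()
    for prefix, ns in ontology.namespaces():
        module.bind(prefix, ns)

    present = _entity_iris(ontology)
    members: set[URIRef] = set()
    worklist = sorted(seed_set)
    while worklist:
        iri = worklist.pop()
        if iri in members:
            continue
        members.add(iri)
        if iri not in present:
            if iri in seed_set:
                warnings.warn(
                    f"seed {iri} not present in ontology; retained as bare declaration",
                    stacklevel=2,
                )
                module.add((iri, RDF.type, OWL.Class))
            continue
        for triple in _node_triples(ontology, iri):
            module.add(triple)
        for ref in _referenced_iris(ontology, iri):
            if ref not in members:
                worklist.append(ref)
    return OntologyModule(graph=module, seed_iris=seed_set)


def merge_graphs(*graphs: Graph) -> Graph:
    """Union of triple sets; every input graph is a subgraph of the result."""
    merged = Graph()
    for g in graphs:
        for prefix, ns in g.namespaces():
            merged.bind(prefix, ns)
        for triple in g:
            merged.add(triple)
    return merged


def canonical_nt(graph: Graph) -> str:
    """Deterministic N-Triples serialization (canonical blank-node labels, sorted)."""
    canon = to_canonical_graph(graph)
    lines = sorted(
        canon.serialize(format="nt").splitlines()
    )
    return "\n".join(line for line in lines if line.strip()) + "\n"


# ---------------------------------------------------------------------------
# the application ontology itself

def build_app_ontology(registry: TermRegistry | None = None) -> Graph:
    """Construct the application-ontology graph (anatomy stand-ins, process
    terms for volume feature extraction, assay subtests, cohort classes)."""
    registry = registry if registry is not None else core_registry()
    g = Graph()
    g.bind("obo", OBO)
    g.bind("nkg", NKG)
    g.bind("owl", OWL)

    def term(label, parents, restrictions=()):
        define_term(label, parents, restrictions, registry=registry).to_graph(g)

    term("anatomical structure", [OWL.Thing])
    term("brain", ["anatomical structure"])
    term("left hippocampus", ["anatomical structure"], [("part of", "some", "brain")])
    term("right hippocampus", ["anatomical structure"], [("part of", "some", "brain")])

    term("feature extraction objective", ["information content entity"])
    term("hippocampal volume measurement datum", ["measurement datum"])
    term("left hippocampal volume measurement datum", ["hippocampal volume measurement datum"])
    term("right hippocampal volume measurement datum", ["hippocampal volume measurement datum"])
    term("intracranial volume measurement datum", ["measurement datum"])

    term("hippocampal volume feature extraction", ["planned process"])
    term("right hippocampal volume feature extraction", ["hippocampal volume feature extraction"])
    term("left hippocampal volume feature extraction", ["hippocampal volume feature extraction"])
    for side in ("right", "left"):
        term(
            f"{side} hippocampal volume feature extraction using the FIRST "
            "segmentation utility from FSL on a T1 MRI image",
            ["planned process", f"{side} hippocampal volume feature extraction"],
            [
                ("has specified input", "some", "image"),
                ("has specified output", "some", f"{side} hippocampal volume measurement datum"),
                ("achieves planned objective", "some", "feature extraction objective"),
            ],
        )
    term(
        "intracranial volume feature extraction",
        ["planned process"],
        [
            ("has specified input", "some", "image"),
            ("has specified output", "some", "intracranial volume measurement datum"),
            ("achieves planned objective", "some", "feature extraction objective"),
        ],
    )

    term(
        "MoCA category fluency subtest",
        ["assay"],
        [("part of", "some", "Montreal cognitive assessment assay")],
    )
    term("cognitive function", [OWL.Thing])
    term("semantic category fluency function", ["cognitive function"])

    term("study subject with Parkinson disease", ["Homo sapiens"])
    term("healthy control study subject", ["Homo sapiens"])
    term("study subject with mild cognitive impairment", ["Homo sapiens"])
    term("pseudonymous subject identifier", ["information content entity"])

    source_prop = APP_TERMS["source dataset name"]
    g.add((source_prop, RDF.type, OWL.AnnotationProperty))
    g.add((source_prop, RDFS.label, Literal("source dataset name")))
    return g
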