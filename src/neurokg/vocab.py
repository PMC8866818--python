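"""Ontology vocabulary: IRI constants, the term registry, and the vendored core ontology.

The knowledge graph is built from OBO Foundry vocabularies (BFO, OBI, IAO,
RO, NPT, NCBITaxon) plus a small application ontology for project-specific
terms (anatomy stand-ins, feature-extraction process types, defined cohort
classes). Only a minimal hand-built module of the OBO terms is vendored, as
Turtle, so nothing is downloaded at run time; full ontology releases can be
loaded on top when available.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from rdflib import Graph, Namespace, URIRef
from rdflib.namespace import RDF, RDFS, OWL

__all__ = [
    "OBO",
    "NKG",
    "NKG_INSTANCE",
    "TERMS",
    "APP_TERMS",
    "TermRegistry",
    "RegistryError",
    "core_registry",
    "load_core_ontology",
]

#: Base namespace for OBO Foundry PURLs.
OBO = Namespace("http://purl.obolibrary.org/obo/")

#: Application-ontology namespace (class/property level terms minted by this project).
NKG = Namespace("https://w3id.org/neurokg/onto/")

#: Namespace under which instance-level IRIs (subjects, assays, datums) are minted.
NKG_INSTANCE = Namespace("https://w3id.org/neurokg/instance/")

# OBO terms used by the instance pattern and the cohort query, keyed by label.
TERMS: dict[str, URIRef] = {
    "Homo sapiens": OBO.NCBITaxon_9606,
    "denotes": OBO.IAO_0000219,
    "has participant": OBO.BFO_0000057,
    "Montreal cognitive assessment assay": OBO.NPT_0020000,
    "assay": OBO.OBI_0000070,
    "has specified output": OBO.OBI_0000299,
    "value specification": OBO.OBI_0001933,
    "measurement datum": OBO.IAO_0000109,
    "has value specification": OBO.OBI_0001938,
    "has specified value": OBO.OBI_0002135,
    "study subject role": OBO.OBI_0000097,
    "inheres in": OBO.RO_0000052,
    "planned process": OBO.OBI_0000011,
    # auxiliary terms needed by the axiom pattern / instance graph
    "has specified input": OBO.OBI_0000293,
    "achieves planned objective": OBO.OBI_0000417,
    "is about": OBO.IAO_0000136,
    "part of": OBO.BFO_0000050,
    "image": OBO.IAO_0000101,
    "information content entity": OBO.IAO_0000030,
    "role": OBO.BFO_0000023,
}

# Application-ontology terms. FMA anatomy and the feature-extraction objective
# are minted here because no canonical IRI for them is wired into the vendored
# module; swap entries in the registry to use the canonical terms instead.
APP_TERMS: dict[str, URIRef] = {
    "anatomical structure": NKG.NKG_0000010,
    "brain": NKG.NKG_0000011,
    "left hippocampus": NKG.NKG_0000012,
    "right hippocampus": NKG.NKG_0000013,
    "feature extraction objective": NKG.NKG_0000020,
    "hippocampal volume measurement datum": NKG.NKG_0000030,
    "left hippocampal volume measurement datum": NKG.NKG_0000031,
    "right hippocampal volume measurement datum": NKG.NKG_0000032,
    "intracranial volume measurement datum": NKG.NKG_0000033,
    "hippocampal volume feature extraction": NKG.NKG_0000040,
    "right hippocampal volume feature extraction": NKG.NKG_0000041,
    "left hippocampal volume feature extraction": NKG.NKG_0000042,
    (
        "right hippocampal volume feature extraction using the FIRST "
        "segmentation utility from FSL on a T1 MRI image"
    ): NKG.NKG_0000043,
    (
        "left hippocampal volume feature extraction using the FIRST "
        "segmentation utility from FSL on a T1 MRI image"
    ): NKG.NKG_0000044,
    "intracranial volume feature extraction": NKG.NKG_0000045,
    "MoCA category fluency subtest": NKG.NKG_0000050,
    "cognitive function": NKG.NKG_0000054,
    "semantic category fluency function": NKG.NKG_0000056,
    "study subject with Parkinson disease": NKG.NKG_0000060,
    "healthy control study subject": NKG.NKG_0000061,
    "pseudonymous subject identifier": NKG.NKG_0000062,
    "study subject with mild cognitive impairment": NKG.NKG_0000070,
    "source dataset name": NKG.NKG_0000080,
}


class RegistryError(KeyError):
    """Raised when a term or IRI cannot be resolved in the registry."""


def _curie_of(iri: URIRef) -> str | None:
    text = str(iri)
    for base in (str(OBO), str(NKG)):
        if text.startswith(base):
            return text[len(base):]
    return None


@dataclass
class TermRegistry:
    """Bidirectional label/CURIE ↔ IRI lookup for the shared vocabulary.

    Keys accepted by :meth:`resolve` are labels (``"planned process"``),
    OBO-style CURIEs (``"OBI_0000011"`` or ``"OBI:0000011"``), or absolute
    IRIs. Every registered IRI must be absolute; an alias may never be
    rebound to a different IRI.
    """

    entries: dict[str, URIRef] = field(default_factory=dict)

    def register(self, label: str, iri: URIRef | str) -> URIRef:
        iri = URIRef(str(iri))
        if "://" not in str(iri):
            raise RegistryError(f"IRI is not absolute: {iri!r}")
        for alias in self._aliases(label, iri):
            existing = self.entries.get(alias)
            if existing is not None and existing != iri:
                raise RegistryError(
                    f"alias {alias!r} already bound to {existing}, cannot rebind to {iri}"
                )
            self.entries[alias] = iri
        return iri

    @staticmethod
    def _aliases(label: str, iri: URIRef) -> list[str]:
        aliases = [label, str(iri)]
        curie = _curie_of(iri)
        if curie is not None:
            aliases.append(curie)
            if "_" in curie:
                prefix, _, local = curie.partition("_")
                aliases.append(f"{prefix}:{local}")
        return aliases

    def resolve(self, key: str) -> URIRef:
        """Return the IRI for a label, CURIE, or IRI; raise RegistryError if unknown."""
        key = str(key)
        if key in self.entries:
            return self.entries[key]
        if key.replace(":", "_") in self.entries:
            return self.entries[key.replace(":", "_")]
        if "://" in key:
            # absolute IRI in a namespace we mint ourselves is acceptable
            if key.startswith(str(NKG)) or key.startswith(str(NKG_INSTANCE)):
                return URIRef(key)
            raise RegistryError(f"unresolvable IRI: {key!r}")
        raise RegistryError(f"unresolvable term: {key!r}")

    def __contains__(self, key: str) -> bool:
        try:
            self.resolve(key)
            return True
        except RegistryError:
            return False

    @property
    def iris(self) -> set[URIRef]:
        return set(self.entries.values())


def core_registry() -> TermRegistry:
    """Registry pre-loaded with the OBO vocabulary and the application terms."""
    reg = TermRegistry()
    for label, iri in TERMS.items():
        reg.register(label, iri)
    for label, iri in APP_TERMS.items():
        reg.register(label, iri)
    return reg


def load_core_ontology() -> Graph:
    """Parse the vendored Turtle module of the core vocabulary."""
    ref = importlib.resources.files("neurokg.data").joinpath("core_terms.ttl")
    graph = Graph()
    graph.parse(data=ref.read_text(encoding="utf-8"), format="turtle")
    graph.bind("obo", OBO)
    graph.bind("nkg", NKG)
    graph.bind("owl", OWL)
    return graph


def term_label(graph: Graph, iri: URIRef) -> str | None:
    label = graph.value(iri, RDFS.label)
    return str(label) if label is not None else None


def is_class(graph: Graph, iri: URIRef) -> bool:
    return (iri, RDF.type, OWL.Class) in graph
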