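"""Vocabulary registry, term definitions, module extraction, and merging."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st
from rdflib import Graph, URIRef, BNode
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS

from neurokg.ontology import (
    DefinitionError,
    build_app_ontology,
    canonical_nt,
    define_term,
    extract_module,
    merge_graphs,
)
from neurokg.vocab import (
    APP_TERMS,
    TERMS,
    RegistryError,
    core_registry,
    load_core_ontology,
)

# the thirteen OBO IRIs the shared vocabulary must expose
CORE_CURIES = [
    "NCBITaxon_9606", "IAO_0000219", "BFO_0000057", "NPT_0020000",
    "OBI_0000070", "OBI_0000299", "OBI_0001933", "IAO_0000109",
    "OBI_0001938", "OBI_0002135", "OBI_0000097", "RO_0000052", "OBI_0000011",
]


class TestRegistry:
    def test_core_iris_present_absolute_and_unique(self, registry):
        iris = [registry.resolve(curie) for curie in CORE_CURIES]
        assert all(str(iri).startswith("http://purl.obolibrary.org/obo/") for iri in iris)
        assert len(set(iris)) == len(CORE_CURIES)

    @pytest.mark.parametrize(
        "key,expected",
        [
            ("planned process", "http://purl.obolibrary.org/obo/OBI_0000011"),
            ("OBI:0000011", "http://purl.obolibrary.org/obo/OBI_0000011"),
            ("NPT_0020000", "http://purl.obolibrary.org/obo/NPT_0020000"),
            ("Montreal cognitive assessment assay",
             "http://purl.obolibrary.org/obo/NPT_0020000"),
        ],
    )
    def test_resolution_by_label_and_curie(self, registry, key, expected):
        assert str(registry.resolve(key)) == expected

    def test_unknown_term_raises_naming_the_key(self, registry):
        with pytest.raises(RegistryError, match="no-such-term"):
            registry.resolve("no-such-term")

    def test_relative_iri_rejected(self, registry):
        with pytest.raises(RegistryError):
            registry.register("x", "not-an-absolute-iri")

    def test_alias_cannot_be_rebound(self, registry):
        with pytest.raises(RegistryError):
            registry.register("planned process", "http://example.org/other")


class TestDefineTerm:
    def test_feature_extraction_term_has_two_parents_three_restrictions(self, registry):
        """The right-hippocampal FIRST-extraction term: 2 subclass axioms to
        named parents plus 3 existential restrictions (input, output, objective)."""
        term = define_term(
            "right hippocampal volume feature extraction using the FIRST "
            "segmentation utility from FSL on a T1 MRI image",
            parents=["planned process", "right hippocampal volume feature extraction"],
            restrictions=[
                ("has specified input", "some", "image"),
                ("has specified output", "some", "right hippocampal volume measurement datum"),
                ("achieves planned objective", "some", "feature extraction objective"),
            ],
            registry=registry,
        )
        assert term.parent_axiom_count == 2
        assert term.restriction_axiom_count == 3
        g = term.to_graph()
        named_parents = [
            o for o in g.objects(term.iri, RDFS.subClassOf) if isinstance(o, URIRef)
        ]
        restriction_parents = [
            o for o in g.objects(term.iri, RDFS.subClassOf) if isinstance(o, BNode)
        ]
        assert len(named_parents) == 2
        assert len(restriction_parents) == 3
        for node in restriction_parents:
            assert (node, RDF.type, OWL.Restriction) in g
            assert g.value(node, OWL.onProperty) is not None
            assert g.value(node, OWL.someValuesFrom) is not None

    def test_minimal_term_single_subclass_axiom(self, registry):
        term = define_term("x", parents=["assay"], registry=registry)
        g = term.to_graph()
        assert len(list(g.objects(term.iri, RDFS.subClassOf))) == 1

    def test_unresolvable_restriction_iri_raises(self, registry):
        with pytest.raises(RegistryError, match="bogus"):
            define_term(
                "x", parents=["assay"],
                restrictions=[("bogus-property", "some", "image")],
                registry=registry,
            )

    def test_empty_parents_rejected(self, registry):
        with pytest.raises(DefinitionError):
            define_term("x", parents=[], registry=registry)

    def test_non_existential_quantifier_rejected(self, registry):
        with pytest.raises(DefinitionError, match="some"):
            define_term(
                "x", parents=["assay"],
                restrictions=[("part of", "only", "assay")],
                registry=registry,
            )


def toy_ontology(edges: list[tuple[str, str]]) -> Graph:
    """Build a subclass-only ontology from (child, parent) label pairs."""
    g = Graph()
    ns = "http://example.org/"
    classes = {c for edge in edges for c in edge}
    for c in classes:
        g.add((URIRef(ns + c), RDF.type, OWL.Class))
    for child, parent in edges:
        g.add((URIRef(ns + child), RDFS.subClassOf, URIRef(ns + parent)))
    return g


def members_of(module) -> set[str]:
    return {str(m).rsplit("/", 1)[-1] for m in module.members}


class TestExtractModule:
    EDGES = [("A", "B"), ("B", "C"), ("D", "E")]

    def test_recursive_closure_from_single_seed(self):
        module = extract_module(toy_ontology(self.EDGES), {URIRef("http://example.org/A")})
        assert members_of(module) == {"A", "B", "C"}
        # the D-E axiom is excluded
        assert (URIRef("http://example.org/D"), None, None) not in module.graph

    def test_disconnected_seed_gets_own_component(self):
        module = extract_module(toy_ontology(self.EDGES), {URIRef("http://example.org/D")})
        assert members_of(module) == {"D", "E"}

    def test_all_seeds_reproduce_input(self):
        onto = toy_ontology(self.EDGES)
        seeds = {s for s in onto.subjects() if isinstance(s, URIRef)}
        module = extract_module(onto, seeds)
        assert set(module.graph) == set(onto)

    def test_missing_seed_kept_as_bare_declaration(self):
        onto = toy_ontology(self.EDGES)
        ghost = URIRef("http://example.org/Ghost")
        with pytest.warns(UserWarning, match="Ghost"):
            module = extract_module(onto, {ghost})
        assert (ghost, RDF.type, OWL.Class) in module.graph

    def test_empty_seeds_rejected(self):
        with pytest.raises(ValueError):
            extract_module(toy_ontology(self.EDGES), set())

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(data=st.data())
    def test_monotone_and_idempotent_on_random_dags(self, data):
        """seeds1 ⊆ seeds2 ⇒ members1 ⊆ members2; re-extraction is a fixpoint."""
        n = data.draw(st.integers(3, 8))
        labels = [f"C{i}" for i in range(n)]
        # edges only from lower to higher index: guaranteed acyclic
        edges = data.draw(
            st.lists(
                st.tuples(st.integers(0, n - 2), st.integers(1, n - 1)).filter(
                    lambda e: e[0] < e[1]
                ),
                min_size=1,
                max_size=12,
            )
        )
        onto = toy_ontology([(labels[a], labels[b]) for a, b in edges])
        present = sorted({s for s in onto.subjects() if isinstance(s, URIRef)})
        seeds2 = set(data.draw(st.lists(st.sampled_from(present), min_size=1, unique=True)))
        seeds1 = set(data.draw(st.lists(st.sampled_from(sorted(seeds2)), min_size=1, unique=True)))

        m1 = extract_module(onto, seeds1)
        m2 = extract_module(onto, seeds2)
        assert m1.members <= m2.members
        again = extract_module(m2.graph, m2.seed_iris)
        assert set(again.graph) == set(m2.graph)

    def test_module_extraction_on_real_vocabulary(self, ontology_graph):
        moca = TERMS["Montreal cognitive assessment assay"]
        module = extract_module(ontology_graph, {moca})
        # subclass chain: MoCA assay → assay → planned process
        assert TERMS["assay"] in module.members
        assert TERMS["planned process"] in module.members


class TestMergeGraphs:
    def test_merge_is_idempotent(self, ontology_graph):
        merged = merge_graphs(ontology_graph, ontology_graph)
        assert set(merged) == set(ontology_graph)

    def test_disjoint_merge_adds_cardinalities(self):
        g1 = toy_ontology([("A", "B")])
        g2 = Graph()
        g2.add((URIRef("http://example.org/x"), URIRef("http://example.org/p"),
                URIRef("http://example.org/y")))
        merged = merge_graphs(g1, g2)
        assert len(merged) == len(g1) + len(g2)

    def test_every_input_is_subgraph_of_result(self, ontology_graph):
        g2 = toy_ontology([("A", "B"), ("B", "C")])
        merged = merge_graphs(ontology_graph, g2)
        assert all(t in merged for t in ontology_graph)
        assert all(t in merged for t in g2)

    def test_merge_commutative_and_associative(self):
        g1 = toy_ontology([("A", "B")])
        g2 = toy_ontology([("B", "C")])
        g3 = toy_ontology([("D", "E")])
        assert set(merge_graphs(g1, g2)) == set(merge_graphs(g2, g1))
        assert set(merge_graphs(merge_graphs(g1, g2), g3)) == set(
            merge_graphs(g1, merge_graphs(g2, g3))
        )

    def test_serialization_round_trip_is_isomorphic(self, ontology_graph, tmp_path):
        """Merge module + app ontology, write Turtle, re-parse: isomorphic."""
        path = tmp_path / "merged.ttl"
        ontology_graph.serialize(destination=str(path), format="turtle")
        back = Graph()
        back.parse(str(path))
        assert isomorphic(ontology_graph, back)


class TestCanonicalSerialization:
    def test_canonical_nt_is_stable_across_parse_cycles(self):
        g = build_app_ontology()
        text1 = canonical_nt(g)
        reparsed = Graph()
        reparsed.parse(data=text1, format="nt")
        assert canonical_nt(reparsed) == text1

    def test_core_ontology_labels_loaded(self):
        g = load_core_ontology()
        assert (TERMS["planned process"], RDFS.label, None) in g
        assert len(g) > 30


def test_app_ontology_terms_are_declared():
    g = build_app_ontology()
    for label in (
        "brain",
        "MoCA category fluency subtest",
        "study subject with mild cognitive impairment",
    ):
        assert (APP_TERMS[label], RDF.type, OWL.Class) in g
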