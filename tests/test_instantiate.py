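"""Instance-pattern construction, conformance validation, provenance."""

from __future__ import annotations

import pytest
from rdflib import Graph, Literal, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import RDF, XSD

from neurokg.instantiate import (
    InstanceGraph,
    InstantiationError,
    instantiate_assessment,
    instantiate_feature_extraction,
    instantiate_icv_extraction,
    instantiate_subject,
    validate_patterns,
)
from neurokg.simulate import generate_cohorts
from neurokg.vocab import APP_TERMS, TERMS

from conftest import small_config

MOCA = TERMS["Montreal cognitive assessment assay"]
HUMAN = TERMS["Homo sapiens"]


def subject_iri(n: int) -> URIRef:
    return URIRef(f"https://w3id.org/neurokg/instance/subj-{n:04d}")


@pytest.fixture
def one_subject():
    ig = InstanceGraph()
    s = subject_iri(1)
    instantiate_subject(ig, s, id_label="abc123", group="PD", prov=("d1", 0))
    return ig, s


class TestInstantiateSubject:
    def test_subject_typed_homo_sapiens(self, one_subject):
        ig, s = one_subject
        assert (s, RDF.type, HUMAN) in ig.graph

    def test_fragment_is_conformant_by_construction(self, one_subject):
        ig, _ = one_subject
        assert validate_patterns(ig).ok

    def test_two_subjects_share_no_instance_nodes(self):
        ig = InstanceGraph()
        instantiate_subject(ig, subject_iri(1), "a", "PD")
        nodes1 = {t[0] for t in ig.graph} | {
            t[2] for t in ig.graph if isinstance(t[2], URIRef)
        }
        ig2 = InstanceGraph()
        instantiate_subject(ig2, subject_iri(2), "b", "HC")
        nodes2 = {t[0] for t in ig2.graph} | {
            t[2] for t in ig2.graph if isinstance(t[2], URIRef)
        }
        instance_ns = "https://w3id.org/neurokg/instance/"
        shared = {
            n for n in nodes1 & nodes2 if str(n).startswith(instance_ns)
        }
        assert shared == set()

    def test_duplicate_subject_rejected(self, one_subject):
        ig, s = one_subject
        with pytest.raises(InstantiationError, match="duplicate"):
            instantiate_subject(ig, s, "x", "PD")

    def test_unknown_group_rejected(self):
        with pytest.raises(InstantiationError, match="group"):
            instantiate_subject(InstanceGraph(), subject_iri(3), "x", "XX")


class TestInstantiateAssessment:
    def test_score_path_exists(self, one_subject):
        """assay → specified output → value specification → literal score."""
        ig, s = one_subject
        assay = instantiate_assessment(ig, s, MOCA, score=24)
        datum = ig.graph.value(assay, TERMS["has specified output"])
        assert datum is not None
        vs = ig.graph.value(datum, TERMS["has value specification"])
        assert vs is not None
        value = ig.graph.value(vs, TERMS["has specified value"])
        assert value == Literal(24, datatype=XSD.integer)
        assert (assay, TERMS["has participant"], s) in ig.graph

    def test_missing_score_yields_no_fragment_and_one_skip(self, one_subject):
        ig, s = one_subject
        before = len(ig)
        result = instantiate_assessment(ig, s, MOCA, score=None, prov=("d1", 7))
        assert result is None
        assert len(ig) == before
        assert ig.skips == [("d1", 7, "missing score")]

    def test_subtest_instantiated_as_part_with_own_output(self, one_subject):
        ig, s = one_subject
        assay = instantiate_assessment(
            ig, s, MOCA, score=24, part_scores={"moca_category_fluency": 15}
        )
        subtests = [
            x for x in ig.graph.subjects(TERMS["part of"], assay)
        ]
        assert len(subtests) == 1
        datum = ig.graph.value(subtests[0], TERMS["has specified output"])
        assert datum is not None
        # the fluency datum is about the subject's fluency function instance
        function = ig.graph.value(datum, TERMS["is about"])
        assert function is not None
        assert (
            function, RDF.type, APP_TERMS["semantic category fluency function"]
        ) in ig.graph

    def test_one_assay_instance_per_generated_subject(
        self, default_mappings, ontology_graph
    ):
        """Count oracle: n subjects each with one MoCA → n assay instances."""
        from conftest import build_graph

        bundle = build_graph(small_config(seed=7), default_mappings, ontology_graph)
        n_rows = sum(len(t.rows) for t in bundle["cohort"].tables)
        assays = list(bundle["graph"].subjects(RDF.type, MOCA))
        assert len(assays) == n_rows == 40


class TestInstantiateFeatureExtraction:
    def test_single_input_single_output_about_hippocampus(self, one_subject):
        ig, s = one_subject
        process = instantiate_feature_extraction(ig, s, 3650.0, side="left")
        inputs = list(ig.graph.objects(process, TERMS["has specified input"]))
        outputs = list(ig.graph.objects(process, TERMS["has specified output"]))
        assert len(inputs) == 1 and len(outputs) == 1
        hippo = ig.graph.value(outputs[0], TERMS["is about"])
        assert str(hippo).endswith("/hippocampus-left")

    def test_left_and_right_yield_distinct_data(self, one_subject):
        ig, s = one_subject
        p_left = instantiate_feature_extraction(ig, s, 3650.0, side="left")
        p_right = instantiate_feature_extraction(ig, s, 3702.0, side="right")
        d_left = ig.graph.value(p_left, TERMS["has specified output"])
        d_right = ig.graph.value(p_right, TERMS["has specified output"])
        assert d_left != d_right
        assert ig.graph.value(d_left, TERMS["is about"]) != \
            ig.graph.value(d_right, TERMS["is about"])

    def test_invalid_side_rejected(self, one_subject):
        ig, s = one_subject
        with pytest.raises(InstantiationError, match="side"):
            instantiate_feature_extraction(ig, s, 3650.0, side="bilateral")

    def test_missing_subject_anatomy_is_error(self):
        ig = InstanceGraph()
        with pytest.raises(InstantiationError, match="hippocampus"):
            instantiate_feature_extraction(ig, subject_iri(9), 3650.0, side="left")


class TestValidatePatterns:
    def build_conformant(self):
        ig = InstanceGraph()
        s = subject_iri(1)
        instantiate_subject(ig, s, "a", "PD")
        instantiate_assessment(ig, s, MOCA, 24)
        instantiate_feature_extraction(ig, s, 3600.0, "left")
        instantiate_icv_extraction(ig, s, 1.45e6)
        return ig, s

    def test_conformant_graph_no_violations(self):
        ig, _ = self.build_conformant()
        report = validate_patterns(ig)
        assert report.ok and report.counts == {}

    def test_removed_identifier_detected_exactly_once(self):
        ig, s = self.build_conformant()
        identifier = next(ig.graph.subjects(TERMS["denotes"], s))
        ig.graph.remove((identifier, TERMS["denotes"], s))
        report = validate_patterns(ig)
        assert report.counts == {"subject-has-identifier": 1}

    def test_duplicated_value_spec_detected_exactly_once(self):
        ig, s = self.build_conformant()
        assay = next(ig.graph.subjects(RDF.type, MOCA))
        datum = ig.graph.value(assay, TERMS["has specified output"])
        ig.graph.add((datum, TERMS["has value specification"],
                      URIRef(str(datum) + "/vs-duplicate")))
        report = validate_patterns(ig)
        assert report.counts == {"single-value-spec": 1}

    def test_report_ordering_deterministic(self):
        ig, s = self.build_conformant()
        identifier = next(ig.graph.subjects(TERMS["denotes"], s))
        ig.graph.remove((identifier, TERMS["denotes"], s))
        role = next(ig.graph.subjects(TERMS["inheres in"], s))
        ig.graph.remove((role, TERMS["inheres in"], s))
        r1 = validate_patterns(ig)
        r2 = validate_patterns(ig)
        assert r1.violations == r2.violations == sorted(r1.violations)


class TestGraphLevelInvariants:
    def test_row_conservation_per_source(self, small_bundle):
        """#rows with a MoCA score == #assay instances attributed via provenance."""
        ig = small_bundle["instance_graph"]
        harmonized = small_bundle["harmonized"]
        for source in ("dataset1", "dataset2"):
            expected = int(
                harmonized[harmonized["source"] == source]["moca_total"].notna().sum()
            )
            assay_triples = [
                t for t, (src, _) in ig.provenance.items()
                if src == source and t[1] == RDF.type and t[2] == MOCA
            ]
            assert len(assay_triples) == expected

    def test_provenance_totality(self, small_bundle):
        ig = small_bundle["instance_graph"]
        assert set(ig.graph) == set(ig.provenance)

    def test_turtle_round_trip_isomorphic(self, small_bundle, tmp_path):
        g = small_bundle["instance_graph"].graph
        path = tmp_path / "instances.ttl"
        g.serialize(destination=str(path), format="turtle")
        back = Graph()
        back.parse(str(path))
        assert isomorphic(g, back)

    def test_generated_cohort_graph_is_conformant(self, small_bundle):
        assert validate_patterns(small_bundle["instance_graph"]).ok
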