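"""Shared fixtures: small synthetic cohorts and fully built knowledge graphs.

Everything is generated programmatically at test time; no fixture files.
"""

from __future__ import annotations

import pytest

from neurokg.instantiate import build_instance_graph
from neurokg.mapping import PseudonymPolicy, harmonize
from neurokg.ontology import build_app_ontology, extract_module, merge_graphs
from neurokg.pipeline import _bundled_mapping
from neurokg.simulate import generate_cohorts, table1_config
from neurokg.vocab import core_registry, load_core_ontology
from rdflib.namespace import RDF


@pytest.fixture(scope="session")
def registry():
    return core_registry()


@pytest.fixture(scope="session")
def ontology_graph():
    return merge_graphs(load_core_ontology(), build_app_ontology())


@pytest.fixture(scope="session")
def default_mappings():
    return _bundled_mapping()


def small_config(seed: int = 0, n_per_group: int = 10):
    """Table-1-calibrated config scaled down for fast graph construction."""
    config = table1_config(seed=seed)
    for source in config.sources:
        for group in source.groups.values():
            group.n = n_per_group
    return config


def build_graph(config, mappings, ontology, salt: str = "test-salt"):
    """Generate → harmonize → instantiate → merge: returns the full bundle."""
    cohort = generate_cohorts(config)
    harmonized, report = harmonize(cohort.tables, mappings)
    ig, index = build_instance_graph(harmonized, PseudonymPolicy(salt))
    seeds = set(ig.graph.objects(None, RDF.type))
    module = extract_module(ontology, seeds)
    merged = merge_graphs(module.graph, ig.graph)
    return {
        "cohort": cohort,
        "harmonized": harmonized,
        "report": report,
        "instance_graph": ig,
        "index": index,
        "graph": merged,
    }


@pytest.fixture(scope="session")
def small_bundle(default_mappings, ontology_graph):
    """One fully built small cohort shared by read-only tests."""
    return build_graph(small_config(seed=42), default_mappings, ontology_graph)
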