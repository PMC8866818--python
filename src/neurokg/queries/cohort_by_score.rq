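# Cohort selection by assessment score.
# Template parameters: ${assay_class} (IRI), ${cmp} (one of < <= >= >),
# ${threshold} (number). Returns one row per qualifying (subject, assay):
# the subject node, its pseudonymous identifier label, and the score.
#
# Direct typing is expressed portably as rdf:type plus exclusion of
# strict-subclass matches instead of a store-specific predicate, and the
# score filter applies to the bound ?score variable. Class-membership
# checks are written as FILTER EXISTS over already-bound nodes, which is
# semantically identical to inline rdf:type patterns but keeps naive
# bottom-up evaluators from cross-joining the type patterns.
PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX human: <http://purl.obolibrary.org/obo/NCBITaxon_9606>
PREFIX denotes: <http://purl.obolibrary.org/obo/IAO_0000219>
PREFIX has_participant: <http://purl.obolibrary.org/obo/BFO_0000057>
PREFIX has_specified_output: <http://purl.obolibrary.org/obo/OBI_0000299>
PREFIX measurement_datum: <http://purl.obolibrary.org/obo/IAO_0000109>
PREFIX has_value_specification: <http://purl.obolibrary.org/obo/OBI_0001938>
PREFIX has_specified_value: <http://purl.obolibrary.org/obo/OBI_0002135>
PREFIX subject_role: <http://purl.obolibrary.org/obo/OBI_0000097>
PREFIX inheres_in: <http://purl.obolibrary.org/obo/RO_0000052>

SELECT ?s ?idl ?score WHERE {
    ?s rdf:type human: .              # s is the individual subject
    ?srole inheres_in: ?s .           # the person bears a study-subject role
    FILTER EXISTS { ?srole rdf:type subject_role: . }
    ?id denotes: ?s .                 # the pseudonymous subject identifier
    ?id rdfs:label ?idl .
    # the subject participated in an assay of the requested class
    ?assay has_participant: ?s .
    FILTER EXISTS { ?assay rdf:type <${assay_class}> . }
    FILTER NOT EXISTS {
        ?assay rdf:type ?subtype .
        ?subtype rdfs:subClassOf+ <${assay_class}> .
        FILTER (?subtype != <${assay_class}>)
    }
    ?assay has_specified_output: ?output .
    FILTER EXISTS { ?output rdf:type measurement_datum: . }
    ?output has_value_specification: ?vs .
    ?vs has_specified_value: ?score .
    FILTER (?score ${cmp} ${threshold})
}
ORDER BY ?idl
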