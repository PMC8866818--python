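@prefix obo: <http://purl.obolibrary.org/obo/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

# Minimal hand-built module of the OBO vocabulary used by the instance
# pattern and the cohort query: labels plus a shallow subclass skeleton.
# This is a vendored stand-in so that no ontology download is required;
# full OBI/IAO/NPT releases can be merged on top.

obo:BFO_0000023 a owl:Class ;
    rdfs:label "role" .

obo:OBI_0000011 a owl:Class ;
    rdfs:label "planned process" .

obo:OBI_0000070 a owl:Class ;
    rdfs:label "assay" ;
    rdfs:subClassOf obo:OBI_0000011 .

obo:NPT_0020000 a owl:Class ;
    rdfs:label "Montreal cognitive assessment assay" ;
    rdfs:subClassOf obo:OBI_0000070 .

obo:NCBITaxon_9606 a owl:Class ;
    rdfs:label "Homo sapiens" .

obo:OBI_0000097 a owl:Class ;
    rdfs:label "study subject role" ;
    rdfs:subClassOf obo:BFO_0000023 .

obo:IAO_0000030 a owl:Class ;
    rdfs:label "information content entity" .

obo:IAO_0000109 a owl:Class ;
    rdfs:label "measurement datum" ;
    rdfs:subClassOf obo:IAO_0000030 .

obo:IAO_0000101 a owl:Class ;
    rdfs:label "image" ;
    rdfs:subClassOf obo:IAO_0000030 .

obo:OBI_0001933 a owl:Class ;
    rdfs:label "value specification" ;
    rdfs:subClassOf obo:IAO_0000030 .

obo:IAO_0000219 a owl:ObjectProperty ;
    rdfs:label "denotes" .

obo:BFO_0000057 a owl:ObjectProperty ;
    rdfs:label "has participant" .

obo:BFO_0000050 a owl:ObjectProperty ;
    rdfs:label "part of" .

obo:RO_0000052 a owl:ObjectProperty ;
    rdfs:label "inheres in" .

obo:IAO_0000136 a owl:ObjectProperty ;
    rdfs:label "is about" .

obo:OBI_0000293 a owl:ObjectProperty ;
    rdfs:label "has specified input" .

obo:OBI_0000299 a owl:ObjectProperty ;
    rdfs:label "has specified output" .

obo:OBI_0000417 a owl:ObjectProperty ;
    rdfs:label "achieves planned objective" .

obo:OBI_0001938 a owl:ObjectProperty ;
    rdfs:label "has value specification" .

obo:OBI_0002135 a owl:DatatypeProperty ;
    rdfs:label "has specified value" .
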