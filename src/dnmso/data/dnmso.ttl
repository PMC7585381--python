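@prefix dnmso: <https://w3id.org/dnmso/1.0#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .

# Vocabulary of the DNMSO format, version 1.0.
# Ordered collections (spectra, predictions, scores, source references,
# sequence elements, supporting peaks, parameters) are encoded as RDF lists
# so that ordering survives round trips. Numeric values are carried as plain
# literals in repr lexical form for bit-exact round trips; inline peak lists
# as one CSV literal ("mz,intensity" per line) per spectrum.

<https://w3id.org/dnmso/1.0> a owl:Ontology ;
    rdfs:label "de novo MS ontology (DNMSO) vocabulary" ;
    owl:versionInfo "1.0" .

## Classes

dnmso:Document a rdfs:Class ;
    rdfs:comment "Root container of one DNMSO instance." .
dnmso:Spectrum a rdfs:Class ;
    rdfs:comment "One MS/MS scan, inline (CSV peaks) or externally referenced." .
dnmso:ExternalSpectrumRef a rdfs:Class ;
    rdfs:comment "Pointer into an external peak-list file (mzML/mzXML/MGF)." .
dnmso:Prediction a rdfs:Class ;
    rdfs:comment "One peptide-spectrum match: a sequence, at least one score, at least one source spectrum." .
dnmso:Score a rdfs:Class .
dnmso:Sequence a rdfs:Class .
dnmso:AminoAcid a rdfs:Class ;
    rdfs:comment "Sequence element: one standard residue (seAminoAcid)." .
dnmso:ModifiedAminoAcid a rdfs:Class ;
    rdfs:subClassOf dnmso:AminoAcid ;
    rdfs:comment "Sequence element that reduces to an amino acid plus a modification reference (seModifiedAminoAcid)." .
dnmso:Gap a rdfs:Class ;
    rdfs:comment "Sequence element: an unexplained monoisotopic mass (Gap)." .
dnmso:SupportingPeak a rdfs:Class ;
    rdfs:comment "Evidence link from a sequence element to one peak of a spectrum." .
dnmso:Modification a rdfs:Class ;
    rdfs:comment "A PTM used in this instance; must reference a PSI-MOD term." .
dnmso:Software a rdfs:Class .
dnmso:CVParam a rdfs:Class .
dnmso:KeyValueParam a rdfs:Class .
dnmso:CVSource a rdfs:Class ;
    rdfs:comment "A controlled vocabulary cited by this instance (PSI-MS, PSI-MOD, ...)." .

## Document properties

dnmso:formatVersion a rdf:Property ; rdfs:domain dnmso:Document .
dnmso:documentId a rdf:Property ; rdfs:domain dnmso:Document .
dnmso:provenance a rdf:Property ; rdfs:domain dnmso:Document ;
    rdfs:comment "Creation metadata as a canonical JSON object literal." .
dnmso:spectrumList a rdf:Property ; rdfs:domain dnmso:Document ;
    rdfs:comment "RDF list of Spectrum nodes, in document order." .
dnmso:predictionList a rdf:Property ; rdfs:domain dnmso:Document .
dnmso:modificationList a rdf:Property ; rdfs:domain dnmso:Document .
dnmso:softwareList a rdf:Property ; rdfs:domain dnmso:Document .
dnmso:cvSourceList a rdf:Property ; rdfs:domain dnmso:Document .

## Shared

dnmso:localId a rdf:Property .
dnmso:nativeId a rdf:Property ;
    rdfs:comment "Scan identifier in the source file (MGF TITLE, mzML id, mzXML num)." .
dnmso:cvAccession a rdf:Property .

## Spectrum

dnmso:precursorMz a rdf:Property ; rdfs:domain dnmso:Spectrum ;
    rdfs:comment "Precursor m/z in Thomson; absent when unknown." .
dnmso:precursorCharge a rdf:Property ; rdfs:domain dnmso:Spectrum .
dnmso:retentionTimeSeconds a rdf:Property ; rdfs:domain dnmso:Spectrum .
dnmso:fragmentation a rdf:Property ; rdfs:domain dnmso:Spectrum ;
    rdfs:comment "One of CID, ETD, HCD, other." .
dnmso:peaksCsv a rdf:Property ; rdfs:domain dnmso:Spectrum ;
    rdfs:comment "Inline peak list: one 'mz,intensity' line per peak, sorted by m/z, repr lexical forms." .
dnmso:externalRef a rdf:Property ; rdfs:domain dnmso:Spectrum ;
    rdfs:range dnmso:ExternalSpectrumRef .
dnmso:filePath a rdf:Property ; rdfs:domain dnmso:ExternalSpectrumRef .
dnmso:formatHint a rdf:Property ; rdfs:domain dnmso:ExternalSpectrumRef .

## Prediction

dnmso:rank a rdf:Property ; rdfs:domain dnmso:Prediction .
dnmso:softwareRef a rdf:Property ; rdfs:domain dnmso:Prediction .
dnmso:scoreList a rdf:Property ; rdfs:domain dnmso:Prediction ;
    rdfs:comment "RDF list of Score nodes; at least one is mandatory." .
dnmso:sourceSpectrumList a rdf:Property ; rdfs:domain dnmso:Prediction ;
    rdfs:comment "RDF list of spectrum local-id literals and/or ExternalSpectrumRef nodes; at least one is mandatory (many-to-many with Spectrum)." .
dnmso:sequence a rdf:Property ; rdfs:domain dnmso:Prediction ; rdfs:range dnmso:Sequence .
dnmso:scoreName a rdf:Property ; rdfs:domain dnmso:Score .
dnmso:scoreValue a rdf:Property ; rdfs:domain dnmso:Score .

## Sequence elements

dnmso:elementList a rdf:Property ; rdfs:domain dnmso:Sequence .
dnmso:residue a rdf:Property .
dnmso:modificationRef a rdf:Property ; rdfs:domain dnmso:ModifiedAminoAcid .
dnmso:gapMass a rdf:Property ; rdfs:domain dnmso:Gap ;
    rdfs:comment "Unexplained monoisotopic mass in Daltons, > 0." .
dnmso:confidence a rdf:Property ;
    rdfs:comment "Per-element confidence in [0, 1]." .
dnmso:supportingPeakList a rdf:Property ;
    rdfs:comment "RDF list of SupportingPeak nodes (proofs for this element)." .
dnmso:spectrumRef a rdf:Property ; rdfs:domain dnmso:SupportingPeak .
dnmso:peakIndex a rdf:Property ; rdfs:domain dnmso:SupportingPeak .

## Modification

dnmso:psimodAccession a rdf:Property ; rdfs:domain dnmso:Modification ;
    rdfs:comment "Mandatory PSI-MOD term reference, pattern MOD:ddddd." .
dnmso:modificationName a rdf:Property ; rdfs:domain dnmso:Modification .
dnmso:monoMassDelta a rdf:Property ; rdfs:domain dnmso:Modification .
dnmso:avgMassDelta a rdf:Property ; rdfs:domain dnmso:Modification .
dnmso:residueSpecificity a rdf:Property ; rdfs:domain dnmso:Modification .
dnmso:terminus a rdf:Property ; rdfs:domain dnmso:Modification ;
    rdfs:comment "One of none, N-term, C-term." .

## Software and CV

dnmso:softwareName a rdf:Property ; rdfs:domain dnmso:Software .
dnmso:softwareVersion a rdf:Property ; rdfs:domain dnmso:Software .
dnmso:parameterList a rdf:Property ; rdfs:domain dnmso:Software .
dnmso:cvRef a rdf:Property ; rdfs:domain dnmso:CVParam .
dnmso:paramName a rdf:Property .
dnmso:paramValue a rdf:Property .
dnmso:fullName a rdf:Property ; rdfs:domain dnmso:CVSource .
dnmso:cvVersion a rdf:Property ; rdfs:domain dnmso:CVSource .
dnmso:uri a rdf:Property ; rdfs:domain dnmso:CVSource .
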