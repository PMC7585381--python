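"""RDF vocabulary and round-trip serialization of DNMSO documents.

The format is ontology-based: a document is an RDF graph in the versioned
DNMSO namespace. Three dialects are supported (Turtle by default, RDF/XML,
JSON-LD). Design points that matter for fidelity:

* Ordered collections (spectra, predictions, sequence elements, scores,
  source references, peaks) are encoded as RDF lists so ordering survives
  round trips exactly.
* Addressable entities (spectra, predictions, modifications, software, CV
  sources) get document-relative IRIs derived from their local ids; blank
  nodes are used only for non-addressable structure and get deterministic
  counter-derived labels, making serialization byte-stable.
* Inline peak lists are carried as a single CSV literal per spectrum
  (``mz,intensity`` per line, ``repr`` lexical forms), which keeps files
  compact and peak values bit-exact.
* All other real numbers are likewise carried with ``repr`` lexical forms in
  plain literals: RDF double lexical forms are not value-preserving through
  every serializer, and self-containment demands exactness.
* Triples in foreign namespaces are preserved opaquely and re-emitted, which
  is what makes the format extensible without coordination.

Validation is rule-based (:func:`dnmso.model.validate`); an external OWL
reasoner can be plugged in by operating on the emitted graph.
"""

from __future__ import annotations

import json
from typing import Iterable, List, Optional, Tuple
from urllib.parse import quote

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.compare import to_isomorphic
from rdflib.namespace import RDF, XSD

from .errors import InvalidDocumentError, RdfParseError, VersionError
from .model import (
    CVParam,
    CVSource,
    Document,
    ExternalSpectrumRef,
    Peak,
    Prediction,
    Score,
    Software,
    Spectrum,
    has_errors,
    validate,
)
from .sequence import (
    AminoAcidElement,
    GapElement,
    Modification,
    ModifiedAminoAcidElement,
    Sequence,
)

DNMSO_BASE = "https://w3id.org/dnmso/"
DNMSO_VERSION = "1.0"
DNMSO = Namespace(f"{DNMSO_BASE}{DNMSO_VERSION}#")

_DIALECTS = {
    "turtle": "turtle",
    "ttl": "turtle",
    "rdfxml": "xml",
    "xml": "xml",
    "jsonld": "json-ld",
    "json-ld": "json-ld",
}


def _format_for(dialect: str) -> str:
    try:
        return _DIALECTS[dialect.lower()]
    except KeyError:
        raise ValueError(f"unknown RDF dialect {dialect!r}") from None


def _num(value: float) -> Literal:
    # repr lexical form in a plain literal: exact through every serializer
    return Literal(repr(float(value)))


def _read_num(lit) -> Optional[float]:
    return None if lit is None else float(str(lit))


class _GraphBuilder:
    """Builds the RDF graph for one document with deterministic blank nodes."""

    def __init__(self, doc: Document):
        self.doc = doc
        self.g = Graph()
        self.g.bind("dnmso", DNMSO)
        self._bcount = 0
        qid = quote(doc.id, safe="")
        self.base = f"urn:dnmso:document/{qid}"
        self.doc_node = URIRef(self.base)

    def bnode(self) -> BNode:
        self._bcount += 1
        return BNode(f"b{self._bcount}")

    def iri(self, kind: str, local_id: str) -> URIRef:
        return URIRef(f"{self.base}/{kind}/{quote(str(local_id), safe='')}")

    def collection(self, items) -> URIRef:
        items = list(items)
        if not items:
            return RDF.nil
        head = self.bnode()
        node = head
        for i, item in enumerate(items):
            self.g.add((node, RDF.first, item))
            nxt = self.bnode() if i + 1 < len(items) else RDF.nil
            self.g.add((node, RDF.rest, nxt))
            node = nxt
        return head

    def build(self) -> Graph:
        g, d = self.g, self.doc_node
        g.add((d, RDF.type, DNMSO.Document))
        g.add((d, DNMSO.formatVersion, Literal(DNMSO_VERSION)))
        g.add((d, DNMSO.documentId, Literal(self.doc.id)))
        g.add((d, DNMSO.provenance,
               Literal(json.dumps(self.doc.provenance, sort_keys=True))))
        if self.doc.spectra:
            g.add((d, DNMSO.spectrumList,
                   self.collection(self._spectrum(s) for s in self.doc.spectra)))
        if self.doc.predictions:
            g.add((d, DNMSO.predictionList,
                   self.collection(self._prediction(p) for p in self.doc.predictions)))
        if self.doc.modifications:
            g.add((d, DNMSO.modificationList,
                   self.collection(self._modification(m) for m in self.doc.modifications)))
        if self.doc.software:
            g.add((d, DNMSO.softwareList,
                   self.collection(self._software(s) for s in self.doc.software)))
        if self.doc.cv_registry:
            g.add((d, DNMSO.cvSourceList,
                   self.collection(self._cv_source(c) for c in self.doc.cv_registry)))
        for triple in self.doc.extra_triples:
            g.add(triple)
        return g

    def _external_ref(self, ref: ExternalSpectrumRef):
        n = self.bnode()
        g = self.g
        g.add((n, RDF.type, DNMSO.ExternalSpectrumRef))
        g.add((n, DNMSO.filePath, Literal(ref.file_path_or_uri)))
        g.add((n, DNMSO.formatHint, Literal(ref.format_hint)))
        g.add((n, DNMSO.nativeId, Literal(ref.native_id)))
        return n

    def _spectrum(self, s: Spectrum):
        n = self.iri("spectrum", s.id)
        g = self.g
        g.add((n, RDF.type, DNMSO.Spectrum))
        g.add((n, DNMSO.localId, Literal(s.id)))
        if s.precursor_mz is not None:
            g.add((n, DNMSO.precursorMz, _num(s.precursor_mz)))
        if s.precursor_charge is not None:
            g.add((n, DNMSO.precursorCharge,
                   Literal(s.precursor_charge, datatype=XSD.integer)))
        if s.retention_time_s is not None:
            g.add((n, DNMSO.retentionTimeSeconds, _num(s.retention_time_s)))
        if s.fragmentation is not None:
            g.add((n, DNMSO.fragmentation, Literal(s.fragmentation)))
        if s.native_id is not None:
            g.add((n, DNMSO.nativeId, Literal(s.native_id)))
        if s.peaks:
            csv_body = "\n".join(f"{p.mz!r},{p.intensity!r}" for p in s.peaks)
            g.add((n, DNMSO.peaksCsv, Literal(csv_body)))
        if s.external_ref is not None:
            g.add((n, DNMSO.externalRef, self._external_ref(s.external_ref)))
        return n

    def _score(self, sc: Score):
        n = self.bnode()
        g = self.g
        g.add((n, RDF.type, DNMSO.Score))
        g.add((n, DNMSO.scoreName, Literal(sc.name)))
        g.add((n, DNMSO.scoreValue, _num(sc.value)))
        if sc.cv_accession is not None:
            g.add((n, DNMSO.cvAccession, Literal(sc.cv_accession)))
        return n

    def _element(self, el):
        n = self.bnode()
        g = self.g
        if isinstance(el, AminoAcidElement):
            g.add((n, RDF.type, DNMSO.AminoAcid))
            g.add((n, DNMSO.residue, Literal(el.residue)))
        elif isinstance(el, ModifiedAminoAcidElement):
            g.add((n, RDF.type, DNMSO.ModifiedAminoAcid))
            g.add((n, DNMSO.residue, Literal(el.residue)))
            g.add((n, DNMSO.modificationRef, Literal(el.modification_ref)))
        elif isinstance(el, GapElement):
            g.add((n, RDF.type, DNMSO.Gap))
            g.add((n, DNMSO.gapMass, _num(el.mass)))
        if el.confidence is not None:
            g.add((n, DNMSO.confidence, _num(el.confidence)))
        if el.supporting_peaks:
            peaks = []
            for spec_id, peak_idx in el.supporting_peaks:
                pn = self.bnode()
                g.add((pn, RDF.type, DNMSO.SupportingPeak))
                g.add((pn, DNMSO.spectrumRef, Literal(spec_id)))
                g.add((pn, DNMSO.peakIndex, Literal(int(peak_idx), datatype=XSD.integer)))
                peaks.append(pn)
            g.add((n, DNMSO.supportingPeakList, self.collection(peaks)))
        return n

    def _prediction(self, p: Prediction):
        n = self.iri("prediction", p.id)
        g = self.g
        g.add((n, RDF.type, DNMSO.Prediction))
        g.add((n, DNMSO.localId, Literal(p.id)))
        if p.rank is not None:
            g.add((n, DNMSO.rank, Literal(int(p.rank), datatype=XSD.integer)))
        if p.software_ref is not None:
            g.add((n, DNMSO.softwareRef, Literal(p.software_ref)))
        if p.scores:
            g.add((n, DNMSO.scoreList, self.collection(self._score(s) for s in p.scores)))
        if p.source_spectrum_refs:
            items = []
            for ref in p.source_spectrum_refs:
                if isinstance(ref, ExternalSpectrumRef):
                    items.append(self._external_ref(ref))
                else:
                    items.append(Literal(ref))
            g.add((n, DNMSO.sourceSpectrumList, self.collection(items)))
        if p.sequence.elements:
            seq = self.bnode()
            g.add((seq, RDF.type, DNMSO.Sequence))
            g.add((seq, DNMSO.elementList,
                   self.collection(self._element(e) for e in p.sequence.elements)))
            g.add((n, DNMSO.sequence, seq))
        return n

    def _modification(self, m: Modification):
        n = self.iri("modification", m.local_id)
        g = self.g
        g.add((n, RDF.type, DNMSO.Modification))
        g.add((n, DNMSO.localId, Literal(m.local_id)))
        g.add((n, DNMSO.psimodAccession, Literal(m.psimod_accession)))
        g.add((n, DNMSO.modificationName, Literal(m.name)))
        g.add((n, DNMSO.monoMassDelta, _num(m.mono_mass_delta)))
        g.add((n, DNMSO.avgMassDelta, _num(m.avg_mass_delta)))
        g.add((n, DNMSO.residueSpecificity, Literal(m.residue_specificity)))
        g.add((n, DNMSO.terminus, Literal(m.terminus)))
        return n

    def _software(self, sw: Software):
        n = self.iri("software", sw.id)
        g = self.g
        g.add((n, RDF.type, DNMSO.Software))
        g.add((n, DNMSO.localId, Literal(sw.id)))
        g.add((n, DNMSO.softwareName, Literal(sw.name)))
        g.add((n, DNMSO.softwareVersion, Literal(sw.version)))
        if sw.parameters:
            items = []
            for param in sw.parameters:
                pn = self.bnode()
                if isinstance(param, CVParam):
                    g.add((pn, RDF.type, DNMSO.CVParam))
                    g.add((pn, DNMSO.cvRef, Literal(param.cv_ref)))
                    g.add((pn, DNMSO.cvAccession, Literal(param.accession)))
                    g.add((pn, DNMSO.paramName, Literal(param.name)))
                    if param.value is not None:
                        g.add((pn, DNMSO.paramValue, Literal(param.value)))
                else:
                    key, value = param
                    g.add((pn, RDF.type, DNMSO.KeyValueParam))
                    g.add((pn, DNMSO.paramName, Literal(key)))
                    g.add((pn, DNMSO.paramValue, Literal(value)))
                items.append(pn)
            g.add((n, DNMSO.parameterList, self.collection(items)))
        return n

    def _cv_source(self, cv: CVSource):
        n = self.iri("cv", cv.id)
        g = self.g
        g.add((n, RDF.type, DNMSO.CVSource))
        g.add((n, DNMSO.localId, Literal(cv.id)))
        g.add((n, DNMSO.fullName, Literal(cv.full_name)))
        g.add((n, DNMSO.cvVersion, Literal(cv.version)))
        g.add((n, DNMSO.uri, Literal(cv.uri)))
        return n


def to_graph(doc: Document) -> Graph:
    """The document's RDF graph (validity not enforced; see serialize)."""
    return _GraphBuilder(doc).build()


def serialize(doc: Document, dialect: str = "turtle") -> bytes:
    """Serialize a document; refuses documents with ERROR-level violations.

    Output is deterministic: serializing the same document twice yields
    byte-identical bytes in every dialect.
    """
    violations = validate(doc)
    if has_errors(violations):
        raise InvalidDocumentError([v for v in violations if v.severity == "ERROR"])
    fmt = _format_for(dialect)
    data = to_graph(doc).serialize(format=fmt)
    if fmt == "json-ld":
        data = json.dumps(json.loads(data), sort_keys=True, indent=1)
    return data.encode("utf-8")


# ---------------------------------------------------------------------------
# Deserialization


class _GraphReader:
    def __init__(self, g: Graph):
        self.g = g
        self.remaining = set(g)

    def take(self, s, p):
        value = self.g.value(s, p)
        if value is not None:
            self.remaining.discard((s, p, value))
        return value

    def take_all(self, s, p):
        values = list(self.g.objects(s, p))
        for v in values:
            self.remaining.discard((s, p, v))
        return values

    def take_type(self, s):
        for t in self.g.objects(s, RDF.type):
            self.remaining.discard((s, RDF.type, t))

    def take_list(self, head):
        items = []
        node = head
        while node is not None and node != RDF.nil:
            first = self.g.value(node, RDF.first)
            rest = self.g.value(node, RDF.rest)
            if first is not None:
                self.remaining.discard((node, RDF.first, first))
                items.append(first)
            if rest is not None:
                self.remaining.discard((node, RDF.rest, rest))
            node = rest
        return items


def deserialize(data, dialect: str = "turtle") -> Document:
    """Parse RDF bytes/text into a Document.

    Cardinality problems in the graph (e.g. a prediction without a source
    spectrum link) are loaded as-is and surfaced by ``validate()``, so
    defective instances can be inspected rather than rejected blindly.
    Unknown triples in foreign namespaces are preserved and re-emitted on
    the next serialization.
    """
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    fmt = _format_for(dialect)
    g = Graph()
    try:
        g.parse(data=data, format=fmt)
    except Exception as e:
        raise RdfParseError(f"cannot parse input as {fmt}: {e}") from None
    doc_node = g.value(predicate=RDF.type, object=DNMSO.Document, any=True)
    if doc_node is None:
        for term in set(p for _, p, _ in g) | set(o for _, _, o in g if isinstance(o, URIRef)):
            ts = str(term)
            if ts.startswith(DNMSO_BASE) and not ts.startswith(str(DNMSO)):
                raise VersionError(
                    f"graph uses an unsupported DNMSO namespace version: {ts}"
                )
        raise VersionError("no DNMSO Document node found in graph")

    r = _GraphReader(g)
    r.take_type(doc_node)
    version = r.take(doc_node, DNMSO.formatVersion)
    if version is not None and str(version) != DNMSO_VERSION:
        raise VersionError(f"unsupported DNMSO format version {str(version)!r}")
    doc_id = r.take(doc_node, DNMSO.documentId)
    prov_lit = r.take(doc_node, DNMSO.provenance)
    provenance = json.loads(str(prov_lit)) if prov_lit is not None else {}
    doc = Document(provenance=provenance, id=str(doc_id) if doc_id else None)
    doc.provenance = provenance  # keep exactly what was stored

    for node in r.take_list(r.take(doc_node, DNMSO.spectrumList)):
        doc.spectra.append(_read_spectrum(r, node))
    for node in r.take_list(r.take(doc_node, DNMSO.predictionList)):
        doc.predictions.append(_read_prediction(r, node))
    for node in r.take_list(r.take(doc_node, DNMSO.modificationList)):
        doc.modifications.append(_read_modification(r, node))
    for node in r.take_list(r.take(doc_node, DNMSO.softwareList)):
        doc.software.append(_read_software(r, node))
    for node in r.take_list(r.take(doc_node, DNMSO.cvSourceList)):
        doc.cv_registry.append(_read_cv_source(r, node))

    doc.extra_triples = sorted(r.remaining, key=lambda t: tuple(x.n3() for x in t))
    return doc


def _read_external_ref(r, node) -> ExternalSpectrumRef:
    r.take_type(node)
    return ExternalSpectrumRef(
        file_path_or_uri=str(r.take(node, DNMSO.filePath) or ""),
        format_hint=str(r.take(node, DNMSO.formatHint) or "other"),
        native_id=str(r.take(node, DNMSO.nativeId) or ""),
    )


def _read_spectrum(r, node) -> Spectrum:
    r.take_type(node)
    local_id = r.take(node, DNMSO.localId)
    charge = r.take(node, DNMSO.precursorCharge)
    frag = r.take(node, DNMSO.fragmentation)
    native = r.take(node, DNMSO.nativeId)
    peaks_lit = r.take(node, DNMSO.peaksCsv)
    peaks = []
    if peaks_lit is not None:
        for line in str(peaks_lit).splitlines():
            mz_s, _, int_s = line.partition(",")
            peaks.append(Peak(float(mz_s), float(int_s)))
    ext_node = r.take(node, DNMSO.externalRef)
    return Spectrum(
        id=str(local_id) if local_id is not None else None,
        precursor_mz=_read_num(r.take(node, DNMSO.precursorMz)),
        precursor_charge=int(charge) if charge is not None else None,
        peaks=peaks,
        external_ref=_read_external_ref(r, ext_node) if ext_node is not None else None,
        retention_time_s=_read_num(r.take(node, DNMSO.retentionTimeSeconds)),
        fragmentation=str(frag) if frag is not None else None,
        native_id=str(native) if native is not None else None,
    )


def _read_score(r, node) -> Score:
    r.take_type(node)
    cv = r.take(node, DNMSO.cvAccession)
    return Score(
        name=str(r.take(node, DNMSO.scoreName) or ""),
        value=_read_num(r.take(node, DNMSO.scoreValue)) or 0.0,
        cv_accession=str(cv) if cv is not None else None,
    )


def _read_element(r, node):
    types = set(r.g.objects(node, RDF.type))
    r.take_type(node)
    conf = _read_num(r.take(node, DNMSO.confidence))
    sp_head = r.take(node, DNMSO.supportingPeakList)
    supporting = None
    if sp_head is not None:
        supporting = []
        for pn in r.take_list(sp_head):
            r.take_type(pn)
            spec_id = str(r.take(pn, DNMSO.spectrumRef) or "")
            idx = r.take(pn, DNMSO.peakIndex)
            supporting.append((spec_id, int(idx) if idx is not None else 0))
    if DNMSO.Gap in types:
        return GapElement(
            mass=_read_num(r.take(node, DNMSO.gapMass)) or 0.0,
            confidence=conf, supporting_peaks=supporting,
        )
    residue = str(r.take(node, DNMSO.residue) or "")
    if DNMSO.ModifiedAminoAcid in types:
        return ModifiedAminoAcidElement(
            residue=residue,
            modification_ref=str(r.take(node, DNMSO.modificationRef) or ""),
            confidence=conf, supporting_peaks=supporting,
        )
    return AminoAcidElement(residue=residue, confidence=conf,
                            supporting_peaks=supporting)


def _read_prediction(r, node) -> Prediction:
    r.take_type(node)
    local_id = r.take(node, DNMSO.localId)
    rank = r.take(node, DNMSO.rank)
    sw = r.take(node, DNMSO.softwareRef)
    scores = [_read_score(r, n) for n in r.take_list(r.take(node, DNMSO.scoreList))]
    refs = []
    for item in r.take_list(r.take(node, DNMSO.sourceSpectrumList)):
        if isinstance(item, Literal):
            refs.append(str(item))
        else:
            refs.append(_read_external_ref(r, item))
    elements = []
    seq_node = r.take(node, DNMSO.sequence)
    if seq_node is not None:
        r.take_type(seq_node)
        for el_node in r.take_list(r.take(seq_node, DNMSO.elementList)):
            elements.append(_read_element(r, el_node))
    return Prediction(
        id=str(local_id) if local_id is not None else None,
        sequence=Sequence(elements),
        scores=scores,
        source_spectrum_refs=refs,
        software_ref=str(sw) if sw is not None else None,
        rank=int(rank) if rank is not None else None,
    )


def _read_modification(r, node) -> Modification:
    r.take_type(node)
    return Modification(
        local_id=str(r.take(node, DNMSO.localId) or ""),
        psimod_accession=str(r.take(node, DNMSO.psimodAccession) or ""),
        name=str(r.take(node, DNMSO.modificationName) or ""),
        mono_mass_delta=_read_num(r.take(node, DNMSO.monoMassDelta)) or 0.0,
        avg_mass_delta=_read_num(r.take(node, DNMSO.avgMassDelta)) or 0.0,
        residue_specificity=str(r.take(node, DNMSO.residueSpecificity) or "any"),
        terminus=str(r.take(node, DNMSO.terminus) or "none"),
    )


def _read_software(r, node) -> Software:
    r.take_type(node)
    params = []
    head = r.take(node, DNMSO.parameterList)
    if head is not None:
        for pn in r.take_list(head):
            types = set(r.g.objects(pn, RDF.type))
            r.take_type(pn)
            name = str(r.take(pn, DNMSO.paramName) or "")
            value = r.take(pn, DNMSO.paramValue)
            if DNMSO.CVParam in types:
                params.append(CVParam(
                    cv_ref=str(r.take(pn, DNMSO.cvRef) or ""),
                    accession=str(r.take(pn, DNMSO.cvAccession) or ""),
                    name=name,
                    value=str(value) if value is not None else None,
                ))
            else:
                params.append((name, str(value) if value is not None else ""))
    return Software(
        id=str(r.take(node, DNMSO.localId) or ""),
        name=str(r.take(node, DNMSO.softwareName) or ""),
        version=str(r.take(node, DNMSO.softwareVersion) or ""),
        parameters=params,
    )


def _read_cv_source(r, node) -> CVSource:
    r.take_type(node)
    return CVSource(
        id=str(r.take(node, DNMSO.localId) or ""),
        full_name=str(r.take(node, DNMSO.fullName) or ""),
        version=str(r.take(node, DNMSO.cvVersion) or ""),
        uri=str(r.take(node, DNMSO.uri) or ""),
    )


# ---------------------------------------------------------------------------
# Semantic equality (the round-trip oracle)


def _canon_ext(ref: Optional[ExternalSpectrumRef]):
    if ref is None:
        return None
    return (ref.file_path_or_uri, ref.format_hint, ref.native_id)


def _canon_element(el):
    conf = None if el.confidence is None else repr(float(el.confidence))
    peaks = tuple(tuple(p) for p in (el.supporting_peaks or ()))
    if isinstance(el, GapElement):
        return ("gap", repr(float(el.mass)), conf, peaks)
    if isinstance(el, ModifiedAminoAcidElement):
        return ("mod", el.residue, el.modification_ref, conf, peaks)
    return ("aa", el.residue, conf, peaks)


def _canon_doc(doc: Document):
    return (
        doc.id,
        json.dumps(doc.provenance, sort_keys=True),
        tuple(
            (
                s.id,
                None if s.precursor_mz is None else repr(float(s.precursor_mz)),
                s.precursor_charge,
                tuple((repr(p.mz), repr(p.intensity)) for p in s.peaks),
                _canon_ext(s.external_ref),
                None if s.retention_time_s is None else repr(float(s.retention_time_s)),
                s.fragmentation,
                s.native_id,
            )
            for s in doc.spectra
        ),
        tuple(
            (
                p.id,
                p.rank,
                p.software_ref,
                tuple((sc.name, repr(float(sc.value)), sc.cv_accession) for sc in p.scores),
                tuple(
                    ref if isinstance(ref, str) else _canon_ext(ref)
                    for ref in p.source_spectrum_refs
                ),
                tuple(_canon_element(el) for el in p.sequence.elements),
            )
            for p in doc.predictions
        ),
        tuple(sorted(
            (m.local_id, m.psimod_accession, m.name, repr(float(m.mono_mass_delta)),
             repr(float(m.avg_mass_delta)), m.residue_specificity, m.terminus)
            for m in doc.modifications
        )),
        tuple(sorted(
            (sw.id, sw.name, sw.version,
             tuple(
                 (p.cv_ref, p.accession, p.name, p.value)
                 if isinstance(p, CVParam) else ("kv",) + tuple(p)
                 for p in sw.parameters
             ))
            for sw in doc.software
        )),
        tuple(sorted((c.id, c.full_name, c.version, c.uri) for c in doc.cv_registry)),
    )


def semantic_equal(a: Document, b: Document) -> bool:
    """True iff the two documents carry the same content after canonical
    ordering; foreign-namespace triples are compared up to graph isomorphism."""
    if _canon_doc(a) != _canon_doc(b):
        return False
    ga, gb = Graph(), Graph()
    for t in a.extra_triples:
        ga.add(t)
    for t in b.extra_triples:
        gb.add(t)
    return to_isomorphic(ga) == to_isomorphic(gb)
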