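"""Converters from legacy de novo result formats into DNMSO documents, and
lossy export to mzIdentML (plus a minimal DNML writer).

Legacy flat-text layouts (PepNovo, Lutefisk) vary across tool versions; the
dialects accepted here are frozen and documented in ``docs/dialects.md``
with committed exemplar files. Files in an unknown layout fail loudly with
a dialect hint rather than being half-parsed.

Converters never emit orphan predictions: a candidate whose spectrum cannot
be matched in the companion spectra file is skipped with a warning. Spectrum
matching tries, in order: exact native-id (MGF TITLE) match, scan index,
then precursor m/z within 0.01 Th; the first match wins and ambiguity is
reported as a warning.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple, Union

from lxml import etree

from .errors import (
    DialectError,
    IdentityConflictError,
    InvalidDocumentError,
    SpectraParseError,
    StructuralError,
    UnresolvedReferenceError,
)
from .model import (
    Document,
    Peak,
    Prediction,
    Score,
    Software,
    Spectrum,
    create_document,
    has_errors,
    validate,
)
from .sequence import (
    AminoAcidElement,
    GapElement,
    Modification,
    ModificationTable,
    ModifiedAminoAcidElement,
    Sequence,
    UNKNOWN_MODIFICATION_ACCESSION,
    parse_sequence,
    render_sequence,
    residue_mono_mass,
)
from .spectra import SpectrumSource

PRECURSOR_MATCH_TOLERANCE_TH = 0.01
MOD_DELTA_TOLERANCE_DA = 0.01


@dataclass
class ConversionReport:
    """Bookkeeping for one conversion run.

    Invariant: ``predictions_converted + records_skipped`` equals the number
    of candidate records seen in the input.
    """

    spectra_read: int = 0
    predictions_converted: int = 0
    records_skipped: int = 0
    warnings: List[str] = field(default_factory=list)
    lossiness: List[str] = field(default_factory=list)

    @property
    def records_seen(self) -> int:
        return self.predictions_converted + self.records_skipped

    def warn(self, message: str) -> None:
        self.warnings.append(message)


def _open_text(source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _load_spectra(doc: Document, spectra_source, report: ConversionReport) -> None:
    if spectra_source is None:
        return
    if not isinstance(spectra_source, SpectrumSource):
        spectra_source = SpectrumSource(spectra_source)
    for s in spectra_source.read():
        doc.add_spectrum(s)
        report.spectra_read += 1


def _match_spectrum(
    doc: Document,
    report: ConversionReport,
    title: Optional[str] = None,
    index: Optional[int] = None,
    mz: Optional[float] = None,
) -> Optional[Spectrum]:
    if title:
        hits = [s for s in doc.spectra if s.native_id == title]
        if len(hits) > 1:
            report.warn(f"ambiguous spectrum title {title!r}; using the first match")
        if hits:
            return hits[0]
    if index is not None and 0 <= index < len(doc.spectra):
        return doc.spectra[index]
    if mz is not None:
        hits = [
            s for s in doc.spectra
            if s.precursor_mz is not None
            and abs(s.precursor_mz - mz) <= PRECURSOR_MATCH_TOLERANCE_TH
        ]
        if len(hits) > 1:
            report.warn(
                f"ambiguous precursor match at {mz} Th; using the first of {len(hits)}"
            )
        if hits:
            return hits[0]
    return None


def _ensure_modifications(doc: Document, seq: Sequence, mod_table) -> None:
    """Copy the modifications a sequence uses into the document."""
    present = {m.local_id for m in doc.modifications}
    for el in seq.elements:
        if isinstance(el, ModifiedAminoAcidElement) and el.modification_ref not in present:
            mod = mod_table.by_accession(el.modification_ref)
            doc.add_modification(mod)
            present.add(mod.local_id)


# ---------------------------------------------------------------------------
# PepNovo-style flat text

_PEPNOVO_HEADER_RE = re.compile(r"^>>\s+(\d+)\s+(.*)$")


def convert_pepnovo(
    results, spectra_source, mod_table: ModificationTable, doc_id: Optional[str] = None
) -> Tuple[Document, ConversionReport]:
    """Convert PepNovo-style ranked candidates plus a companion spectra file.

    Frozen dialect: a ``>> <scan index> <title>`` header opens each queried
    spectrum; candidate rows follow with whitespace-separated columns
    ``rank, rnk_score, pnv_score, n_gap, c_gap, charge, sequence``. Positive
    N-/C-gap masses become leading/trailing gap elements.
    """
    report = ConversionReport()
    doc = create_document({"creator": "dnmso-convert", "source_format": "pepnovo"},
                          id=doc_id)
    _load_spectra(doc, spectra_source, report)
    sw_id = doc.add_software(Software(id="pepnovo", name="PepNovo", version="unknown"))

    fh, owned = _open_text(results)
    try:
        current: Optional[Spectrum] = None
        current_header = None
        saw_header = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            m = _PEPNOVO_HEADER_RE.match(line)
            if m:
                saw_header = True
                index, title = int(m.group(1)), m.group(2).strip()
                current_header = title or str(index)
                current = _match_spectrum(doc, report, title=title, index=index)
                if current is None:
                    report.warn(
                        f"line {lineno}: spectrum {current_header!r} not found in "
                        "companion file; its candidates will be skipped"
                    )
                continue
            if not saw_header:
                raise DialectError(
                    "no '>>' spectrum header found before candidate rows; "
                    "expected the frozen PepNovo dialect (see docs/dialects.md)"
                )
            fields = line.split()
            if len(fields) != 7:
                report.records_skipped += 1
                report.warn(f"line {lineno}: expected 7 columns, got {len(fields)}")
                continue
            if current is None:
                report.records_skipped += 1
                continue
            try:
                rank = int(fields[0])
                rnk_score, pnv_score = float(fields[1]), float(fields[2])
                n_gap, c_gap = float(fields[3]), float(fields[4])
                int(fields[5])  # charge column; spectrum carries the value
                seq = parse_sequence(fields[6], mod_table)
            except Exception as e:
                report.records_skipped += 1
                report.warn(f"line {lineno}: malformed candidate row ({e})")
                continue
            elements = list(seq.elements)
            if n_gap > 0:
                elements.insert(0, GapElement(n_gap))
            if c_gap > 0:
                elements.append(GapElement(c_gap))
            seq = Sequence(elements)
            _ensure_modifications(doc, seq, mod_table)
            doc.add_prediction(Prediction(
                sequence=seq,
                scores=[Score("RnkScr", rnk_score), Score("PnvScr", pnv_score)],
                source_spectrum_refs=[current.id],
                software_ref=sw_id,
                rank=rank,
            ))
            report.predictions_converted += 1
        if not saw_header and report.records_seen == 0 and report.spectra_read >= 0:
            pass  # empty results file: empty document is fine
    finally:
        if owned:
            fh.close()
    return doc, report


# ---------------------------------------------------------------------------
# Lutefisk-style flat text

_LUTEFISK_HEADER_RE = re.compile(r"^>>>\s+(.*)$")
_BRACKET_GAP_RE = re.compile(r"\[(\d+(?:\.\d+)?)\]")


def convert_lutefisk(
    results, spectra_source, mod_table: ModificationTable, doc_id: Optional[str] = None
) -> Tuple[Document, ConversionReport]:
    """Convert Lutefisk-style candidate tables.

    Frozen dialect: ``>>> <title>`` headers; rows with tab/space-separated
    columns ``rank, probability, quality, sequence``. Both score columns are
    kept as distinct named scores. Bracketed masses in the sequence
    (``[100.0]``) are mass gaps.
    """
    report = ConversionReport()
    doc = create_document({"creator": "dnmso-convert", "source_format": "lutefisk"},
                          id=doc_id)
    _load_spectra(doc, spectra_source, report)
    sw_id = doc.add_software(Software(id="lutefisk", name="Lutefisk", version="unknown"))

    fh, owned = _open_text(results)
    try:
        current: Optional[Spectrum] = None
        saw_header = False
        index = -1
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            m = _LUTEFISK_HEADER_RE.match(line)
            if m:
                saw_header = True
                index += 1
                title = m.group(1).strip()
                current = _match_spectrum(doc, report, title=title, index=index)
                if current is None:
                    report.warn(
                        f"line {lineno}: spectrum {title!r} not found in companion "
                        "file; its candidates will be skipped"
                    )
                continue
            if not saw_header:
                raise DialectError(
                    "no '>>>' spectrum header found before candidate rows; "
                    "expected the frozen Lutefisk dialect (see docs/dialects.md)"
                )
            fields = line.split()
            if len(fields) != 4:
                report.records_skipped += 1
                report.warn(f"line {lineno}: expected 4 columns, got {len(fields)}")
                continue
            if current is None:
                report.records_skipped += 1
                continue
            try:
                rank = int(fields[0])
                probability, quality = float(fields[1]), float(fields[2])
                text = _BRACKET_GAP_RE.sub(lambda g: f"({float(g.group(1)):.5f})",
                                           fields[3])
                seq = parse_sequence(text, mod_table)
            except Exception as e:
                report.records_skipped += 1
                report.warn(f"line {lineno}: malformed candidate row ({e})")
                continue
            _ensure_modifications(doc, seq, mod_table)
            doc.add_prediction(Prediction(
                sequence=seq,
                scores=[Score("probability", probability), Score("quality", quality)],
                source_spectrum_refs=[current.id],
                software_ref=sw_id,
                rank=rank,
            ))
            report.predictions_converted += 1
    finally:
        if owned:
            fh.close()
    return doc, report


# ---------------------------------------------------------------------------
# DNML (XML)


def convert_dnml(
    xml_source, mod_table: ModificationTable, doc_id: Optional[str] = None,
    spectra_source=None,
) -> Tuple[Document, ConversionReport]:
    """Convert a DNML file (tree of spectra plus single-score predictions).

    DNML is self-contained (spectra inline) but allows only one score per
    prediction and no merged-spectra semantics; both limitations are noted
    in the report.
    """
    report = ConversionReport()
    report.lossiness.append(
        "DNML carries a single score per prediction and no merged-spectra semantics"
    )
    doc = create_document({"creator": "dnmso-convert", "source_format": "dnml"},
                          id=doc_id)
    sw_id = doc.add_software(Software(id="dnml", name="DNML source", version="1.0"))
    try:
        tree = etree.parse(
            xml_source if hasattr(xml_source, "read") else str(xml_source)
        )
    except etree.XMLSyntaxError as e:
        raise SpectraParseError(f"DNML parse error: {e}") from None
    root = tree.getroot()
    if root.tag != "dnml":
        raise DialectError(f"expected <dnml> root element, got <{root.tag}>")

    for spec_el in root.iter("spectrum"):
        pairs = [
            (float(p.get("mz")), float(p.get("intensity")))
            for p in spec_el.iter("peak")
        ]
        pairs.sort(key=lambda t: t[0])
        charge = spec_el.get("charge")
        doc.add_spectrum(Spectrum(
            id=spec_el.get("id"),
            precursor_mz=float(spec_el.get("pepmass")) if spec_el.get("pepmass") else None,
            precursor_charge=int(charge) if charge else None,
            peaks=[Peak(mz, inten) for mz, inten in pairs],
            native_id=spec_el.get("title") or spec_el.get("id"),
        ))
        report.spectra_read += 1

    for pred_el in root.iter("prediction"):
        refs = [src.get("ref") for src in pred_el.iter("source")]
        seq_el = pred_el.find("sequence")
        try:
            seq = parse_sequence(seq_el.text.strip(), mod_table)
            score = float(pred_el.get("score"))
            rank = int(pred_el.get("rank")) if pred_el.get("rank") else None
            missing = [r for r in refs if not doc.has_spectrum(r)]
            if missing or not refs:
                report.records_skipped += 1
                report.warn(
                    f"prediction {pred_el.get('id')!r}: unresolved spectrum "
                    f"references {missing or '(none given)'}"
                )
                continue
            _ensure_modifications(doc, seq, mod_table)
            doc.add_prediction(Prediction(
                id=pred_el.get("id"),
                sequence=seq,
                scores=[Score("dnml_score", score)],
                source_spectrum_refs=refs,
                software_ref=sw_id,
                rank=rank,
            ))
            report.predictions_converted += 1
        except (TypeError, ValueError, AttributeError) as e:
            report.records_skipped += 1
            report.warn(f"prediction {pred_el.get('id')!r}: malformed ({e})")
    return doc, report


def export_dnml(doc: Document) -> bytes:
    """Minimal, lossy DNML writer: first score only, inline spectra only.

    Exists to close the DNMSO -> DNML -> DNMSO projection loop; everything
    DNML cannot express (extra scores, external references, per-element
    confidence and evidence, software metadata) is dropped.
    """
    mods = doc.modification_map()
    root = etree.Element("dnml", version="1.0")
    spectra_el = etree.SubElement(root, "spectra")
    for s in doc.spectra:
        attrs = {"id": str(s.id)}
        if s.native_id:
            attrs["title"] = s.native_id
        if s.precursor_mz is not None:
            attrs["pepmass"] = repr(s.precursor_mz)
        if s.precursor_charge is not None:
            attrs["charge"] = str(s.precursor_charge)
        spec_el = etree.SubElement(spectra_el, "spectrum", **attrs)
        for pk in s.peaks:
            etree.SubElement(spec_el, "peak", mz=repr(pk.mz),
                             intensity=repr(pk.intensity))
    preds_el = etree.SubElement(root, "predictions")
    for p in doc.predictions:
        attrs = {"id": str(p.id), "score": repr(p.scores[0].value) if p.scores else "0"}
        if p.rank is not None:
            attrs["rank"] = str(p.rank)
        pred_el = etree.SubElement(preds_el, "prediction", **attrs)
        for ref in p.source_spectrum_refs:
            if isinstance(ref, str):
                etree.SubElement(pred_el, "source", ref=ref)
        seq_el = etree.SubElement(pred_el, "sequence")
        seq_el.text = render_sequence(p.sequence, "annotated", mods)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


# ---------------------------------------------------------------------------
# pepXML


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def convert_pepxml(
    xml_source, spectra_source, mod_table: ModificationTable,
    doc_id: Optional[str] = None,
) -> Tuple[Document, ConversionReport]:
    """Convert pepXML search results into a document.

    Each ``search_hit`` under a ``spectrum_query`` becomes one prediction;
    all ``search_score`` entries are kept as named scores. Positional
    modification masses (``mod_aminoacid_mass``, total residue mass) are
    matched against the modification table by monoisotopic delta within
    0.01 Da; an unmatched delta becomes an explicitly uncharacterized
    placeholder modification (accession MOD:00000) with a warning, never a
    silent drop. Database/protein fields are ignored with a lossiness note —
    de novo results carry no database.
    """
    report = ConversionReport()
    doc = create_document({"creator": "dnmso-convert", "source_format": "pepxml"},
                          id=doc_id)
    _load_spectra(doc, spectra_source, report)
    sw_id = doc.add_software(Software(id="pepxml", name="pepXML source",
                                      version="unknown"))
    try:
        tree = etree.parse(
            xml_source if hasattr(xml_source, "read") else str(xml_source)
        )
    except etree.XMLSyntaxError as e:
        raise SpectraParseError(f"pepXML parse error: {e}") from None
    root = tree.getroot()

    # a search_hit must live under a spectrum_query
    for hit in root.iter():
        if _strip_ns(hit.tag) != "search_hit":
            continue
        anc = hit.getparent()
        ok = False
        while anc is not None:
            if _strip_ns(anc.tag) == "spectrum_query":
                ok = True
                break
            anc = anc.getparent()
        if not ok:
            raise StructuralError(
                "pepXML search_hit outside of a spectrum_query element"
            )

    protein_seen = False
    for query in root.iter():
        if _strip_ns(query.tag) != "spectrum_query":
            continue
        title = query.get("spectrum")
        start_scan = query.get("start_scan")
        charge = query.get("assumed_charge")
        neutral = query.get("precursor_neutral_mass")
        mz = None
        if neutral is not None and charge:
            from .sequence import neutral_mass_to_mz
            mz = neutral_mass_to_mz(float(neutral), int(charge))
        spectrum = _match_spectrum(
            doc, report, title=title,
            index=(int(start_scan) - 1) if start_scan else None, mz=mz,
        )
        for hit in query.iter():
            if _strip_ns(hit.tag) != "search_hit":
                continue
            if hit.get("protein"):
                protein_seen = True
            if spectrum is None:
                report.records_skipped += 1
                report.warn(
                    f"spectrum_query {title!r}: no matching spectrum in companion "
                    "file; hit skipped"
                )
                continue
            try:
                seq = _pepxml_hit_sequence(hit, mod_table, doc, report)
            except Exception as e:
                report.records_skipped += 1
                report.warn(f"spectrum_query {title!r}: malformed hit ({e})")
                continue
            scores = [
                Score(el.get("name"), float(el.get("value")))
                for el in hit.iter()
                if _strip_ns(el.tag) == "search_score" and el.get("name")
            ]
            if not scores:
                report.records_skipped += 1
                report.warn(f"spectrum_query {title!r}: hit carries no search_score")
                continue
            rank = hit.get("hit_rank")
            doc.add_prediction(Prediction(
                sequence=seq,
                scores=scores,
                source_spectrum_refs=[spectrum.id],
                software_ref=sw_id,
                rank=int(rank) if rank else None,
            ))
            report.predictions_converted += 1
    if protein_seen:
        report.lossiness.append("protein fields dropped (no database in de novo results)")
    return doc, report


def _pepxml_hit_sequence(hit, mod_table, doc: Document, report) -> Sequence:
    peptide = hit.get("peptide")
    if not peptide:
        raise ValueError("search_hit without peptide attribute")
    elements: List = [AminoAcidElement(r) for r in peptide]
    for r in peptide:
        residue_mono_mass(r)  # alphabet check
    for mod_info in hit.iter():
        if _strip_ns(mod_info.tag) != "mod_aminoacid_mass":
            continue
        position = int(mod_info.get("position"))  # 1-based
        total_mass = float(mod_info.get("mass"))
        residue = peptide[position - 1]
        delta = total_mass - residue_mono_mass(residue)
        match = mod_table.match_by_mono_delta(delta, residue,
                                              tolerance=MOD_DELTA_TOLERANCE_DA)
        if match is None:
            local_id = f"{UNKNOWN_MODIFICATION_ACCESSION}@{delta:+.4f}"
            if local_id not in {m.local_id for m in doc.modifications}:
                doc.add_modification(Modification(
                    local_id=local_id,
                    psimod_accession=UNKNOWN_MODIFICATION_ACCESSION,
                    name=f"uncharacterized modification ({delta:+.4f} Da)",
                    mono_mass_delta=delta,
                    avg_mass_delta=delta,
                    residue_specificity=residue,
                ))
            report.warn(
                f"modification delta {delta:+.4f} Da on {residue} has no table "
                "match within 0.01 Da; recorded as uncharacterized (MOD:00000), "
                "user mapping required"
            )
            elements[position - 1] = ModifiedAminoAcidElement(residue, local_id)
        else:
            if match.local_id not in {m.local_id for m in doc.modifications}:
                doc.add_modification(match)
            elements[position - 1] = ModifiedAminoAcidElement(residue, match.local_id)
    return Sequence(elements)


# ---------------------------------------------------------------------------
# PEAKS-style CSV (documented fixture dialect; proprietary formats are out)

_PEAKS_MOD_RE = re.compile(r"\(([+-]\d+(?:\.\d+)?)\)")


def convert_peaks_csv(
    csv_source, spectra_source, mod_table: ModificationTable,
    doc_id: Optional[str] = None,
) -> Tuple[Document, ConversionReport]:
    """Convert a PEAKS-style CSV export.

    Frozen dialect: header ``scan,peptide,alc,mz,z``; peptides may carry
    inline deltas like ``M(+15.99)`` which are matched to the modification
    table by monoisotopic delta. The ALC (average local confidence, percent)
    column becomes the single score.
    """
    report = ConversionReport()
    doc = create_document({"creator": "dnmso-convert", "source_format": "peaks-csv"},
                          id=doc_id)
    _load_spectra(doc, spectra_source, report)
    sw_id = doc.add_software(Software(id="peaks", name="PEAKS (CSV export)",
                                      version="unknown"))
    fh, owned = _open_text(csv_source)
    try:
        header = fh.readline().strip().lower().split(",")
        expected = ["scan", "peptide", "alc", "mz", "z"]
        if header != expected:
            raise DialectError(
                f"unexpected PEAKS CSV header {header!r}; expected {expected!r} "
                "(see docs/dialects.md)"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 5:
                report.records_skipped += 1
                report.warn(f"line {lineno}: expected 5 columns, got {len(fields)}")
                continue
            scan, peptide, alc, mz, z = fields
            spectrum = _match_spectrum(
                doc, report, title=scan or None,
                mz=float(mz) if mz else None,
            )
            if spectrum is None:
                report.records_skipped += 1
                report.warn(f"line {lineno}: scan {scan!r} not found; row skipped")
                continue
            try:
                seq = _peaks_sequence(peptide, mod_table, doc, report)
                score = float(alc)
            except Exception as e:
                report.records_skipped += 1
                report.warn(f"line {lineno}: malformed row ({e})")
                continue
            doc.add_prediction(Prediction(
                sequence=seq,
                scores=[Score("ALC", score)],
                source_spectrum_refs=[spectrum.id],
                software_ref=sw_id,
            ))
            report.predictions_converted += 1
    finally:
        if owned:
            fh.close()
    return doc, report


def _peaks_sequence(text: str, mod_table, doc: Document, report) -> Sequence:
    elements: List = []
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            m = _PEAKS_MOD_RE.match(text, pos)
            if m is None or not elements or not isinstance(elements[-1], AminoAcidElement):
                raise ValueError(f"malformed modification tag at position {pos}")
            delta = float(m.group(1))
            residue = elements[-1].residue
            match = mod_table.match_by_mono_delta(delta, residue,
                                                  tolerance=MOD_DELTA_TOLERANCE_DA)
            if match is None:
                raise ValueError(f"no modification matching {delta:+.4f} Da on {residue}")
            if match.local_id not in {mm.local_id for mm in doc.modifications}:
                doc.add_modification(match)
            elements[-1] = ModifiedAminoAcidElement(residue, match.local_id)
            pos = m.end()
        else:
            residue_mono_mass(ch)
            elements.append(AminoAcidElement(ch))
            pos += 1
    return Sequence(elements)


# ---------------------------------------------------------------------------
# mzIdentML export (lossy, write-only)

_MZID_NS = "http://psidev.info/psi/pi/mzIdentML/1.1"


def export_mzidentml(doc: Document) -> bytes:
    """Export a document as mzIdentML-structured XML (lossy, write-only).

    One SpectrumIdentificationResult per spectrum with predictions; one
    SpectrumIdentificationItem per prediction (attached to its first source
    spectrum), scores as cvParams when they carry a CV accession and as
    userParams otherwise. No protein or database sections are emitted.
    Gap-containing sequences cannot live in a mzIdentML PeptideSequence, so
    the faithful rendering (with parenthesized gap masses) travels in a
    userParam; per-element confidence and evidence are likewise flattened
    to userParams. Re-import is deliberately unsupported.
    """
    violations = validate(doc)
    if has_errors(violations):
        raise InvalidDocumentError([v for v in violations if v.severity == "ERROR"])
    mods = doc.modification_map()
    nsmap = {None: _MZID_NS}
    root = etree.Element(f"{{{_MZID_NS}}}MzIdentML", nsmap=nsmap, version="1.1.0",
                         id=f"mzid-{doc.id}")

    from .model import CVSource

    cv_list = etree.SubElement(root, f"{{{_MZID_NS}}}cvList")
    # always cite the two ontologies the format leans on
    default_cvs = [
        CVSource("PSI-MS",
                 "Proteomics Standards Initiative Mass Spectrometry Vocabularies",
                 uri="https://www.ebi.ac.uk/ols/ontologies/ms"),
        CVSource("PSI-MOD",
                 "Proteomics Standards Initiative Protein Modifications",
                 uri="https://www.ebi.ac.uk/ols/ontologies/mod"),
    ]
    for cv in doc.cv_registry or default_cvs:
        etree.SubElement(cv_list, f"{{{_MZID_NS}}}cv", id=cv.id,
                         fullName=cv.full_name, uri=cv.uri)

    sw_list = etree.SubElement(root, f"{{{_MZID_NS}}}AnalysisSoftwareList")
    for sw in doc.software or [Software(id="unknown", name="unknown", version="")]:
        etree.SubElement(sw_list, f"{{{_MZID_NS}}}AnalysisSoftware",
                         id=f"SW_{sw.id}", name=sw.name, version=sw.version)

    seq_coll = etree.SubElement(root, f"{{{_MZID_NS}}}SequenceCollection")
    for p in doc.predictions:
        pep = etree.SubElement(seq_coll, f"{{{_MZID_NS}}}Peptide", id=f"PEP_{p.id}")
        letters = "".join(
            el.residue for el in p.sequence.elements
            if not isinstance(el, GapElement)
        )
        pep_seq = etree.SubElement(pep, f"{{{_MZID_NS}}}PeptideSequence")
        pep_seq.text = letters
        letter_pos = 0
        for el in p.sequence.elements:
            if isinstance(el, GapElement):
                continue
            letter_pos += 1
            if isinstance(el, ModifiedAminoAcidElement):
                mod = mods.get(el.modification_ref)
                mod_el = etree.SubElement(
                    pep, f"{{{_MZID_NS}}}Modification",
                    location=str(letter_pos),
                    residues=el.residue,
                )
                if mod is not None:
                    mod_el.set("monoisotopicMassDelta", repr(mod.mono_mass_delta))
                    etree.SubElement(
                        mod_el, f"{{{_MZID_NS}}}cvParam", cvRef="PSI-MOD",
                        accession=mod.psimod_accession, name=mod.name,
                    )

    data_coll = etree.SubElement(root, f"{{{_MZID_NS}}}DataCollection")
    analysis_data = etree.SubElement(data_coll, f"{{{_MZID_NS}}}AnalysisData")
    sil = etree.SubElement(analysis_data,
                           f"{{{_MZID_NS}}}SpectrumIdentificationList", id="SIL_1")

    emitted = set()
    result_idx = 0
    for s in doc.spectra:
        preds = [
            p for p in doc.predictions
            if p.id not in emitted
            and p.source_spectrum_refs
            and isinstance(p.source_spectrum_refs[0], str)
            and p.source_spectrum_refs[0] == s.id
        ]
        if not preds:
            continue
        result_idx += 1
        result = etree.SubElement(
            sil, f"{{{_MZID_NS}}}SpectrumIdentificationResult",
            id=f"SIR_{result_idx}", spectrumID=str(s.native_id or s.id),
        )
        for p in preds:
            emitted.add(p.id)
            item_attrs = {
                "id": f"SII_{p.id}",
                "peptide_ref": f"PEP_{p.id}",
                "passThreshold": "true",
            }
            if p.rank is not None:
                item_attrs["rank"] = str(p.rank)
            if s.precursor_mz is not None:
                item_attrs["experimentalMassToCharge"] = repr(s.precursor_mz)
            if s.precursor_charge is not None:
                item_attrs["chargeState"] = str(s.precursor_charge)
            item = etree.SubElement(
                result, f"{{{_MZID_NS}}}SpectrumIdentificationItem", **item_attrs)
            for sc in p.scores:
                if sc.cv_accession:
                    etree.SubElement(item, f"{{{_MZID_NS}}}cvParam", cvRef="PSI-MS",
                                     accession=sc.cv_accession, name=sc.name,
                                     value=repr(sc.value))
                else:
                    etree.SubElement(item, f"{{{_MZID_NS}}}userParam",
                                     name=sc.name, value=repr(sc.value))
            if any(isinstance(el, GapElement) for el in p.sequence.elements):
                etree.SubElement(item, f"{{{_MZID_NS}}}userParam",
                                 name="dnmso:rendered_sequence",
                                 value=render_sequence(p.sequence, "plain"))
            if len(p.source_spectrum_refs) > 1:
                others = ";".join(
                    r if isinstance(r, str) else r.native_id
                    for r in p.source_spectrum_refs[1:]
                )
                etree.SubElement(item, f"{{{_MZID_NS}}}userParam",
                                 name="dnmso:additional_source_spectra", value=others)
            for i, el in enumerate(p.sequence.elements):
                if el.confidence is not None:
                    etree.SubElement(item, f"{{{_MZID_NS}}}userParam",
                                     name=f"dnmso:element_confidence[{i}]",
                                     value=repr(el.confidence))
                if el.supporting_peaks:
                    ev = ";".join(f"{sid}:{idx}" for sid, idx in el.supporting_peaks)
                    etree.SubElement(item, f"{{{_MZID_NS}}}userParam",
                                     name=f"dnmso:element_evidence[{i}]", value=ev)

    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


# ---------------------------------------------------------------------------
# Registry (runtime-extensible; new formats plug in without touching the API)


@dataclass
class ConverterEntry:
    name: str
    reader: Callable[..., Tuple[Document, ConversionReport]]
    description: str = ""
    needs_spectra: bool = True


class ConverterRegistry:
    def __init__(self):
        self._entries: Dict[str, ConverterEntry] = {}

    def register(self, entry: ConverterEntry) -> "ConverterRegistry":
        if entry.name in self._entries:
            raise IdentityConflictError(
                f"converter {entry.name!r} is already registered"
            )
        self._entries[entry.name] = entry
        return self

    def get(self, name: str) -> ConverterEntry:
        try:
            return self._entries[name]
        except KeyError:
            raise UnresolvedReferenceError(
                f"no converter named {name!r}; known: {sorted(self._entries)}"
            ) from None

    def names(self) -> List[str]:
        return sorted(self._entries)


def _dnml_entry(results, spectra_source=None, mod_table=None, doc_id=None):
    return convert_dnml(results, mod_table, doc_id=doc_id)


def default_registry() -> ConverterRegistry:
    """Registry preloaded with the shipped converters."""
    reg = ConverterRegistry()
    reg.register(ConverterEntry("pepnovo", convert_pepnovo,
                                "PepNovo-style ranked candidate text"))
    reg.register(ConverterEntry("lutefisk", convert_lutefisk,
                                "Lutefisk-style candidate tables"))
    reg.register(ConverterEntry("dnml", _dnml_entry,
                                "DNML XML (self-contained)", needs_spectra=False))
    reg.register(ConverterEntry("pepxml", convert_pepxml, "pepXML search results"))
    reg.register(ConverterEntry("peaks-csv", convert_peaks_csv,
                                "PEAKS-style CSV export"))
    return reg


def register_converter(registry: ConverterRegistry, entry: ConverterEntry):
    """Register a runtime converter; duplicate names are an identity conflict."""
    return registry.register(entry)
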