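"""In-memory model of a DNMSO document and its structural invariants.

A document is a self-describing container for de novo sequencing results:
spectra (inline peak lists or references into external spectra files),
predictions (peptide-spectrum matches with one sequence, at least one score
and at least one source spectrum), the modifications those sequences use,
the software that produced them, and controlled-vocabulary bookkeeping.

Predictions and spectra form a many-to-many network: a prediction may be
derived from several spectra (e.g. CID and ETD scans of the same precursor,
or merged scans), and one spectrum may support many candidate predictions.
Spectra without predictions are allowed; predictions without spectra are not.

Construction through the guarded ``add_*`` operations keeps a document valid
at all times; documents arriving from deserialization or converters are
checked after the fact with :func:`validate`, which reports rule violations
instead of raising.
"""

from __future__ import annotations

import math
import re
import uuid
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Optional, Tuple, Union

from .errors import (
    IdentityConflictError,
    MissingScoreError,
    OrphanPredictionError,
    StructuralError,
    UnresolvedReferenceError,
)
from .sequence import (
    AminoAcidElement,
    CANONICAL_RESIDUES,
    GapElement,
    Modification,
    ModifiedAminoAcidElement,
    Sequence,
)

_ACCESSION_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_-]*:\d+$")
_PSIMOD_RE = re.compile(r"^MOD:\d{5}$")


@dataclass(frozen=True)
class Peak:
    """One centroided peak: m/z in Thomson, intensity in arbitrary units."""

    mz: float
    intensity: float


@dataclass
class ExternalSpectrumRef:
    """Pointer to a spectrum living in an external peak-list file."""

    file_path_or_uri: str
    format_hint: str = "other"  # mzML | mzXML | MGF | other
    native_id: str = ""


@dataclass
class Spectrum:
    """One MS/MS scan, carried inline (peak list) or by external reference.

    At least one of a non-empty peak list or an external reference must be
    present. Inline peaks are kept sorted by ascending m/z.
    """

    id: Optional[str] = None
    precursor_mz: Optional[float] = None  # Thomson; None = unknown
    precursor_charge: Optional[int] = None  # positive int; None = unknown
    peaks: List[Peak] = field(default_factory=list)
    external_ref: Optional[ExternalSpectrumRef] = None
    retention_time_s: Optional[float] = None
    fragmentation: Optional[str] = None  # CID | ETD | HCD | other
    native_id: Optional[str] = None  # scan identifier in the source file


@dataclass
class Score:
    name: str
    value: float
    cv_accession: Optional[str] = None


@dataclass
class CVParam:
    cv_ref: str
    accession: str
    name: str
    value: Optional[str] = None


@dataclass
class CVSource:
    id: str
    full_name: str
    version: str = ""
    uri: str = ""


@dataclass
class Software:
    id: Optional[str] = None
    name: str = ""
    version: str = ""
    parameters: List[Union[CVParam, Tuple[str, str]]] = field(default_factory=list)


@dataclass
class Prediction:
    """One candidate peptide-spectrum match."""

    id: Optional[str] = None
    sequence: Sequence = field(default_factory=Sequence)
    scores: List[Score] = field(default_factory=list)
    source_spectrum_refs: List[Union[str, ExternalSpectrumRef]] = field(default_factory=list)
    software_ref: Optional[str] = None
    rank: Optional[int] = None  # 1 = best for its source-spectrum set


@dataclass(frozen=True)
class Violation:
    """One validation finding; ERROR severity marks paper-mandated rules."""

    rule_id: str
    severity: str  # ERROR | WARNING
    message: str
    element_id: str


class Document:
    """Root container for one DNMSO instance."""

    def __init__(self, provenance: Optional[dict] = None, id: Optional[str] = None):
        self.id: str = id or f"doc-{uuid.uuid4().hex[:12]}"
        self.spectra: List[Spectrum] = []
        self.predictions: List[Prediction] = []
        self.modifications: List[Modification] = []
        self.software: List[Software] = []
        self.cv_registry: List[CVSource] = []
        self.provenance: dict = dict(provenance or {})
        self.provenance.setdefault(
            "timestamp", datetime.now(timezone.utc).isoformat(timespec="seconds")
        )
        #: Foreign-namespace RDF triples preserved opaquely across round trips.
        self.extra_triples: list = []
        self._counters = {"SPEC": 0, "PRED": 0, "SW": 0}

    # -- lookups ----------------------------------------------------------

    def spectrum_by_id(self, spectrum_id: str) -> Spectrum:
        for s in self.spectra:
            if s.id == spectrum_id:
                return s
        raise UnresolvedReferenceError(f"no spectrum with id {spectrum_id!r}")

    def has_spectrum(self, spectrum_id: str) -> bool:
        return any(s.id == spectrum_id for s in self.spectra)

    def prediction_by_id(self, prediction_id: str) -> Prediction:
        for p in self.predictions:
            if p.id == prediction_id:
                return p
        raise UnresolvedReferenceError(f"no prediction with id {prediction_id!r}")

    def modification_map(self) -> Dict[str, Modification]:
        return {m.local_id: m for m in self.modifications}

    def _next_id(self, prefix: str) -> str:
        while True:
            self._counters[prefix] += 1
            candidate = f"{prefix}_{self._counters[prefix]}"
            existing = {
                "SPEC": (s.id for s in self.spectra),
                "PRED": (p.id for p in self.predictions),
                "SW": (s.id for s in self.software),
            }[prefix]
            if candidate not in set(existing):
                return candidate

    # -- guarded construction --------------------------------------------

    def add_spectrum(self, s: Spectrum) -> str:
        _check_spectrum(s)
        if s.id is None:
            s.id = self._next_id("SPEC")
        elif self.has_spectrum(s.id):
            raise IdentityConflictError(f"spectrum id {s.id!r} already in document")
        self.spectra.append(s)
        return s.id

    def add_prediction(self, p: Prediction) -> str:
        if not p.source_spectrum_refs:
            raise OrphanPredictionError(
                "prediction has no source spectra; predictions without "
                "associated spectra are not allowed"
            )
        if not p.scores:
            raise MissingScoreError("prediction must carry at least one score")
        for ref in p.source_spectrum_refs:
            if isinstance(ref, str) and not self.has_spectrum(ref):
                raise UnresolvedReferenceError(
                    f"prediction references unknown spectrum {ref!r}"
                )
            if isinstance(ref, ExternalSpectrumRef) and not ref.native_id:
                raise StructuralError("external spectrum reference needs a native id")
        mods = self.modification_map()
        for i, el in enumerate(p.sequence.elements):
            if isinstance(el, ModifiedAminoAcidElement) and el.modification_ref not in mods:
                raise UnresolvedReferenceError(
                    f"sequence element {i} references unknown modification "
                    f"{el.modification_ref!r}"
                )
        if p.id is None:
            p.id = self._next_id("PRED")
        elif any(q.id == p.id for q in self.predictions):
            raise IdentityConflictError(f"prediction id {p.id!r} already in document")
        self.predictions.append(p)
        return p.id

    def add_modification(self, m: Modification) -> str:
        if any(x.local_id == m.local_id for x in self.modifications):
            raise IdentityConflictError(f"modification id {m.local_id!r} already in document")
        self.modifications.append(m)
        return m.local_id

    def add_software(self, sw: Software) -> str:
        if sw.id is None:
            sw.id = self._next_id("SW")
        elif any(x.id == sw.id for x in self.software):
            raise IdentityConflictError(f"software id {sw.id!r} already in document")
        self.software.append(sw)
        return sw.id

    def add_cv_source(self, cv: CVSource) -> str:
        if any(x.id == cv.id for x in self.cv_registry):
            raise IdentityConflictError(f"CV source id {cv.id!r} already registered")
        self.cv_registry.append(cv)
        return cv.id

    # -- queries ----------------------------------------------------------

    def predictions_for_spectrum(self, spectrum_id: str) -> List[Prediction]:
        """All predictions sourced from the given spectrum, in insertion order."""
        if not self.has_spectrum(spectrum_id):
            raise UnresolvedReferenceError(f"no spectrum with id {spectrum_id!r}")
        return [
            p
            for p in self.predictions
            if any(isinstance(r, str) and r == spectrum_id for r in p.source_spectrum_refs)
        ]

    def is_self_contained(self) -> Tuple[bool, List[ExternalSpectrumRef]]:
        """Whether every prediction-referenced spectrum carries inline peaks.

        Orphan spectra (no referencing prediction) never break
        self-containment; returns the external references that do.
        """
        blocking: List[ExternalSpectrumRef] = []
        for p in self.predictions:
            for ref in p.source_spectrum_refs:
                if isinstance(ref, ExternalSpectrumRef):
                    blocking.append(ref)
                elif isinstance(ref, str):
                    try:
                        s = self.spectrum_by_id(ref)
                    except UnresolvedReferenceError:
                        continue  # dangling ref is validate()'s business
                    if not s.peaks and s.external_ref is not None:
                        blocking.append(s.external_ref)
        return (not blocking, blocking)


def create_document(provenance: Optional[dict] = None, id: Optional[str] = None) -> Document:
    """Create an empty, valid document with the given creation metadata."""
    return Document(provenance=provenance, id=id)


def _finite(x) -> bool:
    return isinstance(x, (int, float)) and math.isfinite(x)


def _check_spectrum(s: Spectrum) -> None:
    """Raise StructuralError when a spectrum breaks its invariants."""
    if not s.peaks and s.external_ref is None:
        raise StructuralError("spectrum needs inline peaks or an external reference")
    if s.external_ref is not None and not s.external_ref.native_id:
        raise StructuralError("external spectrum reference needs a non-empty native id")
    if s.precursor_mz is not None and not (_finite(s.precursor_mz) and s.precursor_mz > 0):
        raise StructuralError("precursor m/z must be finite and > 0")
    if s.precursor_charge is not None and s.precursor_charge < 1:
        raise StructuralError("precursor charge must be a positive integer or unknown")
    last = 0.0
    for i, pk in enumerate(s.peaks):
        if not (_finite(pk.mz) and pk.mz > 0):
            raise StructuralError(f"peak {i}: m/z must be finite and > 0")
        if not (_finite(pk.intensity) and pk.intensity >= 0):
            raise StructuralError(f"peak {i}: intensity must be finite and >= 0")
        if pk.mz < last:
            raise StructuralError(f"peak {i}: peaks must be sorted by ascending m/z")
        last = pk.mz


# ---------------------------------------------------------------------------
# Rule-based validation (in place of OWL reasoning)

def validate(doc: Document) -> List[Violation]:
    """Check every structural invariant; return violations, never raise.

    Deterministic: violations are ordered by offending element id, then rule.
    ERROR-severity rules are the hard constraints of the model (orphan
    predictions, missing scores, dangling references, modifications without
    a PSI-MOD accession, malformed spectra, duplicate ids); WARNINGs are
    advisory (empty provenance, unregistered CV prefixes).
    """
    out: List[Violation] = []

    def err(rule, msg, elem):
        out.append(Violation(rule, "ERROR", msg, elem))

    def warn(rule, msg, elem):
        out.append(Violation(rule, "WARNING", msg, elem))

    for coll, label in (
        ([s.id for s in doc.spectra], "spectrum"),
        ([p.id for p in doc.predictions], "prediction"),
        ([m.local_id for m in doc.modifications], "modification"),
        ([s.id for s in doc.software], "software"),
        ([c.id for c in doc.cv_registry], "cv-source"),
    ):
        seen = set()
        for local_id in coll:
            if local_id in seen:
                err("duplicate-id", f"duplicate {label} id {local_id!r}", str(local_id))
            seen.add(local_id)

    mods = doc.modification_map()
    spectrum_ids = {s.id for s in doc.spectra}

    for s in doc.spectra:
        try:
            _check_spectrum(s)
        except StructuralError as e:
            rule = "unsorted-peaks" if "sorted" in str(e) else "invalid-spectrum"
            err(rule, str(e), str(s.id))

    for m in doc.modifications:
        if not m.has_valid_accession():
            err(
                "missing-psimod",
                f"modification {m.local_id!r} lacks a well-formed PSI-MOD "
                f"accession (got {m.psimod_accession!r})",
                m.local_id,
            )
        if not _finite(m.mono_mass_delta):
            err("invalid-modification", f"modification {m.local_id!r} has non-finite "
                "monoisotopic delta", m.local_id)

    software_ids = {s.id for s in doc.software}
    for p in doc.predictions:
        pid = str(p.id)
        if not p.source_spectrum_refs:
            err("orphan-prediction",
                f"prediction {pid!r} has no source spectra", pid)
        if not p.scores:
            err("missing-score", f"prediction {pid!r} carries no score", pid)
        for sc in p.scores:
            if not sc.name:
                err("invalid-score", f"prediction {pid!r} has a score without a name", pid)
        for ref in p.source_spectrum_refs:
            if isinstance(ref, str) and ref not in spectrum_ids:
                err("unresolved-spectrum-ref",
                    f"prediction {pid!r} references unknown spectrum {ref!r}", pid)
            if isinstance(ref, ExternalSpectrumRef) and not ref.native_id:
                err("invalid-external-ref",
                    f"prediction {pid!r} has an external reference without a "
                    "native id", pid)
        if p.software_ref is not None and p.software_ref not in software_ids:
            err("unresolved-software-ref",
                f"prediction {pid!r} references unknown software {p.software_ref!r}", pid)
        if p.rank is not None and p.rank < 1:
            err("invalid-rank", f"prediction {pid!r} has non-positive rank", pid)
        out.extend(_validate_sequence(doc, p, mods))

    for sw in doc.software:
        for param in sw.parameters:
            if isinstance(param, CVParam) and not _ACCESSION_RE.match(param.accession):
                err("invalid-cv-accession",
                    f"software {sw.id!r} parameter accession "
                    f"{param.accession!r} malformed", str(sw.id))

    cv_ids = {c.id for c in doc.cv_registry}
    for sw in doc.software:
        for param in sw.parameters:
            if isinstance(param, CVParam) and param.cv_ref not in cv_ids:
                warn("unknown-cv-prefix",
                     f"software {sw.id!r} parameter cites unregistered CV "
                     f"source {param.cv_ref!r}", str(sw.id))

    if not doc.provenance.get("creator"):
        warn("empty-provenance", "document has no creator in provenance", doc.id)

    out.sort(key=lambda v: (v.element_id, v.rule_id))
    return out


def _validate_sequence(doc: Document, p: Prediction, mods) -> List[Violation]:
    out: List[Violation] = []
    pid = str(p.id)

    def err(rule, msg):
        out.append(Violation(rule, "ERROR", msg, pid))

    elems = p.sequence.elements
    if not elems:
        err("empty-sequence", f"prediction {pid!r} has an empty sequence")
        return out
    for i, el in enumerate(elems):
        if isinstance(el, (AminoAcidElement, ModifiedAminoAcidElement)):
            if el.residue not in CANONICAL_RESIDUES:
                err("invalid-residue",
                    f"prediction {pid!r} element {i}: residue {el.residue!r} "
                    "not in the canonical alphabet")
        if isinstance(el, ModifiedAminoAcidElement):
            mod = mods.get(el.modification_ref)
            if mod is None:
                err("unresolved-modification-ref",
                    f"prediction {pid!r} element {i}: unknown modification "
                    f"{el.modification_ref!r}")
            else:
                if mod.terminus == "N-term" and i != 0:
                    err("misplaced-terminal-modification",
                        f"prediction {pid!r} element {i}: N-terminal "
                        f"modification {mod.local_id!r} not at the N-terminus")
                if mod.terminus == "C-term" and i != len(elems) - 1:
                    err("misplaced-terminal-modification",
                        f"prediction {pid!r} element {i}: C-terminal "
                        f"modification {mod.local_id!r} not at the C-terminus")
        if isinstance(el, GapElement) and not (_finite(el.mass) and el.mass > 0):
            err("invalid-gap",
                f"prediction {pid!r} element {i}: gap mass must be finite and > 0")
        conf = getattr(el, "confidence", None)
        if conf is not None and not (0.0 <= conf <= 1.0):
            err("invalid-confidence",
                f"prediction {pid!r} element {i}: confidence {conf} outside [0, 1]")
        for spec_id, peak_idx in (getattr(el, "supporting_peaks", None) or []):
            try:
                s = doc.spectrum_by_id(spec_id)
            except UnresolvedReferenceError:
                err("unresolved-supporting-peak",
                    f"prediction {pid!r} element {i}: supporting peak cites "
                    f"unknown spectrum {spec_id!r}")
                continue
            if s.peaks and not (0 <= peak_idx < len(s.peaks)):
                err("unresolved-supporting-peak",
                    f"prediction {pid!r} element {i}: peak index {peak_idx} "
                    f"out of range for spectrum {spec_id!r}")
    return out


def has_errors(violations: List[Violation]) -> bool:
    return any(v.severity == "ERROR" for v in violations)


# Module-level conveniences mirroring the Document methods.

def predictions_for_spectrum(doc: Document, spectrum_id: str) -> List[Prediction]:
    return doc.predictions_for_spectrum(spectrum_id)


def is_self_contained(doc: Document) -> Tuple[bool, List[ExternalSpectrumRef]]:
    return doc.is_self_contained()
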