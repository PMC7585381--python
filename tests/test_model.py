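"""Document construction guards, validation rules and network navigation."""

import random

import pytest

from dnmso import (
    AminoAcidElement,
    ExternalSpectrumRef,
    Modification,
    ModifiedAminoAcidElement,
    Peak,
    Prediction,
    Score,
    Sequence,
    Spectrum,
    create_document,
    has_errors,
    validate,
)
from dnmso.errors import (
    IdentityConflictError,
    MissingScoreError,
    OrphanPredictionError,
    StructuralError,
    UnresolvedReferenceError,
)
from dnmso.simulate import random_document

from conftest import make_spectrum


def _prediction(sid, seq="PEP", score=0.5, **kw):
    return Prediction(
        sequence=Sequence([AminoAcidElement(r) for r in seq]),
        scores=[Score("s", score)],
        source_spectrum_refs=[sid],
        **kw,
    )


class TestCreateDocument:
    def test_empty_document_is_valid(self):
        doc = create_document({"creator": "test"})
        assert len(doc.spectra) == 0 and len(doc.predictions) == 0
        assert validate(doc) == []

    def test_distinct_ids(self):
        assert create_document().id != create_document().id


class TestAddSpectrum:
    def test_roundtrip_by_id(self):
        doc = create_document({"creator": "test"})
        sid = doc.add_spectrum(make_spectrum())
        assert len(doc.spectrum_by_id(sid).peaks) == 3

    def test_unsorted_peaks_rejected(self):
        doc = create_document()
        s = Spectrum(precursor_mz=500.0, peaks=[Peak(300.0, 1.0), Peak(100.0, 2.0)])
        with pytest.raises(StructuralError, match="sorted"):
            doc.add_spectrum(s)

    def test_external_ref_only_accepted(self):
        doc = create_document({"creator": "test"})
        sid = doc.add_spectrum(Spectrum(
            external_ref=ExternalSpectrumRef("run.mzML", "mzML", "scan=9")))
        assert doc.spectrum_by_id(sid).peaks == []

    def test_neither_peaks_nor_ref_rejected(self):
        with pytest.raises(StructuralError):
            create_document().add_spectrum(Spectrum(precursor_mz=500.0))

    def test_duplicate_id_conflict(self):
        doc = create_document()
        doc.add_spectrum(make_spectrum(sid="S1"))
        with pytest.raises(IdentityConflictError):
            doc.add_spectrum(make_spectrum(sid="S1"))

    def test_orphan_spectrum_keeps_document_valid(self):
        doc = create_document({"creator": "test"})
        doc.add_spectrum(make_spectrum())
        assert validate(doc) == []


class TestAddPrediction:
    def test_minimal_prediction_accepted(self):
        doc = create_document({"creator": "test"})
        sid = doc.add_spectrum(make_spectrum())
        pid = doc.add_prediction(_prediction(sid))
        assert doc.prediction_by_id(pid).rank is None
        assert validate(doc) == []

    def test_orphan_prediction_rejected(self):
        doc = create_document()
        p = _prediction("x")
        p.source_spectrum_refs = []
        with pytest.raises(OrphanPredictionError):
            doc.add_prediction(p)

    def test_missing_scores_rejected(self):
        doc = create_document()
        sid = doc.add_spectrum(make_spectrum())
        p = _prediction(sid)
        p.scores = []
        with pytest.raises(MissingScoreError):
            doc.add_prediction(p)

    def test_dangling_spectrum_ref_rejected(self):
        doc = create_document()
        doc.add_spectrum(make_spectrum())
        with pytest.raises(UnresolvedReferenceError):
            doc.add_prediction(_prediction("no-such-spectrum"))

    def test_merged_cid_etd_sources_navigable_both_ways(self):
        doc = create_document({"creator": "test"})
        cid = doc.add_spectrum(make_spectrum(fragmentation="CID"))
        etd = doc.add_spectrum(make_spectrum(fragmentation="ETD"))
        pid = doc.add_prediction(Prediction(
            sequence=Sequence([AminoAcidElement("K")]),
            scores=[Score("s", 1.0)],
            source_spectrum_refs=[cid, etd],
        ))
        for sid in (cid, etd):
            assert [p.id for p in doc.predictions_for_spectrum(sid)] == [pid]


class TestValidateDefectCatalogue:
    """Injected single defects are each flagged with the right rule id;
    their clean twins are not flagged."""

    def _clean(self):
        doc = create_document({"creator": "test"})
        sid = doc.add_spectrum(make_spectrum(sid="S1"))
        doc.add_modification(Modification(
            "phospho-S", "MOD:00046", "O-phospho-L-serine", 79.966331, 79.9799, "S"))
        doc.add_prediction(Prediction(
            id="P1",
            sequence=Sequence([AminoAcidElement("P"),
                               ModifiedAminoAcidElement("S", "phospho-S")]),
            scores=[Score("s", 0.8)],
            source_spectrum_refs=[sid],
        ))
        return doc

    def test_clean_twin_has_no_violations(self):
        assert validate(self._clean()) == []

    @pytest.mark.parametrize(
        "defect, rule_id, element_id",
        [
            (lambda d: d.predictions[0].source_spectrum_refs.clear(),
             "orphan-prediction", "P1"),
            (lambda d: d.predictions[0].scores.clear(), "missing-score", "P1"),
            (lambda d: d.predictions[0].source_spectrum_refs.__setitem__(0, "s99"),
             "unresolved-spectrum-ref", "P1"),
            (lambda d: setattr(d.modifications[0], "psimod_accession", "UNIMOD:21"),
             "missing-psimod", "phospho-S"),
            (lambda d: d.spectra[0].peaks.reverse(), "unsorted-peaks", "S1"),
            (lambda d: d.spectra.append(make_spectrum(sid="S1")), "duplicate-id", "S1"),
            (lambda d: setattr(d.predictions[0].sequence.elements[1],
                               "modification_ref", "ghost"),
             "unresolved-modification-ref", "P1"),
        ],
    )
    def test_single_defect_flagged_with_rule_and_element(self, defect, rule_id,
                                                         element_id):
        doc = self._clean()
        defect(doc)
        violations = validate(doc)
        assert any(v.rule_id == rule_id and v.element_id == element_id
                   and v.severity == "ERROR" for v in violations), violations

    def test_violations_ordered_and_deterministic(self):
        doc = self._clean()
        doc.predictions[0].scores.clear()
        doc.predictions[0].source_spectrum_refs.clear()
        v1, v2 = validate(doc), validate(doc)
        assert v1 == v2
        assert [v.rule_id for v in v1] == sorted(v.rule_id for v in v1)


class TestPredictionsForSpectrum:
    def test_unknown_spectrum_raises(self, small_doc):
        with pytest.raises(UnresolvedReferenceError):
            small_doc.predictions_for_spectrum("nope")

    def test_two_referencing_predictions(self, small_doc):
        sid = small_doc.spectra[0].id
        assert len(small_doc.predictions_for_spectrum(sid)) == 2

    def test_orphan_spectrum_empty(self, small_doc):
        sid = small_doc.add_spectrum(make_spectrum())
        assert small_doc.predictions_for_spectrum(sid) == []

    def test_matches_brute_force_scan_on_random_document(self, rng):
        doc = random_document(rng, max_spectra=15, max_predictions=50)
        for s in doc.spectra:
            brute = [p for p in doc.predictions
                     if s.id in [r for r in p.source_spectrum_refs
                                 if isinstance(r, str)]]
            assert doc.predictions_for_spectrum(s.id) == brute

    def test_navigation_is_an_involution(self, rng):
        # s in p.sources  <=>  p in predictions_for_spectrum(s)
        doc = random_document(rng, max_spectra=10, max_predictions=40)
        for s in doc.spectra:
            backrefs = doc.predictions_for_spectrum(s.id)
            for p in doc.predictions:
                assert (s.id in [r for r in p.source_spectrum_refs
                                 if isinstance(r, str)]) == (p in backrefs)


class TestSelfContainment:
    def test_all_inline_is_self_contained(self, small_doc):
        ok, refs = small_doc.is_self_contained()
        assert ok and refs == []

    def test_prediction_on_external_spectrum_breaks_it(self):
        doc = create_document({"creator": "test"})
        ext = ExternalSpectrumRef("raw.mzML", "mzML", "scan=1")
        sid = doc.add_spectrum(Spectrum(external_ref=ext))
        doc.add_prediction(_prediction(sid))
        ok, refs = doc.is_self_contained()
        assert not ok and refs == [ext]

    def test_orphan_external_spectrum_does_not_break_it(self, small_doc):
        small_doc.add_spectrum(Spectrum(
            external_ref=ExternalSpectrumRef("raw.mzML", "mzML", "scan=1")))
        ok, _ = small_doc.is_self_contained()
        assert ok

    def test_matches_brute_force_over_prediction_sources(self, rng):
        for _ in range(10):
            doc = random_document(rng, max_spectra=12, max_predictions=30)
            expected = all(
                doc.spectrum_by_id(r).peaks
                for p in doc.predictions
                for r in p.source_spectrum_refs if isinstance(r, str)
            )
            assert doc.is_self_contained()[0] == expected


def test_guarded_construction_always_validates_clean():
    rng = random.Random(99)
    for _ in range(5):
        doc = random_document(rng, max_spectra=10, max_predictions=30)
        assert not has_errors(validate(doc))
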