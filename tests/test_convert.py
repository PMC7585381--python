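"""Converters on the frozen dialect exemplars, registry, and lossy exports."""

import io

import pytest
from lxml import etree

from dnmso import (
    ConverterEntry,
    GapElement,
    ModifiedAminoAcidElement,
    SpectrumSource,
    convert_dnml,
    convert_lutefisk,
    convert_peaks_csv,
    convert_pepnovo,
    convert_pepxml,
    create_document,
    default_registry,
    export_dnml,
    export_mzidentml,
    has_errors,
    render_sequence,
    semantic_equal,
    validate,
)
from dnmso.errors import DialectError, IdentityConflictError, StructuralError

MZID = "{http://psidev.info/psi/pi/mzIdentML/1.1}"


@pytest.fixture()
def mgf_source(data_dir):
    return SpectrumSource(data_dir / "spectra_example.mgf")


class TestPepnovo:
    def test_exemplar_counts_ranks_and_scores(self, data_dir, mgf_source, mod_table):
        doc, report = convert_pepnovo(data_dir / "pepnovo_example.txt",
                                      mgf_source, mod_table)
        assert report.spectra_read == 3
        assert report.predictions_converted == 3 == len(doc.predictions)
        assert report.records_skipped == 0
        assert [p.rank for p in doc.predictions] == [1, 2, 1]
        assert {s.name for s in doc.predictions[0].scores} == {"RnkScr", "PnvScr"}
        assert not has_errors(validate(doc))

    def test_n_and_c_gaps_become_gap_elements(self, data_dir, mgf_source, mod_table):
        doc, _ = convert_pepnovo(data_dir / "pepnovo_example.txt",
                                 mgf_source, mod_table)
        ngap = doc.predictions[1].sequence.elements
        assert isinstance(ngap[0], GapElement) and ngap[0].mass == 100.0
        assert render_sequence(doc.predictions[1].sequence) == "(100.00000)AG"
        cgap = doc.predictions[2].sequence.elements
        assert isinstance(cgap[-1], GapElement)
        assert cgap[-1].mass == pytest.approx(128.09496)

    def test_modified_residue_resolved_and_copied(self, data_dir, mgf_source,
                                                  mod_table):
        doc, _ = convert_pepnovo(data_dir / "pepnovo_example.txt",
                                 mgf_source, mod_table)
        el = doc.predictions[2].sequence.elements[0]
        assert isinstance(el, ModifiedAminoAcidElement)
        assert el.modification_ref in {m.local_id for m in doc.modifications}

    def test_report_row_count_matches_line_oracle(self, data_dir, mgf_source,
                                                  mod_table):
        lines = (data_dir / "pepnovo_example.txt").read_text().splitlines()
        candidate_rows = [
            ln for ln in lines
            if ln.strip() and not ln.startswith("#") and not ln.startswith(">>")
        ]
        _, report = convert_pepnovo(data_dir / "pepnovo_example.txt",
                                    mgf_source, mod_table)
        assert report.records_seen == len(candidate_rows)

    def test_unknown_layout_fails_loudly(self, mgf_source, mod_table):
        with pytest.raises(DialectError, match="dialect"):
            convert_pepnovo(io.StringIO("1\t2\t3\n"), mgf_source, mod_table)

    def test_unmatched_spectrum_skipped_with_warning(self, mgf_source, mod_table):
        results = ">> 7 no.such.title\n1\t0.5\t10.0\t0.0\t0.0\t2\tPEP\n"
        doc, report = convert_pepnovo(io.StringIO(results), mgf_source, mod_table)
        assert report.predictions_converted == 0
        assert report.records_skipped == 1
        assert any("no.such.title" in w for w in report.warnings)
        assert not has_errors(validate(doc))  # never an orphan prediction


class TestLutefisk:
    def test_two_score_columns_become_two_scores(self, data_dir, mgf_source,
                                                 mod_table):
        doc, report = convert_lutefisk(data_dir / "lutefisk_example.txt",
                                       mgf_source, mod_table)
        assert report.predictions_converted == 3
        for p in doc.predictions:
            assert [s.name for s in p.scores] == ["probability", "quality"]
        assert not has_errors(validate(doc))

    def test_bracketed_mass_becomes_gap(self, data_dir, mgf_source, mod_table):
        doc, _ = convert_lutefisk(data_dir / "lutefisk_example.txt",
                                  mgf_source, mod_table)
        els = doc.predictions[0].sequence.elements
        assert isinstance(els[0], GapElement) and els[0].mass == 100.0
        assert [getattr(e, "residue", None) for e in els[1:]] == ["A", "G", "K"]

    def test_empty_results_file(self, mgf_source, mod_table):
        doc, report = convert_lutefisk(io.StringIO(""), mgf_source, mod_table)
        assert report.records_seen == 0 and len(doc.predictions) == 0


class TestDnml:
    def test_exemplar_counts_and_single_score(self, data_dir, mod_table):
        doc, report = convert_dnml(data_dir / "dnml_example.xml", mod_table)
        assert report.spectra_read == 2
        assert report.predictions_converted == 2
        assert [s.name for s in doc.predictions[0].scores] == ["dnml_score"]
        assert not has_errors(validate(doc))

    def test_two_sources_for_one_result_both_kept(self, data_dir, mod_table):
        doc, _ = convert_dnml(data_dir / "dnml_example.xml", mod_table)
        assert doc.predictions[1].source_spectrum_refs == ["s0", "s1"]

    def test_lossiness_note_present(self, data_dir, mod_table):
        _, report = convert_dnml(data_dir / "dnml_example.xml", mod_table)
        assert any("merged-spectra" in n for n in report.lossiness)

    def test_projection_roundtrip_on_dnml_expressible_subset(self, data_dir,
                                                             mod_table):
        doc, _ = convert_dnml(data_dir / "dnml_example.xml", mod_table)
        again, report = convert_dnml(io.BytesIO(export_dnml(doc)), mod_table)
        assert report.records_skipped == 0
        # the source was already inside the DNML-expressible subset, so the
        # projection loses nothing further (document identity and creation
        # metadata are per-conversion and excluded from the comparison)
        again.id, again.provenance = doc.id, doc.provenance
        assert semantic_equal(doc, again)


class TestPepxml:
    def test_exemplar_counts_and_all_scores_kept(self, data_dir, mgf_source,
                                                 mod_table):
        doc, report = convert_pepxml(data_dir / "pepxml_example.xml",
                                     mgf_source, mod_table)
        assert report.predictions_converted == 2
        assert {s.name for s in doc.predictions[0].scores} == {
            "denovo_score", "delta_score"}
        assert not has_errors(validate(doc))

    def test_mass_offset_matched_to_bundled_modification(self, data_dir,
                                                         mgf_source, mod_table):
        # position 2 of AMSTERDAM carries 147.0354 Da = M + 15.9949
        doc, _ = convert_pepxml(data_dir / "pepxml_example.xml",
                                mgf_source, mod_table)
        el = doc.predictions[1].sequence.elements[1]
        assert isinstance(el, ModifiedAminoAcidElement)
        mod = doc.modification_map()[el.modification_ref]
        assert mod.psimod_accession == "MOD:00719"

    def test_protein_fields_dropped_with_note(self, data_dir, mgf_source,
                                              mod_table):
        _, report = convert_pepxml(data_dir / "pepxml_example.xml",
                                   mgf_source, mod_table)
        assert any("protein" in n for n in report.lossiness)

    def test_unmatched_delta_becomes_uncharacterized_placeholder(
            self, mgf_source, mod_table):
        xml = """<msms_pipeline_analysis><msms_run_summary>
          <spectrum_query spectrum="example.0" start_scan="1"
                          precursor_neutral_mass="998.0" assumed_charge="2">
            <search_result><search_hit hit_rank="1" peptide="PEK">
              <modification_info>
                <mod_aminoacid_mass position="1" mass="300.0"/>
              </modification_info>
              <search_score name="s" value="0.5"/>
            </search_hit></search_result>
          </spectrum_query>
        </msms_run_summary></msms_pipeline_analysis>"""
        doc, report = convert_pepxml(io.BytesIO(xml.encode()), mgf_source,
                                     mod_table)
        el = doc.predictions[0].sequence.elements[0]
        mod = doc.modification_map()[el.modification_ref]
        assert mod.psimod_accession == "MOD:00000"
        assert any("uncharacterized" in w for w in report.warnings)
        assert not has_errors(validate(doc))

    def test_hit_outside_spectrum_query_is_structural_error(self, mgf_source,
                                                            mod_table):
        xml = ("<msms_pipeline_analysis><search_hit hit_rank='1' peptide='PEK'/>"
               "</msms_pipeline_analysis>")
        with pytest.raises(StructuralError):
            convert_pepxml(io.BytesIO(xml.encode()), mgf_source, mod_table)


class TestPeaksCsv:
    def test_exemplar_conversion(self, data_dir, mgf_source, mod_table):
        doc, report = convert_peaks_csv(data_dir / "peaks_example.csv",
                                        mgf_source, mod_table)
        assert report.predictions_converted == 2
        assert doc.predictions[0].scores[0].name == "ALC"
        el = doc.predictions[1].sequence.elements[0]
        assert isinstance(el, ModifiedAminoAcidElement)
        assert doc.modification_map()[el.modification_ref].psimod_accession == \
            "MOD:00046"
        assert not has_errors(validate(doc))

    def test_wrong_header_fails_loudly(self, mgf_source, mod_table):
        with pytest.raises(DialectError):
            convert_peaks_csv(io.StringIO("a,b,c\n"), mgf_source, mod_table)


class TestRegistry:
    def test_all_shipped_converters_listed(self):
        assert default_registry().names() == [
            "dnml", "lutefisk", "peaks-csv", "pepnovo", "pepxml"]

    def test_runtime_registration_and_duplicate_rejection(self):
        reg = default_registry()
        entry = ConverterEntry("tsv", lambda *a, **k: (create_document(), None))
        reg.register(entry)
        assert reg.get("tsv") is entry
        with pytest.raises(IdentityConflictError):
            reg.register(ConverterEntry("tsv", lambda: None))


class TestConservation:
    """No converter invents spectra or drops converted predictions."""

    @pytest.mark.parametrize("name", ["pepnovo", "lutefisk", "dnml", "pepxml",
                                      "peaks-csv"])
    def test_report_counts_match_document(self, name, data_dir, mod_table):
        reg = default_registry()
        entry = reg.get(name)
        results = {
            "pepnovo": "pepnovo_example.txt",
            "lutefisk": "lutefisk_example.txt",
            "dnml": "dnml_example.xml",
            "pepxml": "pepxml_example.xml",
            "peaks-csv": "peaks_example.csv",
        }[name]
        source = SpectrumSource(data_dir / "spectra_example.mgf")
        doc, report = entry.reader(data_dir / results, spectra_source=source,
                                   mod_table=mod_table)
        assert report.predictions_converted == len(doc.predictions)
        assert report.predictions_converted + report.records_skipped == \
            report.records_seen
        assert len(doc.spectra) == report.spectra_read
        assert not has_errors(validate(doc))


class TestMzIdentMLExport:
    def test_one_item_per_prediction_all_scores_as_params(self, data_dir,
                                                          mgf_source, mod_table):
        doc, _ = convert_pepnovo(data_dir / "pepnovo_example.txt", mgf_source,
                                 mod_table)
        root = etree.fromstring(export_mzidentml(doc))
        items = root.findall(f".//{MZID}SpectrumIdentificationItem")
        assert len(items) == len(doc.predictions)
        by_pep = {i.get("peptide_ref"): i for i in items}
        for p in doc.predictions:
            item = by_pep[f"PEP_{p.id}"]
            params = [el for el in item
                      if el.tag in (f"{MZID}cvParam", f"{MZID}userParam")]
            names = [el.get("name") for el in params]
            for sc in p.scores:
                assert sc.name in names

    def test_gaps_only_in_userparams(self, data_dir, mgf_source, mod_table):
        doc, _ = convert_pepnovo(data_dir / "pepnovo_example.txt", mgf_source,
                                 mod_table)
        root = etree.fromstring(export_mzidentml(doc))
        # PeptideSequence elements hold residue letters only
        for el in root.findall(f".//{MZID}PeptideSequence"):
            assert el.text.isalpha()
        rendered = [el.get("value") for el in root.iter(f"{MZID}userParam")
                    if el.get("name") == "dnmso:rendered_sequence"]
        assert any("(100.00000)" in v for v in rendered)

    def test_no_protein_or_database_sections(self, data_dir, mgf_source,
                                             mod_table):
        doc, _ = convert_pepxml(data_dir / "pepxml_example.xml", mgf_source,
                                mod_table)
        root = etree.fromstring(export_mzidentml(doc))
        for forbidden in ("DBSequence", "ProteinDetectionList", "SearchDatabase"):
            assert root.find(f".//{MZID}{forbidden}") is None
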