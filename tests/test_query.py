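"""Score filtering, SPARQL queries and cross-tool consensus."""

import random

import pytest

from dnmso import (
    AminoAcidElement,
    ConsensusParams,
    GapElement,
    Prediction,
    Score,
    ScoreConstraint,
    Sequence,
    consensus,
    create_document,
    filter_predictions,
    has_errors,
    parse_constraint,
    run_query,
    semantic_equal,
    serialize,
    deserialize,
    validate,
)
from dnmso.errors import QueryError, StructuralError
from dnmso.query import _COMPARATORS
from dnmso.simulate import random_document

from conftest import make_spectrum

COMPARATORS = sorted(_COMPARATORS)


def _doc_with_scores(values, name="score"):
    doc = create_document({"creator": "test"})
    sid = doc.add_spectrum(make_spectrum())
    for v in values:
        doc.add_prediction(Prediction(
            sequence=Sequence([AminoAcidElement("K")]),
            scores=[Score(name, v)],
            source_spectrum_refs=[sid],
        ))
    return doc


class TestParseConstraint:
    @pytest.mark.parametrize("expr, comparator, threshold", [
        ("X>0.5", "greater", 0.5),
        ("X<0.5", "lesser", 0.5),
        ("X=0.5", "equal", 0.5),
        ("X>=0.5", "greater_or_equal", 0.5),
        ("PnvScr <= -2e1", "lesser_or_equal", -20.0),
    ])
    def test_grammar(self, expr, comparator, threshold):
        c = parse_constraint(expr)
        assert (c.comparator, c.threshold) == (comparator, threshold)

    @pytest.mark.parametrize("bad", ["", "X", ">=0.5", "X>>0.5", "X>=abc"])
    def test_rejects_malformed(self, bad):
        with pytest.raises(QueryError):
            parse_constraint(bad)


class TestFilterPredictions:
    def test_greater_or_equal_keeps_two_of_three(self):
        doc = _doc_with_scores([0.9, 0.5, 0.2])
        out = filter_predictions(doc, [ScoreConstraint("score",
                                                       "greater_or_equal", 0.5)])
        assert len(out.predictions) == 2
        assert not has_errors(validate(out))

    def test_unknown_score_name_filters_everything(self):
        doc = _doc_with_scores([0.9, 0.5])
        out = filter_predictions(doc, [ScoreConstraint("nope", "greater", 0.0)])
        assert out.predictions == []

    def test_spectra_never_deleted(self):
        doc = _doc_with_scores([0.9, 0.5])
        out = filter_predictions(doc, [ScoreConstraint("score", "greater", 2.0)])
        assert len(out.spectra) == len(doc.spectra)
        assert not has_errors(validate(out))

    def test_idempotent_under_semantic_equality(self, rng):
        doc = random_document(rng, max_spectra=8, max_predictions=30)
        constraints = [ScoreConstraint("score_a", "greater", 0.4)]
        once = filter_predictions(doc, constraints)
        twice = filter_predictions(once, constraints)
        assert semantic_equal(once, twice)

    def test_matches_brute_force_oracle(self):
        rng = random.Random(777)
        names = ["score_a", "score_b", "score_c"]
        for _ in range(20):
            doc = random_document(rng, max_spectra=6, max_predictions=30,
                                  score_names=names)
            constraints = [
                ScoreConstraint(rng.choice(names), rng.choice(COMPARATORS),
                                rng.random())
                for _ in range(rng.randint(1, 3))
            ]
            combine = rng.choice(["all", "any"])
            mode = all if combine == "all" else any

            def passes(p, c):
                carried = {s.name: s.value for s in p.scores}
                if c.score_name not in carried:
                    return False
                return _COMPARATORS[c.comparator](carried[c.score_name],
                                                  c.threshold)

            expected = [p.id for p in doc.predictions
                        if mode(passes(p, c) for c in constraints)]
            got = [p.id for p in
                   filter_predictions(doc, constraints, combine).predictions]
            assert got == expected

    def test_requires_constraints(self, small_doc):
        with pytest.raises(StructuralError):
            filter_predictions(small_doc, [])


class TestRunQuery:
    PREFIX = "PREFIX dnmso: <https://w3id.org/dnmso/1.0#>\n"

    def test_select_all_predictions(self, small_doc):
        _, rows = run_query(small_doc,
                            self.PREFIX + "SELECT ?p WHERE { ?p a dnmso:Prediction }")
        assert len(rows) == 2

    def test_shared_spectrum_pairs_match_brute_force(self, rng):
        doc = random_document(rng, max_spectra=6, max_predictions=25)
        q = self.PREFIX + """
        SELECT DISTINCT ?a ?b WHERE {
          ?a a dnmso:Prediction ; dnmso:sourceSpectrumList/rdf:rest*/rdf:first ?s .
          ?b a dnmso:Prediction ; dnmso:sourceSpectrumList/rdf:rest*/rdf:first ?s .
          FILTER (?a != ?b)
        }"""
        q = ("PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>\n" + q)
        _, rows = run_query(doc, q)
        brute = set()
        for a in doc.predictions:
            for b in doc.predictions:
                if a.id != b.id and set(
                        r for r in a.source_spectrum_refs if isinstance(r, str)
                ) & set(r for r in b.source_spectrum_refs if isinstance(r, str)):
                    brute.add((a.id, b.id))
        assert len(rows) == len(brute)

    def test_foreign_namespace_query_empty_not_error(self, small_doc):
        _, rows = run_query(
            small_doc,
            "SELECT ?x WHERE { ?x a <http://example.org/other#Thing> }")
        assert rows == []

    def test_syntax_error_reported(self, small_doc):
        with pytest.raises(QueryError):
            run_query(small_doc, "SELECT WHERE {{{")


def _tool_doc(sequences, creator="tool"):
    """One document with one spectrum and one rank-1 prediction per sequence."""
    doc = create_document({"creator": creator})
    for i, seq_text in enumerate(sequences):
        sid = doc.add_spectrum(make_spectrum(native_id=f"scan.{i}"))
        doc.add_prediction(Prediction(
            sequence=Sequence([AminoAcidElement(r) for r in seq_text]),
            scores=[Score("s", 0.9)],
            source_spectrum_refs=[sid],
            rank=1,
        ))
    return doc


class TestConsensus:
    def test_strict_majority(self):
        docs = [_tool_doc(["PEPTIDE"]), _tool_doc(["PEPTIDE"]),
                _tool_doc(["PEPTLDE"])]
        out, _ = consensus(docs, ConsensusParams(min_agreement=2))
        assert len(out.predictions) == 1
        p = out.predictions[0]
        assert "".join(e.residue for e in p.sequence.elements) == "PEPTIDE"
        scores = {s.name: s.value for s in p.scores}
        assert scores["agreement_count"] == 2
        assert scores["mean_normalized_rank"] == 1.0

    def test_il_equivalence_joins_the_isobaric_candidate(self):
        docs = [_tool_doc(["PEPTIDE"]), _tool_doc(["PEPTIDE"]),
                _tool_doc(["PEPTLDE"])]
        out, _ = consensus(docs, ConsensusParams(min_agreement=2,
                                                 equivalence="IL_equivalent"))
        scores = {s.name: s.value for s in out.predictions[0].scores}
        assert scores["agreement_count"] == 3

    def test_min_agreement_above_tool_count_yields_nothing(self):
        docs = [_tool_doc(["PEPTIDE"]), _tool_doc(["PEPTIDE"])]
        out, _ = consensus(docs, ConsensusParams(min_agreement=3))
        assert out.predictions == []

    def test_gap_aware_matches_mass_consistent_gap(self, mod_table):
        from dnmso.simulate import replace_run_with_gap

        seq = Sequence([AminoAcidElement(r) for r in "PEPTIDEK"])
        gapped = replace_run_with_gap(seq, 2, 3, {})
        doc_a = _tool_doc(["PEPTIDEK"])
        doc_b = create_document({"creator": "tool-b"})
        sid = doc_b.add_spectrum(make_spectrum(native_id="scan.0"))
        doc_b.add_prediction(Prediction(
            sequence=gapped, scores=[Score("s", 0.8)],
            source_spectrum_refs=[sid], rank=1))
        strict, _ = consensus([doc_a, doc_b], ConsensusParams(min_agreement=2))
        assert strict.predictions == []
        gap_aware, _ = consensus(
            [doc_a, doc_b],
            ConsensusParams(min_agreement=2, gap_aware=True))
        assert len(gap_aware.predictions) == 1

    def test_unmatched_spectra_skipped_with_warning(self):
        doc_a = _tool_doc(["PEPTIDE"])
        doc_b = create_document({"creator": "tool-b"})
        sid = doc_b.add_spectrum(make_spectrum(native_id="other.scan"))
        doc_b.add_prediction(Prediction(
            sequence=Sequence([AminoAcidElement("K")]),
            scores=[Score("s", 0.8)], source_spectrum_refs=[sid], rank=1))
        out, warnings = consensus([doc_a, doc_b], ConsensusParams())
        assert out.predictions == []
        assert warnings

    def test_output_is_valid_and_roundtrippable(self):
        docs = [_tool_doc(["PEPTIDE", "AGAR"]), _tool_doc(["PEPTIDE", "AGAR"])]
        out, _ = consensus(docs, ConsensusParams())
        assert not has_errors(validate(out))
        assert semantic_equal(out, deserialize(serialize(out)))

    def test_matches_brute_force_equivalence_class_oracle(self):
        rng = random.Random(4242)
        alphabet = "ACDEFGHKMNPQRSTVWY"
        for _ in range(10):
            n_spectra = rng.randint(1, 5)
            n_tools = rng.randint(2, 4)
            truths = ["".join(rng.choice(alphabet) for _ in range(6))
                      for _ in range(n_spectra)]
            per_tool_seqs = []
            for _t in range(n_tools):
                seqs = []
                for t_seq in truths:
                    if rng.random() < 0.5:
                        seqs.append(t_seq)
                    else:
                        pos = rng.randrange(len(t_seq))
                        letter = rng.choice([c for c in alphabet
                                             if c != t_seq[pos]])
                        seqs.append(t_seq[:pos] + letter + t_seq[pos + 1:])
                per_tool_seqs.append(seqs)
            docs = [_tool_doc(seqs, creator=f"tool{t}")
                    for t, seqs in enumerate(per_tool_seqs)]
            min_agreement = rng.randint(2, n_tools)
            out, _ = consensus(docs, ConsensusParams(min_agreement=min_agreement))
            got = {
                out.spectrum_by_id(p.source_spectrum_refs[0]).native_id:
                "".join(e.residue for e in p.sequence.elements)
                for p in out.predictions
            }
            expected = {}
            for i in range(n_spectra):
                counts = {}
                for seqs in per_tool_seqs:
                    counts[seqs[i]] = counts.get(seqs[i], 0) + 1
                best = max(counts.values())
                if best >= min_agreement:
                    winners = {s for s, c in counts.items() if c == best}
                    # the implementation breaks ties by first-tool order
                    in_tool_order = [seqs[i] for seqs in per_tool_seqs]
                    expected[f"scan.{i}"] = next(
                        s for s in in_tool_order if s in winners)
            assert got == expected

    def test_needs_two_documents(self):
        with pytest.raises(StructuralError):
            consensus([_tool_doc(["PEP"])], ConsensusParams())
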