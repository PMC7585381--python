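# Methods

This note documents the model behind `dnmso`, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish.

## The data model and its hard rules

A DNMSO document is a container for de novo peptide-spectrum matches (PSMs)
and exactly the context they need: spectra, modifications, software and
controlled-vocabulary references. The deliberately excluded concerns are
sample handling and experiment metadata (they belong to the referenced
spectra standards or a dedicated experiment ontology) and anything
database-related (protein accessions, search databases) — de novo
sequencing has no database, and carrying those fields invites
misinterpretation of de novo confidence as database-search confidence.

Hard (ERROR-level) rules, enforced both at construction time and by the
rule-based `validate()`:

* a prediction has at least one score and at least one source spectrum;
  predictions without spectra are never allowed, while orphan spectra are
  fine (most scans are never assigned);
* every spectrum reference, modification reference, software reference and
  supporting-peak reference resolves within the document;
* every modification carries a well-formed PSI-MOD accession
  (`MOD:` + 5 digits) plus its own mono/average mass deltas, so instances
  remain interpretable standalone;
* inline peak lists are sorted by m/z with positive m/z and non-negative
  intensities; local ids are unique per collection;
* N-/C-terminal modifications may only sit at their respective sequence
  ends; per-element confidence lies in [0, 1].

Advisory (WARNING-level) checks — empty provenance, CV params citing an
unregistered vocabulary — never fail validation. Prediction–spectrum links
form a many-to-many network by design: multi-spectrum predictions model
CID/ETD pairs and merged scans; multi-prediction spectra model ranked
candidate lists and multi-tool results.

Validation is deterministic and rule-based rather than OWL reasoning: the
same graph constraints are checked, but offline, with stable ordering
(by element id, then rule id) and no reasoner dependency. An external
reasoner can always be run on the serialized graph.

## Sequences, masses, gaps

Sequences are ordered elements: amino acid, modified amino acid (which
"reduces" to its amino acid when the modification is stripped), or a mass
gap. Gaps carry **monoisotopic** Daltons — de novo tools work on
monoisotopic masses — and the design invariant is mass closure: replacing
any residue run by a gap of its summed mass leaves the neutral mass
unchanged, so `sequence_mono_mass` always reconciles with the precursor via
`M = (m/z − m_p) · z` (proton `m_p` = 1.007276 Da, water = 18.010565 Da).
Renderings: plain (`G(100.00000)A`, gaps to five decimals, modifications
dropped) and annotated (`S[MOD:00046]`); parsing accepts any decimal
precision and is the exact inverse of annotated rendering. I/L (and K/Q)
ambiguity is deliberately *not* collapsed in the model; I/L equivalence is
an explicit option only where sequences are compared (consensus).

The bundled modification table is a ~30-entry synthetic stand-in for
PSI-MOD (`data/psimod_subset.synthetic.tsv`): field-standard mass deltas
(phospho +79.966331, oxidation +15.994915, acetyl +42.010565, ...) under
PSI-MOD-style accessions. It is the reference for accession lookup,
name lookup (unique-match only) and delta matching (0.01 Da tolerance;
residue-specific entries beat catch-all entries at equal error; earlier
rows win remaining ties). A full PSI-MOD OBO file can be loaded instead via
`load_psimod_obo`.

## Serialization

The RDF vocabulary (shipped as `data/dnmso.ttl`, namespace
`https://w3id.org/dnmso/1.0#`) makes three non-obvious commitments:

* **RDF lists for every ordered collection** (spectra, predictions, scores,
  source refs, sequence elements, supporting peaks). Repeated properties
  would be idiomatic RDF but lose ordering; order is semantics here.
* **Numbers as `repr` lexical forms in plain literals.** `xsd:double`
  literals are not value-preserving through every serializer (Turtle
  writers may reformat to 6 significant digits), and self-containment
  demands bit-exact peaks. Inline peaks are one CSV literal per spectrum
  (`mz,intensity` per line); SPARQL numeric filters need an explicit
  `xsd:double()` cast.
* **Deterministic output**: addressable entities get document-relative IRIs
  from their local ids; blank nodes (list cells, scores, elements) get
  counter-derived labels per serialization, so serializing the same
  document twice is byte-identical in every dialect (JSON-LD is
  additionally key-sorted).

Deserialization is lenient about cardinality — a hand-written file missing
a prediction's spectrum link loads and is then reported by `validate()` —
and strict about namespace version. Triples outside the DNMSO namespace are
kept opaquely and re-emitted, which is the extensibility contract; they are
compared by graph isomorphism in `semantic_equal`.

## Converters

Legacy flat-text layouts vary by tool version and are nowhere normatively
specified, so each supported dialect is frozen (docs/dialects.md + exemplar
files) and unknown layouts fail loudly. Converters never emit orphan
predictions: unmatched candidates are skipped with a warning. Spectrum
matching order — native id, scan index, precursor m/z within 0.01 Th —
reflects reliability: titles are authoritative, indices survive re-exports,
precursor matching is a last resort and warns on ambiguity. pepXML
modification masses (total residue mass) are matched by delta within
0.01 Da; unmatched deltas become an explicit "uncharacterized" placeholder
(MOD:00000) with a warning rather than being dropped — the user must map
them, but no information silently vanishes. mzIdentML export is lossy by
design and write-only: gaps cannot live in a `PeptideSequence`, so the
faithful rendering travels in a userParam, as do per-element confidence and
evidence; no protein/database sections are emitted and re-import is out of
scope.

## Filtering, SPARQL, consensus

Score constraints support the five comparators (>, <, =, >=, <=) combined
all-of/any-of; a prediction lacking the named score *fails* the constraint
(conservative — absence of evidence is not a pass). Filtering keeps all
spectra (orphaning them is legal) and is idempotent.

Consensus is defined here (the format itself only promises that such
queries are expressible): per matched spectrum, compare the top-ranked
candidates (configurable `max_rank`) of each tool under strict equality,
optionally with I/L equivalence, optionally gap-aware (a gap matches a
residue run whose summed mass is within `gap_tolerance_da`, default
0.01 Da; note gap-awareness makes equivalence non-transitive, so classes
are built greedily in tool order). If at least `min_agreement` tools agree,
one consensus prediction is emitted with `agreement_count` and
`mean_normalized_rank` (mean of 1/rank over the agreeing tools). The
strategy is a plain function and can be swapped. Tie-breaks are
deterministic: the first equivalence class in tool order wins.

## Synthetic data: what it shows and what it does not

The generator produces random peptides (default length 7–12, the typical
tryptic range), doubly charged precursors consistent with the peptide mass,
and complete singly protonated b/y ladders plus uniform-random noise peaks
at a 1:1 ratio with log-uniform intensities. Defaults: 20 spectra, 3 tools,
3 ranked candidates per spectrum, 10% per-residue modification rate
(phospho-S/T/Y, oxidized M), 10% gap-perturbation rate, full agreement
unless configured otherwise. Disagreeing top candidates are pairwise
distinct substitutions drawn from an alphabet excluding I/L, so strict and
I/L-equivalent comparisons count the same disagreements.

This exercises parsing, mass arithmetic, linkage and consensus logic
end to end with a known ground truth. It does **not** emulate real
fragmentation physics: no realistic intensity model, no missing fragments,
no isotope envelopes, no chimeric spectra. Passing tests therefore
establish the format and API's correctness, not any claim about de novo
sequencing accuracy on real data — no scoring algorithm is implemented or
needed here.

Problem sizes used by the test suite and `scripts/acceptance.py` (100
random documents up to 50 spectra / 200 predictions across three RDF
dialects; 1000 CSV round trips; 500 peptides for mass consistency; 100×5
filter oracle cases; 20-spectrum consensus datasets) run in roughly three
minutes on one CPU.

## Known limitations

* mzIdentML export is structural (well-formed, required elements), not
  XSD-certified; re-import is unsupported, mirroring the one-way design.
* The mzML/mzXML readers cover centroided peak lists (64/32-bit, plain or
  zlib) and MS2 scans only; vendor formats, MS1 and profile/centroid
  distinctions are out of scope.
* The bundled PSI-MOD subset is a curated synthetic stand-in, not the
  ontology itself; exact term coverage requires a user-supplied OBO file.
* Score scales are tool-native and are not normalized across tools;
  consensus scoring uses ranks, not score values, for exactly that reason.
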