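# Frozen legacy dialects

De novo tools never standardized their output layouts, and the exact column
order varies across tool versions. The converters in `dnmso.convert` accept
exactly the dialects specified here; each dialect is additionally frozen as a
committed exemplar file under `tests/data/`, which is the normative instance.
Files in an unknown layout raise `DialectError` with a hint instead of being
half-parsed.

## PepNovo-style ranked candidates (`pepnovo`)

Exemplar: `tests/data/pepnovo_example.txt`.

* Lines starting with `#` are comments; blank lines are ignored.
* `>> <scan index> <title>` opens the candidate block for one queried
  spectrum. The title is matched against the companion spectra file (MGF
  TITLE / mzML id / mzXML scan number) first; the zero-based scan index is
  the fallback.
* Candidate rows: 7 whitespace-separated columns
  `rank  rnk_score  pnv_score  n_gap  c_gap  charge  sequence`.
* `n_gap`/`c_gap` are monoisotopic masses in Daltons; values > 0 become a
  leading/trailing mass gap on the converted sequence.
* The sequence column uses the package's annotated rendering: residues,
  `(mass)` gaps, `X[MOD:nnnnn]` modified residues.
* Both score columns are kept (`RnkScr`, `PnvScr`).

## Lutefisk-style candidate table (`lutefisk`)

Exemplar: `tests/data/lutefisk_example.txt`.

* `>>> <title>` opens a block; comment/blank rules as above.
* Candidate rows: 4 columns `rank  probability  quality  sequence`.
* Bracketed numeric masses in the sequence (`[100.0]`) are mass gaps;
  `X[MOD:nnnnn]` tags are modifications.
* Both score columns become distinct named scores (`probability`,
  `quality`).

## DNML (`dnml`)

Exemplar: `tests/data/dnml_example.xml`. Self-contained XML:
`<dnml>` root, `<spectra>` with `<spectrum id title pepmass charge>` and
`<peak mz intensity>` children, `<predictions>` with
`<prediction id score rank>`, one or more `<source ref>` children and a
`<sequence>` text child in annotated rendering. DNML carries exactly one
score per prediction; the converter names it `dnml_score`.

## pepXML (`pepxml`)

Exemplar: `tests/data/pepxml_example.xml`. Standard
`spectrum_query`/`search_result`/`search_hit` structure; all `search_score`
entries are kept; `mod_aminoacid_mass/@mass` is the *total* mass of the
modified residue (pepXML convention) and is matched to the modification
table by monoisotopic delta within 0.01 Da. `protein` attributes are
dropped with a lossiness note.

## PEAKS-style CSV (`peaks-csv`)

Exemplar: `tests/data/peaks_example.csv`. Header `scan,peptide,alc,mz,z`;
peptides may carry `(+15.99)`-style deltas after a residue, matched to the
modification table by delta. Only this documented CSV export dialect is
supported; PEAKS' proprietary project formats are out of scope.

## Spectrum matching

All converters that take a companion spectra file match candidates to scans
in this order, first hit wins, ambiguity warned:

1. exact native-id (MGF `TITLE`, mzML `id`, mzXML `num`) match;
2. scan index (position in the file);
3. precursor m/z within 0.01 Th.

Candidates whose spectrum cannot be matched are skipped with a warning —
converted documents never contain predictions without source spectra.
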