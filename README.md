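# dnmso

An ontology-backed standard format — and the API around it — for de novo
peptide-sequencing results from tandem mass spectrometry.

## Why

De novo sequencing assigns a peptide sequence to an MS/MS spectrum without a
protein database. Unlike database search (where mzIdentML is the community
standard), every de novo tool ships its own ad hoc results format, which
makes downstream integration — and especially ensemble/consensus analysis
across tools — needlessly painful. `dnmso` implements DNMSO, a lean,
RDF/ontology-based representation for peptide-spectrum matches (PSMs) from
de novo sequencing, together with everything needed to use it in practice:

* a validated in-memory **data model**: `Document`, `Spectrum`, `Prediction`
  (a PSM: one sequence, ≥1 score, ≥1 source spectrum), `Modification`
  (always referencing a PSI-MOD term with mono/average mass deltas),
  sequences built from amino acids, modified amino acids and **mass gaps**,
  with optional per-element confidence and supporting-peak evidence;
* a many-to-many prediction–spectrum network: one prediction may use
  several spectra (e.g. CID + ETD scans of the same precursor, or merged
  scans) and one spectrum may support many candidates. Spectra without
  predictions are allowed; predictions without spectra are not;
* **self-containment**: spectra can be stored inline as CSV peak lists
  (bit-exact round trip), so a single file carries all the raw data its
  predictions rest on;
* **spectra readers** for MGF, mzML and mzXML (MS2 scans);
* round-trip **RDF serialization** (Turtle, RDF/XML, JSON-LD) in a
  versioned vocabulary (`src/dnmso/data/dnmso.ttl`), deterministic and
  extensible — foreign-namespace triples survive round trips;
* **converters** from PepNovo-style, Lutefisk-style, DNML, pepXML and
  PEAKS-style CSV outputs (see `docs/dialects.md`), plus lossy export to
  **mzIdentML**;
* **filtering** on any number of named scores with greater/lesser/equal
  constraints, **SPARQL** queries, and **consensus prediction** across
  tools;
* a deterministic **synthetic-data generator** (ground-truth peptides,
  b/y-ion spectra, per-tool outputs) powering the whole test surface.

Key mass conventions: monoisotopic Daltons; neutral peptide mass
`M = Σ residue masses (+ modification Δs) + Σ gap masses + 18.010565`;
precursor relation `M = (m/z − 1.007276) · z`.

## Worked example

```bash
dnmso fixtures --seed 5 --n 4 --tools 3 -o fx/            # synthetic dataset
dnmso convert fx/pepnovo_results.txt  --from pepnovo  --spectra fx/spectra.mgf -o pepnovo.ttl
dnmso convert fx/lutefisk_results.txt --from lutefisk --spectra fx/spectra.mgf -o lutefisk.ttl
dnmso convert fx/pepxml_results.xml   --from pepxml   --spectra fx/spectra.mgf -o pepxml.ttl
dnmso consensus pepnovo.ttl lutefisk.ttl pepxml.ttl --min-agreement 2 -o consensus.ttl
dnmso export consensus.ttl --to mzidentml -o consensus.mzid
```

The convert steps each report (on stderr)

```
spectra read: 4; predictions converted: 12; records skipped: 0
```

— 4 scans from the companion MGF and 3 ranked candidates per scan, none
skipped. The consensus step prints

```
4 consensus predictions
```

— with `--seed 5` all three simulated tools agree on every spectrum, so each
of the 4 scans yields one consensus prediction, scored with
`agreement_count` (here 3) and `mean_normalized_rank` (mean of 1/rank over
agreeing tools; 1.0 when all agreed at rank 1). The exported mzIdentML
contains one `SpectrumIdentificationItem` per prediction with all scores as
cvParam/userParam entries.

The same flows are available as a library:

```python
from dnmso import (SpectrumSource, convert_pepnovo, load_psimod_subset,
                   filter_predictions, parse_constraint, serialize)

doc, report = convert_pepnovo("fx/pepnovo_results.txt",
                              SpectrumSource("fx/spectra.mgf"),
                              load_psimod_subset())
kept = filter_predictions(doc, [parse_constraint("RnkScr>=0.5")])
open("kept.ttl", "wb").write(serialize(kept, "turtle"))
```

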