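"""Deterministic synthetic data: ground-truth peptides, their MS/MS spectra
and legacy tool outputs, for exercising the whole conversion/consensus stack.

The generator emulates what a de novo experiment hands downstream tools:
random tryptic-length peptides, singly protonated b/y fragment ladders
(prefix mass + proton for b ions; suffix mass + water + proton for y ions),
a doubly charged precursor consistent with the peptide's neutral mass, and
log-uniform intensities with uniform-random noise peaks mixed in at a 1:1
ratio. Intensity realism is irrelevant here because no scoring algorithm is
implemented; what matters is mass arithmetic and file-format coverage.

Tool outputs are written in the frozen dialects that the converters accept
(PepNovo-style, Lutefisk-style, pepXML, DNML). Per ``agreement_profile``,
all tools report the true sequence at rank 1, or each tool reports a
distinct perturbation (a substitution, or a mass-exact gap replacing a
residue run), so consensus recovery has a known ground truth.
"""

from __future__ import annotations

import base64
import random
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence as TSequence, Tuple

from .model import Peak, Spectrum
from .sequence import (
    AminoAcidElement,
    GapElement,
    Modification,
    ModificationTable,
    ModifiedAminoAcidElement,
    PROTON_MASS,
    RESIDUE_MONO_MASS,
    Sequence,
    WATER_MONO_MASS,
    load_psimod_subset,
    render_sequence,
    residue_mono_mass,
    sequence_mono_mass,
)

#: substitution alphabet for perturbations; I and L excluded so strict and
#: I/L-equivalent comparisons agree on what counts as a disagreement
_SUBSTITUTION_ALPHABET = "ACDEFGHMNPQRSTVWY"

#: modifications the generator may place on applicable residues
_GENERATOR_MODS = ("MOD:00046", "MOD:00047", "MOD:00048", "MOD:00719")

TOOL_FORMATS = ("pepnovo", "lutefisk", "pepxml", "dnml")


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 42
    n_spectra: int = 20
    n_tools: int = 3
    peptide_length_range: Tuple[int, int] = (7, 12)
    modification_rate: float = 0.1
    gap_rate: float = 0.1
    agreement_profile: float = 1.0
    candidates_per_spectrum: int = 3
    noise_peak_ratio: float = 1.0

    def __post_init__(self):
        for p in (self.modification_rate, self.gap_rate, self.agreement_profile):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_spectra < 1 or self.n_tools < 1:
            raise ValueError("counts must be positive")
        if self.n_tools > len(TOOL_FORMATS):
            raise ValueError(f"at most {len(TOOL_FORMATS)} tools supported")


def element_mono_mass(el, mods: Dict[str, Modification]) -> float:
    if isinstance(el, GapElement):
        return el.mass
    if isinstance(el, ModifiedAminoAcidElement):
        return residue_mono_mass(el.residue) + mods[el.modification_ref].mono_mass_delta
    return residue_mono_mass(el.residue)


def fragment_mzs(seq: Sequence, mods: Dict[str, Modification]) -> List[float]:
    """Singly protonated b and y ion m/z values for a peptide sequence."""
    masses = [element_mono_mass(el, mods) for el in seq.elements]
    out = []
    prefix = 0.0
    for m in masses[:-1]:
        prefix += m
        out.append(prefix + PROTON_MASS)  # b ion
    suffix = 0.0
    for m in reversed(masses[1:]):
        suffix += m
        out.append(suffix + WATER_MONO_MASS + PROTON_MASS)  # y ion
    return out


def generate_ground_truth(spec: FixtureSpec) -> List[Tuple[Sequence, Spectrum]]:
    """Random peptides with theoretical b/y spectra; deterministic per seed."""
    rng = random.Random(spec.seed)
    table = load_psimod_subset()
    mods = {acc: table.by_accession(acc) for acc in _GENERATOR_MODS}
    residues = sorted(RESIDUE_MONO_MASS)
    out = []
    for i in range(spec.n_spectra):
        length = rng.randint(*spec.peptide_length_range)
        elements: List = []
        for _ in range(length):
            r = rng.choice(residues)
            applicable = [m for m in mods.values() if m.applies_to(r)]
            if applicable and rng.random() < spec.modification_rate:
                elements.append(ModifiedAminoAcidElement(r, rng.choice(applicable).local_id))
            else:
                elements.append(AminoAcidElement(r))
        seq = Sequence(elements)
        neutral = sequence_mono_mass(seq, mods)
        charge = 2
        precursor_mz = neutral / charge + PROTON_MASS
        frag = fragment_mzs(seq, mods)
        pairs = [(mz, 10.0 ** rng.uniform(2.0, 5.0)) for mz in frag]
        n_noise = int(round(len(frag) * spec.noise_peak_ratio))
        for _ in range(n_noise):
            pairs.append((rng.uniform(50.0, precursor_mz * charge),
                          10.0 ** rng.uniform(1.0, 3.0)))
        pairs.sort(key=lambda t: t[0])
        spectrum = Spectrum(
            precursor_mz=precursor_mz,
            precursor_charge=charge,
            peaks=[Peak(mz, inten) for mz, inten in pairs],
            native_id=f"fixture.{i}",
            fragmentation="CID",
        )
        out.append((seq, spectrum))
    return out


def replace_run_with_gap(seq: Sequence, start: int, length: int,
                         mods: Dict[str, Modification]) -> Sequence:
    """Replace ``length`` elements from ``start`` by one mass-exact gap."""
    if length < 1 or start < 0 or start + length > len(seq.elements):
        raise ValueError("gap run out of range")
    gap_mass = sum(element_mono_mass(el, mods)
                   for el in seq.elements[start:start + length])
    elements = (list(seq.elements[:start]) + [GapElement(gap_mass)]
                + list(seq.elements[start + length:]))
    return Sequence(elements)


def _perturb(seq: Sequence, rng: random.Random, position: int, letter_index: int,
             mods: Dict[str, Modification], allow_gap: bool,
             gap_rate: float) -> Sequence:
    """A sequence that differs from ``seq``: a substitution at ``position``
    using the ``letter_index``-th admissible letter (distinct indices give
    pairwise distinct outputs), or occasionally a mass-exact gap."""
    if allow_gap and len(seq.elements) >= 3 and rng.random() < gap_rate:
        start = rng.randrange(len(seq.elements) - 1)
        run = rng.randint(2, min(3, len(seq.elements) - start))
        return replace_run_with_gap(seq, start, run, mods)
    el = seq.elements[position]
    original = getattr(el, "residue", None)
    choices = [c for c in _SUBSTITUTION_ALPHABET if c != original]
    letter = choices[letter_index % len(choices)]
    elements = list(seq.elements)
    elements[position] = AminoAcidElement(letter)
    return Sequence(elements)


# ---------------------------------------------------------------------------
# Spectra file writers (MGF plus minimal standard-conforming mzML/mzXML,
# enough for the readers' contract to be exercised end to end)


def write_mgf(spectra: TSequence[Spectrum], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            if s.native_id:
                fh.write(f"TITLE={s.native_id}\n")
            if s.precursor_mz is not None:
                fh.write(f"PEPMASS={s.precursor_mz!r}\n")
            if s.precursor_charge is not None:
                fh.write(f"CHARGE={s.precursor_charge}+\n")
            if s.retention_time_s is not None:
                fh.write(f"RTINSECONDS={s.retention_time_s!r}\n")
            for pk in s.peaks:
                fh.write(f"{pk.mz!r} {pk.intensity!r}\n")
            fh.write("END IONS\n")


def _b64_doubles(values, byte_order="<") -> str:
    raw = struct.pack(f"{byte_order}{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(spectra: TSequence[Spectrum], path) -> None:
    """Minimal mzML 1.1 with uncompressed 64-bit little-endian peak arrays."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        f'  <run id="run1" defaultInstrumentConfigurationRef="IC1">',
        f'    <spectrumList count="{len(spectra)}">',
    ]
    for idx, s in enumerate(spectra):
        native_id = s.native_id or f"scan={idx + 1}"
        mz_b64 = _b64_doubles([p.mz for p in s.peaks])
        int_b64 = _b64_doubles([p.intensity for p in s.peaks])
        lines.append(
            f'      <spectrum index="{idx}" id="{native_id}" '
            f'defaultArrayLength="{len(s.peaks)}">')
        lines.append('        <cvParam cvRef="MS" accession="MS:1000511" '
                     'name="ms level" value="2"/>')
        if s.precursor_mz is not None:
            lines.append('        <precursorList count="1"><precursor>'
                         '<selectedIonList count="1"><selectedIon>')
            lines.append(
                f'          <cvParam cvRef="MS" accession="MS:1000744" '
                f'name="selected ion m/z" value="{s.precursor_mz!r}"/>')
            if s.precursor_charge is not None:
                lines.append(
                    f'          <cvParam cvRef="MS" accession="MS:1000041" '
                    f'name="charge state" value="{s.precursor_charge}"/>')
            lines.append('        </selectedIon></selectedIonList>'
                         '</precursor></precursorList>')
        lines.append('        <binaryDataArrayList count="2">')
        for accession, name, b64 in (
            ("MS:1000514", "m/z array", mz_b64),
            ("MS:1000515", "intensity array", int_b64),
        ):
            lines.append(f'          <binaryDataArray encodedLength="{len(b64)}">')
            lines.append('            <cvParam cvRef="MS" accession="MS:1000523" '
                         'name="64-bit float"/>')
            lines.append('            <cvParam cvRef="MS" accession="MS:1000576" '
                         'name="no compression"/>')
            lines.append(f'            <cvParam cvRef="MS" accession="{accession}" '
                         f'name="{name}"/>')
            lines.append(f'            <binary>{b64}</binary>')
            lines.append('          </binaryDataArray>')
        lines.append('        </binaryDataArrayList>')
        lines.append('      </spectrum>')
    lines += ['    </spectrumList>', '  </run>', '</mzML>', '']
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def write_mzxml(spectra: TSequence[Spectrum], path) -> None:
    """Minimal mzXML 3.2 with network-order interleaved 64-bit peak pairs."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f'  <msRun scanCount="{len(spectra)}">',
    ]
    for idx, s in enumerate(spectra):
        interleaved = []
        for p in s.peaks:
            interleaved += [p.mz, p.intensity]
        b64 = _b64_doubles(interleaved, byte_order=">")
        lines.append(f'    <scan num="{idx + 1}" msLevel="2" '
                     f'peaksCount="{len(s.peaks)}">')
        if s.precursor_mz is not None:
            charge_attr = (f' precursorCharge="{s.precursor_charge}"'
                           if s.precursor_charge is not None else "")
            lines.append(f'      <precursorMz{charge_attr}>'
                         f'{s.precursor_mz!r}</precursorMz>')
        lines.append('      <peaks compressionType="none" compressedLen="0" '
                     'precision="64" byteOrder="network" '
                     f'contentType="m/z-int">{b64}</peaks>')
        lines.append('    </scan>')
    lines += ['  </msRun>', '</mzXML>', '']
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Tool-output writers


def _candidate_sets(
    truth: TSequence[Tuple[Sequence, Spectrum]],
    spec: FixtureSpec,
    mods: Dict[str, Modification],
) -> List[List[List[Tuple[int, Sequence, float]]]]:
    """candidates[spectrum][tool] = [(rank, sequence, score), ...].

    Rank-1 candidates follow ``agreement_profile``: either every tool reports
    the true sequence, or each tool reports a pairwise-distinct perturbation.
    Lower ranks are always perturbations.
    """
    rng = random.Random(spec.seed + 1)
    out = []
    for spectrum_idx, (seq, _) in enumerate(truth):
        agree = rng.random() < spec.agreement_profile
        position = rng.randrange(len(seq.elements))
        per_tool = []
        for tool_idx in range(spec.n_tools):
            # pepXML carries no gap notation, so that tool never emits gaps
            allow_gap = TOOL_FORMATS[tool_idx] != "pepxml"
            candidates = []
            for rank in range(1, spec.candidates_per_spectrum + 1):
                if rank == 1 and agree:
                    cand = seq
                elif rank == 1:
                    # disagreeing top candidates must be pairwise distinct:
                    # substitutions with tool-specific letters, never gaps
                    cand = _perturb(seq, rng, position, tool_idx, mods,
                                    False, 0.0)
                else:
                    cand = _perturb(seq, rng, position,
                                    spec.n_tools + tool_idx * 10 + rank, mods,
                                    allow_gap, spec.gap_rate)
                lo, hi = {1: (0.7, 1.0), 2: (0.4, 0.7)}.get(rank, (0.1, 0.4))
                candidates.append((rank, cand, rng.uniform(lo, hi)))
            per_tool.append(candidates)
        out.append(per_tool)
    return out


def write_tool_outputs(
    truth: TSequence[Tuple[Sequence, Spectrum]],
    spec: FixtureSpec,
    outdir,
) -> Dict[str, Path]:
    """Write the companion MGF plus one results file per simulated tool.

    Returns a mapping from file role (``spectra_mgf``, ``pepnovo``, ...) to
    the written path. Each results file is a valid instance of its frozen
    dialect and every candidate references a spectrum in the companion MGF.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = load_psimod_subset()
    mods = {m.psimod_accession: m for m in table}
    paths: Dict[str, Path] = {}

    mgf_path = outdir / "spectra.mgf"
    write_mgf([s for _, s in truth], mgf_path)
    paths["spectra_mgf"] = mgf_path

    candidates = _candidate_sets(truth, spec, mods)
    for tool_idx in range(spec.n_tools):
        fmt = TOOL_FORMATS[tool_idx]
        path = outdir / f"{fmt}_results.{'xml' if fmt in ('pepxml', 'dnml') else 'txt'}"
        writer = {
            "pepnovo": _write_pepnovo,
            "lutefisk": _write_lutefisk,
            "pepxml": _write_pepxml,
            "dnml": _write_dnml,
        }[fmt]
        writer(truth, candidates, tool_idx, mods, path)
        paths[fmt] = path
    return paths


def _write_pepnovo(truth, candidates, tool_idx, mods, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# PepNovo-style output (DNMSO frozen dialect)\n")
        fh.write("#Index\tRnkScr\tPnvScr\tN-Gap\tC-Gap\tCharge\tSequence\n")
        for idx, (_, spectrum) in enumerate(truth):
            fh.write(f">> {idx} {spectrum.native_id}\n")
            for rank, seq, score in candidates[idx][tool_idx]:
                text = render_sequence(seq, "annotated", mods)
                pnv = 10.0 + 90.0 * score
                fh.write(f"{rank}\t{score:.4f}\t{pnv:.2f}\t0.0\t0.0\t"
                         f"{spectrum.precursor_charge}\t{text}\n")


def _write_lutefisk(truth, candidates, tool_idx, mods, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Lutefisk-style output (DNMSO frozen dialect)\n")
        fh.write("#Rank\tPr(c)\tQuality\tSequence\n")
        for idx, (_, spectrum) in enumerate(truth):
            fh.write(f">>> {spectrum.native_id}\n")
            for rank, seq, score in candidates[idx][tool_idx]:
                text = render_sequence(seq, "annotated", mods)
                # Lutefisk writes gaps as bracketed masses
                text = text.replace("(", "[").replace(")", "]")
                fh.write(f"{rank}\t{score:.4f}\t{score * 0.9:.4f}\t{text}\n")


def _write_pepxml(truth, candidates, tool_idx, mods, path) -> None:
    from lxml import etree

    root = etree.Element("msms_pipeline_analysis")
    run = etree.SubElement(root, "msms_run_summary")
    for idx, (_, spectrum) in enumerate(truth):
        neutral = (spectrum.precursor_mz - PROTON_MASS) * spectrum.precursor_charge
        query = etree.SubElement(
            run, "spectrum_query",
            spectrum=spectrum.native_id,
            start_scan=str(idx + 1),
            precursor_neutral_mass=repr(neutral),
            assumed_charge=str(spectrum.precursor_charge),
        )
        result = etree.SubElement(query, "search_result")
        for rank, seq, score in candidates[idx][tool_idx]:
            letters = "".join(getattr(el, "residue", "") for el in seq.elements)
            hit = etree.SubElement(result, "search_hit",
                                   hit_rank=str(rank), peptide=letters)
            mod_positions = [
                (i + 1, el) for i, el in enumerate(seq.elements)
                if isinstance(el, ModifiedAminoAcidElement)
            ]
            if mod_positions:
                info = etree.SubElement(hit, "modification_info")
                for pos, el in mod_positions:
                    total = (residue_mono_mass(el.residue)
                             + mods[el.modification_ref].mono_mass_delta)
                    etree.SubElement(info, "mod_aminoacid_mass",
                                     position=str(pos), mass=repr(total))
            etree.SubElement(hit, "search_score", name="denovo_score",
                             value=f"{score:.4f}")
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=True, encoding="UTF-8"))


def _write_dnml(truth, candidates, tool_idx, mods, path) -> None:
    from lxml import etree

    root = etree.Element("dnml", version="1.0")
    spectra_el = etree.SubElement(root, "spectra")
    for idx, (_, spectrum) in enumerate(truth):
        spec_el = etree.SubElement(
            spectra_el, "spectrum",
            id=f"s{idx}", title=spectrum.native_id,
            pepmass=repr(spectrum.precursor_mz),
            charge=str(spectrum.precursor_charge),
        )
        for pk in spectrum.peaks:
            etree.SubElement(spec_el, "peak", mz=repr(pk.mz),
                             intensity=repr(pk.intensity))
    preds_el = etree.SubElement(root, "predictions")
    counter = 0
    for idx in range(len(truth)):
        for rank, seq, score in candidates[idx][tool_idx]:
            counter += 1
            pred_el = etree.SubElement(preds_el, "prediction", id=f"p{counter}",
                                       score=f"{score:.4f}", rank=str(rank))
            etree.SubElement(pred_el, "source", ref=f"s{idx}")
            seq_el = etree.SubElement(pred_el, "sequence")
            seq_el.text = render_sequence(seq, "annotated", mods)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=True, encoding="UTF-8"))


# ---------------------------------------------------------------------------
# Random whole documents (round-trip and filtering test surface)


def random_document(
    rng: random.Random,
    max_spectra: int = 50,
    max_predictions: int = 200,
    score_names: TSequence[str] = ("score_a", "score_b", "score_c"),
) -> "Document":
    """A random valid document: mixed inline/external spectra, predictions
    with modifications, gaps, confidences, supporting peaks and 1-3 scores."""
    from .model import ExternalSpectrumRef, Prediction, Score, Software, create_document

    table = load_psimod_subset()
    mods = [table.by_accession(acc) for acc in _GENERATOR_MODS]
    doc = create_document({"creator": "dnmso-simulate", "seed_note": "random"})
    for m in mods:
        doc.add_modification(m)
    sw_id = doc.add_software(Software(name="simulator", version="1.0"))

    n_spectra = rng.randint(1, max_spectra)
    inline_ids = []
    for i in range(n_spectra):
        if rng.random() < 0.8:
            n_peaks = rng.randint(3, 20)
            pairs = sorted(
                (rng.uniform(100.0, 1500.0), 10.0 ** rng.uniform(1.0, 5.0))
                for _ in range(n_peaks)
            )
            sid = doc.add_spectrum(Spectrum(
                precursor_mz=rng.uniform(300.0, 900.0),
                precursor_charge=rng.choice([None, 1, 2, 3]),
                peaks=[Peak(mz, inten) for mz, inten in pairs],
                retention_time_s=rng.choice([None, rng.uniform(0.0, 3600.0)]),
                fragmentation=rng.choice([None, "CID", "ETD", "HCD"]),
                native_id=f"scan.{i}",
            ))
            inline_ids.append(sid)
        else:
            doc.add_spectrum(Spectrum(
                precursor_mz=rng.uniform(300.0, 900.0),
                external_ref=ExternalSpectrumRef(
                    file_path_or_uri=f"run_{i}.mzML", format_hint="mzML",
                    native_id=f"scan={i}",
                ),
                native_id=f"ext.{i}",
            ))

    residues = sorted(RESIDUE_MONO_MASS)
    n_predictions = rng.randint(0, max_predictions)
    for _ in range(n_predictions):
        elements: List = []
        for _ in range(rng.randint(4, 10)):
            u = rng.random()
            if u < 0.1:
                elements.append(GapElement(rng.uniform(50.0, 400.0)))
            elif u < 0.2:
                mod = rng.choice(mods)
                residue = (mod.residue_specificity[0]
                           if mod.residue_specificity != "any"
                           else rng.choice(residues))
                elements.append(ModifiedAminoAcidElement(residue, mod.local_id))
            else:
                elements.append(AminoAcidElement(rng.choice(residues)))
        el = rng.choice(elements)
        if rng.random() < 0.3:
            el.confidence = rng.random()
        if inline_ids and rng.random() < 0.3:
            sid = rng.choice(inline_ids)
            n_pk = len(doc.spectrum_by_id(sid).peaks)
            el.supporting_peaks = [(sid, rng.randrange(n_pk))]
        refs = rng.sample([s.id for s in doc.spectra],
                          k=min(len(doc.spectra), rng.choice([1, 1, 1, 2])))
        doc.add_prediction(Prediction(
            sequence=Sequence(elements),
            scores=[Score(name, rng.random())
                    for name in rng.sample(list(score_names),
                                           k=rng.randint(1, len(score_names)))],
            source_spectrum_refs=refs,
            software_ref=sw_id,
            rank=rng.choice([None, 1, 2, 3]),
        ))
    return doc
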