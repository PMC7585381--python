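"""Peptide sequences as ordered elements: amino acids, modified amino acids
and mass gaps.

De novo sequencing tools rarely explain a whole precursor mass with residues;
unexplained stretches are carried as explicit mass gaps so that the sum of
element masses (plus one water) always reconstructs the neutral peptide mass.
Modified residues keep their underlying amino acid and point at a
:class:`Modification` that must reference a PSI-MOD term, so instances stay
interpretable without the full PSI-MOD ontology at hand.

Mass conventions: monoisotopic Daltons throughout; neutral peptide mass =
sum of residue masses + modification deltas + gap masses + one water
(18.010565 Da). Charge enters only when converting to/from precursor m/z:
neutral = (m/z - proton) * z with proton = 1.007276 Da.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence as TSequence, Tuple, Union

from .errors import (
    AlphabetError,
    AmbiguityError,
    IdentityConflictError,
    SequenceSyntaxError,
    StructuralError,
    UnresolvedModificationError,
    UnresolvedReferenceError,
)

#: Monoisotopic masses of the 20 standard amino-acid residues, in Daltons.
RESIDUE_MONO_MASS = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER_MONO_MASS = 18.010565
PROTON_MASS = 1.007276

CANONICAL_RESIDUES = frozenset(RESIDUE_MONO_MASS)

_PSIMOD_RE = re.compile(r"^MOD:\d{5}$")

#: Accession used for mass shifts that could not be matched to the table
#: (the PSI-MOD root term "protein modification").
UNKNOWN_MODIFICATION_ACCESSION = "MOD:00000"


def residue_mono_mass(residue: str) -> float:
    """Monoisotopic mass of a standard amino-acid residue in Daltons."""
    try:
        return RESIDUE_MONO_MASS[residue]
    except KeyError:
        raise AlphabetError(
            f"unknown residue {residue!r}: not one of the 20 standard amino acids"
        ) from None


@dataclass
class Modification:
    """A post-translational modification, always tied to a PSI-MOD accession.

    Mass deltas are recorded in both monoisotopic and average Daltons so an
    instance remains usable without loading PSI-MOD itself.
    """

    local_id: str
    psimod_accession: str
    name: str
    mono_mass_delta: float
    avg_mass_delta: float
    residue_specificity: str = "any"  # "any" or a string of residue letters
    terminus: str = "none"  # none | N-term | C-term

    def applies_to(self, residue: str) -> bool:
        return self.residue_specificity == "any" or residue in self.residue_specificity

    def has_valid_accession(self) -> bool:
        return bool(self.psimod_accession) and bool(
            _PSIMOD_RE.match(self.psimod_accession)
        )


SupportingPeak = Tuple[str, int]  # (spectrum local id, peak index)


@dataclass
class AminoAcidElement:
    residue: str
    confidence: Optional[float] = None
    supporting_peaks: Optional[TSequence[SupportingPeak]] = None

    kind = "seAminoAcid"


@dataclass
class ModifiedAminoAcidElement:
    """A residue plus modification; stripping the modification yields a
    plain :class:`AminoAcidElement` with the same residue."""

    residue: str
    modification_ref: str
    confidence: Optional[float] = None
    supporting_peaks: Optional[TSequence[SupportingPeak]] = None

    kind = "seModifiedAminoAcid"

    def demodified(self) -> AminoAcidElement:
        return AminoAcidElement(
            self.residue, confidence=self.confidence,
            supporting_peaks=self.supporting_peaks,
        )


@dataclass
class GapElement:
    """A contiguous unexplained stretch, carried as a monoisotopic mass."""

    mass: float
    confidence: Optional[float] = None
    supporting_peaks: Optional[TSequence[SupportingPeak]] = None

    kind = "Gap"


SequenceElement = Union[AminoAcidElement, ModifiedAminoAcidElement, GapElement]


@dataclass
class Sequence:
    """Ordered, non-empty list of sequence elements."""

    elements: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.elements)

    def __len__(self):
        return len(self.elements)

    def demodified(self) -> "Sequence":
        """The sequence with every modified residue reduced to its amino acid."""
        out = []
        for el in self.elements:
            out.append(el.demodified() if isinstance(el, ModifiedAminoAcidElement) else el)
        return Sequence(out)


def check_sequence(seq: Sequence, mods: Optional[Mapping[str, Modification]] = None) -> None:
    """Raise :class:`StructuralError` if the sequence breaks an invariant.

    Checks non-emptiness, residue alphabet, gap positivity, confidence range
    and (when a modification table is given) that terminal modifications sit
    at their respective ends.
    """
    if not seq.elements:
        raise StructuralError("sequence must contain at least one element")
    for i, el in enumerate(seq.elements):
        if isinstance(el, (AminoAcidElement, ModifiedAminoAcidElement)):
            if el.residue not in CANONICAL_RESIDUES:
                raise AlphabetError(f"element {i}: residue {el.residue!r} not canonical")
        elif isinstance(el, GapElement):
            if not (el.mass > 0 and el.mass == el.mass and el.mass != float("inf")):
                raise StructuralError(f"element {i}: gap mass must be finite and > 0")
        conf = getattr(el, "confidence", None)
        if conf is not None and not (0.0 <= conf <= 1.0):
            raise StructuralError(f"element {i}: confidence {conf} outside [0, 1]")
        if mods is not None and isinstance(el, ModifiedAminoAcidElement):
            mod = mods.get(el.modification_ref)
            if mod is not None and mod.terminus == "N-term" and i != 0:
                raise StructuralError(f"element {i}: N-terminal modification not at N-terminus")
            if mod is not None and mod.terminus == "C-term" and i != len(seq.elements) - 1:
                raise StructuralError(f"element {i}: C-terminal modification not at C-terminus")


def sequence_mono_mass(seq: Sequence, mods: Mapping[str, Modification]) -> float:
    """Neutral monoisotopic peptide mass of a sequence, in Daltons.

    Sum of residue masses (plus modification deltas) and gap masses, plus one
    water for the termini.
    """
    total = WATER_MONO_MASS
    for i, el in enumerate(seq.elements):
        if isinstance(el, AminoAcidElement):
            total += residue_mono_mass(el.residue)
        elif isinstance(el, ModifiedAminoAcidElement):
            total += residue_mono_mass(el.residue)
            try:
                mod = mods[el.modification_ref]
            except KeyError:
                raise UnresolvedReferenceError(
                    f"element {i}: modification ref {el.modification_ref!r} "
                    "not in modification table"
                ) from None
            total += mod.mono_mass_delta
        elif isinstance(el, GapElement):
            total += el.mass
        else:  # pragma: no cover - defensive
            raise StructuralError(f"element {i}: unknown element type {type(el)!r}")
    return total


def mz_to_neutral_mass(mz: float, charge: int) -> float:
    """Neutral mass from precursor m/z and positive charge."""
    return (mz - PROTON_MASS) * charge


def neutral_mass_to_mz(mass: float, charge: int) -> float:
    return mass / charge + PROTON_MASS


# ---------------------------------------------------------------------------
# Rendering and parsing


def render_sequence(
    seq: Sequence,
    style: str = "plain",
    mods: Optional[Mapping[str, Modification]] = None,
) -> str:
    """Render a sequence as text.

    plain
        Residue letters only; gaps as ``(m)`` with the unexplained mass to
        five decimals; modifications dropped.
    annotated
        Like plain, but each modified residue is followed by its PSI-MOD
        accession in square brackets, e.g. ``S[MOD:00046]``. Requires the
        modification table to look accessions up.
    """
    if style not in ("plain", "annotated"):
        raise ValueError(f"unknown style {style!r}")
    parts = []
    for el in seq.elements:
        if isinstance(el, GapElement):
            parts.append(f"({el.mass:.5f})")
        elif isinstance(el, ModifiedAminoAcidElement):
            if style == "annotated":
                if mods is None or el.modification_ref not in mods:
                    raise UnresolvedReferenceError(
                        f"modification ref {el.modification_ref!r} not resolvable "
                        "for annotated rendering"
                    )
                parts.append(f"{el.residue}[{mods[el.modification_ref].psimod_accession}]")
            else:
                parts.append(el.residue)
        else:
            parts.append(el.residue)
    return "".join(parts)


_TOKEN_RE = re.compile(
    r"(?P<residue>[A-Z])"
    r"|\((?P<gap>[0-9]+(?:\.[0-9]+)?)\)"
    r"|\[(?P<acc>MOD:\d{5})\]"
)


def parse_sequence(
    text: str,
    mod_table: Optional["ModificationTable"] = None,
) -> Sequence:
    """Parse plain or annotated sequence text back into a :class:`Sequence`.

    ``X[MOD:nnnnn]`` tokens need a modification table to resolve the
    accession; the resulting element references the table entry's local id.
    """
    if not isinstance(text, str) or text == "":
        raise SequenceSyntaxError("empty sequence text")
    elements: list = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise SequenceSyntaxError(
                f"cannot parse sequence at position {pos}: {text[pos:pos + 12]!r}"
            )
        if m.group("residue"):
            r = m.group("residue")
            if r not in CANONICAL_RESIDUES:
                raise AlphabetError(f"position {pos}: residue {r!r} not canonical")
            elements.append(AminoAcidElement(r))
        elif m.group("gap"):
            elements.append(GapElement(float(m.group("gap"))))
        else:
            acc = m.group("acc")
            if not elements or not isinstance(elements[-1], AminoAcidElement):
                raise SequenceSyntaxError(
                    f"position {pos}: modification tag must follow a residue"
                )
            if mod_table is None:
                raise UnresolvedModificationError(
                    f"position {pos}: no modification table to resolve {acc}"
                )
            mod = mod_table.by_accession(acc)
            prev = elements.pop()
            elements.append(ModifiedAminoAcidElement(prev.residue, mod.local_id))
        pos = m.end()
    if not elements:
        raise SequenceSyntaxError("sequence text contains no elements")
    return Sequence(elements)


# ---------------------------------------------------------------------------
# Modification tables


class ModificationTable:
    """Lookup table of modifications, by PSI-MOD accession or by name."""

    def __init__(self, mods: Iterable[Modification]):
        self._mods = list(mods)
        self._by_acc = {}
        for m in self._mods:
            if m.psimod_accession in self._by_acc:
                raise IdentityConflictError(
                    f"duplicate accession {m.psimod_accession!r} in table"
                )
            self._by_acc[m.psimod_accession] = m

    def __iter__(self):
        return iter(self._mods)

    def __len__(self):
        return len(self._mods)

    def by_accession(self, accession: str) -> Modification:
        try:
            return self._by_acc[accession]
        except KeyError:
            raise UnresolvedModificationError(
                f"no modification with accession {accession!r} in table"
            ) from None

    def resolve(self, query: str) -> Modification:
        """Resolve a modification by accession, or by name if unique."""
        if not query:
            raise SequenceSyntaxError("empty modification query")
        if _PSIMOD_RE.match(query):
            return self.by_accession(query)
        matches = [m for m in self._mods if m.name == query]
        if not matches:
            raise UnresolvedModificationError(f"no modification named {query!r}")
        if len(matches) > 1:
            raise AmbiguityError(
                f"{len(matches)} modifications named {query!r}; use an accession"
            )
        return matches[0]

    def match_by_mono_delta(
        self, delta: float, residue: Optional[str] = None, tolerance: float = 0.01
    ) -> Optional[Modification]:
        """Best table entry whose monoisotopic delta is within ``tolerance``
        Da of ``delta`` (and which applies to ``residue``, when given)."""
        best = None
        best_key = (tolerance, 1)
        for m in self._mods:
            if residue is not None and not m.applies_to(residue):
                continue
            err = abs(m.mono_mass_delta - delta)
            # residue-specific entries beat catch-all ("any") ones at equal
            # error; earlier table entries win remaining ties
            key = (err, 0 if m.residue_specificity != "any" else 1)
            if err <= tolerance and key < best_key:
                best, best_key = m, key
        return best


def load_psimod_subset() -> ModificationTable:
    """Load the bundled modification table.

    The table is a small synthetic stand-in for PSI-MOD: a curated subset of
    common modifications with field-standard monoisotopic/average mass deltas
    and accessions in the PSI-MOD style, sufficient for self-contained DNMSO
    instances and for converter delta-matching. Supply a full PSI-MOD OBO
    file via :func:`load_psimod_obo` when exact ontology coverage matters.
    """
    ref = resources.files("dnmso").joinpath("data/psimod_subset.synthetic.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        return _read_mod_tsv(fh)


def _read_mod_tsv(fh) -> ModificationTable:
    reader = csv.DictReader(fh, delimiter="\t")
    mods = []
    for row in reader:
        mods.append(
            Modification(
                local_id=row["accession"],
                psimod_accession=row["accession"],
                name=row["name"],
                mono_mass_delta=float(row["mono_delta"]),
                avg_mass_delta=float(row["avg_delta"]),
                residue_specificity=row["residues"],
                terminus=row["terminus"],
            )
        )
    return ModificationTable(mods)


def load_psimod_obo(path) -> ModificationTable:
    """Load modifications from a user-supplied PSI-MOD OBO file.

    Reads term accessions, names and the DiffMono/DiffAvg xrefs. Terms
    without a defined monoisotopic delta are skipped.
    """
    import obonet

    graph = obonet.read_obo(path)
    mods = []
    for node, data in graph.nodes(data=True):
        if not node.startswith("MOD:"):
            continue
        xrefs = {}
        for pv in data.get("xref", []):
            if " " in pv:
                key, val = pv.split(" ", 1)
                xrefs[key.rstrip(":")] = val.strip('"')
        mono = xrefs.get("DiffMono")
        if mono in (None, "", "none"):
            continue
        try:
            mono_f = float(mono)
            avg_f = float(xrefs.get("DiffAvg", mono))
        except ValueError:
            continue
        origin = xrefs.get("Origin", "any").replace(",", "").strip()
        residues = origin if origin and origin.isalpha() and origin != "X" else "any"
        term = {"N-term": "N-term", "C-term": "C-term"}.get(
            xrefs.get("TermSpec", "none"), "none"
        )
        mods.append(
            Modification(
                local_id=node,
                psimod_accession=node,
                name=data.get("name", node),
                mono_mass_delta=mono_f,
                avg_mass_delta=avg_f,
                residue_specificity=residues,
                terminus=term,
            )
        )
    return ModificationTable(mods)
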