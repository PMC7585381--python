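"""Score-constraint filtering, SPARQL queries and cross-tool consensus.

Filtering mirrors how results files are trimmed before sharing: any number
of named-score constraints with greater/lesser/equal comparators, combined
with all-of or any-of semantics. A prediction that does not carry a score
with the constrained name fails that constraint (conservative semantics).

Consensus combines the top-ranked predictions that several tools produced
for the same spectrum. Spectra are matched across documents by native id
first, then position, then precursor m/z; sequences are compared strictly,
optionally with I/L treated as indistinguishable (they are isobaric and no
fragmentation-based method can separate them), and optionally gap-aware:
a mass gap matches a residue run whose summed monoisotopic mass lies within
a tolerance. When at least ``min_agreement`` tools agree, one consensus
prediction is emitted with an ``agreement_count`` score and the mean of
1/rank over the agreeing tools (``mean_normalized_rank``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence as TSequence, Tuple

from .errors import QueryError, StructuralError
from .model import Document, Prediction, Score, Software, create_document
from .sequence import (
    AminoAcidElement,
    GapElement,
    ModifiedAminoAcidElement,
    Sequence,
    residue_mono_mass,
)

_COMPARATORS = {
    "greater": lambda v, t: v > t,
    "lesser": lambda v, t: v < t,
    "equal": lambda v, t: v == t,
    "greater_or_equal": lambda v, t: v >= t,
    "lesser_or_equal": lambda v, t: v <= t,
}


@dataclass(frozen=True)
class ScoreConstraint:
    """One threshold on a named score."""

    score_name: str
    comparator: str  # greater | lesser | equal | greater_or_equal | lesser_or_equal
    threshold: float

    def __post_init__(self):
        if not self.score_name:
            raise StructuralError("score constraint needs a non-empty score name")
        if self.comparator not in _COMPARATORS:
            raise StructuralError(
                f"unknown comparator {self.comparator!r}; "
                f"expected one of {sorted(_COMPARATORS)}"
            )
        if not math.isfinite(self.threshold):
            raise StructuralError("score constraint threshold must be finite")

    def satisfied_by(self, p: Prediction) -> bool:
        """True iff the prediction carries the named score and it passes.

        Missing score -> fail (never silently pass).
        """
        for sc in p.scores:
            if sc.name == self.score_name:
                return _COMPARATORS[self.comparator](sc.value, self.threshold)
        return False


_CONSTRAINT_RE = re.compile(r"^\s*(?P<name>[^<>=]+?)\s*(?P<op>>=|<=|>|<|=)\s*(?P<thr>[-+0-9.eE]+)\s*$")
_OP_TO_COMPARATOR = {
    ">": "greater",
    "<": "lesser",
    "=": "equal",
    ">=": "greater_or_equal",
    "<=": "lesser_or_equal",
}


def parse_constraint(expression: str) -> ScoreConstraint:
    """Parse ``"Name>=0.5"``-style expressions into a :class:`ScoreConstraint`."""
    m = _CONSTRAINT_RE.match(expression)
    if m is None:
        raise QueryError(
            f"cannot parse score constraint {expression!r}; expected "
            "<name><op><number> with op one of >, <, =, >=, <="
        )
    try:
        threshold = float(m.group("thr"))
    except ValueError:
        raise QueryError(f"non-numeric threshold in {expression!r}") from None
    return ScoreConstraint(m.group("name"), _OP_TO_COMPARATOR[m.group("op")], threshold)


def filter_predictions(
    doc: Document,
    constraints: TSequence[ScoreConstraint],
    combine: str = "all",
) -> Document:
    """New document keeping exactly the predictions that pass the constraints.

    All spectra, modifications, software and CV sources are carried over
    (spectra may become orphans, which is permitted; predictions may not).
    An empty result is a valid document.
    """
    if not constraints:
        raise StructuralError("at least one score constraint is required")
    if combine not in ("all", "any"):
        raise StructuralError(f"combine must be 'all' or 'any', got {combine!r}")
    mode = all if combine == "all" else any

    out = create_document(provenance=dict(doc.provenance), id=doc.id)
    out.provenance = dict(doc.provenance)
    out.spectra = list(doc.spectra)
    out.modifications = list(doc.modifications)
    out.software = list(doc.software)
    out.cv_registry = list(doc.cv_registry)
    out.predictions = [
        p for p in doc.predictions
        if mode(c.satisfied_by(p) for c in constraints)
    ]
    return out


def run_query(doc: Document, sparql_text: str):
    """Run a SPARQL SELECT over the document's RDF graph.

    Returns ``(variable names, rows)`` where each row is a tuple of terms.
    """
    from .rdf import to_graph

    g = to_graph(doc)
    try:
        result = g.query(sparql_text)
    except Exception as e:  # rdflib raises several parser exception types
        raise QueryError(f"SPARQL query failed: {e}") from None
    variables = [str(v) for v in (result.vars or [])]
    rows = [tuple(row) for row in result]
    return variables, rows


# ---------------------------------------------------------------------------
# Consensus


@dataclass
class ConsensusParams:
    """Settings for cross-tool consensus construction."""

    min_agreement: int = 2
    equivalence: str = "strict"  # strict | IL_equivalent
    gap_tolerance_da: float = 0.01
    gap_aware: bool = False
    max_rank: int = 1  # compare top-ranked candidates only, by default
    score_aggregation: str = "mean_normalized_rank"

    def __post_init__(self):
        if self.min_agreement < 2:
            raise StructuralError("min_agreement must be at least 2")
        if self.equivalence not in ("strict", "IL_equivalent"):
            raise StructuralError(f"unknown equivalence mode {self.equivalence!r}")


def _sequence_key(seq: Sequence, mods: Dict, il_equivalent: bool) -> tuple:
    """Canonical hashable form of a sequence under the chosen equivalence."""
    key = []
    for el in seq.elements:
        if isinstance(el, GapElement):
            key.append(("gap", round(el.mass, 5)))
        elif isinstance(el, ModifiedAminoAcidElement):
            mod = mods.get(el.modification_ref)
            acc = mod.psimod_accession if mod is not None else el.modification_ref
            residue = el.residue
            if il_equivalent and residue == "I":
                residue = "L"
            key.append(("mod", residue, acc))
        else:
            residue = el.residue
            if il_equivalent and residue == "I":
                residue = "L"
            key.append(("aa", residue))
    return tuple(key)


def _gap_aware_equal(a: Sequence, b: Sequence, mods_a, mods_b,
                     il: bool, tol: float) -> bool:
    """Equality where a gap may stand in for a residue run of matching mass."""

    def masses(seq, mods):
        out = []
        for el in seq.elements:
            if isinstance(el, GapElement):
                out.append(("gap", el.mass))
            elif isinstance(el, ModifiedAminoAcidElement):
                mod = mods.get(el.modification_ref)
                delta = mod.mono_mass_delta if mod is not None else 0.0
                out.append(("res", residue_mono_mass(el.residue) + delta))
            else:
                out.append(("res", residue_mono_mass(el.residue)))
        return out

    ma, mb = masses(a, mods_a), masses(b, mods_b)

    def match(i, j):
        if i == len(ma) and j == len(mb):
            return True
        if i < len(ma) and ma[i][0] == "gap":
            # consume a run of residues (or a gap) on the other side
            total = 0.0
            jj = j
            while jj <= len(mb):
                if abs(total - ma[i][1]) <= tol and match(i + 1, jj):
                    return True
                if jj == len(mb):
                    break
                total += mb[jj][1]
                jj += 1
            return False
        if j < len(mb) and mb[j][0] == "gap":
            total = 0.0
            ii = i
            while ii <= len(ma):
                if abs(total - mb[j][1]) <= tol and match(ii, j + 1):
                    return True
                if ii == len(ma):
                    break
                total += ma[ii][1]
                ii += 1
            return False
        if i < len(ma) and j < len(mb):
            ea, eb = a.elements[i], b.elements[j]
            ra = getattr(ea, "residue", None)
            rb = getattr(eb, "residue", None)
            if ra is None or rb is None:
                return False
            if il:
                ra = "L" if ra == "I" else ra
                rb = "L" if rb == "I" else rb
            if ra != rb:
                return False
            return match(i + 1, j + 1)
        return False

    return match(0, 0)


def _spectrum_match_key(s, position: int) -> str:
    if s.native_id:
        return f"title:{s.native_id}"
    return f"index:{position}"


def _top_predictions(doc: Document, spectrum_id: str, max_rank: int) -> List[Prediction]:
    preds = doc.predictions_for_spectrum(spectrum_id)
    return [p for p in preds if (p.rank or 1) <= max_rank]


def consensus(
    docs: TSequence[Document],
    params: Optional[ConsensusParams] = None,
) -> Tuple[Document, List[str]]:
    """Combine per-tool documents into a consensus document.

    Returns the consensus document and a list of warnings (e.g. spectra that
    could not be matched across inputs). The output is itself a valid DNMSO
    document: every consensus prediction is sourced from the matched
    spectrum (taken from the first document that carries it) and scored with
    ``agreement_count`` and ``mean_normalized_rank``.
    """
    params = params or ConsensusParams()
    if len(docs) < 2:
        raise StructuralError("consensus needs at least two documents")
    warnings: List[str] = []
    il = params.equivalence == "IL_equivalent"

    out = create_document({"creator": "dnmso-consensus"})
    sw_id = out.add_software(Software(id="dnmso-consensus", name="dnmso-consensus",
                                      version="1.0"))

    # group spectra across documents
    groups: Dict[str, List[Tuple[int, object]]] = {}
    order: List[str] = []
    for doc_idx, doc in enumerate(docs):
        for pos, s in enumerate(doc.spectra):
            key = _spectrum_match_key(s, pos)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((doc_idx, s))

    seen_mods = set()
    for key in order:
        members = groups[key]
        present_docs = {doc_idx for doc_idx, _ in members}
        if len(present_docs) < 2:
            warnings.append(f"spectrum {key} present in only one document; skipped")
            continue

        # candidate top predictions per tool
        per_tool: List[Tuple[int, Prediction]] = []
        for doc_idx, s in members:
            for p in _top_predictions(docs[doc_idx], s.id, params.max_rank):
                per_tool.append((doc_idx, p))
        if not per_tool:
            continue

        # equivalence classes
        classes: List[List[Tuple[int, Prediction]]] = []
        if params.gap_aware:
            for doc_idx, p in per_tool:
                placed = False
                for cls in classes:
                    ref_idx, ref = cls[0]
                    if _gap_aware_equal(
                        p.sequence, ref.sequence,
                        docs[doc_idx].modification_map(),
                        docs[ref_idx].modification_map(),
                        il, params.gap_tolerance_da,
                    ):
                        cls.append((doc_idx, p))
                        placed = True
                        break
                if not placed:
                    classes.append([(doc_idx, p)])
        else:
            by_key: Dict[tuple, List[Tuple[int, Prediction]]] = {}
            for doc_idx, p in per_tool:
                k = _sequence_key(p.sequence, docs[doc_idx].modification_map(), il)
                by_key.setdefault(k, []).append((doc_idx, p))
            classes = list(by_key.values())

        # agreement counts distinct tools, not candidate rows
        def tool_count(cls):
            return len({doc_idx for doc_idx, _ in cls})

        best, best_count = None, -1
        for cls in classes:  # first class wins ties (deterministic)
            c = tool_count(cls)
            if c > best_count:
                best, best_count = cls, c
        if best is None or best_count < params.min_agreement:
            continue

        rep_idx, rep = best[0]
        spectrum = next(s for doc_idx, s in members if doc_idx == rep_idx)
        if not out.has_spectrum(spectrum.id):
            out.add_spectrum(spectrum)
        for el in rep.sequence.elements:
            if isinstance(el, ModifiedAminoAcidElement):
                mod = docs[rep_idx].modification_map().get(el.modification_ref)
                if mod is not None and mod.local_id not in seen_mods:
                    out.add_modification(mod)
                    seen_mods.add(mod.local_id)
        per_tool_best: Dict[int, int] = {}
        for doc_idx, p in best:
            rank = p.rank or 1
            if doc_idx not in per_tool_best or rank < per_tool_best[doc_idx]:
                per_tool_best[doc_idx] = rank
        mean_norm_rank = sum(1.0 / r for r in per_tool_best.values()) / len(per_tool_best)
        out.add_prediction(Prediction(
            sequence=Sequence(list(rep.sequence.elements)),
            scores=[
                Score("agreement_count", float(tool_count(best))),
                Score("mean_normalized_rank", mean_norm_rank),
            ],
            source_spectrum_refs=[spectrum.id],
            software_ref=sw_id,
            rank=1,
        ))

    return out, warnings
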