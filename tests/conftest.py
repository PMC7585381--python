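import random
from pathlib import Path

import pytest

from dnmso import (
    Document,
    Peak,
    Prediction,
    Score,
    Spectrum,
    create_document,
    load_psimod_subset,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mod_table():
    return load_psimod_subset()


@pytest.fixture()
def data_dir() -> Path:
    return DATA_DIR


def make_spectrum(sid=None, mz=500.25, charge=2, peaks=((100.1, 200.0), (250.5, 1500.0), (380.2, 90.5)), **kw):
    return Spectrum(
        id=sid,
        precursor_mz=mz,
        precursor_charge=charge,
        peaks=[Peak(m, i) for m, i in peaks],
        **kw,
    )


@pytest.fixture()
def small_doc() -> Document:
    """One inline spectrum, two predictions sharing it."""
    from dnmso import AminoAcidElement, Sequence

    doc = create_document({"creator": "test"})
    sid = doc.add_spectrum(make_spectrum())
    for rank, score in ((1, 0.9), (2, 0.4)):
        doc.add_prediction(Prediction(
            sequence=Sequence([AminoAcidElement(r) for r in "PEPTIDE"]),
            scores=[Score("score", score)],
            source_spectrum_refs=[sid],
            rank=rank,
        ))
    return doc


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240501)
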