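"""Reading MS/MS spectra (MGF, mzML, mzXML) and the inline CSV peak format.

Only MS-level-2 scans are of interest here; MS1 handling, vendor raw formats
and peak picking are out of scope. Readers normalize peak order (stable sort
by m/z) so every yielded :class:`~dnmso.model.Spectrum` satisfies the model
invariants regardless of input ordering.

The CSV representation is what makes a document self-contained: one
``mz,intensity`` line per peak at full precision (``repr`` round-trip exact),
preceded by ``#key=value`` comment lines carrying id, precursor m/z, charge
and optional metadata.
"""

from __future__ import annotations

import io
import logging
import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, List, Optional, Union

from .errors import SpectraParseError, TruncationError
from .model import Peak, Spectrum

log = logging.getLogger("dnmso.spectra")


@dataclass
class SpectrumSource:
    """A declared spectra input: a path or stream plus its format."""

    path_or_stream: Union[str, os.PathLike, io.IOBase]
    format: str = ""  # MGF | mzML | mzXML | CSV; "" = detect from suffix
    dialect_notes: str = ""

    def detect_format(self) -> str:
        if self.format:
            return self.format
        path = str(self.path_or_stream)
        suffix = path.rsplit(".", 1)[-1].lower()
        mapping = {"mgf": "MGF", "mzml": "mzML", "mzxml": "mzXML", "csv": "CSV"}
        if suffix not in mapping:
            raise SpectraParseError(f"cannot detect spectra format of {path!r}")
        return mapping[suffix]

    def read(self) -> Iterator[Spectrum]:
        fmt = self.detect_format()
        reader = {
            "MGF": read_mgf,
            "mzML": read_mzml,
            "mzXML": read_mzxml,
        }.get(fmt)
        if reader is None:
            raise SpectraParseError(f"no reader for spectra format {fmt!r}")
        return reader(self.path_or_stream)


def _open_text(source):
    if hasattr(source, "read"):
        return source, False
    return open(source, "r", encoding="utf-8"), True


def _sorted_peaks(pairs) -> List[Peak]:
    return [Peak(mz, inten) for mz, inten in sorted(pairs, key=lambda t: t[0])]


# ---------------------------------------------------------------------------
# MGF

def read_mgf(source) -> Iterator[Spectrum]:
    """Iterate over the scans of a Mascot Generic Format peak list.

    TITLE becomes the spectrum's native id, the first PEPMASS token the
    precursor m/z, and ``CHARGE=2+`` a charge of 2. A missing CHARGE (or an
    ambiguous list such as ``2+ and 3+``) leaves the charge unknown. A block
    that is never closed by END IONS raises :class:`TruncationError` naming
    the block index; a non-numeric peak line names its line number.
    """
    fh, owned = _open_text(source)
    try:
        yield from _parse_mgf(fh)
    finally:
        if owned:
            fh.close()


def _parse_charge(raw: str) -> Optional[int]:
    raw = raw.strip()
    if not raw:
        return None
    if "and" in raw or "," in raw:
        warnings.warn(f"ambiguous MGF charge list {raw!r}; charge left unknown")
        return None
    sign = -1 if raw.endswith("-") else 1
    digits = raw.rstrip("+-")
    try:
        value = sign * int(digits)
    except ValueError:
        return None
    return value if value > 0 else None

def _parse_mgf(fh) -> Iterator[Spectrum]:
    in_block = False
    block_index = -1
    headers = {}
    pairs = []
    for lineno, raw in enumerate(fh, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise TruncationError(
                    f"block {block_index}: BEGIN IONS before END IONS (line {lineno})"
                )
            in_block = True
            block_index += 1
            headers, pairs = {}, []
        elif line == "END IONS":
            if not in_block:
                raise SpectraParseError(f"line {lineno}: END IONS without BEGIN IONS")
            in_block = False
            yield _mgf_block_to_spectrum(headers, pairs)
        elif in_block:
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                headers[key.upper()] = value.strip()
            else:
                fields = line.replace(",", " ").split()
                try:
                    mz = float(fields[0])
                    inten = float(fields[1]) if len(fields) > 1 else 0.0
                except (ValueError, IndexError):
                    raise SpectraParseError(
                        f"line {lineno}: malformed peak line {line!r}"
                    ) from None
                pairs.append((mz, inten))
        # lines outside blocks other than headers are ignored (MGF allows
        # global parameters; they do not affect the per-scan contract here)
    if in_block:
        raise TruncationError(f"block {block_index}: file ended before END IONS")


def _mgf_block_to_spectrum(headers, pairs) -> Spectrum:
    precursor_mz = None
    if "PEPMASS" in headers:
        try:
            precursor_mz = float(headers["PEPMASS"].split()[0])
        except (ValueError, IndexError):
            precursor_mz = None
    charge = _parse_charge(headers.get("CHARGE", ""))
    rt = None
    if "RTINSECONDS" in headers:
        try:
            rt = float(headers["RTINSECONDS"])
        except ValueError:
            rt = None
    return Spectrum(
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=_sorted_peaks(pairs),
        retention_time_s=rt,
        native_id=headers.get("TITLE") or None,
    )


# ---------------------------------------------------------------------------
# mzML / mzXML. Compact readers on lxml: MS2 scans only, native scan id
# preserved, base64-encoded float arrays (64- or 32-bit, plain or zlib).


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_floats(b64_text: str, bits: int, byte_order: str, compressed: bool):
    import base64
    import struct
    import zlib

    raw = base64.b64decode(b64_text.encode("ascii"))
    if compressed:
        raw = zlib.decompress(raw)
    fmt_char = "d" if bits == 64 else "f"
    count = len(raw) // (bits // 8)
    return struct.unpack(f"{byte_order}{count}{fmt_char}", raw)


def _parse_xml(source):
    from lxml import etree

    try:
        return etree.parse(source if hasattr(source, "read") else str(source))
    except etree.XMLSyntaxError as e:
        raise SpectraParseError(f"malformed XML: {e}") from None


def read_mzml(source) -> Iterator[Spectrum]:
    """Yield the MS-level-2 scans of an mzML 1.1 file.

    The scan's mzML ``id`` attribute is preserved as the native id; precursor
    m/z and charge are taken from the first selected ion when present
    (missing precursor -> warning, unknown). Peak arrays may be 64- or
    32-bit floats, plain or zlib-compressed.
    """
    tree = _parse_xml(source)
    for spec_el in tree.iter():
        if _local(spec_el.tag) != "spectrum":
            continue
        params = {
            el.get("accession"): el.get("value")
            for el in spec_el.iter() if _local(el.tag) == "cvParam"
        }
        if params.get("MS:1000511") != "2":  # ms level
            continue
        native_id = spec_el.get("id")
        precursor_mz = None
        charge = None
        for ion in spec_el.iter():
            if _local(ion.tag) != "selectedIon":
                continue
            ion_params = {
                el.get("accession"): el.get("value")
                for el in ion if _local(el.tag) == "cvParam"
            }
            if "MS:1000744" in ion_params:  # selected ion m/z
                precursor_mz = float(ion_params["MS:1000744"])
            if "MS:1000041" in ion_params:  # charge state
                charge = int(ion_params["MS:1000041"])
            break
        if precursor_mz is None:
            warnings.warn(f"MS2 scan {native_id!r} has no precursor; left unknown")
        arrays = {}
        for arr_el in spec_el.iter():
            if _local(arr_el.tag) != "binaryDataArray":
                continue
            accs = {
                el.get("accession")
                for el in arr_el.iter() if _local(el.tag) == "cvParam"
            }
            binary = next(
                (el for el in arr_el.iter() if _local(el.tag) == "binary"), None)
            if binary is None or not (binary.text or "").strip():
                continue
            values = _decode_floats(
                binary.text.strip(),
                bits=32 if "MS:1000521" in accs else 64,
                byte_order="<",
                compressed="MS:1000574" in accs,
            )
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        yield _arrays_to_spectrum(arrays.get("mz"), arrays.get("intensity"),
                                  native_id, precursor_mz, charge)


def read_mzxml(source) -> Iterator[Spectrum]:
    """Yield the MS-level-2 scans of an mzXML 3.x file.

    The scan number becomes the native id; peaks are interleaved
    m/z-intensity floats in the byte order the file declares.
    """
    tree = _parse_xml(source)
    for scan_el in tree.iter():
        if _local(scan_el.tag) != "scan":
            continue
        if scan_el.get("msLevel") != "2":
            continue
        native_id = str(scan_el.get("num"))
        precursor_mz = None
        charge = None
        peaks_text = None
        bits, byte_order, compressed = 64, ">", False
        for child in scan_el:
            tag = _local(child.tag)
            if tag == "precursorMz":
                try:
                    precursor_mz = float(child.text)
                except (TypeError, ValueError):
                    precursor_mz = None
                if child.get("precursorCharge"):
                    charge = int(child.get("precursorCharge"))
            elif tag == "peaks":
                peaks_text = (child.text or "").strip()
                bits = int(child.get("precision", "64"))
                byte_order = ">" if child.get("byteOrder", "network") == "network" else "<"
                compressed = child.get("compressionType", "none") == "zlib"
        if precursor_mz is None:
            warnings.warn(f"MS2 scan {native_id!r} has no precursor; left unknown")
        mz_values, int_values = [], []
        if peaks_text:
            flat = _decode_floats(peaks_text, bits, byte_order, compressed)
            mz_values, int_values = flat[0::2], flat[1::2]
        yield _arrays_to_spectrum(mz_values, int_values, native_id,
                                  precursor_mz, charge)


def _arrays_to_spectrum(mz_array, intensity_array, native_id, precursor_mz, charge):
    pairs = []
    if mz_array is not None and intensity_array is not None:
        pairs = list(zip((float(x) for x in mz_array),
                         (float(y) for y in intensity_array)))
    if not pairs:
        warnings.warn(f"MS2 scan {native_id!r} has an empty peak list")
    return Spectrum(
        precursor_mz=precursor_mz,
        precursor_charge=charge,
        peaks=_sorted_peaks(pairs),
        native_id=native_id,
    )


# ---------------------------------------------------------------------------
# Inline CSV representation

def spectrum_to_csv(s: Spectrum) -> str:
    """Render a spectrum's inline peaks as the DNMSO CSV dialect.

    Comma separator, '.' decimal point, LF line endings; peak values are
    written with ``repr`` so that parsing them back is bit-exact. Metadata
    travels in ``#key=value`` comment lines.
    """
    if not s.peaks:
        raise SpectraParseError("spectrum has no inline peaks to render as CSV")
    lines = []
    if s.id is not None:
        lines.append(f"#id={s.id}")
    if s.native_id is not None:
        lines.append(f"#native_id={s.native_id}")
    if s.precursor_mz is not None:
        lines.append(f"#precursor_mz={s.precursor_mz!r}")
    if s.precursor_charge is not None:
        lines.append(f"#charge={s.precursor_charge}")
    if s.retention_time_s is not None:
        lines.append(f"#retention_time_s={s.retention_time_s!r}")
    if s.fragmentation is not None:
        lines.append(f"#fragmentation={s.fragmentation}")
    for pk in s.peaks:
        lines.append(f"{pk.mz!r},{pk.intensity!r}")
    return "\n".join(lines) + "\n"


def csv_to_spectrum(text: str) -> Spectrum:
    """Parse the DNMSO CSV dialect back into a spectrum.

    Unsorted rows are normalized (stable sort by m/z); ragged rows and
    negative intensities are rejected with the offending row number.
    """
    meta = {}
    pairs = []
    for rowno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            continue
        fields = line.split(",")
        if len(fields) != 2:
            raise SpectraParseError(
                f"row {rowno}: expected 'mz,intensity', got {line!r}"
            )
        try:
            mz, inten = float(fields[0]), float(fields[1])
        except ValueError:
            raise SpectraParseError(f"row {rowno}: non-numeric value in {line!r}") from None
        if mz <= 0:
            raise SpectraParseError(f"row {rowno}: m/z must be > 0")
        if inten < 0:
            raise SpectraParseError(f"row {rowno}: negative intensity")
        pairs.append((mz, inten))
    s = Spectrum(
        id=meta.get("id"),
        native_id=meta.get("native_id"),
        precursor_mz=float(meta["precursor_mz"]) if "precursor_mz" in meta else None,
        precursor_charge=int(meta["charge"]) if "charge" in meta else None,
        retention_time_s=(
            float(meta["retention_time_s"]) if "retention_time_s" in meta else None
        ),
        fragmentation=meta.get("fragmentation"),
        peaks=_sorted_peaks(pairs),
    )
    return s
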