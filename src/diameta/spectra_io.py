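"""Readers and writers for the standard formats the pipeline touches.

mzML 1.1 (read + write of the subset the pipeline needs), MGF peak lists,
FASTA protein databases, and the annotation TSV. All m/z values are in
Thomson; retention times are converted to seconds on read.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .model import (
    DiaWindowScheme,
    ProteinRecord,
    Pseudospectrum,
    SpectraRun,
    SpectrumRecord,
)

# PSI-MS controlled-vocabulary accessions used by the reader/writer.
_CV_MS_LEVEL = "MS:1000511"
_CV_CENTROID = "MS:1000127"
_CV_PROFILE = "MS:1000128"
_CV_SCAN_START = "MS:1000016"
_CV_ISO_TARGET = "MS:1000827"
_CV_ISO_LOWER = "MS:1000828"
_CV_ISO_UPPER = "MS:1000829"
_CV_MZ_ARRAY = "MS:1000514"
_CV_INT_ARRAY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_NO_COMPRESSION = "MS:1000576"
_CV_ZLIB = "MS:1000574"


class MzmlParseError(ValueError):
    """Raised for malformed or unsupported mzML input."""


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(text: str, dtype: str, compressed: bool) -> np.ndarray:
    raw = base64.b64decode(text.encode("ascii")) if text else b""
    if compressed:
        raw = zlib.decompress(raw)
    fmt = "d" if dtype == "f64" else "f"
    n = len(raw) // struct.calcsize(fmt)
    return np.array(struct.unpack(f"<{n}{fmt}", raw), dtype=float)


def _parse_spectrum(elem: ET.Element) -> SpectrumRecord:
    ms_level: int | None = None
    rt: float | None = None
    centroided = False
    profile = False
    iso_target = iso_lower = iso_upper = None
    mz: np.ndarray | None = None
    intensity: np.ndarray | None = None

    for cv in elem.iter():
        if _localname(cv.tag) != "cvParam":
            continue
        acc = cv.get("accession", "")
        if acc == _CV_MS_LEVEL:
            ms_level = int(cv.get("value", "0"))
        elif acc == _CV_CENTROID:
            centroided = True
        elif acc == _CV_PROFILE:
            profile = True

    for scan in elem.iter():
        if _localname(scan.tag) != "scan":
            continue
        for cv in scan:
            if _localname(cv.tag) == "cvParam" and cv.get("accession") == _CV_SCAN_START:
                value = float(cv.get("value", "0"))
                unit = cv.get("unitName", "second")
                rt = value * 60.0 if unit.startswith("minute") else value
        break

    for iso in elem.iter():
        if _localname(iso.tag) != "isolationWindow":
            continue
        for cv in iso:
            if _localname(cv.tag) != "cvParam":
                continue
            acc = cv.get("accession")
            if acc == _CV_ISO_TARGET:
                iso_target = float(cv.get("value", "0"))
            elif acc == _CV_ISO_LOWER:
                iso_lower = float(cv.get("value", "0"))
            elif acc == _CV_ISO_UPPER:
                iso_upper = float(cv.get("value", "0"))
        break

    for bda in elem.iter():
        if _localname(bda.tag) != "binaryDataArray":
            continue
        dtype = "f64"
        compressed = False
        kind = None
        text = ""
        for cv in bda:
            name = _localname(cv.tag)
            if name == "cvParam":
                acc = cv.get("accession")
                if acc == _CV_F64:
                    dtype = "f64"
                elif acc == _CV_F32:
                    dtype = "f32"
                elif acc == _CV_ZLIB:
                    compressed = True
                elif acc == _CV_NO_COMPRESSION:
                    compressed = False
                elif acc == _CV_MZ_ARRAY:
                    kind = "mz"
                elif acc == _CV_INT_ARRAY:
                    kind = "intensity"
            elif name == "binary":
                text = cv.text or ""
        values = _decode_binary(text, dtype, compressed)
        if kind == "mz":
            mz = values
        elif kind == "intensity":
            intensity = values

    if ms_level is None:
        raise MzmlParseError("spectrum lacks an 'ms level' cvParam")
    if profile and not centroided:
        raise MzmlParseError(
            "profile-mode spectrum encountered: centroid required"
        )
    if rt is None:
        raise MzmlParseError("spectrum lacks a 'scan start time' cvParam")
    if mz is None or intensity is None:
        mz = mz if mz is not None else np.empty(0)
        intensity = intensity if intensity is not None else np.empty(0)

    window = None
    if ms_level == 2:
        if iso_target is None or iso_lower is None or iso_upper is None:
            raise MzmlParseError(
                "MS2 spectrum lacks isolation-window metadata "
                "(target/lower offset/upper offset)"
            )
        window = (round(iso_target - iso_lower, 6), round(iso_target + iso_upper, 6))

    return SpectrumRecord(
        ms_level=ms_level,
        retention_time=rt,
        mz=mz,
        intensity=intensity,
        precursor_window=window,
    )


def _infer_scheme(windows: list[tuple[float, float]]) -> DiaWindowScheme:
    if not windows:
        return DiaWindowScheme(start=0.0, end=0.0, width=1.0, windows=())
    uniq = sorted(set(windows))
    widths = [round(u - l, 6) for l, u in uniq]
    width = max(set(widths), key=widths.count)
    return DiaWindowScheme(
        start=uniq[0][0], end=uniq[-1][1], width=width, windows=tuple(uniq)
    )


def read_mzml(path: str | Path) -> SpectraRun:
    """Parse an mzML file into a :class:`SpectraRun`.

    The window scheme is inferred from the observed MS2 isolation windows.
    Profile-mode spectra and MS2 spectra without isolation-window metadata
    are rejected.
    """
    path = Path(path)
    spectra: list[SpectrumRecord] = []
    run_id = path.stem
    try:
        for event, elem in ET.iterparse(str(path), events=("end",)):
            name = _localname(elem.tag)
            if name == "run":
                run_id = elem.get("id", run_id)
            if name != "spectrum":
                continue
            spectra.append(_parse_spectrum(elem))
            elem.clear()
    except ET.ParseError as exc:
        line, col = exc.position
        offset = _byte_offset(path, line, col)
        raise MzmlParseError(
            f"malformed mzML in {path}: {exc.msg} at byte offset {offset} "
            f"(line {line}, column {col})"
        ) from exc

    scheme = _infer_scheme(
        [s.precursor_window for s in spectra if s.precursor_window is not None]
    )
    return SpectraRun(run_id=run_id, spectra=spectra, window_scheme=scheme)


def _byte_offset(path: Path, line: int, col: int) -> int:
    offset = 0
    with open(path, "rb") as fh:
        for i, raw in enumerate(fh, start=1):
            if i == line:
                return offset + col
            offset += len(raw)
    return offset


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: SpectraRun, path: str | Path) -> None:
    """Serialize a run as minimal mzML 1.1 (64-bit, uncompressed arrays)."""
    path = Path(path)
    lines: list[str] = []
    lines.append('<?xml version="1.0" encoding="utf-8"?>')
    lines.append('<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">')
    lines.append(f'  <run id="{run.run_id}">')
    lines.append(f'    <spectrumList count="{len(run.spectra)}">')
    for i, s in enumerate(run.spectra):
        lines.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{s.n_peaks}">'
        )
        lines.append(
            f'        <cvParam cvRef="MS" accession="{_CV_MS_LEVEL}" '
            f'name="ms level" value="{s.ms_level}"/>'
        )
        lines.append(
            f'        <cvParam cvRef="MS" accession="{_CV_CENTROID}" '
            'name="centroid spectrum" value=""/>'
        )
        lines.append('        <scanList count="1"><scan>')
        lines.append(
            f'          <cvParam cvRef="MS" accession="{_CV_SCAN_START}" '
            f'name="scan start time" value="{s.retention_time:.6f}" '
            'unitName="second"/>'
        )
        lines.append("        </scan></scanList>")
        if s.precursor_window is not None:
            lower, upper = s.precursor_window
            target = (lower + upper) / 2.0
            half = (upper - lower) / 2.0
            lines.append('        <precursorList count="1"><precursor>')
            lines.append("          <isolationWindow>")
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_ISO_TARGET}" '
                f'name="isolation window target m/z" value="{target:.6f}"/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_ISO_LOWER}" '
                f'name="isolation window lower offset" value="{half:.6f}"/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_ISO_UPPER}" '
                f'name="isolation window upper offset" value="{half:.6f}"/>'
            )
            lines.append("          </isolationWindow>")
            lines.append("        </precursor></precursorList>")
        lines.append('        <binaryDataArrayList count="2">')
        for kind_acc, kind_name, values in (
            (_CV_MZ_ARRAY, "m/z array", s.mz),
            (_CV_INT_ARRAY, "intensity array", s.intensity),
        ):
            b64 = _b64(values)
            lines.append(f'          <binaryDataArray encodedLength="{len(b64)}">')
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_F64}" '
                'name="64-bit float" value=""/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{_CV_NO_COMPRESSION}" '
                'name="no compression" value=""/>'
            )
            lines.append(
                f'            <cvParam cvRef="MS" accession="{kind_acc}" '
                f'name="{kind_name}" value=""/>'
            )
            lines.append(f"            <binary>{b64}</binary>")
            lines.append("          </binaryDataArray>")
        lines.append("        </binaryDataArrayList>")
        lines.append("      </spectrum>")
    lines.append("    </spectrumList>")
    lines.append("  </run>")
    lines.append("</mzML>")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# MGF


def write_mgf(pseudospectra: Iterable[Pseudospectrum], path: str | Path) -> None:
    """Write pseudospectra as an MGF peak list.

    Each spectrum must carry at least one fragment; spectra without
    fragments are rejected upstream and never reach serialization.
    """
    path = Path(path)
    blocks: list[str] = []
    for ps in pseudospectra:
        if ps.n_fragments == 0:
            raise ValueError("pseudospectrum with 0 fragments cannot be serialized")
        lines = [
            "BEGIN IONS",
            f"TITLE={ps.provenance}",
            f"PEPMASS={ps.precursor_mz:.6f}",
            f"CHARGE={ps.charge}+",
            f"RTINSECONDS={ps.rt:.4f}",
            f"#COMPLEMENTARY={ps.n_complementary}",
        ]
        for mz, inten in zip(ps.fragment_mz, ps.fragment_intensity):
            lines.append(f"{mz:.6f} {inten:.4f}")
        lines.append("END IONS")
        blocks.append("\n".join(lines))
    path.write_text("\n\n".join(blocks) + ("\n" if blocks else ""))


def read_mgf(path: str | Path) -> list[Pseudospectrum]:
    """Read an MGF file written by :func:`write_mgf`."""
    out: list[Pseudospectrum] = []
    in_block = False
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line == "BEGIN IONS":
            in_block, header, peaks = True, {}, []
        elif line == "END IONS":
            mzs, intens = zip(*sorted(peaks)) if peaks else ((), ())
            out.append(
                Pseudospectrum(
                    precursor_mz=float(header.get("PEPMASS", "0")),
                    charge=int(header.get("CHARGE", "2+").rstrip("+")),
                    rt=float(header.get("RTINSECONDS", "0")),
                    fragment_mz=tuple(mzs),
                    fragment_intensity=tuple(intens),
                    provenance=header.get("TITLE", ""),
                    n_complementary=int(header.get("#COMPLEMENTARY", "0")),
                )
            )
            in_block = False
        elif in_block:
            if line.startswith("#COMPLEMENTARY"):
                key, _, value = line.partition("=")
                header[key] = value
            elif "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                header[key] = value
            else:
                parts = line.split()
                peaks.append((float(parts[0]), float(parts[1])))
    return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; the record ID is the header token up to the
    first whitespace. Duplicate IDs and empty sequences are errors."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id in FASTA: {pid!r}")
        seen.add(pid)
        records.append(ProteinRecord(protein_id=pid, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Annotation table


class AnnotationTable:
    """protein_id -> {phylum, genus, function}; missing lookups return None."""

    RANKS = ("phylum", "genus", "function")

    def __init__(self, entries: dict[str, dict[str, str]] | None = None) -> None:
        self._entries = entries or {}

    def lookup(self, protein_id: str, rank: str) -> str | None:
        if rank not in self.RANKS:
            raise KeyError(f"unknown rank {rank!r}; expected one of {self.RANKS}")
        entry = self._entries.get(protein_id)
        if entry is None:
            return None
        return entry.get(rank) or None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._entries


def read_annotations(path: str | Path) -> AnnotationTable:
    """Read a TSV with columns protein_id, phylum, genus, kegg_category.

    Empty cells mean "unannotated at that rank".
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"protein_id", "phylum", "genus", "kegg_category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation TSV missing columns: {sorted(missing)}")
    entries: dict[str, dict[str, str]] = {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        if pid in entries:
            raise ValueError(f"duplicate protein id in annotation TSV: {pid!r}")
        entries[pid] = {
            "phylum": row.phylum,
            "genus": row.genus,
            "function": row.kegg_category,
        }
    return AnnotationTable(entries)


def write_annotations(
    rows: Iterable[tuple[str, str, str, str]], path: str | Path
) -> None:
    """Write (protein_id, phylum, genus, kegg_category) rows as TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\tphylum\tgenus\tkegg_category\n")
        for pid, phylum, genus, kegg in rows:
            fh.write(f"{pid}\t{phylum}\t{genus}\t{kegg}\n")
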