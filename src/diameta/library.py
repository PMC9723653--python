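"""Pseudospectral library assembly and the library TSV dialect."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

from .masses import PROTON
from .model import LibraryEntry, PeptideMatch, Pseudospectrum
from .search import peptide_neutral_mass, strip_modifications

MAX_LIBRARY_FRAGMENTS = 6
MIN_LIBRARY_FRAGMENTS = 3

_COLUMNS = (
    "peptide",
    "charge",
    "precursor_mz",
    "reference_rt",
    "fragment_mz",
    "fragment_intensity",
    "protein_ids",
)


def build_library(
    accepted: Sequence[PeptideMatch],
    pseudospectra: Sequence[Pseudospectrum] | None = None,
    max_fragments: int = MAX_LIBRARY_FRAGMENTS,
    min_fragments: int = MIN_LIBRARY_FRAGMENTS,
) -> list[LibraryEntry]:
    """Build one library entry per (peptide, charge) from accepted matches.

    The best-scoring supporting match wins; its matched theoretical ions
    become the entry's fragments (top ``max_fragments`` by intensity,
    normalized to max 1). Matches with fewer than ``min_fragments``
    matched ions are excluded.
    """
    best: dict[tuple[str, int], PeptideMatch] = {}
    for m in accepted:
        if m.is_decoy:
            continue
        key = (m.peptide, m.charge)
        prev = best.get(key)
        if prev is None or (m.score, m.spectrum_id) > (prev.score, prev.spectrum_id):
            best[key] = m

    entries: list[LibraryEntry] = []
    for (peptide, charge), m in sorted(best.items()):
        if len(m.matched_peaks) < min_fragments:
            continue
        top = sorted(m.matched_peaks, key=lambda p: (-p[1], p[0]))[:max_fragments]
        top.sort(key=lambda p: p[0])
        peak_max = max(p[1] for p in top)
        mzs = tuple(p[0] for p in top)
        intensities = tuple(p[1] / peak_max for p in top)
        precursor_mz = peptide_neutral_mass(peptide) / charge + PROTON
        entries.append(
            LibraryEntry(
                peptide=peptide,
                charge=charge,
                precursor_mz=precursor_mz,
                reference_rt=m.rt,
                fragment_mz=mzs,
                fragment_intensity=intensities,
                protein_ids=m.protein_ids,
            )
        )
    return entries


def write_library(entries: Iterable[LibraryEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for e in entries:
            fh.write(
                f"{e.peptide}\t{e.charge}\t{e.precursor_mz:.6f}\t"
                f"{e.reference_rt:.4f}\t"
                f"{';'.join(f'{mz:.6f}' for mz in e.fragment_mz)}\t"
                f"{';'.join(f'{i:.4f}' for i in e.fragment_intensity)}\t"
                f"{';'.join(e.protein_ids)}\n"
            )


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read the library TSV dialect; malformed rows raise with line number."""
    entries: list[LibraryEntry] = []
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"empty library file: {path}")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != _COLUMNS:
        raise ValueError(f"unexpected library header in {path}: {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(_COLUMNS):
            raise ValueError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} columns, "
                f"got {len(parts)}"
            )
        peptide, charge, pmz, rt, fmz, fint, pids = parts
        entries.append(
            LibraryEntry(
                peptide=peptide,
                charge=int(charge),
                precursor_mz=float(pmz),
                reference_rt=float(rt),
                fragment_mz=tuple(float(x) for x in fmz.split(";")),
                fragment_intensity=tuple(float(x) for x in fint.split(";")),
                protein_ids=tuple(pids.split(";")) if pids else (),
            )
        )
    return entries


def library_overlap(
    a: Sequence[LibraryEntry],
    b: Sequence[LibraryEntry],
    strip_mods: bool = True,
) -> float:
    """Jaccard overlap of the peptide sets of two libraries."""

    def peptides(entries: Sequence[LibraryEntry]) -> set[str]:
        if strip_mods:
            return {strip_modifications(e.peptide) for e in entries}
        return {e.peptide for e in entries}

    pa, pb = peptides(a), peptides(b)
    union = pa | pb
    if not union:
        return 0.0
    return len(pa & pb) / len(union)
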