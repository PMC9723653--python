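"""Core domain types shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np


@dataclass(frozen=True)
class DiaWindowScheme:
    """Consecutive half-open DIA isolation windows covering [start, end).

    A precursor at exactly a window boundary belongs to the upper window;
    this makes window membership deterministic.
    """

    start: float
    end: float
    width: float
    windows: tuple[tuple[float, float], ...]

    @property
    def count(self) -> int:
        return len(self.windows)

    def window_for(self, mz: float) -> tuple[float, float] | None:
        """Return the (lower, upper) window containing ``mz``, or None."""
        if not (self.start <= mz < self.end):
            return None
        idx = int((mz - self.start) // self.width)
        idx = min(idx, len(self.windows) - 1)
        lower, upper = self.windows[idx]
        # guard against float edge effects at boundaries
        if mz < lower and idx > 0:
            idx -= 1
        elif mz >= upper and idx < len(self.windows) - 1:
            idx += 1
        lower, upper = self.windows[idx]
        if lower <= mz < upper:
            return (lower, upper)
        return None

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.windows)


def build_window_scheme(start: float, end: float, width: float) -> DiaWindowScheme:
    """Partition [start, end) into consecutive half-open windows of ``width``.

    The last window is truncated at ``end`` when the range is not an exact
    multiple of the width.
    """
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    windows: list[tuple[float, float]] = []
    lower = start
    while lower < end - 1e-9:
        upper = min(lower + width, end)
        windows.append((lower, upper))
        lower = upper
    return DiaWindowScheme(start=start, end=end, width=width, windows=tuple(windows))


@dataclass(frozen=True)
class SpectrumRecord:
    """One centroided spectrum: MS1 survey scan or windowed MS2 scan."""

    ms_level: int
    retention_time: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray
    precursor_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.ms_level not in (1, 2):
            raise ValueError(f"ms_level must be 1 or 2, got {self.ms_level}")
        if (self.ms_level == 2) != (self.precursor_window is not None):
            raise ValueError("precursor_window must be present iff ms_level == 2")
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and np.any(np.diff(mz) < 0):
            order = np.argsort(mz, kind="stable")
            mz = mz[order]
            inten = inten[order]
        if np.any(inten < 0):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


@dataclass
class SpectraRun:
    """A full DIA acquisition: time-ordered spectra plus the window scheme."""

    run_id: str
    spectra: list[SpectrumRecord]
    window_scheme: DiaWindowScheme

    def __post_init__(self) -> None:
        rts = [s.retention_time for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be ordered by non-decreasing retention time")
        known = set(self.window_scheme.windows)
        for s in self.spectra:
            if s.ms_level == 2 and s.precursor_window not in known:
                raise ValueError(
                    f"MS2 window {s.precursor_window} not in the run's window scheme"
                )

    def ms1_spectra(self) -> list[SpectrumRecord]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self, window: tuple[float, float]) -> list[SpectrumRecord]:
        return [
            s
            for s in self.spectra
            if s.ms_level == 2 and s.precursor_window == window
        ]

    @property
    def cycle_time(self) -> float:
        """Median spacing between consecutive MS1 scans (seconds)."""
        rts = np.array([s.retention_time for s in self.ms1_spectra()])
        if rts.size < 2:
            return 1.0
        return float(np.median(np.diff(rts)))


@dataclass(frozen=True)
class ProteinRecord:
    """A database protein: FASTA header token plus uppercase sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id!r} has an empty sequence")
        from .masses import PROTEIN_ALPHABET

        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r} contains non-standard residues {sorted(bad)}"
            )


@dataclass
class IonTrace:
    """A chromatographic feature: an m/z channel followed across scans."""

    mz: float  # intensity-weighted mean of member peaks
    scan_rts: np.ndarray
    intensities: np.ndarray
    source_level: int
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.scan_rts = np.asarray(self.scan_rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.scan_rts.shape != self.intensities.shape:
            raise ValueError("scan_rts and intensities must have equal length")
        if np.any(self.intensities <= 0):
            raise ValueError("trace intensities must be > 0")
        if (self.source_level == 2) != (self.window is not None):
            raise ValueError("window must be present iff source_level == 2")

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensities))

    @property
    def apex_rt(self) -> float:
        return float(self.scan_rts[self.apex_index])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities[self.apex_index])

    def __len__(self) -> int:
        return int(self.scan_rts.size)


@dataclass
class FragmentAssignment:
    """A fragment trace attached to a precursor group."""

    trace: IonTrace
    pearson_r: float
    apex_dt: float
    complementary: bool = False


@dataclass
class PrecursorGroup:
    """An MS1 precursor trace with its correlated fragment traces."""

    precursor: IonTrace
    charge: int
    neutral_mass: float
    fragments: list[FragmentAssignment] = field(default_factory=list)


@dataclass(frozen=True)
class Pseudospectrum:
    """A DDA-like spectrum deconvolved from DIA data."""

    precursor_mz: float
    charge: int
    rt: float
    fragment_mz: tuple[float, ...]
    fragment_intensity: tuple[float, ...]
    provenance: str  # "<run_id>:<group index>"
    n_complementary: int = 0

    def __post_init__(self) -> None:
        if len(self.fragment_mz) != len(self.fragment_intensity):
            raise ValueError("fragment m/z and intensity lists must have equal length")
        if any(b < a for a, b in zip(self.fragment_mz, self.fragment_mz[1:])):
            raise ValueError("fragment m/z must be sorted ascending")

    @property
    def n_fragments(self) -> int:
        return len(self.fragment_mz)


@dataclass
class PeptideMatch:
    """A peptide-to-pseudospectrum match with FDR bookkeeping."""

    spectrum_id: str
    peptide: str  # modified sequence, e.g. "PEPTM(ox)IDEK"
    charge: int
    score: float
    is_decoy: bool
    protein_ids: tuple[str, ...]
    rt: float = 0.0
    precursor_mz: float = 0.0
    q_value: float = 1.0
    matched_peaks: tuple[tuple[float, float, str], ...] = ()
    # matched_peaks entries: (observed m/z, observed intensity, ion label)


@dataclass(frozen=True)
class LibraryEntry:
    """One assay in the pseudospectral library: a (peptide, charge) pair."""

    peptide: str
    charge: int
    precursor_mz: float
    reference_rt: float
    fragment_mz: tuple[float, ...]
    fragment_intensity: tuple[float, ...]  # relative, max = 1
    protein_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.fragment_mz) != len(self.fragment_intensity):
            raise ValueError("fragment lists must have equal length")
        if len(self.fragment_mz) < 3:
            raise ValueError("library entries require at least 3 fragments")


@dataclass
class PeakGroup:
    """A picked chromatographic peak for one library entry in one run."""

    entry: LibraryEntry
    run_id: str
    apex_rt: float
    fragment_areas: tuple[float, ...]
    group_score: float | None  # mean pairwise Pearson r; None if < 2 usable XICs

    @property
    def total_area(self) -> float:
        return float(sum(self.fragment_areas))


def as_peak_arrays(
    peaks: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Split a list of (m/z, intensity) pairs into sorted parallel arrays."""
    if not peaks:
        return np.empty(0), np.empty(0)
    arr = np.asarray(peaks, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    return arr[order, 0], arr[order, 1]
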