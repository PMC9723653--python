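"""Targeted quantification of library peptides across DIA runs.

For each library entry, fragment XICs are extracted from the isolation
window containing the precursor, a peak group is picked by fragment
co-elution score, runs are aligned by a median RT shift over anchor
peptides, and per-peptide areas are assembled into a peptide x run matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .model import LibraryEntry, PeakGroup, SpectraRun

logger = logging.getLogger(__name__)


@dataclass
class QuantParams:
    rt_half_window: float = 150.0
    fragment_tolerance: float = 0.02
    anchor_score: float = 0.9
    min_anchors: int = 3
    valley_fraction: float = 0.05


def extract_xic(
    run: SpectraRun,
    entry: LibraryEntry,
    rt_half_window: float = 150.0,
    fragment_tolerance: float = 0.02,
    shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-fragment chromatograms around the entry's reference RT.

    Returns (scan RTs, intensity matrix of shape n_scans x n_fragments),
    or None when the precursor m/z falls outside the run's window scheme.
    Intensities are summed over all peaks within +/- fragment_tolerance.
    """
    window = run.window_scheme.window_for(entry.precursor_mz)
    if window is None:
        logger.warning(
            "precursor %.4f m/z of %s/%d+ outside the window scheme; skipped",
            entry.precursor_mz,
            entry.peptide,
            entry.charge,
        )
        return None
    center = entry.reference_rt + shift
    spectra = [
        s
        for s in run.ms2_spectra(window)
        if abs(s.retention_time - center) <= rt_half_window
    ]
    if not spectra:
        return np.empty(0), np.empty((0, len(entry.fragment_mz)))
    rts = np.array([s.retention_time for s in spectra])
    xics = np.zeros((len(spectra), len(entry.fragment_mz)))
    for si, s in enumerate(spectra):
        for fi, fmz in enumerate(entry.fragment_mz):
            lo = np.searchsorted(s.mz, fmz - fragment_tolerance, side="left")
            hi = np.searchsorted(s.mz, fmz + fragment_tolerance, side="right")
            if hi > lo:
                xics[si, fi] = s.intensity[lo:hi].sum()
    return rts, xics


def _peak_bounds(
    total: np.ndarray, apex: int, valley_fraction: float
) -> tuple[int, int]:
    floor = valley_fraction * total[apex]
    lb = apex
    while lb > 0 and total[lb - 1] <= total[lb] and total[lb] > floor:
        lb -= 1
    ub = apex
    while ub < len(total) - 1 and total[ub + 1] <= total[ub] and total[ub] > floor:
        ub += 1
    return lb, ub


def _group_score(xics: np.ndarray) -> float | None:
    usable = [j for j in range(xics.shape[1]) if np.ptp(xics[:, j]) > 0]
    if len(usable) < 2:
        return None
    rs = []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            r = np.corrcoef(xics[:, usable[a]], xics[:, usable[b]])[0, 1]
            if np.isfinite(r):
                rs.append(r)
    if not rs:
        return None
    return float(np.mean(rs))


def pick_peak_group(
    entry: LibraryEntry,
    run_id: str,
    rts: np.ndarray,
    xics: np.ndarray,
    valley_fraction: float = 0.05,
) -> PeakGroup | None:
    """Pick the best chromatographic peak from extracted fragment XICs.

    Candidate apexes are local maxima of the summed chromatogram; the one
    with the highest fragment co-elution score wins (ties go to the apex
    nearest the library reference RT). Areas are trapezoidal over the
    peak bounds (nearest valleys, or the 5 %-of-apex floor). Returns None
    for empty or flat chromatograms.
    """
    if rts.size < 3:
        return None
    total = xics.sum(axis=1)
    if total.max() <= 0:
        return None
    # candidate apexes must reach 5% of the strongest signal so that tiny
    # perfectly-correlated noise blips cannot outscore the real peak
    apexes, _ = find_peaks(total, height=0.05 * total.max())
    if apexes.size == 0:
        return None
    best: tuple[float, float, int, tuple[int, int]] | None = None
    for apex in apexes:
        lb, ub = _peak_bounds(total, int(apex), valley_fraction)
        if ub - lb < 2:
            continue
        score = _group_score(xics[lb : ub + 1])
        # quantize the co-elution score so near-ties fall through to the
        # nearest-reference-RT rule
        score_key = round(score, 3) if score is not None else -2.0
        closeness = -abs(rts[apex] - entry.reference_rt)
        key = (score_key, closeness, int(apex), (lb, ub))
        if best is None or key[:2] > best[:2]:
            best = key
    if best is None:
        return None
    _, _, apex, (lb, ub) = best
    areas = tuple(
        float(np.trapezoid(xics[lb : ub + 1, j], rts[lb : ub + 1]))
        for j in range(xics.shape[1])
    )
    score = _group_score(xics[lb : ub + 1])
    return PeakGroup(
        entry=entry,
        run_id=run_id,
        apex_rt=float(rts[apex]),
        fragment_areas=areas,
        group_score=score,
    )


def _extract_groups(
    run: SpectraRun,
    library: Sequence[LibraryEntry],
    params: QuantParams,
    shift: float = 0.0,
) -> dict[tuple[str, int], PeakGroup]:
    groups: dict[tuple[str, int], PeakGroup] = {}
    for entry in library:
        xic = extract_xic(
            run, entry, params.rt_half_window, params.fragment_tolerance, shift
        )
        if xic is None:
            continue
        group = pick_peak_group(
            entry, run.run_id, xic[0], xic[1], params.valley_fraction
        )
        if group is not None:
            groups[(entry.peptide, entry.charge)] = group
    return groups


def align_runs(
    groups_by_run: dict[str, dict[tuple[str, int], PeakGroup]],
    anchor_score: float = 0.9,
    min_anchors: int = 3,
) -> dict[str, float]:
    """Per-run RT shift from anchor peptides found confidently in all runs.

    The shift is the median of (apex RT - library reference RT) over
    anchors; with fewer than ``min_anchors`` anchors the shift falls back
    to 0 with a warning.
    """
    run_ids = list(groups_by_run)
    if not run_ids:
        return {}
    common = set.intersection(*(set(g) for g in groups_by_run.values()))
    anchors = [
        key
        for key in sorted(common)
        if all(
            groups_by_run[r][key].group_score is not None
            and groups_by_run[r][key].group_score >= anchor_score
            for r in run_ids
        )
    ]
    shifts: dict[str, float] = {}
    if len(anchors) < min_anchors:
        logger.warning(
            "only %d alignment anchors (need %d); RT shifts set to 0",
            len(anchors),
            min_anchors,
        )
        return {r: 0.0 for r in run_ids}
    for r in run_ids:
        deltas = [
            groups_by_run[r][key].apex_rt - groups_by_run[r][key].entry.reference_rt
            for key in anchors
        ]
        shifts[r] = float(np.median(deltas))
    return shifts


def quantify_all(
    runs: Sequence[SpectraRun],
    library: Sequence[LibraryEntry],
    params: QuantParams | None = None,
) -> pd.DataFrame:
    """Quantify all library peptides across runs.

    Two-pass targeted extraction: an initial pass yields anchor peptides
    for median-shift RT alignment, then extraction is re-run with shifted
    windows. Rows are peptides (areas summed over charge states), columns
    are run IDs, values are summed fragment areas; NaN marks peptides with
    no peak group in a run.
    """
    params = params or QuantParams()
    if not library:
        return pd.DataFrame(index=pd.Index([], name="peptide"))

    first_pass = {
        run.run_id: _extract_groups(run, library, params) for run in runs
    }
    shifts = align_runs(first_pass, params.anchor_score, params.min_anchors)
    final = {
        run.run_id: _extract_groups(run, library, params, shifts.get(run.run_id, 0.0))
        for run in runs
    }

    peptides = sorted({e.peptide for e in library})
    run_ids = [run.run_id for run in runs]
    matrix = pd.DataFrame(np.nan, index=pd.Index(peptides, name="peptide"), columns=run_ids)
    for run_id, groups in final.items():
        sums: dict[str, float] = {}
        for (peptide, _charge), group in groups.items():
            sums[peptide] = sums.get(peptide, 0.0) + group.total_area
        for peptide, area in sums.items():
            matrix.loc[peptide, run_id] = area
    return matrix


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
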