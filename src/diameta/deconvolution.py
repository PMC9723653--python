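"""Deconvolution of DIA runs into DDA-like pseudospectra.

Ion traces are detected independently in the MS1 map and in each isolation
window's MS2 map by greedy peak linking across consecutive scans. Fragment
traces are grouped to precursor traces by elution-profile Pearson
correlation and apex proximity, complementary y/b ion pairs are flagged,
and each surviving precursor-fragment group is emitted as a pseudospectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .masses import ISOTOPE_SPACING, PROTON, ppm_delta
from .model import (
    DiaWindowScheme,
    FragmentAssignment,
    IonTrace,
    PrecursorGroup,
    Pseudospectrum,
    SpectraRun,
    SpectrumRecord,
)


@dataclass
class DeconvolutionParams:
    """Tunable knobs of the deconvolution stage (all config-exposed)."""

    trace_mz_tolerance_ppm: float = 10.0
    min_trace_length: int = 4
    max_gap: int = 1
    min_intensity: float = 0.0
    corr_min: float = 0.8
    apex_rt_tolerance: float | None = None  # None -> 1.5 x cycle time
    min_fragments: int = 3
    isotope_tolerance_ppm: float = 10.0


@dataclass
class _OpenTrace:
    mz: float  # running intensity-weighted mean
    rts: list[float] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)
    weight: float = 0.0
    gap: int = 0

    def add(self, mz: float, rt: float, intensity: float) -> None:
        self.weight += intensity
        self.mz += (mz - self.mz) * intensity / self.weight
        self.rts.append(rt)
        self.intensities.append(intensity)
        self.gap = 0


def detect_ion_traces(
    spectra: list[SpectrumRecord],
    trace_mz_tolerance_ppm: float = 10.0,
    min_trace_length: int = 4,
    max_gap: int = 1,
    min_intensity: float = 0.0,
) -> list[IonTrace]:
    """Link peaks across consecutive scans into chromatographic traces.

    A peak joins the open trace whose running intensity-weighted m/z is
    nearest within the ppm tolerance (ties break toward the lower-m/z
    trace); each peak joins at most one trace and each trace accepts at
    most one peak per scan. A trace missing from more than ``max_gap``
    consecutive scans is closed. Traces shorter than ``min_trace_length``
    scans or with apex intensity below ``min_intensity`` are discarded.
    """
    if not spectra:
        return []
    level = spectra[0].ms_level
    window = spectra[0].precursor_window
    for s in spectra:
        if s.ms_level != level or s.precursor_window != window:
            raise ValueError("all spectra must share one MS level and window")

    open_traces: list[_OpenTrace] = []
    closed: list[_OpenTrace] = []

    for spec in spectra:
        open_traces.sort(key=lambda t: t.mz)
        trace_mzs = np.array([t.mz for t in open_traces])
        # candidate (|dmz|, trace mz, trace idx, peak idx) sorted for greedy
        # nearest-m/z assignment with lower-m/z tie-break
        candidates: list[tuple[float, float, int, int]] = []
        for pi in range(spec.n_peaks):
            pmz = spec.mz[pi]
            if trace_mzs.size == 0:
                continue
            tol = ppm_delta(pmz, trace_mz_tolerance_ppm)
            lo = np.searchsorted(trace_mzs, pmz - tol, side="left")
            hi = np.searchsorted(trace_mzs, pmz + tol, side="right")
            for ti in range(lo, hi):
                candidates.append((abs(trace_mzs[ti] - pmz), trace_mzs[ti], ti, pi))
        candidates.sort()
        used_traces: set[int] = set()
        used_peaks: set[int] = set()
        for _, _, ti, pi in candidates:
            if ti in used_traces or pi in used_peaks:
                continue
            used_traces.add(ti)
            used_peaks.add(pi)
            open_traces[ti].add(
                float(spec.mz[pi]), spec.retention_time, float(spec.intensity[pi])
            )
        # age unextended traces; close those exceeding the gap limit
        still_open: list[_OpenTrace] = []
        for ti, trace in enumerate(open_traces):
            if ti in used_traces:
                still_open.append(trace)
            else:
                trace.gap += 1
                if trace.gap > max_gap:
                    closed.append(trace)
                else:
                    still_open.append(trace)
        open_traces = still_open
        # unassigned peaks open new traces
        for pi in range(spec.n_peaks):
            if pi in used_peaks or spec.intensity[pi] <= 0:
                continue
            t = _OpenTrace(mz=float(spec.mz[pi]))
            t.add(float(spec.mz[pi]), spec.retention_time, float(spec.intensity[pi]))
            open_traces.append(t)

    closed.extend(open_traces)

    traces: list[IonTrace] = []
    for t in closed:
        if len(t.rts) < min_trace_length:
            continue
        if max(t.intensities) < min_intensity:
            continue
        traces.append(
            IonTrace(
                mz=t.mz,
                scan_rts=np.array(t.rts),
                intensities=np.array(t.intensities),
                source_level=level,
                window=window,
            )
        )
    traces.sort(key=lambda tr: (tr.mz, tr.apex_rt))
    return traces


def estimate_charge(
    trace: IonTrace,
    ms1_spectra: list[SpectrumRecord],
    isotope_tolerance_ppm: float = 10.0,
) -> int:
    """Infer precursor charge from the isotope companion in the apex scan.

    Looks for a peak at mz + 1.00335/z for z in {1, 2, 3, 4} and returns
    the z whose companion is most intense; falls back to 2 (the dominant
    tryptic charge state) when no companion is found.
    """
    if trace.source_level != 1:
        raise ValueError("charge estimation requires an MS1 trace")
    apex_rt = trace.apex_rt
    apex_scan = min(ms1_spectra, key=lambda s: abs(s.retention_time - apex_rt), default=None)
    if apex_scan is None or apex_scan.n_peaks == 0:
        return 2
    best_z, best_intensity = 2, 0.0
    tol = ppm_delta(trace.mz, isotope_tolerance_ppm)
    for z in (1, 2, 3, 4):
        companion = trace.mz + ISOTOPE_SPACING / z
        lo = np.searchsorted(apex_scan.mz, companion - tol, side="left")
        hi = np.searchsorted(apex_scan.mz, companion + tol, side="right")
        if hi > lo:
            intensity = float(apex_scan.intensity[lo:hi].max())
            if intensity > best_intensity:
                best_z, best_intensity = z, intensity
    return best_z if best_intensity > 0 else 2


def remove_isotope_traces(
    traces: list[IonTrace],
    isotope_tolerance_ppm: float = 10.0,
    apex_rt_tolerance: float = 3.0,
) -> list[IonTrace]:
    """Drop MS1 traces that are the M+1 isotope of a stronger trace.

    A trace is an isotope companion when a more intense trace sits at
    mz - 1.00335/z (z in 1..4) with a nearby apex. Keeping companions
    would emit one spurious pseudospectrum per isotope peak.
    """
    by_intensity = sorted(traces, key=lambda t: -t.apex_intensity)
    mzs = np.array([t.mz for t in traces])
    order = np.argsort(mzs)
    sorted_mzs = mzs[order]
    suppressed: set[int] = set()
    index_of = {id(t): i for i, t in enumerate(traces)}
    for t in by_intensity:
        ti = index_of[id(t)]
        if ti in suppressed:
            continue
        for z in (1, 2, 3, 4):
            companion = t.mz + ISOTOPE_SPACING / z
            tol = ppm_delta(companion, isotope_tolerance_ppm)
            lo = np.searchsorted(sorted_mzs, companion - tol, side="left")
            hi = np.searchsorted(sorted_mzs, companion + tol, side="right")
            for k in range(lo, hi):
                ci = int(order[k])
                cand = traces[ci]
                if ci == ti or ci in suppressed:
                    continue
                if cand.apex_intensity > t.apex_intensity:
                    continue
                if abs(cand.apex_rt - t.apex_rt) <= apex_rt_tolerance:
                    suppressed.add(ci)
    return [t for i, t in enumerate(traces) if i not in suppressed]


_UNDEFINED = None


def elution_correlation(a: IonTrace, b: IonTrace) -> float | None:
    """Pearson correlation of two elution profiles on the shared scan grid.

    Scan times are matched after rounding to microseconds; scans missing
    from one trace inside the overlap contribute zero intensity. Returns
    None (undefined) when the traces share fewer than 3 scan times or
    either aligned vector is constant.
    """
    map_a = {round(rt, 6): i for rt, i in zip(a.scan_rts, a.intensities)}
    map_b = {round(rt, 6): i for rt, i in zip(b.scan_rts, b.intensities)}
    shared = set(map_a) & set(map_b)
    if len(shared) < 3:
        return _UNDEFINED
    lo = max(min(map_a), min(map_b))
    hi = min(max(map_a), max(map_b))
    grid = sorted(t for t in set(map_a) | set(map_b) if lo <= t <= hi)
    va = np.array([map_a.get(t, 0.0) for t in grid])
    vb = np.array([map_b.get(t, 0.0) for t in grid])
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        return _UNDEFINED
    r = np.corrcoef(va, vb)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def group_fragments(
    ms1_traces: list[IonTrace],
    ms2_traces: dict[tuple[float, float], list[IonTrace]],
    scheme: DiaWindowScheme,
    corr_min: float = 0.8,
    apex_rt_tolerance: float = 3.0,
    min_fragments: int = 3,
    charges: dict[int, int] | None = None,
) -> list[PrecursorGroup]:
    """Attach co-eluting fragment traces to each precursor trace.

    Candidate fragments come from the isolation window containing the
    precursor m/z, must apex within ``apex_rt_tolerance`` of the precursor
    apex and correlate with Pearson r >= ``corr_min``. A fragment trace may
    join several precursor groups (co-elution is expected in chimeric
    windows). Groups with fewer than ``min_fragments`` fragments are
    dropped. ``charges`` maps precursor-trace index to charge (default 2).
    """
    groups: list[PrecursorGroup] = []
    for i, prec in enumerate(ms1_traces):
        window = scheme.window_for(prec.mz)
        if window is None:
            continue
        charge = (charges or {}).get(i, 2)
        neutral_mass = charge * (prec.mz - PROTON)
        fragments: list[FragmentAssignment] = []
        for frag in ms2_traces.get(window, []):
            dt = abs(frag.apex_rt - prec.apex_rt)
            if dt > apex_rt_tolerance:
                continue
            r = elution_correlation(prec, frag)
            if r is None or r < corr_min:
                continue
            fragments.append(FragmentAssignment(trace=frag, pearson_r=r, apex_dt=dt))
        if len(fragments) < min_fragments:
            continue
        fragments.sort(key=lambda f: (-f.trace.apex_intensity, f.trace.mz))
        groups.append(
            PrecursorGroup(
                precursor=prec,
                charge=charge,
                neutral_mass=neutral_mass,
                fragments=fragments,
            )
        )
    return groups


def flag_complementary(
    group: PrecursorGroup, fragment_tolerance: float = 0.02
) -> PrecursorGroup:
    """Mark fragment pairs whose m/z sum matches M + 2 protons.

    Fragments are assumed singly charged, so a complementary b_i / y_{n-i}
    pair satisfies mz_i + mz_j = M + 2 * 1.007276 within the tolerance.
    The flag is annotation only; no fragment is removed.
    """
    target = group.neutral_mass + 2 * PROTON
    frags = group.fragments
    mzs = np.array([f.trace.mz for f in frags])
    order = np.argsort(mzs)
    sorted_mzs = mzs[order]
    for i, f in enumerate(frags):
        need = target - f.trace.mz
        lo = np.searchsorted(sorted_mzs, need - fragment_tolerance, side="left")
        hi = np.searchsorted(sorted_mzs, need + fragment_tolerance, side="right")
        for k in range(lo, hi):
            j = int(order[k])
            if j != i:
                frags[i].complementary = True
                frags[j].complementary = True
    return group


def build_pseudospectra(
    groups: list[PrecursorGroup], run_id: str = ""
) -> list[Pseudospectrum]:
    """Emit one pseudospectrum per precursor-fragment group.

    Fragment intensity is the fragment trace's apex intensity; output is
    deterministically ordered by (precursor apex RT, precursor m/z).
    """
    ordered = sorted(groups, key=lambda g: (g.precursor.apex_rt, g.precursor.mz))
    out: list[Pseudospectrum] = []
    for idx, g in enumerate(ordered):
        pairs = sorted(
            (f.trace.mz, f.trace.apex_intensity) for f in g.fragments
        )
        out.append(
            Pseudospectrum(
                precursor_mz=g.precursor.mz,
                charge=g.charge,
                rt=g.precursor.apex_rt,
                fragment_mz=tuple(p[0] for p in pairs),
                fragment_intensity=tuple(p[1] for p in pairs),
                provenance=f"{run_id}:{idx}",
                n_complementary=sum(f.complementary for f in g.fragments),
            )
        )
    return out


def deconvolve_run(
    run: SpectraRun, params: DeconvolutionParams | None = None
) -> list[Pseudospectrum]:
    """Full deconvolution of one DIA run.

    Detects MS1 and per-window MS2 traces, suppresses isotope companion
    traces, estimates precursor charges, groups fragments by correlation
    and apex proximity, flags complementary ion pairs, and emits
    pseudospectra.
    """
    params = params or DeconvolutionParams()
    apex_tol = params.apex_rt_tolerance
    if apex_tol is None:
        apex_tol = 1.5 * run.cycle_time

    ms1_spectra = run.ms1_spectra()
    ms1_traces = detect_ion_traces(
        ms1_spectra,
        params.trace_mz_tolerance_ppm,
        params.min_trace_length,
        params.max_gap,
        params.min_intensity,
    )
    ms1_traces = remove_isotope_traces(
        ms1_traces, params.isotope_tolerance_ppm, apex_tol
    )
    ms2_traces: dict[tuple[float, float], list[IonTrace]] = {}
    for window in run.window_scheme:
        specs = run.ms2_spectra(window)
        if specs:
            ms2_traces[window] = detect_ion_traces(
                specs,
                params.trace_mz_tolerance_ppm,
                params.min_trace_length,
                params.max_gap,
                params.min_intensity,
            )
    charges = {
        i: estimate_charge(t, ms1_spectra, params.isotope_tolerance_ppm)
        for i, t in enumerate(ms1_traces)
    }
    groups = group_fragments(
        ms1_traces,
        ms2_traces,
        run.window_scheme,
        corr_min=params.corr_min,
        apex_rt_tolerance=apex_tol,
        min_fragments=params.min_fragments,
        charges=charges,
    )
    for g in groups:
        flag_complementary(g)
    return build_pseudospectra(groups, run_id=run.run_id)
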