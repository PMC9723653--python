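import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diameta.deconvolution import (
    DeconvolutionParams,
    build_pseudospectra,
    deconvolve_run,
    detect_ion_traces,
    elution_correlation,
    estimate_charge,
    flag_complementary,
    group_fragments,
    remove_isotope_traces,
)
from diameta.masses import PROTON
from diameta.model import (
    FragmentAssignment,
    IonTrace,
    PrecursorGroup,
    SpectrumRecord,
    build_window_scheme,
)
from diameta.search import theoretical_fragments
from diameta.spectra_io import write_mgf

from conftest import recovery_fraction


def _ms1(rt, peaks):
    mz, inten = zip(*peaks) if peaks else ((), ())
    return SpectrumRecord(1, rt, np.array(mz), np.array(inten))


def _trace(mz, rts, intensities, level=1, window=None):
    return IonTrace(
        mz=mz,
        scan_rts=np.array(rts, float),
        intensities=np.array(intensities, float),
        source_level=level,
        window=window,
    )


def pearson_oracle(x, y):
    """Textbook Pearson formula, independent of numpy's implementation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


class TestDetectIonTraces:
    def test_single_planted_trace(self):
        spectra = [
            _ms1(float(i), [(500.0 * (1 + 1e-6), v)])
            for i, v in enumerate([1, 5, 10, 5, 1])
        ]
        traces = detect_ion_traces(spectra)
        assert len(traces) == 1
        t = traces[0]
        assert len(t) == 5
        assert t.apex_rt == 2.0
        assert t.apex_intensity == 10.0
        assert abs(t.mz - 500.0) / 500.0 * 1e6 < 5

    def test_gap_rule_terminates_trace(self):
        # peak present only in scans 0 and 4; max_gap=1 splits it into two
        # one-scan stubs, both below min_trace_length=4
        spectra = [
            _ms1(float(i), [(500.0, 5.0)] if i in (0, 4) else [])
            for i in range(5)
        ]
        traces = detect_ion_traces(spectra, min_trace_length=4, max_gap=1)
        assert traces == []

    def test_gap_within_limit_bridged(self):
        spectra = [
            _ms1(float(i), [(500.0, 5.0)] if i != 2 else []) for i in range(5)
        ]
        traces = detect_ion_traces(spectra, min_trace_length=4, max_gap=1)
        assert len(traces) == 1
        assert len(traces[0]) == 4

    def test_nearest_mz_wins(self):
        # two adjacent channels 30 ppm apart: each keeps its own trace
        spectra = [
            _ms1(float(i), [(500.000, 10.0), (500.015, 20.0)]) for i in range(5)
        ]
        traces = detect_ion_traces(spectra, trace_mz_tolerance_ppm=10)
        assert len(traces) == 2
        assert traces[0].mz == pytest.approx(500.000, abs=1e-4)
        assert traces[1].mz == pytest.approx(500.015, abs=1e-4)

    def test_min_intensity_filter(self):
        spectra = [_ms1(float(i), [(500.0, 2.0)]) for i in range(5)]
        assert detect_ion_traces(spectra, min_intensity=5.0) == []
        assert len(detect_ion_traces(spectra, min_intensity=1.0)) == 1

    def test_empty_input(self):
        assert detect_ion_traces([]) == []

    def test_mixed_levels_rejected(self):
        spectra = [
            _ms1(0.0, [(500.0, 1.0)]),
            SpectrumRecord(2, 1.0, np.array([500.0]), np.array([1.0]), (400, 415)),
        ]
        with pytest.raises(ValueError):
            detect_ion_traces(spectra)

    def test_simulated_ms1_recovery(self, clean_setup):
        community, run = clean_setup
        traces = detect_ion_traces(run.ms1_spectra())
        planted = np.array([p.precursor_mz for p in community.manifest.peptides])
        hit = 0
        trace_mzs = np.array([t.mz for t in traces])
        for mz in planted:
            if np.any(np.abs(trace_mzs - mz) / mz * 1e6 <= 10):
                hit += 1
        assert hit >= 0.96 * len(planted)


class TestEstimateCharge:
    def _scan(self, peaks):
        mz, inten = zip(*peaks)
        return SpectrumRecord(1, 0.0, np.array(mz), np.array(inten))

    def test_charge_two_spacing(self):
        trace = _trace(500.0, [0.0], [10.0])
        scan = self._scan([(500.0, 10.0), (500.0 + 1.00335 / 2, 5.0)])
        assert estimate_charge(trace, [scan]) == 2

    def test_charge_one_spacing(self):
        trace = _trace(500.0, [0.0], [10.0])
        scan = self._scan([(500.0, 10.0), (501.00335, 5.0)])
        assert estimate_charge(trace, [scan]) == 1

    def test_fallback_charge_two(self):
        trace = _trace(500.0, [0.0], [10.0])
        scan = self._scan([(500.0, 10.0), (700.0, 5.0)])
        assert estimate_charge(trace, [scan]) == 2

    def test_charge_three_spacing(self):
        trace = _trace(500.0, [0.0], [10.0])
        scan = self._scan([(500.0, 10.0), (500.0 + 1.00335 / 3, 5.0)])
        assert estimate_charge(trace, [scan]) == 3


class TestElutionCorrelation:
    def test_perfect_scaling(self):
        a = _trace(500.0, range(5), [1, 5, 10, 5, 1])
        b = _trace(600.0, range(5), [2, 10, 20, 10, 2])
        assert elution_correlation(a, b) == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = _trace(500.0, range(5), [1, 5, 10, 5, 1])
        b = _trace(600.0, range(5), [10, 5, 1, 5, 10])
        assert elution_correlation(a, b) < 0

    def test_insufficient_overlap_undefined(self):
        a = _trace(500.0, [0, 1, 2, 3], [1, 2, 3, 4])
        b = _trace(600.0, [3, 4, 5, 6], [1, 2, 3, 4])
        assert elution_correlation(a, b) is None

    def test_constant_profile_undefined(self):
        a = _trace(500.0, range(5), [3, 3, 3, 3, 3])
        b = _trace(600.0, range(5), [1, 5, 10, 5, 1])
        assert elution_correlation(a, b) is None

    @given(
        st.lists(
            st.tuples(
                st.floats(0.1, 100),
                st.floats(0.1, 100),
            ),
            min_size=5,
            max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_textbook_oracle(self, pairs):
        xs = [p[0] for p in pairs]
        ys = [p[1] for p in pairs]
        a = _trace(500.0, range(len(xs)), xs)
        b = _trace(600.0, range(len(ys)), ys)
        r = elution_correlation(a, b)
        if len(set(xs)) == 1 or len(set(ys)) == 1:
            assert r is None
        else:
            assert r == pytest.approx(pearson_oracle(xs, ys), abs=1e-12)


class TestGrouping:
    scheme = build_window_scheme(400, 1000, 15)

    def _setup_groups(self, frag_shift=0.0):
        rts = list(range(7))
        profile = [1, 4, 10, 20, 10, 4, 1]
        prec = _trace(500.0, rts, profile)
        frags = [
            _trace(300.0, rts, profile, level=2, window=(490, 505)),
            _trace(350.0, rts, profile, level=2, window=(490, 505)),
            _trace(
                420.0,
                [r + frag_shift for r in rts],
                profile,
                level=2,
                window=(490, 505),
            ),
        ]
        return prec, frags

    def test_three_coeluting_fragments(self):
        prec, frags = self._setup_groups()
        groups = group_fragments(
            [prec], {(490, 505): frags}, self.scheme, apex_rt_tolerance=1.5
        )
        assert len(groups) == 1
        assert len(groups[0].fragments) == 3

    def test_apex_rule_drops_shifted_fragment(self):
        prec, frags = self._setup_groups(frag_shift=4.0)
        groups = group_fragments(
            [prec],
            {(490, 505): frags},
            self.scheme,
            apex_rt_tolerance=1.5,
            min_fragments=2,
        )
        assert len(groups) == 1
        assert len(groups[0].fragments) == 2

    def test_min_fragments_drops_group(self):
        prec, frags = self._setup_groups()
        groups = group_fragments(
            [prec], {(490, 505): frags[:2]}, self.scheme, min_fragments=3
        )
        assert groups == []

    def test_fragments_sorted_by_intensity(self):
        rts = list(range(7))
        profile = np.array([1, 4, 10, 20, 10, 4, 1], float)
        prec = _trace(500.0, rts, profile)
        frags = [
            _trace(300.0, rts, profile * 2, level=2, window=(490, 505)),
            _trace(350.0, rts, profile * 5, level=2, window=(490, 505)),
            _trace(420.0, rts, profile * 1, level=2, window=(490, 505)),
        ]
        groups = group_fragments([prec], {(490, 505): frags}, self.scheme)
        intensities = [f.trace.apex_intensity for f in groups[0].fragments]
        assert intensities == sorted(intensities, reverse=True)

    def test_two_coeluting_precursors_separate_groups(self, clean_acq):
        """Two precursors in one window with identical apexes but disjoint
        fragment sets are resolved into two groups."""
        from diameta.simulate import CommunitySpec, generate_community, simulate_run

        community = generate_community(
            CommunitySpec(proteins_per_taxon=1, planted_per_protein=2, seed=21)
        )
        peps = community.manifest.peptides[:2]
        for p in community.manifest.peptides:
            p.apex_rt = 100.0  # force exact co-elution
        run = simulate_run(community, clean_acq, run_seed=0, run_id="co")
        pseudo = deconvolve_run(run)
        for p in peps:
            matches = [
                ps
                for ps in pseudo
                if abs(ps.precursor_mz - p.precursor_mz) / p.precursor_mz * 1e6 <= 10
            ]
            assert matches, f"no pseudospectrum for {p.sequence}"
            planted = set(np.round(p.fragment_mz, 2))
            got = set(np.round(matches[0].fragment_mz, 2))
            assert len(planted & got) / len(planted) >= 0.9


class TestComplementary:
    def _group(self, frag_mzs, neutral_mass=1000.0):
        rts = list(range(5))
        profile = [1, 5, 10, 5, 1]
        frags = [
            FragmentAssignment(
                trace=_trace(m, rts, profile, level=2, window=(490, 505)),
                pearson_r=1.0,
                apex_dt=0.0,
            )
            for m in frag_mzs
        ]
        prec = _trace((neutral_mass / 2) + PROTON, rts, profile)
        return PrecursorGroup(
            precursor=prec, charge=2, neutral_mass=neutral_mass, fragments=frags
        )

    def test_matching_pair_flagged(self):
        g = self._group([400.007276, 602.007276], neutral_mass=1000.0)
        flag_complementary(g)
        assert all(f.complementary for f in g.fragments)

    def test_non_matching_pair_not_flagged(self):
        g = self._group([400.0, 500.0], neutral_mass=1000.0)
        flag_complementary(g)
        assert not any(f.complementary for f in g.fragments)

    def test_full_ladder_all_pairs_flagged(self):
        """Every b_i / y_{n-i} pair of a tryptic ladder is complementary."""
        from diameta.search import peptide_neutral_mass

        peptide = "SAMPLEPEPTIDEK"
        mass = peptide_neutral_mass(peptide)
        ions = theoretical_fragments(peptide, precursor_charge=2)
        g = self._group([mz for mz, _ in ions], neutral_mass=mass)
        flag_complementary(g)
        assert all(f.complementary for f in g.fragments)
        # enumeration oracle: n-1 complementary pairs per peptide
        n_pairs = sum(
            1
            for i, (mi, _) in enumerate(ions)
            for mj, _ in ions[i + 1 :]
            if abs(mi + mj - (mass + 2 * PROTON)) <= 0.02
        )
        assert n_pairs >= len(peptide) - 1


class TestPseudospectra:
    def test_empty_groups(self):
        assert build_pseudospectra([]) == []

    def test_fragments_sorted_by_mz(self):
        rts = list(range(5))
        profile = [1, 5, 10, 5, 1]
        frags = [
            FragmentAssignment(
                trace=_trace(m, rts, profile, level=2, window=(490, 505)),
                pearson_r=1.0,
                apex_dt=0.0,
            )
            for m in (420.0, 300.0, 350.0)
        ]
        g = PrecursorGroup(
            precursor=_trace(500.0, rts, profile),
            charge=2,
            neutral_mass=997.98,
            fragments=frags,
        )
        ps = build_pseudospectra([g], run_id="r")[0]
        assert ps.fragment_mz == (300.0, 350.0, 420.0)
        assert ps.provenance == "r:0"

    def test_noise_free_recovery_is_complete(self, clean_setup, clean_pseudospectra):
        community, _ = clean_setup
        manifest = community.manifest
        assert len(clean_pseudospectra) == len(manifest.peptides)
        assert recovery_fraction(manifest, clean_pseudospectra) == 1.0

    def test_noise_free_all_fragments_recovered(self, clean_setup, clean_pseudospectra):
        community, _ = clean_setup
        mzs = np.array([ps.precursor_mz for ps in clean_pseudospectra])
        for p in community.manifest.peptides:
            i = int(np.argmin(np.abs(mzs - p.precursor_mz)))
            ps = clean_pseudospectra[i]
            got = np.array(ps.fragment_mz)
            for fmz in p.fragment_mz:
                assert np.any(np.abs(got - fmz) <= 0.02), (
                    f"fragment {fmz} of {p.sequence} missing"
                )

    def test_noisy_recovery_at_least_80pct(self, noisy_setup, noisy_pseudospectra):
        community, _ = noisy_setup
        assert recovery_fraction(community.manifest, noisy_pseudospectra) >= 0.8

    def test_deterministic_mgf_output(self, tmp_path, clean_setup):
        _, run = clean_setup
        a = deconvolve_run(run)
        b = deconvolve_run(run)
        pa, pb = tmp_path / "a.mgf", tmp_path / "b.mgf"
        write_mgf(a, pa)
        write_mgf(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_peak_conservation_across_windows(self, clean_setup):
        """No trace mixes peaks from different windows or levels."""
        _, run = clean_setup
        for window in list(run.window_scheme)[:5]:
            traces = detect_ion_traces(run.ms2_spectra(window))
            for t in traces:
                assert t.window == window
                assert t.source_level == 2


class TestIsotopeSuppression:
    def test_m_plus_one_trace_removed(self):
        rts = list(range(5))
        profile = [1, 5, 10, 5, 1]
        mono = _trace(500.0, rts, profile)
        iso = _trace(500.0 + 1.00335 / 2, rts, [0.5, 2.5, 5, 2.5, 0.5])
        kept = remove_isotope_traces([mono, iso])
        assert kept == [mono]

    def test_unrelated_trace_kept(self):
        rts = list(range(5))
        profile = [1, 5, 10, 5, 1]
        a = _trace(500.0, rts, profile)
        b = _trace(503.7, rts, profile)
        assert len(remove_isotope_traces([a, b])) == 2
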