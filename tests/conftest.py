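"""Shared fixtures: synthetic communities and simulated DIA runs.

Expensive simulations are session-scoped; each fixture owns its community
instance because retention-time assignment mutates the manifest in place.
"""

from __future__ import annotations

import numpy as np
import pytest

from diameta.deconvolution import deconvolve_run
from diameta.simulate import (
    AcquisitionSpec,
    CommunitySpec,
    assign_retention_times,
    generate_community,
    simulate_run,
)


def make_community(**kwargs):
    defaults = dict(proteins_per_taxon=6, planted_per_protein=3, seed=7)
    defaults.update(kwargs)
    return generate_community(CommunitySpec(**defaults))


@pytest.fixture(scope="session")
def clean_acq() -> AcquisitionSpec:
    return AcquisitionSpec(
        gradient_length=900.0, noise_rate=0.0, fragment_dropout=0.0
    )


@pytest.fixture(scope="session")
def noisy_acq() -> AcquisitionSpec:
    return AcquisitionSpec(
        gradient_length=600.0, noise_rate=10.0, fragment_dropout=0.05
    )


@pytest.fixture(scope="session")
def clean_setup(clean_acq):
    """Noise-free, non-co-eluting community + run: exact recovery regime."""
    community = make_community()
    assign_retention_times(community.manifest, clean_acq, seed=7, coeluting=False)
    run = simulate_run(community, clean_acq, run_seed=1, run_id="clean0")
    return community, run


@pytest.fixture(scope="session")
def noisy_setup(noisy_acq):
    """Default-noise community + run with random (co-eluting) elution."""
    community = make_community()
    assign_retention_times(community.manifest, noisy_acq, seed=7, coeluting=True)
    run = simulate_run(community, noisy_acq, run_seed=1, run_id="noisy0")
    return community, run


@pytest.fixture(scope="session")
def clean_pseudospectra(clean_setup):
    _, run = clean_setup
    return deconvolve_run(run)


@pytest.fixture(scope="session")
def noisy_pseudospectra(noisy_setup):
    _, run = noisy_setup
    return deconvolve_run(run)


def manifest_library(community, max_fragments: int = 6):
    """Library entries built straight from the ground-truth manifest."""
    from diameta.model import LibraryEntry

    entries = []
    for p in community.manifest.peptides:
        order = np.argsort(p.fragment_intensity)[::-1][:max_fragments]
        order = sorted(order, key=lambda i: p.fragment_mz[i])
        mzs = tuple(p.fragment_mz[i] for i in order)
        rel = tuple(p.fragment_intensity[i] for i in order)
        top = max(rel)
        entries.append(
            LibraryEntry(
                peptide=p.sequence,
                charge=p.charge,
                precursor_mz=p.precursor_mz,
                reference_rt=p.apex_rt,
                fragment_mz=mzs,
                fragment_intensity=tuple(r / top for r in rel),
                protein_ids=p.protein_ids,
            )
        )
    return entries


@pytest.fixture(scope="session")
def replicate_quant(noisy_acq):
    """Two technical replicates pushed through the full workflow."""
    from diameta.library import build_library
    from diameta.quantify import quantify_all
    from diameta.search import search_run
    from diameta.simulate import replicate_runs

    community = make_community()
    assign_retention_times(community.manifest, noisy_acq, seed=7)
    runs, factors = replicate_runs(community, noisy_acq, n=2, base_seed=3)
    pseudospectra = []
    for run in runs:
        pseudospectra.extend(deconvolve_run(run))
    accepted, _ = search_run(pseudospectra, community.proteins)
    library = build_library(accepted)
    matrix = quantify_all(runs, library)
    return community, runs, library, matrix


def ppm_close(a: float, b: float, ppm: float = 10.0) -> bool:
    return abs(a - b) / b * 1e6 <= ppm


def recovery_fraction(manifest, pseudospectra, ppm: float = 10.0) -> float:
    """Fraction of planted peptides with a pseudospectrum at their m/z."""
    if not manifest.peptides:
        return 0.0
    mzs = np.array([ps.precursor_mz for ps in pseudospectra])
    rts = np.array([ps.rt for ps in pseudospectra])
    hit = 0
    for p in manifest.peptides:
        sel = np.abs(mzs - p.precursor_mz) / p.precursor_mz * 1e6 <= ppm
        if np.any(sel & (np.abs(rts - p.apex_rt) < 20.0)):
            hit += 1
    return hit / len(manifest.peptides)
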