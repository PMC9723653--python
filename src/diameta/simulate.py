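"""Ground-truth simulator: synthetic microbial communities and DIA runs.

Generates a multi-taxon protein database with controlled tryptic sites and
peptide sharing, plants peptides with Gaussian chromatographic elution into
a DIA acquisition (MS1 survey scans interleaved with consecutive isolation
windows), and keeps a complete manifest so every upstream module can be
scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .masses import ISOTOPE_SPACING, mz_from_neutral_mass
from .model import ProteinRecord, SpectraRun, SpectrumRecord, build_window_scheme
from .search import peptide_neutral_mass, theoretical_fragments

DEFAULT_TAXA: tuple[tuple[str, str, float], ...] = (
    ("Firmicutes", "Lactobacillus", 1.5),
    ("Firmicutes", "Enterococcus", 1.2),
    ("Firmicutes", "Clostridium", 1.0),
    ("Firmicutes", "Faecalibacterium", 2.0),
    ("Firmicutes", "Roseburia", 0.8),
    ("Bacteroidetes", "Bacteroides", 2.5),
    ("Bacteroidetes", "Prevotella", 1.0),
    ("Actinobacteria", "Bifidobacterium", 1.3),
    ("Actinobacteria", "Collinsella", 0.6),
    ("Proteobacteria", "Escherichia", 1.1),
    ("Proteobacteria", "Klebsiella", 0.7),
    ("Verrucomicrobia", "Akkermansia", 0.9),
)

DEFAULT_KEGG = (
    "Carbohydrate metabolism",
    "Amino acid metabolism",
    "Energy metabolism",
    "Translation",
    "Membrane transport",
)

# residues used inside simulated tryptic peptides: no K/R (reserved for the
# C-terminus), no P (would suppress cleavage), no X
_INTERIOR = "ACDEFGHILMNQSTVWY"
_TERMINAL = "KR"


@dataclass
class CommunitySpec:
    taxa: tuple[tuple[str, str, float], ...] = DEFAULT_TAXA
    proteins_per_taxon: int = 20
    blocks_per_protein: int = 8  # tryptic building blocks per protein
    planted_per_protein: int = 3  # blocks that actually fly in the runs
    shared_peptide_fraction: float = 0.0
    kegg_categories: tuple[str, ...] = DEFAULT_KEGG
    min_peptide_length: int = 8
    max_peptide_length: int = 14
    seed: int = 0


@dataclass
class AcquisitionSpec:
    ms1_range: tuple[float, float] = (375.0, 1500.0)
    dia_start: float = 400.0
    dia_end: float = 1000.0
    dia_width: float = 15.0
    cycle_time: float = 2.0
    gradient_length: float = 600.0
    elution_sigma: float = 4.0
    noise_rate: float = 10.0  # expected noise peaks per scan (Poisson)
    noise_intensity: float = 50.0  # exponential mean of noise peaks
    fragment_dropout: float = 0.0
    response_sigma: float = 0.8  # log-normal per-peptide response factor
    base_abundance: float = 1.0e4
    min_peak_intensity: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "dia_width",
            "cycle_time",
            "gradient_length",
            "elution_sigma",
            "base_abundance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PlantedPeptide:
    """Complete ground truth for one planted peptide."""

    sequence: str
    protein_ids: tuple[str, ...]
    phylum: str
    genus: str
    function: str
    charge: int
    precursor_mz: float
    apex_rt: float
    fragment_mz: tuple[float, ...]
    fragment_intensity: tuple[float, ...]  # relative, max = 1
    abundance: float


@dataclass
class TruthManifest:
    peptides: list[PlantedPeptide] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = [vars(p) for p in self.peptides]
        Path(path).write_text(json.dumps(payload, indent=1, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        payload = json.loads(Path(path).read_text())
        peptides = [
            PlantedPeptide(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in entry.items()
                }
            )
            for entry in payload
        ]
        return cls(peptides=peptides)


@dataclass
class Community:
    proteins: list[ProteinRecord]
    annotation_rows: list[tuple[str, str, str, str]]
    manifest: TruthManifest
    spec: CommunitySpec


def _sample_peptide(
    rng: np.random.Generator, spec: CommunitySpec, seen: set[str]
) -> str:
    while True:
        length = int(rng.integers(spec.min_peptide_length, spec.max_peptide_length + 1))
        body = "".join(rng.choice(list(_INTERIOR), size=length - 1))
        pep = body + str(rng.choice(list(_TERMINAL)))
        if pep not in seen:
            seen.add(pep)
            return pep


def generate_community(
    spec: CommunitySpec,
    precursor_range: tuple[float, float] = (400.0, 1000.0),
) -> Community:
    """Build a synthetic community: FASTA proteins, annotations, manifest.

    Proteins are concatenations of unique tryptic peptide blocks; a
    configurable fraction of planted peptides is additionally inserted
    into a protein of a different taxon to exercise ambiguous annotation.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    seen: set[str] = set()

    blocks: dict[str, list[str]] = {}  # protein_id -> peptide blocks
    protein_meta: dict[str, tuple[str, str, str]] = {}  # pid -> (phylum, genus, kegg)
    planted: list[tuple[str, str]] = []  # (sequence, protein_id)
    taxon_proteins: dict[str, list[str]] = {}

    for phylum, genus, _weight in spec.taxa:
        taxon_proteins[genus] = []
        for pi in range(spec.proteins_per_taxon):
            pid = f"{genus[:4].upper()}_{pi:03d}"
            kegg = str(rng.choice(list(spec.kegg_categories)))
            protein_meta[pid] = (phylum, genus, kegg)
            taxon_proteins[genus].append(pid)
            blocks[pid] = [
                _sample_peptide(rng, spec, seen)
                for _ in range(spec.blocks_per_protein)
            ]
            chosen = rng.choice(
                spec.blocks_per_protein,
                size=min(spec.planted_per_protein, spec.blocks_per_protein),
                replace=False,
            )
            for b in sorted(chosen):
                planted.append((blocks[pid][b], pid))

    # cross-taxon sharing: insert a planted peptide into a second protein
    # belonging to a different genus
    peptide_proteins: dict[str, list[str]] = {}
    for seq, pid in planted:
        peptide_proteins.setdefault(seq, []).append(pid)
    genera = [g for _, g, _ in spec.taxa]
    for seq, pid in planted:
        if spec.shared_peptide_fraction <= 0:
            break
        if rng.random() >= spec.shared_peptide_fraction:
            continue
        own_genus = protein_meta[pid][1]
        others = [g for g in genera if g != own_genus]
        target_genus = str(rng.choice(others))
        target_pid = str(rng.choice(taxon_proteins[target_genus]))
        blocks[target_pid].append(seq)
        peptide_proteins[seq].append(target_pid)

    proteins = [
        ProteinRecord(protein_id=pid, sequence="".join(blocks[pid]))
        for pid in sorted(blocks)
    ]
    annotation_rows = [
        (pid, *protein_meta[pid]) for pid in sorted(protein_meta)
    ]

    weight_of = {genus: w for _, genus, w in spec.taxa}
    manifest = TruthManifest()
    lo, hi = precursor_range
    for seq in sorted(peptide_proteins):
        pids = tuple(sorted(set(peptide_proteins[seq])))
        mass = peptide_neutral_mass(seq)
        charge = None
        for z in (2, 3):
            mz = mz_from_neutral_mass(mass, z)
            if lo <= mz < hi:
                charge = z
                break
        if charge is None:
            continue  # precursor falls outside the DIA range at 2+/3+
        fragments = [
            (fmz, label)
            for fmz, label in theoretical_fragments(seq, precursor_charge=2)
            if 150.0 <= fmz <= 1800.0
        ]
        rel = rng.uniform(0.2, 1.0, size=len(fragments))
        rel /= rel.max()
        phylum, genus, kegg = protein_meta[pids[0]]
        labels = {protein_meta[p][1] for p in pids}
        phyla = {protein_meta[p][0] for p in pids}
        keggs = {protein_meta[p][2] for p in pids}
        manifest.peptides.append(
            PlantedPeptide(
                sequence=seq,
                protein_ids=pids,
                phylum=phylum if len(phyla) == 1 else "ambiguous",
                genus=genus if len(labels) == 1 else "ambiguous",
                function=kegg if len(keggs) == 1 else "ambiguous",
                charge=charge,
                precursor_mz=mz_from_neutral_mass(mass, charge),
                apex_rt=0.0,  # assigned by assign_retention_times
                fragment_mz=tuple(f[0] for f in fragments),
                fragment_intensity=tuple(rel.tolist()),
                abundance=float(
                    weight_of[genus]
                    * rng.lognormal(mean=0.0, sigma=0.8)
                ),
            )
        )
    return Community(
        proteins=proteins,
        annotation_rows=annotation_rows,
        manifest=manifest,
        spec=spec,
    )


def assign_retention_times(
    manifest: TruthManifest,
    acq: AcquisitionSpec,
    seed: int = 0,
    coeluting: bool = True,
) -> None:
    """Assign elution apexes in place.

    With ``coeluting=True`` apexes are uniform over the usable gradient.
    With ``coeluting=False`` peptides sharing an isolation window get
    apexes spaced at least 10 elution sigmas apart: elution profiles are
    truncated at 4 sigma, so consecutive peaks are separated by a gap the
    trace linker cannot bridge, even for fragments sharing an m/z channel.
    """
    rng = np.random.default_rng(seed)
    margin = 4.0 * acq.elution_sigma
    lo, hi = margin, acq.gradient_length - margin
    if hi <= lo:
        raise ValueError("gradient too short for the elution peak width")
    if coeluting:
        for p in manifest.peptides:
            p.apex_rt = float(rng.uniform(lo, hi))
        return
    scheme = build_window_scheme(acq.dia_start, acq.dia_end, acq.dia_width)
    by_window: dict[tuple[float, float], list[PlantedPeptide]] = {}
    for p in manifest.peptides:
        window = scheme.window_for(p.precursor_mz)
        if window is None:
            continue
        by_window.setdefault(window, []).append(p)
    spacing_min = 10.0 * acq.elution_sigma
    for window, peptides in sorted(by_window.items()):
        if len(peptides) == 1:
            peptides[0].apex_rt = float(rng.uniform(lo, hi))
            continue
        span = hi - lo
        spacing = span / (len(peptides) - 1) if len(peptides) > 1 else span
        if spacing < spacing_min:
            raise ValueError(
                f"window {window}: {len(peptides)} peptides cannot be "
                f"spaced {spacing_min:.0f}s apart in a {span:.0f}s gradient"
            )
        order = rng.permutation(len(peptides))
        for rank, idx in enumerate(order):
            peptides[int(idx)].apex_rt = float(lo + rank * spacing)


def simulate_run(
    community: Community,
    acq: AcquisitionSpec,
    run_seed: int = 0,
    run_id: str = "run0",
    abundance_factors: dict[str, float] | None = None,
    rt_shift: float = 0.0,
) -> SpectraRun:
    """Synthesize one DIA run from the community manifest.

    Each cycle holds one MS1 survey scan followed by every isolation
    window's MS2 scan, all time-stamped at the cycle start. Precursors
    carry a monoisotopic + M+1 isotope pair in MS1; fragments follow the
    same Gaussian elution profile, thinned by the dropout probability.
    Uniform noise peaks are added at the configured Poisson rate.
    """
    rng = np.random.default_rng(run_seed)
    scheme = build_window_scheme(acq.dia_start, acq.dia_end, acq.dia_width)
    factors = abundance_factors or {}

    by_window: dict[tuple[float, float], list[tuple[PlantedPeptide, np.ndarray, np.ndarray]]] = {
        w: [] for w in scheme
    }
    ms1_entries: list[tuple[PlantedPeptide, float]] = []
    for p in community.manifest.peptides:
        window = scheme.window_for(p.precursor_mz)
        if window is None:
            continue
        keep = rng.random(len(p.fragment_mz)) >= acq.fragment_dropout
        fmz = np.array(p.fragment_mz)[keep]
        frel = np.array(p.fragment_intensity)[keep]
        scale = p.abundance * factors.get(p.sequence, 1.0) * acq.base_abundance
        by_window[window].append((p, fmz, frel * scale))
        ms1_entries.append((p, scale))

    n_cycles = int(acq.gradient_length / acq.cycle_time)
    sigma = acq.elution_sigma
    spectra: list[SpectrumRecord] = []
    ms1_lo, ms1_hi = acq.ms1_range

    def gaussian(p: PlantedPeptide, t: float) -> float:
        dt = t - (p.apex_rt + rt_shift)
        if abs(dt) > 4.0 * sigma:
            return 0.0
        return float(np.exp(-0.5 * (dt / sigma) ** 2))

    for cycle in range(n_cycles):
        t = cycle * acq.cycle_time
        # MS1 survey scan
        peaks: list[tuple[float, float]] = []
        for p, scale in ms1_entries:
            g = gaussian(p, t)
            inten = scale * g
            if inten < acq.min_peak_intensity:
                continue
            peaks.append((p.precursor_mz, inten))
            peaks.append((p.precursor_mz + ISOTOPE_SPACING / p.charge, 0.5 * inten))
        n_noise = int(rng.poisson(acq.noise_rate))
        for _ in range(n_noise):
            peaks.append(
                (
                    float(rng.uniform(ms1_lo, ms1_hi)),
                    float(rng.exponential(acq.noise_intensity)),
                )
            )
        mz, inten = _to_arrays(peaks)
        spectra.append(
            SpectrumRecord(ms_level=1, retention_time=t, mz=mz, intensity=inten)
        )
        # MS2 scans, one per window
        for window in scheme:
            peaks = []
            for p, fmz, fint in by_window[window]:
                g = gaussian(p, t)
                if g == 0.0:
                    continue
                for m, i in zip(fmz, fint):
                    v = i * g
                    if v >= acq.min_peak_intensity:
                        peaks.append((float(m), float(v)))
            n_noise = int(rng.poisson(acq.noise_rate))
            for _ in range(n_noise):
                peaks.append(
                    (
                        float(rng.uniform(100.0, 1800.0)),
                        float(rng.exponential(acq.noise_intensity)),
                    )
                )
            mz, inten = _to_arrays(peaks)
            spectra.append(
                SpectrumRecord(
                    ms_level=2,
                    retention_time=t,
                    mz=mz,
                    intensity=inten,
                    precursor_window=window,
                )
            )
    return SpectraRun(run_id=run_id, spectra=spectra, window_scheme=scheme)


def _to_arrays(peaks: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    if not peaks:
        return np.empty(0), np.empty(0)
    arr = np.asarray(peaks)
    order = np.argsort(arr[:, 0], kind="stable")
    return arr[order, 0], arr[order, 1]


def replicate_runs(
    community: Community,
    acq: AcquisitionSpec,
    n: int = 3,
    jitter_sigma: float = 0.0,
    base_seed: int = 0,
) -> tuple[list[SpectraRun], list[dict[str, float]]]:
    """Simulate n replicate runs with per-run log-normal abundance jitter.

    jitter_sigma = 0 gives technical replicates (identical planted
    abundances; noise and dropout still differ between runs). Returns the
    runs and the per-run abundance factor maps.
    """
    runs: list[SpectraRun] = []
    factor_maps: list[dict[str, float]] = []
    rng = np.random.default_rng(base_seed)
    for i in range(n):
        if jitter_sigma > 0:
            factors = {
                p.sequence: float(rng.lognormal(mean=0.0, sigma=jitter_sigma))
                for p in community.manifest.peptides
            }
        else:
            factors = {}
        run_seed = int(rng.integers(0, 2**31 - 1))
        runs.append(
            simulate_run(
                community,
                acq,
                run_seed=run_seed,
                run_id=f"rep{i}",
                abundance_factors=factors,
            )
        )
        factor_maps.append(factors)
    return runs, factor_maps
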