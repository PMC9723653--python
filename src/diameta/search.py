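"""Database search of pseudospectra with target-decoy FDR control.

A single built-in engine: tryptic in-silico digestion, theoretical b/y
fragment generation, a hyperscore-style match score, and q-value filtering
at the configured FDR threshold. Parent tolerance defaults to 10 ppm and
fragment tolerance to 0.02 Da.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .masses import (
    CARBAMIDOMETHYL,
    OXIDATION,
    PROTON,
    RESIDUE_MASSES,
    WATER,
    neutral_mass_from_mz,
)
from .model import PeptideMatch, ProteinRecord, Pseudospectrum

OXIDATION_TAG = "(ox)"


@dataclass
class DigestConfig:
    missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    # fixed carbamidomethyl-C and variable oxidation-M (<= 1 per peptide)
    # are built into the mass/fragment calculators below
    max_oxidations: int = 1


@dataclass
class SearchConfig:
    parent_tolerance_ppm: float = 10.0
    fragment_tolerance: float = 0.02
    fdr_threshold: float = 0.01
    decoy_prefix: str = "DECOY_"

    def __post_init__(self) -> None:
        if self.parent_tolerance_ppm <= 0 or self.fragment_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")


# ---------------------------------------------------------------------------
# Digestion


def digest(
    protein: ProteinRecord | str, cfg: DigestConfig | None = None
) -> set[str]:
    """In-silico tryptic digestion.

    Cleaves after K or R except when the next residue is P; emits all
    products with at most ``missed_cleavages`` internal cleavage sites and
    length within bounds. Peptides containing X are excluded.
    """
    cfg = cfg or DigestConfig()
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    n = len(seq)
    # cleavage points: index i means a cut between seq[i-1] and seq[i]
    cuts = [0]
    for i in range(1, n):
        if seq[i - 1] in "KR" and seq[i] != "P":
            cuts.append(i)
    cuts.append(n)
    out: set[str] = set()
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + cfg.missed_cleavages, len(cuts))):
            pep = seq[cuts[a] : cuts[b]]
            if cfg.min_length <= len(pep) <= cfg.max_length and "X" not in pep:
                out.add(pep)
    return out


# ---------------------------------------------------------------------------
# Peptide masses and fragments


def parse_peptide(peptide: str) -> list[tuple[str, float]]:
    """Split a modified sequence into (residue, mod mass) pairs.

    Carbamidomethyl-C is fixed and applied implicitly; oxidized methionine
    is written ``M(ox)``.
    """
    out: list[tuple[str, float]] = []
    i = 0
    while i < len(peptide):
        res = peptide[i]
        if res not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue {res!r} in peptide {peptide!r}")
        mod = CARBAMIDOMETHYL if res == "C" else 0.0
        i += 1
        if peptide[i : i + len(OXIDATION_TAG)] == OXIDATION_TAG:
            if res != "M":
                raise ValueError(f"oxidation tag on non-methionine in {peptide!r}")
            mod += OXIDATION
            i += len(OXIDATION_TAG)
        out.append((res, mod))
    return out


def strip_modifications(peptide: str) -> str:
    return peptide.replace(OXIDATION_TAG, "")


def peptide_neutral_mass(peptide: str) -> float:
    """Monoisotopic neutral mass of a (possibly modified) peptide."""
    residues = parse_peptide(peptide)
    return sum(RESIDUE_MASSES[r] + m for r, m in residues) + WATER


def oxidation_variants(peptide: str, max_oxidations: int = 1) -> list[str]:
    """The unmodified peptide plus each single-oxidation variant."""
    variants = [peptide]
    if max_oxidations >= 1:
        for i, res in enumerate(peptide):
            if res == "M":
                variants.append(peptide[: i + 1] + OXIDATION_TAG + peptide[i + 1 :])
    return variants


def theoretical_fragments(
    peptide: str, precursor_charge: int = 2
) -> list[tuple[float, str]]:
    """Sorted theoretical b/y fragment m/z values with ion labels.

    Fragments are singly charged; doubly charged fragments are added when
    the precursor charge is >= 3. Labels look like ``b3``, ``y5``,
    ``y5^2``.
    """
    residues = parse_peptide(peptide)
    masses = [RESIDUE_MASSES[r] + m for r, m in residues]
    n = len(masses)
    prefix = np.cumsum(masses)
    total = prefix[-1]
    ions: list[tuple[float, str]] = []
    frag_charges = [1] if precursor_charge < 3 else [1, 2]
    for i in range(1, n):
        b_neutral = prefix[i - 1]  # sum of first i residues
        y_neutral = total - prefix[i - 1] + WATER
        for z in frag_charges:
            suffix = "" if z == 1 else f"^{z}"
            ions.append(((b_neutral + z * PROTON) / z, f"b{i}{suffix}"))
            ions.append(((y_neutral + z * PROTON) / z, f"y{n - i}{suffix}"))
    ions.sort()
    return ions


# ---------------------------------------------------------------------------
# Scoring


def match_fragments(
    spectrum: Pseudospectrum,
    peptide: str,
    fragment_tolerance: float = 0.02,
    precursor_charge: int | None = None,
) -> list[tuple[float, float, str]]:
    """Match observed fragments to theoretical ions.

    Each observed fragment matches at most one theoretical ion (the
    nearest within the tolerance). Returns (observed m/z, observed
    intensity, ion label) triples.
    """
    charge = precursor_charge if precursor_charge is not None else spectrum.charge
    theo = theoretical_fragments(peptide, charge)
    theo_mz = [t[0] for t in theo]
    matched: list[tuple[float, float, str]] = []
    for mz, intensity in zip(spectrum.fragment_mz, spectrum.fragment_intensity):
        lo = bisect_left(theo_mz, mz - fragment_tolerance)
        hi = bisect_right(theo_mz, mz + fragment_tolerance)
        if hi <= lo:
            continue
        best = min(range(lo, hi), key=lambda k: (abs(theo_mz[k] - mz), theo[k][1]))
        matched.append((mz, intensity, theo[best][1]))
    return matched


def score_match(
    spectrum: Pseudospectrum,
    peptide: str,
    fragment_tolerance: float = 0.02,
) -> float:
    """Hyperscore-style match score.

    ln[(sum of matched intensity) * min(Nb, 20)! * min(Ny, 20)!] with
    observed intensities normalized so the base peak is 100; Nb/Ny count
    distinct matched b/y ions. Zero when nothing matches; clamped at 0.
    """
    score, _ = _score_with_matches(spectrum, peptide, fragment_tolerance)
    return score


def _score_with_matches(
    spectrum: Pseudospectrum,
    peptide: str,
    fragment_tolerance: float,
) -> tuple[float, list[tuple[float, float, str]]]:
    matched = match_fragments(spectrum, peptide, fragment_tolerance)
    if not matched:
        return 0.0, []
    base = max(spectrum.fragment_intensity)
    if base <= 0:
        return 0.0, []
    total = sum(100.0 * inten / base for _, inten, _ in matched)
    labels = {label for _, _, label in matched}
    nb = sum(1 for lab in labels if lab.startswith("b"))
    ny = sum(1 for lab in labels if lab.startswith("y"))
    score = (
        math.log(total)
        + math.log(math.factorial(min(nb, 20)))
        + math.log(math.factorial(min(ny, 20)))
    )
    return max(score, 0.0), matched


# ---------------------------------------------------------------------------
# Decoys and FDR


def make_decoys(
    proteins: Sequence[ProteinRecord], decoy_prefix: str = "DECOY_"
) -> list[ProteinRecord]:
    """Full-sequence-reversal decoys, one per target protein."""
    return [
        ProteinRecord(
            protein_id=decoy_prefix + p.protein_id, sequence=p.sequence[::-1]
        )
        for p in proteins
    ]


def fdr_filter(
    matches: Sequence[PeptideMatch], threshold: float = 0.01
) -> list[PeptideMatch]:
    """Assign q-values and return accepted target matches.

    At score cutoff s the FDR estimate is (#decoys >= s + 1) / max(#targets
    >= s, 1); the q-value is the running minimum of this estimate over
    cutoffs at or above each match's score. Targets with q <= threshold
    are accepted. All input matches get their ``q_value`` set in place.
    """
    if not matches:
        return []
    ordered = sorted(matches, key=lambda m: (-m.score, m.is_decoy, m.peptide))
    n = len(ordered)
    targets = decoys = 0
    fdr_at = [0.0] * n
    for i, m in enumerate(ordered):
        if m.is_decoy:
            decoys += 1
        else:
            targets += 1
        fdr_at[i] = (decoys + 1) / max(targets, 1)
    # score ties share the estimate at the last (worst) index of the tie
    for i in range(n - 2, -1, -1):
        if ordered[i].score == ordered[i + 1].score:
            fdr_at[i] = fdr_at[i + 1]
    q = [0.0] * n
    running = math.inf
    for i in range(n - 1, -1, -1):
        running = min(running, fdr_at[i])
        q[i] = min(running, 1.0)
    for m, qv in zip(ordered, q):
        m.q_value = qv
    return [m for m, qv in zip(ordered, q) if not m.is_decoy and qv <= threshold]


# ---------------------------------------------------------------------------
# The engine


@dataclass
class _Candidate:
    mass: float
    peptide: str
    is_decoy: bool
    protein_ids: tuple[str, ...]


@dataclass
class PeptideIndex:
    """Mass-sorted index of digested target + decoy peptides."""

    candidates: list[_Candidate] = field(default_factory=list)
    _masses: list[float] = field(default_factory=list)

    @classmethod
    def build(
        cls,
        proteins: Sequence[ProteinRecord],
        digest_cfg: DigestConfig | None = None,
        search_cfg: SearchConfig | None = None,
    ) -> "PeptideIndex":
        digest_cfg = digest_cfg or DigestConfig()
        search_cfg = search_cfg or SearchConfig()
        decoys = make_decoys(proteins, search_cfg.decoy_prefix)

        target_map: dict[str, set[str]] = {}
        for p in proteins:
            for pep in digest(p, digest_cfg):
                target_map.setdefault(pep, set()).add(p.protein_id)
        decoy_map: dict[str, set[str]] = {}
        for p in decoys:
            for pep in digest(p, digest_cfg):
                if pep in target_map:  # shared sequences count as targets
                    continue
                decoy_map.setdefault(pep, set()).add(p.protein_id)

        cands: list[_Candidate] = []
        for pep_map, is_decoy in ((target_map, False), (decoy_map, True)):
            for pep in sorted(pep_map):
                pids = tuple(sorted(pep_map[pep]))
                for variant in oxidation_variants(pep, digest_cfg.max_oxidations):
                    cands.append(
                        _Candidate(
                            mass=peptide_neutral_mass(variant),
                            peptide=variant,
                            is_decoy=is_decoy,
                            protein_ids=pids,
                        )
                    )
        cands.sort(key=lambda c: c.mass)
        idx = cls(candidates=cands, _masses=[c.mass for c in cands])
        return idx

    def lookup(self, neutral_mass: float, tolerance_ppm: float) -> list[_Candidate]:
        tol = neutral_mass * tolerance_ppm * 1e-6
        lo = bisect_left(self._masses, neutral_mass - tol)
        hi = bisect_right(self._masses, neutral_mass + tol)
        return self.candidates[lo:hi]


def search_run(
    pseudospectra: Sequence[Pseudospectrum],
    proteins: Sequence[ProteinRecord],
    digest_cfg: DigestConfig | None = None,
    search_cfg: SearchConfig | None = None,
    index: PeptideIndex | None = None,
) -> tuple[list[PeptideMatch], list[PeptideMatch]]:
    """Search pseudospectra against a protein database.

    Returns (accepted matches at the FDR threshold, all best-per-spectrum
    matches with q-values assigned). Only the best-scoring match per
    pseudospectrum enters FDR estimation; ties prefer targets, then
    lexicographically smaller peptides.
    """
    digest_cfg = digest_cfg or DigestConfig()
    search_cfg = search_cfg or SearchConfig()
    if index is None:
        index = PeptideIndex.build(proteins, digest_cfg, search_cfg)

    best_matches: list[PeptideMatch] = []
    for ps in pseudospectra:
        neutral = neutral_mass_from_mz(ps.precursor_mz, ps.charge)
        best: PeptideMatch | None = None
        for cand in index.lookup(neutral, search_cfg.parent_tolerance_ppm):
            score, matched = _score_with_matches(
                ps, cand.peptide, search_cfg.fragment_tolerance
            )
            if score <= 0:
                continue
            key = (-score, cand.is_decoy, cand.peptide)
            if best is None or key < (-best.score, best.is_decoy, best.peptide):
                best = PeptideMatch(
                    spectrum_id=ps.provenance,
                    peptide=cand.peptide,
                    charge=ps.charge,
                    score=score,
                    is_decoy=cand.is_decoy,
                    protein_ids=cand.protein_ids,
                    rt=ps.rt,
                    precursor_mz=ps.precursor_mz,
                    matched_peaks=tuple(matched),
                )
        if best is not None:
            best_matches.append(best)

    accepted = fdr_filter(best_matches, search_cfg.fdr_threshold)
    return accepted, best_matches


def write_matches(matches: Iterable[PeptideMatch], path: str | Path) -> None:
    """Write matches as a TSV (one row per pseudospectrum match)."""
    with open(path, "w") as fh:
        fh.write(
            "spectrum_id\tpeptide\tcharge\tscore\tq_value\tis_decoy\tprotein_ids\n"
        )
        for m in matches:
            fh.write(
                f"{m.spectrum_id}\t{m.peptide}\t{m.charge}\t{m.score:.6f}\t"
                f"{m.q_value:.6f}\t{int(m.is_decoy)}\t{';'.join(m.protein_ids)}\n"
            )
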