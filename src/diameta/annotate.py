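"""Peptide-centric taxonomic and functional annotation and profiles.

Each peptide inherits the consensus annotation of all its possible source
proteins: a single distinct label wins, conflicting labels give
"ambiguous", and no labels at all give "unknown". Unannotated source
proteins never conflict with existing annotations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import AnnotationTable

AMBIGUOUS = "ambiguous"
UNKNOWN = "unknown"
OTHER = "other"

RANKS = ("phylum", "genus", "function")


def annotate_peptide(
    peptide: str,
    protein_ids: Sequence[str],
    table: AnnotationTable,
    rank: str,
) -> str:
    """Consensus label of a peptide at one rank.

    Labels of all source proteins are collected, dropping unannotated
    ones; exactly one distinct label -> that label, none -> "unknown",
    two or more -> "ambiguous".
    """
    if not protein_ids:
        raise ValueError("annotate_peptide requires at least one source protein")
    labels = {
        label
        for pid in protein_ids
        if (label := table.lookup(pid, rank)) is not None
    }
    if not labels:
        return UNKNOWN
    if len(labels) == 1:
        return next(iter(labels))
    return AMBIGUOUS


@dataclass
class PeptideAnnotation:
    peptide: str
    phylum: str
    genus: str
    function: str

    def label(self, rank: str) -> str:
        return getattr(self, rank)


def annotate_peptides(
    peptide_proteins: Mapping[str, Sequence[str]], table: AnnotationTable
) -> list[PeptideAnnotation]:
    """Annotate every peptide at all ranks from its source-protein sets."""
    return [
        PeptideAnnotation(
            peptide=pep,
            phylum=annotate_peptide(pep, pids, table, "phylum"),
            genus=annotate_peptide(pep, pids, table, "genus"),
            function=annotate_peptide(pep, pids, table, "function"),
        )
        for pep, pids in sorted(peptide_proteins.items())
    ]


def build_profile(
    labels: Iterable[str], threshold: float = 0.005
) -> dict[str, float]:
    """Percentage profile with small named categories merged into "other".

    Named labels holding strictly less than ``threshold`` of the peptides
    are aggregated into "other"; labels at exactly the threshold are
    retained. "ambiguous" and "unknown" are always reported separately.
    """
    counts = Counter(labels)
    total = sum(counts.values())
    if total == 0:
        return {}
    profile: dict[str, float] = {}
    other = 0.0
    for label, count in counts.items():
        fraction = count / total
        if label not in (AMBIGUOUS, UNKNOWN) and fraction < threshold:
            other += fraction
        else:
            profile[label] = 100.0 * fraction
    if other > 0:
        profile[OTHER] = profile.get(OTHER, 0.0) + 100.0 * other
    return dict(sorted(profile.items(), key=lambda kv: (-kv[1], kv[0])))


def replicate_overlap(ids_a: set[str], ids_b: set[str]) -> float:
    """Shared peptides divided by the total peptides of the pair (Jaccard)."""
    union = ids_a | ids_b
    if not union:
        return 0.0
    return len(ids_a & ids_b) / len(union)


def quant_correlation(
    matrix: pd.DataFrame, run_a: str, run_b: str
) -> tuple[float, int]:
    """Pearson r of log10(area + 1) over peptides quantified in both runs."""
    sub = matrix[[run_a, run_b]].dropna()
    n_shared = len(sub)
    if n_shared < 3:
        raise ValueError(
            f"need >= 3 peptides shared by {run_a} and {run_b}, got {n_shared}"
        )
    a = np.log10(sub[run_a].to_numpy() + 1.0)
    b = np.log10(sub[run_b].to_numpy() + 1.0)
    r, _ = stats.pearsonr(a, b)
    return float(r), n_shared


def genus_by_function_table(
    annotations: Sequence[PeptideAnnotation], function_filter: str
) -> dict[str, int]:
    """Genus-wise peptide counts within one functional category.

    Ambiguous/unknown genus labels are kept as explicit rows; the counts
    sum to the number of peptides in the category.
    """
    counts: Counter[str] = Counter(
        ann.genus for ann in annotations if ann.function == function_filter
    )
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))


def overlap_matrix(peptide_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise replicate-overlap matrix over runs."""
    runs = list(peptide_sets)
    mat = pd.DataFrame(1.0, index=runs, columns=runs)
    for i, a in enumerate(runs):
        for b in runs[i + 1 :]:
            v = replicate_overlap(peptide_sets[a], peptide_sets[b])
            mat.loc[a, b] = v
            mat.loc[b, a] = v
    return mat


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise quantification-correlation matrix over runs."""
    runs = list(matrix.columns)
    mat = pd.DataFrame(1.0, index=runs, columns=runs)
    for i, a in enumerate(runs):
        for b in runs[i + 1 :]:
            try:
                r, _ = quant_correlation(matrix, a, b)
            except ValueError:
                r = np.nan
            mat.loc[a, b] = r
            mat.loc[b, a] = r
    return mat


def write_annotation_table(
    annotations: Sequence[PeptideAnnotation], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tphylum\tgenus\tfunction\n")
        for ann in annotations:
            fh.write(f"{ann.peptide}\t{ann.phylum}\t{ann.genus}\t{ann.function}\n")


def write_profile(profile: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("label\tpercentage\n")
        for label, pct in profile.items():
            fh.write(f"{label}\t{pct:.6f}\n")


def plot_profile(profile: Mapping[str, float], path: str | Path, title: str = "") -> None:
    """Stacked-bar rendering of a single profile (optional output)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    bottom = 0.0
    for label, pct in profile.items():
        ax.bar([0], [pct], bottom=bottom, label=label)
        bottom += pct
    ax.set_ylabel("% of peptides")
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="center left", bbox_to_anchor=(1.0, 0.5))
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
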