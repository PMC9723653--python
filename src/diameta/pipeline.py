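"""End-to-end pipeline: deconvolve -> search -> library -> quantify -> annotate."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .annotate import (
    annotate_peptides,
    build_profile,
    correlation_matrix,
    overlap_matrix,
    write_annotation_table,
    write_profile,
)
from .deconvolution import DeconvolutionParams, deconvolve_run
from .library import build_library, read_library, write_library
from .quantify import QuantParams, quantify_all, write_matrix
from .search import DigestConfig, SearchConfig, search_run, write_matches
from .spectra_io import read_annotations, read_fasta, read_mzml, write_mgf

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "runs",
    "fasta",
    "annotations",
    "output_dir",
    "seed",
    "library",
    "deconvolution",
    "search",
    "library_params",
    "quantify",
    "annotate",
}


@dataclass
class PipelineConfig:
    runs: list[str]
    fasta: str | None = None
    annotations: str | None = None
    output_dir: str = "diameta_out"
    seed: int = 0
    library: str | None = None  # external library short-circuits deconvolution+search
    deconvolution: dict[str, Any] = field(default_factory=dict)
    search: dict[str, Any] = field(default_factory=dict)
    library_params: dict[str, Any] = field(default_factory=dict)
    quantify: dict[str, Any] = field(default_factory=dict)
    annotate: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if not raw.get("runs"):
            raise ValueError("config must list at least one run")
        if not raw.get("library") and not raw.get("fasta"):
            raise ValueError("config needs either a FASTA database or a library")
        return cls(**raw)

    def digest_hash(self) -> str:
        # output_dir is a location, not a parameter: same inputs written to
        # two directories must hash identically
        payload = {k: v for k, v in vars(self).items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Stages: deconvolve each run -> pool pseudospectra -> search -> build
    library -> quantify all runs -> annotate -> reports. An externally
    supplied library skips the deconvolution and search stages. A missing
    annotation table skips the annotation stage with a warning.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "read-runs"
    try:
        runs = [read_mzml(p) for p in config.runs]
        logger.info("loaded %d runs", len(runs))

        proteins = read_fasta(config.fasta) if config.fasta else []

        if config.library:
            stage = "load-library"
            library = read_library(config.library)
            logger.info("external library: %d entries", len(library))
        else:
            stage = "deconvolve"
            decon_params = DeconvolutionParams(**config.deconvolution)
            pseudospectra = []
            for run in runs:
                ps = deconvolve_run(run, decon_params)
                logger.info("run %s: %d pseudospectra", run.run_id, len(ps))
                pseudospectra.extend(ps)
            if pseudospectra:
                write_mgf(pseudospectra, out / "pseudospectra.mgf")
            _write_pseudospectrum_report(pseudospectra, out / "pseudospectra.tsv")

            stage = "search"
            search_cfg = SearchConfig(**config.search)
            digest_cfg = DigestConfig()
            accepted, all_matches = search_run(
                pseudospectra, proteins, digest_cfg, search_cfg
            )
            logger.info(
                "search: %d/%d pseudospectra accepted at %.1f%% FDR",
                len(accepted),
                len(all_matches),
                100 * search_cfg.fdr_threshold,
            )
            write_matches(all_matches, out / "matches.tsv")

            stage = "build-library"
            library = build_library(accepted, **config.library_params)
            logger.info("library: %d entries", len(library))

        write_library(library, out / "library.tsv")

        stage = "quantify"
        quant_params = QuantParams(**config.quantify)
        matrix = quantify_all(runs, library, quant_params)
        write_matrix(matrix, out / "quant_matrix.tsv")
        logger.info("quantified %d peptides across %d runs", *matrix.shape)

        stage = "annotate"
        if config.annotations and Path(config.annotations).exists():
            table = read_annotations(config.annotations)
            peptide_proteins = {}
            for e in library:
                peptide_proteins.setdefault(e.peptide, set()).update(e.protein_ids)
            annotations = annotate_peptides(
                {p: sorted(v) for p, v in peptide_proteins.items()}, table
            )
            write_annotation_table(annotations, out / "annotations.tsv")
            threshold = config.annotate.get("threshold", 0.005)
            for rank in ("phylum", "genus", "function"):
                profile = build_profile(
                    [a.label(rank) for a in annotations], threshold
                )
                write_profile(profile, out / f"profile_{rank}.tsv")
            _write_metrics(matrix, out)
        else:
            logger.warning("no annotation table; annotation stage skipped")
            _write_metrics(matrix, out)

        stage = "provenance"
        (out / "provenance.json").write_text(
            json.dumps(
                {
                    "tool": "diameta",
                    "version": __version__,
                    "config_hash": config.digest_hash(),
                    "n_runs": len(runs),
                },
                indent=1,
            )
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _write_pseudospectrum_report(pseudospectra, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("run_id\tprecursor_mz\tcharge\trt\tn_fragments\tn_complementary\n")
        for ps in pseudospectra:
            run_id = ps.provenance.rsplit(":", 1)[0]
            fh.write(
                f"{run_id}\t{ps.precursor_mz:.6f}\t{ps.charge}\t{ps.rt:.4f}\t"
                f"{ps.n_fragments}\t{ps.n_complementary}\n"
            )


def _write_metrics(matrix, out: Path) -> None:
    peptide_sets = {
        run_id: set(matrix.index[matrix[run_id].notna()]) for run_id in matrix.columns
    }
    overlap_matrix(peptide_sets).to_csv(out / "metrics_overlap.tsv", sep="\t")
    correlation_matrix(matrix).to_csv(out / "metrics_correlation.tsv", sep="\t")
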