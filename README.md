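# diameta

Untargeted DIA metaproteomics toolkit. From centroided DIA runs (mzML) and a
protein FASTA, `diameta`:

1. **deconvolves** each run into DDA-like pseudospectra (ion-trace detection
   in MS1 and per-isolation-window MS2 maps, fragment-to-precursor grouping
   by elution-profile Pearson correlation and apex proximity, complementary
   y/b-ion flagging),
2. **identifies** peptides by database search (tryptic in-silico digestion,
   b/y fragment matching, hyperscore-style scoring) with target-decoy FDR
   control at 1%,
3. assembles a **pseudospectral library** (one assay per peptide/charge,
   top-6 fragments),
4. **quantifies** library peptides in every run by targeted fragment XIC
   extraction with co-elution-scored peak picking and median-shift RT
   alignment, and
5. produces **peptide-centric taxonomic and functional profiles** (consensus
   annotation over all source proteins: unique label / ambiguous / unknown)
   plus replicate-reproducibility metrics.

A first-class **simulator** generates multi-taxon communities and DIA runs
with the standard acquisition geometry (MS1 survey scans of 375–1500 m/z
interleaved with 40 consecutive 15 m/z isolation windows over 400–1000 m/z,
Gaussian elution, co-eluting precursors, noise) together with a complete
ground-truth manifest, so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic dataset (FASTA + annotations + manifest + mzML runs)
diameta simulate --out sim/ --seed 7 --n-replicates 3

# individual stages
diameta deconvolve sim/rep0.mzML --out rep0.mgf
diameta search rep0.mgf --fasta sim/community.fasta --out matches.tsv
diameta build-library rep0.mgf --fasta sim/community.fasta --out library.tsv
diameta quantify sim/rep0.mzML sim/rep1.mzML --library library.tsv --out matrix.tsv
diameta annotate --library library.tsv --annotations sim/annotations.tsv --out ann/

# full pipeline from a YAML config
diameta run config.yaml --out results/ --seed 1
# DDA-assisted-style entry: supply an external library, skip deconvolution+search
diameta run config.yaml --library external_library.tsv
```

Minimal `config.yaml`:

```yaml
runs: [sim/rep0.mzML, sim/rep1.mzML]
fasta: sim/community.fasta
annotations: sim/annotations.tsv
output_dir: results
seed: 1
search: {fdr_threshold: 0.01}
```

The pipeline writes `pseudospectra.mgf`, `matches.tsv`, `library.tsv`,
`quant_matrix.tsv`, `annotations.tsv`, per-rank `profile_*.tsv`, pairwise
`metrics_overlap.tsv` / `metrics_correlation.tsv`, and `provenance.json`
(tool version + config hash). Reruns on identical inputs are
artifact-identical.

## Library TSV dialect

Tab-separated with columns `peptide`, `charge`, `precursor_mz`,
`reference_rt` (seconds), `fragment_mz` / `fragment_intensity`
(semicolon-joined, intensities relative to 1), `protein_ids`
(semicolon-joined). Externally built libraries in the same dialect can be
supplied via `--library`.

## Conventions

- m/z in Thomson, retention times in seconds (mzML minutes converted on read).
- DIA windows are half-open `[lower, upper)`; a precursor at a boundary
  belongs to the upper window.
- Fixed carbamidomethyl-C (+57.02146 Da); variable oxidation-M
  (+15.99491 Da, at most one, written `M(ox)`).
- Decoys are full-sequence reversals prefixed `DECOY_`; the FDR estimator is
  `(#decoys + 1) / #targets` with q-value monotonization.
- Profile-mode spectra are rejected (centroided input required).
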