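# conformer-ddg

Conformer-ensemble-aware analysis of the stability effects of single amino
acid substitutions (SASs). A protein's native state is an ensemble of
conformers, and the estimated folding free-energy change (ΔΔG) of a
substitution depends on which conformer it is computed from. This package
quantifies that dependence and evaluates how conformer-selection strategies
affect disease-vs-neutral discrimination from ΔΔG values.

What it does:

* **Structure geometry** — parses single- and multi-model PDB files,
  superposes conformer pairs with the Kabsch algorithm on commonly resolved
  Cα positions (pairwise RMSD matrix, RMSDmax), and computes per-residue
  solvent-accessible surface area with a deterministic Shrake–Rupley
  sampler (golden-spiral point set, probe 1.4 Å), with buried/exposed
  classes at 20 Å² and per-position ΔASA across conformers.
* **Variant I/O** — TSV readers/writers for SAS annotation tables and
  per-(SAS, conformer) ΔΔG tables in kcal/mol (positive = destabilizing,
  `NA` = missing), a convenience reader for the fixed-width human-variant
  list dialect, and an adapter contract for external stability engines
  (FoldX-style; the engine itself is out of scope).
* **Ensemble statistics** — per-SAS min/max/mean ΔΔG and spread,
  three-way stability classification at a symmetric threshold (default
  ±2 kcal/mol), conformer-ambiguity flags per SAS and per protein, and a
  binned signed-ΔASA vs ΔΔG-spread report.
* **Evaluation** — disease-vs-neutral prediction (|ΔΔG| > τ ⇒ disease)
  under five conformer-selection strategies (Global, Minimum, Maximum,
  Average, Random baseline with resampling p-value), MCC / accuracy /
  specificity / sensitivity, per-conformer metrics, the fraction of SASs
  with a perfectly agreeing conformer, bound-state enrichment of the
  max-ΔΔG conformer, and two-sample Kolmogorov–Smirnov comparisons.
* **Synthetic data** — a seeded hierarchical generator (proteins →
  conformers → SASs → per-conformer ΔΔG with right-skewed conformer
  deviations) calibrated to realistic class-conditional min/max ΔΔG means,
  plus toy multi-conformer PDB fixtures with closed-form pairwise RMSD.

## Command line

The `conformer-ddg` entry point provides four subcommands; every run writes
a `manifest.json` recording inputs, configuration and outputs.

```sh
# generate a synthetic dataset (sas.tsv, ddg.tsv, conformers.tsv)
conformer-ddg simulate --n-proteins 119 --seed 1 --out runs/sim

# RMSD + ASA for a directory of PDB files (one protein per file,
# MODEL blocks = conformers)
conformer-ddg geometry pdbs/ --out runs/geo

# per-SAS summaries, ambiguity report, binned ΔASA analysis
conformer-ddg analyze runs/sim/ddg.tsv runs/sim/sas.tsv \
    --geometry-dir runs/geo --tau 2.0 --out runs/ana

# strategy comparison table + per-conformer metrics + p-value
conformer-ddg evaluate runs/sim/ddg.tsv runs/sim/sas.tsv \
    --seed 1 --n-resamples 1000 --out runs/ev
```

Exit codes: 0 success, 1 data error, 2 usage error.

## Input formats

* SAS table: TSV with header `protein_id  position  wt_aa  mut_aa  label`;
  labels `Disease`/`Polymorphism` (any case) normalize to
  `disease`/`neutral`.
* ΔΔG table: TSV with header `protein_id position wt_aa mut_aa
  conformer_id ddg_kcal_mol`; the literal `NA` marks a missing cell; each
  SAS needs at least one value.
* Structures: PDB format; alternate locations resolve to the
  highest-occupancy copy, waters/HETATM/hydrogens are excluded from the
  ASA atom set.

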