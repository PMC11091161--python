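# locohd

Local composition Hellinger distance (LoCoHD) for protein structures: a
metric that compares the *chemical composition* of two local residue
environments rather than their coordinates.

Structures are mapped to clouds of typed "primitive" atoms under one of
four typing schemes; each anchor atom gets a radius-indexed composition
vector (the fraction of each primitive type within a sphere), and an
anchor pair is scored by the Hellinger distance between the two
composition profiles averaged over a probability density on the radius
(default: uniform on 3–10 Å, hetero-residue contacts only). Because
compositions only change at neighbor distances, the integral is
evaluated exactly as a finite sum.

## What's here

- `locohd.structure_io` — PDB/mmCIF reading (Biopython-backed),
  standardization (heavy atoms of canonical residues, altloc and
  occupancy policy), chain pairing by sequence alignment, pruning of a
  reference/model pair to a common atom inventory, PDB writing.
- `locohd.primitives` — the FA, CG, FA+Cent and CG+Cent typing schemes.
  Rule tables are packaged plain-text data (`src/locohd/data/*.txt`) and
  can be replaced with `--scheme-file`/`scheme_file=`. Only a handful of
  assignments are published for these schemes; the shipped tables
  document every choice (protonation at pH 7, His aromatic, etc.) but
  exact numeric parity with other implementations is not guaranteed.
- `locohd.core` — environments, composition vectors, the Hellinger
  distance and the exact piecewise score; uniform weight function.
- `locohd.workflows` — ensemble distance matrices (per anchor and
  averaged), SVD-superposition (Kabsch) RMSD, complete-linkage
  clustering, Spearman correlation, reference-vs-model per-residue
  scoring with external score joining (e.g. lDDT, which this package
  consumes but never computes), trajectory time series and Sarle's
  bimodality coefficient (uniform-distribution reference 5/9 ≈ 0.555).
- `locohd.randstats` — random residue-pair sampling protocol,
  per-type-pair descriptor tables, Beta-distribution ML fit with KS test,
  20×20 mean-score matrix.
- `locohd.fixtures` — deterministic synthetic inputs: toy clouds,
  minimal PDB files for arbitrary sequences, noise/cluster ensembles and
  two-state trajectories with planted truth. Side chains are named
  placeholders at crude geometry, not physical models.

## CLI

```sh
locohd compare REF.pdb MODEL.pdb --scheme FA+Cent --out out/
locohd ensemble ENSEMBLE.pdb --scheme CG --with-rmsd --cluster-k 2 --out out/
locohd trajectory FRAMES.pdb --scheme CG+Cent --out out/
locohd sample-random *.pdb --scheme FA+Cent --seed 1 --out out/
locohd fixtures --kind trajectory --n 30 --seed 1 --out out/
```

Shared flags: `--scheme {FA,CG,FA+Cent,CG+Cent}`, `--wmin/--wmax` (weight
bounds, Å), `--hetero-only/--all-contacts`, `--seed`, `--out`. Every
command echoes its exact configuration to `config.json` in the output
directory and is byte-reproducible for fixed inputs and seed. Exit
codes: 0 ok, 2 configuration, 3 input/parse, 4 domain error.

Trajectories are consumed as multi-model PDB; export frames from binary
trajectory formats upstream (e.g. with MDAnalysis) before analysis.

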