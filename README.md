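# morphodisp

Landmark-based cranial shape disparity analysis: generalized Procrustes
superimposition, allometry-corrected principal components, and
bootstrap-equalized delta-variance permutation tests for comparing the
morphological disparity of two groups (e.g. two mammalian clades), whole-skull
or per skull region.

## What it does

- **`morphodisp.landmark_io`** — read/write 3D landmark tables (`csv_long`,
  `csv_wide`, and a 3D TPS dialect), species metadata (clade, sex, diet,
  habitat, activity — closed vocabularies), and landmark schemes that assign
  landmarks to skull regions. A built-in 32-landmark cranial scheme
  (`load_scheme("table3")`) tags each landmark as oral, viscerocranial
  (oral/non-oral/both), or neurocranial and supports region queries
  (`whole_skull`, `neurocranium`, `viscerocranium`, `viscerocranium_non_oral`,
  `oral`).
- **`morphodisp.superimposition`** — centroid size, Kabsch rotations
  (reflections excluded), iterative generalized Procrustes analysis with
  unit-centroid-size scaling, and partial Procrustes distances.
- **`morphodisp.shape_space`** — PCA of aligned shapes; allometric size
  correction by regressing PC scores on log centroid size and re-decomposing
  the residuals; 2D convex-hull morphospace areas.
- **`morphodisp.disparity`** — Procrustes variance per group, stratified
  bootstrap equalization of group sizes, the delta-variance permutation test
  (pooled residual distances shuffled between groups), Bonferroni thresholds,
  and a battery runner producing one test per (grouping × skull region) with
  the emitted row count as the Bonferroni divisor.
- **`morphodisp.synthetic`** — synthetic landmark studies with known ground
  truth: tangent-space perturbations with planted variance, optional
  allometric signal tied to log centroid size, per-region variance
  multipliers, and clade/sex/ecology labels.

## CLI

Three subcommands, each driven by a YAML config and a global seed; every
output directory gets a `manifest.json` with per-file sha256 checksums, and
re-running with an unchanged config is bit-identical.

```bash
# generate a synthetic two-clade study
morphodisp simulate --config examples/sim.yaml --out scratch/sim

# full chain: read -> GPA -> allometry correction -> disparity battery
morphodisp run --config examples/run.yaml --out scratch/run \
    --regions whole_skull,neurocranium,viscerocranium,viscerocranium_non_oral,oral

# PC scores (raw + size-corrected), percent variance, hull areas
morphodisp pca --config examples/run.yaml --out scratch/pca
```

A minimal `run` config:

```yaml
landmarks: scratch/sim/landmarks.csv
metadata: scratch/sim/metadata.csv
scheme: table3
regions: [whole_skull, neurocranium]
seed: 1
plan: {n_bootstrap: 1000, n_permutations: 1000}
groupings:
  - label: all
    filter_a: {clade: marsupial}
    filter_b: {clade: placental}
```

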