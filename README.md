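# hemevox

Structure–function analysis of heme-binding pockets: does the tertiary
structure of a heme protein's active site determine its biological
function?  `hemevox` implements the full analysis pipeline for that
question — from structure files to a trained 3-D convolutional classifier
and pocket-shape statistics — for the four classical heme-protein function
classes: oxygen binders (OB), oxidoreductases (OR), dual-function proteins
(OB–OR) and electron-transport proteins (ET).

## What it does

1. **Site extraction** (`hemevox.sites`) — parses PDBx/mmCIF files,
   resolves alternate locations by occupancy (largest wins; smallest
   altloc id on ties), locates Fe–porphyrin cofactors (HEM/HEA/HEB/HEC/HEO),
   and filters sites: the 25-heavy-atom skeleton must be complete, an
   amino-acid or water axial ligand must lie within 3.1 Å of the iron,
   heme coverage by the host protein must reach 0.6, and redundant chains
   (greedy global-identity filter, threshold configurable from 25 % to
   99.99 %) are dropped.
2. **Function labelling** (`hemevox.function`) — a fixed cascade over EC
   numbers, GO terms, entry keywords and descriptions, plus curated
   dual-function overrides for dehaloperoxidase and engineered myoglobins.
   Classes are encoded as multi-label bit vectors, one position per
   function: OB = (0,1), OR = (1,0), OB–OR = (1,1), and in the three-label
   scheme OB = (0,1,0), OR = (1,0,0), OB–OR = (1,1,0), ET = (0,0,1).
3. **Voxelization** (`hemevox.voxel`) — every pocket is expressed in a
   heme-centric frame (xy = least-squares plane of the four methine
   carbons, x along the in-plane CHA→CHC direction, origin at the methine
   barycenter) and binned into a binary occupancy cube (24 Å edge, 1 Å
   voxels, four element channels C/N/O/S).
4. **Classification** (`hemevox.nn`, `hemevox.model`) — a compact 3-D CNN
   (three 2×2×2 convolutions with 64/128/128 channels, batch norm, max
   pooling, two dense layers, sigmoid multi-label head; with a 22-point
   input edge the flattened layer has 128,000 units) trained with SGD
   (learning rate 0.01, batch 32) on binary cross-entropy, evaluated by
   stratified five-fold cross-validation.  The headline score is

   ```
   Sacc = Σ_c N_c^TP / Σ_c N_c
   ```

   over the class list L, where a prediction counts as a true positive
   only when the whole label vector matches exactly.
5. **Occlusion analysis** (`hemevox.occlusion`) — re-scores trained models
   after zeroing voxels outside or inside a shrinking cube of parameter r,
   reporting Sacc against r and against the retained volume
   ((24−2r)³ outside, 24³−(2r)³ inside).
6. **Cavity-shape dispersion** (`hemevox.cavity`) — binary cavity vectors
   on a fixed 1 Å lattice within 8.5 Å of the iron (1 = cavity, 0 =
   within a van-der-Waals radius of a protein atom), compared across a
   group I by the mean distance from the barycenter
   d̄_I = (1/N_I) Σ_i ‖v_i − μ_I‖.
7. **Synthetic data** (`hemevox.synthetic`) — a generator of labelled
   heme sites whose protein clouds carry class-distinctive geometric
   motifs, so the entire pipeline is testable without any download.

The network is implemented directly in NumPy (im2col convolutions,
hand-written backpropagation verified against numerical gradients), so the
package has no deep-learning-framework dependency.

## Worked example

Five-fold cross-validation on a synthetic 3-class dataset (30 sites per
class, 3 Å voxels, 12 epochs):

```python
import hemevox as hv
from hemevox.model import TrainConfig, cross_validate

specs = hv.default_class_specs(("OB-like", "OR-like", "ET-like"), seed=0)
ds = hv.generate_dataset(specs, n_per_class=30, seed=0)
X = hv.stack_voxels(ds.sites, edge=24.0, voxel=3.0)
run = cross_validate(X, ds.class_names, scheme="three-label",
                     config=TrainConfig(epochs=12, seed=0))
mean, sd = run.sacc_mean_sd()
print(f"Sacc = {mean:.3f} +/- {sd:.3f}")
print(run.summary.to_frame("combined"))
```

prints

```
Sacc = 0.978 +/- 0.027
    OB  OR  ET  Others
OB  29   0   0       1
OR   0  30   0       0
ET   0   0  29       1
```

i.e. 88 of 90 held-out sites get the exact label vector right; the two
misses produce the all-zero vector, which decodes to the catch-all
"Others" outcome.  The same run object feeds `occlusion_sweep` and the
cavity vectors feed `group_table`, which on this dataset reports per-class
dispersions d̄ of 17.7–21.2 with within-class sd below 0.5 — synthetic
classes are internally far more homogeneous than real protein families.

The same workflow is available from a shell:

```sh
hemevox simulate --classes OB,OR,ET --n 30 --seed 0 --out synth/
hemevox extract  --cif-dir synth/ --out extracted/
hemevox assign   --annotations synth/annotations.csv --sites extracted/sites.csv --out labels.csv
hemevox voxelize --cif-dir synth/ --voxel 3 --out voxels.npz
hemevox train    --voxels voxels.npz --labels labels.csv --scheme three-label --epochs 12 --out run/
hemevox occlude  --run run/ --voxels voxels.npz --mode outside --out occl/
hemevox cavity   --cif-dir synth/ --groups labels.csv --out cavity/
```

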