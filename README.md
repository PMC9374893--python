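# wmlseg

Cross-resolution white-matter-lesion segmentation: train a high-resolution 3D
"T1-space" lesion segmenter from sparse, thick-slice 2D "FLAIR-space" target
masks via a spatially sparse loss — together with loss-ranked training-set
curation, white-matter region partitioning, augmentations, and
thick-slice-space DICE evaluation. Everything is exercisable on synthetic
paired-resolution phantoms; no scanner data or GPU is required.

## The idea

A thick-slice 2D FLAIR stack carries reliable lesion labels but only a few
slices' worth of spatial information; the 3D T1 volume has full resolution
but ambiguous contrast (lesions look like gray matter). During training, each
FLAIR voxel center is back-projected onto the *single nearest* high-res voxel
(optionally through an augmentation transform) and contributes one squared
error term there. High-res voxels that are not the nearest neighbour of any
FLAIR center get no loss and exactly zero gradient — the target is never
interpolated, so the model, exposed to many subjects, fills in the missing
resolution itself instead of learning interpolation artifacts. An auxiliary
dense cortical-ribbon output (weight 0.001 by default) stabilizes training.

Because no deep-learning framework is assumed, the three U-shaped network
topologies (index-preserving max-unpooling, skip *sums*, instance norm,
scalable widths) run on a small numpy layer library with hand-written,
finite-difference-verified backprop (`wmlseg.nn`).

## CLI

```sh
# synthetic paired-resolution dataset (NIfTI + manifest CSV)
wmlseg simulate --out-dir data/ --n-subjects 8 --shape 32 32 48 \
    --pv-radius 4 --jc-radius 2 --lesions 2 0 2

# two-step FLAIR-space curation workflow: mimic-train, rank, (correct), retrain
wmlseg train-flair --manifest data/manifest.csv --out-dir flair_run/
wmlseg curate --manifest data/manifest.csv \
    --model flair_run/flair_model.npz --out ranked.csv

# cross-modality high-res training from thick-slice targets
wmlseg train-t1 --manifest data/manifest.csv --out-dir t1_run/ \
    --loss sparse        # or: --loss dense (interpolating baseline)

# region net with simulated-lacune augmentation
wmlseg train-roi --manifest data/manifest.csv --out-dir roi_run/

# inference + regional lesion volumes
wmlseg segment data/sub-000/t1.nii.gz --model t1_run/t1_model.npz \
    --out-dir seg/

# DICE in resampled thick-slice space
wmlseg evaluate --manifest eval.csv --out-dir eval_out/
```

Rigid FLAIR-to-T1 transforms are plain-text 4x4 matrices (NIfTI world-mm
convention, acting on homogeneous coordinates). The canonical high-res
working grid is 184 x 202 x 72 voxels at 1 x 1 x 1.5 mm (`wmlseg.io.CANONICAL_GRID`).

## Package layout

| module | role |
| --- | --- |
| `wmlseg.grids` | grids, rigid transforms, FLAIR-to-T1 sampling maps, resampling |
| `wmlseg.phantom` | synthetic paired-resolution phantoms + target corruption |
| `wmlseg.nn` / `wmlseg.nets` | numpy layers with backprop; the three U-Net topologies |
| `wmlseg.losses` | sparse cross-resolution loss, ribbon loss, dense baseline |
| `wmlseg.augment` | constrained random affines, histogram warps, simulated lacunes |
| `wmlseg.training` | batch-1 ADAM loop, loss-ranked curation, T1 training driver |
| `wmlseg.rois` | periventricular / deep / juxtacortical partition, regional volumes |
| `wmlseg.evaluation` | DICE in thick-slice space, volume-binned summaries, paired t |
| `wmlseg.io` / `wmlseg.cli` | NIfTI, manifests, configs, the `wmlseg` CLI |
| `wmlseg.experiments` | seeded desk-scale experiments behind the acceptance report |
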