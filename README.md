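# nucseg

Training-free detection, instance segmentation and counting of
fluorescent-labeled cell nuclei in microscopy images.

High-throughput time-lapse screens produce thousands of large frames per
experiment, and learning-based segmenters need per-dataset annotation and
retraining to follow them. `nucseg` targets the biologist who needs
reliable nucleus counts and masks *now*: a classical, fully interpretable
pipeline whose handful of parameters (filter bandwidths, structuring-
element radii, a minimum object size) can be read and adjusted directly,
with no training phase at all.

## Method

For a frame *I* the pipeline computes, in order:

1. **Bilateral smoothing** — each pixel becomes the weighted mean
   `Σ I(q)·c(p,q)·s(p,q) / Σ c(p,q)·s(p,q)` with Gaussian spatial kernel
   `c = exp(−‖p−q‖²/2σ_s²)` and intensity kernel
   `s = exp(−(I(p)−I(q))²/2σ_c²)`; defaults σ_c = 1, σ_s = the global
   intensity standard deviation. Denoises while preserving nuclear edges.
2. **White top-hat** — `T = I − (I ∘ b)`, opening by a flat disk of
   radius 21 px; removes uneven illumination, keeps nuclei.
3. **Foreground refinement** — Otsu threshold, hole filling, opening
   (disk r = 1), deletion of components < 40 px (strict), closing
   (disk r = 2).
4. **Seed selection** — 5×5 chamfer Euclidean distance transform of the
   mask, stretched to [0, 255]; regional maxima (5×5 window) dilated by a
   disk of radius 3 become one labeled marker per nucleus.
5. **Marker-controlled watershed** — flooding of the Laplacian edge image
   from the seeds through a (value, FIFO) priority queue, confined to the
   foreground; touching nuclei split along the edge ridge between them.

Evaluation utilities score segmentations with `DSC = 2|S∩T|/(|S|+|T|)`
and `IoU = |S∩T|/|S∪T|` (percent, with `IoU = DSC/(2−DSC)`), and count
agreement with Pearson correlation and Bland-Altman limits
(bias ± 1.96 SD of automated − manual differences). A synthetic scene
generator renders nuclei images with exact ground-truth label maps.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

```python
from nucseg import SceneSpec, generate_scene, segment_image, count_cells, dice

sample = generate_scene(SceneSpec(height=256, width=256, n_nuclei=12, seed=3))
labels = segment_image(sample.image)
print("planted:", sample.n_nuclei)
print("counted:", count_cells(labels))
print(f"dice vs truth: {dice(labels, sample.truth):.2f} %")
```

prints

```
planted: 12
counted: 12
dice vs truth: 97.45 %
```

All twelve planted nuclei are recovered as separate instances and the
binary mask overlaps the exact ground truth at DSC ≈ 97% — the missing
few percent are the soft rim pixels around each nucleus, which sit near
the threshold.

The same pipeline runs from the shell over whole folders:

```sh
nucseg synth -o frames -n 5 --max-count 40   # synthetic frames + truth/
nucseg segment frames -o out -w 4            # label maps, counts.csv, manifest.json
nucseg evaluate out frames/truth -o report.csv
```

Label maps keep the input file names (so predictions pair with truth by
name) and are written alongside `counts.csv`. Worker counts only change
throughput: outputs are byte-identical for any `-w`.

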