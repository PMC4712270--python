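# tjquant

Morphometry of tight-junction immunostaining and related blood–brain
barrier (BBB) markers in 2D fluorescence micrographs, with the group
statistics used to compare stress or treatment groups against an unstressed
control.

Brain capillary endothelial cells seal the BBB with tight junctions (TJs)
whose principal proteins, claudin-5 and occludin, appear in confocal images
as branched linear strands along vessel walls. Stress and disease fragment
and simplify this network, change transporter (GLUT-1) and astroglial
(GFAP) staining intensity, and alter capillary ultrastructure. `tjquant`
implements the image-analysis battery used to quantify those changes:

* **ROI intensity** — ten 7×7-px rectangles placed at random on intensely
  immunolabeled structures and five on background; per-pixel averages; the
  background average subtracted from the labeled-area average.
* **Complexity index** — the thresholded TJ network is thinned to a
  one-pixel skeleton; `CI = (number of branch points) / (strand length)`,
  with diagonal steps weighted √2. A fragmented, less branched network has
  a lower CI.
* **Mean object size** — summed connected-component area divided by
  component count on the thresholded image.
* **Image entropy** — Shannon entropy `H = −Σ p log₂ p` of the 256-bin
  gray-level histogram of the grayscale image; disordered staining raises
  H (0 ≤ H ≤ 8 bits).
* **Cell density** — threshold to 1-bit, label particles, keep those with
  area > 50 µm² and circularity `4πA/P²` in [0, 1], report cells per
  1000 µm².
* **Ultrastructure tally** — categorical per-capillary electron-microscopy
  annotations (luminal membrane, tight junction, basal membrane, astroglia)
  aggregated into percentage tables by region × group.
* **Group statistics** — per-group normality gate (Lilliefors KS), then
  one-way ANOVA + Bonferroni pairwise tests, or Kruskal–Wallis + Dunn's
  tests on the rank branch; results as mean ± SEM in percent of control
  with `*`/`**`/`***` significance grades at p < 0.05/0.01/0.001.

No suitable public image set accompanies the procedures, so the package
ships a first-class synthetic-data module that renders the three staining
phenotypes with exact ground truth: branched junction-strand networks with
controllable branch density and fragmentation, blob-shaped intensity
fields, and fields of non-overlapping elliptical cells. Every metric is
validated against these ground truths.

## Worked example

```python
from tjquant import (JunctionSimParams, simulate_junction_image,
                     threshold_image, skeletonize_mask, skeleton_metrics,
                     image_entropy)
from tjquant.morphometry import prune_spurs

img, truth = simulate_junction_image(
    JunctionSimParams(seed=0, branch_prob=0.05, fragmentation=0.0, noise_sd=0.0))
mask = threshold_image(img)                      # Otsu, threshold recorded
skel = prune_spurs(skeletonize_mask(mask), 4)    # 1-px skeleton, spurs removed
m = skeleton_metrics(skel)
print(m.n_branch_points, len(truth.true_branch_points))
print(round(m.strand_length_px, 1), round(m.complexity_index, 5))
print(round(image_entropy(img).entropy_bits, 3))
```

prints

```
121 121
11124.0 0.01088
0.497
```

— the detected branch-point count equals the generator's ground truth
exactly; the network has ~11 100 px of strand at complexity 0.0109; the
noise-free two-level image has low histogram entropy (0.497 bits).

A full run — simulate two groups, measure every image, normalize to
control, test — is one command:

```bash
tjquant run --config run.yaml
```

which writes `metrics.csv` (one row per image), `stats_<metric>.csv`
(pairwise adjusted p-values), `report_<metric>.csv` (mean ± SEM in percent
of control with stars) and `provenance.json` (every parameter and derived
seed). Subcommands `simulate`, `intensity`, `junctions`, `density`,
`emtally` and `stats` expose the individual stages.

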