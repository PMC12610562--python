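# kernelpheno

Threshold-based computer vision for high-throughput walnut kernel
phenotyping on staged 100-cell trays.

Walnut breeding programs grade kernel (pellicle) color on a four-point
ordinal scale — amber (1), light amber (2), light (3), extra light (4) —
and grade drives price, so subjective human scoring directly affects
growers. This package replaces that scoring with objective, repeatable
measurements from staged tray photographs: shelled kernel halves are placed
embryo-side down in a blue 10 × 10 tray (two adjacent columns per tree
sample, label sticker under the first column of each pair) and photographed
under fixed lighting at 3300 × 3120 px.

The pipeline is deliberately simple and fully rule-based:

1. **Geometry** — barrel-lens correction with the radial polynomial
   `r_src = r (a r³ + b r² + c r + d)`, `d = 1 − (a+b+c)`, default
   coefficients `(0, −0.22, 0)`; rotation estimated from the x-offset of
   the tray's left edge between the top and bottom 20% scan bands; scan
   cropping to the canonical 2780 × 2780 tray.
2. **Segmentation** — inside each fixed 270 × 270 px cell, a pixel is
   *tray* iff `r − b ≤ −40` (the blue tray vs. warm kernels); everything
   else is kernel. Cells with fewer than 500 kernel pixels are empty (the
   debris filter). Per kernel: pixel count, mean and 10/25/50/75/90th
   percentiles of R, G, B and CIELAB L\*, a\*, b\*.
3. **Color grades** — ordinal human scores are regressed on median L\*
   (`score = α + β L*`) and the fitted line inverted at 1.5 / 2.5 / 3.5 to
   get three equally spaced L\* cutoffs; kernels and individual pixels are
   then classified into the four bands (per-kernel *pixel composition*).
4. **Blank detection** — underdeveloped ("blank") kernels, ~2.4% of the
   crop, are flagged by a logistic GLM on kernel size, 10th-percentile L\*,
   mean red and mean blue, and excluded from color datasets. Evaluation
   reports accuracy, precision, recall and F1 with blank as the positive
   class.
5. **Aggregation** — labels attach samples to column pairs; the two halves
   of each nut are averaged (unweighted) into per-nut records; agreement
   between two measurement methods is summarized by r², slope and mean
   (percent) difference.

A synthetic tray generator (`kernelpheno.synthetic_tray`) renders captures
with exact ground truth — masks whose pixel counts are exact, known colors,
known rotation — so the entire pipeline is testable without real images.

## Worked example

```python
import pandas as pd
from kernelpheno import (synthetic_tray as st, image_geometry as ig,
                         grid_segmentation as gs, pipeline_io as pio)

scene = st.random_scene(seed=7)            # full 3300x3120 capture, 100 kernels
image, truth = st.render_tray(scene)

res = ig.preprocess(image, barrel=None)    # rotation + crop (no lens model here)
print(res.angle_deg, res.image.shape[:2])  # 0.000 (2780, 2780)

records = gs.segment_image(res.image, st.TrayGeometry().grid(), image_id="tray00007")
print(sum(not r.is_empty for r in records))  # 100

sidecar = pd.DataFrame({"image_id": "tray00007",
                        "column": list(truth.labels),
                        "label": list(truth.labels.values())})
nuts = pio.group_into_nuts(records, pio.decode_labels(sidecar=sidecar,
                                                      image_id="tray00007"))
print(pio.nuts_to_frame(nuts)[["label", "nut_index", "n_pixels", "L_p50"]].head(3))
```

prints

```
     label  nut_index  n_pixels     L_p50
GEN0007-C1          1   14145.0 70.832324
GEN0007-C1          2   13915.0 60.644114
GEN0007-C1          3   11421.0 59.168802
```

`n_pixels` is the per-nut mean kernel size in pixels (a size proxy at fixed
camera distance) and `L_p50` the per-nut median lightness, the quantity the
color grade is calibrated on. On this noise-free tray, per-nut median L\*
agrees with the generator's ground truth at r² = 1.000, slope 1.000.

The same stages are available from the shell:

```bash
kernelpheno simulate --seed 7 --out-dir trays/
kernelpheno preprocess trays/tray00007.png --out-dir cropped/
kernelpheno segment cropped/tray00007_cropped.png --out records.csv
kernelpheno aggregate --records records.csv --labels sidecar.csv --out nuts.csv
kernelpheno compare --x a.csv:L_p50 --y b.csv:L_p50
```

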