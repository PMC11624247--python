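# psicic

Segmentation, detection and sector annotation of red/white **sectored
*Saccharomyces cerevisiae* colonies** in plate images.

Yeast carrying the Sup35 prion grow into white [PSI+] colonies; cells that
lose the prion produce red [psi-] pigment, and prion loss during colony
growth appears as red wedge-shaped *sectors* inside a white colony. The
number and size of sectors record prion-curing events, but plate images are
usually scored by hand as just "sectored or not". This package is for
experimentalists and modelers who want that structure quantified per colony,
at plate scale.

## What it does

1. **Simulate** — renders synthetic plates (table, plate, border with
   aberrations, circular colonies with red angular sectors, Poisson shot
   noise) together with pixel-exact ground-truth masks, so the segmentation
   network trains without any hand-annotated data.
2. **Segment** — a U-Net-style fully convolutional network maps an RGB
   plate image to a per-pixel 3-class label mask (background / red colony /
   white colony), at the input's full resolution.
3. **Detect** — a circle Hough transform on the binarized mask locates
   colonies; detections near the image border are excluded and square crops
   are cut from the image and mask.
4. **Annotate** — each colony's boundary skeleton is decomposed into
   monochrome arcs; arcs are closed into "idealized sectors" by radii from
   their endpoints to the colony center. Each region R is scored by its
   purity

   `p(R) = (pixels matching R's color) / (all colony pixels in R)`,

   and regions with p < 0.5 are iteratively corrected: their boundary arc
   is flipped to the other color and same-color neighbors merge (the
   mediant inequality guarantees merged regions stay above threshold). The
   colony purity `p_w` is the size-weighted mean of region purities.
5. **Classify** — no red region → [PSI+]; no white region → [psi-];
   otherwise sectored with sector count = number of red regions (S1, S2,
   ...), plus precision/recall/F1 evaluation against ground truth.

## Worked example

```python
import dataclasses
from psicic import colonysim, platedetect, sectorannot, classify_eval

spec = dataclasses.replace(
    colonysim.scaled_spec(256, rng_seed=7), n_colonies=5, noise_enabled=False
)
plate = colonysim.generate_plate(spec)

detections = platedetect.detect_colonies(plate.class_mask, spec.radius_range)
print(f"{len(detections)} colonies detected")

for det in detections[:3]:
    crop = platedetect.crop_colony(plate.image, plate.class_mask, det, pad_factor=1.5)
    ann = sectorannot.annotate_colony(crop.mask)
    call = classify_eval.assign_class(ann)
    print(
        f"colony at {det.center}: {call.label:4s}  "
        f"a={ann.a} b={ann.b} p_w={ann.weighted_purity:.3f}"
    )
```

prints

```
5 colonies detected
colony at (115, 129): S1    a=1 b=1 p_w=0.997
colony at (82, 76): S1    a=1 b=1 p_w=0.981
colony at (81, 216): S1    a=1 b=1 p_w=0.996
```

Each colony was generated with exactly one red sector; the annotation finds
one red and one white region (`a=1`, `b=1`), classifies the colony S1
(sectored, one sector), and reports a colony purity `p_w` near 1, meaning
the proposed idealized sectors almost perfectly match the segmentation.

The trainable parts expose a sklearn-style estimator interface:

```python
from psicic import UNetSegmenter, SectorAnnotator

seg = UNetSegmenter(input_size=128, epochs=100).fit(train_images, train_masks)
masks = seg.predict(test_images)
labels = SectorAnnotator().predict(colony_crops)  # "PSI+" / "psi-" / "S1" ...
```

## Command line

```
psicic simulate --n-images 30 --image-size 128 --seed 0 --out-dir plates/
psicic train    --data-dir plates/ --profile desk --out-dir run/
psicic segment  --weights run/model.npz --image plate.png --out mask.png
psicic detect   --mask mask.png --min-radius 10 --max-radius 14 --out det.csv
psicic annotate --mask colony.png --out ann.json --overlay overlay.png
psicic run-all  --out-dir run/ --profile desk --seed 0        # full pipeline
psicic run-all  --out-dir run/ --oracle --n-images 6          # ground-truth masks
```

`run-all` writes per-stage artifacts (plates, predicted masks,
`detections.csv`, `annotations.jsonl`, `per_colony_calls.csv`,
`metrics.json`) plus a manifest, and is resumable stage by stage. The
`--oracle` mode feeds ground-truth masks directly to detection and
annotation, exercising the geometric pipeline independently of training.

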