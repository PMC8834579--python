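# nucleoshape

Quantitative analysis of nuclear morphology and nuclear-envelope
abnormalities in 2D fluorescence micrographs.

Deviations from a cell type's normal nuclear shape — lobulation, envelope
blebs, envelope invaginations (the nucleoplasmic reticulum), micronuclei —
accompany cancers, laminopathies and premature-aging syndromes, and scoring
them by eye is slow and observer-biased. `nucleoshape` provides an automated
pipeline for cell biologists and high-content-screening groups: it segments
nuclei from a DNA stain, computes a panel of shape descriptors per nucleus,
and detects micronuclei, intranuclear lamin-B structures and nuclear blebs,
emitting tidy per-object CSV tables and a JSON run summary.

## Shape descriptors

For a nucleus of area *A* and perimeter *P* (both measured on the sub-pixel
0.5-level contour polygon, so a circle scores exactly 1):

| descriptor | definition | circle |
|---|---|---|
| form factor (circularity) | 4πA / P² | 1 |
| eccentricity | √(1 − (b/a)²) of the moment-equivalent ellipse | 0 |
| axis ratio | a / b | 1 |
| solidity | A / A(convex hull), pixel-counted | 1 |
| mean negative curvature | mean of the signed boundary curvature κ(s) over concave arcs | 0 |
| elliptic Fourier | harmonics needed at 95% fidelity, or Σₙ₌₂ Eₙ / E₁ with Eₙ = aₙ²+bₙ²+cₙ²+dₙ² | 1 / ≈0 |
| radial asymmetry | fraction of pixels outside the largest inscribed circle | ≈0 |
| point asymmetry | fraction of pixels with no partner under reflection through the centroid | 0 |

Different descriptors are sensitive to different aberrations: eccentricity
separates elongated from round nuclei, while solidity and form factor
respond to lobulation and blebs.

## Abnormality detectors

* **Micronuclei** — dual-threshold segmentation of the DNA (or
  envelope/nucleoplasm) stain, nucleus cleanup by iterated erosion/dilation,
  cell territories by nuclear-mask dilation (or a whole-cell stain), then
  classification by comparative size within the cell: an object is a
  micronucleus when its equivalent diameter is at most 1/3 of its nucleus'
  diameter. Reports the micronucleation frequency (% of nuclei with ≥ 1
  micronucleus).
* **Envelope invaginations** — high-lamin-B objects per nucleus; shrinking
  the nucleus mask by a few pixels separates envelope-rim lamin from
  intranuclear lamin, whose components are counted and measured.
* **Blebs** — two pipelines: (A) subtraction of the filled lamin-B object
  from a permissively thresholded chromatin object (blebs contain less DNA
  and lack lamin B), with per-bleb enrichment of any extra channel
  (e.g. lamin A/C); (B) a purely morphological variant for single-stain
  images: an aggressive disk opening cuts blebs off the nuclear core, and
  residuals that touch the core are kept unless they are small *and*
  circular (micronuclei).

A synthetic-micrograph generator (`nucleoshape.synthetic`) renders
multichannel scenes with planted nuclei, micronuclei, blebs and
invagination tubes plus a ground-truth table, so every operator is testable
against known answers without any image downloads.

## Worked example

```python
from nucleoshape import RunConfig, SceneSpec, render_scene, run_pipeline

spec = SceneSpec(shape=(900, 900), n_nuclei=16, micronucleus_prob=0.3,
                 bleb_prob=0.3, invagination_count=(0, 2), seed=14)
channels, truth = render_scene(spec)
summary = run_pipeline({"demo": channels}, RunConfig(),
                       which=("shape", "micronuclei", "invaginations", "blebs"),
                       outdir="demo_out")
print(summary.n_nuclei, summary.micronucleus_frequency,
      summary.bleb_frequency, summary.mean_invagination_count)
```

prints `16 25.0 12.5 0.625`: all 16 nuclei are found, 25.0% carry a
micronucleus, 12.5% carry a bleb and nuclei hold 0.625 intranuclear lamin
objects on average — each number equal to the planted ground truth of this
scene (`truth.frequency("micronucleus")` is 25.0, `truth.frequency("bleb")`
is 12.5). The run writes `nuclei.csv` (one row per nucleus with the full
descriptor panel; this scene averages form factor 0.9011, solidity 0.9605,
eccentricity 0.5844), `micronuclei.csv`, `invaginations.csv`, `blebs.csv`
and `summary.json` into `demo_out/`.

The same works from a shell on real images:

```bash
nucleoshape run --dna dapi.tif --laminb lmnb1.tif --out results/ \
    --which shape --which blebs
nucleoshape simulate --out scene/ --seed 7
nucleoshape score --truth scene/truth_micronucleus.tif \
    --detections my_detections.tif
```

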