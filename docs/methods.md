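# Methods

## Coordinate and measurement conventions

All images are 2D arrays in 0-based `(row, col)` coordinates, origin
top-left. Intensities are never rescaled on load, so thresholds are either
raw values, quantiles, or fractions of an automatically determined (Otsu)
threshold; any metric's dependence on acquisition intensity therefore
remains observable. Objects use 8-connectivity, background 4-connectivity.
Holes in nuclear masks are filled before any shape analysis: every
descriptor here is a statement about the outer contour.

## Contours, area and perimeter

The nuclear contour is the sub-pixel 0.5-level iso-contour (marching
squares). Binary masks are lightly Gaussian-smoothed (σ = 1 px by default)
before tracing so the contour interpolates the stair-stepped rasterization;
graded coverage masks (e.g. from supersampled rendering) are traced as-is.
Area and perimeter are the shoelace area and polygon length of this
contour. The choice matters: pixel-edge perimeter counting gives a
rasterized circle a form factor near 0.79, destroying the defining property
that a circle scores 1, whereas the contour-polygon estimator converges to
the true perimeter (a radius-50 disk measures ≥ 0.99). Form factors above 1
can arise only from residual estimator bias and are clipped to 1 (with a
warning beyond float noise).

## Descriptor definitions and numerical choices

* **Eccentricity / axis ratio** come from the ellipse with the same second
  central moments as the pixel region — the convention of standard
  region-analysis software — rather than a literal bounding ellipse. A
  degenerate (collinear) region reports eccentricity 1 and an infinite
  axis ratio.
* **Solidity** is pixel-counted on both sides of the ratio: object pixels
  over pixel centres inside (or on) the convex hull of the object's pixel
  centres. This makes it exactly reproducible by brute-force enumeration,
  which the tests exploit.
* **Mean negative curvature**: the contour is resampled to 256 uniform
  arc-length points and periodically Gaussian-smoothed over 2% of the
  contour length (raw raster contours otherwise produce stair-step
  curvature noise; the scale is a config parameter since no canonical value
  exists). Signed curvature κ = (x′y″ − y′x″)/(x′²+y′²)^{3/2} with the
  contour oriented so convex arcs are positive; the reported value is the
  mean over {κ < 0}, or 0 for a fully convex outline. With smoothing
  disabled, a dense analytic peanut contour reproduces the closed-form
  polar-curvature value within 2%.
* **Elliptic Fourier descriptors** use the classical chord-length
  (Kuhl–Giardina) coefficients. The *coefficient ratio* is the high- to
  first-harmonic energy ratio Σₙ₌₂..₂₀ Eₙ / E₁, Eₙ = aₙ²+bₙ²+cₙ²+dₙ² —
  rotation- and phase-invariant, with a larger dynamic range than solidity
  for mild deformations. Note that in chord-length parametrisation an
  ellipse is *not* exactly one harmonic: a 2:1 ellipse has a residual ratio
  of ~6·10⁻³ (this is a property of the parametrisation, verified against a
  direct FFT of the arc-length-resampled contour). *Harmonics needed* is
  the smallest N whose reconstruction lies within (1 − fidelity) × the
  equivalent radius of the curve, measured as geometric (nearest-point)
  deviation rather than deviation at equal parameter values — so circles
  and mild ellipses need exactly one harmonic; strongly elongated ellipses
  may need more at the default fidelity 0.95 because the first-harmonic
  ellipse has slightly contracted axes.
* **Radial asymmetry** centres the largest inscribed circle at the maximum
  of the Euclidean distance transform; ties go to the lexicographically
  smallest (row, col) for determinism. **Point asymmetry** reflects each
  pixel through the pixel-centre centroid, rounding halves toward +∞; both
  are exact pixel counts.

## Segmentation

Foreground is `intensity > threshold` (global Otsu by default; fixed and
quantile alternatives), hole-filled, minimum-area-filtered. Touching nuclei
are split by watershed on the negated distance transform. Watershed seeds
are h-maxima (depth 4 px) of the distance map after σ = 2 smoothing: seed
depth must exceed the boundary raggedness that pixel noise induces (~2 px)
while staying far below the peak-to-saddle contrast of genuinely fused
nuclei, so fused disks split but single elongated or lobulated nuclei do
not fragment. Pre-smoothing of the intensity image is **off** by default —
it erases exactly the contour irregularities under study — and is recorded
in the per-run QC when enabled. Border-touching nuclei are flagged and
excluded from pooled statistics (truncated contours corrupt every
descriptor). Mitotic nuclei are flagged by integrated (summed) DNA
intensity above median + 3 × MAD across the image's nuclei: condensed
mitotic chromatin roughly doubles the integrated signal, and the sum tracks
DNA content where the mean confounds with area. With fewer than four nuclei
the robust statistics are undefined and no flags are set.

## Micronucleus detection

One stain (DNA, envelope or nucleoplasm) is segmented twice: the primary
Otsu threshold defines nuclei, and a second pass at 0.5 × Otsu catches
dimmer micronuclei. Objects ≥ 200 px² are nucleus candidates; smaller ones
(≥ 10 px², to reject noise specks) are micronucleus candidates. Nuclei are
cleaned by iterated per-label erosion/dilation (2 iterations) which removes
spurs and attached debris without merging labels. Cell territories are the
nuclear masks dilated by 25 px (a fibroblast-scale default), with collisions
resolved by nearest-nucleus distance; a whole-cell stain replaces the
dilation when available. A candidate whose centroid lies in the territory
of nucleus *k* is classified as a micronucleus of *k* iff its
equivalent-circle diameter √(4A/π) is ≤ 1/3 of the nucleus' equivalent
diameter (the threshold is exact: a candidate at precisely 1/3 is
accepted). Oversized candidates are reported as unclassified; candidates
outside all territories are discarded. The frequency readout counts each
nucleus once regardless of how many micronuclei it carries.

## Invagination detection

Per nucleus, "high lamin B" pixels are segmented with a per-nucleus Otsu
threshold on the denoised lamin-B channel. A fixed intensity quantile is
available as an option but is not the default: a quantile threshold moves
with the structure fraction, so nuclei with many invaginations push it into
the structure intensities and fragment the tubes (on synthetic scenes,
24/30 versus 30/30 exact counts). The nucleus mask is then eroded by
`shrink_px` (default 4 px at ~0.1 µm/px imagery — larger than segmentation
jitter plus the lamin ring half-width); a lamin component counts as
intranuclear when ≥ 50% of its pixels survive the erosion, which keeps rim
fragments that leak a pixel inward from masquerading as invaginations.
Counts, areas and per-nucleus area fractions are reported; erosion is
anti-extensive, so the intranuclear area is non-increasing in `shrink_px`
(asserted in tests). Over-shrunk nuclei yield a zeroed, flagged result.

## Bleb detection

**Lamin-gap subtraction.** Chromatin is segmented at 0.5 × the Otsu
threshold — deliberately permissive because blebs contain less DNA than the
nuclear body. The lamin-B *object* is the filled interior of the
thresholded lamin ring, not the ring pixels (otherwise the whole
nucleoplasm would read as chromatin lacking lamin B). Because the ring is
interrupted at the bleb neck, it is dilated by `lamin_gap_close_px`
(default 12, bridging gaps up to 24 px), hole-filled and eroded back; plain
morphological closing cannot bridge such gaps (the thin bridge does not
survive the closing erosion). Candidates are connected components of
chromatin minus lamin object that (i) are ≥ 40 px² and ≤ half of the parent
nucleus area, (ii) have in-radius ≥ 3 px (thinner residues are boundary
slivers), (iii) protrude ≥ 5 px beyond the lamin object — a bleb by
definition protrudes past the lamina, while the shallow chromatin lens
exposed where the gap was bridged does not — and (iv) touch the lamin
object (8-adjacency). Per-bleb enrichment of any extra channel is the mean
intensity over bleb pixels divided by the mean over the parent lamin
object. The subtraction readout over-counts bleb area by the neck lens plus
~1 px of permissive-threshold boundary shift: +8–25% for blebs of
150–270 px² and up to ~35% below 150 px² on synthetic scenes; IoU-based
detection is unaffected. Chromatin-free blebs are invisible to this method
by construction.

**Morphological cut-off.** For single-stain images, each nucleus object is
opened with a disk of radius `bleb_max_iter` px (default 11): the radius
must exceed the largest bleb radius of interest so blebs are cut off the
core, and stay below the smallest nucleus in-radius so the core survives.
Residual components touching the core (8-adjacency — at exactly diagonal
contact the touch test passes; a one-pixel gap fails) are bleb candidates;
a candidate that is *both* small (< 150 px²) *and* circular (form factor
> 0.85) is rejected as a micronucleus — a conjunction, so small irregular
blebs are retained. Detached residuals are left to the micronucleus
pathway. Both pipelines agree on ≥ 90% of blebbed-nucleus calls on
synthetic scenes where every bleb contains chromatin and has a lamin gap.

## Synthetic scenes

The generator places Fourier-perturbed ellipses (radius 16–22 px, axis
ratio 1–1.6, low-order lobulation up to a few percent) on a jittered grid
sized so satellites never collide, and renders: a lamin-B ring (width 3 px)
along each contour; optional blebs as disks centred 0.55 r outside a random
boundary point, with chromatin at 0.6 × the nuclear DNA level and a ring
gap of 1.6 × the bleb radius; optional micronuclei as disks of 0.15–0.25 ×
the nucleus equivalent diameter placed 4–14 px outside the boundary within
the cell territory; and optional intranuclear lamin tubes (width 3 px,
chords of 0.3–0.8 of the locally available span) kept clear of the ring —
modelling how a mid-plane confocal section shows an invagination whose
envelope connection lies out of plane. lamin A/C fills the nucleoplasm and
is enriched 1.5× in blebs. All shapes are rendered at 4× supersampling and
box-down-sampled, keeping rasterization bias below the descriptors' 2%
tolerances; Gaussian background noise (default σ = 40 against a DNA level
of 200, i.e. SNR 5) and optional Poisson shot noise are applied last. A
single integer seed drives one generator through the whole scene, so equal
specs render bit-identically; the bleb radius is drawn whether or not a
bleb is planted, so toggling bleb probability leaves every other shape in
the scene unchanged (used for paired with/without-bleb comparisons).

What the generator does **not** emulate: optics (no PSF, no depth of
field), uneven illumination, staining heterogeneity, touching or
overlapping cells, apoptotic or mitotic figures, chromatin texture, or 3D
structure. Passing planted-recovery tests therefore demonstrates that the
algorithms are correct implementations of their definitions under
realistic size, contrast and noise regimes — not that real micrographs of
arbitrary quality will be analysed error-free.

Detector performance is scored by greedy one-to-one IoU matching against
the planted masks (IoU ≥ 0.3 by default); sensitivity, false discovery
rate and per-nucleus count error are reported.

## Problem sizes used in the validation suite

Unit tests run on single constructed shapes and 9–30-nucleus scenes. The
at-scale recovery tests use 500 nuclei at 20% planted micronucleus
frequency (recovered within the 95% Clopper–Pearson interval of the
realised truth; sensitivity ≥ 0.95, FDR ≤ 0.05), 200 nuclei with 0–5
planted invaginations (≥ 90% exact per-nucleus counts), and 300 nuclei at
30% planted bleb prevalence (≥ 90% method concordance, prevalence within
the 95% interval). These sizes give binomial intervals a few percent wide —
tight enough to detect systematic detector bias — while the whole suite
stays conveniently fast on a single CPU.

## Known limitations

* 2D only; descriptors conflate envelope folds with invaginations, as any
  single-section analysis must.
* The lamin-gap bleb method requires a lamin-B channel and chromatin in the
  bleb; the morphological method requires the bleb to be resolvable by the
  opening radius.
* The micronucleus/nucleus split is a pure size rule within a cell
  territory; heavily clustered cells with wrong territory assignments will
  mis-assign parents.
* Ruptured versus intact status of blebs and micronuclei is not assessed
  (requires live-cell reporters).
* Group statistics between experimental conditions are intentionally out of
  scope: the tool emits per-object tables for downstream analysis.
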