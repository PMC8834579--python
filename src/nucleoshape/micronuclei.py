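"""Micronucleus detection for high-content screening images.

Micronuclei are small extranuclear chromatin bodies wrapped in their own
envelope; they score genome instability. The pipeline mirrors standard
high-content practice: segment bright objects from a DNA (or nuclear-
envelope / nucleoplasm) stain with a dual-threshold pass so dim micronuclei
survive, clean the nuclear masks by iterated erosion/dilation, approximate
each cell's territory by dilating its nucleus (or by a whole-cell stain),
then classify every small object inside a territory by its size relative to
the resident nucleus — the maximum micronuclear diameter defaults to one
third of the nucleus diameter. "Diameter" is always the equivalent-circle
diameter ``sqrt(4 A / pi)``, which stays meaningful for non-circular blobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential

from .config import RunConfig
from .io import ChannelImage
from .segmentation import LabelMask

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class MicronucleusRecord:
    """One classified micronucleus, linked to its parent nucleus."""

    parent_nucleus_label: int
    det_label: int
    area_px: float
    equivalent_diameter: float
    centroid_row: float
    centroid_col: float
    diameter_ratio: float
    mean_intensity: dict[str, float] = field(default_factory=dict)


def _equivalent_diameter(area: float) -> float:
    return float(np.sqrt(4.0 * area / np.pi))


def cleanup_nuclei(mask: LabelMask, n_iter: int) -> LabelMask:
    """Per-label morphological opening (erode x n, dilate x n, disk(1)).

    Clears spurs and attached small objects from each nuclear mask; labels
    are preserved for survivors, objects eroded to nothing are dropped.
    ``n_iter = 0`` is the identity.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    labels = mask.labels
    if n_iter == 0:
        return LabelMask(labels.copy())
    out = np.zeros_like(labels)
    footprint = disk(1)
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        pad = n_iter + 1
        sub = np.pad(labels[sl] == lab, pad)
        er = ndi.binary_erosion(sub, structure=footprint, iterations=n_iter)
        if not er.any():
            continue
        op = ndi.binary_dilation(er, structure=footprint, iterations=n_iter)
        op = op[pad:-pad, pad:-pad]
        out[sl][op] = lab
    out, _, _ = relabel_sequential(out)
    return LabelMask(out.astype(np.int32))


def approximate_cells(
    nuclei: LabelMask,
    dilation_px: int = 25,
    whole_cell: ChannelImage | None = None,
) -> LabelMask:
    """Approximate per-cell territories around each nucleus.

    Without a whole-cell stain each nucleus is dilated by ``dilation_px``;
    where dilations collide, pixels go to the nucleus whose mask is nearest
    (Euclidean distance transform). With a whole-cell stain, its Otsu
    foreground is assigned to the nearest nucleus instead. Every territory
    contains its nucleus and territories are disjoint.
    """
    labels = nuclei.labels
    if nuclei.count == 0:
        raise ValueError("empty nucleus mask")
    dist, (ir, ic) = ndi.distance_transform_edt(labels == 0, return_indices=True)
    nearest = labels[ir, ic]
    if whole_cell is not None:
        img = whole_cell.pixels.astype(float)
        fg = img > threshold_otsu(img) if img.max() > img.min() else np.zeros_like(img, bool)
        region = fg | (labels > 0)
    else:
        if dilation_px < 1:
            raise ValueError("dilation_px must be >= 1 without a whole-cell stain")
        region = dist <= dilation_px
    cells = np.where(region, nearest, 0)
    return LabelMask(cells.astype(np.int32))


def classify_micronuclei(
    candidates: LabelMask,
    nuclei: LabelMask,
    cells: LabelMask,
    max_ratio: float = 1.0 / 3.0,
    channels: dict[str, np.ndarray] | None = None,
) -> tuple[list[MicronucleusRecord], list[int], list[int]]:
    """Classify small objects as micronuclei by comparative size within a cell.

    A candidate whose centroid falls in the territory of nucleus *k* becomes
    a micronucleus of *k* when its equivalent diameter is at most
    ``max_ratio`` times the nucleus' equivalent diameter. Oversized objects
    are returned as unclassified; objects outside all territories are
    discarded. Returns ``(records, unclassified_labels, discarded_labels)``.
    """
    if not 0 < max_ratio < 1:
        raise ValueError("max_ratio must be in (0, 1)")
    nuc_areas = nuclei.areas()
    nuc_diam = {lab: _equivalent_diameter(a) for lab, a in nuc_areas.items()}
    records: list[MicronucleusRecord] = []
    unclassified: list[int] = []
    discarded: list[int] = []
    labels = candidates.labels
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == lab
        coords = np.argwhere(sub)
        area = len(coords)
        cr, cc = coords.mean(axis=0)
        row = int(round(cr)) + sl[0].start
        col = int(round(cc)) + sl[1].start
        parent = int(cells.labels[row, col])
        if parent == 0:
            discarded.append(lab)
            continue
        d_obj = _equivalent_diameter(area)
        if d_obj <= max_ratio * nuc_diam[parent] + 1e-12:
            means = {}
            if channels:
                full = np.zeros(labels.shape, bool)
                full[sl] = sub
                for role, img in channels.items():
                    means[role] = float(np.asarray(img, dtype=float)[full].mean())
            records.append(
                MicronucleusRecord(
                    parent_nucleus_label=parent,
                    det_label=lab,
                    area_px=float(area),
                    equivalent_diameter=d_obj,
                    centroid_row=float(cr + sl[0].start),
                    centroid_col=float(cc + sl[1].start),
                    diameter_ratio=d_obj / nuc_diam[parent],
                    mean_intensity=means,
                )
            )
        else:
            unclassified.append(lab)
    return records, unclassified, discarded


def micronucleus_frequency(n_nuclei: int, records: list[MicronucleusRecord]) -> float:
    """Percentage of nuclei with one or more associated micronuclei."""
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    parents = {r.parent_nucleus_label for r in records}
    return 100.0 * len(parents) / n_nuclei


@dataclass
class MicronucleusDetection:
    """Full output of :func:`detect_micronuclei`."""

    nuclei: LabelMask
    cells: LabelMask
    records: list[MicronucleusRecord]
    detection_mask: LabelMask
    unclassified: list[int]
    frequency: float


def detect_micronuclei(
    dna: ChannelImage,
    cfg: RunConfig | None = None,
    channels: dict[str, np.ndarray] | None = None,
    whole_cell: ChannelImage | None = None,
) -> MicronucleusDetection:
    """End-to-end micronucleus detection on a DNA-type stain.

    The candidate pass thresholds at ``mn_low_threshold_factor`` times the
    Otsu threshold of the denoised image, so micronuclei dimmer than the
    primary nuclei are still segmented; objects at least
    ``min_nucleus_area`` px^2 become nuclei, smaller ones candidates.
    """
    cfg = cfg or RunConfig()
    img = dna.pixels.astype(float)
    if cfg.mn_smooth_sigma > 0:
        img = ndi.gaussian_filter(img, cfg.mn_smooth_sigma)
    if img.max() == img.min():
        raise ValueError("blank image: cannot threshold")
    thr_hi = float(threshold_otsu(img))
    thr_lo = thr_hi * cfg.mn_low_threshold_factor
    fg = img > thr_lo
    lbl, n = ndi.label(fg, structure=_STRUCT8)
    areas = np.bincount(lbl.ravel())
    nuc_mask = np.zeros_like(lbl)
    cand_mask = np.zeros_like(lbl)
    for lab in range(1, n + 1):
        if areas[lab] >= cfg.min_nucleus_area:
            nuc_mask[lbl == lab] = lab
        elif areas[lab] >= cfg.mn_min_area:
            cand_mask[lbl == lab] = lab
    nuc_mask, _, _ = relabel_sequential(nuc_mask)
    cand_mask, _, _ = relabel_sequential(cand_mask)
    nuclei = cleanup_nuclei(LabelMask(nuc_mask.astype(np.int32)), cfg.cleanup_iter)
    if nuclei.count == 0:
        raise ValueError("no nuclei found")
    cells = approximate_cells(nuclei, cfg.cell_dilation_px, whole_cell=whole_cell)
    all_channels = dict(channels or {})
    all_channels.setdefault("dna", dna.pixels)
    records, unclassified, _ = classify_micronuclei(
        LabelMask(cand_mask.astype(np.int32)),
        nuclei,
        cells,
        max_ratio=cfg.mn_max_ratio,
        channels=all_channels,
    )
    det = np.zeros_like(cand_mask)
    for i, rec in enumerate(records, start=1):
        det[cand_mask == rec.det_label] = i
        rec.det_label = i
    return MicronucleusDetection(
        nuclei=nuclei,
        cells=cells,
        records=records,
        detection_mask=LabelMask(det.astype(np.int32)),
        unclassified=unclassified,
        frequency=micronucleus_frequency(nuclei.count, records),
    )
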