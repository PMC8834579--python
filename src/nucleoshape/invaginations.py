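"""Nuclear-envelope invagination (nucleoplasmic reticulum) quantification.

Invaginations are lamin-coated tubular infoldings of the envelope into the
nuclear interior; in a 2D confocal section they appear as lamin-B lines or
spots inside the nucleus. The pipeline detects high-lamin-B areas per
nucleus, then erodes ("shrinks") the nuclear mask by a few pixels so lamin
at the envelope rim separates from lamin in the interior; connected
intranuclear lamin components are counted and measured. The shrink distance
must exceed segmentation jitter plus the lamin ring width (default 4 px at
~0.1 um/px imagery).
"""

from __future__ import annotations

from dataclasses import dataclass

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
class InvaginationResult:
    """Intranuclear lamin-B readouts for one nucleus."""

    nucleus_label: int
    intranuclear_laminB_area: float
    intranuclear_object_count: int
    intranuclear_area_fraction: float
    shrink_px: int
    nucleus_vanished: bool = False


def detect_lamin_objects(
    laminB: ChannelImage,
    nuclei: LabelMask,
    threshold: str | float = "otsu",
    min_size: int = 20,
    smooth_sigma: float = 1.0,
) -> LabelMask:
    """Segment high-lamin-B areas inside each nucleus.

    The threshold adapts per nucleus, computed from the (denoised) lamin-B
    intensities within that nucleus: ``threshold='otsu'`` (default) splits
    the bimodal bright-structure / dark-nucleoplasm histogram per nucleus; a
    float in (0, 1) thresholds at that intensity quantile instead. Otsu is
    the default because a fixed quantile couples the threshold to the
    structure fraction — nuclei with many invaginations push a quantile
    threshold into the structure intensities and fragment the tubes.
    Components below ``min_size`` are discarded as noise.
    """
    if laminB.role != "laminB":
        raise ValueError(f"expected the lamin-B channel, got role {laminB.role!r}")
    if isinstance(threshold, float) and not 0 < threshold < 1:
        raise ValueError("quantile threshold must be in (0, 1)")
    img = laminB.pixels.astype(float)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, smooth_sigma)
    out = np.zeros(img.shape, bool)
    labels = nuclei.labels
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        inside = labels[sl] == lab
        vals = img[sl][inside]
        if threshold == "otsu":
            thr = float(threshold_otsu(vals)) if vals.max() > vals.min() else float(vals.max())
        else:
            thr = float(np.quantile(vals, threshold))
        out[sl] |= inside & (img[sl] > thr)
    lbl, _ = ndi.label(out, structure=_STRUCT8)
    if min_size > 0:
        areas = np.bincount(lbl.ravel())
        lbl[np.isin(lbl, np.flatnonzero(areas < min_size))] = 0
    lbl, _, _ = relabel_sequential(lbl)
    return LabelMask(lbl.astype(np.int32))


def split_peripheral_internal(
    lamin_objects: LabelMask,
    nuclei: LabelMask,
    shrink_px: int = 4,
    min_size: int = 20,
    interior_frac: float = 0.5,
) -> list[InvaginationResult]:
    """Separate envelope lamin from intranuclear lamin per nucleus.

    The nucleus mask is eroded by ``shrink_px``; lamin components whose
    pixels lie at least ``interior_frac`` inside the eroded mask count as
    intranuclear (the fraction rule keeps an envelope-rim fragment leaking a
    pixel or two inward from masquerading as an invagination). Component
    pixels are then clipped to the eroded mask for the area readouts. If
    erosion leaves nothing of a nucleus the result is zeroed and flagged.
    """
    if shrink_px < 1:
        raise ValueError("shrink_px must be >= 1")
    labels = nuclei.labels
    lamin = lamin_objects.labels
    results: list[InvaginationResult] = []
    footprint = disk(shrink_px)
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        pad = 1
        pad_sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, labels.shape)
        )
        nuc = ndi.binary_fill_holes(labels[pad_sl] == lab)
        nuc_area = int(nuc.sum())
        eroded = ndi.binary_erosion(nuc, structure=footprint)
        if not eroded.any():
            results.append(
                InvaginationResult(lab, 0.0, 0, 0.0, shrink_px, nucleus_vanished=True)
            )
            continue
        lam_sub = lamin[pad_sl]
        intr = np.zeros_like(nuc)
        for comp in np.unique(lam_sub[nuc & (lam_sub > 0)]):
            comp_mask = lam_sub == comp
            frac = comp_mask[eroded].sum() / comp_mask.sum()
            if frac >= interior_frac:
                intr |= comp_mask & eroded
        comp_lbl, n_comp = ndi.label(intr, structure=_STRUCT8)
        if min_size > 0 and n_comp:
            areas = np.bincount(comp_lbl.ravel())
            keep = np.flatnonzero(areas >= min_size)
            keep = keep[keep > 0]
            intr = np.isin(comp_lbl, keep)
            n_comp = len(keep)
        area = float(intr.sum())
        results.append(
            InvaginationResult(
                nucleus_label=lab,
                intranuclear_laminB_area=area,
                intranuclear_object_count=int(n_comp),
                intranuclear_area_fraction=area / nuc_area if nuc_area else 0.0,
                shrink_px=shrink_px,
            )
        )
    return results


def detect_invaginations(
    laminB: ChannelImage,
    nuclei: LabelMask,
    cfg: RunConfig | None = None,
) -> tuple[list[InvaginationResult], LabelMask]:
    """Full invagination pipeline: lamin objects, shrink, split, count."""
    cfg = cfg or RunConfig()
    threshold = "otsu" if cfg.lamin_threshold_method == "otsu" else cfg.lamin_quantile
    lamin_objects = detect_lamin_objects(
        laminB,
        nuclei,
        threshold=threshold,
        min_size=cfg.lamin_min_size,
        smooth_sigma=cfg.lamin_smooth_sigma,
    )
    results = split_peripheral_internal(
        lamin_objects,
        nuclei,
        shrink_px=cfg.shrink_px,
        min_size=cfg.lamin_min_size,
        interior_frac=cfg.interior_frac,
    )
    return results, lamin_objects
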