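"""Nuclear-envelope bleb detection.

A bleb is a protrusion of the nuclear membrane through a gap in the lamina;
blebs typically lack lamin B and often contain less DNA than the nuclear
body. Two complementary pipelines are provided:

* **lamin-gap subtraction** — segment a chromatin object from the DNA stain
  with a deliberately permissive threshold (blebs are dim), segment the
  lamin-B object as the filled interior of the lamin ring, and keep
  connected components of (chromatin minus lamin object) that are adjacent
  to the lamin object and of plausible bleb size. Only chromatin-containing
  blebs can be found this way.
* **morphological cut-off** — on a single nuclear-envelope or nucleoplasm
  stain, open each nucleus object aggressively so protrusions are cut off
  from the core; residual components touching the core are bleb candidates,
  and candidates that are both small and highly circular are rejected as
  micronuclei (micronuclei are typically smaller and more circular than
  blebs).

"Touching" means 8-adjacency between the residual component and the core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import perimeter_crofton
from skimage.morphology import disk
from skimage.segmentation import relabel_sequential

from .config import RunConfig
from .io import ChannelImage
from .segmentation import LabelMask

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class BlebRecord:
    """One detected bleb, linked to its parent nucleus."""

    nucleus_label: int
    method: str  # 'lamin_gap' | 'morphological'
    area_px: float
    relative_area: float
    centroid_row: float
    centroid_col: float
    touches_nucleus: bool
    enrichment: dict[str, float] = field(default_factory=dict)


def _touches(component: np.ndarray, core: np.ndarray) -> bool:
    """8-adjacency between a residual component and the nuclear core."""
    return bool((ndi.binary_dilation(component, structure=_STRUCT8) & core).any())


def bleb_enrichment(
    channel: np.ndarray,
    bleb_mask: np.ndarray,
    lamin_object_mask: np.ndarray,
) -> float:
    """Mean channel intensity in the bleb over the mean in the lamin-B object.

    The readout used to quantify recruitment of a protein of interest
    (e.g. lamin A/C) to bleb sites.
    """
    bleb_mask = np.asarray(bleb_mask) > 0
    lamin_object_mask = np.asarray(lamin_object_mask) > 0
    if not bleb_mask.any() or not lamin_object_mask.any():
        raise ValueError("empty region: enrichment undefined")
    img = np.asarray(channel, dtype=float)
    return float(img[bleb_mask].mean() / img[lamin_object_mask].mean())


def _lamin_object_mask(laminB: ChannelImage, cfg: RunConfig) -> np.ndarray:
    """Filled interior of the thresholded lamin-B ring.

    A gap in the ring (the bleb neck) would defeat a plain hole fill, so the
    ring is dilated by ``lamin_gap_close_px`` (bridging gaps up to twice
    that), hole-filled, and eroded back. The filled interior — not the ring
    pixels — is the lamin object, otherwise the whole nucleoplasm would read
    as "chromatin lacking lamin B".
    """
    img = laminB.pixels.astype(float)
    if cfg.bleb_smooth_sigma > 0:
        img = ndi.gaussian_filter(img, cfg.bleb_smooth_sigma)
    if img.max() == img.min():
        return np.zeros(img.shape, bool)
    ring = img > threshold_otsu(img)
    if cfg.lamin_gap_close_px > 0:
        fp = disk(cfg.lamin_gap_close_px)
        grown = ndi.binary_dilation(ring, structure=fp)
        filled = ndi.binary_fill_holes(grown)
        return ndi.binary_erosion(filled, structure=fp, border_value=1)
    return ndi.binary_fill_holes(ring)


def detect_blebs_lamin_gap(
    dna: ChannelImage,
    laminB: ChannelImage,
    cfg: RunConfig | None = None,
    extra_channels: dict[str, np.ndarray] | None = None,
) -> tuple[list[BlebRecord], LabelMask]:
    """Blebs as chromatin areas lacking lamin B.

    The chromatin threshold is permissive (``bleb_dna_threshold_factor``
    times the Otsu threshold) because blebs often contain less DNA than the
    nuclear body. Candidates must touch the lamin object and have an area in
    ``[min_bleb_area, max_bleb_frac * nucleus area]``. When extra channels
    are given, per-bleb enrichment versus the parent lamin object is
    reported. Returns the records and a label mask of accepted blebs.
    """
    if laminB is None:
        raise ValueError(
            "lamin-B channel missing: use detect_blebs_morphological instead"
        )
    cfg = cfg or RunConfig()
    dna_img = dna.pixels.astype(float)
    if cfg.bleb_smooth_sigma > 0:
        dna_img = ndi.gaussian_filter(dna_img, cfg.bleb_smooth_sigma)
    if dna_img.max() == dna_img.min():
        return [], LabelMask(np.zeros(dna_img.shape, dtype=np.int32))
    thr = float(threshold_otsu(dna_img)) * cfg.bleb_dna_threshold_factor
    chromatin = dna_img > thr
    lamin_obj = _lamin_object_mask(laminB, cfg)
    lamin_lbl, _ = ndi.label(lamin_obj, structure=_STRUCT8)
    lamin_areas = np.bincount(lamin_lbl.ravel())
    residual = chromatin & ~lamin_obj
    dist_from_obj = ndi.distance_transform_edt(~lamin_obj)
    cand_lbl, n_cand = ndi.label(residual, structure=_STRUCT8)
    records: list[BlebRecord] = []
    det = np.zeros_like(cand_lbl)
    for lab, sl in enumerate(ndi.find_objects(cand_lbl), start=1):
        if sl is None:
            continue
        pad_sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, cand_lbl.shape)
        )
        comp = cand_lbl[pad_sl] == lab
        area = float(comp.sum())
        if area < cfg.min_bleb_area:
            continue
        if ndi.distance_transform_edt(comp).max() < cfg.bleb_min_thickness:
            continue  # thin chromatin sliver along the lamin-object rim
        if float(dist_from_obj[pad_sl][comp].max()) < cfg.bleb_min_protrusion:
            # does not protrude beyond the lamina: a lens of nuclear
            # chromatin exposed where the gap was bridged, not a bleb
            continue
        ring_neighbours = lamin_lbl[pad_sl][
            ndi.binary_dilation(comp, structure=_STRUCT8) & (lamin_lbl[pad_sl] > 0)
        ]
        if ring_neighbours.size == 0:
            continue  # not adjacent to any lamin object
        parent = int(np.bincount(ring_neighbours).argmax())
        nucleus_area = float(lamin_areas[parent])
        if area > cfg.max_bleb_frac * nucleus_area:
            continue
        coords = np.argwhere(comp)
        enr = {}
        if extra_channels:
            full = np.zeros(cand_lbl.shape, bool)
            full[pad_sl] = comp
            for role, img in extra_channels.items():
                enr[role] = bleb_enrichment(img, full, lamin_lbl == parent)
        records.append(
            BlebRecord(
                nucleus_label=parent,
                method="lamin_gap",
                area_px=area,
                relative_area=area / nucleus_area,
                centroid_row=float(coords[:, 0].mean() + pad_sl[0].start),
                centroid_col=float(coords[:, 1].mean() + pad_sl[1].start),
                touches_nucleus=True,
                enrichment=enr,
            )
        )
        det[pad_sl][comp] = len(records)
    return records, LabelMask(det.astype(np.int32))


def detect_blebs_morphological(
    stain: ChannelImage,
    cfg: RunConfig | None = None,
) -> tuple[list[BlebRecord], LabelMask]:
    """Blebs cut off the nuclear core by aggressive morphological opening.

    Works on any single stain that covers nucleus and bleb (nucleoplasm,
    envelope or DNA). Each segmented object is opened with a disk of radius
    ``bleb_max_iter`` pixels (one erosion/dilation pass per pixel of
    radius); the radius must exceed the largest bleb radius of interest so
    the opening cuts blebs off the core, while staying below the nucleus
    in-radius so the core survives. Residual components that touch the core
    are bleb candidates unless they are thinner than ``bleb_min_thickness``
    (rasterization slivers along the core boundary) or look like micronuclei
    (area < ``mn_reject_max_area`` AND form factor >
    ``mn_reject_min_circularity``). Non-touching residual objects are left
    to the micronucleus pathway.
    """
    cfg = cfg or RunConfig()
    img = stain.pixels.astype(float)
    if cfg.bleb_smooth_sigma > 0:
        img = ndi.gaussian_filter(img, cfg.bleb_smooth_sigma)
    if img.max() == img.min():
        return [], LabelMask(np.zeros(img.shape, dtype=np.int32))
    thr = float(threshold_otsu(img)) * cfg.bleb_dna_threshold_factor
    fg = img > thr
    lbl, n = ndi.label(fg, structure=_STRUCT8)
    areas = np.bincount(lbl.ravel())
    small = np.flatnonzero(areas < cfg.min_nucleus_area)
    lbl[np.isin(lbl, small)] = 0
    lbl, _, _ = relabel_sequential(lbl)
    records: list[BlebRecord] = []
    det = np.zeros_like(lbl)
    footprint = disk(cfg.bleb_max_iter)
    for lab, sl in enumerate(ndi.find_objects(lbl), start=1):
        if sl is None:
            continue
        pad = cfg.bleb_max_iter + 2
        pad_sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, lbl.shape)
        )
        obj = ndi.binary_fill_holes(lbl[pad_sl] == lab)
        er = ndi.binary_erosion(obj, structure=footprint)
        if not er.any():
            continue
        core = ndi.binary_dilation(er, structure=footprint) & obj
        core_area = float(core.sum())
        residual = obj & ~core
        res_lbl, n_res = ndi.label(residual, structure=_STRUCT8)
        for rlab in range(1, n_res + 1):
            comp = res_lbl == rlab
            area = float(comp.sum())
            if area < cfg.min_bleb_area:
                continue
            if ndi.distance_transform_edt(comp).max() < cfg.bleb_min_thickness:
                continue  # thin boundary sliver left by the opening
            if not _touches(comp, core):
                continue  # detached object: micronucleus pathway, not a bleb
            ff = _component_form_factor(comp)
            if area < cfg.mn_reject_max_area and ff > cfg.mn_reject_min_circularity:
                continue  # small and round: reject as micronucleus
            coords = np.argwhere(comp)
            records.append(
                BlebRecord(
                    nucleus_label=lab,
                    method="morphological",
                    area_px=area,
                    relative_area=area / (core_area + area),
                    centroid_row=float(coords[:, 0].mean() + pad_sl[0].start),
                    centroid_col=float(coords[:, 1].mean() + pad_sl[1].start),
                    touches_nucleus=True,
                )
            )
            det[pad_sl][comp] = len(records)
    return records, LabelMask(det.astype(np.int32))


def _component_form_factor(mask: np.ndarray) -> float:
    area = float(mask.sum())
    perim = float(perimeter_crofton(mask, directions=4))
    if perim == 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / perim**2)


def bleb_frequency(n_nuclei: int, records: list[BlebRecord]) -> tuple[float, float]:
    """Percentage of nuclei with >= 1 bleb, and the mean bleb area (px^2)."""
    if n_nuclei < 1:
        raise ValueError("need at least one nucleus")
    blebbed = {r.nucleus_label for r in records}
    freq = 100.0 * len(blebbed) / n_nuclei
    mean_area = float(np.mean([r.area_px for r in records])) if records else 0.0
    return freq, mean_area
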