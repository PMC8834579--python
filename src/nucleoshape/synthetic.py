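"""Synthetic fluorescence micrographs with planted ground truth.

Renders multichannel scenes that emulate the salient features of real
nuclear-morphology imagery: round-to-lobulated nuclei (Fourier-perturbed
ellipses), a lamin-B ring along each nuclear contour, intranuclear lamin-B
tubes (envelope invaginations as they appear in a mid-plane confocal
section, where the tube's connection to the envelope lies out of plane),
membrane blebs with dimmer DNA and a lamin-B gap at the neck, small
circular micronuclei inside the cell territory, and Gaussian background
noise with optional Poisson shot noise. Shapes are rendered with 4x
supersampling followed by box down-sampling so rasterization bias stays
well below the few-percent tolerances of the shape descriptors.

Every stochastic choice flows from one integer seed through a single
generator, so identical specs render bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.measure import block_reduce

from .io import ChannelImage

_SS = 4  # supersampling factor


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; defaults model a fibroblast field.

    Geometry is in final-image pixels. ``lobulation`` holds maximum
    amplitudes of radius perturbations ``cos(k*theta)`` for harmonics
    k = 2..5 (per-nucleus amplitudes are drawn uniformly in [0, max]).
    Intensity levels are arbitrary camera units; the default noise sigma of
    40 against a DNA level of 200 gives a signal-to-noise ratio of 5.
    """

    shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 20
    nucleus_radius: tuple[float, float] = (16.0, 22.0)
    axis_ratio: tuple[float, float] = (1.0, 1.6)
    lobulation: tuple[float, ...] = (0.0, 0.03, 0.02, 0.01)
    micronucleus_prob: float = 0.0
    mn_diameter_ratio: tuple[float, float] = (0.15, 0.25)
    bleb_prob: float = 0.0
    bleb_radius: tuple[float, float] = (6.0, 10.0)
    bleb_dna_fraction: float = 0.6
    bleb_lamin_gap: bool = True
    bleb_chromatin: bool = True
    invagination_count: tuple[int, int] = (0, 0)
    tube_width: float = 3.0
    tube_length_frac: tuple[float, float] = (0.3, 0.8)
    ring_width: float = 3.0
    dna_level: float = 200.0
    mn_dna_fraction: float = 0.9
    lamin_level: float = 200.0
    laminac_level: float = 100.0
    laminac_bleb_enrichment: float = 1.5
    background: float = 10.0
    noise_sigma: float = 40.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("micronucleus_prob", "bleb_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("nucleus_radius", "bleb_radius", "tube_width", "ring_width"):
            v = getattr(self, name)
            lo = v[0] if isinstance(v, (tuple, list)) else v
            if lo <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def to_toml(self) -> str:
        from .config import _fmt

        lines = ["[scene]"]
        for f in fields(self):
            lines.append(f"{f.name} = {_fmt(getattr(self, f.name))}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, path) -> "SceneSpec":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        table = data.get("scene", data)
        kwargs = {}
        for f in fields(cls):
            if f.name in table:
                v = table[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        unknown = set(table) - {f.name for f in fields(cls)}
        if unknown:
            raise ValueError(f"unknown scene keys: {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class TruthObject:
    """One planted object: its identity, analytic parameters and pixel mask."""

    kind: str  # nucleus | micronucleus | bleb | invagination
    obj_id: int
    parent_id: int | None
    centroid: tuple[float, float]
    params: dict
    coords: np.ndarray  # (N, 2) int pixel coordinates, final resolution

    @property
    def area(self) -> int:
        return len(self.coords)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


@dataclass
class GroundTruth:
    """Planted-object table for one rendered scene."""

    shape: tuple[int, int]
    objects: list[TruthObject] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[TruthObject]:
        return [o for o in self.objects if o.kind == kind]

    @property
    def n_nuclei(self) -> int:
        return len(self.of_kind("nucleus"))

    def counts_per_nucleus(self, kind: str) -> dict[int, int]:
        counts = {o.obj_id: 0 for o in self.of_kind("nucleus")}
        for o in self.of_kind(kind):
            counts[o.parent_id] += 1
        return counts

    def frequency(self, kind: str) -> float:
        """Percentage of nuclei with >= 1 planted object of the given kind."""
        counts = self.counts_per_nucleus(kind)
        if not counts:
            raise ValueError("no nuclei in ground truth")
        return 100.0 * sum(c > 0 for c in counts.values()) / len(counts)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for o in self.objects:
            rows.append(
                {
                    "kind": o.kind,
                    "obj_id": o.obj_id,
                    "parent_id": -1 if o.parent_id is None else o.parent_id,
                    "centroid_row": o.centroid[0],
                    "centroid_col": o.centroid[1],
                    "area_px": o.area,
                    **{f"param_{k}": v for k, v in o.params.items()},
                }
            )
        return pd.DataFrame(rows)


def _ellipse_radius(theta: np.ndarray, a: float, b: float) -> np.ndarray:
    return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _downsample(mask_ss: np.ndarray) -> np.ndarray:
    return block_reduce(mask_ss.astype(float), (_SS, _SS), np.mean)


def _disk_ss(shape_ss, centre, radius):
    rr, cc = np.ogrid[: shape_ss[0], : shape_ss[1]]
    cr = (centre[0] + 0.5) * _SS - 0.5
    cc0 = (centre[1] + 0.5) * _SS - 0.5
    return (rr - cr) ** 2 + (cc - cc0) ** 2 <= (radius * _SS) ** 2


class _Patch:
    """Local supersampled canvas for one nucleus and its satellites."""

    def __init__(self, r0: int, c0: int, h: int, w: int):
        self.r0, self.c0 = r0, c0
        self.h, self.w = h, w
        self.shape_ss = (h * _SS, w * _SS)

    def to_local(self, pts_rc: np.ndarray) -> np.ndarray:
        return pts_rc - np.array([self.r0, self.c0])

    def local_ss_polygon(self, pts_rc: np.ndarray) -> np.ndarray:
        # final-resolution pixel (r, c) covers SS rows r*S .. r*S+S-1; its
        # centre maps to (r + 0.5) * S - 0.5 in SS pixel-centre coordinates
        loc = self.to_local(pts_rc)
        return (loc + 0.5) * _SS - 0.5


def _add_patch(target: np.ndarray, patch: _Patch, graded: np.ndarray, level: float) -> None:
    target[patch.r0 : patch.r0 + patch.h, patch.c0 : patch.c0 + patch.w] += graded * level


def _coords_global(patch: _Patch, pixmask: np.ndarray) -> np.ndarray:
    coords = np.argwhere(pixmask)
    return coords + np.array([patch.r0, patch.c0])


def render_scene(spec: SceneSpec) -> tuple[dict[str, ChannelImage], GroundTruth]:
    """Render one scene; returns dna/laminB/laminAC channels and the truth."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape
    a_max = spec.nucleus_radius[1] * math.sqrt(spec.axis_ratio[1])
    a_max *= 1.0 + sum(spec.lobulation)
    # per-side clearance around a nucleus: room for blebs / micronuclei only
    # when those features are enabled, so plain scenes pack densely
    side = 8.0
    if spec.bleb_prob > 0:
        side = max(side, 1.2 * spec.bleb_radius[1] + 6.0)
    if spec.micronucleus_prob > 0:
        r_mn_max = spec.mn_diameter_ratio[1] * a_max
        side = max(side, 14.0 + r_mn_max + 4.0)
    cell = int(math.ceil(2 * (a_max + side)))
    rows, cols = H // cell, W // cell
    capacity = rows * cols
    if spec.n_nuclei > capacity:
        raise ValueError(
            f"infeasible packing: {spec.n_nuclei} nuclei need more than "
            f"{capacity} grid cells of {cell} px in a {H}x{W} image"
        )
    slots = rng.permutation(capacity)[: spec.n_nuclei]
    dna = np.zeros((H, W))
    laminb = np.zeros((H, W))
    laminac = np.zeros((H, W))
    truth = GroundTruth(shape=(H, W))
    next_id = 1
    for slot in slots:
        gr, gc = divmod(int(slot), cols)
        jitter = rng.uniform(-0.05 * cell, 0.05 * cell, size=2)
        centre = np.array([(gr + 0.5) * cell + jitter[0], (gc + 0.5) * cell + jitter[1]])
        next_id = _render_nucleus(
            spec, rng, centre, dna, laminb, laminac, truth, next_id
        )
    for img in (dna, laminb, laminac):
        img += spec.background
    if spec.poisson:
        dna[:] = rng.poisson(np.clip(dna, 0, None))
        laminb[:] = rng.poisson(np.clip(laminb, 0, None))
        laminac[:] = rng.poisson(np.clip(laminac, 0, None))
    if spec.noise_sigma > 0:
        dna += rng.normal(0.0, spec.noise_sigma, size=dna.shape)
        laminb += rng.normal(0.0, spec.noise_sigma, size=laminb.shape)
        laminac += rng.normal(0.0, spec.noise_sigma, size=laminac.shape)
    channels = {
        "dna": ChannelImage(np.clip(dna, 0, None), "dna"),
        "laminB": ChannelImage(np.clip(laminb, 0, None), "laminB"),
        "laminAC": ChannelImage(np.clip(laminac, 0, None), "laminAC"),
    }
    return channels, truth


def _render_nucleus(spec, rng, centre, dna, laminb, laminac, truth, next_id) -> int:
    H, W = spec.shape
    nucleus_id = next_id
    next_id += 1
    R = rng.uniform(*spec.nucleus_radius)
    q = rng.uniform(*spec.axis_ratio)
    a, b = R * math.sqrt(q), R / math.sqrt(q)
    angle = rng.uniform(0.0, math.pi)
    amps = np.array([rng.uniform(0.0, amp) for amp in spec.lobulation])
    phases = rng.uniform(0.0, 2 * math.pi, size=len(amps))
    has_bleb = rng.uniform() < spec.bleb_prob
    # drawn unconditionally so the random stream (hence every other shape in
    # the scene) is identical whether or not this nucleus gets a bleb
    rb = rng.uniform(*spec.bleb_radius)
    if not has_bleb:
        rb = 0.0
    bleb_theta = rng.uniform(0.0, 2 * math.pi)
    n_tubes = int(rng.integers(spec.invagination_count[0], spec.invagination_count[1] + 1))
    has_mn = rng.uniform() < spec.micronucleus_prob
    mn_ratio = rng.uniform(*spec.mn_diameter_ratio)
    mn_dir = rng.uniform(0.0, 2 * math.pi)
    mn_gap = rng.uniform(4.0, 14.0)

    theta = np.linspace(0.0, 2 * math.pi, 721)[:-1]
    rho = _ellipse_radius(theta, a, b)
    for k, (amp, ph) in enumerate(zip(amps, phases), start=2):
        rho = rho * (1.0 + amp * np.cos(k * theta + ph))
    brows = centre[0] + rho * np.sin(theta + angle)
    bcols = centre[1] + rho * np.cos(theta + angle)
    boundary = np.column_stack([brows, bcols])

    pad = int(math.ceil(2.2 * rb + 30.0))
    r0 = int(math.floor(brows.min())) - pad
    c0 = int(math.floor(bcols.min())) - pad
    r1 = int(math.ceil(brows.max())) + pad
    c1 = int(math.ceil(bcols.max())) + pad
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, H), min(c1, W)
    patch = _Patch(r0, c0, r1 - r0, c1 - c0)

    poly_ss = patch.local_ss_polygon(boundary)
    nuc_ss = polygon2mask(patch.shape_ss, poly_ss)
    graded_nuc = _downsample(nuc_ss)
    _add_patch(dna, patch, graded_nuc, spec.dna_level)
    _add_patch(laminac, patch, graded_nuc, spec.laminac_level)
    pixmask = graded_nuc >= 0.5
    ecc = math.sqrt(1.0 - (b / a) ** 2) if a >= b else 0.0
    truth.objects.append(
        TruthObject(
            kind="nucleus",
            obj_id=nucleus_id,
            parent_id=None,
            centroid=tuple(np.argwhere(pixmask).mean(axis=0) + [patch.r0, patch.c0]),
            params={
                "radius": R,
                "semi_major": a,
                "semi_minor": b,
                "angle": angle,
                "eccentricity": ecc,
                "lobulated": float(amps.sum() > 0),
            },
            coords=_coords_global(patch, pixmask),
        )
    )

    d_in = ndi.distance_transform_edt(nuc_ss)
    d_out = ndi.distance_transform_edt(~nuc_ss)
    half_ss = spec.ring_width * _SS / 2.0
    ring_ss = (nuc_ss & (d_in <= half_ss)) | (~nuc_ss & (d_out <= half_ss))

    if has_bleb:
        idx = int(bleb_theta / (2 * math.pi) * len(theta)) % len(theta)
        anchor = boundary[idx]
        outward = anchor - centre
        outward = outward / np.linalg.norm(outward)
        bcentre = anchor + outward * (0.55 * rb)
        bdisk_ss = _disk_ss(patch.shape_ss, patch.to_local(bcentre), rb)
        bleb_ss = bdisk_ss & ~nuc_ss
        graded_bleb = _downsample(bleb_ss)
        if spec.bleb_chromatin:
            _add_patch(dna, patch, graded_bleb, spec.dna_level * spec.bleb_dna_fraction)
        _add_patch(
            laminac, patch, graded_bleb, spec.laminac_level * spec.laminac_bleb_enrichment
        )
        if spec.bleb_lamin_gap:
            anchor_ss = (patch.to_local(anchor) + 0.5) * _SS - 0.5
            rr, cc = np.ogrid[: patch.shape_ss[0], : patch.shape_ss[1]]
            near = (rr - anchor_ss[0]) ** 2 + (cc - anchor_ss[1]) ** 2 <= (0.8 * rb * _SS) ** 2
            ring_ss &= ~near
        bmask = graded_bleb >= 0.5
        if bmask.any():
            truth.objects.append(
                TruthObject(
                    kind="bleb",
                    obj_id=next_id,
                    parent_id=nucleus_id,
                    centroid=tuple(
                        np.argwhere(bmask).mean(axis=0) + [patch.r0, patch.c0]
                    ),
                    params={"radius": rb, "chromatin": float(spec.bleb_chromatin)},
                    coords=_coords_global(patch, bmask),
                )
            )
            next_id += 1

    tubes_ss = np.zeros(patch.shape_ss, bool)
    placed_segments: list[tuple[np.ndarray, np.ndarray]] = []
    inner_margin_ss = (spec.ring_width / 2.0 + spec.tube_width / 2.0 + 2.5) * _SS
    for _ in range(n_tubes):
        seg = _sample_tube(
            spec, rng, patch, d_in, inner_margin_ss, placed_segments
        )
        if seg is None:
            continue
        p0, p1 = seg
        tube_ss = _segment_mask(patch.shape_ss, p0, p1, spec.tube_width * _SS / 2.0)
        tube_ss &= d_in > (spec.ring_width / 2.0) * _SS  # stay off the ring
        graded_tube = _downsample(tube_ss)
        tmask = graded_tube >= 0.5
        if tmask.sum() < 6:
            continue
        tubes_ss |= tube_ss
        placed_segments.append((p0, p1))
        truth.objects.append(
            TruthObject(
                kind="invagination",
                obj_id=next_id,
                parent_id=nucleus_id,
                centroid=tuple(np.argwhere(tmask).mean(axis=0) + [patch.r0, patch.c0]),
                params={
                    "width": spec.tube_width,
                    "length": float(np.linalg.norm(p1 - p0) / _SS),
                },
                coords=_coords_global(patch, tmask),
            )
        )
        next_id += 1

    _add_patch(laminb, patch, _downsample(ring_ss | tubes_ss), spec.lamin_level)

    if has_mn:
        d_nuc = 2.0 * math.sqrt(pixmask.sum() / math.pi)
        r_mn = max(mn_ratio * d_nuc / 2.0, 1.5)
        for attempt in range(40):
            direction = mn_dir + attempt * 0.9
            unit = np.array([math.sin(direction + angle), math.cos(direction + angle)])
            rho_dir = float(
                _ellipse_radius(np.array([direction]), a, b)[0] * (1.0 + amps.sum())
            )
            mcentre = centre + unit * (rho_dir + mn_gap + r_mn)
            lr, lc = patch.to_local(mcentre)
            if not (
                r_mn + 2 <= lr < patch.h - r_mn - 2
                and r_mn + 2 <= lc < patch.w - r_mn - 2
            ):
                continue
            lr_ss = int((lr + 0.5) * _SS - 0.5)
            lc_ss = int((lc + 0.5) * _SS - 0.5)
            if d_out[lr_ss, lc_ss] < (r_mn + 3.0) * _SS:
                continue  # would touch the nucleus (or its bleb side)
            if has_bleb and np.linalg.norm(mcentre - bcentre) < rb + r_mn + 4.0:
                continue
            mn_ss = _disk_ss(patch.shape_ss, (lr, lc), r_mn)
            graded_mn = _downsample(mn_ss)
            _add_patch(dna, patch, graded_mn, spec.dna_level * spec.mn_dna_fraction)
            mmask = graded_mn >= 0.5
            truth.objects.append(
                TruthObject(
                    kind="micronucleus",
                    obj_id=next_id,
                    parent_id=nucleus_id,
                    centroid=tuple(
                        np.argwhere(mmask).mean(axis=0) + [patch.r0, patch.c0]
                    ),
                    params={"radius": r_mn, "diameter_ratio": 2 * r_mn / d_nuc},
                    coords=_coords_global(patch, mmask),
                )
            )
            next_id += 1
            break
    return next_id


def _sample_tube(spec, rng, patch, d_in_ss, margin_ss, placed, max_tries: int = 30):
    """Sample one invagination chord inside the nucleus interior.

    Walks a random line through the interior, keeps the longest stretch that
    clears the envelope ring by the safety margin, and places a sub-segment
    of the requested length fraction on it. Returns SS-coordinate endpoints
    or None when no placement clears the margin and the spacing to
    previously placed tubes.
    """
    h_ss, w_ss = d_in_ss.shape
    interior = np.argwhere(d_in_ss > margin_ss)
    if len(interior) == 0:
        return None
    for _ in range(max_tries):
        pivot = interior[rng.integers(len(interior))].astype(float)
        beta = rng.uniform(0.0, math.pi)
        direction = np.array([math.sin(beta), math.cos(beta)])
        ts = np.arange(-max(h_ss, w_ss), max(h_ss, w_ss), _SS / 2.0)
        pts = pivot[None, :] + ts[:, None] * direction[None, :]
        rr = np.clip(np.round(pts[:, 0]).astype(int), 0, h_ss - 1)
        cc = np.clip(np.round(pts[:, 1]).astype(int), 0, w_ss - 1)
        valid = d_in_ss[rr, cc] > margin_ss
        # longest contiguous valid run containing the pivot
        runs = _runs(valid)
        centre_idx = int(np.argmin(np.abs(ts)))
        run = next(((s, e) for s, e in runs if s <= centre_idx < e), None)
        if run is None:
            continue
        s, e = run
        run_len = (e - s - 1) * _SS / 2.0
        if run_len < 10.0 * _SS:
            continue
        frac = rng.uniform(*spec.tube_length_frac)
        seg_len = max(frac * run_len, 8.0 * _SS)
        seg_len = min(seg_len, run_len)
        slack = run_len - seg_len
        offset = rng.uniform(0.0, slack) if slack > 0 else 0.0
        t0 = ts[s] + offset
        p0 = pivot + t0 * direction
        p1 = pivot + (t0 + seg_len) * direction
        if any(
            _segment_distance(p0, p1, q0, q1)
            < (spec.tube_width + 3.0) * _SS
            for q0, q1 in placed
        ):
            continue
        return p0, p1
    return None


def _runs(valid: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], valid, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def _segment_mask(shape, p0, p1, half_width):
    r_lo = max(int(min(p0[0], p1[0]) - half_width - 2), 0)
    r_hi = min(int(max(p0[0], p1[0]) + half_width + 3), shape[0])
    c_lo = max(int(min(p0[1], p1[1]) - half_width - 2), 0)
    c_hi = min(int(max(p0[1], p1[1]) + half_width + 3), shape[1])
    out = np.zeros(shape, bool)
    if r_hi <= r_lo or c_hi <= c_lo:
        return out
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    pts = np.stack([rr, cc], axis=-1).astype(float)
    d = _point_segment_distance(pts.reshape(-1, 2), p0, p1).reshape(rr.shape)
    out[r_lo:r_hi, c_lo:c_hi] = d <= half_width
    return out


def _point_segment_distance(pts, p0, p1):
    v = p1 - p0
    L2 = float(v @ v)
    if L2 == 0:
        return np.linalg.norm(pts - p0, axis=1)
    t = np.clip(((pts - p0) @ v) / L2, 0.0, 1.0)
    proj = p0 + t[:, None] * v
    return np.linalg.norm(pts - proj, axis=1)


def _segment_distance(p0, p1, q0, q1) -> float:
    samples = np.linspace(0.0, 1.0, 17)
    pa = p0 + samples[:, None] * (p1 - p0)
    qa = q0 + samples[:, None] * (q1 - q0)
    d1 = _point_segment_distance(pa, q0, q1).min()
    d2 = _point_segment_distance(qa, p0, p1).min()
    return float(min(d1, d2))


@dataclass
class Score:
    """Detection performance against planted ground truth."""

    sensitivity: float
    fdr: float
    count_error: float
    n_true: int
    n_detected: int
    n_matched: int


def _coord_sets(masks_or_coords, shape) -> list[np.ndarray]:
    out = []
    for m in masks_or_coords:
        arr = np.asarray(m)
        if arr.ndim == 2 and arr.shape[1] == 2 and arr.dtype.kind in "iu":
            coords = arr
        else:
            coords = np.argwhere(arr > 0)
        out.append(np.sort(coords[:, 0].astype(np.int64) * shape[1] + coords[:, 1]))
    return out


def detections_from_mask(label_mask) -> list[np.ndarray]:
    """Split a label mask into per-object coordinate arrays."""
    labels = np.asarray(getattr(label_mask, "labels", label_mask))
    out = []
    for lab, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        coords = np.argwhere(labels[sl] == lab)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        out.append(coords)
    return out


def score_detections(
    truth_objects: list[TruthObject],
    detections,
    shape: tuple[int, int],
    iou_min: float = 0.3,
    detection_parents: list[int] | None = None,
) -> Score:
    """Greedy one-to-one IoU matching of detections against planted objects.

    ``detections`` is a list of boolean masks or (N, 2) integer coordinate
    arrays. Pairs are matched in order of descending intersection-over-union
    and count as true positives when IoU >= ``iou_min``. ``count_error`` is
    the mean absolute per-nucleus difference between true and detected
    object counts when ``detection_parents`` maps each detection to a truth
    nucleus id, otherwise the absolute global count difference.
    """
    if not 0.0 < iou_min <= 1.0:
        raise ValueError("iou_min must be in (0, 1]")
    truth_sets = _coord_sets([o.coords for o in truth_objects], shape)
    det_sets = _coord_sets(detections, shape)
    pairs = []
    for i, ts in enumerate(truth_sets):
        for j, ds in enumerate(det_sets):
            inter = np.intersect1d(ts, ds, assume_unique=True).size
            if inter == 0:
                continue
            iou = inter / (ts.size + ds.size - inter)
            if iou >= iou_min:
                pairs.append((iou, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    used_t: set[int] = set()
    used_d: set[int] = set()
    matched = []
    for iou, i, j in pairs:
        if i in used_t or j in used_d:
            continue
        used_t.add(i)
        used_d.add(j)
        matched.append((i, j))
    tp = len(matched)
    n_true = len(truth_sets)
    n_det = len(det_sets)
    sensitivity = tp / n_true if n_true else 1.0
    fdr = (n_det - tp) / n_det if n_det else 0.0
    if detection_parents is not None:
        true_counts: dict[int, int] = {}
        for o in truth_objects:
            true_counts[o.parent_id] = true_counts.get(o.parent_id, 0) + 1
        det_counts: dict[int, int] = {}
        for p in detection_parents:
            det_counts[p] = det_counts.get(p, 0) + 1
        keys = set(true_counts) | set(det_counts)
        count_error = (
            float(
                np.mean(
                    [abs(true_counts.get(k, 0) - det_counts.get(k, 0)) for k in keys]
                )
            )
            if keys
            else 0.0
        )
    else:
        count_error = float(abs(n_true - n_det))
    return Score(sensitivity, fdr, count_error, n_true, n_det, tp)
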