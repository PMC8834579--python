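"""Run configuration: every tunable parameter of the analysis modules.

All thresholds are expressed either in raw intensity units or as quantiles /
fractions of an automatically determined threshold; intensity images are never
rescaled on load, so intensity-dependence of any metric remains testable.
Configurations serialise to a plain-text TOML file and round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass
from pathlib import Path


def _fmt(value) -> str:
    """Format one value as a TOML literal (round-trip exact for floats)."""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_fmt(v) for v in value) + "]"
    raise TypeError(f"cannot serialise {type(value)!r} to TOML")


@dataclass
class RunConfig:
    """All tunable parameters, with documented defaults.

    Segmentation
    ------------
    smooth_sigma : Gaussian pre-smoothing of the DNA channel in pixels.
        Default 0 (off): smoothing removes the very contour irregularities
        under study, so the user must opt in; the choice is recorded in QC.
    threshold_method : 'otsu' (default), 'fixed' or 'quantile'.
    threshold_value / threshold_quantile : used by 'fixed' / 'quantile'.
    min_area : smallest object kept as a nucleus (px^2).
    watershed : split touching nuclei by distance-transform watershed.
    watershed_h : h-maxima depth (px) for watershed seeds; two touching
        nuclei are split only when the distance-transform saddle between
        them is at least this far below both peaks, which keeps elongated
        or lobulated single nuclei from being over-segmented.
    mitotic_k_mad : a nucleus is flagged mitotic when its integrated DNA
        intensity exceeds median + k * MAD over all nuclei in the image.
    exclude_border : flag (and exclude from statistics) border-touching nuclei.

    Shape descriptors
    -----------------
    contour_smooth_sigma : Gaussian sigma (px) applied to a *binary* mask
        before sub-pixel contour extraction; graded masks are traced as-is.
    contour_points : arc-length resampling count for curvature/EFD input.
    curvature_sigma_frac : curvature smoothing scale as a fraction of the
        contour length (default 0.02).
    efd_fidelity : reconstruction fidelity for the harmonics-needed mode;
        mean deviation must fall below (1 - fidelity) * equivalent radius.
    efd_n_fixed : highest harmonic pooled in the coefficient-ratio mode.
    efd_max_harmonics : search cap for harmonics-needed.

    Micronucleus detection
    ----------------------
    mn_max_ratio : maximum micronucleus/nucleus equivalent-diameter ratio
        (default 1/3).
    mn_min_area : minimum candidate area (px^2), rejects noise specks.
    mn_low_threshold_factor : the candidate pass thresholds at this fraction
        of the primary (Otsu) threshold so dim micronuclei are not lost.
    mn_smooth_sigma : Gaussian denoising used by the micronucleus pipeline.
    min_nucleus_area : objects at least this large are nucleus candidates.
    cleanup_iter : erosion/dilation iterations of the nucleus cleanup.
    cell_dilation_px : nuclear-mask dilation approximating the cell boundary.

    Invagination detection
    ----------------------
    lamin_quantile : per-nucleus intensity quantile defining "high lamin B".
    lamin_min_size : minimum intranuclear lamin component (px^2).
    lamin_smooth_sigma : Gaussian denoising of the lamin channel.
    shrink_px : nucleus erosion separating envelope from interior lamin.
    interior_frac : a lamin component counts as intranuclear when at least
        this fraction of its pixels lies inside the eroded nucleus.

    Bleb detection
    --------------
    bleb_dna_threshold_factor : chromatin is segmented at this fraction of
        the Otsu threshold (permissive, because blebs contain less DNA).
    bleb_smooth_sigma : Gaussian denoising for both bleb pipelines.
    lamin_gap_close_px : morphological closing radius that bridges the
        lamin-B gap at a bleb neck so the lamin object can be hole-filled.
    min_bleb_area / max_bleb_frac : candidate size window; the upper bound
        is a fraction of the parent nucleus area.
    bleb_max_iter : opening radius in px (1 px eroded per iteration) that
        cuts blebs off the nuclear core in the morphological pipeline; must
        exceed the largest expected bleb radius and stay below the nucleus
        in-radius.
    bleb_min_thickness : minimum in-radius (px) of a residual component;
        thinner residues are rasterization slivers along the core boundary,
        not blebs.
    bleb_min_protrusion : minimum distance (px) a lamin-gap candidate must
        reach beyond the lamin-B object; must exceed the depth of the
        boundary lens left where the ring gap was bridged (about half of
        lamin_gap_close_px), since a bleb by definition protrudes beyond
        the lamina while the lens lies within the nuclear silhouette.
    mn_reject_max_area / mn_reject_min_circularity : a residual object that
        is BOTH smaller than this area AND more circular than this form
        factor is rejected as a micronucleus rather than a bleb.
    """

    # segmentation
    smooth_sigma: float = 0.0
    threshold_method: str = "otsu"
    threshold_value: float = 0.0
    threshold_quantile: float = 0.95
    min_area: int = 100
    watershed: bool = True
    watershed_h: float = 4.0
    mitotic_k_mad: float = 3.0
    exclude_border: bool = True
    # shape descriptors
    contour_smooth_sigma: float = 1.0
    contour_points: int = 256
    curvature_sigma_frac: float = 0.02
    efd_fidelity: float = 0.95
    efd_n_fixed: int = 20
    efd_max_harmonics: int = 64
    # micronuclei
    mn_max_ratio: float = 1.0 / 3.0
    mn_min_area: int = 10
    mn_low_threshold_factor: float = 0.5
    mn_smooth_sigma: float = 1.0
    min_nucleus_area: int = 200
    cleanup_iter: int = 2
    cell_dilation_px: int = 25
    # invaginations
    lamin_threshold_method: str = "otsu"
    lamin_quantile: float = 0.80
    lamin_min_size: int = 20
    lamin_smooth_sigma: float = 1.0
    shrink_px: int = 4
    interior_frac: float = 0.5
    # blebs
    bleb_dna_threshold_factor: float = 0.5
    bleb_smooth_sigma: float = 1.0
    lamin_gap_close_px: int = 12
    min_bleb_area: int = 40
    max_bleb_frac: float = 0.5
    bleb_max_iter: int = 11
    bleb_min_thickness: float = 3.0
    bleb_min_protrusion: float = 5.0
    mn_reject_max_area: float = 150.0
    mn_reject_min_circularity: float = 0.85
    # randomness (synthetic data / any stochastic step)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.threshold_method not in ("otsu", "fixed", "quantile"):
            raise ValueError(f"unknown threshold_method {self.threshold_method!r}")
        if self.lamin_threshold_method not in ("otsu", "quantile"):
            raise ValueError(
                f"unknown lamin_threshold_method {self.lamin_threshold_method!r}"
            )
        positive = [
            ("contour_points", self.contour_points),
            ("efd_n_fixed", self.efd_n_fixed),
            ("efd_max_harmonics", self.efd_max_harmonics),
            ("shrink_px", self.shrink_px),
            ("cell_dilation_px", self.cell_dilation_px),
            ("bleb_max_iter", self.bleb_max_iter),
        ]
        for name, v in positive:
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        nonneg = [
            ("smooth_sigma", self.smooth_sigma),
            ("min_area", self.min_area),
            ("mitotic_k_mad", self.mitotic_k_mad),
            ("contour_smooth_sigma", self.contour_smooth_sigma),
            ("curvature_sigma_frac", self.curvature_sigma_frac),
            ("watershed_h", self.watershed_h),
            ("mn_min_area", self.mn_min_area),
            ("mn_smooth_sigma", self.mn_smooth_sigma),
            ("cleanup_iter", self.cleanup_iter),
            ("lamin_min_size", self.lamin_min_size),
            ("lamin_smooth_sigma", self.lamin_smooth_sigma),
            ("bleb_smooth_sigma", self.bleb_smooth_sigma),
            ("lamin_gap_close_px", self.lamin_gap_close_px),
            ("min_bleb_area", self.min_bleb_area),
            ("mn_reject_max_area", self.mn_reject_max_area),
            ("bleb_min_protrusion", self.bleb_min_protrusion),
            ("bleb_min_thickness", self.bleb_min_thickness),
        ]
        for name, v in nonneg:
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        unit_open = [
            ("mn_max_ratio", self.mn_max_ratio),
            ("lamin_quantile", self.lamin_quantile),
            ("efd_fidelity", self.efd_fidelity),
            ("max_bleb_frac", self.max_bleb_frac),
            ("interior_frac", self.interior_frac),
            ("mn_reject_min_circularity", self.mn_reject_min_circularity),
            ("threshold_quantile", self.threshold_quantile),
            ("mn_low_threshold_factor", self.mn_low_threshold_factor),
            ("bleb_dna_threshold_factor", self.bleb_dna_threshold_factor),
        ]
        for name, v in unit_open:
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")

    def to_toml(self) -> str:
        lines = ["[nucleoshape]"]
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {_fmt(getattr(self, f.name))}")
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_toml())

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        table = data.get("nucleoshape", data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(table) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**table)

    def hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()[:16]
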