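"""End-to-end orchestration: segment, describe, detect, summarise.

Emits tidy per-object tables (one CSV row per nucleus / micronucleus /
invagination / bleb) plus a per-run JSON summary. Group comparisons between
experimental conditions are deliberately left to downstream statistics on
the emitted tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .blebs import BlebRecord, bleb_frequency, detect_blebs_lamin_gap, detect_blebs_morphological
from .config import RunConfig
from .descriptors import NucleusRecord, measure_all
from .invaginations import InvaginationResult, detect_invaginations
from .io import ChannelImage, write_records, write_summary
from .micronuclei import MicronucleusRecord, detect_micronuclei
from .segmentation import segment_nuclei

ANALYSES = ("shape", "micronuclei", "invaginations", "blebs")


@dataclass
class RunSummary:
    """Pooled readouts of one run."""

    n_images: int
    n_nuclei: int
    n_excluded: int
    descriptor_means: dict[str, float] = field(default_factory=dict)
    descriptor_medians: dict[str, float] = field(default_factory=dict)
    micronucleus_frequency: float | None = None
    bleb_frequency: float | None = None
    mean_bleb_area: float | None = None
    mean_invagination_count: float | None = None
    mean_invagination_area_fraction: float | None = None
    config_hash: str = ""
    version: str = __version__
    timestamp: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_DESCRIPTOR_COLS = (
    "area_px",
    "perimeter_px",
    "equivalent_diameter",
    "form_factor",
    "eccentricity",
    "axis_ratio",
    "solidity",
    "mean_negative_curvature",
    "efd_harmonics_needed",
    "efd_coefficient_ratio",
    "radial_asymmetry_frac",
    "point_asymmetry_frac",
)


def run_pipeline(
    images: dict[str, dict[str, ChannelImage]],
    cfg: RunConfig | None = None,
    which: tuple[str, ...] = ("shape",),
    outdir: str | Path | None = None,
    strict: bool = False,
    timestamp: str | None = None,
) -> RunSummary:
    """Run the requested analyses over a set of images.

    ``images`` maps an image name to its channels by role. Nuclei flagged
    as border-touching or mitotic are excluded from pooled statistics but
    still listed (flagged) in the per-nucleus table.
    """
    cfg = cfg or RunConfig()
    unknown = set(which) - set(ANALYSES)
    if unknown:
        raise ValueError(f"unknown analyses: {sorted(unknown)}")
    if not images:
        raise ValueError("no images found")
    nucleus_rows: list[NucleusRecord] = []
    mn_rows: list[MicronucleusRecord] = []
    inv_rows: list[InvaginationResult] = []
    bleb_rows: list[BlebRecord] = []
    n_nuclei = 0
    n_excluded = 0
    mn_freqs: list[float] = []
    bleb_nuc_counts: list[int] = []
    for name, channels in images.items():
        if "dna" not in channels:
            raise ValueError(f"image {name!r} has no DNA channel")
        dna = channels["dna"]
        mask, qc = segment_nuclei(dna, cfg)
        retained = mask.count - len(qc.excluded())
        n_nuclei += retained
        n_excluded += len(qc.excluded())
        if "shape" in which and mask.count:
            nucleus_rows.extend(measure_all(mask.labels, qc=qc, cfg=cfg))
        if "micronuclei" in which:
            det = detect_micronuclei(dna, cfg, whole_cell=channels.get("wholeCell"))
            mn_rows.extend(det.records)
            mn_freqs.append(det.frequency)
        if "invaginations" in which:
            if "laminB" not in channels:
                _skip(name, "invaginations", "lamin-B channel missing", strict)
            elif mask.count:
                results, _ = detect_invaginations(channels["laminB"], mask, cfg)
                inv_rows.extend(results)
        if "blebs" in which:
            if "laminB" in channels:
                recs, _ = detect_blebs_lamin_gap(
                    dna,
                    channels["laminB"],
                    cfg,
                    extra_channels={
                        r: c.pixels for r, c in channels.items() if r == "laminAC"
                    },
                )
            else:
                recs, _ = detect_blebs_morphological(dna, cfg)
            bleb_rows.extend(recs)
            if mask.count:
                bleb_nuc_counts.append(mask.count)
    summary = RunSummary(
        n_images=len(images),
        n_nuclei=n_nuclei,
        n_excluded=n_excluded,
        config_hash=cfg.hash(),
        timestamp=timestamp,
    )
    kept = [r for r in nucleus_rows if not (r.touches_border or r.mitotic)]
    if kept:
        for col in _DESCRIPTOR_COLS:
            vals = np.array([getattr(r, col) for r in kept], dtype=float)
            finite = vals[np.isfinite(vals)]
            if finite.size:
                summary.descriptor_means[col] = float(finite.mean())
                summary.descriptor_medians[col] = float(np.median(finite))
    if "micronuclei" in which and mn_freqs:
        summary.micronucleus_frequency = float(np.mean(mn_freqs))
    if "blebs" in which and bleb_nuc_counts:
        freq, mean_area = bleb_frequency(sum(bleb_nuc_counts), bleb_rows)
        summary.bleb_frequency = freq
        summary.mean_bleb_area = mean_area
    if "invaginations" in which and inv_rows:
        summary.mean_invagination_count = float(
            np.mean([r.intranuclear_object_count for r in inv_rows])
        )
        summary.mean_invagination_area_fraction = float(
            np.mean([r.intranuclear_area_fraction for r in inv_rows])
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if "shape" in which:
            write_records(nucleus_rows, outdir / "nuclei.csv", record_type=NucleusRecord)
        if "micronuclei" in which:
            write_records(mn_rows, outdir / "micronuclei.csv", record_type=MicronucleusRecord)
        if "invaginations" in which:
            write_records(
                inv_rows, outdir / "invaginations.csv", record_type=InvaginationResult
            )
        if "blebs" in which:
            write_records(bleb_rows, outdir / "blebs.csv", record_type=BlebRecord)
        write_summary(summary.to_dict(), outdir / "summary.json")
        cfg.save(outdir / "config.toml")
    return summary


def _skip(name: str, analysis: str, reason: str, strict: bool) -> None:
    msg = f"image {name!r}: skipping {analysis} ({reason})"
    if strict:
        raise ValueError(msg)
    warnings.warn(msg, stacklevel=3)
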