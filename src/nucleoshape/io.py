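"""Image and table input/output.

Pixel convention used throughout the package: 0-based ``(row, col)``
coordinates with the origin at the top-left corner. Intensities are loaded
unscaled — an 8-bit and a 16-bit image of the same field keep their native
dynamic ranges.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

CHANNEL_ROLES = ("dna", "laminB", "laminAC", "nuclearEnvelope", "wholeCell")


@dataclass
class ChannelImage:
    """One 2D intensity image with a declared biological role.

    ``role`` identifies the stain: a DNA dye (DAPI/Hoechst), lamin B,
    lamin A/C, a generic nuclear-envelope marker, or a whole-cell stain.
    """

    pixels: np.ndarray
    role: str
    pixel_size_um: float | None = None
    bit_depth: int | str = field(default=0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2D image, got shape {self.pixels.shape}")
        if min(self.pixels.shape) < 16:
            raise ValueError(f"image too small: {self.pixels.shape} (need >= 16 px per side)")
        if self.role not in CHANNEL_ROLES:
            raise ValueError(f"unknown channel role {self.role!r}; expected one of {CHANNEL_ROLES}")
        if self.pixels.size and float(self.pixels.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_depth == 0:
            self.bit_depth = _bit_depth_of(self.pixels.dtype)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _bit_depth_of(dtype: np.dtype) -> int | str:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    return "float"


def read_image(
    path: str | Path,
    role: str,
    page: int | None = None,
    channel: int | None = None,
    pixel_size_um: float | None = None,
) -> ChannelImage:
    """Read a single-plane TIFF or PNG into a :class:`ChannelImage`.

    ``page`` selects the plane of a multi-page TIFF (required when the file
    has more than one page). ``channel`` selects one channel of an RGB(A)
    image (required for colour PNGs). Pixels are loaded unscaled.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and arr.shape[0] > 4:
            # colour image: channels last
            if channel is None:
                raise ValueError(
                    f"{path.name} has {arr.shape[-1]} channels; pass a channel selector"
                )
            arr = arr[..., channel]
        else:
            # plane stack: pages first
            if page is None:
                raise ValueError(
                    f"ambiguous plane: {path.name} has {arr.shape[0]} pages; "
                    "pass a page index"
                )
            arr = arr[page]
    elif arr.ndim != 2:
        raise ValueError(f"{path.name}: unsupported image dimensionality {arr.shape}")
    return ChannelImage(arr, role, pixel_size_um=pixel_size_um)


def write_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label mask as a 16-bit TIFF."""
    labels = np.asarray(labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored in a 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(str(path)), dtype=np.int32)


def _flatten(record) -> dict:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        record = dataclasses.asdict(record)
    flat = {}
    for key, value in record.items():
        if isinstance(value, dict):
            for sub, v in value.items():
                flat[f"{key}_{sub}"] = v
        elif isinstance(value, (tuple, list)) and key == "centroid":
            flat["centroid_row"], flat["centroid_col"] = value
        else:
            flat[key] = value
    return flat


def _schema_columns(record_type) -> list[str]:
    cols = []
    for f in dataclasses.fields(record_type):
        if f.name == "centroid":
            cols += ["centroid_row", "centroid_col"]
        else:
            cols.append(f.name)
    return cols


def write_records(records, path: str | Path, record_type=None) -> None:
    """Write a homogeneous collection of records to CSV (header always present).

    Records may be dataclass instances or plain dicts sharing a schema.
    Floats are written at full precision so that write→read round-trips.
    """
    records = list(records)
    if not records and record_type is None:
        raise ValueError("empty collection: pass record_type to define the header")
    rows = [_flatten(r) for r in records]
    if rows:
        columns = list(rows[0].keys())
        for row in rows[1:]:
            if list(row.keys()) != columns:
                raise ValueError("records do not share a schema")
    else:
        columns = _schema_columns(record_type)
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
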