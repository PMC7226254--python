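"""Live-cell counting from multi-field fluorescence images.

Mirrors a high-content-screening readout: per field, threshold the GFP
channel, label 8-connected foreground objects, and keep objects passing
area / roundness / intensity filters; per well, sum accepted objects over all
fields. Roundness is the isoperimetric ratio 4*pi*A/P^2 clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.measure import label, regionprops

from .config import SegmentationParams

__all__ = [
    "FieldImage",
    "CellDetection",
    "WellCount",
    "robust_threshold",
    "segment_field",
    "count_well",
    "count_image_dir",
    "read_field_tiff",
]


@dataclass
class FieldImage:
    """One acquired field: a 2-D intensity grid plus its plate address."""

    pixels: np.ndarray
    plate_id: str = ""
    well: str = ""
    field_index: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("FieldImage.pixels must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("FieldImage.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("FieldImage.pixels must be non-negative")


@dataclass
class CellDetection:
    """One segmented object and its filter outcome."""

    centroid: tuple[float, float]
    area: int
    roundness: float
    mean_intensity: float
    accepted: bool
    touches_border: bool = False


@dataclass
class WellCount:
    """Accepted-cell count of a well plus per-field breakdown for QC."""

    plate_id: str
    well: str
    count: int
    field_counts: list[int] = field(default_factory=list)


def robust_threshold(pixels: np.ndarray, k: float) -> float:
    """Background-robust intensity threshold: median + k * 1.4826 * MAD.

    The scaled median absolute deviation estimates the background sigma since
    cells occupy a small area fraction. Floored one unit above the median so a
    perfectly flat background never segments.
    """
    med = float(np.median(pixels))
    mad = float(np.median(np.abs(pixels - med)))
    return med + max(k * 1.4826 * mad, 1.0)


def _roundness(area: float, perimeter: float) -> float:
    if perimeter <= 0:
        return 1.0  # single pixel / degenerate object: treat as round
    return float(np.clip(4.0 * np.pi * area / perimeter**2, 0.0, 1.0))


def segment_field(
    image: FieldImage | np.ndarray, params: SegmentationParams | None = None
) -> list[CellDetection]:
    """Segment one field into candidate cells with accept/reject flags.

    Foreground is ``pixels >= threshold`` (absolute, or robust data-driven
    when ``params.intensity_threshold`` is None); objects are 8-connected
    components. Each object is accepted iff it passes the area range,
    the minimum roundness, the minimum mean intensity, and (by default) does
    not touch the image border. All objects are returned, accepted or not.
    An all-background image yields an empty list.
    """
    params = params or SegmentationParams()
    if isinstance(image, FieldImage):
        pixels = image.pixels
    else:
        pixels = FieldImage(np.asarray(image)).pixels
    if pixels.size == 0:
        raise ValueError("image is empty")

    thr = (
        params.intensity_threshold
        if params.intensity_threshold is not None
        else robust_threshold(pixels, params.threshold_k)
    )
    mask = pixels >= thr
    labels = label(mask, connectivity=2)
    h, w = pixels.shape
    detections: list[CellDetection] = []
    for prop in regionprops(labels, intensity_image=pixels):
        area = int(prop.area)
        roundness = _roundness(area, prop.perimeter)
        mean_int = float(prop.intensity_mean)
        minr, minc, maxr, maxc = prop.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        accepted = (
            params.min_area <= area <= params.max_area
            and roundness >= params.min_roundness
            and mean_int >= params.min_mean_intensity
            and not (params.exclude_border and touches)
        )
        detections.append(
            CellDetection(
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area=area,
                roundness=roundness,
                mean_intensity=mean_int,
                accepted=accepted,
                touches_border=touches,
            )
        )
    return detections


def count_well(
    fields: Sequence[FieldImage | np.ndarray], params: SegmentationParams | None = None
) -> WellCount:
    """Sum accepted detections over a well's fields (order-invariant)."""
    fields = list(fields)
    if not fields:
        raise ValueError("count_well requires at least one field")
    plate_id = well = ""
    for f in fields:
        if isinstance(f, FieldImage):
            plate_id, well = f.plate_id, f.well
            break
    per_field = [sum(d.accepted for d in segment_field(f, params)) for f in fields]
    return WellCount(plate_id=plate_id, well=well, count=int(sum(per_field)), field_counts=per_field)


def read_field_tiff(path: str | Path) -> np.ndarray:
    """Read a single-channel 8/16-bit TIFF field."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing field image: {path}")
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel 2-D image, got shape {arr.shape}")
    return arr


def count_image_dir(
    image_dir: str | Path, params: SegmentationParams | None = None
) -> pd.DataFrame:
    """Count every well found in a directory of ``plate_well_field.tif`` files.

    Returns a table (plate_id, well, count, field_counts). Raises
    :class:`FileNotFoundError` naming the directory if it holds no fields.
    """
    image_dir = Path(image_dir)
    groups: dict[tuple[str, str], list[Path]] = {}
    for path in sorted(image_dir.glob("*.tif")):
        parts = path.stem.rsplit("_", 2)
        if len(parts) != 3:
            continue
        plate_id, well, _ = parts
        groups.setdefault((plate_id, well), []).append(path)
    if not groups:
        raise FileNotFoundError(f"no plate_well_field.tif images found in {image_dir}")
    rows = []
    for (plate_id, well), paths in sorted(groups.items()):
        imgs = [FieldImage(read_field_tiff(p), plate_id, well, i + 1) for i, p in enumerate(paths)]
        wc = count_well(imgs, params)
        rows.append(
            dict(
                plate_id=plate_id,
                well=well,
                count=wc.count,
                field_counts=";".join(str(c) for c in wc.field_counts),
            )
        )
    return pd.DataFrame(rows, columns=["plate_id", "well", "count", "field_counts"])
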