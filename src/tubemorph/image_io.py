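"""Reading micrographs, selecting the analysis channel, and persisting outputs.

All images are carried through the pipeline as :class:`GrayImage`: a
single-channel 2-D float raster in ``[0, 1]``, optionally annotated with the
physical size of one pixel in micrometres.  Intensities are normalised by the
source bit-depth maximum (255 or 65535) so that every downstream histogram
operation can work on a fixed 256-bin framing of ``[0, 1]``.

Physical scaling is always supplied through configuration (either a direct
µm/px value or the microscope acquisition fields), never read from file
metadata: resolution tags are unreliable across heterogeneous inputs and a
config-supplied value keeps batch analyses reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: file suffixes accepted by default (lower-case, without dot)
DEFAULT_EXTENSIONS = frozenset({"tif", "tiff", "png", "jpg", "jpeg"})

MIN_SIZE = 8

# canonical column order of the statistics table
STATS_COLUMNS = [
    "filename",
    "vessel_area_px2",
    "skeleton_length_px",
    "mean_width_px",
    "n_branch_points",
    "n_crossing_points",
    "threshold_used",
    "vessel_area_um2",
    "skeleton_length_um",
    "mean_width_um",
    "pixel_size_um",
]


class InputError(ValueError):
    """Raised for unreadable/undecodable inputs or empty input directories."""


@dataclass(frozen=True)
class GrayImage:
    """Single-channel 2-D intensity raster, float in [0, 1].

    Parameters
    ----------
    pixels
        2-D float array with values in ``[0, 1]``.
    pixel_size_um
        Physical edge length of one pixel in micrometres, if known.
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D raster, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIZE or px.shape[1] < MIN_SIZE:
            raise InputError(
                f"image {px.shape} smaller than {MIN_SIZE}x{MIN_SIZE} rejected"
            )
        if not np.isfinite(px).all():
            raise InputError("image contains non-finite intensities")
        if px.min() < 0.0 or px.max() > 1.0:
            raise InputError("intensities must lie in [0, 1]")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be strictly positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same metadata, new raster (clipped into [0, 1] for float safety)."""
        return replace(self, pixels=np.clip(pixels, 0.0, 1.0))


@dataclass(frozen=True)
class ChannelSpec:
    """Which plane of a (possibly multi-channel) file to analyse.

    ``selector`` is one of ``red``/``green``/``blue``/``gray`` or an integer
    channel index.  ``gray`` on a colour file takes the mean of all colour
    channels.  A colour selector on a single-channel file falls back to that
    single channel (with a warning); on a file that has channels but not the
    requested one it is an error.
    """

    selector: str | int = "green"

    _NAMED = {"red": 0, "green": 1, "blue": 2}

    def __post_init__(self) -> None:
        if isinstance(self.selector, str):
            if self.selector not in (*self._NAMED, "gray"):
                raise InputError(
                    f"unknown channel selector {self.selector!r}; "
                    f"expected red/green/blue/gray or an integer index"
                )
        elif self.selector < 0:
            raise InputError("channel index must be >= 0")


def microscope_pixel_size_um(
    camera_pixel_size_um: float,
    objective: float,
    lens: float = 1.0,
    c_mount: float = 1.0,
    binning: int = 1,
) -> float:
    """Physical sample-plane pixel size from acquisition settings.

    ``camera_px_size * binning / (objective * lens * c_mount)`` — e.g. a
    2.76 µm camera pixel behind a 10x objective images 0.276 µm of sample
    per pixel.
    """
    total_mag = objective * lens * c_mount
    if total_mag <= 0 or camera_pixel_size_um <= 0 or binning <= 0:
        raise InputError("microscope factors must be strictly positive")
    return camera_pixel_size_um * binning / total_mag


def discover_inputs(
    input_dir: str | Path,
    extensions: Iterable[str] = DEFAULT_EXTENSIONS,
) -> list[Path]:
    """List image files in ``input_dir``, sorted by name.

    Ordering is deterministic: case-sensitive lexicographic order of the file
    name (uppercase before lowercase, as in ASCII).  Matching against
    ``extensions`` is case-insensitive.
    """
    d = Path(input_dir)
    if not d.is_dir():
        raise InputError(f"input directory {d} does not exist or is not a directory")
    exts = {e.lower().lstrip(".") for e in extensions}
    files = sorted(
        p for p in d.iterdir()
        if p.is_file() and p.suffix.lower().lstrip(".") in exts
    )
    if not files:
        raise InputError(f"no images found in {d} (extensions: {sorted(exts)})")
    return files


def _select_channel(arr: np.ndarray, channel: ChannelSpec) -> np.ndarray:
    if arr.ndim == 2:
        if channel.selector != "gray" and channel.selector not in (0,):
            logger.warning(
                "file is single-channel; ignoring channel selector %r",
                channel.selector,
            )
        return arr
    if arr.ndim != 3:
        raise InputError(f"cannot interpret image with ndim={arr.ndim}")
    # channels-last; tolerate RGBA by ignoring alpha for 'gray'
    n = arr.shape[2]
    sel = channel.selector
    if sel == "gray":
        return arr[:, :, : min(n, 3)].mean(axis=2)
    idx = ChannelSpec._NAMED[sel] if isinstance(sel, str) else sel
    if idx >= n:
        raise InputError(f"channel {sel!r} not available in file with {n} channels")
    return arr[:, :, idx]


def read_image(
    path: str | Path,
    channel: ChannelSpec = ChannelSpec("gray"),
    pixel_size_um: float | None = None,
) -> GrayImage:
    """Read an 8/16-bit TIFF/PNG/JPEG and return the selected channel.

    Intensities are rescaled to ``[0, 1]`` by dividing by the bit-depth
    maximum of the source dtype.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap every decoder failure
        raise InputError(f"cannot decode {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        scale = 1.0
    else:
        raise InputError(f"unsupported dtype {arr.dtype} in {path}")
    plane = _select_channel(arr, channel).astype(float) / scale
    return GrayImage(np.clip(plane, 0.0, 1.0), pixel_size_um=pixel_size_um)


@dataclass
class StageOutputPlan:
    """Where per-stage intermediate images go.

    One subdirectory per pipeline stage under ``root_dir``; file names keep
    the input image's basename.  Masks are written as 8-bit 0/255 PNG, float
    images are min-max stretched to 8-bit PNG (a constant image maps to all
    zeros by convention).
    """

    root_dir: Path
    created: list[Path] = field(default_factory=list)

    @classmethod
    def for_input_dir(cls, input_dir: str | Path) -> "StageOutputPlan":
        return cls(root_dir=Path(input_dir) / "tubemorph_out")

    def stage_dir(self, stage_name: str) -> Path:
        d = self.root_dir / stage_name
        d.mkdir(parents=True, exist_ok=True)
        return d


def _to_uint8(img_or_mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(img_or_mask)
    if arr.dtype == bool:
        return arr.astype(np.uint8) * 255
    arr = arr.astype(float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi <= lo:  # degenerate stretch: constant image -> all zeros
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def write_stage_image(
    img_or_mask: np.ndarray | GrayImage,
    stage_name: str,
    plan: StageOutputPlan,
    basename: str,
) -> Path:
    """Persist one stage output as PNG; returns the written path.

    Deterministic and idempotent: the same input always produces the same
    bytes.
    """
    if isinstance(img_or_mask, GrayImage):
        img_or_mask = img_or_mask.pixels
    out = plan.stage_dir(stage_name) / f"{Path(basename).stem}.png"
    iio.imwrite(out, _to_uint8(img_or_mask))
    plan.created.append(out)
    return out


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Morphometrics records -> one-row-per-image DataFrame.

    Physical-unit columns are left empty (NaN) when the pixel size is
    unknown.  Extra provenance columns (the parameter set used) may follow
    the canonical columns.
    """
    rows = []
    for rec in records:
        row = rec.as_dict() if hasattr(rec, "as_dict") else dict(rec)
        rows.append(row)
    frame = pd.DataFrame(rows)
    ordered = [c for c in STATS_COLUMNS if c in frame.columns]
    extra = [c for c in frame.columns if c not in ordered]
    return frame[ordered + extra]


def write_statistics(
    records: Sequence,
    path: str | Path,
    xlsx: bool = False,
) -> Path:
    """Write the per-image statistics table.

    CSV is always written (comma separated, ``.`` decimal, UTF-8); an XLSX
    twin is written next to it when ``xlsx`` is true.
    """
    if len(records) == 0:
        raise InputError("no records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = records_to_frame(records)
    frame.to_csv(path, index=False, encoding="utf-8")
    if xlsx:
        frame.to_excel(path.with_suffix(".xlsx"), index=False)
    return path


def read_statistics(path: str | Path) -> pd.DataFrame:
    """Re-parse a statistics CSV written by :func:`write_statistics`."""
    return pd.read_csv(path, encoding="utf-8")
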