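"""Domain types and file IO for images, masks, z-stacks and measurement tables.

All downstream modules consume only the types defined here:

* :class:`ImageSample` — a 2D single-channel intensity image with a physical
  pixel size in micrometres; the unit of inference.
* :class:`ZStack` — an ordered stack of equally shaped slices, reduced to an
  :class:`ImageSample` by maximum-intensity projection.
* :class:`ClassMasks` — the pair of co-registered binary masks (rod, ring)
  that is both the annotation format and the thresholded prediction format.

Tabular measurements travel as pandas DataFrames (see
:func:`write_measurements`); CSV is the single export dialect so the output
can be interrogated by third-party graphing/analysis packages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: column order of a measurement table CSV (one row per image id)
MEASUREMENT_COLUMNS = [
    "id",
    "n_rods",
    "n_rings",
    "rod_mean_area_um2",
    "rod_mean_perimeter_um",
    "rod_perimeter_area_ratio",
    "ring_mean_area_um2",
    "ring_mean_perimeter_um",
    "ring_perimeter_area_ratio",
    "rod_ring_ratio",
]


class InputError(ValueError):
    """Raised when an input file or argument violates a documented contract."""


@dataclass
class ImageSample:
    """A 2D intensity image plus the physical size of one pixel side (µm)."""

    id: str
    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InputError(
                f"ImageSample pixels must be 2D, got shape {self.pixels.shape}"
            )
        if self.pixels.size == 0:
            raise InputError("ImageSample pixels must be non-empty")
        if not (self.pixel_size_um > 0):
            raise InputError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("ImageSample intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def field_of_view_um(self) -> tuple[float, float]:
        """Physical extent (height, width) of the imaged field in µm."""
        h, w = self.pixels.shape
        return h * self.pixel_size_um, w * self.pixel_size_um


@dataclass
class ZStack:
    """An ordered list of equally shaped 2D slices sharing one pixel size."""

    id: str
    slices: list[np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise InputError("ZStack needs at least one slice")
        self.slices = [np.asarray(s) for s in self.slices]
        shape = self.slices[0].shape
        for i, s in enumerate(self.slices):
            if s.ndim != 2 or s.shape != shape:
                raise InputError(
                    f"slice {i} has shape {s.shape}, expected {shape} (2D, uniform)"
                )
        if not (self.pixel_size_um > 0):
            raise InputError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")


@dataclass
class ClassMasks:
    """Co-registered binary masks for the two RR classes."""

    id: str
    rod: np.ndarray
    ring: np.ndarray

    def __post_init__(self) -> None:
        self.rod = np.asarray(self.rod, dtype=bool)
        self.ring = np.asarray(self.ring, dtype=bool)
        if self.rod.ndim != 2 or self.rod.shape != self.ring.shape:
            raise InputError(
                f"rod/ring masks must be 2D with identical shapes, got "
                f"{self.rod.shape} vs {self.ring.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.rod.shape  # type: ignore[return-value]

    def classes(self) -> dict[str, np.ndarray]:
        return {"rod": self.rod, "ring": self.ring}


def _to_single_channel(arr: np.ndarray, channel: int, path: Path) -> np.ndarray:
    """Reduce an imageio array to a single 2D channel.

    Channel axis is taken as the trailing axis when it is small (<= 4,
    the RGB/RGBA convention); otherwise a 3D array is treated as a stack
    and rejected here (use :func:`read_zstack`).
    """
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] <= 4:
        if not 0 <= channel < arr.shape[-1]:
            raise InputError(
                f"channel {channel} out of range for {arr.shape[-1]}-channel "
                f"image {path}"
            )
        return arr[..., channel]
    raise InputError(
        f"{path}: expected a 2D image or an H x W x C image with C <= 4, "
        f"got shape {arr.shape}"
    )


def read_image(path: str | Path, pixel_size_um: float, *, channel: int = 0,
               id: str | None = None) -> ImageSample:
    """Read a TIFF/PNG/JPEG image as a single-channel :class:`ImageSample`.

    Multi-channel images are reduced by selecting ``channel`` (default: the
    first), since the model consumes only the IMPDH2 channel and averaging
    would dilute signal. Lossless formats round-trip bit-exactly. JPEG is
    accepted but a warning is logged: compression artefacts may alter
    downstream metrics.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    try:
        arr = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - wrap decoder errors uniformly
        raise InputError(f"cannot decode image {path}: {exc}") from exc
    if arr.size == 0:
        raise InputError(f"zero-sized image: {path}")
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        logger.warning(
            "%s is JPEG; compression artefacts may alter segmentation metrics "
            "(prefer TIFF/PNG)", path,
        )
    pixels = _to_single_channel(arr, channel, path)
    return ImageSample(id=id or path.stem, pixels=pixels,
                       pixel_size_um=pixel_size_um)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask image (values {0, max} or {0, 1}) as a boolean array.

    Any file with more than two distinct pixel values is rejected — masks are
    strictly binary by contract.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"mask file not found: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[-1] <= 4:
        # accept greyscale saved with redundant channels
        if not all(np.array_equal(arr[..., 0], arr[..., c])
                   for c in range(1, min(arr.shape[-1], 3))):
            raise InputError(f"{path}: multi-channel mask with differing channels")
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise InputError(f"{path}: mask must be 2D, got shape {arr.shape}")
    values = np.unique(arr)
    if len(values) > 2:
        raise InputError(
            f"{path}: mask must contain exactly two values, found {values.tolist()}"
        )
    return arr != 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit PNG with values {0, 255} (lossless)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def write_image(sample: ImageSample, path: str | Path) -> None:
    """Write image pixels; 16-bit for TIFF/PNG after rounding, clipped at 0."""
    path = Path(path)
    px = np.clip(np.rint(sample.pixels), 0, 65535).astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, px)
    else:
        iio.imwrite(path, px)


def read_zstack(path: str | Path, pixel_size_um: float,
                id: str | None = None) -> ZStack:
    """Read a multi-page TIFF as a :class:`ZStack` (single page → one slice)."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise InputError(f"stack file not found: {path}")
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InputError(f"{path}: expected a 2D/3D TIFF, got shape {arr.shape}")
    return ZStack(id=id or path.stem, slices=list(arr),
                  pixel_size_um=pixel_size_um)


def max_intensity_projection(stack: ZStack) -> ImageSample:
    """Per-pixel maximum over slices — the standard 2D reduction of a z-stack.

    Invariant to slice order; identity on single-slice stacks. Pixel size is
    carried over unchanged.
    """
    proj = np.max(np.stack(stack.slices, axis=0), axis=0)
    return ImageSample(id=stack.id, pixels=proj,
                       pixel_size_um=stack.pixel_size_um)


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as UTF-8 CSV with a fixed column order.

    Column order is :data:`MEASUREMENT_COLUMNS`; missing per-class means (for
    images with zero objects of that class) are written as empty fields.
    Re-reading with :func:`read_measurements` reproduces the table.
    """
    if table.columns.tolist() and "id" in table.columns:
        if table["id"].duplicated().any():
            raise InputError("measurement table has duplicate image ids")
    cols = [c for c in MEASUREMENT_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in MEASUREMENT_COLUMNS
    ]
    table.loc[:, cols].to_csv(Path(path), index=False, encoding="utf-8")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement table CSV written by :func:`write_measurements`."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"measurement file not found: {path}")
    df = pd.read_csv(path)
    if df.empty and "id" not in df.columns:
        raise InputError(f"{path}: not a measurement table (no header)")
    return df


def load_config(path: str | Path) -> dict:
    """Load a YAML key-value run configuration file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping at top level")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(Path(path), "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
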