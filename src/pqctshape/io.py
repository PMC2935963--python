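"""Reading and writing raw pQCT cross-section images and analysis configs.

The scanner export is a headerless binary of unsigned 16-bit attenuation
samples in row-major order; the geometry (width, height, in-plane voxel
size) is not stored in the file and must be supplied by configuration.
The default geometry is the 283 x 283 pixel, 0.5 mm-voxel export of the
Stratec XCT-2000.

Coordinate conventions used by the whole package
------------------------------------------------
* pixel (row r, col c), 0-based, occupies the square
  [c*v, (c+1)*v) x [r*v, (r+1)*v) in mm, with v the voxel size;
* its center is at (x, y) = ((c + 0.5) * v, (r + 0.5) * v);
* x increases to the right, y increases DOWNWARD (image convention);
* all contour points emitted downstream are pixel centers in mm.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

from .errors import ConfigError, RawFormatError

#: Threshold bounds of the original analysis software; values outside this
#: band are accepted only with an explicit override.
THRESHOLD_RANGE = (200, 1000)

DEFAULT_WIDTH = 283
DEFAULT_HEIGHT = 283
DEFAULT_VOXEL_MM = 0.5
DEFAULT_THRESHOLD = 450


@dataclass(frozen=True)
class ImageGeometry:
    """Physical description of a raw scan export."""

    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    voxel_size: float = DEFAULT_VOXEL_MM
    byte_order: str = "little"

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ConfigError("image dimensions must be positive")
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be positive (mm per pixel)")
        if self.byte_order not in ("little", "big"):
            raise ConfigError("byte_order must be 'little' or 'big'")

    @property
    def nbytes(self) -> int:
        """Expected raw-file length: width x height x 2 bytes."""
        return self.width * self.height * 2

    @property
    def dtype(self) -> np.dtype:
        return np.dtype("<u2" if self.byte_order == "little" else ">u2")


@dataclass
class ScanImage:
    """A 2-D grid of 16-bit attenuation values with physical geometry."""

    geometry: ImageGeometry
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (self.geometry.height, self.geometry.width):
            raise ConfigError(
                f"value grid shape {self.values.shape} does not match geometry "
                f"({self.geometry.height}, {self.geometry.width})"
            )
        if self.values.dtype != np.uint16:
            if self.values.min() < 0 or self.values.max() > 65535:
                raise ConfigError("attenuation values must lie in [0, 65535]")
            self.values = self.values.astype(np.uint16)

    @property
    def voxel_size(self) -> float:
        return self.geometry.voxel_size


def read_raw(path: str | os.PathLike, geometry: ImageGeometry) -> ScanImage:
    """Read a headerless 16-bit raw export.

    The first sample in the file is pixel (row 0, col 0); samples are
    row-major and the row index increases downward.
    """
    size = os.path.getsize(path)
    if size != geometry.nbytes:
        raise RawFormatError(
            f"{path}: expected {geometry.nbytes} bytes "
            f"({geometry.width}x{geometry.height}x2), found {size}"
        )
    data = np.fromfile(path, dtype=geometry.dtype)
    grid = data.reshape(geometry.height, geometry.width).astype(np.uint16)
    return ScanImage(geometry, grid)


def write_raw(image: ScanImage, path: str | os.PathLike) -> str:
    """Write an image as a headerless raw file readable by :func:`read_raw`."""
    image.values.astype(image.geometry.dtype).tofile(path)
    return os.fspath(path)


def load_image(
    path: str | os.PathLike,
    geometry: ImageGeometry | None = None,
    voxel_size: float | None = None,
) -> ScanImage:
    """Load a scan from raw, or from 16-bit grayscale TIFF/PNG.

    For ``.raw`` inputs `geometry` is required. For TIFF/PNG the pixel grid
    comes from the file and only the voxel size is needed (default 0.5 mm).
    """
    ext = os.path.splitext(os.fspath(path))[1].lower()
    if ext in (".raw", ".bin", ""):
        if geometry is None:
            raise ConfigError("raw input requires an explicit ImageGeometry")
        return read_raw(path, geometry)
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse spurious color axis of grayscale exports
        arr = arr[..., 0]
    v = voxel_size if voxel_size is not None else (
        geometry.voxel_size if geometry is not None else DEFAULT_VOXEL_MM
    )
    geom = ImageGeometry(width=arr.shape[1], height=arr.shape[0], voxel_size=v)
    return ScanImage(geom, arr.astype(np.uint16))


@dataclass
class AnalysisConfig:
    """Validated parameters of one shape analysis run."""

    threshold: float = DEFAULT_THRESHOLD
    voxel_size: float = DEFAULT_VOXEL_MM
    width: int = DEFAULT_WIDTH
    height: int = DEFAULT_HEIGHT
    open_iterations: int = 1
    connectivity: int = 8
    seed: tuple[int, int] | str = "auto"
    byte_order: str = "little"
    allow_threshold_override: bool = False
    subpixel: bool = False

    def __post_init__(self):
        lo, hi = THRESHOLD_RANGE
        if not (lo <= self.threshold <= hi) and not self.allow_threshold_override:
            raise ConfigError(
                f"threshold {self.threshold} outside the supported range "
                f"{lo}-{hi}; set allow_threshold_override to force it"
            )
        if self.voxel_size <= 0:
            raise ConfigError("voxel_size must be positive")
        if self.open_iterations < 0:
            raise ConfigError("open_iterations must be >= 0")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")

    @property
    def geometry(self) -> ImageGeometry:
        return ImageGeometry(
            width=self.width,
            height=self.height,
            voxel_size=self.voxel_size,
            byte_order=self.byte_order,
        )


_REQUIRED_CONFIG_KEYS = ("threshold", "voxel_size", "width", "height")
_OPTIONAL_CONFIG_KEYS = (
    "open_iterations",
    "connectivity",
    "seed",
    "byte_order",
    "allow_threshold_override",
    "subpixel",
)


def load_config(path: str | os.PathLike) -> AnalysisConfig:
    """Load and validate a JSON key-value analysis configuration.

    Required keys: ``threshold``, ``voxel_size``, ``width``, ``height``.
    Optional: ``open_iterations``, ``connectivity``, ``seed`` ("auto" or
    [row, col]), ``byte_order``, ``allow_threshold_override``, ``subpixel``.
    """
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: not valid JSON: {exc}") from exc
    missing = [k for k in _REQUIRED_CONFIG_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing required key(s): {', '.join(missing)}")
    kwargs = {}
    for key in _REQUIRED_CONFIG_KEYS + _OPTIONAL_CONFIG_KEYS:
        if key not in raw:
            continue
        val = raw[key]
        if key in ("threshold", "voxel_size"):
            try:
                val = float(val)
            except (TypeError, ValueError):
                raise ConfigError(f"{path}: key '{key}' is not numeric: {val!r}")
        elif key in ("width", "height", "open_iterations", "connectivity"):
            try:
                val = int(val)
            except (TypeError, ValueError):
                raise ConfigError(f"{path}: key '{key}' is not an integer: {val!r}")
        elif key == "seed" and val != "auto":
            try:
                val = (int(val[0]), int(val[1]))
            except (TypeError, ValueError, IndexError):
                raise ConfigError(f"{path}: seed must be 'auto' or [row, col]")
        kwargs[key] = val
    unknown = set(raw) - set(_REQUIRED_CONFIG_KEYS) - set(_OPTIONAL_CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")
    return AnalysisConfig(**kwargs)


def pixel_centers_to_mm(rc: np.ndarray, voxel_size: float) -> np.ndarray:
    """Map (row, col) pixel indices to (x, y) mm pixel-center coordinates."""
    rc = np.atleast_2d(np.asarray(rc, dtype=float))
    x = (rc[:, 1] + 0.5) * voxel_size
    y = (rc[:, 0] + 0.5) * voxel_size
    return np.column_stack([x, y])


__all__ = [
    "ImageGeometry",
    "ScanImage",
    "AnalysisConfig",
    "read_raw",
    "write_raw",
    "load_image",
    "load_config",
    "pixel_centers_to_mm",
    "THRESHOLD_RANGE",
    "DEFAULT_THRESHOLD",
    "DEFAULT_VOXEL_MM",
]
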