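"""AFM height-image container and file I/O.

Images are square-pixel height maps in nanometres.  On disk an image is a
single-channel 32-bit float TIFF whose values are heights in nm, paired
with a JSON sidecar (same stem, ``.json``) carrying the pixel size and the
generation seed if any.  A plain whitespace-delimited matrix text format
with a one-line header is accepted as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import FormatError, InvalidSpecError

MIN_PIXELS = 16


@dataclass(frozen=True)
class PixelGeometry:
    """Raster geometry of a scan: pixel counts and square pixel size in nm."""

    pixels_x: int
    pixels_y: int
    pixel_size: float  # nm per pixel

    def __post_init__(self):
        if self.pixels_x < MIN_PIXELS or self.pixels_y < MIN_PIXELS:
            raise InvalidSpecError(
                f"image must be at least {MIN_PIXELS} px on a side, got "
                f"{self.pixels_x} x {self.pixels_y}"
            )
        if not self.pixel_size > 0:
            raise InvalidSpecError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def width_nm(self) -> float:
        return self.pixels_x * self.pixel_size

    @property
    def height_nm(self) -> float:
        return self.pixels_y * self.pixel_size

    @property
    def area_um2(self) -> float:
        """Scanned area in square micrometres."""
        return self.width_nm * self.height_nm * 1e-6


@dataclass
class AFMImage:
    """A height map in nm with its pixel geometry.

    ``flattened`` records whether the background (scan-line offsets, plane
    tilt) has already been removed; detection requires a flattened image.
    """

    heights: np.ndarray  # shape (pixels_y, pixels_x), nm
    geom: PixelGeometry
    flattened: bool = False
    provenance: str = ""
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise InvalidSpecError("heights must be a 2-D array")
        ny, nx = self.heights.shape
        if (nx, ny) != (self.geom.pixels_x, self.geom.pixels_y):
            raise InvalidSpecError(
                f"heights shape {self.heights.shape} does not match geometry "
                f"({self.geom.pixels_y}, {self.geom.pixels_x})"
            )
        if not np.all(np.isfinite(self.heights)):
            raise InvalidSpecError("heights must be finite")

    def with_heights(self, heights: np.ndarray, *, flattened: bool | None = None,
                     provenance: str | None = None) -> "AFMImage":
        """A copy with new height data (geometry preserved)."""
        return AFMImage(
            heights=heights,
            geom=self.geom,
            flattened=self.flattened if flattened is None else flattened,
            provenance=self.provenance if provenance is None else provenance,
            seed=self.seed,
        )


def write_image(img: AFMImage, path: str | Path) -> Path:
    """Write a float32 TIFF plus JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, img.heights.astype(np.float32))
    sidecar = {
        "pixel_size_nm": img.geom.pixel_size,
        "field_nm": [img.geom.width_nm, img.geom.height_nm],
        "seed": img.seed,
        "flattened": img.flattened,
        "provenance": img.provenance,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
    )
    return path


def read_image(path: str | Path) -> AFMImage:
    """Read a height map from TIFF+sidecar or matrix text.

    TIFF requires the JSON sidecar for the pixel size.  Text files start
    with a header line ``# pixel_size_nm <value>`` followed by the matrix.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing JSON sidecar for {path}")
        try:
            meta = json.loads(sidecar_path.read_text())
            pixel_size = float(meta["pixel_size_nm"])
        except (KeyError, ValueError, json.JSONDecodeError) as exc:
            raise FormatError(f"bad sidecar {sidecar_path}: {exc}") from exc
        heights = tifffile.imread(path).astype(float)
        if heights.ndim != 2:
            raise FormatError(f"{path}: expected a single-channel 2-D image")
        geom = PixelGeometry(heights.shape[1], heights.shape[0], pixel_size)
        return AFMImage(
            heights=heights,
            geom=geom,
            flattened=bool(meta.get("flattened", False)),
            provenance=str(meta.get("provenance", str(path))),
            seed=meta.get("seed"),
        )
    return _read_matrix_text(path)


def _read_matrix_text(path: Path) -> AFMImage:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise FormatError(
            f"{path}: matrix text must start with '# pixel_size_nm <value>'"
        )
    header = lines[0].lstrip("#").split()
    if len(header) < 2 or header[0] != "pixel_size_nm":
        raise FormatError(f"{path}: bad header line {lines[0]!r}")
    try:
        pixel_size = float(header[1])
    except ValueError as exc:
        raise FormatError(f"{path}: bad pixel size {header[1]!r}") from exc
    try:
        heights = np.loadtxt(lines[1:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse matrix: {exc}") from exc
    geom = PixelGeometry(heights.shape[1], heights.shape[0], pixel_size)
    return AFMImage(heights=heights, geom=geom, provenance=str(path))


def write_matrix_text(img: AFMImage, path: str | Path) -> Path:
    """Write the plain-text matrix format understood by :func:`read_image`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_nm {img.geom.pixel_size!r}\n")
        np.savetxt(fh, img.heights, fmt="%.6f")
    return path
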