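"""Image flattening and single-particle grain detection.

The measurement chain follows standard AFM grain-analysis practice:

1. robust per-scanline polynomial flattening (particle pixels are excluded
   iteratively), followed by global plane removal, so the mica background
   sits at height zero;
2. robust background statistics (median / MAD of the sub-decile pixels);
3. segmentation of pixels above ``baseline + k * rms``, per-grain apex
   height ``h`` and equivalent-disk radius ``r`` of the connected region
   above half the apex height — exactly the two quantities the
   spherical-segment volume formula consumes.

Quality-control flags (``edge``, ``small``, ``eccentric``, ``merged``) mark
grains whose h or r would be biased; flagged grains are excluded from
volumetrics by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage import measure, morphology

from .errors import ContractError, FlatteningError, FormatError
from .image import AFMImage

TABLE_COLUMNS = ["x_nm", "y_nm", "h_nm", "r_nm", "area_nm2", "flags"]
QC_FLAGS = ("edge", "merged", "small", "eccentric")


@dataclass(frozen=True)
class DetectionConfig:
    """Grain-detection parameters.

    threshold_multiplier
        Segmentation threshold in units of background RMS above baseline.
    min_height
        Grains with apex height below this (nm) are flagged ``small``.
    min_area
        Grains covering fewer pixels than this are flagged ``small``.
    edge_margin
        Grains within this many pixels of the border are flagged ``edge``.
    max_eccentricity
        Half-height regions more elongated than this are flagged
        ``eccentric`` (an ideal cap is circular).
    merged_particle_policy
        ``"exclude"`` flags grains whose half-height region holds more than
        one regional maximum (two particles fused into one grain);
        ``"keep"`` measures them anyway.
    """

    threshold_multiplier: float = 5.0
    min_height: float = 1.0
    min_area: int = 4
    edge_margin: int = 2
    max_eccentricity: float = 0.95
    merged_particle_policy: str = "exclude"

    def __post_init__(self):
        if not self.threshold_multiplier > 0:
            raise ContractError("threshold_multiplier must be > 0")
        if self.min_area < 1:
            raise ContractError("min_area must be >= 1")
        if self.edge_margin < 0:
            raise ContractError("edge_margin must be >= 0")
        if self.merged_particle_policy not in ("exclude", "keep"):
            raise ContractError("merged_particle_policy must be 'exclude' or 'keep'")


def _robust_sd(values: np.ndarray) -> float:
    """1.4826 * median absolute deviation — SD estimate immune to outliers."""
    if values.size == 0:
        return 0.0
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def flatten_image(
    img: AFMImage, order: int = 1, *, reject_sigma: float = 3.0, max_iter: int = 5
) -> AFMImage:
    """Remove scan-line offsets and plane tilt; background median -> 0.

    Each scan line gets a polynomial of the given order fitted to its
    background pixels — pixels more than ``reject_sigma`` robust SDs above
    the current fit (particles) are excluded and the fit repeated — and
    subtracted.  A global least-squares plane over background pixels is
    then removed and the background median subtracted.
    """
    if img.flattened:
        raise ContractError("image is already flattened")
    z = img.heights.copy()
    ny, nx = z.shape
    x = np.arange(nx, dtype=float)
    for iy in range(ny):
        row = z[iy]
        mask = np.ones(nx, dtype=bool)
        fit = np.zeros(nx)
        for _ in range(max_iter):
            if mask.sum() < order + 2:
                raise FlatteningError(
                    f"scan line {iy}: too few background pixels to fit"
                )
            coef = np.polynomial.polynomial.polyfit(x[mask], row[mask], order)
            fit = np.polynomial.polynomial.polyval(x, coef)
            resid = row - fit
            sd = _robust_sd(resid[mask])
            new_mask = resid <= max(reject_sigma * sd, 1e-12)
            if new_mask.sum() < order + 2 or np.array_equal(new_mask, mask):
                break
            mask = new_mask
        z[iy] = row - fit

    # global plane over background pixels (one-sided rejection again)
    med = np.median(z)
    sd = _robust_sd(z.ravel())
    bg = z <= med + max(reject_sigma * sd, 1e-12)
    if not bg.any():
        raise FlatteningError("no background pixels left for plane removal")
    yy, xx = np.nonzero(bg)
    design = np.column_stack([np.ones(xx.size), xx, yy])
    coef, *_ = np.linalg.lstsq(design, z[bg], rcond=None)
    xg, yg = np.meshgrid(np.arange(nx), np.arange(ny))
    z -= coef[0] + coef[1] * xg + coef[2] * yg
    z -= np.median(z[bg])
    return img.with_heights(z, flattened=True, provenance=img.provenance + "|flattened")


# Order-statistic calibration for Gaussian background pixels after the top
# decile (particles) is discarded: the median of the lower 90% sits at the
# 45th percentile of the noise, norminv(0.45) = -0.12566 sigma, and the
# median one-sided deviation below it spans norminv(0.45)-norminv(0.225)
# = 0.62975 sigma.
_LOW_MEDIAN_SIGMA = 0.1256613
_ONE_SIDED_SCALE = 1.0 / 0.6297495


def estimate_background(img: AFMImage) -> tuple[float, float]:
    """Background baseline and RMS roughness of a (flattened) image.

    Robust to particles: statistics come from the pixels below the upper
    decile (adsorbed particles occupy the top of the height distribution
    on a flattened scan), with the truncation bias of that selection
    removed under a Gaussian noise model.  Returns ``(baseline, rms)`` in
    nm; an all-zero image gives ``(0, 0)``.
    """
    z = img.heights.ravel()
    low = z[z <= np.quantile(z, 0.9)]
    low_median = float(np.median(low))
    below = low_median - low[low <= low_median]
    rms = _ONE_SIDED_SCALE * float(np.median(below)) if below.size else 0.0
    baseline = low_median + _LOW_MEDIAN_SIGMA * rms
    return baseline, rms


def _half_height_region(
    z: np.ndarray, apex: tuple[int, int], level: float, bbox: tuple[int, int, int, int]
) -> np.ndarray:
    """Boolean mask of the connected region >= level that contains the apex.

    Works on a window around the grain's bounding box, growing the window
    until the region no longer touches its border (the half-height contour
    can extend beyond the segmentation threshold's footprint).
    """
    ny, nx = z.shape
    min_r, min_c, max_r, max_c = bbox
    pad = max(max_r - min_r, max_c - min_c, 4)
    while True:
        r0, c0 = max(min_r - pad, 0), max(min_c - pad, 0)
        r1, c1 = min(max_r + pad, ny), min(max_c + pad, nx)
        window = z[r0:r1, c0:c1] >= level
        labels = measure.label(window, connectivity=2)
        lab = labels[apex[0] - r0, apex[1] - c0]
        region = labels == lab
        touches = (
            region[0, :].any() or region[-1, :].any()
            or region[:, 0].any() or region[:, -1].any()
        )
        full_image = r0 == 0 and c0 == 0 and r1 == ny and c1 == nx
        if not touches or full_image:
            mask = np.zeros_like(z, dtype=bool)
            mask[r0:r1, c0:c1] = region
            return mask
        pad *= 2


def _refine_apex_height(
    z: np.ndarray,
    center: tuple[float, float],
    baseline: float,
    h0: float,
    r0: float,
    px: float,
) -> float:
    """Noise-robust apex height via a local cap-model average.

    The raw maximum over a grain's footprint rides on the upper tail of the
    pixel noise and overestimates h; a smoothed maximum instead loses the
    profile curvature.  Averaging raw pixels over the inner part of the
    half-height disk cancels the noise, and the spherical-cap model supplies the
    curvature correction: a cap of sphere radius R has profile
    z(rho) = h - R + sqrt(R^2 - rho^2), so
    h = mean(z) + mean(R - sqrt(R^2 - rho^2)), with R recovered from the
    provisional (h0, r0) measurement.  ``center`` is the sub-pixel
    particle centre (row, col), e.g. the half-height region's centroid.
    """
    sphere_radius = (r0 * r0 + h0 * h0 / 4.0) / h0
    radius_px = max(1.0, 0.7 * r0 / px)
    n = int(np.ceil(radius_px)) + 1
    ny, nx = z.shape
    icy, icx = int(round(center[0])), int(round(center[1]))
    ir0, ir1 = max(icy - n, 0), min(icy + n + 1, ny)
    ic0, ic1 = max(icx - n, 0), min(icx + n + 1, nx)
    dy = (np.arange(ir0, ir1) - center[0])[:, None]
    dx = (np.arange(ic0, ic1) - center[1])[None, :]
    rho2 = dy * dy + dx * dx
    sel = rho2 <= radius_px * radius_px
    if not sel.any():
        return h0
    mean_z = float(z[ir0:ir1, ic0:ic1][sel].mean()) - baseline
    rho2_nm2 = rho2[sel] * px * px
    sag = sphere_radius - np.sqrt(np.maximum(sphere_radius**2 - rho2_nm2, 0.0))
    return mean_z + float(sag.mean())


def detect_particles(img: AFMImage, cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """Segment and measure grains; returns a particle table.

    Columns: ``x_nm, y_nm, h_nm, r_nm, area_nm2, flags`` — ``flags`` is a
    semicolon-joined subset of ``edge;merged;small;eccentric`` (empty for
    clean particles).  ``h`` is apex height above baseline, ``r`` the
    equivalent-disk radius of the half-height region, ``area`` that
    region's area.  Requires a flattened image.
    """
    cfg = cfg or DetectionConfig()
    if not img.flattened:
        raise ContractError("detect_particles requires a flattened image")
    z = img.heights
    px = img.geom.pixel_size
    baseline, rms = estimate_background(img)
    threshold = baseline + cfg.threshold_multiplier * rms
    mask = z > threshold
    if not mask.any():
        return _empty_table()

    labels = measure.label(mask, connectivity=2)
    # regional maxima (for merged-grain detection): prominence above twice
    # the noise, computed on a lightly smoothed copy when noise is present
    noisy = rms > 1e-12
    if noisy:
        peak_img = gaussian_filter(z, 1.0)
        h_min = 2.0 * rms
    else:
        peak_img = z
        h_min = 1e-9 * max(float(z.max()) - baseline, 1.0)
    maxima = measure.label(morphology.h_maxima(peak_img, h_min), connectivity=2)

    ny, nx = z.shape
    rows = []
    for region in measure.regionprops(labels, intensity_image=z):
        flags: set[str] = set()
        r0, c0, r1, c1 = region.bbox
        # apex pixel: from the smoothed image on noisy scans so a single
        # noise spike cannot masquerade as the summit
        local = np.where(region.image, peak_img[r0:r1, c0:c1], -np.inf)
        ar, ac = np.unravel_index(np.argmax(local), local.shape)
        apex = (r0 + ar, c0 + ac)
        h = float(peak_img[apex] if noisy else z[apex]) - baseline

        if region.area < cfg.min_area or h < cfg.min_height:
            flags.add("small")
        m = cfg.edge_margin
        if r0 < m or c0 < m or r1 > ny - m or c1 > nx - m:
            flags.add("edge")

        if "small" in flags:
            # sub-threshold noise blobs: their half-height level sits inside
            # the noise floor, so the contour analysis is meaningless (and
            # can flood); record the thresholded footprint instead
            area_px = int(region.area)
            r = float(np.sqrt(area_px * px * px / np.pi))
        else:
            level = baseline + h / 2.0
            hh = _half_height_region(z, apex, level, region.bbox)
            area_px = int(hh.sum())
            r = float(np.sqrt(area_px * px * px / np.pi))
            if noisy and h > 0 and area_px >= cfg.min_area:
                hh_center = tuple(np.argwhere(hh).mean(axis=0))
                h_ref = _refine_apex_height(z, hh_center, baseline, h, r, px)
                if h_ref > 0:
                    h = h_ref
                    level = baseline + h / 2.0
                    hh = _half_height_region(z, apex, level, region.bbox)
                    area_px = int(hh.sum())
                    r = float(np.sqrt(area_px * px * px / np.pi))
            hh_props = measure.regionprops(hh.astype(np.uint8))
            if hh_props and hh_props[0].eccentricity > cfg.max_eccentricity:
                flags.add("eccentric")
            peak_labels = np.unique(maxima[hh])
            if (peak_labels > 0).sum() > 1:
                flags.add("merged")

        cy, cx = region.centroid_weighted
        rows.append(
            {
                "x_nm": cx * px,
                "y_nm": cy * px,
                "h_nm": h,
                "r_nm": r,
                "area_nm2": area_px * px * px,
                "flags": ";".join(sorted(flags)),
            }
        )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if cfg.merged_particle_policy == "keep":
        table["flags"] = [
            ";".join(f for f in fl.split(";") if f and f != "merged")
            for fl in table["flags"]
        ]
    return table


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=TABLE_COLUMNS).astype(
        {c: float for c in TABLE_COLUMNS[:-1]} | {"flags": str}
    )


def unflagged(table: pd.DataFrame) -> pd.DataFrame:
    """The subset of a particle table carrying no QC flags."""
    if table.empty:
        return table
    return table[table["flags"].fillna("") == ""].reset_index(drop=True)


def write_particle_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a particle table as CSV (column order fixed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out["flags"] = out["flags"].fillna("") if "flags" in out else ""
    out.to_csv(path, index=False, columns=TABLE_COLUMNS, float_format="%.9g")
    return path


def read_particle_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a particle-table CSV.

    Raises :class:`FormatError` naming the offending row for missing
    columns, non-numeric h/r, or non-positive h/r on unflagged rows.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"flags": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns and c != "flags"]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    if "flags" not in df.columns:
        df["flags"] = ""
    df["flags"] = df["flags"].fillna("")
    for col in ("x_nm", "y_nm", "h_nm", "r_nm", "area_nm2"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric {col} in data row {bad[0] + 1}"
            )
        df[col] = vals.astype(float)
    clean = df["flags"] == ""
    for col in ("h_nm", "r_nm"):
        bad = np.nonzero((df[col].to_numpy() <= 0) & clean.to_numpy())[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-positive {col} in data row {bad[0] + 1}"
            )
    return df[TABLE_COLUMNS]
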