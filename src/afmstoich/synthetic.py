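"""Synthetic AFM fields of spherical-cap particles with known ground truth.

Real scans of purified receptors on mica show well-separated globular
particles on an almost atomically flat background, contaminated by scan
artifacts: per-line DC offsets, an overall plane tilt and pixel roughness.
This module draws particle populations from one or two volume
subpopulations (e.g. a ~417 nm^3 free-receptor peak and a ~1174 nm^3
complex peak), renders them as spherical caps onto such a background, and
writes reproducible fixture sets (TIFF + JSON sidecar + ground-truth CSV)
so every downstream stage can be tested against exact truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry
from .errors import InvalidSpecError, PlacementError
from .image import AFMImage, PixelGeometry, write_image

GROUND_TRUTH_COLUMNS = ["x_nm", "y_nm", "h_nm", "r_nm", "volume_nm3", "component"]


@dataclass(frozen=True)
class ComponentSpec:
    """One volume subpopulation: mixture weight, truncated-normal volume
    distribution (nm^3) and the cap aspect ratio h/R of its particles."""

    weight: float
    volume_mean: float
    volume_sd: float
    aspect: float

    def __post_init__(self):
        if not self.weight > 0:
            raise InvalidSpecError(f"component weight must be > 0, got {self.weight}")
        if not self.volume_mean > 0:
            raise InvalidSpecError(f"volume_mean must be > 0, got {self.volume_mean}")
        if self.volume_sd < 0:
            raise InvalidSpecError(f"volume_sd must be >= 0, got {self.volume_sd}")
        if not (0 < self.aspect <= geometry.ASPECT_MAX):
            raise InvalidSpecError(f"aspect must lie in (0, 2], got {self.aspect}")


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of :class:`ComponentSpec` plus a particle count and seed."""

    components: tuple[ComponentSpec, ...]
    n_particles: int
    seed: int

    def __post_init__(self):
        comps = tuple(
            c if isinstance(c, ComponentSpec) else ComponentSpec(*c)
            for c in self.components
        )
        object.__setattr__(self, "components", comps)
        if not comps:
            raise InvalidSpecError("population needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(f"component weights must sum to 1, got {total}")
        if self.n_particles < 0:
            raise InvalidSpecError("n_particles must be >= 0")


@dataclass(frozen=True)
class BackgroundSpec:
    """Background artifact model: white pixel roughness, per-scanline DC
    offsets and a global plane tilt (nm of height per nm of travel)."""

    rms_roughness: float = 0.0
    line_offset_sd: float = 0.0
    plane_tilt: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if self.rms_roughness < 0 or self.line_offset_sd < 0:
            raise InvalidSpecError("noise amplitudes must be non-negative")


@dataclass(frozen=True)
class ParticleGroundTruth:
    """One simulated particle: cap dimensions and exact molecular volume."""

    center: tuple[float, float]  # (x, y) nm; NaN until placed
    sphere_radius: float  # R, nm
    apex_height: float  # h, nm
    half_height_radius: float  # r, nm
    volume: float  # Vm, nm^3
    component_index: int


def sample_particle_population(spec: PopulationSpec) -> list[ParticleGroundTruth]:
    """Draw particles from the mixture; centres are assigned at render time.

    Each particle's target volume is drawn from its component's normal
    distribution truncated at zero (non-positive draws are rejected and
    redrawn), then converted to cap dimensions (R, h, r) at the component's
    aspect ratio so that the cap's molecular volume equals the draw exactly.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    idx = rng.choice(len(weights), size=spec.n_particles, p=weights / weights.sum())
    particles: list[ParticleGroundTruth] = []
    for comp_i in idx:
        comp = spec.components[comp_i]
        volume = rng.normal(comp.volume_mean, comp.volume_sd)
        while volume <= 0.0:
            volume = rng.normal(comp.volume_mean, comp.volume_sd)
        sphere_radius, apex_height, half_r = geometry.solve_cap(volume, comp.aspect)
        particles.append(
            ParticleGroundTruth(
                center=(float("nan"), float("nan")),
                sphere_radius=sphere_radius,
                apex_height=apex_height,
                half_height_radius=half_r,
                volume=volume,
                component_index=int(comp_i),
            )
        )
    return particles


def _place_centers(
    particles: list[ParticleGroundTruth],
    geom: PixelGeometry,
    min_separation: float,
    rng: np.random.Generator,
    max_tries: int,
) -> np.ndarray:
    """Rejection-sample non-overlapping centres; PlacementError on failure."""
    centers = np.empty((len(particles), 2))
    for i, p in enumerate(particles):
        margin = geometry.base_radius(p.sphere_radius, p.apex_height) + 2 * geom.pixel_size
        lo_x, hi_x = margin, geom.width_nm - margin
        lo_y, hi_y = margin, geom.height_nm - margin
        if hi_x <= lo_x or hi_y <= lo_y:
            raise PlacementError(i, len(particles))
        for _ in range(max_tries):
            cand = rng.uniform([lo_x, lo_y], [hi_x, hi_y])
            if i == 0 or np.all(
                np.hypot(*(centers[:i] - cand).T) >= min_separation
            ):
                centers[i] = cand
                break
        else:
            raise PlacementError(i, len(particles))
    return centers


def _render_background(geom: PixelGeometry, bg: BackgroundSpec) -> np.ndarray:
    rng = np.random.default_rng(bg.seed)
    z = rng.normal(0.0, bg.rms_roughness, (geom.pixels_y, geom.pixels_x)) \
        if bg.rms_roughness > 0 else np.zeros((geom.pixels_y, geom.pixels_x))
    if bg.line_offset_sd > 0:
        z += rng.normal(0.0, bg.line_offset_sd, (geom.pixels_y, 1))
    tx, ty = bg.plane_tilt
    if tx or ty:
        x = np.arange(geom.pixels_x) * geom.pixel_size
        y = np.arange(geom.pixels_y) * geom.pixel_size
        z += tx * x[None, :] + ty * y[:, None]
    return z


def render_afm_image(
    particles: list[ParticleGroundTruth],
    geom: PixelGeometry,
    bg: BackgroundSpec | None = None,
    min_separation: float = 80.0,
    *,
    seed: int | None = None,
    tip_radius: float = 0.0,
    max_tries: int = 200,
) -> tuple[AFMImage, pd.DataFrame]:
    """Render particles onto a noisy background; returns image + placements.

    The height at a pixel is background plus the maximum over all particles
    of the cap profile (particles do not interpenetrate additively).
    Pixel centres sit at ``index * pixel_size``.  ``tip_radius > 0``
    optionally dilates the particle layer with a spherical tip, emulating
    tip convolution (broadens the apparent half-height radius; off by
    default, matching the idealised volume formula).

    Raises :class:`PlacementError` (naming the count placed) if the
    particles cannot all be placed ``min_separation`` apart.
    """
    bg = bg or BackgroundSpec()
    rng = np.random.default_rng(bg.seed + 1 if seed is None else seed)
    centers = _place_centers(particles, geom, min_separation, rng, max_tries)

    px = geom.pixel_size
    layer = np.zeros((geom.pixels_y, geom.pixels_x))
    for p, (cx, cy) in zip(particles, centers):
        extent = geometry.base_radius(p.sphere_radius, p.apex_height)
        ix_lo = max(int((cx - extent) / px) - 1, 0)
        ix_hi = min(int((cx + extent) / px) + 2, geom.pixels_x)
        iy_lo = max(int((cy - extent) / px) - 1, 0)
        iy_hi = min(int((cy + extent) / px) + 2, geom.pixels_y)
        xs = np.arange(ix_lo, ix_hi) * px - cx
        ys = np.arange(iy_lo, iy_hi) * px - cy
        rho = np.hypot(xs[None, :], ys[:, None])
        patch = geometry.cap_profile(rho, p.sphere_radius, p.apex_height)
        np.maximum(
            layer[iy_lo:iy_hi, ix_lo:ix_hi], patch, out=layer[iy_lo:iy_hi, ix_lo:ix_hi]
        )
    if tip_radius > 0.0:
        layer = _tip_dilate(layer, tip_radius, px)

    heights = _render_background(geom, bg) + layer
    placements = pd.DataFrame(
        {
            "x_nm": centers[:, 0],
            "y_nm": centers[:, 1],
            "h_nm": [p.apex_height for p in particles],
            "r_nm": [p.half_height_radius for p in particles],
            "volume_nm3": [p.volume for p in particles],
            "component": [p.component_index for p in particles],
        }
    )
    img = AFMImage(
        heights=heights,
        geom=geom,
        flattened=False,
        provenance="synthetic",
        seed=bg.seed,
    )
    return img, placements


def _tip_dilate(layer: np.ndarray, tip_radius: float, pixel_size: float) -> np.ndarray:
    """Grey-scale dilation with an (inverted) spherical tip apex."""
    from scipy.ndimage import grey_dilation

    n = int(np.ceil(tip_radius / pixel_size))
    coords = np.arange(-n, n + 1) * pixel_size
    rho2 = coords[None, :] ** 2 + coords[:, None] ** 2
    inside = rho2 <= tip_radius**2
    tip = np.full(rho2.shape, np.inf)
    tip[inside] = tip_radius - np.sqrt(tip_radius**2 - rho2[inside])
    return grey_dilation(layer, structure=-tip)


def write_fixture_set(
    directory: str | Path,
    geom: PixelGeometry,
    population: PopulationSpec,
    background: BackgroundSpec,
    n_images: int,
    *,
    min_separation: float = 80.0,
    name: str = "field",
) -> dict:
    """Write ``n_images`` reproducible scans plus ground truth and manifest.

    Per-image seeds are spawned deterministically from the population and
    background seeds, so the same call reproduces byte-identical files.
    Returns the manifest (also written as ``manifest.json``).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i in range(n_images):
        pop_i = PopulationSpec(
            components=population.components,
            n_particles=population.n_particles,
            seed=int(np.random.SeedSequence(population.seed, spawn_key=(i,)).generate_state(1)[0] % (2**31)),
        )
        bg_i = BackgroundSpec(
            rms_roughness=background.rms_roughness,
            line_offset_sd=background.line_offset_sd,
            plane_tilt=background.plane_tilt,
            seed=int(np.random.SeedSequence(background.seed, spawn_key=(i,)).generate_state(1)[0] % (2**31)),
        )
        particles = sample_particle_population(pop_i)
        img, placements = render_afm_image(
            particles, geom, bg_i, min_separation, seed=bg_i.seed + 1
        )
        stem = f"{name}_{i:03d}"
        tiff_path = write_image(img, directory / f"{stem}.tif")
        truth_path = directory / f"{stem}_truth.csv"
        placements.to_csv(truth_path, index=False, float_format="%.9g")
        entries.append(
            {
                "image": tiff_path.name,
                "sidecar": tiff_path.with_suffix(".json").name,
                "truth": truth_path.name,
                "n_particles": len(particles),
                "population_seed": pop_i.seed,
                "background_seed": bg_i.seed,
                "sha256": hashlib.sha256(tiff_path.read_bytes()).hexdigest(),
            }
        )
    manifest = {
        "n_images": n_images,
        "geometry": {
            "pixels_x": geom.pixels_x,
            "pixels_y": geom.pixels_y,
            "pixel_size_nm": geom.pixel_size,
        },
        "population": {
            "seed": population.seed,
            "n_particles": population.n_particles,
            "components": [
                {
                    "weight": c.weight,
                    "volume_mean": c.volume_mean,
                    "volume_sd": c.volume_sd,
                    "aspect": c.aspect,
                }
                for c in population.components
            ],
        },
        "background": {
            "seed": background.seed,
            "rms_roughness": background.rms_roughness,
            "line_offset_sd": background.line_offset_sd,
            "plane_tilt": list(background.plane_tilt),
        },
        "min_separation_nm": min_separation,
        "images": entries,
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest


def load_ground_truth(directory: str | Path) -> pd.DataFrame:
    """Concatenate every per-image truth table in a fixture directory,
    adding an ``image`` column with the TIFF file name."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    frames = []
    for entry in manifest["images"]:
        df = pd.read_csv(directory / entry["truth"])
        df["image"] = entry["image"]
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=GROUND_TRUTH_COLUMNS + ["image"])
    return pd.concat(frames, ignore_index=True)
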