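"""End-to-end orchestration: scans -> particles -> volumes -> peaks ->
stoichiometry -> molarity, from a single validated configuration.

A pipeline run mirrors the full single-particle AFM quantification: flatten
and detect on every input image (or load pre-measured particle tables),
compute molecular volumes, fit the volume histogram with one or two
Gaussian peaks, split the distribution at a cut-off volume, assign a
subunit composition to the largest-volume peak against reference receptor
volumes, and convert windowed particle counts to sample molarity.  With a
fixed seed the report is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import concentration as conc
from . import detect, image, stoichiometry, synthetic, volumetrics
from .errors import ConfigError, PipelineError

log = logging.getLogger("afmstoich")

REPORT_SCHEMA_VERSION = 1

DEFAULT_REFERENCES = (
    {"name": "P2X4", "volume": 417.0, "uncertainty": 0.0},
    {"name": "5HT3A", "volume": 757.0, "uncertainty": 0.0},
)


@dataclass(frozen=True)
class SimulateConfig:
    """Synthetic-input block: renders images instead of loading them."""

    n_images: int
    particles_per_image: int
    components: tuple[dict, ...]
    pixels_x: int = 1024
    pixels_y: int = 1024
    pixel_size: float = 2000.0 / 1024
    rms_roughness: float = 0.3
    line_offset_sd: float = 1.0
    plane_tilt: tuple[float, float] = (0.005, 0.005)
    min_separation: float = 80.0


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Exactly one of ``images`` (TIFF/matrix paths), ``tables`` (particle
    CSV paths) or ``simulate`` must be given.
    """

    images: tuple[str, ...] | None = None
    tables: tuple[str, ...] | None = None
    simulate: SimulateConfig | None = None
    detection: detect.DetectionConfig = field(default_factory=detect.DetectionConfig)
    bin_width: float = 50.0
    k: int = 2
    cutoff: float = 800.0
    references: tuple[stoichiometry.ReferenceComponent, ...] = ()
    max_counts: int = 3
    tolerance_z: float = 3.0
    packing_loss: float = 0.0
    windows: tuple[conc.CountingWindow, ...] = ()
    total_mica_area_um2: float = 1e7
    elution_volume_ul: float = 50.0
    scanned_area_um2: float | None = None  # required with `tables` input
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        sources = [s is not None for s in (self.images, self.tables, self.simulate)]
        if sum(sources) != 1:
            raise ConfigError(
                "exactly one input source required: images, tables or simulate"
            )
        for group in (self.images, self.tables):
            for p in group or ():
                if not Path(p).exists():
                    raise ConfigError(f"input path does not exist: {p}")
        if self.tables is not None and self.scanned_area_um2 is None:
            raise ConfigError(
                "scanned_area_um2 is required when input is particle tables"
            )
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        if self.k not in (1, 2):
            raise ConfigError("k must be 1 or 2")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        if not self.references:
            raise ConfigError("at least one reference component is required")


_SIMULATE_KEYS = {f.name for f in dataclasses.fields(SimulateConfig)}
_DETECT_KEYS = {f.name for f in dataclasses.fields(detect.DetectionConfig)}
_TOP_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build and validate a :class:`PipelineConfig` from plain data
    (e.g. parsed YAML).  Unknown keys are rejected with their name."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    kw = dict(raw)
    if kw.get("simulate") is not None:
        sim = kw["simulate"]
        bad = set(sim) - _SIMULATE_KEYS
        if bad:
            raise ConfigError(f"unknown simulate keys: {sorted(bad)}")
        sim = dict(sim)
        sim["components"] = tuple(dict(c) for c in sim.get("components", ()))
        if "plane_tilt" in sim:
            sim["plane_tilt"] = tuple(sim["plane_tilt"])
        kw["simulate"] = SimulateConfig(**sim)
    if kw.get("detection") is not None:
        det = kw["detection"]
        bad = set(det) - _DETECT_KEYS
        if bad:
            raise ConfigError(f"unknown detection keys: {sorted(bad)}")
        kw["detection"] = detect.DetectionConfig(**det)
    refs = kw.get("references") or [dict(r) for r in DEFAULT_REFERENCES]
    kw["references"] = tuple(
        stoichiometry.ReferenceComponent(
            name=str(r["name"]),
            volume=float(r["volume"]),
            volume_uncertainty=float(r.get("uncertainty", 0.0)),
        )
        for r in refs
    )
    kw["windows"] = tuple(
        conc.CountingWindow(float(w["lo"]), float(w["hi"]), str(w.get("species", "")))
        for w in kw.get("windows") or ()
    )
    for key in ("images", "tables"):
        if kw.get(key) is not None:
            kw[key] = tuple(str(p) for p in kw[key])
    try:
        return PipelineConfig(**kw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw or {})


def _stage(report: dict, name: str, fn, output_dir: Path | None):
    log.info("stage %s: start", name)
    try:
        result = fn()
    except Exception as exc:  # noqa: BLE001 — rewrapped with the stage name
        if output_dir is not None:
            _write_report(report, output_dir, partial=True)
        raise PipelineError(name, exc) from exc
    log.info("stage %s: done", name)
    return result


def _write_report(report: dict, output_dir: Path, partial: bool = False) -> Path:
    output_dir.mkdir(parents=True, exist_ok=True)
    name = "report.partial.json" if partial else "report.json"
    path = output_dir / name
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path


def _acquire_particles(cfg: PipelineConfig, report: dict, output_dir: Path | None):
    """Stage 1+2: obtain a particle table and the total scanned area."""
    import pandas as pd

    if cfg.tables is not None:
        frames = [detect.read_particle_table(p) for p in cfg.tables]
        table = pd.concat(frames, ignore_index=True)
        return table, float(cfg.scanned_area_um2)

    if cfg.simulate is not None:
        sim = cfg.simulate
        geom = image.PixelGeometry(sim.pixels_x, sim.pixels_y, sim.pixel_size)
        comps = tuple(
            synthetic.ComponentSpec(
                weight=float(c["weight"]),
                volume_mean=float(c["volume_mean"]),
                volume_sd=float(c["volume_sd"]),
                aspect=float(c["aspect"]),
            )
            for c in sim.components
        )
        images = []
        for i in range(sim.n_images):
            pop = synthetic.PopulationSpec(
                components=comps,
                n_particles=sim.particles_per_image,
                seed=int(
                    np.random.SeedSequence(cfg.seed, spawn_key=(i, 0)).generate_state(1)[0]
                    % (2**31)
                ),
            )
            bg = synthetic.BackgroundSpec(
                rms_roughness=sim.rms_roughness,
                line_offset_sd=sim.line_offset_sd,
                plane_tilt=sim.plane_tilt,
                seed=int(
                    np.random.SeedSequence(cfg.seed, spawn_key=(i, 1)).generate_state(1)[0]
                    % (2**31)
                ),
            )
            particles = synthetic.sample_particle_population(pop)
            img, _ = synthetic.render_afm_image(
                particles, geom, bg, sim.min_separation
            )
            images.append(img)
        scanned = sim.n_images * geom.area_um2
    else:
        images = [image.read_image(p) for p in cfg.images]
        scanned = sum(im.geom.area_um2 for im in images)

    frames = []
    for i, img in enumerate(images):
        flat = img if img.flattened else detect.flatten_image(img)
        tbl = detect.detect_particles(flat, cfg.detection)
        tbl["image"] = i
        frames.append(tbl)
        log.info(
            "image %d: %d grains (%d unflagged)",
            i, len(tbl), len(detect.unflagged(tbl)),
        )
    table = pd.concat(frames, ignore_index=True) if frames else detect._empty_table()
    return table, float(scanned)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return (and optionally write) the report.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    stages completed so far are preserved in ``report.partial.json`` when
    an output directory is configured.
    """
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    report: dict = {
        "software": {"name": "afmstoich", "version": __version__},
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": _echo_config(cfg),
        "stages": {},
    }
    stages = report["stages"]

    table, scanned_area = _stage(
        report, "detect", lambda: _acquire_particles(cfg, report, out_dir), out_dir
    )
    n_unflagged = len(detect.unflagged(table))
    stages["detect"] = {
        "n_particles": int(len(table)),
        "n_unflagged": int(n_unflagged),
        "n_flagged": int(len(table) - n_unflagged),
        "scanned_area_um2": scanned_area,
    }
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        detect.write_particle_table(table, out_dir / "particles.csv")

    volumes = _stage(
        report, "volumes", lambda: volumetrics.volumes_from_table(table), out_dir
    )
    stages["volumes"] = {"n": int(len(volumes))}

    hist = _stage(
        report,
        "histogram",
        lambda: volumetrics.build_histogram(volumes.to_numpy(), cfg.bin_width),
        out_dir,
    )
    stages["histogram"] = {
        "bin_width_nm3": hist.bin_width,
        "n_bins": int(len(hist.counts)),
        "n_total": hist.n_total,
    }
    if out_dir is not None:
        hist.to_frame().to_csv(out_dir / "histogram.csv", index=False)

    fit = _stage(
        report, "fit", lambda: volumetrics.fit_gaussian_mixture(hist, cfg.k), out_dir
    )
    stages["fit"] = fit.to_dict()
    stages["fit"]["model_selection_advisory"] = volumetrics.model_selection_advisory(hist)

    props = _stage(
        report,
        "proportions",
        lambda: {
            "fit_area": volumetrics.component_proportions(
                fit, cfg.cutoff, "fit_area"
            ).to_dict(),
            "raw_count": volumetrics.component_proportions(
                None, cfg.cutoff, "raw_count", volumes=volumes.to_numpy()
            ).to_dict(),
        },
        out_dir,
    )
    stages["proportions"] = props

    def _assign():
        peak = fit.components[-1]  # largest-volume peak: the candidate complex
        se = fit.mean_se[-1]
        ranked = stoichiometry.assign_stoichiometry(
            peak.mean, se, cfg.references, cfg.max_counts, cfg.tolerance_z,
            cfg.packing_loss,
        )
        return {
            "peak_mean_nm3": peak.mean,
            "peak_se_nm3": se,
            "references": [
                {"name": r.name, "volume_nm3": r.volume,
                 "uncertainty_nm3": r.volume_uncertainty}
                for r in cfg.references
            ],
            "top": ranked[0].to_dict() | {"label": ranked[0].label(cfg.references)},
            "ranking": [a.to_dict() for a in ranked[:5]],
        }

    stages["stoichiometry"] = _stage(report, "stoichiometry", _assign, out_dir)

    def _concentration():
        out = []
        vols = volumes.to_numpy()
        per_image_area = scanned_area / max(
            int(table["image"].max()) + 1 if "image" in table and len(table) else 1, 1
        )
        for window in cfg.windows or _default_windows(fit):
            est = conc.estimate_concentration(
                vols, window, scanned_area,
                cfg.total_mica_area_um2, cfg.elution_volume_ul,
            )
            entry = {"window": {"lo_nm3": window.lo, "hi_nm3": window.hi,
                                "species": window.species}}
            entry.update(est.to_dict())
            if "image" in table.columns and table["image"].nunique() >= 2:
                reps = []
                for _, group in table.groupby("image"):
                    gv = volumetrics.volumes_from_table(group).to_numpy()
                    reps.append(
                        conc.estimate_molarity(
                            conc.count_density(gv, window, per_image_area),
                            cfg.total_mica_area_um2, cfg.elution_volume_ul,
                        )
                    )
                mean, se = conc.aggregate_series(reps)
                entry["replicates"] = {
                    "n": len(reps), "molarity_mean_M": mean, "molarity_se_M": se,
                    "molarity_mean_pM": mean * 1e12, "molarity_se_pM": se * 1e12,
                }
            out.append(entry)
        return out

    stages["concentration"] = _stage(report, "concentration", _concentration, out_dir)

    if out_dir is not None:
        report["outputs"] = {
            "particles": "particles.csv",
            "histogram": "histogram.csv",
            "report": "report.json",
        }
        _write_report(report, out_dir)
    return report


def _default_windows(fit: volumetrics.MixtureFit) -> tuple[conc.CountingWindow, ...]:
    """One counting window per fitted peak: mean +/- one fitted sigma."""
    return tuple(
        conc.CountingWindow(
            max(c.mean - c.sigma, 1e-9), c.mean + c.sigma, f"peak{i}"
        )
        for i, c in enumerate(fit.components)
    )


def _echo_config(cfg: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    echo = convert(cfg)
    # the output location does not affect the computation; omitting it keeps
    # reports byte-identical across reruns into different directories
    echo.pop("output_dir", None)
    return echo


DEMO_CONFIG: dict = {
    "simulate": {
        "n_images": 6,
        "particles_per_image": 60,
        "pixels_x": 512,
        "pixels_y": 512,
        "pixel_size": 2000.0 / 512,
        "components": [
            {"weight": 0.58, "volume_mean": 417.0, "volume_sd": 60.0,
             "aspect": 0.1026},
            {"weight": 0.42, "volume_mean": 1174.0, "volume_sd": 120.0,
             "aspect": 0.1026},
        ],
    },
    "k": 2,
    "bin_width": 50.0,
    "cutoff": 800.0,
    "references": [dict(r) for r in DEFAULT_REFERENCES],
    "windows": [
        {"lo": 403, "hi": 431, "species": "P2X4"},
        {"lo": 991, "hi": 1209, "species": "P2X4/5HT3A"},
    ],
    "total_mica_area_um2": 1e7,
    "elution_volume_ul": 50.0,
}


def make_demo(seed: int, directory: str | Path) -> tuple[Path, dict]:
    """Write the demo configuration and its expected report.

    Simulates a small two-population receptor preparation, runs the full
    pipeline into ``directory`` and stores the configuration
    (``config.yaml``) beside the outputs.  Reruns with the same seed
    reproduce ``report.json`` byte-for-byte.  Returns the config path and
    the report.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw = json.loads(json.dumps(DEMO_CONFIG))  # deep copy
    raw["seed"] = int(seed)
    raw["output_dir"] = str(directory)
    config_path = directory / "config.yaml"
    config_path.write_text(yaml.safe_dump(raw, sort_keys=True))
    cfg = config_from_dict(raw)
    report = run_pipeline(cfg)
    return config_path, report
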