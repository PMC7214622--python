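"""Synthetic-field generator: populations, rendering, fixture sets."""

import json

import numpy as np
import pytest
from skimage import measure

from afmstoich import (
    AFMImage,
    BackgroundSpec,
    ComponentSpec,
    PixelGeometry,
    PlacementError,
    PopulationSpec,
    render_afm_image,
    sample_particle_population,
)
from afmstoich import geometry as geo
from afmstoich.errors import InvalidSpecError
from afmstoich.synthetic import write_fixture_set
from afmstoich.volumetrics import particle_volume

from conftest import DEFAULT_ASPECT


class TestSamplePopulation:
    def test_single_monomer_particle_has_reference_dimensions(self):
        aspect = geo.aspect_for_height(417.0, 3.0)
        spec = PopulationSpec((ComponentSpec(1.0, 417.0, 0.0, aspect),), 1, seed=0)
        (p,) = sample_particle_population(spec)
        assert p.volume == pytest.approx(417.0)
        assert p.apex_height == pytest.approx(3.0, rel=1e-9)
        assert p.half_height_radius == pytest.approx(9.246, abs=1e-3)

    def test_zero_particles_gives_empty_list(self):
        spec = PopulationSpec(
            (ComponentSpec(1.0, 417.0, 60.0, DEFAULT_ASPECT),), 0, seed=0
        )
        assert sample_particle_population(spec) == []

    def test_equal_weights_split_binomially(self):
        n = 10_000
        spec = PopulationSpec(
            (
                ComponentSpec(0.5, 417.0, 60.0, DEFAULT_ASPECT),
                ComponentSpec(0.5, 1174.0, 120.0, DEFAULT_ASPECT),
            ),
            n,
            seed=5,
        )
        counts = np.bincount(
            [p.component_index for p in sample_particle_population(spec)], minlength=2
        )
        # 3-sigma binomial bound around n/2
        bound = 3 * np.sqrt(n * 0.25)
        assert abs(counts[0] - n / 2) < bound

    def test_stored_volume_matches_volume_formula(self):
        spec = PopulationSpec(
            (
                ComponentSpec(0.5, 417.0, 60.0, DEFAULT_ASPECT),
                ComponentSpec(0.5, 1174.0, 120.0, 0.3),
            ),
            500,
            seed=9,
        )
        for p in sample_particle_population(spec):
            recomputed = particle_volume(p.apex_height, p.half_height_radius)
            assert recomputed == pytest.approx(p.volume, rel=1e-9)
            assert p.volume > 0

    def test_same_seed_reproduces_population(self):
        spec = PopulationSpec(
            (ComponentSpec(1.0, 417.0, 60.0, DEFAULT_ASPECT),), 50, seed=3
        )
        a = sample_particle_population(spec)
        b = sample_particle_population(spec)
        key = lambda p: (p.sphere_radius, p.apex_height, p.half_height_radius,
                         p.volume, p.component_index)
        assert [key(p) for p in a] == [key(p) for p in b]

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidSpecError):
            PopulationSpec(
                (
                    ComponentSpec(0.6, 417.0, 60.0, DEFAULT_ASPECT),
                    ComponentSpec(0.6, 1174.0, 120.0, DEFAULT_ASPECT),
                ),
                10,
                seed=0,
            )


class TestRender:
    geom = PixelGeometry(256, 256, 4.0)

    def test_empty_field_is_all_zero(self):
        img, placements = render_afm_image([], self.geom, BackgroundSpec(), 50.0)
        assert np.all(img.heights == 0.0)
        assert placements.empty

    def test_single_particle_peak_height_within_pixel_curvature(self):
        aspect = geo.aspect_for_height(800.0, 5.0)
        spec = PopulationSpec((ComponentSpec(1.0, 800.0, 0.0, aspect),), 1, seed=2)
        particles = sample_particle_population(spec)
        img, _ = render_afm_image(particles, self.geom, BackgroundSpec(seed=7), 50.0)
        # apex may fall between pixel centres: loss bounded by the profile
        # curvature over half a pixel diagonal
        R = particles[0].sphere_radius
        eps = (self.geom.pixel_size * np.sqrt(2) / 2) ** 2 / (2 * R) + 1e-9
        assert 5.0 - eps <= img.heights.max() <= 5.0 + 1e-9

    def test_particles_render_as_disjoint_blobs_at_min_separation(self):
        spec = PopulationSpec(
            (ComponentSpec(1.0, 600.0, 50.0, DEFAULT_ASPECT),), 10, seed=4
        )
        particles = sample_particle_population(spec)
        geom = PixelGeometry(500, 500, 4.0)  # 2000 nm field
        img, placements = render_afm_image(
            particles, geom, BackgroundSpec(seed=1), min_separation=100.0
        )
        assert len(placements) == 10
        level = min(p.apex_height for p in particles) / 2.0
        labels = measure.label(img.heights > level, connectivity=2)
        assert labels.max() == 10
        # realized centres honour the separation
        xy = placements[["x_nm", "y_nm"]].to_numpy()
        d = np.hypot(*(xy[:, None, :] - xy[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 100.0

    def test_rendered_profile_crosses_half_height_at_r(self):
        aspect = geo.aspect_for_height(1174.0, 4.24)
        spec = PopulationSpec((ComponentSpec(1.0, 1174.0, 0.0, aspect),), 1, seed=6)
        particles = sample_particle_population(spec)
        geom = PixelGeometry(256, 256, 2.0)
        img, placements = render_afm_image(particles, geom, BackgroundSpec(), 50.0)
        p = particles[0]
        cx, cy = placements.loc[0, ["x_nm", "y_nm"]]
        iy = int(round(cy / geom.pixel_size))
        row = img.heights[iy]
        x = np.arange(geom.pixels_x) * geom.pixel_size
        above = np.nonzero(row >= p.apex_height / 2.0)[0]
        # crossing radius on each side of the apex, to within half a pixel
        # plus the offset of the sampled row from the true centre
        slack = geom.pixel_size / 2 + abs(cy - iy * geom.pixel_size) + 1e-9
        left = cx - x[above[0] - 1 : above[0] + 1].mean()
        right = x[above[-1] : above[-1] + 2].mean() - cx
        assert abs(left - p.half_height_radius) <= slack
        assert abs(right - p.half_height_radius) <= slack

    def test_unplaceable_request_raises_with_count(self):
        spec = PopulationSpec(
            (ComponentSpec(1.0, 600.0, 0.0, DEFAULT_ASPECT),), 50, seed=1
        )
        particles = sample_particle_population(spec)
        small = PixelGeometry(64, 64, 2.0)  # 128 nm field cannot hold 50
        with pytest.raises(PlacementError) as err:
            render_afm_image(particles, small, BackgroundSpec(), min_separation=60.0)
        assert err.value.placed < 50

    def test_tip_dilation_broadens_but_preserves_height(self):
        aspect = geo.aspect_for_height(800.0, 5.0)
        spec = PopulationSpec((ComponentSpec(1.0, 800.0, 0.0, aspect),), 1, seed=2)
        particles = sample_particle_population(spec)
        img0, _ = render_afm_image(particles, self.geom, BackgroundSpec(), 50.0)
        img1, _ = render_afm_image(
            particles, self.geom, BackgroundSpec(), 50.0, tip_radius=10.0
        )
        level = particles[0].apex_height / 2
        assert (img1.heights > level).sum() > (img0.heights > level).sum()
        assert img1.heights.max() == pytest.approx(img0.heights.max(), abs=1e-9)


class TestFixtureSet:
    geom = PixelGeometry(64, 64, 4.0)
    population = PopulationSpec(
        (ComponentSpec(1.0, 417.0, 40.0, DEFAULT_ASPECT),), 3, seed=21
    )
    background = BackgroundSpec(0.2, 0.5, (0.001, 0.0), seed=22)

    def test_rerun_is_byte_identical(self, tmp_path):
        m1 = write_fixture_set(
            tmp_path / "a", self.geom, self.population, self.background, 3,
            min_separation=40.0,
        )
        m2 = write_fixture_set(
            tmp_path / "b", self.geom, self.population, self.background, 3,
            min_separation=40.0,
        )
        assert m1["images"] == m2["images"]  # includes per-file sha256
        for e1 in m1["images"]:
            a = (tmp_path / "a" / e1["image"]).read_bytes()
            b = (tmp_path / "b" / e1["image"]).read_bytes()
            assert a == b

    def test_manifest_lists_every_image(self, tmp_path):
        manifest = write_fixture_set(
            tmp_path / "set", self.geom, self.population, self.background, 4,
            min_separation=40.0,
        )
        assert manifest["n_images"] == 4
        assert len(manifest["images"]) == 4
        for entry in manifest["images"]:
            assert (tmp_path / "set" / entry["image"]).exists()
            assert (tmp_path / "set" / entry["truth"]).exists()
        on_disk = json.loads((tmp_path / "set" / "manifest.json").read_text())
        assert on_disk == manifest

    def test_empty_set_allowed(self, tmp_path):
        manifest = write_fixture_set(
            tmp_path / "none", self.geom, self.population, self.background, 0
        )
        assert manifest["images"] == []
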