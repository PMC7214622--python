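"""Volume formula, histograms, Gaussian-mixture fits, proportions, z-tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import kstest

from afmstoich import volumetrics as vol
from afmstoich.errors import ContractError, DegenerateFitError


def segment_volume_oracle(h: float, r: float) -> float:
    """Independent evaluation of the spherical-segment volume.

    Algebraically expanded form pi*h*r^2/2 + pi*h^3/6, computed with plain
    ``math`` scalar arithmetic.
    """
    return math.pi * h * r * r / 2.0 + math.pi * h**3 / 6.0


class TestParticleVolume:
    def test_zero_height_particle_has_zero_volume(self):
        assert vol.particle_volume(0.0, 5.0) == 0.0

    def test_hand_computed_value(self):
        # (10*pi/6) * (300 + 100)
        assert vol.particle_volume(10.0, 10.0) == pytest.approx(2094.3951, abs=1e-4)

    def test_reference_monomer_volume(self):
        assert vol.particle_volume(3.0, 9.246) == pytest.approx(417.0, abs=0.1)

    def test_negative_input_rejected(self):
        with pytest.raises(ContractError):
            vol.particle_volume(-1.0, 5.0)
        with pytest.raises(ContractError):
            vol.particle_volume(1.0, -5.0)

    @given(h=st.floats(0.0, 100.0), r=st.floats(0.0, 100.0))
    def test_matches_independent_oracle(self, h, r):
        expected = segment_volume_oracle(h, r)
        assert vol.particle_volume(h, r) == pytest.approx(
            expected, rel=1e-12, abs=1e-12
        )

    @given(
        h=st.floats(0.1, 50.0),
        r=st.floats(0.1, 50.0),
        bump=st.floats(1e-3, 10.0),
    )
    def test_strictly_increasing_in_each_argument(self, h, r, bump):
        base = vol.particle_volume(h, r)
        assert vol.particle_volume(h + bump, r) > base
        assert vol.particle_volume(h, r + bump) > base


class TestVolumesFromTable:
    def _table(self, n_flagged):
        n = 10
        return pd.DataFrame(
            {
                "x_nm": np.arange(n, dtype=float),
                "y_nm": np.arange(n, dtype=float),
                "h_nm": np.full(n, 3.0),
                "r_nm": np.full(n, 9.246),
                "area_nm2": np.full(n, 268.6),
                "flags": ["edge"] * n_flagged + [""] * (n - n_flagged),
            }
        )

    def test_counts_unflagged_only_by_default(self):
        assert len(vol.volumes_from_table(self._table(0))) == 10
        assert len(vol.volumes_from_table(self._table(3))) == 7
        assert len(vol.volumes_from_table(self._table(3), include_flagged=True)) == 10

    def test_empty_table_gives_empty_series(self):
        empty = self._table(0).iloc[0:0]
        assert vol.volumes_from_table(empty).empty


class TestHistogram:
    def test_hand_binned_example(self):
        hist = vol.build_histogram([100.0, 150.0, 450.0], 100.0, (0.0, 500.0))
        assert list(hist.counts) == [0, 2, 0, 0, 1]
        assert hist.n_total == 3

    @given(
        st.lists(st.floats(1.0, 5000.0), min_size=1, max_size=200),
        st.sampled_from([10.0, 50.0, 130.0]),
    )
    def test_counts_conserve_n(self, volumes, width):
        hist = vol.build_histogram(volumes, width)
        assert hist.counts.sum() == len(volumes)
        assert np.all(np.diff(hist.bin_edges) > 0)

    def test_interior_edge_goes_to_upper_bin(self):
        hist = vol.build_histogram([100.0], 100.0, (0.0, 500.0))
        assert list(hist.counts) == [0, 1, 0, 0, 0]

    def test_empty_input_rejected(self):
        with pytest.raises(ContractError):
            vol.build_histogram([], 50.0)


class TestMixtureFit:
    def test_single_gaussian_mean_within_three_se(self, rng):
        v = rng.normal(500.0, 50.0, 2000)
        fit = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 1)
        assert fit.converged
        assert abs(fit.components[0].mean - 500.0) < 3 * fit.mean_se[0]

    def test_two_component_recovery(self, rng):
        v = np.concatenate(
            [rng.normal(417.0, 60.0, 1000), rng.normal(1174.0, 120.0, 1000)]
        )
        fit = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 2)
        assert fit.components[0].mean == pytest.approx(417.0, rel=0.05)
        assert fit.components[1].mean == pytest.approx(1174.0, rel=0.05)
        assert fit.r_squared >= 0.9
        assert fit.components[0].mean < fit.components[1].mean

    def test_too_few_bins_rejected(self):
        hist = vol.build_histogram([100.0, 420.0], 400.0)
        with pytest.raises(ContractError):
            vol.fit_gaussian_mixture(hist, 2)

    def test_collapsed_sigma_raises_degenerate(self, rng):
        # a spike far narrower than the bins, plus sparse outliers so the
        # non-empty-bin precondition is met
        v = np.concatenate(
            [rng.normal(525.0, 4.0, 500), [125.0, 225.0, 325.0, 725.0, 825.0]]
        )
        hist = vol.build_histogram(v, 50.0, (0.0, 1000.0))
        with pytest.raises(DegenerateFitError):
            vol.fit_gaussian_mixture(hist, 1)

    def test_recovery_improves_with_sample_size(self):
        """Mean recovery error shrinks with n; at n=500 and 4-sigma
        separation both means land within 10%."""
        sigma = 80.0
        errors = {n: [] for n in (200, 500, 2000)}
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            for n in errors:
                for sep in (2.0, 4.0, 6.0):
                    mu1, mu2 = 600.0, 600.0 + sep * sigma
                    v = np.concatenate(
                        [rng.normal(mu1, sigma, n // 2), rng.normal(mu2, sigma, n - n // 2)]
                    )
                    try:
                        fit = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 2)
                    except Exception:
                        errors[n].append(1.0)  # failed fit counts as full miss
                        continue
                    err = max(
                        abs(fit.components[0].mean - mu1) / mu1,
                        abs(fit.components[1].mean - mu2) / mu2,
                    )
                    errors[n].append(err)
                    if n == 500 and sep == 4.0:
                        assert err < 0.10
        assert np.mean(errors[2000]) < np.mean(errors[200])

    def test_advisory_prefers_two_peaks_on_bimodal_data(self, rng):
        v = np.concatenate(
            [rng.normal(417.0, 60.0, 800), rng.normal(1174.0, 120.0, 800)]
        )
        advisory = vol.model_selection_advisory(vol.build_histogram(v, 50.0))
        assert advisory["preferred_by_bic"] == "k=2"


class TestProportions:
    def _fit(self, components, ses=None):
        comps = tuple(vol.GaussianComponent(*c) for c in components)
        return vol.MixtureFit(
            k=len(comps),
            components=comps,
            mean_se=tuple(ses or [1.0] * len(comps)),
            r_squared=0.99,
            converged=True,
            fit_range=(0.0, 2000.0),
            n_total=1000,
            bin_width=50.0,
        )

    def test_mirrored_components_split_evenly(self):
        fit = self._fit([(10.0, 600.0, 50.0), (10.0, 1000.0, 50.0)])
        res = vol.component_proportions(fit, 800.0)
        assert res.fraction_above == pytest.approx(0.5, abs=1e-9)
        assert res.fraction_below + res.fraction_above == pytest.approx(1.0)

    def test_component_far_below_cutoff_contributes_nothing(self):
        fit = self._fit([(10.0, 400.0, 50.0)])
        res = vol.component_proportions(fit, 800.0)  # mu + 6 sigma < cutoff
        assert res.fraction_above < 1e-8

    def test_42_percent_mixture_recovered_by_both_methods(self, rng):
        n = 2000
        n_hi = int(0.42 * n)
        v = np.concatenate(
            [rng.normal(417.0, 60.0, n - n_hi), rng.normal(1174.0, 120.0, n_hi)]
        )
        mc_se = math.sqrt(0.42 * 0.58 / n)
        fit = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 2)
        for res in (
            vol.component_proportions(fit, 800.0),
            vol.component_proportions(None, 800.0, "raw_count", volumes=v),
        ):
            assert abs(res.fraction_above - 0.42) < 3 * mc_se

    def test_methods_agree_on_well_specified_mixture(self, rng):
        v = np.concatenate(
            [rng.normal(417.0, 60.0, 1200), rng.normal(1174.0, 120.0, 800)]
        )
        fit = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 2)
        a = vol.component_proportions(fit, 800.0).fraction_above
        b = vol.component_proportions(None, 800.0, "raw_count", volumes=v).fraction_above
        assert abs(a - b) < 3 * math.sqrt(0.4 * 0.6 / len(v))

    def test_cutoff_outside_range_flagged_not_rejected(self):
        fit = self._fit([(10.0, 600.0, 50.0)])
        res = vol.component_proportions(fit, 5000.0)
        assert res.cutoff_outside_range


class TestComparePeaks:
    def test_identical_fits_give_null_shift(self, rng):
        v = rng.normal(500.0, 50.0, 1000)
        fit = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 1)
        (res,) = vol.compare_peaks(fit, fit)
        assert res["z"] == 0.0
        assert res["p_value"] == pytest.approx(1.0)

    def test_reported_peak_pair_is_not_significant(self):
        # free-receptor peak before vs after agonist: 489 +/- 24 vs 505 +/- 15
        z, p = vol.peak_z(489.0, 24.0, 505.0, 15.0)
        assert abs(z) == pytest.approx(0.565, abs=0.001)
        assert p > 0.05

    def test_mismatched_component_counts_rejected(self, rng):
        v = rng.normal(500.0, 50.0, 1000)
        w = np.concatenate([v, rng.normal(1200.0, 100.0, 1000)])
        f1 = vol.fit_gaussian_mixture(vol.build_histogram(v, 50.0), 1)
        f2 = vol.fit_gaussian_mixture(vol.build_histogram(w, 50.0), 2)
        with pytest.raises(ContractError):
            vol.compare_peaks(f1, f2)

    def test_p_values_uniform_under_null(self):
        """Fits of independent draws from one population give uniform p."""
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(120):
            fits = [
                vol.fit_gaussian_mixture(
                    vol.build_histogram(rng.normal(500.0, 60.0, 400), 30.0), 1
                )
                for _ in range(2)
            ]
            ps.append(vol.compare_peaks(fits[0], fits[1])[0]["p_value"])
        assert kstest(np.array(ps), "uniform").pvalue > 0.01
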