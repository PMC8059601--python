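import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pyrodiv import (
    FireRecordSet,
    GridSpec,
    Raster,
    build_trait_stack,
    delineate_patches,
    fri_trait,
    recency_weights,
    season_trait,
    severity_trait,
)

from conftest import square_event


class TestRecencyWeights:
    @pytest.mark.parametrize(
        "n, decay, expected",
        [
            (3, 0.5, [4 / 7, 2 / 7, 1 / 7]),
            (4, 0.0, [0.25, 0.25, 0.25, 0.25]),
            (3, 1.0, [1.0, 0.0, 0.0]),
            (1, 0.5, [1.0]),
        ],
    )
    def test_known_weights(self, n, decay, expected):
        assert recency_weights(n, decay) == pytest.approx(expected)

    @given(
        n=st.integers(min_value=1, max_value=25),
        decay=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_weights_normalized_and_geometric(self, n, decay):
        w = recency_weights(n, decay)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(w) <= 1e-15)  # non-increasing with age
        for k in range(n - 1):
            if w[k] > 0:
                assert w[k + 1] / w[k] == pytest.approx(1.0 - decay, abs=1e-12)

    def test_invalid_decay_rejected(self):
        with pytest.raises(ValueError):
            recency_weights(3, 1.5)
        with pytest.raises(ValueError):
            recency_weights(0, 0.5)


class TestFriTrait:
    def test_two_burns_default_decay(self):
        # intervals most-recent-first: 18, 10, 5 with weights 4/7, 2/7, 1/7
        assert fri_trait([1990, 2000], 1985, 2018, 0.5) == 14

    def test_most_recent_only(self):
        assert fri_trait([2000], 1985, 2018, 1.0) == 18

    def test_equal_weights_round_half_even(self):
        # intervals 18 and 15 -> mean 16.5 -> 16 under round-half-even
        assert fri_trait([2000], 1985, 2018, 0.0) == 16

    def test_burn_outside_window_rejected(self):
        with pytest.raises(ValueError):
            fri_trait([1980], 1985, 2018, 0.5)


class TestSeasonTrait:
    def test_january_first(self):
        assert season_trait([1], 0.5) == pytest.approx(1.0)

    def test_leap_day_wraps_to_new_year(self):
        assert season_trait([366], 0.5) == pytest.approx(1.0)

    def test_opposed_days_cancel(self):
        assert season_trait([1, 183], 0.0) == pytest.approx(0.0, abs=1e-9)


class TestSeverityTrait:
    def test_saturated_input(self):
        assert severity_trait([3.0], 0.5) == 3.0

    def test_weighted_mean_rounds_to_half(self):
        # (2*2 + 1*1)/3 = 1.667 -> 1.5 on the 0.5 lattice
        assert severity_trait([2.0, 1.0], 0.5) == 1.5

    def test_constant_input_any_decay(self):
        for decay in (0.0, 0.3, 1.0):
            assert severity_trait([1.0, 1.0, 1.0], decay) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            severity_trait([3.5], 0.5)


class TestDelineatePatches:
    def grid(self, n=5, cell=30.0):
        return GridSpec(x_min=0, y_max=n * cell, cell_size=cell, nrows=n, ncols=n)

    def test_diagonal_blocks_connect(self):
        # two high-severity blocks touching only diagonally: 8-connectivity
        # merges them into one 9-cell patch
        sev = np.full((5, 5), np.nan)
        sev[0:2, 0:2] = 2.8
        sev[2:4, 2:4] = 2.8
        sev[4, 4] = 2.8
        out = delineate_patches(Raster(sev, self.grid())).data
        cell_ha = 30.0**2 / 1e4
        expected = round(np.log(9 * cell_ha), 1)
        assert np.all(out[np.isfinite(sev)] == pytest.approx(expected))

    def test_single_cell_patch_log_area(self):
        sev = np.full((5, 5), np.nan)
        sev[2, 2] = 1.0
        out = delineate_patches(Raster(sev, self.grid())).data
        assert out[2, 2] == pytest.approx(round(np.log(0.09), 1))

    def test_uniform_grid_single_component(self):
        sev = np.full((5, 5), 0.5)
        out = delineate_patches(Raster(sev, self.grid())).data
        assert np.unique(out).size == 1

    def test_area_conservation(self):
        rng = np.random.default_rng(1)
        sev = rng.uniform(0, 3, size=(8, 8))
        sev[0, :] = np.nan
        g = self.grid(8)
        out = delineate_patches(Raster(sev, g)).data
        assert np.isfinite(out).sum() == np.isfinite(sev).sum()


class TestBuildTraitStack:
    def test_unburned_pixel_conventions(self, small_grid):
        records = FireRecordSet(
            [square_event(small_grid, "a", 1990, size=2)], 1985, 2018, small_grid
        )
        stack = build_trait_stack(records)
        assert stack.fri[9, 9] == 33  # record_end - record_start
        assert stack.severity[9, 9] == 0.0
        assert np.isnan(stack.season[9, 9])
        assert np.isnan(stack.patch[9, 9])

    def test_empty_record_set_all_unburned(self, small_grid):
        stack = build_trait_stack(FireRecordSet([], 1985, 2018, small_grid))
        assert np.all(stack.fri == 33)
        assert np.all(stack.severity == 0.0)
        assert np.isnan(stack.season).all()

    def test_two_burn_pixel_matches_scalar_traits(self, simple_records):
        stack = build_trait_stack(simple_records, decay=0.5)
        # pixel (0, 0) burned in 1990 (CBI 1.0, doy 150) and 2000 (CBI 2.0, doy 250)
        assert stack.fri[0, 0] == fri_trait([1990, 2000], 1985, 2018, 0.5)
        assert stack.severity[0, 0] == severity_trait([2.0, 1.0], 0.5)
        assert stack.season[0, 0] == season_trait([250, 150], 0.5)

    def test_decay_one_keeps_most_recent(self, simple_records):
        stack = build_trait_stack(simple_records, decay=1.0)
        assert stack.severity[0, 0] == 2.0
        assert stack.season[0, 0] == season_trait([250], 1.0)
        assert stack.fri[0, 0] == 2018 - 2000

    def test_decay_zero_is_plain_average(self, simple_records):
        stack = build_trait_stack(simple_records, decay=0.0)
        assert stack.severity[0, 0] == severity_trait([2.0, 1.0], 0.0)
        expected_season = round(
            np.mean(np.cos(2 * np.pi * (np.array([150, 250]) - 1) / 365)), 1
        )
        assert stack.season[0, 0] == pytest.approx(expected_season)

    def test_event_order_does_not_matter(self, small_grid):
        events = [
            square_event(small_grid, "a", 1990, doy=150, size=6, severity=1.0),
            square_event(small_grid, "b", 2000, doy=250, size=4, severity=2.0),
            square_event(small_grid, "c", 1995, doy=180, size=5, severity=0.5),
        ]
        s1 = build_trait_stack(FireRecordSet(events, 1985, 2018, small_grid))
        s2 = build_trait_stack(FireRecordSet(events[::-1], 1985, 2018, small_grid))
        for name in ("fri", "severity", "season", "patch"):
            a, b = s1.trait_arrays()[name], s2.trait_arrays()[name]
            assert np.array_equal(a, b, equal_nan=True)

    def test_discretization_lattice(self, simple_records):
        stack = build_trait_stack(simple_records)
        sev = stack.severity[np.isfinite(stack.severity)]
        assert np.allclose(np.round(sev / 0.5) * 0.5, sev)
        season = stack.season[np.isfinite(stack.season)]
        assert np.allclose(np.round(season / 0.1) * 0.1, season, atol=1e-9)

    def test_stack_io_round_trip(self, tmp_path, simple_records):
        from pyrodiv import TraitStack

        stack = build_trait_stack(simple_records)
        stack.write(tmp_path / "tr")
        back = TraitStack.read(tmp_path / "tr")
        assert back.decay == stack.decay
        assert back.record_length == stack.record_length
        for name in ("fri", "severity", "season", "patch"):
            assert np.allclose(
                back.trait_arrays()[name], stack.trait_arrays()[name],
                atol=1e-6, equal_nan=True,
            )
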