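"""Occurrence thinning, filters, backgrounds and correlation screening."""

import numpy as np
import pandas as pd
import pytest

import nichedyn as nd
from nichedyn.occurrences import DEFAULT_THINNING_RADIUS, meets_minimum


def occ_table(lons, lats, status="native", species="sp"):
    return pd.DataFrame(
        {
            "species": species,
            "longitude": np.asarray(lons, float),
            "latitude": np.asarray(lats, float),
            "status": status,
        }
    )


def haversine_deg(lon1, lat1, lon2, lat2):
    """Great-circle distance in degrees of arc (oracle)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return np.degrees(2 * np.arcsin(np.sqrt(h)))


class TestDisaggregate:
    def test_single_point_unchanged(self):
        occ = occ_table([1.0], [2.0])
        out = nd.disaggregate(occ, seed=0)
        pd.testing.assert_frame_equal(out, occ)

    def test_mutually_close_cluster_keeps_exactly_one(self):
        occ = occ_table([0.0, 0.01, 0.02], [0.0, 0.01, 0.0])
        out = nd.disaggregate(occ, seed=1)
        assert len(out) == 1

    def test_distant_points_all_kept(self):
        occ = occ_table([0.0, 1.0], [0.0, 0.0])
        out = nd.disaggregate(occ, seed=1)
        assert len(out) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_no_retained_pair_within_radius(self, seed):
        rng = np.random.default_rng(seed)
        occ = occ_table(rng.uniform(0, 0.5, 200), rng.uniform(40, 40.5, 200))
        out = nd.disaggregate(occ, seed=seed)
        lon = out["longitude"].to_numpy()
        lat = out["latitude"].to_numpy()
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert (
                    haversine_deg(lon[i], lat[i], lon[j], lat[j])
                    > DEFAULT_THINNING_RADIUS
                )

    @pytest.mark.parametrize("seed", [0, 5])
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        occ = occ_table(rng.uniform(0, 0.4, 150), rng.uniform(-0.2, 0.2, 150))
        once = nd.disaggregate(occ, seed=seed)
        twice = nd.disaggregate(once, seed=seed + 1)
        pd.testing.assert_frame_equal(twice, once)

    def test_statuses_thinned_independently(self):
        both = pd.concat(
            [occ_table([0.0], [0.0], "native"), occ_table([0.0], [0.0], "alien")],
            ignore_index=True,
        )
        out = nd.disaggregate(both, seed=0)
        assert sorted(out["status"]) == ["alien", "native"]

    def test_empty_input(self):
        occ = occ_table([], [])
        assert nd.disaggregate(occ, seed=0).empty

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            nd.disaggregate(occ_table([0.0], [0.0]), radius=0.0)


class TestMinimumFilter:
    def test_threshold_boundary(self):
        at = pd.concat(
            [occ_table(np.arange(40), np.zeros(40), s) for s in ("native", "alien")]
        )
        assert meets_minimum(at)
        below = pd.concat(
            [
                occ_table(np.arange(39), np.zeros(39), "native"),
                occ_table(np.arange(400), np.zeros(400), "alien"),
            ]
        )
        assert not meets_minimum(below)

    def test_zero_minimum_always_keeps(self):
        occ = occ_table([0.0], [0.0])
        assert meets_minimum(occ, minimum=0)

    def test_multi_species_filter(self):
        good = pd.concat(
            [occ_table(np.arange(45), np.zeros(45), s, "good") for s in ("native", "alien")]
        )
        bad = pd.concat(
            [occ_table(np.arange(10), np.zeros(10), s, "bad") for s in ("native", "alien")]
        )
        out = nd.filter_min_occurrences(pd.concat([good, bad], ignore_index=True))
        assert set(out["species"]) == {"good"}


class TestAssignBackground:
    def test_background_is_union_of_occupied_regions(self, landscape):
        climate, regions = landscape
        geom = climate.geometry
        # occurrences placed in two known regions for the native range
        targets = regions.region_ids[:2]
        lons, lats = [], []
        for rid in targets:
            r, c = np.argwhere(regions.labels == rid)[0]
            lons.append(geom.x_centers[c])
            lats.append(geom.y_centers[r])
        occ = pd.concat(
            [
                occ_table(lons, lats, "native"),
                occ_table([lons[0]], [lats[0]], "alien"),
            ],
            ignore_index=True,
        )
        _, bg = nd.assign_background(occ, regions, climate)
        expected = int(np.isin(regions.labels, targets).sum())
        assert len(bg.cells["native"]) == expected
        assert sorted(bg.region_ids["native"]) == sorted(targets)

    def test_single_region_map_gives_full_extent(self, landscape):
        climate, _ = landscape
        whole = nd.RegionMap(climate.geometry, np.zeros(climate.geometry.shape, int))
        occ = pd.concat(
            [occ_table([-5.0], [35.0], "native"), occ_table([-4.0], [36.0], "alien")],
            ignore_index=True,
        )
        _, bg = nd.assign_background(occ, whole, climate)
        assert len(bg.cells["native"]) == climate.geometry.nrows * climate.geometry.ncols

    def test_out_of_map_occurrences_dropped(self, landscape, caplog):
        climate, regions = landscape
        occ = pd.concat(
            [
                occ_table([-5.0, 100.0], [35.0, 35.0], "native"),
                occ_table([-4.0], [36.0], "alien"),
            ],
            ignore_index=True,
        )
        with caplog.at_level("WARNING"):
            kept, bg = nd.assign_background(occ, regions, climate)
        assert len(kept) == 2
        assert bg.n_dropped == 1

    def test_monotone_in_occurrences(self, landscape):
        climate, regions = landscape
        occ = pd.concat(
            [occ_table([-5.0], [35.0], "native"), occ_table([-4.0], [36.0], "alien")],
            ignore_index=True,
        )
        _, bg_small = nd.assign_background(occ, regions, climate)
        more = pd.concat([occ, occ_table([-1.0], [38.0], "native")], ignore_index=True)
        _, bg_big = nd.assign_background(more, regions, climate)
        small_cells = set(map(tuple, bg_small.cells["native"][["row", "col"]].to_numpy()))
        big_cells = set(map(tuple, bg_big.cells["native"][["row", "col"]].to_numpy()))
        assert small_cells <= big_cells

    def test_occurrence_cells_inside_own_background(self, species_surfaces):
        occ = species_surfaces["occ"]
        bg = species_surfaces["background"]
        for status in ("native", "alien"):
            occ_cells = set(
                map(tuple, occ.loc[occ["status"] == status, ["row", "col"]].to_numpy())
            )
            bg_cells = set(map(tuple, bg.cells[status][["row", "col"]].to_numpy()))
            assert occ_cells <= bg_cells


class TestCorrelationScreen:
    def test_duplicated_variable_reported_with_r_one(self):
        rng = np.random.default_rng(0)
        a = rng.random(50)
        report = nd.screen_variable_correlations(pd.DataFrame({"a": a, "b": a.copy()}))
        assert report == [("a", "b", pytest.approx(1.0))]

    def test_independent_variables_clean(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((10_000, 4)), columns=list("abcd"))
        assert nd.screen_variable_correlations(df) == []

    def test_anticorrelation_uses_absolute_value(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(5000)
        b = -0.87 * a + np.sqrt(1 - 0.87**2) * rng.standard_normal(5000)
        report = nd.screen_variable_correlations(pd.DataFrame({"a": a, "b": b}))
        assert len(report) == 1 and report[0][2] < -0.8

    def test_zero_variance_reported_as_undefined(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        report = nd.screen_variable_correlations(df)
        assert len(report) == 1 and np.isnan(report[0][2])

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            nd.screen_variable_correlations(pd.DataFrame({"a": [1.0], "b": [2.0]}))


class TestOccurrenceIO:
    def test_round_trip(self, tmp_path):
        occ = occ_table([1.5, -2.5], [10.0, 20.0])
        path = tmp_path / "occ.csv"
        nd.write_occurrences(occ, path)
        pd.testing.assert_frame_equal(nd.read_occurrences(path), occ)

    def test_bad_status_rejected(self):
        occ = occ_table([0.0], [0.0], status="invasive")
        with pytest.raises(ValueError, match="status"):
            nd.write_occurrences(occ, "/dev/null")

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            nd.disaggregate(occ_table([500.0], [0.0]))
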