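"""Virtual landscape and virtual species generators."""

import numpy as np
import pandas as pd
import pytest

import nichedyn as nd
from nichedyn.grids import aggregate_to_coarse, read_grid, write_grid
from nichedyn.synthetic import BASE_VARIABLES, _WBAL_FLOOR


def morans_i(grid):
    """Brute-force Moran's I with rook adjacency on a full grid."""
    x = grid - grid.mean()
    num = 0.0
    w = 0
    nr, nc = grid.shape
    for di, dj in ((0, 1), (1, 0)):
        a = x[: nr - di, : nc - dj]
        b = x[di:, dj:]
        num += 2 * (a * b).sum()
        w += 2 * a.size
    return (x.size / w) * num / (x * x).sum()


class TestGenerateLandscape:
    def test_deterministic_under_fixed_seed(self, geometry):
        a = nd.generate_landscape(5, geometry, 2.0, n_regions=6)
        b = nd.generate_landscape(5, geometry, 2.0, n_regions=6)
        for var in nd.VARIABLES:
            np.testing.assert_array_equal(a[0].layers[var], b[0].layers[var])
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_identity_correlation_gives_uncorrelated_fields(self):
        geom = nd.GridGeometry(0, 0, 0.25, 100, 100)
        climate, _ = nd.generate_landscape(3, geom, autocorrelation_range=0.0)
        x = np.column_stack([climate.layers[v].ravel() for v in BASE_VARIABLES])
        # wbal clipping can leave a residual trace; check pre-clip variables
        corr = np.corrcoef(x, rowvar=False)
        off = corr[~np.eye(len(BASE_VARIABLES), dtype=bool)]
        assert np.abs(off).max() < 0.1

    def test_requested_cross_correlations_are_approached(self):
        geom = nd.GridGeometry(0, 0, 0.25, 100, 100)
        target = nd.default_cross_correlation()
        climate, _ = nd.generate_landscape(4, geom, 0.0, cross_correlation=target)
        x = np.column_stack([climate.layers[v].ravel() for v in BASE_VARIABLES])
        corr = np.corrcoef(x, rowvar=False)
        assert np.abs(corr - target).max() < 0.1

    def test_zero_autocorrelation_range_gives_white_fields(self):
        geom = nd.GridGeometry(0, 0, 0.25, 40, 40)
        climate, _ = nd.generate_landscape(7, geom, autocorrelation_range=0.0)
        assert abs(morans_i(climate.layers["bio5"])) < 0.05

    def test_smoothing_induces_spatial_autocorrelation(self):
        geom = nd.GridGeometry(0, 0, 0.25, 40, 40)
        climate, _ = nd.generate_landscape(7, geom, autocorrelation_range=3.0)
        assert morans_i(climate.layers["bio5"]) > 0.5

    def test_bio7_is_bio5_minus_bio6(self, landscape):
        climate, _ = landscape
        np.testing.assert_allclose(
            climate.layers["bio7"], climate.layers["bio5"] - climate.layers["bio6"]
        )

    def test_regions_partition_the_extent(self, landscape):
        _, regions = landscape
        assert len(regions.region_ids) >= 2
        assert regions.labels.shape == regions.geometry.shape

    @pytest.mark.parametrize(
        "bad",
        [
            0.9 * np.eye(5),
            np.eye(5) + np.triu(np.full((5, 5), 0.2), k=1),
            np.eye(4),
        ],
        ids=["not-unit-diagonal", "asymmetric", "wrong-shape"],
    )
    def test_bad_correlation_matrix_rejected(self, geometry, bad):
        with pytest.raises(ValueError):
            nd.generate_landscape(1, geometry, 1.0, cross_correlation=bad)

    def test_non_psd_correlation_rejected(self, geometry):
        m = np.eye(5)
        m[0, 1] = m[1, 0] = 0.9
        m[1, 2] = m[2, 1] = 0.9
        m[0, 2] = m[2, 0] = -0.9  # violates transitivity -> negative eigenvalue
        with pytest.raises(ValueError, match="positive semidefinite"):
            nd.generate_landscape(1, geometry, 1.0, cross_correlation=m)


class TestWaterBalance:
    def test_monthly_stacks_sum_to_wbal_layer(self, geometry):
        climate, _ = nd.generate_landscape(9, geometry, 1.0, include_monthly=True)
        wbal = nd.compute_wbal(climate.monthly_precipitation, climate.monthly_pet)
        np.testing.assert_allclose(wbal, climate.layers["wbal"], atol=1e-9)
        assert (climate.monthly_precipitation > 0).all()
        assert climate.layers["wbal"].min() >= _WBAL_FLOOR

    def test_balanced_months_give_zero(self):
        stack = np.random.default_rng(0).random((12, 4, 4)) * 100
        np.testing.assert_array_equal(nd.compute_wbal(stack, stack), np.zeros((4, 4)))

    def test_constant_surplus(self):
        prec = np.full((12, 3, 3), 100.0)
        pet = np.full((12, 3, 3), 40.0)
        np.testing.assert_allclose(nd.compute_wbal(prec, pet), np.full((3, 3), 720.0))

    def test_matches_per_cell_loop_oracle(self):
        rng = np.random.default_rng(42)
        prec = rng.random((12, 6, 7)) * 300
        pet = rng.random((12, 6, 7)) * 150
        expected = np.zeros((6, 7))
        for m in range(12):
            for i in range(6):
                for j in range(7):
                    expected[i, j] += prec[m, i, j] - pet[m, i, j]
        np.testing.assert_allclose(nd.compute_wbal(prec, pet), expected, atol=1e-9)

    def test_mismatched_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            nd.compute_wbal(np.zeros((12, 4, 4)), np.zeros((12, 4, 5)))
        with pytest.raises(ValueError, match="12"):
            nd.compute_wbal(np.zeros((11, 4, 4)), np.zeros((11, 4, 4)))


class TestAggregation:
    def test_constant_grid_unchanged(self):
        out = aggregate_to_coarse(np.full((6, 6), 3.25), 3)
        np.testing.assert_allclose(out, np.full((2, 2), 3.25))

    def test_block_mean(self):
        out = aggregate_to_coarse(np.array([[1.0, 2.0], [3.0, 4.0]]), 2)
        np.testing.assert_allclose(out, [[2.5]])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        grid = rng.random((8, 8))
        out = aggregate_to_coarse(grid, 4)
        for i in range(2):
            for j in range(2):
                assert out[i, j] == pytest.approx(
                    grid[4 * i : 4 * i + 4, 4 * j : 4 * j + 4].mean(), abs=1e-12
                )

    def test_non_divisible_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            aggregate_to_coarse(np.zeros((6, 6)), 4)


class TestGridIO:
    def test_round_trip(self, tmp_path, landscape):
        climate, _ = landscape
        path = tmp_path / "bio5.txt"
        write_grid(path, climate.layers["bio5"], climate.geometry)
        grid, geom = read_grid(path)
        np.testing.assert_allclose(grid, climate.layers["bio5"], rtol=1e-9)
        assert geom == climate.geometry


class TestVirtualSpecies:
    def test_deterministic_under_fixed_seed(self, landscape):
        climate, _ = landscape
        masks = np.zeros(climate.geometry.shape, bool)
        masks[:, :20] = True
        spec = nd.VirtualSpeciesSpec(name="sp", seed=3, n_native=50, n_alien=50)
        a = nd.sample_virtual_species(spec, climate, masks, ~masks)
        b = nd.sample_virtual_species(spec, climate, masks, ~masks)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError, match="n_native"):
            nd.VirtualSpeciesSpec(name="sp", n_native=0)

    def test_overlapping_masks_rejected(self, landscape):
        climate, _ = landscape
        mask = np.ones(climate.geometry.shape, bool)
        spec = nd.VirtualSpeciesSpec(name="sp")
        with pytest.raises(ValueError, match="disjoint"):
            nd.sample_virtual_species(spec, climate, mask, mask)

    def test_fully_unfilled_alien_range_rejected(self, landscape):
        climate, _ = landscape
        native = np.zeros(climate.geometry.shape, bool)
        native[:, :20] = True
        spec = nd.VirtualSpeciesSpec(
            name="sp", unfilled_mask=np.ones(climate.geometry.shape, bool)
        )
        with pytest.raises(ValueError, match="suitability"):
            nd.sample_virtual_species(spec, climate, native, ~native)

    def test_occurrence_climate_recovers_niche_center(self):
        # large n: the sample mean of z-scored climate at native occurrences
        # matches the suitability-weighted landscape mean (the attainable
        # optimum given finite availability) within sampling error, and the
        # abstract niche center loosely
        from nichedyn.synthetic import _suitability

        geom = nd.GridGeometry(0, 0, 0.25, 80, 80)
        climate, _ = nd.generate_landscape(21, geom, 3.0)
        rr, cc = np.indices(geom.shape)
        native = (rr + cc) % 2 == 0
        k = len(BASE_VARIABLES)
        spec = nd.VirtualSpeciesSpec(
            name="sp", covariance=np.eye(k) * 0.45**2, n_native=3000, n_alien=1, seed=5
        )
        occ = nd.sample_virtual_species(spec, climate, native, ~native)
        occ = occ[occ["status"] == "native"]
        row, col = geom.cell_of(occ["longitude"].to_numpy(), occ["latitude"].to_numpy())
        srows, scols, suit = _suitability(
            climate, native, BASE_VARIABLES, spec.center, spec.covariance
        )
        for i, var in enumerate(BASE_VARIABLES):
            layer = climate.layers[var]
            zvals = (layer[row, col] - layer.mean()) / layer.std()
            zcells = (layer[srows, scols] - layer.mean()) / layer.std()
            attainable = np.average(zcells, weights=suit)
            sem = zvals.std() / np.sqrt(len(zvals))
            assert abs(zvals.mean() - attainable) < 4 * sem
            assert abs(zvals.mean() - spec.center[i]) < 0.15

    def test_ground_truth_attached(self, landscape):
        climate, _ = landscape
        masks = np.zeros(climate.geometry.shape, bool)
        masks[:, :20] = True
        spec = nd.VirtualSpeciesSpec(name="sp", seed=3, n_native=40, n_alien=40)
        occ = nd.sample_virtual_species(spec, climate, masks, ~masks)
        assert occ.attrs["ground_truth"]["name"] == "sp"
        assert occ.attrs["ground_truth"]["seed"] == 3
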