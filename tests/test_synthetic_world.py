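"""Synthetic world: grid geometry, emission/met invariants, surrogate chemistry."""

import numpy as np
import pytest

from shipair import synthetic_world as sw


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

class TestBuildGrid:
    def test_deterministic_per_seed(self):
        a = sw.build_grid(48, 48, 36.0, seed=5)
        b = sw.build_grid(48, 48, 36.0, seed=5)
        np.testing.assert_array_equal(a.land_mask, b.land_mask)
        np.testing.assert_array_equal(a.dist_coast_nm, b.dist_coast_nm)
        np.testing.assert_array_equal(a.port_mask, b.port_mask)

    def test_full_scale_dimensions(self):
        g = sw.build_grid(137, 136, 36.0, seed=0)
        assert g.shape == (136, 137)

    def test_signed_distance_brute_force(self, grid32):
        """Signed distance matches an exhaustive nearest-opposite-cell scan."""
        g = grid32
        land_idx = np.argwhere(g.land_mask)
        sea_idx = np.argwhere(~g.land_mask)
        rng = np.random.default_rng(1)
        cells = rng.choice(g.nx * g.ny, size=60, replace=False)
        for flat in cells:
            y, x = divmod(flat, g.nx)
            opp = sea_idx if g.land_mask[y, x] else land_idx
            d = np.sqrt(((opp - [y, x]) ** 2).sum(axis=1)).min()
            expect = (d - 0.5) * g.cell_km / 1.852
            if g.land_mask[y, x]:
                expect = -expect
            assert g.dist_coast_nm[y, x] == pytest.approx(expect)

    def test_sign_change_exactly_at_coastline(self, grid32):
        g = grid32
        assert np.all(g.dist_coast_nm[~g.land_mask] >= 0)
        assert np.all(g.dist_coast_nm[g.land_mask] < 0)

    def test_sea_cells_adjacent_to_land_are_near(self, grid32):
        g = grid32
        near_limit = 36.0 / 1.852  # one cell in nautical miles
        land = g.land_mask
        for y, x in np.argwhere(~land):
            y0, y1 = max(0, y - 1), min(g.ny, y + 2)
            x0, x1 = max(0, x - 1), min(g.nx, x + 2)
            if land[y0:y1, x0:x1].any():
                assert g.dist_coast_nm[y, x] < near_limit

    def test_regions_partition_coastal_land(self, grid32):
        g = grid32
        coastal = g.coastal_land_mask()
        assert coastal.any()
        counts = sum(g.region_mask(r).sum() for r in sw.COASTAL_REGIONS)
        assert counts == coastal.sum()
        assert not (coastal & ~g.land_mask).any()
        # CBS is north of SEC is north of SC (band ordering by row index)
        rows = {r: np.argwhere(g.region_mask(r))[:, 0] for r in sw.COASTAL_REGIONS}
        assert rows["CBS"].max() < rows["SEC"].min() + g.ny  # bands exist
        assert rows["CBS"].mean() < rows["SEC"].mean() < rows["SC"].mean()

    def test_single_connected_land_and_sea(self, grid32):
        from scipy import ndimage
        g = grid32
        assert ndimage.label(g.land_mask)[1] == 1
        assert ndimage.label(~g.land_mask)[1] == 1

    def test_rejects_tiny_or_zoneless_grids(self):
        with pytest.raises(sw.WorldError):
            sw.build_grid(8, 8, 36.0, seed=0)
        with pytest.raises(sw.WorldError):
            sw.build_grid(16, 16, 36.0, seed=0)  # sea narrower than 200 Nm

    def test_ports_are_sea_cells_adjacent_to_land(self, grid32):
        from scipy import ndimage
        g = grid32
        assert g.port_mask.sum() == 5
        assert not (g.port_mask & g.land_mask).any()
        near_land = ndimage.binary_dilation(g.land_mask, np.ones((3, 3)))
        assert (g.port_mask <= near_land).all()


# ---------------------------------------------------------------------------
# Emissions / met generation
# ---------------------------------------------------------------------------

class TestGenerateMonth:
    def test_invariant_sweep_many_seeds(self, grid32):
        params = sw.WorldParams()
        for seed in range(100):
            s = sw.generate_month(grid32, params, year_index=seed % 5,
                                  month_label=sw.MONTHS[seed % 4], seed=seed)
            s.emissions.validate(grid32)  # non-negativity + land/sea support
            s.met.validate()

    def test_deterministic(self, grid32):
        params = sw.WorldParams()
        a = sw.generate_month(grid32, params, 1, "Apr", seed=9)
        b = sw.generate_month(grid32, params, 1, "Apr", seed=9)
        np.testing.assert_array_equal(a.emissions.land, b.emissions.land)
        np.testing.assert_array_equal(a.met.pblh, b.met.pblh)

    def test_fuel_switch_so2_ratio(self, grid32):
        params = sw.WorldParams()
        for month in sw.MONTHS:
            y0 = sw.generate_month(grid32, params, 0, month, seed=2)
            y4 = sw.generate_month(grid32, params, 4, month, seed=2)
            ratio = (y4.emissions.shipping_species("SO2").sum() /
                     y0.emissions.shipping_species("SO2").sum())
            assert ratio == pytest.approx(0.30, abs=0.02)

    def test_shipping_shares_near_target(self, dataset32):
        samples, grid, params = dataset32
        target = params.shipping_share_target
        for s in samples:
            for species in ("SO2", "NOx"):
                if species == "SO2" and \
                        s.year_index == params.fuel_switch_year_index:
                    continue  # the fuel switch intentionally breaks the share
                ship = s.emissions.shipping_species(species).sum()
                land = s.emissions.land_species(species).sum()
                assert abs(ship / (ship + land) - target) <= 0.03

    def test_rejects_bad_month(self, grid32):
        with pytest.raises(sw.WorldError):
            sw.generate_month(grid32, sw.WorldParams(), 0, "Feb", seed=0)

    def test_shipping_confined_to_water_and_river(self, grid32):
        s = sw.generate_month(grid32, sw.WorldParams(), 2, "Jul", seed=4)
        off = grid32.land_mask & ~grid32.river_mask
        assert np.all(s.emissions.shipping[:, :, off] == 0)
        assert s.emissions.shipping.sum() > 0


# ---------------------------------------------------------------------------
# Surrogate chemistry
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def base_sample(dataset32):
    samples, grid, params = dataset32
    return [s for s in samples if s.year_index == 4 and s.month_label == "Jan"][0]


class TestSurrogateChemistry:
    def test_zero_shipping_gives_zero_shipping_pm(self, dataset32, base_sample):
        _, grid, params = dataset32
        e = base_sample.emissions.copy()
        e.shipping[...] = 0.0
        out = sw.surrogate_chemistry(e, base_sample.met, params)
        assert np.all(out.shipping_pm25() == 0)

    def test_additive_tagging_exact(self, dataset32, base_sample):
        truth = base_sample.truth
        total = sum(truth.pm25[i] for i in range(len(sw.SOURCE_GROUPS)))
        np.testing.assert_array_equal(truth.total_pm25(), total)

    def test_components_bounded_by_group_pm(self, dataset32):
        samples, _, _ = dataset32
        for s in samples:
            comp_sum = s.truth.components.sum(axis=1)
            assert np.all(comp_sum <= s.truth.pm25 + 1e-9)

    def test_primary_homogeneity(self, dataset32, base_sample):
        """Doubling one group's primary PM doubles its POM contribution."""
        _, grid, params = dataset32
        e = base_sample.emissions.copy()
        vi = sw.VESSEL_CLASSES.index("OGV")
        e.shipping[vi, sw.SHIP_SPECIES.index("PM")] *= 2.0
        out = sw.surrogate_chemistry(e, base_sample.met, params)
        ref = base_sample.truth
        np.testing.assert_allclose(out.group_component("OGV", "pom"),
                                   2.0 * ref.group_component("OGV", "pom"))
        # secondary components of the scaled group are untouched
        np.testing.assert_allclose(out.group_component("OGV", "nitrate"),
                                   ref.group_component("OGV", "nitrate"))

    def test_shipping_so2_response_is_linear(self, dataset32, base_sample):
        _, grid, params = dataset32
        coastal = grid.coastal_land_mask()
        lam = np.arange(0.0, 1.0, 0.1)
        base_mean = base_sample.truth.shipping_pm25()[coastal].mean()
        bens = []
        for f in 1.0 - lam:
            e = base_sample.emissions.copy()
            e.shipping[:, sw.SHIP_SPECIES.index("SO2")] *= f
            out = sw.surrogate_chemistry(e, base_sample.met, params)
            bens.append(base_mean - out.shipping_pm25()[coastal].mean())
        r2 = np.corrcoef(lam, bens)[0, 1] ** 2
        assert r2 >= 0.99

    def test_land_nox_titration_dip(self, dataset32):
        """Benefit declines near the 80% land-NOx cut, then recovers."""
        samples, grid, params = dataset32
        coastal = grid.coastal_land_mask()
        base = [s for s in samples if s.year_index == 4]
        j = sw.LAND_SPECIES.index("NOx")

        def mean_benefit(factor):
            vals = []
            for s in base:
                e = s.emissions.copy()
                e.land[:, j] *= factor
                out = sw.surrogate_chemistry(e, s.met, params)
                vals.append(s.truth.shipping_pm25()[coastal].mean() -
                            out.shipping_pm25()[coastal].mean())
            return np.mean(vals)

        bens = [mean_benefit(1.0 - 0.1 * i) for i in range(11)]
        assert bens[8] < bens[7] or bens[8] < bens[9]
        # interior stationary point: the sequence is not monotone
        diffs = np.diff(bens)
        assert (diffs < 0).any() and (diffs > 0).any()

    def test_oxidant_surface_not_separable(self, dataset32):
        """Interaction sum-of-squares of X over the NOx x VOC grid is positive."""
        _, _, params = dataset32
        ns = np.linspace(0.05, 1.0, 10)
        vs = np.linspace(0.05, 1.0, 10)
        X = np.array([[sw.oxidant_factor(n, v, params) for v in vs] for n in ns])
        inter = X - X.mean(axis=0) - X.mean(axis=1)[:, None] + X.mean()
        assert (inter ** 2).sum() > 1e-6

    def test_oxidant_monotone_in_voc(self, dataset32):
        _, _, params = dataset32
        vals = [sw.oxidant_factor(0.7, v, params) for v in np.linspace(0.1, 1.5, 12)]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_negative_emissions(self, dataset32, base_sample):
        _, _, params = dataset32
        e = base_sample.emissions.copy()
        e.land[0, 0, 0, 0] = -1.0
        with pytest.raises(sw.WorldError):
            sw.surrogate_chemistry(e, base_sample.met, params)

    def test_deterministic_operator(self, dataset32, base_sample):
        _, _, params = dataset32
        a = sw.surrogate_chemistry(base_sample.emissions, base_sample.met, params)
        b = sw.surrogate_chemistry(base_sample.emissions, base_sample.met, params)
        np.testing.assert_array_equal(a.pm25, b.pm25)


# ---------------------------------------------------------------------------
# Dataset + I/O
# ---------------------------------------------------------------------------

class TestDataset:
    def test_counts_and_test_flags(self, dataset32):
        samples, _, _ = dataset32
        assert len(samples) == 20
        assert sum(s.is_test for s in samples) == 4
        assert all(s.truth is not None for s in samples)

    def test_requires_two_years(self, grid32):
        with pytest.raises(sw.WorldError):
            sw.make_dataset(grid32, sw.WorldParams(), n_years=1, seed=0)

    def test_netcdf_round_trip_bitwise(self, dataset32, tmp_path):
        samples, grid, params = dataset32
        path = tmp_path / "world.nc"
        sw.save_dataset(path, samples, grid, params)
        loaded, grid2, params2 = sw.load_dataset(path)
        assert len(loaded) == len(samples)
        np.testing.assert_array_equal(grid2.dist_coast_nm, grid.dist_coast_nm)
        for a, b in zip(samples, loaded):
            assert (a.year_index, a.month_label, a.is_test) == \
                (b.year_index, b.month_label, b.is_test)
            np.testing.assert_array_equal(a.emissions.land, b.emissions.land)
            np.testing.assert_array_equal(a.emissions.shipping,
                                          b.emissions.shipping)
            np.testing.assert_array_equal(a.met.as_stack(), b.met.as_stack())
            np.testing.assert_array_equal(a.truth.pm25, b.truth.pm25)
            np.testing.assert_array_equal(a.truth.components,
                                          b.truth.components)
        assert params2.ref_land_nox == pytest.approx(params.ref_land_nox)

    def test_read_error_carries_path(self, tmp_path):
        with pytest.raises(OSError, match="no_such"):
            sw.load_dataset(tmp_path / "no_such.nc")

    def test_dataset_deterministic(self, grid32):
        p1, p2 = sw.WorldParams(), sw.WorldParams()
        a = sw.make_dataset(grid32, p1, n_years=2, seed=11)
        b = sw.make_dataset(grid32, p2, n_years=2, seed=11)
        for s, t in zip(a, b):
            np.testing.assert_array_equal(s.truth.pm25, t.truth.pm25)
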