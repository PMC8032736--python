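"""Tests for cohort construction, scenario runs and regional aggregation."""

import numpy as np
import pandas as pd
import pytest

from cflux import region as rg
from cflux.region import (Cohort, RegionGrid, aggregate, annualize,
                          build_cohorts, carbon_balance, run_scenario)
from cflux.severity import SeverityRecord
from cflux.synthgen import FireEvent, SynthConfig, gen_climate


def sev(dnbr, fid=0, year=2000):
    return SeverityRecord(fire_id=fid, year=year, area_km2=10.0,
                          dnbr_raw=dnbr, dnbr_background=0.0, dnbr=dnbr)


def grid_2x2(sub=10):
    return RegionGrid(ny=2, nx=2, cell_area_km2=np.full((2, 2), 2500.0),
                      forest_frac=np.full((2, 2), 0.8), subpixels=sub)


def fire(fid, year, bounds, dnbr=400.0):
    return (FireEvent(fid, year, 30.0, bounds, dnbr), sev(dnbr, fid, year))


@pytest.fixture(scope="module")
def small_forcing():
    cfg = SynthConfig(ny=2, nx=2, year_start=1998, year_end=2005, seed=4)
    return gen_climate(cfg)


class TestBuildCohorts:
    def test_no_fires_one_cohort_per_cell(self):
        cohorts = build_cohorts(grid_2x2(), [])
        assert len(cohorts) == 4
        assert all(c.area_frac == 1.0 and not c.burned for c in cohorts)

    def test_half_cell_fire_splits_evenly(self):
        cohorts = build_cohorts(grid_2x2(), [fire(0, 2000, (0, 10, 0, 5))])
        cell00 = [c for c in cohorts if (c.iy, c.ix) == (0, 0)]
        assert sorted(c.area_frac for c in cell00) == [0.5, 0.5]
        burned = next(c for c in cell00 if c.burned)
        assert burned.fires[0][0] == 2000

    def test_overlapping_fires_make_multifire_cohorts(self):
        cohorts = build_cohorts(
            grid_2x2(),
            [fire(0, 2000, (0, 6, 0, 6)), fire(1, 2005, (3, 9, 3, 9))],
        )
        cell00 = [c for c in cohorts if (c.iy, c.ix) == (0, 0)]
        assert len(cell00) == 4  # unburned, fire0-only, fire1-only, reburn
        reburn = next(c for c in cell00 if len(c.fires) == 2)
        assert [y for y, _ in reburn.fires] == [2000, 2005]
        assert reburn.area_frac == pytest.approx(9 / 100)

    def test_fractions_match_pixel_counting_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            b = []
            for fid, year in ((0, 1999), (1, 2003)):
                r0, c0 = rng.integers(0, 6, 2)
                h, w = rng.integers(2, 5, 2)
                b.append(fire(fid, year, (int(r0), int(r0 + h), int(c0), int(c0 + w))))
            cohorts = build_cohorts(grid_2x2(), b)
            # independent oracle: vectorized boolean stack per pixel
            masks = []
            for ev, _ in b:
                m = np.zeros((20, 20), dtype=bool)
                r0, r1, c0, c1 = ev.bounds
                m[r0:r1, c0:c1] = True
                masks.append(m)
            stack = np.stack(masks)
            for cohort in cohorts:
                iy, ix = cohort.iy, cohort.ix
                block = stack[:, iy * 10:(iy + 1) * 10, ix * 10:(ix + 1) * 10]
                signature = block[0].astype(int) + 2 * block[1].astype(int)
                code = sum(1 << s.fire_id for _, s in cohort.fires)
                assert cohort.area_frac == pytest.approx(
                    (signature == code).sum() / 100
                )

    def test_fire_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside grid"):
            build_cohorts(grid_2x2(), [fire(0, 2000, (0, 25, 0, 5))])

    def test_fractions_sum_to_one_per_cell(self):
        rng = np.random.default_rng(5)
        fires = [
            fire(i, 1998 + i, tuple(map(int, (
                r0 := rng.integers(0, 15), r0 + rng.integers(1, 5),
                c0 := rng.integers(0, 15), c0 + rng.integers(1, 5)))))
            for i in range(6)
        ]
        cohorts = build_cohorts(grid_2x2(), fires)
        sums = {}
        for c in cohorts:
            sums[(c.iy, c.ix)] = sums.get((c.iy, c.ix), 0.0) + c.area_frac
        assert all(s == pytest.approx(1.0) for s in sums.values())


class TestRunScenario:
    def test_empty_fire_list_equals_nofire(self, small_forcing, params):
        cohorts = build_cohorts(grid_2x2(), [])
        a = run_scenario(cohorts, small_forcing, params, with_fire=True,
                         spinup_years=30)
        b = run_scenario(cohorts, small_forcing, params, with_fire=False,
                         spinup_years=30)
        for fa, fb in zip(a, b):
            pd.testing.assert_frame_equal(fa, fb)

    def test_emissions_only_in_fire_year(self, small_forcing, params):
        cohorts = build_cohorts(grid_2x2(), [fire(0, 2000, (0, 10, 0, 10))])
        runs = run_scenario(cohorts, small_forcing, params, spinup_years=30)
        for cohort, df in zip(cohorts, runs):
            if cohort.burned:
                assert (df.loc[df.year == 2000, "emis_total"] > 0).all()
                assert (df.loc[df.year != 2000, "emis_total"] == 0).all()
            else:
                assert (df["emis_total"] == 0).all()

    def test_order_independence(self, small_forcing, params):
        cohorts = build_cohorts(grid_2x2(), [fire(0, 2000, (0, 10, 0, 10))])
        fwd = run_scenario(cohorts, small_forcing, params, spinup_years=30)
        rev = run_scenario(cohorts[::-1], small_forcing, params, spinup_years=30)
        for fa, fb in zip(fwd, rev[::-1]):
            pd.testing.assert_frame_equal(fa, fb)


class TestAggregate:
    def annual(self, years, **values):
        df = pd.DataFrame({"year": years})
        for col in rg.ANNUAL_COLUMNS[1:]:
            df[col] = values.get(col, 0.0)
        return df

    def test_equal_fraction_cell_mean(self):
        grid = RegionGrid(ny=1, nx=1, cell_area_km2=np.array([[1.0]]),
                          forest_frac=np.array([[1.0]]), subpixels=2)
        cohorts = [Cohort(0, 0, (), 0.5), Cohort(0, 0, (), 0.5)]
        series = [self.annual([2000], npp=10.0), self.annual([2000], npp=20.0)]
        ledger = aggregate(series, cohorts, grid)
        assert ledger["npp"][0] == pytest.approx(15.0 * 1e-6)  # Tg over 1 km2

    def test_unit_chain_g_per_m2_km2_to_tg(self):
        grid = RegionGrid(ny=1, nx=1, cell_area_km2=np.array([[1.0]]),
                          forest_frac=np.array([[1.0]]), subpixels=1)
        ledger = aggregate([self.annual([2000], nep=1.0)],
                           [Cohort(0, 0, (), 1.0)], grid)
        assert ledger["nep"][0] == pytest.approx(1e-6)

    def test_three_cell_toy_matches_direct_summation(self):
        grid = RegionGrid(ny=1, nx=3,
                          cell_area_km2=np.array([[100.0, 200.0, 300.0]]),
                          forest_frac=np.array([[1.0, 0.5, 0.8]]), subpixels=2)
        rng = np.random.default_rng(8)
        cohorts, series = [], []
        years = [2000, 2001]
        for ix in range(3):
            for frac in (0.25, 0.75):
                cohorts.append(Cohort(0, ix, (), frac))
                series.append(self.annual(
                    years,
                    npp=float(rng.uniform(1, 5)),
                    rh=float(rng.uniform(1, 5)),
                    nep=float(rng.uniform(-1, 1)),
                    emis_total=float(rng.uniform(0, 2)),
                ))
        ledger = aggregate(series, cohorts, grid)
        for col in ("npp", "rh", "nep", "emis_total"):
            brute = sum(
                df[col].to_numpy() * c.area_frac
                * grid.forest_area_km2(c.iy, c.ix) * 1e-6
                for c, df in zip(cohorts, series)
            )
            np.testing.assert_allclose(ledger[col].to_numpy(), brute, rtol=1e-12)

    def test_split_cohort_invariance(self):
        grid = RegionGrid(ny=1, nx=1, cell_area_km2=np.array([[50.0]]),
                          forest_frac=np.array([[1.0]]), subpixels=1)
        one = aggregate([self.annual([2000], npp=7.0)],
                        [Cohort(0, 0, (), 1.0)], grid)
        halves = aggregate(
            [self.annual([2000], npp=7.0), self.annual([2000], npp=7.0)],
            [Cohort(0, 0, (), 0.5), Cohort(0, 0, (), 0.5)], grid)
        pd.testing.assert_frame_equal(one, halves)

    def test_bad_fraction_sum_rejected(self):
        grid = RegionGrid(ny=1, nx=1, cell_area_km2=np.array([[1.0]]),
                          forest_frac=np.array([[1.0]]), subpixels=1)
        with pytest.raises(ValueError, match="sum to 1"):
            aggregate([self.annual([2000])], [Cohort(0, 0, (), 0.7)], grid)

    def test_ledger_identity_cbf(self):
        grid = RegionGrid(ny=1, nx=1, cell_area_km2=np.array([[1000.0]]),
                          forest_frac=np.array([[1.0]]), subpixels=1)
        years = list(range(2000, 2010))
        rng = np.random.default_rng(9)
        df = self.annual(years)
        df["nep"] = rng.normal(0, 5, len(years))
        df["emis_total"] = rng.uniform(0, 3, len(years))
        ledger = aggregate([df], [Cohort(0, 0, (), 1.0)], grid)
        np.testing.assert_allclose(
            ledger["cbf"].to_numpy(),
            ledger["cb"].to_numpy() - ledger["emis_total"].cumsum().to_numpy(),
            rtol=1e-12,
        )


class TestCarbonBalance:
    def ledger(self, nep_total, emis_total):
        return pd.DataFrame(
            {"year": [2016], "nep": [nep_total], "emis_total": [emis_total]}
        )

    def test_printed_component_identities(self):
        bal = carbon_balance(self.ledger(59.0, 1769.8), self.ledger(1030.0, 0.0))
        assert bal.nep_gap == pytest.approx(971.0)
        assert bal.reduction == pytest.approx(2740.8)
        assert bal.cbf == pytest.approx(59.0 - 1769.8)

    def test_zero_emissions_cbf_equals_cb(self):
        bal = carbon_balance(self.ledger(100.0, 0.0), self.ledger(100.0, 0.0))
        assert bal.cbf == bal.cb_fire

    def test_mismatched_years_rejected(self):
        a = self.ledger(1.0, 0.0)
        b = self.ledger(1.0, 0.0).assign(year=[2015])
        with pytest.raises(ValueError, match="mismatched"):
            carbon_balance(a, b)


class TestAnnualize:
    @pytest.mark.parametrize(
        "total,years,expected",
        [(1769.8, 31, 57.1), (59.0, 31, 1.9), (0.0, 10, 0.0)],
    )
    def test_rates(self, total, years, expected):
        assert annualize(total, years) == expected

    def test_invalid_years(self):
        with pytest.raises(ValueError):
            annualize(10.0, 0)
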