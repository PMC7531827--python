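"""Unit, boundary and partition tests for the hierarchical classifier."""

import numpy as np
import pandas as pd
import pytest

from wbcs import (
    classify_cell,
    classify_grid,
    build_isobioclimate_catalog,
    default_ruleset,
    isobioclimate_long_name,
)
from wbcs.classifier import (
    classify_bioclimate,
    classify_continentality,
    classify_macrobioclimate,
    classify_ombrotype,
    classify_thermotype,
    classify_variant,
)
from wbcs.indices import BioclimaticIndices

RS = default_ruleset()


def fake_indices(io, ps, pw, summer_p, summer_t):
    """Minimal valid index object for exercising the variant rules."""
    return BioclimaticIndices(
        Ti=np.full(12, 10.0), T=10.0, Tmax=25.0, Tmin=-10.0, M=-5.0, m=-15.0,
        Tp=1000.0, Tps=600.0, Ic=35.0, It=0.0, C=120.0, Itc=120.0,
        P=ps + pw, Pp=ps + pw, Ps=ps, Pw=pw, Pps=ps, Ppw=0.0, Pss=ps, Psw=pw,
        Pcm1=0.0, Pcm2=0.0, Pcm3=0.0, Io=io, Iosi=np.array(summer_p) / np.array(summer_t),
        Ios2=1.0, Iosc3=1.0, Iosc4=1.0, Iod2=0.0, summer_months=(5, 6, 7),
        summer_precip=np.asarray(summer_p, float), summer_temp=np.asarray(summer_t, float),
        hemisphere="north", summer_arid=True, T200=10.0, M200=-5.0,
        Itc200=120.0, Tp200=1000.0,
    )


class TestContinentality:
    @pytest.mark.parametrize(
        "ic, expected",
        [
            (30.0, ("Continental", "Eucontinental", "weak")),
            (37.0, ("Continental", "Eucontinental", "strong")),  # boundary goes up
            (10.5, ("Hyperoceanic", "Subhyperoceanic", "weak")),
            (0.0, ("Hyperoceanic", "Ultrahyperoceanic", "strong")),
            (66.0, ("Continental", "Hypercontinental", "strong")),
            (70.0, ("Continental", "Hypercontinental", "strong")),  # clamps up
        ],
    )
    def test_printed_rows(self, ic, expected):
        assert classify_continentality(ic, RS) == expected

    def test_every_printed_endpoint_goes_up(self):
        for row in RS.continentality.rows[1:]:
            t, s, lv = classify_continentality(row["lo"], RS)
            assert (t, s, lv) == (row["type"], row["subtype"], row["level"])

    def test_negative_ic_rejected(self):
        with pytest.raises(ValueError):
            classify_continentality(-0.1, RS)

    def test_partition_sweep(self):
        ics = np.round(np.arange(0.0, 66.01, 0.01), 2)
        idx = RS.continentality.lookup(ics)
        assert idx.shape == ics.shape  # exactly one row for every value
        # monotone non-decreasing class index with Ic
        assert np.all(np.diff(idx) >= 0)


class TestMacrobioclimate:
    def test_summer_aridity_separates_mediterranean_from_temperate(self):
        assert classify_macrobioclimate(1200.0, True, 48.0, RS) == "MEDITERRANEAN"
        assert classify_macrobioclimate(1200.0, False, 48.0, RS) == "TEMPERATE"

    def test_cold_bands(self):
        assert classify_macrobioclimate(550.0, False, 48.0, RS) == "BOREAL"
        assert classify_macrobioclimate(200.0, False, 48.0, RS) == "POLAR"

    def test_low_latitude_is_tropical(self):
        assert classify_macrobioclimate(2500.0, True, 10.0, RS) == "TROPICAL"


class TestBioclimate:
    def test_desertic_continental_vs_oceanic(self):
        assert classify_bioclimate("MEDITERRANEAN", 33.0, 0.7, RS) == "MEDC"
        assert classify_bioclimate("MEDITERRANEAN", 19.0, 0.7, RS) == "MEDO"

    def test_temperate_xeric(self):
        assert classify_bioclimate("TEMPERATE", 30.0, 2.8, RS) == "TEXE"
        assert classify_bioclimate("TEMPERATE", 30.0, 4.5, RS) == "TECO"

    def test_undefined_io_takes_wettest_band(self):
        assert classify_bioclimate("TEMPERATE", 30.0, float("nan"), RS) == "TECO"

    def test_partition_sweep_all_macros(self):
        ios = np.round(np.arange(0.0, 30.01, 0.01), 2)
        for macro, table in RS.bioclimate.items():
            idx = table.lookup(ios)
            assert idx.shape == ios.shape
            assert np.all(np.diff(idx) >= 0)


class TestVariant:
    def test_steppic_all_three_conditions(self):
        idx = fake_indices(io=3.0, ps=100.0, pw=50.0,
                           summer_p=[20.0, 15.0, 18.0], summer_t=[20.0, 22.0, 21.0])
        assert classify_variant("MEDITERRANEAN", idx, RS) == "Stp"

    def test_io_above_steppe_ceiling(self):
        idx = fake_indices(io=7.0, ps=100.0, pw=50.0,
                           summer_p=[20.0, 15.0, 18.0], summer_t=[20.0, 22.0, 21.0])
        assert classify_variant("MEDITERRANEAN", idx, RS) == "Nor"

    def test_submediterranean_threshold(self):
        # July 40 mm at 20 deg: 40 < 2.8 * 20 = 56
        idx = fake_indices(io=7.0, ps=120.0, pw=130.0,
                           summer_p=[60.0, 40.0, 60.0], summer_t=[19.0, 20.0, 19.0])
        assert classify_variant("TEMPERATE", idx, RS) == "Sbm"
        # mediterranean macro is not eligible for Sbm
        assert classify_variant("MEDITERRANEAN", idx, RS) == "Nor"

    def test_steppe_requires_every_summer_month_dry(self):
        idx = fake_indices(io=3.0, ps=100.0, pw=50.0,
                           summer_p=[70.0, 15.0, 18.0], summer_t=[20.0, 22.0, 21.0])
        # July 70 >= 3*20: steppe fails, submediterranean ineligible (med)
        assert classify_variant("MEDITERRANEAN", idx, RS) == "Nor"

    def test_io_floor_is_exclusive(self):
        idx = fake_indices(io=0.2, ps=10.0, pw=5.0,
                           summer_p=[1.0, 1.0, 1.0], summer_t=[20.0, 22.0, 21.0])
        assert classify_variant("MEDITERRANEAN", idx, RS) == "Nor"


class TestThermotype:
    def test_continental_dispatches_to_tp(self):
        assert classify_thermotype("MEDITERRANEAN", 33.0, 500.0, 1200.0, RS) == "Sme"

    def test_oceanic_with_high_itc_uses_itc(self):
        assert classify_thermotype("MEDITERRANEAN", 15.0, 300.0, 700.0, RS) == "Mme"

    def test_oceanic_with_low_itc_falls_back_to_tp(self):
        assert classify_thermotype("MEDITERRANEAN", 15.0, 80.0, 700.0, RS) == "Ome"

    def test_boreal_always_by_tp(self):
        assert classify_thermotype("BOREAL", 10.0, 500.0, 445.0, RS) == "Obo"

    def test_gelid_floor(self):
        assert classify_thermotype("TEMPERATE", 33.0, -100.0, 0.0, RS) == "Gel"


class TestOmbrotype:
    @pytest.mark.parametrize(
        "io, code", [(0.7, "Ari"), (0.0, "Uha"), (1.5, "Sar"), (2.8, "Sec"), (50.0, "Uhh")]
    )
    def test_lookup(self, io, code):
        assert classify_ombrotype(io, 1000.0, RS) == code

    def test_gelid_cells_are_supersnowy(self):
        assert classify_ombrotype(float("nan"), 50.0, RS) == "Ssnw"

    def test_monotone_with_io(self):
        rng = np.random.default_rng(0)
        ios = np.sort(rng.uniform(0, 30, 500))
        ranks = RS.ombrotype.lookup(ios)
        assert np.all(np.diff(ranks) >= 0)

    def test_partition_sweep(self):
        ios = np.round(np.arange(0.0, 30.01, 0.01), 2)
        assert RS.ombrotype.lookup(ios).shape == ios.shape


class TestCellPipeline:
    def test_desert_steppe_cell(self, fixture_grid):
        grid, targets = fixture_grid
        cells = {c.cell_id: c for c in grid.cells()}
        # locate the engineered MEDC Sme Ari cell by its target labels
        row = targets[(targets.bioclimate == "MEDC")
                      & (targets.thermotype == "Sme")
                      & (targets.ombrotype == "Ari")].iloc[0]
        got = classify_cell(cells[row.cell_id], RS)
        assert got.isobioclimate == "MEDC Sme Ari"
        assert (
            isobioclimate_long_name(got.isobioclimate, RS)
            == "mediterranean desertic continental, supramediterranean, arid"
        )
        assert got.variant == "Stp"

    def test_determinism(self, fixture_grid):
        grid, _ = fixture_grid
        c = next(iter(grid.cells()))
        assert classify_cell(c, RS) == classify_cell(c, RS)

    def test_vectorised_equals_scalar_on_fixtures(self, fixture_grid):
        grid, _ = fixture_grid
        table = classify_grid(grid, RS)
        for i, c in enumerate(grid.cells()):
            ref = classify_cell(c, RS)
            assert table.at[i, "isobioclimate"] == ref.isobioclimate
            assert table.at[i, "variant"] == ref.variant
            assert table.at[i, "macrobioclimate"] == ref.macrobioclimate
            assert table.at[i, "continentality_subtype"] == ref.continentality[1]

    def test_vectorised_equals_scalar_on_synthetic(self, small_grids, small_labels):
        grid, table = small_grids[0], small_labels[0]
        rng = np.random.default_rng(2)
        cells = list(grid.cells())
        for i in rng.choice(len(cells), 60, replace=False):
            ref = classify_cell(cells[i], RS)
            assert table.at[int(i), "isobioclimate"] == ref.isobioclimate
            assert table.at[int(i), "variant"] == ref.variant

    def test_mediterranean_iff_summer_arid(self, small_grids, small_labels):
        from wbcs import compute_indices

        g, lab = small_grids[0], small_labels[0]
        idx = compute_indices(g.tmin, g.tmax, g.prec, g.lat, g.elevation, RS)
        med = (lab["macrobioclimate"] == "MEDITERRANEAN").to_numpy()
        arid = idx["summer_arid"].to_numpy(bool)
        # among warm-enough cells, mediterranean <-> summer aridity
        warm = idx["Tp200"].to_numpy() >= RS.macrobioclimate["boreal_tp200_max"]
        assert np.array_equal(med[warm], arid[warm])
        assert not med[~warm].any()


class TestCatalog:
    def toy(self, codes):
        return pd.DataFrame({"isobioclimate": codes})

    def test_two_codes_two_keys(self):
        cat = build_isobioclimate_catalog([self.toy(["MEDC Sme Ari", "MEXC Mme Sar"])], RS)
        assert set(cat.values()) == {1, 2}

    def test_idempotent_under_no_new_codes(self, small_labels):
        cat12 = build_isobioclimate_catalog(small_labels[:2], RS)
        cat123 = build_isobioclimate_catalog(small_labels[:2] + [small_labels[1]], RS)
        assert cat12 == cat123

    def test_stable_across_runs(self, small_labels):
        a = build_isobioclimate_catalog(small_labels, RS)
        b = build_isobioclimate_catalog(list(reversed(small_labels)), RS)
        assert a == b
        assert sorted(a.values()) == list(range(1, len(a) + 1))
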