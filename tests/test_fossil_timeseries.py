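import numpy as np
import pandas as pd
import pytest

from phenoceiling.energetics import EnergyLine, energy_equivalent_log10
from phenoceiling.exceptions import InvalidArgumentError
from phenoceiling.fossil_timeseries import (
    BinGrid,
    DEFAULT_GRID,
    DEFAULT_REGIMES,
    align_proxies,
    assign_bin,
    bin_extrema,
    build_ceiling,
    build_series_table,
    filter_localities,
    range_through,
    sampling_probability_glires,
)

LAG = EnergyLine(alpha=2.8, beta=-1.2)
UNG = EnergyLine(alpha=2.2, beta=-0.45)


def make_records(rows):
    return pd.DataFrame(rows, columns=[
        "taxon", "genus", "clade", "locality_id",
        "age_max", "age_min", "mass_log10", "mass_se_log10"])


class TestFilterLocalities:
    @pytest.mark.parametrize("age_max,age_min,kept", [
        (50.0, 40.0, False),   # 10 Myr span: excluded
        (36.0, 33.0, True),    # 3 Myr: kept
        (40.2, 36.0, True),    # exactly 4.2 Myr: kept (strict 'exceeding')
        (40.3, 36.0, False),   # just over
    ])
    def test_uncertainty_cutoff(self, age_max, age_min, kept):
        rec = make_records([("t", "g", "lagomorph", "L", age_max, age_min,
                             0.0, 0.0)])
        out = filter_localities(rec)
        assert (len(out) == 1) is kept


class TestAssignBin:
    def test_grid_start_is_bin_zero(self):
        assert assign_bin(43.5) == 0

    def test_interior_age(self):
        # 2.0 Ma lies in the bin spanning 3.0-1.5 Ma
        k = assign_bin(2.0)
        assert DEFAULT_GRID.older_edges[k] == pytest.approx(3.0)
        assert DEFAULT_GRID.older_edges[k] - 1.5 == pytest.approx(1.5)

    def test_boundary_goes_to_older_bin(self):
        assert assign_bin(42.0) == 0
        assert assign_bin(40.5) == 1

    def test_out_of_range(self):
        with pytest.raises(InvalidArgumentError):
            assign_bin(44.0)

    def test_every_age_maps_to_exactly_one_bin(self):
        for age in np.linspace(0, 43.5, 1001):
            k = assign_bin(age)
            assert 0 <= k < DEFAULT_GRID.n_bins


class TestRangeThrough:
    def test_interval_fills_gaps(self):
        assert list(range_through([5, 9])) == [5, 6, 7, 8, 9]

    def test_single_occurrence_single_bin(self):
        assert list(range_through([7])) == [7]

    def test_idempotent_on_duplicates(self):
        assert list(range_through([4, 4])) == [4]

    def test_monotone_in_occurrences(self):
        base = set(range_through([5, 9]))
        more = set(range_through([5, 9, 3]))
        assert base <= more

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            range_through([])


class TestBinExtrema:
    def test_single_bin_toy(self):
        rec = make_records([
            ("Lep a", "Lep", "lagomorph", "L1", 33.1, 32.9,
             np.log10(0.8), 0.0),
            ("Art b", "Art", "artiodactyl", "L1", 33.1, 32.9,
             np.log10(2.0), 0.0),
        ])
        ext = bin_extrema(rec)
        b = assign_bin(33.0)
        assert ext.at[b, "m_maxlag"] == pytest.approx(np.log10(0.8))
        assert ext.at[b, "m_minart"] == pytest.approx(np.log10(2.0))
        assert np.isnan(ext.at[b, "m_minper"])

    def test_empty_bins_absent(self):
        rec = make_records([
            ("Lep a", "Lep", "lagomorph", "L1", 33.1, 32.9, 0.0, 0.0)])
        ext = bin_extrema(rec)
        b = assign_bin(33.0)
        assert ext.drop(index=b).isna().all().all()

    def test_range_through_carries_mass_between_occurrences(self):
        rec = make_records([
            ("Lep a", "Lep", "lagomorph", "L1", 36.1, 35.9, 0.3, 0.0),
            ("Lep a", "Lep", "lagomorph", "L2", 30.1, 29.9, 0.3, 0.0)])
        ext = bin_extrema(rec)
        b1, b2 = assign_bin(36.0), assign_bin(30.0)
        np.testing.assert_allclose(ext["m_maxlag"][b1:b2 + 1], 0.3)


class TestSamplingProbability:
    def test_three_of_four_example(self):
        """3 of 4 range-through genera sampled: p=0.75,
        empirical logit ln(3.5/1.5) ~ 0.847."""
        rows = []
        # genera A, B, C sampled in the bin containing 30.0 Ma
        for g in "ABC":
            rows.append((f"{g} sp", g, "rodent", f"L{g}", 30.1, 29.9,
                         -1.0, 0.0))
        # genus D occurs in the flanking bins only -> range-through
        rows.append(("D sp", "D", "rodent", "LD1", 31.6, 31.4, -1.0, 0.0))
        rows.append(("D sp", "D", "rodent", "LD2", 28.6, 28.4, -1.0, 0.0))
        out = sampling_probability_glires(make_records(rows))
        b = assign_bin(30.0)
        assert out.at[b, "p"] == pytest.approx(0.75)
        assert out.at[b, "r_glires"] == pytest.approx(np.log(3.5 / 1.5))

    def test_all_sampled_finite(self):
        rows = [(f"{g} sp", g, "rodent", f"L{g}", 30.1, 29.9, -1.0, 0.0)
                for g in "ABCD"]
        out = sampling_probability_glires(make_records(rows))
        b = assign_bin(30.0)
        assert out.at[b, "p"] == 1.0
        assert np.isfinite(out.at[b, "r_glires"])
        assert out.at[b, "r_glires"] == pytest.approx(np.log(4.5 / 0.5))

    def test_k_never_exceeds_n(self, scenario):
        out = sampling_probability_glires(scenario["records"])
        assert (out["n_sampled"] <= out["n_genera"]).all()

    def test_empty_bins_nan(self):
        rows = [("A sp", "A", "rodent", "L", 30.1, 29.9, -1.0, 0.0)]
        out = sampling_probability_glires(make_records(rows))
        assert np.isnan(out["r_glires"].drop(index=assign_bin(30.0))).all()


class TestAlignProxies:
    def test_d18o_bin_mean(self):
        grid = BinGrid(start=30.0, width=2.0, n_bins=2)
        d18o = pd.DataFrame({"age": [29.5, 28.5], "value": [1.0, 2.0]})
        out = align_proxies(d18o, None, grid)
        assert out.at[0, "d18o"] == pytest.approx(1.5)
        assert np.isnan(out.at[1, "d18o"])

    def test_hypsodonty_linear_interpolation(self):
        grid = BinGrid(start=30.0, width=2.0, n_bins=2)  # midpoints 29, 27
        h = pd.DataFrame({"age": [30.0, 28.0], "value": [1.0, 2.0]})
        out = align_proxies(None, h, grid)
        assert out.at[0, "h_ung"] == pytest.approx(1.5)  # at 29 Ma
        assert np.isnan(out.at[1, "h_ung"])              # 27 Ma: no extrapolation

    def test_boundary_record_uses_binning_rule(self):
        grid = BinGrid(start=30.0, width=2.0, n_bins=2)
        d18o = pd.DataFrame({"age": [28.0], "value": [3.0]})
        out = align_proxies(d18o, None, grid)
        assert out.at[0, "d18o"] == pytest.approx(3.0)  # older bin
        assert np.isnan(out.at[1, "d18o"])


class TestBuildCeiling:
    def make_extrema(self):
        ext = pd.DataFrame(index=pd.RangeIndex(DEFAULT_GRID.n_bins),
                           columns=["m_maxlag", "m_minart", "m_minper"],
                           dtype=float)
        ext["m_minart"] = 0.2
        ext["m_minper"] = 1.2
        return ext

    def test_perissodactyl_window_uses_energy_equivalence(self):
        ext = self.make_extrema()
        ceil = build_ceiling(ext, LAG, UNG)
        b30 = assign_bin(30.0)
        expected = float(energy_equivalent_log10(LAG, UNG, 1.2))
        assert ceil[b30] == pytest.approx(expected, abs=1e-12)

    def test_artiodactyl_window_passthrough(self):
        ext = self.make_extrema()
        ceil = build_ceiling(ext, LAG, UNG)
        b20 = assign_bin(20.0)
        assert ceil[b20] == pytest.approx(0.2)

    def test_outside_windows_absent(self):
        ext = self.make_extrema()
        ceil = build_ceiling(ext, LAG, UNG)
        assert np.isnan(ceil[assign_bin(42.0)])  # older than all regimes

    def test_missing_source_gives_absent(self):
        ext = self.make_extrema()
        ext["m_minper"] = np.nan
        ceil = build_ceiling(ext, LAG, UNG)
        assert np.isnan(ceil[assign_bin(30.0)])
        assert np.isfinite(ceil[assign_bin(20.0)])

    def test_bad_regime_rejected(self):
        ext = self.make_extrema()
        with pytest.raises(InvalidArgumentError):
            build_ceiling(ext, LAG, UNG, regimes=[(10.0, 20.0, "x")])


class TestPipelineProperties:
    def test_filter_bin_commutes(self, scenario):
        rec = scenario["records"]
        a = bin_extrema(filter_localities(rec))
        filtered = filter_localities(rec)
        b = bin_extrema(filtered)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_noise_full_series_reproduces_truth(self, noiseless_scenario):
        scen = noiseless_scenario
        table = build_series_table(
            scen["records"], scen["line_lag"], scen["line_ung"],
            d18o=scen["proxies"]["d18o"], h_ung=scen["proxies"]["h_ung"],
            grid=scen["grid"])
        truth = scen["truth"]
        occupied = np.isfinite(truth["m_maxlag"])
        np.testing.assert_allclose(table["m_maxlag"][occupied],
                                   truth["m_maxlag"][occupied], atol=1e-10)
        np.testing.assert_allclose(table["m_minper"][occupied],
                                   truth["m_minper"][occupied], atol=1e-10)
        np.testing.assert_allclose(table["r_glires"][occupied],
                                   truth["r_glires"][occupied], atol=1e-10)
        np.testing.assert_allclose(table["m_ceiling"][occupied],
                                   truth["m_ceiling"][occupied], atol=1e-10)
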