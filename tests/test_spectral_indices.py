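"""Index formulas, band lookup, CSV validation, and the symbol-by-symbol oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saltspec import indices
from saltspec.exceptions import BandMissingError, FormatError, SaltspecError
from saltspec.spectra import SpectraSet, read_spectra_csv


def make_spectra(values_by_nm=None, fill=0.5, grid=None, n_plots=1):
    """A SpectraSet with constant reflectance except at specified bands."""
    if grid is None:
        grid = np.arange(350.0, 2501.0)
    refl = np.full((n_plots, grid.size), fill, dtype=float)
    for nm, value in (values_by_nm or {}).items():
        refl[:, int(np.argmin(np.abs(grid - nm)))] = value
    meta = pd.DataFrame({"plot_id": [f"P{i}" for i in range(n_plots)],
                         "genotype": "G", "season": "S1", "replicate": 1})
    return SpectraSet(grid, refl, meta)


# ---------------------------------------------------------------------------
# independent symbol-by-symbol oracle (distinct code path from the registry)
# ---------------------------------------------------------------------------

def oracle(R, name):
    """Evaluate one index directly from its published band formula."""
    nd = lambda a, b: (R(a) - R(b)) / (R(a) + R(b))
    if name == "BNDVI":
        return nd(1245, 415)
    if name == "GNDVI":
        return nd(1245, 550)
    if name == "RNDVI":
        return nd(1245, 680)
    if name == "Chl_red-edge":
        return R(760) / R(710) - 1
    if name == "EVI":
        return 2.5 * ((R(782) - R(675)) / (R(782) + 6 * R(675) - 7.5 * R(445) + 1))
    if name == "MTVI":
        return 1.2 * (1.2 * (R(800) - R(550)) - 2.5 * (R(670) - R(550)))
    if name == "OSAVI":
        return 1.16 * (R(800) - R(670)) / (R(800) + R(670) + 0.16)
    if name == "RWI":
        return R(970) / R(900)
    if name == "NWI":
        return nd(970, 850)
    if name == "NDWI":
        return nd(737, 1360)
    if name == "NDMI":
        return nd(2200, 1100)
    if name == "DMCI":
        return nd(2305, 1495)
    if name == "NMDI":
        return (R(860) - (R(1640) - R(2130))) / (R(860) + (R(1640) - R(2130)))
    if name == "SWSI":
        return (R(803) - R(681)) / np.sqrt(R(1326) - R(1507))
    raise KeyError(name)


FLAT_EXPECTED = {
    "BNDVI": 0.0, "GNDVI": 0.0, "RNDVI": 0.0, "Chl_red-edge": 0.0, "EVI": 0.0,
    "MTVI": 0.0, "OSAVI": 0.0, "RWI": 1.0, "NWI": 0.0, "NDWI": 0.0,
    "NDMI": 0.0, "DMCI": 0.0, "NMDI": 1.0,
}

RATIO_TYPE = ["BNDVI", "GNDVI", "RNDVI", "Chl_red-edge", "RWI", "NWI", "NDWI",
              "NDMI", "DMCI", "NMDI"]
SCALE_SENSITIVE = ["EVI", "MTVI", "OSAVI", "SWSI"]
ND_TYPE = ["BNDVI", "GNDVI", "RNDVI", "NWI", "NDWI", "NDMI", "DMCI"]


class TestFormulas:
    @pytest.mark.parametrize("name,expected", sorted(FLAT_EXPECTED.items()))
    def test_flat_spectrum_identities(self, name, expected):
        s = make_spectra(fill=0.5)
        assert compute_one(s, name) == pytest.approx(expected, abs=1e-12)

    def test_flat_spectrum_swsi_is_flagged_missing(self):
        s = make_spectra(fill=0.5)
        with pytest.warns(RuntimeWarning, match="radicand"):
            assert np.isnan(compute_one(s, "SWSI"))

    def test_bndvi_hand_value(self):
        s = make_spectra({1245: 0.45, 415: 0.05})
        assert compute_one(s, "BNDVI") == pytest.approx(0.8, abs=1e-12)

    def test_swsi_hand_value(self):
        s = make_spectra({803: 0.5, 681: 0.1, 1326: 0.30, 1507: 0.14})
        assert compute_one(s, "SWSI") == pytest.approx(1.0, abs=1e-12)

    def test_zero_denominator_flags_missing_not_raises(self):
        s = make_spectra({1245: 0.2, 415: -0.2})
        with pytest.warns(RuntimeWarning, match="denominator"):
            assert np.isnan(compute_one(s, "BNDVI"))

    def test_equals_symbol_by_symbol_oracle_on_random_spectra(self):
        rng = np.random.default_rng(42)
        grid = np.arange(350.0, 2501.0)
        refl = rng.uniform(0.05, 0.95, size=(100, grid.size))
        meta = pd.DataFrame({"plot_id": [f"P{i}" for i in range(100)],
                             "genotype": "G", "season": "S1", "replicate": 1})
        s = SpectraSet(grid, refl, meta)
        lookup = {nm: s.reflectance_at(nm) for nm in indices.ALL_BANDS}
        for name in indices.ALL_INDEX_NAMES:
            with np.errstate(invalid="ignore"):
                expected = oracle(lambda nm: lookup[nm], name)
            with pytest.warns(RuntimeWarning) if name == "SWSI" else _nullcontext():
                got = indices.compute_index(s, name)
            mask = np.isfinite(expected)
            assert np.isnan(got[~mask]).all()
            np.testing.assert_allclose(got[mask], expected[mask], atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.1, 10.0))
    def test_scale_invariance_splits_the_registry(self, c):
        rng = np.random.default_rng(7)
        grid = np.arange(350.0, 2501.0)
        base = rng.uniform(0.2, 0.8, size=grid.size)
        meta = pd.DataFrame({"plot_id": ["P0"], "genotype": "G",
                             "season": "S1", "replicate": 1})
        s1 = SpectraSet(grid, base[None, :], meta)
        s2 = SpectraSet(grid, c * base[None, :], meta)
        for name in RATIO_TYPE:
            assert compute_one(s2, name) == pytest.approx(compute_one(s1, name),
                                                          rel=1e-9, abs=1e-12)
        if abs(c - 1.0) > 1e-3:
            for name in SCALE_SENSITIVE:
                a, b = compute_one(s1, name), compute_one(s2, name)
                if np.isfinite(a) and np.isfinite(b):
                    assert a != pytest.approx(b, rel=1e-6)

    def test_normalized_difference_indices_bounded(self):
        rng = np.random.default_rng(3)
        grid = np.arange(350.0, 2501.0)
        refl = rng.uniform(1e-4, 1.0, size=(50, grid.size))
        meta = pd.DataFrame({"plot_id": [f"P{i}" for i in range(50)],
                             "genotype": "G", "season": "S1", "replicate": 1})
        s = SpectraSet(grid, refl, meta)
        for name in ND_TYPE:
            values = indices.compute_index(s, name)
            assert np.all(values >= -1) and np.all(values <= 1)


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


def compute_one(s, name):
    return float(indices.compute_index(s, name)[0])


class TestBandLookup:
    def test_exact_hit(self):
        s = make_spectra({970: 0.7})
        assert s.reflectance_at(970)[0] == 0.7

    def test_tie_goes_to_lower_wavelength(self):
        grid = np.arange(349.0, 2502.0, 2.0)  # 349, 351, ..., so 970 ties 969/971
        s = make_spectra({969: 0.61, 971: 0.62}, grid=grid)
        assert s.reflectance_at(970, tolerance=1.0)[0] == 0.61

    def test_out_of_range_raises(self):
        s = make_spectra()
        with pytest.raises(BandMissingError):
            s.reflectance_at(3000)


class TestIndexTable:
    def test_fixture_spectra_full_table(self, spectra_set):
        table = indices.compute_index_table(spectra_set)
        assert table.shape == (144, 4 + 14)
        assert np.isfinite(table[list(indices.ALL_INDEX_NAMES)].to_numpy()).all()

    def test_empty_request_returns_metadata_only(self, spectra_set):
        table = indices.compute_index_table(spectra_set, names=[])
        assert list(table.columns) == ["plot_id", "genotype", "season", "replicate"]

    def test_unknown_name_lists_registry(self, spectra_set):
        with pytest.raises(SaltspecError, match="BNDVI"):
            indices.compute_index_table(spectra_set, names=["NDVI42"])


class TestSpectraCsv:
    def test_fixture_round_trip(self, fixture_bundle):
        s = read_spectra_csv(fixture_bundle["spectra"])
        assert s.n_plots == 144 and s.wavelengths.size == 2151

    def test_shuffled_wavelength_columns_are_sorted(self, tmp_path):
        df = pd.DataFrame({"plot_id": ["P0"], "genotype": ["G"], "season": ["S1"],
                           "replicate": [1], "w500": [0.5], "w350": [0.1],
                           "w420": [0.3]})
        path = tmp_path / "s.csv"
        df.to_csv(path, index=False)
        s = read_spectra_csv(path)
        assert s.wavelengths.tolist() == [350.0, 420.0, 500.0]
        assert s.reflectance[0].tolist() == [0.1, 0.3, 0.5]

    def test_non_numeric_cell_names_plot_and_wavelength(self, tmp_path):
        df = pd.DataFrame({"plot_id": ["P7"], "genotype": ["G"], "season": ["S1"],
                           "replicate": [1], "w350": ["NA"], "w351": [0.2]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(FormatError, match=r"P7.*350"):
            read_spectra_csv(path)
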