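"""The fourteen spectral reflectance indices (SRIs) used for salt-tolerance screening.

Seven vegetation indices (pigment / biomass / red-edge sensitive) and seven
water indices (NIR and SWIR water-absorption sensitive). All are simple band
arithmetic on raw reflectance; ``R(nm)`` denotes the reflectance at the grid
band nearest the requested wavelength (1 nm tolerance, no interpolation).

Two printed-formula quirks are handled explicitly:

* NMDI is computed as ``(R860 - (R1640 - R2130)) / (R860 + (R1640 - R2130))``;
  the constant-860 reading is dimensionally inconsistent and collapses to ~1.
* SWSI divides by ``sqrt(R1326 - R1507)``; when the radicand is <= 0 the index
  is returned as a flagged missing value (NaN) with a warning rather than a
  complex number.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import SaltspecError
from .spectra import METADATA_COLUMNS, SpectraSet

logger = logging.getLogger(__name__)

# Band getter: maps nm -> per-plot reflectance vector.
Bands = Callable[[float], np.ndarray]


def _safe_div(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = den == 0
    if np.any(bad):
        warnings.warn(f"{name}: zero denominator in {int(bad.sum())} plot(s); "
                      "flagged as missing", RuntimeWarning, stacklevel=3)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, num / np.where(bad, 1.0, den))
    return out


def _nd(r: Bands, a: float, b: float, name: str) -> np.ndarray:
    """Normalized difference (R_a - R_b)/(R_a + R_b)."""
    ra, rb = r(a), r(b)
    return _safe_div(ra - rb, ra + rb, name)


def _bndvi(r: Bands) -> np.ndarray:
    return _nd(r, 1245, 415, "BNDVI")


def _gndvi(r: Bands) -> np.ndarray:
    return _nd(r, 1245, 550, "GNDVI")


def _rndvi(r: Bands) -> np.ndarray:
    return _nd(r, 1245, 680, "RNDVI")


def _chl_red_edge(r: Bands) -> np.ndarray:
    return _safe_div(r(760), r(710), "Chl_red-edge") - 1.0


def _evi(r: Bands) -> np.ndarray:
    return 2.5 * _safe_div(r(782) - r(675), r(782) + 6 * r(675) - 7.5 * r(445) + 1, "EVI")


def _mtvi(r: Bands) -> np.ndarray:
    return 1.2 * (1.2 * (r(800) - r(550)) - 2.5 * (r(670) - r(550)))


def _osavi(r: Bands) -> np.ndarray:
    return 1.16 * _safe_div(r(800) - r(670), r(800) + r(670) + 0.16, "OSAVI")


def _rwi(r: Bands) -> np.ndarray:
    return _safe_div(r(970), r(900), "RWI")


def _nwi(r: Bands) -> np.ndarray:
    return _nd(r, 970, 850, "NWI")


def _ndwi(r: Bands) -> np.ndarray:
    return _nd(r, 737, 1360, "NDWI")


def _ndmi(r: Bands) -> np.ndarray:
    return _nd(r, 2200, 1100, "NDMI")


def _dmci(r: Bands) -> np.ndarray:
    return _nd(r, 2305, 1495, "DMCI")


def _nmdi(r: Bands) -> np.ndarray:
    diff = r(1640) - r(2130)
    return _safe_div(r(860) - diff, r(860) + diff, "NMDI")


def _swsi(r: Bands) -> np.ndarray:
    radicand = r(1326) - r(1507)
    bad = radicand <= 0
    if np.any(bad):
        warnings.warn(f"SWSI: non-positive radicand R1326-R1507 in {int(bad.sum())} "
                      "plot(s); flagged as missing", RuntimeWarning, stacklevel=3)
    with np.errstate(invalid="ignore"):
        root = np.where(bad, np.nan, np.sqrt(np.where(bad, 1.0, radicand)))
    return _safe_div(r(803) - r(681), root, "SWSI")


@dataclass(frozen=True)
class SRIDefinition:
    """One registered index: name, category, bands used, and its evaluator."""

    name: str
    category: str  # 'vegetation' | 'water'
    bands: tuple[float, ...]
    func: Callable[[Bands], np.ndarray]


SRI_REGISTRY: dict[str, SRIDefinition] = {
    d.name: d
    for d in [
        SRIDefinition("BNDVI", "vegetation", (1245, 415), _bndvi),
        SRIDefinition("GNDVI", "vegetation", (1245, 550), _gndvi),
        SRIDefinition("RNDVI", "vegetation", (1245, 680), _rndvi),
        SRIDefinition("Chl_red-edge", "vegetation", (760, 710), _chl_red_edge),
        SRIDefinition("EVI", "vegetation", (782, 675, 445), _evi),
        SRIDefinition("MTVI", "vegetation", (800, 550, 670), _mtvi),
        SRIDefinition("OSAVI", "vegetation", (800, 670), _osavi),
        SRIDefinition("RWI", "water", (970, 900), _rwi),
        SRIDefinition("NWI", "water", (970, 850), _nwi),
        SRIDefinition("NDWI", "water", (737, 1360), _ndwi),
        SRIDefinition("NDMI", "water", (2200, 1100), _ndmi),
        SRIDefinition("DMCI", "water", (2305, 1495), _dmci),
        SRIDefinition("NMDI", "water", (860, 1640, 2130), _nmdi),
        SRIDefinition("SWSI", "water", (803, 681, 1326, 1507), _swsi),
    ]
}

ALL_INDEX_NAMES: tuple[str, ...] = tuple(SRI_REGISTRY)
ALL_BANDS: tuple[float, ...] = tuple(sorted({b for d in SRI_REGISTRY.values() for b in d.bands}))


def compute_index(spectra: SpectraSet, name: str, band_tolerance: float = 1.0) -> np.ndarray:
    """Evaluate one registered index for every plot in ``spectra``."""
    if name not in SRI_REGISTRY:
        raise SaltspecError(
            f"unknown index {name!r}; registered: {', '.join(ALL_INDEX_NAMES)}"
        )
    cache: dict[float, np.ndarray] = {}

    def r(nm: float) -> np.ndarray:
        if nm not in cache:
            cache[nm] = spectra.reflectance_at(nm, tolerance=band_tolerance)
        return cache[nm]

    return np.asarray(SRI_REGISTRY[name].func(r), dtype=float)


def compute_index_table(
    spectra: SpectraSet,
    names: Sequence[str] | None = None,
    band_tolerance: float = 1.0,
) -> pd.DataFrame:
    """Compute the requested indices (default: all 14) for every plot.

    Returns a table with the plot metadata followed by one column per index.
    Missing values (guarded denominators / radicands) are kept as NaN and
    counted in the log, never dropped.
    """
    if names is None:
        names = ALL_INDEX_NAMES
    unknown = [n for n in names if n not in SRI_REGISTRY]
    if unknown:
        raise SaltspecError(
            f"unknown index name(s) {unknown}; registered: {', '.join(ALL_INDEX_NAMES)}"
        )
    out = spectra.metadata[METADATA_COLUMNS].copy()
    for name in names:
        values = compute_index(spectra, name, band_tolerance=band_tolerance)
        n_missing = int(np.isnan(values).sum())
        if n_missing:
            logger.warning("index %s: %d missing value(s) out of %d plots",
                           name, n_missing, spectra.n_plots)
        out[name] = values
    return out


def required_bands(names: Iterable[str] | None = None) -> tuple[float, ...]:
    """All wavelengths needed to evaluate the given (default: all) indices."""
    if names is None:
        return ALL_BANDS
    return tuple(sorted({b for n in names for b in SRI_REGISTRY[n].bands}))
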