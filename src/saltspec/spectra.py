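"""Canopy reflectance spectra: container, band lookup, and wide-CSV I/O.

A spectrum is one reflectance vector per field plot on a common, strictly
ascending wavelength grid (nm). The field instrument delivers 350-2500 nm at a
1 nm interval, so band extraction is nearest-neighbour with a 1 nm tolerance
and no interpolation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import BandMissingError, FormatError

METADATA_COLUMNS = ["plot_id", "genotype", "season", "replicate"]

_WL_RE = re.compile(r"^w(\d+(?:\.\d+)?)$")


@dataclass
class SpectraSet:
    """Per-plot reflectance matrix plus plot metadata.

    Parameters
    ----------
    wavelengths : array of nm, strictly ascending.
    reflectance : (n_plots, n_wavelengths) array of reflectance fractions.
    metadata : DataFrame with columns plot_id, genotype, season, replicate,
        row-aligned with ``reflectance``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    metadata: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise FormatError("wavelength grid must be a non-empty 1-D array")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise FormatError("wavelength grid must be strictly ascending")
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise FormatError(
                f"reflectance has {self.reflectance.shape[1]} columns but the grid "
                f"has {self.wavelengths.size} wavelengths"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise FormatError("reflectance contains non-finite values")
        self.metadata = self.metadata.reset_index(drop=True)
        if len(self.metadata) != self.reflectance.shape[0]:
            raise FormatError("metadata rows do not align with reflectance rows")
        missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing:
            raise FormatError(f"metadata is missing columns: {missing}")

    @property
    def n_plots(self) -> int:
        return self.reflectance.shape[0]

    def band_index(self, target_nm: float, tolerance: float = 1.0) -> int:
        """Index of the grid wavelength nearest ``target_nm`` (ties to lower).

        Raises :class:`BandMissingError` if the nearest grid point is farther
        than ``tolerance`` nm.
        """
        wl = self.wavelengths
        pos = int(np.searchsorted(wl, target_nm))
        candidates = [i for i in (pos - 1, pos) if 0 <= i < wl.size]
        # lower wavelength first, so '<' keeps it on distance ties
        best = min(candidates, key=lambda i: abs(wl[i] - target_nm))
        if abs(wl[best] - target_nm) > tolerance:
            raise BandMissingError(
                f"no grid wavelength within {tolerance} nm of {target_nm} nm "
                f"(grid spans {wl[0]:g}-{wl[-1]:g} nm)"
            )
        return best

    def reflectance_at(self, target_nm: float, tolerance: float = 1.0) -> np.ndarray:
        """Reflectance of every plot at the grid band nearest ``target_nm``."""
        return self.reflectance[:, self.band_index(target_nm, tolerance)]

    def to_dataframe(self) -> pd.DataFrame:
        """Wide table: metadata columns then one ``w<nm>`` column per band."""
        cols = {f"w{wl:g}": self.reflectance[:, j] for j, wl in enumerate(self.wavelengths)}
        return pd.concat([self.metadata[METADATA_COLUMNS], pd.DataFrame(cols)], axis=1)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def read_spectra_csv(path) -> SpectraSet:
    """Load a wide spectra CSV (``plot_id, genotype, season, replicate, w350, ...``).

    Wavelength columns are sorted ascending on load; non-numeric reflectance
    cells are rejected with the offending plot and wavelength named.
    """
    try:
        raw = pd.read_csv(path)
    except OSError as exc:  # pragma: no cover - passthrough with context
        raise FormatError(f"cannot read spectra file {path}: {exc}") from exc
    missing = [c for c in METADATA_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    wl_cols = [(float(m.group(1)), c) for c in raw.columns if (m := _WL_RE.match(str(c)))]
    if not wl_cols:
        raise FormatError(f"{path}: no wavelength columns of the form 'w<nm>' found")
    wl_cols.sort(key=lambda t: t[0])
    wavelengths = np.array([t[0] for t in wl_cols])
    values = np.empty((len(raw), len(wl_cols)))
    for j, (wl, col) in enumerate(wl_cols):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            plot = raw.loc[bad.idxmax(), "plot_id"]
            raise FormatError(
                f"{path}: non-numeric reflectance for plot_id={plot!r} at {wl:g} nm"
            )
        values[:, j] = numeric.to_numpy()
    return SpectraSet(wavelengths, values, raw[METADATA_COLUMNS].copy())
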