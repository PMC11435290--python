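"""Destructive laboratory assays: leaf water status, chlorophyll, and group means.

Leaf relative water content (LRWC) is computed from fresh, turgid and dry
section weights as ``100 * (FW - DW) / (TW - DW)``. Total chlorophyll comes
from the acetone-extract absorbances at 645 and 663 nm,
``Chlt = 20.21 * A645 + 8.02 * A663`` (ug per mL of extract); when the extract
volume and the fresh sample mass are supplied, the concentration is also
expressed per gram of fresh weight. Published trait tables report
mg g^-1 FW but never state the conversion used, so both values are exposed
rather than guessing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SaltspecError


def leaf_relative_water_content(fresh_weight, turgid_weight, dry_weight):
    """LRWC (%) from section weights; scalar or elementwise on arrays.

    Weight units cancel, so grams and milligrams give identical results.
    A fresh weight outside [DW, TW] is physically suspect (field noise) and
    warns but still yields a value, preserving plot counts for the balanced
    ANOVA. TW == DW is degenerate and raises.
    """
    fw = np.asarray(fresh_weight, dtype=float)
    tw = np.asarray(turgid_weight, dtype=float)
    dw = np.asarray(dry_weight, dtype=float)
    if np.any(tw == dw):
        raise SaltspecError("degenerate sample: turgid weight equals dry weight")
    out_of_range = (fw < np.minimum(dw, tw)) | (fw > np.maximum(dw, tw))
    if np.any(out_of_range):
        warnings.warn(
            f"{int(np.sum(out_of_range))} sample(s) have FW outside [DW, TW]; "
            "values returned unchanged", RuntimeWarning, stacklevel=2)
    result = 100.0 * (fw - dw) / (tw - dw)
    return float(result) if result.ndim == 0 else result


def total_chlorophyll(a645, a663, extract_volume_ml=None, sample_mass_g=None):
    """Total chlorophyll from extract absorbances.

    Returns the extract concentration ``20.21*A645 + 8.02*A663`` in ug mL^-1.
    If both ``extract_volume_ml`` and ``sample_mass_g`` are given, returns a
    ``(ug_per_ml, mg_per_g_fw)`` pair where
    ``mg_per_g_fw = ug_per_ml * volume / (1000 * mass)``.
    """
    a645 = np.asarray(a645, dtype=float)
    a663 = np.asarray(a663, dtype=float)
    raw = 20.21 * a645 + 8.02 * a663
    raw_out = float(raw) if raw.ndim == 0 else raw
    if extract_volume_ml is None and sample_mass_g is None:
        return raw_out
    if extract_volume_ml is None or sample_mass_g is None:
        raise ConfigurationError(
            "extract_volume_ml and sample_mass_g must be given together")
    if np.any(np.asarray(extract_volume_ml) <= 0) or np.any(np.asarray(sample_mass_g) <= 0):
        raise ConfigurationError("extract volume and sample mass must be positive")
    per_g = raw * extract_volume_ml / (1000.0 * sample_mass_g)
    return raw_out, (float(per_g) if np.ndim(per_g) == 0 else per_g)


def genotype_means(
    table: pd.DataFrame,
    by: str | tuple[str, ...] = "genotype",
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean of each numeric variable per genotype (or genotype x season).

    Idempotent on already-aggregated tables. Returns one row per group with a
    trailing ``n_plots`` column giving the group size; empty groups cannot
    arise from a groupby and pandas drops NaN keys with a warning here.
    """
    keys = [by] if isinstance(by, str) else list(by)
    missing = [k for k in keys if k not in table.columns]
    if missing:
        raise SaltspecError(f"grouping column(s) {missing} not in table")
    if value_columns is None:
        drop = set(keys) | {"plot_id", "replicate", "season"}
        value_columns = [
            c for c in table.columns
            if c not in drop and pd.api.types.is_numeric_dtype(table[c])
        ]
    if table[keys].isna().any().any():
        warnings.warn("rows with missing group labels are excluded", RuntimeWarning,
                      stacklevel=2)
    grouped = table.groupby(keys, sort=False, dropna=True)
    means = grouped[value_columns].mean().reset_index()
    means["n_plots"] = grouped.size().to_numpy()
    return means
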