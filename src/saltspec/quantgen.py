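"""Quantitative genetics of a two-season RCBD salinity trial.

Combined-season analysis of variance (season fixed, genotype random,
replication nested in season), Tukey HSD letter groups, variance components
from expected mean squares, and the derived genetic parameters:

* broad-sense heritability ``h2 = var_g / (var_g + var_gs/y + var_e/(y*r))``
* genotypic / phenotypic coefficients of variation ``100*sqrt(var)/mean``
  (signed by the mean, so negative-mean indices carry negative CVs)
* genetic advance under truncation selection ``GA = k * h2 * sigma_p`` and
  genetic gain ``GG = 100*GA/mean``, with ``k = phi(z_p)/p`` the standardized
  selection differential (2.06 at 5% selected).

All sums of squares are closed-form cell-mean decompositions, valid because
the design is required to be balanced; unbalanced layouts are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import BalanceError, ConfigurationError, SaltspecError

__all__ = [
    "anova_single_season", "anova_combined", "tukey_letters",
    "variance_components", "heritability", "coefficient_of_variation",
    "selection_intensity", "genetic_gain", "genetic_parameter_table",
    "VarianceComponents", "RCBDModel", "RCBDResults",
]


def _check_balance(table: pd.DataFrame, variable: str, keys: list[str]) -> None:
    if variable not in table.columns:
        raise SaltspecError(f"variable {variable!r} not in table")
    counts = table.groupby(keys, sort=False).size()
    if counts.nunique() != 1:
        offending = counts[counts != counts.mode().iloc[0]]
        raise BalanceError(
            f"unbalanced design for {variable!r}: cell counts differ at "
            f"{offending.index.tolist()[:5]}")
    full = 1
    for k in keys:
        full *= table[k].nunique()
    if len(counts) != full:
        raise BalanceError(f"missing cells for {variable!r}: expected {full} "
                           f"{'x'.join(keys)} cells, found {len(counts)}")


def _anova_frame(terms, dfs, sss) -> pd.DataFrame:
    ms = [ss / df if df > 0 else np.nan for ss, df in zip(sss, dfs)]
    err_ms = ms[-1]
    out = pd.DataFrame({"df": dfs, "sum_sq": sss, "mean_sq": ms}, index=terms)
    f_vals, p_vals = [], []
    for term, m in zip(terms, ms):
        if term == "error" or not np.isfinite(err_ms) or err_ms == 0:
            f_vals.append(np.nan)
            p_vals.append(np.nan)
        else:
            f = m / err_ms
            f_vals.append(f)
            p_vals.append(stats.f.sf(f, out.loc[term, "df"], out.loc["error", "df"]))
    out["F"] = f_vals
    out["p"] = p_vals
    return out


def anova_single_season(
    table: pd.DataFrame,
    variable: str,
    season=None,
    genotype_col: str = "genotype",
    season_col: str = "season",
    rep_col: str = "replicate",
) -> pd.DataFrame:
    """Single-season RCBD ANOVA: replication, genotype, error.

    ``season`` selects the rows when the table spans several seasons.
    """
    data = table if season is None else table[table[season_col] == season]
    if season is not None and data.empty:
        raise SaltspecError(f"no rows for season {season!r}")
    if season is None and season_col in data.columns and data[season_col].nunique() > 1:
        raise SaltspecError("table spans several seasons; pass season=...")
    _check_balance(data, variable, [genotype_col, rep_col])
    y = data[variable].to_numpy(float)
    grand = y.mean()
    total_ss = float(np.sum((y - grand) ** 2))
    rep_means = data.groupby(rep_col)[variable].mean()
    geno_means = data.groupby(genotype_col)[variable].mean()
    g, r = len(geno_means), len(rep_means)
    ss_r = g * float(np.sum((rep_means - grand) ** 2))
    ss_g = r * float(np.sum((geno_means - grand) ** 2))
    ss_e = max(total_ss - ss_r - ss_g, 0.0)
    frame = _anova_frame(["replication", "genotype", "error"],
                         [r - 1, g - 1, (r - 1) * (g - 1)], [ss_r, ss_g, ss_e])
    frame.attrs.update(n_genotypes=g, n_reps=r, n_seasons=1)
    return frame


def anova_combined(
    table: pd.DataFrame,
    variable: str,
    genotype_col: str = "genotype",
    season_col: str = "season",
    rep_col: str = "replicate",
) -> pd.DataFrame:
    """Combined two-(or more-)season RCBD ANOVA.

    Terms: season (S), replication within season R(S), genotype (G), S x G,
    error; all F ratios are against the pooled error mean square.
    """
    for col in (genotype_col, season_col, rep_col):
        if col not in table.columns:
            raise SaltspecError(f"column {col!r} not in table")
    if table[season_col].nunique() < 2:
        raise SaltspecError("single season supplied; use anova_single_season")
    _check_balance(table, variable, [genotype_col, season_col, rep_col])
    y = table[variable].to_numpy(float)
    grand = y.mean()
    total_ss = float(np.sum((y - grand) ** 2))
    season_means = table.groupby(season_col)[variable].mean()
    geno_means = table.groupby(genotype_col)[variable].mean()
    sr_means = table.groupby([season_col, rep_col])[variable].mean()
    sg_means = table.groupby([season_col, genotype_col])[variable].mean()
    ny, g = len(season_means), len(geno_means)
    r = len(sr_means) // ny
    n = len(y)
    ss_s = (n // ny) * float(np.sum((season_means - grand) ** 2))
    ss_rs = g * float(np.sum((sr_means - sr_means.index.get_level_values(0)
                              .map(season_means)) ** 2))
    ss_g = ny * r * float(np.sum((geno_means - grand) ** 2))
    sg = sg_means.reset_index(name="m")
    sg["expect"] = (sg[season_col].map(season_means) + sg[genotype_col].map(geno_means)
                    - grand)
    ss_sg = r * float(np.sum((sg["m"] - sg["expect"]) ** 2))
    ss_e = max(total_ss - ss_s - ss_rs - ss_g - ss_sg, 0.0)
    dfs = [ny - 1, ny * (r - 1), g - 1, (ny - 1) * (g - 1)]
    dfs.append(n - 1 - sum(dfs))
    frame = _anova_frame(
        ["season", "rep_within_season", "genotype", "season_x_genotype", "error"],
        dfs, [ss_s, ss_rs, ss_g, ss_sg, ss_e])
    frame.attrs.update(n_genotypes=g, n_reps=r, n_seasons=ny)
    return frame


def tukey_letters(
    means: pd.Series,
    ms_error: float,
    df_error: int,
    n_per_mean: int,
    alpha: float = 0.05,
) -> pd.Series:
    """Compact letter display from Tukey's honestly significant difference.

    ``HSD = q(1-alpha; g, df_error) * sqrt(MSE / n)``; means are scanned in
    descending order and maximal runs of mutually non-significant means share
    a letter (insert-and-absorb). Means within HSD of each other always share
    at least one letter.
    """
    if n_per_mean <= 0:
        raise ConfigurationError("n_per_mean must be positive")
    if df_error < 1:
        raise ConfigurationError("df_error must be >= 1")
    means = means.astype(float).sort_values(ascending=False)
    g = len(means)
    if g == 1:
        return pd.Series(["a"], index=means.index)
    hsd = stats.studentized_range.ppf(1 - alpha, g, df_error) * np.sqrt(ms_error / n_per_mean)
    values = means.to_numpy()
    # for each mean, the furthest (descending-sorted) mean it does not differ from
    spans = []
    for i in range(g):
        j = i
        while j + 1 < g and values[i] - values[j + 1] <= hsd:
            j += 1
        spans.append((i, j))
    # keep maximal spans only (absorb contained ones)
    maximal = [s for s in spans if not any(o[0] <= s[0] and s[1] <= o[1] and o != s
                                           for o in spans)]
    maximal = sorted(set(maximal))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(g)]
    for rank, (lo, hi) in enumerate(maximal):
        letter = alphabet[rank % len(alphabet)] * (1 + rank // len(alphabet))
        for i in range(lo, hi + 1):
            letters[i] += letter
    return pd.Series(letters, index=means.index)


@dataclass(frozen=True)
class VarianceComponents:
    """Genotypic, genotype-by-season and residual variances plus their sum.

    ``var_p`` is the phenotypic variance on a genotype-mean basis,
    ``var_g + var_gy/y + var_e/(y*r)`` — the heritability denominator.
    """

    var_g: float
    var_gy: float
    var_e: float
    n_reps: int
    n_seasons: int
    truncated: tuple[str, ...] = ()

    @property
    def var_p(self) -> float:
        return self.var_g + self.var_gy / self.n_seasons + self.var_e / (
            self.n_seasons * self.n_reps)


def variance_components(
    combined: pd.DataFrame,
    n_reps: int | None = None,
    n_seasons: int | None = None,
    method: str = "ems",
) -> VarianceComponents:
    """Variance components from a combined ANOVA table.

    ``method='ems'`` (default) solves the expected mean squares of the
    genotype-random, season-fixed model: ``var_g = (MS_G - MS_GxS)/(r*y)``,
    ``var_gy = (MS_GxS - MS_e)/r``. ``method='single_stratum'`` reproduces the
    single-factor textbook shortcut ``var_g = (MS_G - MS_e)/r`` sometimes
    quoted in field-trial reports; it ignores the interaction stratum and is
    kept only for comparison. Negative estimates are clipped to zero and
    flagged in ``truncated``.
    """
    r = n_reps if n_reps is not None else combined.attrs.get("n_reps")
    y = n_seasons if n_seasons is not None else combined.attrs.get("n_seasons")
    if not r or not y:
        raise ConfigurationError("replicate and season counts are required")
    g = combined.attrs.get("n_genotypes")
    if g and combined.loc["genotype", "df"] != g - 1:
        raise ConfigurationError("genotype df inconsistent with genotype count")
    if combined.loc["error", "df"] <= 0:
        raise ConfigurationError("error stratum has no degrees of freedom")
    ms_g = combined.loc["genotype", "mean_sq"]
    ms_gs = combined.loc["season_x_genotype", "mean_sq"]
    ms_e = combined.loc["error", "mean_sq"]
    if method == "ems":
        var_g = (ms_g - ms_gs) / (r * y)
        var_gy = (ms_gs - ms_e) / r
    elif method == "single_stratum":
        var_g = (ms_g - ms_e) / r
        var_gy = (ms_gs - ms_e) / r
    else:
        raise ConfigurationError(f"unknown variance-component method {method!r}")
    truncated = []
    if var_g < 0:
        var_g, truncated = 0.0, truncated + ["var_g"]
    if var_gy < 0:
        var_gy, truncated = 0.0, truncated + ["var_gy"]
    return VarianceComponents(float(var_g), float(var_gy), float(ms_e),
                              int(r), int(y), tuple(truncated))


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability ``var_g / var_p`` as a fraction in [0, 1]."""
    if vc.var_p == 0:
        return 0.0
    return float(vc.var_g / vc.var_p)


def coefficient_of_variation(variance: float, mean: float) -> float:
    """``100 * sqrt(variance) / mean`` (%); inherits the sign of the mean."""
    if variance < 0:
        raise ConfigurationError("variance must be non-negative")
    if mean == 0:
        raise SaltspecError("coefficient of variation undefined for zero mean")
    return float(100.0 * np.sqrt(variance) / mean)


def selection_intensity(p: float) -> float:
    """Standardized selection differential ``k = phi(z_p) / p``.

    ``z_p`` is the standard-normal upper-``p`` quantile; at ``p = 0.05`` this
    is the familiar 2.06.
    """
    if not 0 < p < 1:
        raise ConfigurationError("selected fraction must lie in (0, 1)")
    z = stats.norm.ppf(1 - p)
    return float(stats.norm.pdf(z) / p)


def genetic_gain(
    h2: float,
    sigma_p: float | None = None,
    mean: float | None = None,
    k: float = 2.06,
    pcv: float | None = None,
) -> tuple[float, float]:
    """Genetic advance ``GA = k * h2 * sigma_p`` and gain ``GG = 100*GA/mean``.

    ``h2`` is a fraction. Either ``sigma_p`` (phenotypic SD, trait units, with
    ``mean`` for GG) or ``pcv`` (phenotypic CV in %, whence ``GG = k*h2*pcv``
    directly) must be supplied.
    """
    if pcv is not None:
        gg = float(k * h2 * pcv)
        if mean is not None and sigma_p is None:
            sigma_p = abs(pcv) * mean / 100.0
        ga = float(k * h2 * sigma_p) if sigma_p is not None else float("nan")
        return ga, gg
    if sigma_p is None:
        raise ConfigurationError("supply sigma_p or pcv")
    ga = float(k * h2 * sigma_p)
    if mean is None or mean == 0:
        if mean == 0:
            raise SaltspecError("genetic gain undefined for zero mean")
        return ga, float("nan")
    return ga, float(100.0 * ga / mean)


def genetic_parameter_table(
    table: pd.DataFrame,
    variables: list[str] | None = None,
    selected_fraction: float = 0.05,
    vc_method: str = "ems",
    genotype_col: str = "genotype",
    season_col: str = "season",
    rep_col: str = "replicate",
) -> pd.DataFrame:
    """Combined ANOVA -> variance components -> genetic parameters per variable.

    One row per trait / index: mean, variance components, h2 (%), GCV, PCV,
    GA, GG. Requires at least two genotypes and a balanced design.
    """
    if variables is None:
        skip = {genotype_col, season_col, rep_col, "plot_id"}
        variables = [c for c in table.columns
                     if c not in skip and pd.api.types.is_numeric_dtype(table[c])]
    if table[genotype_col].nunique() < 2:
        raise SaltspecError("need at least two genotypes")
    k = selection_intensity(selected_fraction)
    rows = []
    for var in variables:
        anova = anova_combined(table, var, genotype_col, season_col, rep_col)
        vc = variance_components(anova, method=vc_method)
        h2 = heritability(vc)
        mean = float(table[var].mean())
        if vc.var_p == 0:
            gcv = pcv = gg = ga = 0.0
        else:
            gcv = coefficient_of_variation(vc.var_g, mean)
            pcv = coefficient_of_variation(vc.var_p, mean)
            ga, gg = genetic_gain(h2, sigma_p=float(np.sqrt(vc.var_p)), mean=mean, k=k)
        rows.append({
            "variable": var, "mean": mean,
            "var_g": vc.var_g, "var_gy": vc.var_gy, "var_e": vc.var_e,
            "var_p": vc.var_p, "h2_pct": 100.0 * h2,
            "GCV": gcv, "PCV": pcv, "GA": ga, "GG": gg,
            "truncated": ",".join(vc.truncated),
        })
    return pd.DataFrame(rows).set_index("variable")


class RCBDModel:
    """Two-season RCBD trial model for one response variable.

    statsmodels-style entry point: construct from a plot-level table, call
    :meth:`fit`, inspect the returned :class:`RCBDResults`.
    """

    def __init__(self, table: pd.DataFrame, response: str,
                 genotype_col: str = "genotype", season_col: str = "season",
                 rep_col: str = "replicate"):
        self.table = table
        self.response = response
        self.genotype_col = genotype_col
        self.season_col = season_col
        self.rep_col = rep_col

    @classmethod
    def from_csv(cls, path, response: str, **kwargs) -> "RCBDModel":
        return cls(pd.read_csv(path), response, **kwargs)

    def fit(self, alpha: float = 0.05, selected_fraction: float = 0.05,
            vc_method: str = "ems") -> "RCBDResults":
        anova = anova_combined(self.table, self.response, self.genotype_col,
                               self.season_col, self.rep_col)
        by_season = {
            s: anova_single_season(self.table, self.response, season=s,
                                   genotype_col=self.genotype_col,
                                   season_col=self.season_col, rep_col=self.rep_col)
            for s in self.table[self.season_col].unique()
        }
        vc = variance_components(anova, method=vc_method)
        h2 = heritability(vc)
        params = genetic_parameter_table(
            self.table, [self.response], selected_fraction, vc_method,
            self.genotype_col, self.season_col, self.rep_col)
        means = self.table.groupby(self.genotype_col)[self.response].mean()
        n_per_mean = anova.attrs["n_reps"] * anova.attrs["n_seasons"]
        letters = tukey_letters(means, anova.loc["error", "mean_sq"],
                                int(anova.loc["error", "df"]), n_per_mean, alpha)
        return RCBDResults(self, anova, by_season, vc, h2, params, letters, alpha)


@dataclass
class RCBDResults:
    """Fit products of :class:`RCBDModel` with a printable summary."""

    model: RCBDModel
    anova: pd.DataFrame
    anova_by_season: dict
    components: VarianceComponents
    h2: float
    genetic_params: pd.DataFrame
    tukey: pd.Series
    alpha: float

    def summary(self) -> str:
        p = self.genetic_params.iloc[0]
        lines = [
            f"RCBD combined-season analysis of {self.model.response!r}",
            f"  genotypes={self.anova.attrs['n_genotypes']} "
            f"seasons={self.anova.attrs['n_seasons']} reps={self.anova.attrs['n_reps']}",
            "", self.anova.round(4).to_string(), "",
            f"  var_g={self.components.var_g:.4f}  var_gy={self.components.var_gy:.4f}"
            f"  var_e={self.components.var_e:.4f}  var_p={self.components.var_p:.4f}",
            f"  h2={100 * self.h2:.2f}%  GCV={p['GCV']:.2f}%  PCV={p['PCV']:.2f}%"
            f"  GA={p['GA']:.3f}  GG={p['GG']:.2f}%",
            f"  Tukey groups (alpha={self.alpha}): "
            + ", ".join(f"{g}:{l}" for g, l in self.tukey.items()),
        ]
        return "\n".join(lines)
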