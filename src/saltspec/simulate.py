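"""Synthetic salt-stress field trial: phenotypes, canopy spectra, marker panels.

The generator emulates a two-season randomized complete block trial of 24
wheat genotypes (3 replicates) under field salinity. A single latent
per-genotype "tolerance score" drives all four morpho-physiological traits and
a subset of SSR loci, which is the one knob that reproduces the observed
co-clustering of traits, spectral indices, and marker groups.

Trait model (per trait, per plot)::

    y[i,j,k] = mu + S_j + B_k(j) + G_i + GS_ij + e_ijk

with G_i ~ N(0, var_g) built from the shared latent score, GS ~ N(0, var_gs),
e ~ N(0, var_e). Default variance components are back-solved from the
published combined-ANOVA mean squares of the real trial, so the simulated
heritabilities are the study's own conditions.

Canopy spectra are a smooth continuum (visible baseline, logistic red edge,
biomass-scaled NIR plateau, dry-matter SWIR decline) multiplied by
``1 - sum(depth_f * Gauss(lambda; c_f, w_f))`` over pigment/water/dry-matter
absorption features, where each depth saturates Michaelis-style in its trait
driver. Additive white noise, clipped to (0.001, 0.999).

Marker panels are binary band matrices: linked loci have band probability
``logistic(slope * z_i)`` in the genotype tolerance z-score, unlinked loci are
Bernoulli(background frequency).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import indices
from .exceptions import ConfigurationError
from .spectra import SpectraSet

TRAITS = ("PDW", "LRWC", "Chlt", "GY")


@dataclass(frozen=True)
class FieldDesign:
    """RCBD layout: genotypes x seasons x replicates."""

    n_genotypes: int = 24
    n_seasons: int = 2
    n_reps: int = 3
    genotype_ids: tuple[str, ...] | None = None
    season_ids: tuple[str, ...] | None = None

    def __post_init__(self):
        if min(self.n_genotypes, self.n_seasons, self.n_reps) < 1:
            raise ConfigurationError("all design counts must be >= 1")
        for attr, n in (("genotype_ids", self.n_genotypes), ("season_ids", self.n_seasons)):
            ids = getattr(self, attr)
            if ids is not None and (len(ids) != n or len(set(ids)) != n):
                raise ConfigurationError(f"{attr} must be {n} unique labels")

    @property
    def genotypes(self) -> tuple[str, ...]:
        if self.genotype_ids is not None:
            return tuple(self.genotype_ids)
        return tuple(f"G{i + 1:02d}" for i in range(self.n_genotypes))

    @property
    def seasons(self) -> tuple[str, ...]:
        if self.season_ids is not None:
            return tuple(self.season_ids)
        return tuple(f"S{j + 1}" for j in range(self.n_seasons))

    @property
    def n_plots(self) -> int:
        return self.n_genotypes * self.n_seasons * self.n_reps


@dataclass(frozen=True)
class TraitSpec:
    """Simulation parameters for one trait (units of the trait itself)."""

    grand_mean: float
    var_g: float
    var_gs: float
    var_e: float
    season_shifts: tuple[float, ...] = (0.0, 0.0)
    block_sd: float = 0.0
    loading: float = 0.9  # weight of the shared tolerance score in G_i

    def __post_init__(self):
        if min(self.var_g, self.var_gs, self.var_e) < 0 or self.block_sd < 0:
            raise ConfigurationError("variances and block SD must be non-negative")
        if not (np.isfinite(self.loading) and -1.0 <= self.loading <= 1.0):
            raise ConfigurationError("trait loading must be finite in [-1, 1]")


def default_trait_specs() -> dict[str, TraitSpec]:
    """Per-trait defaults matching the real trial.

    Variance components are back-solved from the published combined-ANOVA mean
    squares (sigma2_g = (MS_G - MS_GxS)/(r*y), sigma2_gy = (MS_GxS - MS_e)/r
    clipped at 0, sigma2_e = MS_e); grand means sit mid-range of the reported
    genotype means; season shifts are back-solved from the season mean square.
    """
    return {
        "PDW": TraitSpec(5.3, 0.31070, 0.0, 0.0963, (0.019, -0.019), 0.04),
        "LRWC": TraitSpec(68.0, 10.33615, 5.00107, 5.725, (0.695, -0.695), 0.30),
        "Chlt": TraitSpec(1.9, 0.21867, 0.08383, 0.0561, (0.113, -0.113), 0.05),
        "GY": TraitSpec(3.8, 0.24223, 0.0, 0.0486, (0.026, -0.026), 0.03),
    }


def true_heritability(spec: TraitSpec, n_seasons: int, n_reps: int) -> float:
    """Design (ground-truth) broad-sense heritability for a trait spec."""
    var_p = spec.var_g + spec.var_gs / n_seasons + spec.var_e / (n_seasons * n_reps)
    return 0.0 if var_p == 0 else spec.var_g / var_p


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption feature with a saturating trait driver."""

    center_nm: float
    width_nm: float
    max_depth: float
    driver: str  # 'chlorophyll' | 'water' | 'dry_matter'
    saturation: float

    def __post_init__(self):
        if self.width_nm <= 0 or self.saturation <= 0:
            raise ConfigurationError("feature width and saturation must be positive")
        if self.driver not in ("chlorophyll", "water", "dry_matter"):
            raise ConfigurationError(f"unknown absorption driver {self.driver!r}")


def default_absorption_features() -> tuple[AbsorptionFeature, ...]:
    # Chlorophyll wells at 430/670 nm (the weaker 550 well leaves the green
    # reflectance bump between them); water bands at 970/1200/1450/1940 nm;
    # dry-matter features in the SWIR. Every registered index band responds to
    # at least one driver through these features or the biomass-scaled continuum.
    return (
        AbsorptionFeature(430, 40, 0.78, "chlorophyll", 1.2),
        AbsorptionFeature(550, 35, 0.32, "chlorophyll", 1.2),
        AbsorptionFeature(670, 38, 0.80, "chlorophyll", 1.2),
        AbsorptionFeature(970, 40, 0.42, "water", 3.2),
        AbsorptionFeature(1200, 50, 0.38, "water", 3.2),
        AbsorptionFeature(1450, 85, 0.72, "water", 3.2),
        AbsorptionFeature(1940, 115, 0.85, "water", 3.2),
        AbsorptionFeature(2100, 70, 0.18, "dry_matter", 5.0),
        AbsorptionFeature(2305, 90, 0.22, "dry_matter", 5.0),
    )


@dataclass(frozen=True)
class SpectraSimSpec:
    """Canopy reflectance continuum + absorption-feature parameters."""

    wavelength_start: float = 350.0
    wavelength_stop: float = 2500.0
    wavelength_step: float = 1.0
    vis_baseline: float = 0.045
    nir_plateau_base: float = 0.62
    biomass_saturation: float = 1.8  # PDW half-saturation of the NIR plateau
    red_edge_center: float = 712.0
    red_edge_width: float = 14.0
    swir_decline_max: float = 0.55  # dry-matter driven fractional decline at 2500 nm
    swir_decline_saturation: float = 3.0
    absorption_features: tuple[AbsorptionFeature, ...] = field(
        default_factory=default_absorption_features)
    noise_sd: float = 0.0035

    def __post_init__(self):
        if not (0 < self.vis_baseline < 1 and 0 < self.nir_plateau_base < 1):
            raise ConfigurationError("reflectance parameters must lie in (0, 1)")
        if self.red_edge_width <= 0 or self.wavelength_step <= 0:
            raise ConfigurationError("widths and grid step must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise SD must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(self.wavelength_start,
                         self.wavelength_stop + 0.5 * self.wavelength_step,
                         self.wavelength_step)


@dataclass(frozen=True)
class MarkerSimSpec:
    """SSR band-matrix simulation parameters."""

    n_markers: int = 34
    n_linked: int = 20
    linkage_slope: float = 1.5
    background_freq: float = 0.35

    def __post_init__(self):
        if not 0 <= self.n_linked <= self.n_markers:
            raise ConfigurationError("need 0 <= n_linked <= n_markers")
        if not 0 < self.background_freq < 1:
            raise ConfigurationError("background_freq must lie in (0, 1)")


def simulate_trait_panel(
    design: FieldDesign,
    specs: dict[str, TraitSpec] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate the plot-level trait table plus its ground truth.

    Returns ``(table, truth)`` where the table has one row per plot
    (``plot_id, genotype, season, replicate`` plus one column per trait) and
    ``truth`` holds the latent tolerance z-scores, per-trait genotype effects
    ``G_i``, interaction draws ``GS_ij``, and the design heritabilities.
    """
    if specs is None:
        specs = default_trait_specs()
    rng = np.random.default_rng(seed)
    g, y, r = design.n_genotypes, design.n_seasons, design.n_reps
    tolerance = rng.standard_normal(g)  # shared latent tolerance score

    rows = {
        "plot_id": [], "genotype": [], "season": [], "replicate": [],
    }
    geno_idx = np.repeat(np.arange(g), y * r)
    season_idx = np.tile(np.repeat(np.arange(y), r), g)
    rep_idx = np.tile(np.arange(r), g * y)
    rows["genotype"] = [design.genotypes[i] for i in geno_idx]
    rows["season"] = [design.seasons[j] for j in season_idx]
    rows["replicate"] = (rep_idx + 1).tolist()
    rows["plot_id"] = [
        f"{design.genotypes[i]}_{design.seasons[j]}_R{k + 1}"
        for i, j, k in zip(geno_idx, season_idx, rep_idx)
    ]
    table = pd.DataFrame(rows)

    truth: dict = {
        "seed": int(seed),
        "tolerance_scores": dict(zip(design.genotypes, tolerance.tolist())),
        "genotype_effects": {},
        "interaction_effects": {},
        "true_h2": {},
        "variance_components": {},
    }
    for trait, spec in specs.items():
        if len(spec.season_shifts) < y:
            raise ConfigurationError(
                f"{trait}: {len(spec.season_shifts)} season shifts for {y} seasons")
        rho = spec.loading
        independent = rng.standard_normal(g)
        g_eff = np.sqrt(spec.var_g) * (rho * tolerance
                                       + np.sqrt(max(0.0, 1 - rho ** 2)) * independent)
        gs_eff = rng.normal(0.0, np.sqrt(spec.var_gs), size=(g, y))
        block = rng.normal(0.0, spec.block_sd, size=(y, r))
        noise = rng.normal(0.0, np.sqrt(spec.var_e), size=g * y * r)
        values = (spec.grand_mean
                  + np.asarray(spec.season_shifts)[season_idx]
                  + block[season_idx, rep_idx]
                  + g_eff[geno_idx]
                  + gs_eff[geno_idx, season_idx]
                  + noise)
        table[trait] = values
        truth["genotype_effects"][trait] = dict(zip(design.genotypes, g_eff.tolist()))
        truth["interaction_effects"][trait] = {
            design.genotypes[i]: gs_eff[i].tolist() for i in range(g)
        }
        truth["true_h2"][trait] = true_heritability(spec, y, r)
        truth["variance_components"][trait] = {
            "var_g": spec.var_g, "var_gs": spec.var_gs, "var_e": spec.var_e,
        }
    return table, truth


def _driver_values(traits: pd.DataFrame) -> dict[str, np.ndarray]:
    required = {"Chlt", "LRWC", "PDW"}
    missing = required - set(traits.columns)
    if missing:
        raise ConfigurationError(f"trait table is missing columns {sorted(missing)}")
    pdw = traits["PDW"].to_numpy(float)
    return {
        "chlorophyll": traits["Chlt"].to_numpy(float),
        "water": traits["LRWC"].to_numpy(float) / 100.0 * pdw,  # canopy water proxy
        "dry_matter": pdw,
    }


def simulate_canopy_spectra(
    traits: pd.DataFrame,
    spec: SpectraSimSpec | None = None,
    seed: int = 0,
) -> SpectraSet:
    """One canopy reflectance spectrum per plot, driven by the plot's traits."""
    if spec is None:
        spec = SpectraSimSpec()
    wl = spec.wavelengths
    # the grid must be able to serve every registered index band
    for band in indices.ALL_BANDS:
        if not (wl[0] - 1.0 <= band <= wl[-1] + 1.0):
            raise ConfigurationError(
                f"wavelength grid {wl[0]:g}-{wl[-1]:g} nm does not cover the "
                f"{band:g} nm band required by the index registry")
    rng = np.random.default_rng(seed)
    drivers = _driver_values(traits)
    n = len(traits)

    pdw = drivers["dry_matter"]
    nir_level = spec.nir_plateau_base * (pdw / (pdw + spec.biomass_saturation))
    red_edge = 1.0 / (1.0 + np.exp(-(wl - spec.red_edge_center) / spec.red_edge_width))
    continuum = (spec.vis_baseline
                 + (nir_level[:, None] - spec.vis_baseline) * red_edge[None, :])
    # dry-matter controlled SWIR decline beyond 1300 nm
    decline_frac = spec.swir_decline_max * pdw / (pdw + spec.swir_decline_saturation)
    ramp = np.clip((wl - 1300.0) / 1200.0, 0.0, None)
    continuum = continuum * (1.0 - decline_frac[:, None] * ramp[None, :])

    absorption = np.zeros((n, wl.size))
    for feat in spec.absorption_features:
        x = drivers[feat.driver]
        depth = feat.max_depth * x / (x + feat.saturation)
        shape = np.exp(-0.5 * ((wl - feat.center_nm) / feat.width_nm) ** 2)
        absorption += depth[:, None] * shape[None, :]
    reflectance = continuum * (1.0 - absorption)
    if spec.noise_sd > 0:
        reflectance = reflectance + rng.normal(0.0, spec.noise_sd, reflectance.shape)
    reflectance = np.clip(reflectance, 0.001, 0.999)
    meta_cols = ["plot_id", "genotype", "season", "replicate"]
    return SpectraSet(wl, reflectance, traits[meta_cols].copy())


def simulate_marker_panel(
    tolerance_scores: dict[str, float] | pd.Series,
    spec: MarkerSimSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Binary SSR band matrix (genotypes x markers) plus the truly linked loci.

    Linked loci carry bands with probability
    ``logistic(slope * z_i + logit(background_freq))`` where ``z_i`` is the
    genotype's tolerance z-score, so a zero slope degrades every locus to the
    background band frequency and a saturating slope turns linked loci into
    the indicator of a positive score; unlinked loci are iid
    Bernoulli(background_freq).
    """
    if spec is None:
        spec = MarkerSimSpec()
    scores = pd.Series(tolerance_scores, dtype=float)
    rng = np.random.default_rng(seed)
    names = [f"SSR{m + 1:02d}" for m in range(spec.n_markers)]
    linked = sorted(rng.choice(spec.n_markers, size=spec.n_linked, replace=False).tolist())
    z = scores.to_numpy()
    probs = np.full((len(scores), spec.n_markers), spec.background_freq)
    if spec.n_linked:
        offset = np.log(spec.background_freq / (1.0 - spec.background_freq))
        with np.errstate(over="ignore"):
            probs[:, linked] = 1.0 / (
                1.0 + np.exp(-(spec.linkage_slope * z + offset)))[:, None]
    bands = (rng.random(probs.shape) < probs).astype(int)
    matrix = pd.DataFrame(bands, index=pd.Index(scores.index, name="genotype"),
                          columns=names)
    return matrix, [names[m] for m in linked]


def write_fixture_bundle(
    directory,
    design: FieldDesign | None = None,
    trait_specs: dict[str, TraitSpec] | None = None,
    spectra_spec: SpectraSimSpec | None = None,
    marker_spec: MarkerSimSpec | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate a full trial and write spectra/trait/marker CSVs + truth JSON.

    Files round-trip bit-identically through the package readers, and the same
    seed always produces byte-identical files.
    """
    if design is None:
        design = FieldDesign()
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        traits, truth = simulate_trait_panel(design, trait_specs, seed=seed)
        spectra = simulate_canopy_spectra(traits, spectra_spec, seed=seed + 1)
        markers, linked = simulate_marker_panel(
            pd.Series(truth["tolerance_scores"]), marker_spec, seed=seed + 2)
        truth["linked_markers"] = linked
        paths = {
            "traits": directory / "traits.csv",
            "spectra": directory / "spectra.csv",
            "markers": directory / "markers.csv",
            "truth": directory / "ground_truth.json",
        }
        traits.to_csv(paths["traits"], index=False)
        spectra.to_csv(paths["spectra"])
        markers.to_csv(paths["markers"])
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    except OSError as exc:
        raise ConfigurationError(f"cannot write fixture bundle under {directory}: {exc}") from exc
    return paths
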