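"""End-to-end orchestration: one config in, a report bundle of tables out.

Stage order follows the analysis narrative: spectral indices -> trait
assembly -> ANOVA / genetic parameters -> diversity & Mantel -> marker
association -> calibration / PLSR / PCA. Inputs are either three CSVs
(spectra, traits, markers) or a ``simulate`` block that generates the whole
trial from a seed. Every stage's outputs are written into the bundle
directory and listed in the run log; a failure aborts with the stage named.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, association, assays, diversity, estimation, indices
from . import quantgen, simulate
from .exceptions import ConfigurationError, SaltspecError
from .spectra import read_spectra_csv

logger = logging.getLogger(__name__)

TRAITS = list(simulate.TRAITS)


@dataclass
class PipelineConfig:
    """Inputs, statistical settings and seeds for a full pipeline run."""

    output_dir: str = "saltspec_out"
    spectra_csv: str | None = None
    traits_csv: str | None = None
    markers_csv: str | None = None
    simulate: bool = False
    seed: int = 1
    n_genotypes: int = 24
    n_seasons: int = 2
    n_reps: int = 3
    alpha: float = 0.05
    selected_fraction: float = 0.05
    n_clusters: int = 3
    mantel_permutations: int = 9999
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10
    val_fraction: float = 0.25
    cv_repeats: int = 10
    plsr_max_factors: int = 8
    band_tolerance: float = 1.0

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigurationError("seed must be an integer")
        if self.simulate:
            return
        for name in ("spectra_csv", "traits_csv", "markers_csv"):
            path = getattr(self, name)
            if path is None:
                raise ConfigurationError(f"{name} is required unless simulate=true")
            if not Path(path).exists():
                raise ConfigurationError(f"{name}: file not found: {path}")


@dataclass
class ReportBundle:
    """Paths of everything one pipeline run produced."""

    output_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    log_file: Path | None = None

    def register(self, key: str, path: Path) -> Path:
        self.files[key] = path
        logger.info("wrote %s -> %s", key, path)
        return path


def _stage(name):
    def wrap(func):
        def run(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return func(*args, **kwargs)
            except SaltspecError as exc:
                raise SaltspecError(f"[stage {name}] {exc}") from exc
        return run
    return wrap


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages and write the report bundle."""
    config.validate()  # pre-flight: nothing is written if inputs are broken
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out)
    bundle.log_file = out / "run.log"
    handler = logging.FileHandler(bundle.log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("saltspec")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("saltspec %s, config: %s", __version__, dataclasses.asdict(config))
        (out / "config.json").write_text(
            json.dumps(dataclasses.asdict(config), indent=2))
        bundle.register("config", out / "config.json")

        # --- inputs ---------------------------------------------------------
        if config.simulate:
            design = simulate.FieldDesign(config.n_genotypes, config.n_seasons,
                                          config.n_reps)
            fixture_dir = out / "inputs"
            paths = simulate.write_fixture_bundle(fixture_dir, design,
                                                  seed=config.seed)
            for key, path in paths.items():
                bundle.register(f"input_{key}", path)
            spectra = read_spectra_csv(paths["spectra"])
            traits = pd.read_csv(paths["traits"])
            markers = diversity.read_marker_csv(paths["markers"])
        else:
            spectra = read_spectra_csv(config.spectra_csv)
            traits = pd.read_csv(config.traits_csv)
            markers = diversity.read_marker_csv(config.markers_csv)

        # --- stage 1: spectral indices -------------------------------------
        sri = _stage("indices")(indices.compute_index_table)(
            spectra, band_tolerance=config.band_tolerance)
        sri.to_csv(bundle.register("sri_table", out / "sri_table.csv"), index=False)

        # --- stage 2: trait assembly ---------------------------------------
        trait_cols = [t for t in TRAITS if t in traits.columns]
        plot_table = traits.merge(
            sri, on=["plot_id", "genotype", "season", "replicate"], validate="1:1")
        sri_cols = [c for c in sri.columns if c in indices.ALL_INDEX_NAMES]
        geno_traits = assays.genotype_means(traits, value_columns=trait_cols)
        geno_sri = assays.genotype_means(sri, value_columns=sri_cols)
        geno_traits.to_csv(bundle.register("genotype_trait_means",
                                           out / "genotype_trait_means.csv"), index=False)
        geno_sri.to_csv(bundle.register("genotype_sri_means",
                                        out / "genotype_sri_means.csv"), index=False)

        # --- stage 3: ANOVA + genetic parameters ---------------------------
        @_stage("genetics")
        def genetics():
            anova_rows = []
            letters = {}
            for var in trait_cols + sri_cols:
                combined = quantgen.anova_combined(plot_table, var)
                for term, row in combined.iterrows():
                    anova_rows.append({"variable": var, "analysis": "combined",
                                       "term": term, **row.to_dict()})
                for season in plot_table["season"].unique():
                    single = quantgen.anova_single_season(plot_table, var,
                                                          season=season)
                    for term, row in single.iterrows():
                        anova_rows.append({"variable": var, "analysis": str(season),
                                           "term": term, **row.to_dict()})
                means = plot_table.groupby("genotype")[var].mean()
                n_per = combined.attrs["n_reps"] * combined.attrs["n_seasons"]
                letters[var] = quantgen.tukey_letters(
                    means, combined.loc["error", "mean_sq"],
                    int(combined.loc["error", "df"]), n_per, config.alpha)
            params = quantgen.genetic_parameter_table(
                plot_table, trait_cols + sri_cols,
                selected_fraction=config.selected_fraction)
            return pd.DataFrame(anova_rows), params, pd.DataFrame(letters)

        anova_table, genetic_params, tukey = genetics()
        anova_table.to_csv(bundle.register("anova", out / "anova.csv"), index=False)
        genetic_params.to_csv(bundle.register("genetic_parameters",
                                              out / "genetic_parameters.csv"))
        tukey.to_csv(bundle.register("tukey_letters", out / "tukey_letters.csv"))

        # --- stage 4: diversity + Mantel -----------------------------------
        @_stage("diversity")
        def diversity_stage():
            markers_aligned = markers.loc[sorted(markers.index)]
            d_markers = diversity.jaccard_distance_matrix(markers_aligned)
            order = d_markers.labels
            d_traits = diversity.standardized_euclidean_distance(
                geno_traits.set_index("genotype").loc[order, trait_cols])
            d_sri = diversity.standardized_euclidean_distance(
                geno_sri.set_index("genotype").loc[order, sri_cols])
            results = {}
            for tag, dmat in (("markers", d_markers), ("traits", d_traits),
                              ("sri", d_sri)):
                dmat.to_csv(bundle.register(f"distance_{tag}",
                                            out / f"distance_{tag}.csv"))
                tree = diversity.upgma(dmat)
                newick_path = out / f"upgma_{tag}.nwk"
                newick_path.write_text(tree.to_newick() + "\n")
                bundle.register(f"upgma_{tag}", newick_path)
                results[f"clusters_{tag}"] = tree.cut(config.n_clusters)
            clusters = pd.DataFrame(results)
            clusters.to_csv(bundle.register("clusters", out / "clusters.csv"))
            mantel = {
                "traits_vs_markers": diversity.mantel_test(
                    d_traits, d_markers, config.mantel_permutations,
                    seed=config.seed).to_dict(),
                "sri_vs_markers": diversity.mantel_test(
                    d_sri, d_markers, config.mantel_permutations,
                    seed=config.seed + 1).to_dict(),
            }
            path = out / "mantel.json"
            path.write_text(json.dumps(mantel, indent=2))
            bundle.register("mantel", path)
            return order

        order = diversity_stage()

        # --- stage 5: marker-trait association ------------------------------
        @_stage("association")
        def association_stage():
            responses = pd.concat(
                [geno_traits.set_index("genotype")[trait_cols],
                 geno_sri.set_index("genotype")[sri_cols]], axis=1).loc[order]
            return association.association_table(
                responses, markers.loc[order],
                alpha_enter=config.alpha_enter, alpha_remove=config.alpha_remove)

        assoc = association_stage()
        assoc.to_csv(bundle.register("association", out / "association.csv"),
                     index=False)

        # --- stage 6: calibration / PLSR / PCA ------------------------------
        @_stage("calibration")
        def calibration_stage():
            cal = estimation.calibration_table(plot_table, plot_table,
                                               sri_cols, trait_cols)
            plsr_rows = {}
            X = plot_table[sri_cols].dropna(axis=1)
            for trait in trait_cols:
                report = estimation.plsr_evaluate(
                    X, plot_table[trait], val_fraction=config.val_fraction,
                    n_repeats=config.cv_repeats, seed=config.seed,
                    max_factors=config.plsr_max_factors)
                plsr_rows[trait] = report.to_dict()
            features = pd.concat(
                [geno_traits.set_index("genotype")[trait_cols],
                 geno_sri.set_index("genotype")[sri_cols]], axis=1)
            pca = estimation.pca_correlation(features)
            return cal, plsr_rows, pca

        cal, plsr_rows, pca = calibration_stage()
        cal.to_csv(bundle.register("calibration", out / "calibration.csv"),
                   index=False)
        (out / "plsr.json").write_text(json.dumps(plsr_rows, indent=2))
        bundle.register("plsr", out / "plsr.json")
        pca.loadings.to_csv(bundle.register("pca_loadings", out / "pca_loadings.csv"))
        pca.scores.to_csv(bundle.register("pca_scores", out / "pca_scores.csv"))
        pd.Series(pca.explained, index=pca.loadings.columns, name="explained") \
            .to_csv(bundle.register("pca_explained", out / "pca_explained.csv"))

        manifest = {k: str(v) for k, v in bundle.files.items()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        logger.info("pipeline complete: %d files", len(bundle.files))
    finally:
        root.removeHandler(handler)
        handler.close()
    return bundle
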