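"""End-to-end orchestration: cohort -> (trend, cluster) -> association ->
age-matched sensitivity -> DASH, with a reproducible run manifest.

A single global seed is fanned out to each stochastic stage by hashing
the stage name, so stage-level results are reproducible independently of
stage order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc, cluster, dash, match, synth, trend
from .cohort import Cohort


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    output_dir: str | Path
    seed: int = 0
    cohort_path: str | Path | None = None      # None -> synthetic scenario
    schema_path: str | Path | None = None
    scenario_n: int = 447
    scenario_separation: float = 0.9
    categories: tuple[str, ...] = ("food_item", "dietary_behavior",
                                   "cooking_method")
    k: int | None = None                        # None -> automatic selection
    model_names: tuple[str, ...] = ("Model 1", "Model 2", "Model 3",
                                    "Model 4", "Model 5")
    match_calipers: tuple[float, ...] = (0.0, 2.0)
    run_dash: bool = True
    reference: object | None = None

    def to_dict(self) -> dict:
        doc = {
            "seed": self.seed,
            "cohort_path": (str(self.cohort_path)
                            if self.cohort_path else None),
            "schema_path": (str(self.schema_path)
                            if self.schema_path else None),
            "scenario_n": self.scenario_n,
            "scenario_separation": self.scenario_separation,
            "categories": list(self.categories),
            "k": self.k,
            "model_names": list(self.model_names),
            "match_calipers": list(self.match_calipers),
            "run_dash": self.run_dash,
            "reference": self.reference,
        }
        return doc

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir=None) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        out = output_dir or doc.pop("output_dir", "dietclust_run")
        doc.pop("output_dir", None)
        for key in ("categories", "model_names", "match_calipers"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(output_dir=out, **doc)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis, writing artifacts to the output dir.

    Returns a manifest dict (also written as ``manifest.json``).  On a
    stage failure a :class:`StageError` names the stage; partial outputs
    written so far are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": {},
        "artifacts": {},
    }

    def record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = str(path.relative_to(out))

    def run_stage(stage: str, fn):
        manifest["stage_seeds"][stage] = stage_seed(config.seed, stage)
        try:
            return fn(manifest["stage_seeds"][stage])
        except Exception as exc:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise StageError(stage, exc) from exc

    # ---- cohort ----------------------------------------------------------
    def _cohort(seed: int) -> tuple[Cohort, pd.Series | None]:
        if config.cohort_path is not None:
            from .cohort import load_cohort
            from .schema import bdhq_schema
            schema = (config.schema_path if config.schema_path
                      else bdhq_schema())
            return load_cohort(config.cohort_path, schema), None
        scenario = synth.study_like_preset(
            seed=seed, n=config.scenario_n,
            separation=config.scenario_separation)
        cohort, latent = synth.generate_cohort(scenario)
        latent.to_csv(out / "latent_labels.csv")  # evaluation only
        record("latent_labels", out / "latent_labels.csv")
        return cohort, latent

    cohort, _latent = run_stage("cohort", _cohort)
    if cohort.provenance is not None:
        cohort.provenance.to_json(out / "cascade.json")
        record("cascade", out / "cascade.json")

    # ---- cluster ---------------------------------------------------------
    def _cluster(seed: int):
        matrix = cluster.encode_matrix(cohort, config.categories)
        cfg = cluster.ClusteringConfig(seed=seed, k=config.k)
        embedding = cluster.embed_umap(matrix, cfg)
        diagnostics = cluster.select_k(embedding, cfg)
        k = config.k if config.k is not None else diagnostics.selected_k
        assignment = cluster.kmeans_assign(embedding, k, cfg, diagnostics)
        embedding.coordinates.to_csv(out / "embedding.csv")
        assignment.labels.to_csv(out / "labels.csv")
        (out / "selection_diagnostics.json").write_text(
            json.dumps(diagnostics.to_dict(), indent=2))
        cluster.scatter_contour_plot(embedding, assignment.labels,
                                     cfg.kde_bandwidth,
                                     out / "embedding_contour.png")
        record("embedding_contour", out / "embedding_contour.png")
        record("embedding", out / "embedding.csv")
        record("labels", out / "labels.csv")
        record("selection_diagnostics", out / "selection_diagnostics.json")
        return assignment

    assignment = run_stage("cluster", _cluster)
    labels = assignment.labels

    # ---- trend -----------------------------------------------------------
    def _trend(seed: int):
        table = trend.trend_table(cohort, labels)
        table.to_csv(out / "trend_table.csv")
        rank = trend.rank_clusters(table)
        rank.to_csv(out / "cluster_rank_summary.csv")
        record("trend_table", out / "trend_table.csv")
        record("cluster_rank_summary", out / "cluster_rank_summary.csv")
        return table

    run_stage("trend", _trend)

    # ---- association -----------------------------------------------------
    def _assoc(seed: int):
        y = cohort.data["incident_hypertension"].astype(int).to_numpy()
        table = assoc.contingency_by_cluster(y, labels.to_numpy(),
                                             reference=config.reference)
        table.to_frame().to_csv(out / "contingency.csv")
        record("contingency", out / "contingency.csv")
        crude = assoc.crude_or(table)
        specs = assoc.model_specs(list(config.model_names))
        adjusted = assoc.fit_models(cohort.data, labels, specs,
                                    reference=table.reference)
        frame = assoc.or_results_frame(crude + adjusted)
        frame.to_csv(out / "odds_ratios.csv", index=False)
        record("odds_ratios", out / "odds_ratios.csv")
        return table, frame

    table, _ = run_stage("assoc", _assoc)

    # ---- age-matched sensitivity ----------------------------------------
    def _match(seed: int):
        report = match.age_distribution_report(cohort.data["age"], labels)
        report.to_csv(out / "age_distribution.csv")
        record("age_distribution", out / "age_distribution.csv")
        match.age_dot_plot(cohort.data["age"], labels,
                           out / "age_distribution.png")
        rows = []
        for caliper in config.match_calipers:
            spec = match.MatchSpec(caliper=caliper)
            matched, mlabels = match.build_matched_cohort(cohort, labels,
                                                          spec)
            drop = () if spec.adjust_for_age else ("age",)
            specs = assoc.model_specs(list(config.model_names), drop=drop)
            results = assoc.fit_models(matched.data, mlabels, specs,
                                       reference=table.reference)
            frame = assoc.or_results_frame(results)
            frame.insert(0, "caliper", caliper)
            frame.insert(1, "matched_n", len(matched))
            rows.append(frame)
        all_rows = pd.concat(rows, ignore_index=True)
        all_rows.to_csv(out / "matched_odds_ratios.csv", index=False)
        record("matched_odds_ratios", out / "matched_odds_ratios.csv")
        return all_rows

    run_stage("match", _match)

    # ---- DASH ------------------------------------------------------------
    if config.run_dash:
        def _dash(seed: int):
            rng = np.random.default_rng(seed)
            components = synthetic_dash_components(cohort, labels, rng)
            scored = dash.dash_score(components)
            scored.to_csv(out / "dash_scores.csv")
            record("dash_scores", out / "dash_scores.csv")
            comparison = dash.dash_by_cluster(scored["total"].to_numpy(),
                                              labels.to_numpy())
            comparison["composition"].to_csv(out / "dash_composition.csv")
            record("dash_composition", out / "dash_composition.csv")
            return scored

        run_stage("dash", _dash)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def synthetic_dash_components(cohort: Cohort, labels,
                              rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic numeric DASH component intakes (servings or g/day).

    Stands in for the nutrient-level intakes the diet-quality score is
    defined on, which are not derivable from the ordinal frequency
    responses.  Each component loads on the mapped weight of thematically
    related questionnaire items plus noise, so clusters inherit plausible
    DASH contrasts.
    """
    weights = trend.participant_weights(cohort)
    n = len(cohort)

    def level(cols, scale=1.0):
        base = weights[[c for c in cols if c in weights.columns]].mean(axis=1)
        return (base * scale + rng.normal(0, 0.35 * scale, n)).clip(lower=0.05)

    comp = pd.DataFrame(index=cohort.data.index)
    comp["fruits"] = level(["citrus_fruit", "other_fruits",
                            "persimmons_strawberries_kiwifruit"])
    comp["vegetables"] = level(["green_leafy_vegetables", "tomatoes",
                                "carrots_pumpkin", "cabbage_chinese_cabbage"])
    comp["nuts_legumes"] = level(["natto", "tofu_fried_tofu"])
    comp["low_fat_dairy"] = level(["reduced_fat_milk_yogurt", "milk_yogurt"])
    comp["whole_grains"] = level(["other_grains", "buckwheat_noodles"])
    comp["sodium"] = (pd.to_numeric(cohort.data["salt_intake"],
                                    errors="coerce")
                      .fillna(10.0) + rng.normal(0, 0.5, n)).clip(lower=1.0)
    comp["sweetened_beverages"] = level(["cola_soft_drink", "juice_100pct"])
    comp["red_processed_meats"] = level(["pork_beef", "ham_sausage_bacon"])
    return comp
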