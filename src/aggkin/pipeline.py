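"""End-to-end orchestration: features -> selection -> banding -> models ->
attribution, with reproducibility metadata.

The pipeline runs in one of three modes depending on what the configuration
provides:

* **full** — per-condition trajectories are read (or generated), the
  17-descriptor feature table is computed, and every downstream stage runs;
* **statistics-only** — a precomputed feature table CSV is supplied and the
  descriptor stage is skipped (the usual mode when the MD feature table
  comes from elsewhere);
* **conditions-only** — only the formulation table is available; the
  covariate correlations and the aggregation-band summary are produced.

Every numeric output is a pure function of the configuration and seed:
CSVs are written with a fixed float format and JSON with sorted keys, so
reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptors, regress, shapley, statsel, synthgen, trajio

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest records the failure point."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Only ``output_dir`` is mandatory.  ``condition_table`` defaults to the
    packaged 49-condition fixture.  ``trajectories`` maps condition id to a
    list of trajectory file paths; ``pka_tables`` maps condition id to a
    CSV of ionisable sites (residue_index, site_label, pka, site_class).
    """

    output_dir: str = "aggkin_out"
    condition_table: str | None = None
    feature_table: str | None = None
    trajectories: dict[int, list[str]] = field(default_factory=dict)
    pka_tables: dict[int, str] = field(default_factory=dict)
    descriptor: descriptors.DescriptorConfig = field(
        default_factory=descriptors.DescriptorConfig)
    band_edges: tuple[float, float] = (0.0, 4.0)
    banding_feature: str = "average native contact"
    banding_threshold: float = 0.814
    banding_direction: str = "below_flags_high"
    redundancy_threshold: float = 0.8
    keep_features: list[str] = field(default_factory=list)
    models: list[str] = field(default_factory=lambda: ["ols", "pls"])
    k: int = 10
    k_range: tuple[int, int] = (2, 31)
    seed: int = 0
    shapley_method: str = "auto"          # "auto" | "exact" | "permutation"
    shapley_permutations: int = 200
    response_column: str = "ln_v"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "descriptor" in raw:
            raw["descriptor"] = descriptors.DescriptorConfig(**raw["descriptor"])
        if "trajectories" in raw:
            raw["trajectories"] = {int(k): list(v)
                                   for k, v in raw["trajectories"].items()}
        if "pka_tables" in raw:
            raw["pka_tables"] = {int(k): v
                                 for k, v in raw["pka_tables"].items()}
        for key in ("band_edges", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else
                 v.__dict__ if hasattr(v, "__dict__") else v)
             for k, v in self.__dict__.items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _read_pka_csv(path) -> list[descriptors.PkaSite]:
    df = pd.read_csv(path)
    return [
        descriptors.PkaSite(
            residue_index=int(r.residue_index), site_label=str(r.site_label),
            pka=float(r.pka), site_class=str(r.site_class),
        )
        for r in df.itertuples(index=False)
    ]


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str)
                    + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage the configuration enables and write the report bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    On stage failure the partial outputs are kept, the manifest records the
    failure point, and :class:`PipelineError` is raised.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "artifacts": [],
        "warnings": [],
        "failure": None,
        "mode": None,
    }
    collected: list[warnings.WarningMessage] = []

    def _emit(name: str) -> None:
        manifest["artifacts"].append(name)

    stage = "setup"
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            stage = "condition-table"
            if config.condition_table:
                conditions = trajio.read_condition_table(config.condition_table)
            else:
                conditions = synthgen.condition_table_fixture()
            cond_df = conditions.to_frame()

            stage = "feature-table"
            feature_df = None
            provenance = None
            if config.feature_table:
                feature_df = pd.read_csv(config.feature_table, index_col=0)
                feature_df.index.name = "condition_id"
                manifest["mode"] = "statistics-only"
            elif config.trajectories:
                reps = {
                    cid: [trajio.read_structure(p) for p in paths]
                    for cid, paths in config.trajectories.items()
                }
                pka = {cid: _read_pka_csv(p)
                       for cid, p in config.pka_tables.items()}
                pH = {cid: cond_df.loc[cid, "pH"] for cid in reps}
                feature_df, provenance = descriptors.build_feature_table(
                    reps, pka, pH, config=config.descriptor)
                manifest["mode"] = "full"
            else:
                manifest["mode"] = "conditions-only"
            if feature_df is not None:
                _write_csv(feature_df, out / "feature_table.csv")
                _emit("feature_table.csv")
                if provenance is not None:
                    _write_json(provenance, out / "feature_provenance.json")

            response_series = None
            if feature_df is not None and \
                    config.response_column in feature_df.columns:
                response_series = feature_df.pop(config.response_column)

            stage = "correlations"
            if feature_df is not None:
                stats_df = feature_df.join(cond_df, how="left")
                if response_series is not None:
                    stats_df[config.response_column] = response_series
            else:
                stats_df = cond_df
            for method in ("pearson", "spearman"):
                cm = statsel.correlation_matrix(stats_df, method)
                _write_csv(cm.r, out / f"correlation_{method}.csv")
                _emit(f"correlation_{method}.csv")

            stage = "feature-selection"
            y = stats_df[config.response_column]
            if feature_df is not None:
                feat_cols = [c for c in feature_df.columns
                             if c in stats_df.columns]
                corr = statsel.correlation_matrix(stats_df[feat_cols],
                                                  "pearson")
                target = stats_df[feat_cols].apply(lambda c: c.corr(y))
                retained, removal_log = statsel.select_nonredundant(
                    corr, target, config.redundancy_threshold,
                    keep=config.keep_features)
                _write_json({"retained": retained, "log": removal_log},
                            out / "retained_features.json")
                _emit("retained_features.json")
            else:
                retained = None

            stage = "banding"
            lo, hi = config.band_edges
            if feature_df is not None and \
                    config.banding_feature in feature_df.columns:
                bc = statsel.banded_classifier(
                    feature_df[config.banding_feature].reindex(y.index),
                    y, config.banding_threshold, config.banding_direction,
                    config.band_edges)
                report = bc.to_dict()
            else:
                yv = y.to_numpy()
                report = {
                    "n": int(yv.size),
                    "low": int(np.sum(yv < lo)),
                    "medium": int(np.sum((yv >= lo) & (yv <= hi))),
                    "high": int(np.sum(yv > hi)),
                    "band_edges": [lo, hi],
                    "note": "no banding feature available; counts only",
                }
            _write_json(report, out / "banding_report.json")
            _emit("banding_report.json")

            stage = "model-building"
            if feature_df is not None:
                X = feature_df[retained] if retained else feature_df
                X = X.dropna(axis=1, how="any")
                yfit = y.loc[X.index]
                specs = [regress.ModelSpec(kind=m,
                                           kwargs=({"seed": config.seed}
                                                   if m in regress.SKLEARN_CANDIDATES
                                                   else {}))
                         for m in config.models]

                ksens_spec = next((s for s in specs if s.kind == "pls"),
                                  specs[0])
                ksens, recommended_k = regress.k_sensitivity(
                    ksens_spec, X, yfit,
                    range(config.k_range[0], config.k_range[1] + 1),
                    seed=config.seed)
                _write_csv(ksens, out / "k_sensitivity.csv")
                _emit("k_sensitivity.csv")

                reports = [regress.cross_validate(s, X, yfit, config.k,
                                                  config.seed)
                           for s in specs]
                _write_json({"recommended_k": recommended_k,
                             "reports": [r.to_dict() for r in reports]},
                            out / "cv_reports.json")
                _emit("cv_reports.json")

                selection = regress.select_model(reports)
                _write_json(
                    {"selected": selection.selected,
                     "excluded_for_instability":
                         selection.excluded_for_instability,
                     "rule": selection.rule,
                     "ranking": selection.ranking.to_dict(orient="records")},
                    out / "model_selection.json")
                _emit("model_selection.json")

                stage = "final-model"
                sel_spec = next(s for s in specs
                                if s.label == selection.selected)
                final = sel_spec.build(yfit.to_numpy(), X.to_numpy(),
                                       list(X.columns)).fit()
                (out / "final_model.json").write_text(final.to_json() + "\n")
                _emit("final_model.json")
                parity = regress.metrics(yfit, final.predict(X))
                _write_json(parity, out / "parity_metrics.json")
                _emit("parity_metrics.json")

                stage = "shapley"
                p = X.shape[1]
                method = config.shapley_method
                # exact enumeration is batched over 2^p x n rows; keep it
                # for small retained sets and sample permutations otherwise
                if method == "auto":
                    method = "exact" if p <= 10 else "permutation"
                result = shapley.explain_rows(
                    final.predict, X, X.to_numpy(), method=method,
                    n_permutations=config.shapley_permutations,
                    seed=config.seed, feature_names=list(X.columns))
                ranking = shapley.global_importance(result)
                ranking.to_csv(out / "shapley_ranking.csv", index=False,
                               float_format=FLOAT_FMT)
                _emit("shapley_ranking.csv")

            stage = "residue-map"
            if manifest["mode"] == "full" and config.trajectories:
                rmsf_rows = {}
                for cid, paths in config.trajectories.items():
                    per_rep = [descriptors.rmsf_per_residue(
                        trajio.read_structure(p), config=config.descriptor)
                        for p in paths]
                    rmsf_rows[cid] = pd.concat(per_rep, axis=1).mean(axis=1)
                rmsf_matrix = pd.DataFrame(rmsf_rows).T.sort_index()
                if rmsf_matrix.shape[0] >= 3:
                    r2 = statsel.residue_level_r2(
                        rmsf_matrix, y.loc[rmsf_matrix.index])
                    first_cid = sorted(config.trajectories)[0]
                    ref = trajio.read_structure(
                        config.trajectories[first_cid][0])
                    trajio.write_bfactor_map(
                        ref, r2.fillna(0.0).to_dict(),
                        out / "residue_r2_bfactor.pdb")
                    _emit("residue_r2_bfactor.pdb")

        collected = list(caught)
    except Exception as exc:
        manifest["failure"] = {"stage": stage, "error": str(exc)}
        manifest["warnings"] = [str(w.message) for w in collected]
        _write_json(manifest, out / "manifest.json")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["warnings"] = [str(w.message) for w in collected]
    _write_json(manifest, out / "manifest.json")
    return manifest
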