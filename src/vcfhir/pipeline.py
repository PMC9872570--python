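"""Pipeline orchestration: simulate -> vcf2matrix -> fhir2table -> merge
-> {cluster, pgx, export}, with a validated config and a run manifest.

Every stage runs on the local filesystem; the manifest records each
stage's parameters, row/column counts and output-file SHA-256 digests,
so a re-run with the same config is verifiably byte-identical for the
deterministic stages.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import analysis, cohort_sim, fhir_flatten, variant_matrix

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Aggregated, human-readable config validation failure."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Model):
    n: int = Field(default=200, ge=1)
    missing_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    background_sites: int = Field(default=100, ge=0)
    untreated_arm: bool = False


class LdConfig(_Model):
    r2: float = Field(default=0.5, ge=0.0, le=1.0)
    window: int = Field(default=50, ge=2)
    step: int = Field(default=5, ge=1)


class ClusterConfig(_Model):
    enabled: bool = True
    method: Literal["kmeans", "dbscan", "spectral"] = "kmeans"
    k: int | Literal["auto"] = "auto"
    k_range: list[int] = Field(default_factory=lambda: list(range(1, 9)))
    eps: float = Field(default=0.5, gt=0.0)
    min_samples: int = Field(default=5, ge=1)
    gamma: float = Field(default=1.0, gt=0.0)


class PgxConfig(_Model):
    enabled: bool = True
    alpha: float = Field(default=0.01, gt=0.0, lt=1.0)


class ExportConfig(_Model):
    enabled: bool = True
    format: Literal["parquet", "csv"] = "csv"


class PipelineConfig(_Model):
    out_dir: str = "pipeline_out"
    seed: int = 0
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    ld: LdConfig = Field(default_factory=LdConfig)
    cluster: ClusterConfig = Field(default_factory=ClusterConfig)
    pgx: PgxConfig = Field(default_factory=PgxConfig)
    export: ExportConfig = Field(default_factory=ExportConfig)


def validate_config(document: dict) -> PipelineConfig:
    """Validate a config document; all violations are reported at once."""
    try:
        cfg = PipelineConfig.model_validate(document or {})
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc']) or '<root>'}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigError("invalid pipeline config:\n" + "\n".join(lines)) from exc
    logger.info("resolved config: %s", cfg.model_dump())
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages in dependency order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.model_dump(), "stages": []}

    def record(stage: str, params: dict, counts: dict, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "counts": counts,
                "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
            }
        )
        logger.info("stage %s done: %s", stage, counts)

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        module = cohort_sim.default_module()
        module.untreated_arm = config.simulate.untreated_arm
        cohort = cohort_sim.write_cohort(
            out, n=config.simulate.n, seed=config.seed, module=module,
            missing_rate=config.simulate.missing_rate,
            n_background_sites=config.simulate.background_sites,
        )
        record(
            stage, config.simulate.model_dump(), {"patients": len(cohort)},
            [out / "truth.tsv"],
        )
    except Exception as exc:
        _abort(manifest, out, stage, exc)

    # --- vcf2matrix ---------------------------------------------------------
    stage = "vcf2matrix"
    try:
        vcfs = sorted((out / "vcf").glob("*.vcf"))
        matrix = variant_matrix.vcfs_to_matrix(
            vcfs, reference=None, r2_threshold=config.ld.r2,
            window=config.ld.window, step=config.ld.step,
        )
        matrix_path = out / "matrix.tsv"
        variant_matrix.write_tsv(matrix, matrix_path)
        record(
            stage, config.ld.model_dump(),
            {"patients": len(matrix.patients), "variants": len(matrix.site_keys)},
            [matrix_path],
        )
    except Exception as exc:
        _abort(manifest, out, stage, exc)

    # --- fhir2table ---------------------------------------------------------
    stage = "fhir2table"
    try:
        bundles = fhir_flatten.load_bundle_dir(out / "fhir")
        clinical = fhir_flatten.flatten_bundles(bundles)
        clinical_path = out / "clinical.parquet"
        fhir_flatten.write_columnar(clinical, clinical_path)
        record(
            stage, {}, {"patients": len(clinical), "columns": len(clinical.columns)},
            [clinical_path],
        )
    except Exception as exc:
        _abort(manifest, out, stage, exc)

    # --- merge --------------------------------------------------------------
    stage = "merge"
    try:
        merged, drop = analysis.merge_tables(clinical, matrix)
        merged_path = out / "merged.parquet"
        merged.to_parquet(merged_path, index=False)
        drop_path = out / "drop_report.json"
        drop_path.write_text(
            json.dumps(
                {"clinical_only": drop.clinical_only, "genomic_only": drop.genomic_only},
                indent=1,
            )
        )
        record(
            stage, {},
            {"rows": len(merged), "dropped": drop.n_dropped},
            [merged_path, drop_path],
        )
    except Exception as exc:
        _abort(manifest, out, stage, exc)

    # --- cluster ------------------------------------------------------------
    if config.cluster.enabled:
        stage = "cluster"
        try:
            fc = analysis.FeatureConfig(
                genotype_columns=[c for c in merged.columns if c.endswith(":GT")],
                categorical_columns=[c for c in ("gender", "medication_1") if c in merged],
                numeric_columns=[c for c in ("age",) if c in merged],
            )
            X = analysis.encode_features(merged, fc).to_numpy()
            cc = config.cluster
            if cc.method == "kmeans":
                k = cc.k
                curve = None
                if k == "auto":
                    k, curve = analysis.elbow_select(X, cc.k_range, seed=config.seed)
                clust = analysis.kmeanspp(X, int(k), seed=config.seed)
            elif cc.method == "dbscan":
                clust = analysis.dbscan(X, eps=cc.eps, min_samples=cc.min_samples)
                curve = None
            else:
                k = cc.k
                curve = None
                if k == "auto":
                    k, curve = analysis.elbow_select(X, cc.k_range, seed=config.seed)
                clust = analysis.spectral(X, int(k), gamma=cc.gamma, seed=config.seed)
            metrics: dict = {
                "method": cc.method, "k": clust.k, "inertia": clust.inertia,
                "noise_fraction": clust.noise_fraction,
            }
            mask = clust.labels != analysis.NOISE
            if clust.k >= 2:
                metrics["davies_bouldin"] = analysis.davies_bouldin(X[mask], clust.labels[mask])
                metrics["calinski_harabasz"] = analysis.calinski_harabasz(X[mask], clust.labels[mask])
                metrics["silhouette"] = analysis.silhouette(X[mask], clust.labels[mask])
            if curve is not None:
                metrics["inertia_curve"] = dict(zip(map(str, cc.k_range), curve))
            metrics_path = out / "cluster_metrics.json"
            metrics_path.write_text(json.dumps(metrics, indent=1))
            record(stage, cc.model_dump(), {"k": clust.k, "rows": len(X)}, [metrics_path])
        except Exception as exc:
            _abort(manifest, out, stage, exc)

    # --- pgx ----------------------------------------------------------------
    if config.pgx.enabled:
        stage = "pgx"
        try:
            pgx_col = f"{cohort_sim.PGX_SITE.key}:GT"
            results, contingency = analysis.pgx_study(
                merged, pgx_col, alpha=config.pgx.alpha
            )
            report = pd.DataFrame(
                [
                    {"carrier": r.carrier, "drug": r.drug, "n": r.n,
                     "survivors": r.survivors, "z": r.z, "p": r.p,
                     "significant": r.significant, "testable": r.testable}
                    for r in results
                ]
            )
            report_path = out / "pgx_report.tsv"
            report.to_csv(report_path, sep="\t", index=False)
            cont_path = out / "pgx_contingency.tsv"
            contingency.to_csv(cont_path, sep="\t", index=False)
            record(
                stage, config.pgx.model_dump(),
                {"groups": len(results),
                 "significant": int(sum(r.significant for r in results))},
                [report_path, cont_path],
            )
        except Exception as exc:
            _abort(manifest, out, stage, exc)

    # --- export -------------------------------------------------------------
    if config.export.enabled:
        stage = "export"
        try:
            ext = "csv" if config.export.format == "csv" else "parquet"
            export_path = out / f"merged_export.{ext}"
            if ext == "csv":
                merged.to_csv(export_path, index=False)
            else:
                merged.to_parquet(export_path, index=False)
            record(stage, config.export.model_dump(), {"rows": len(merged)}, [export_path])
        except Exception as exc:
            _abort(manifest, out, stage, exc)

    manifest["completed_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _abort(manifest: dict, out: Path, stage: str, exc: Exception) -> None:
    """Persist the upstream manifest, then surface the failing stage."""
    manifest["failed_stage"] = stage
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    raise StageError(stage, exc) from exc
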