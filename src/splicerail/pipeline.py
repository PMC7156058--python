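"""End-to-end orchestration: simulate -> preprocess -> evaluate -> power -> railway.

A run is described by a :class:`RunConfig` (loadable from a YAML file; CLI
flags override file values) and executed by :func:`run_pipeline`, which
writes every stage's output as tab-delimited text plus a JSON manifest
recording the package version, seeds, input digests and output paths.
Rerunning the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .evaluation import evaluate_with_null
from .power import (
    PowerConfig,
    mal_pool_from_evaluation,
    power_table,
    residual_pool_from_evaluation,
    write_power_table,
)
from .predictor import PredictorConfig, read_gene_set
from .preprocess import (
    build_probe_table,
    emit_gene_tables,
    load_cel_directory,
    load_tabular_matrix,
    pca_report,
    read_annotation,
    read_phenotype,
)
from .railway import railway_table
from .synthetic import SyntheticConfig, generate_dataset, write_fixture

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Paths plus per-stage configuration for one pipeline run."""

    output_dir: str = "splicerail_run"
    cel_dir: str | None = None
    matrix_path: str | None = None
    annotation_path: str | None = None
    phenotype_path: str | None = None
    gene_set_path: str | None = None
    railway_gene: str | None = None
    simulate: bool = False
    emit_genes: bool = False
    log_level: str = "INFO"
    seed: int = 0
    n_null: int = 1000
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    predictor: PredictorConfig = field(default_factory=PredictorConfig)
    power: PowerConfig = field(default_factory=PowerConfig)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        synth = SyntheticConfig(**raw.pop("synthetic", {}))
        pred = PredictorConfig(**{
            k: (tuple(v) if k == "gene_set" and v is not None else v)
            for k, v in raw.pop("predictor", {}).items()
        })
        power_raw = raw.pop("power", {})
        for key in ("effects", "study_sizes"):
            if key in power_raw:
                power_raw[key] = tuple(power_raw[key])
        return cls(synthetic=synth, predictor=pred,
                   power=PowerConfig(**power_raw), **raw)

    def validate_paths(self) -> None:
        if self.simulate:
            return
        required = {
            "annotation_path": self.annotation_path,
            "phenotype_path": self.phenotype_path,
        }
        if self.cel_dir is None and self.matrix_path is None:
            raise PipelineError(
                "configuration: neither a CEL directory nor a tabular "
                "matrix path was given"
            )
        for name, value in required.items():
            if value is None:
                raise PipelineError(f"configuration: {name} is required")
            if not Path(value).exists():
                raise PipelineError(f"configuration: {name} {value!r} does not exist")
        if self.cel_dir is not None and not Path(self.cel_dir).is_dir():
            raise PipelineError(f"configuration: cel_dir {self.cel_dir!r} does not exist")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _with_seed(cfg, seed: int):
    return dataclasses.replace(cfg, seed=seed)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every requested stage in order; return the run manifest.

    The global seed propagates deterministically to each stage.  A stage
    failure raises :class:`PipelineError` naming the stage; outputs written
    before the failure stay on disk next to an ``INCOMPLETE`` marker.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")

    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
        "inputs": {},
        "outputs": {},
        "defaults": {
            "selection_metric": cfg.predictor.selection_metric,
            "r2_definition": "squared Pearson correlation of pooled predictions",
            "null_model": "phenotype permutation through the full pipeline",
            "power_statistic": cfg.power.statistic,
        },
    }
    stage = "setup"
    try:
        cfg.validate_paths()

        if cfg.simulate:
            stage = "simulate"
            synth = _with_seed(cfg.synthetic, cfg.seed)
            dataset = generate_dataset(synth)
            fixture_dir = out / "fixture"
            paths = write_fixture(dataset, fixture_dir)
            cfg.cel_dir = str(fixture_dir)
            cfg.annotation_path = str(paths["annotation"])
            cfg.phenotype_path = str(paths["phenotype"])
            if cfg.gene_set_path is None:
                cfg.gene_set_path = str(paths["biomarker_genes"])
            manifest["stages"].append("simulate")
            logger.info("simulated %d probes x %d participants",
                        synth.n_probes, synth.n_participants)

        stage = "preprocess"
        annotation = read_annotation(cfg.annotation_path)
        mal = read_phenotype(cfg.phenotype_path)
        if cfg.cel_dir is not None:
            cel_paths = sorted(Path(cfg.cel_dir).glob("*.CEL"))
            raw = load_cel_directory(cel_paths, annotation)
        else:
            raw = load_tabular_matrix(cfg.matrix_path)
            raw = raw.loc[annotation.index.intersection(raw.index)]
            annotation = annotation.loc[raw.index]
        table, report = build_probe_table(raw, annotation)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        pca_report(table).to_csv(out / "pca_scores.tsv", sep="\t")
        manifest["inputs"] = {
            "annotation": _sha256(Path(cfg.annotation_path)),
            "phenotype": _sha256(Path(cfg.phenotype_path)),
        }
        manifest["stages"].append("preprocess")
        if cfg.emit_genes:
            gene_dir = out / "genes"
            emit_gene_tables(table, gene_dir)
            manifest["outputs"]["gene_tables"] = str(gene_dir)

        stage = "evaluate"
        pred_cfg = _with_seed(cfg.predictor, cfg.seed)
        if cfg.gene_set_path is not None:
            pred_cfg = dataclasses.replace(
                pred_cfg, gene_set=read_gene_set(cfg.gene_set_path)
            )
        result = evaluate_with_null(table, mal, pred_cfg, n_null=cfg.n_null)
        summary = pd.DataFrame(
            [
                {
                    "model": pred_cfg.model_kind,
                    "r2": result.r2,
                    "r2_variance_explained": result.r2_variance_explained,
                    "p_value": result.p_value,
                    "rmsd": result.rmsd,
                    "n_repetitions": result.n_repetitions,
                    "n_null": len(result.null_r2),
                }
            ]
        )
        summary.to_csv(out / "evaluation_summary.tsv", sep="\t", index=False)
        result.records().to_csv(out / "pooled_predictions.tsv", sep="\t", index=False)
        manifest["outputs"]["evaluation"] = str(out / "evaluation_summary.tsv")
        manifest["stages"].append("evaluate")

        stage = "power"
        pw_cfg = _with_seed(cfg.power, cfg.seed)
        pw = power_table(
            pw_cfg,
            residual_pool_from_evaluation(result),
            mal_pool_from_evaluation(result),
        )
        write_power_table(pw, out / "power_table.tsv")
        manifest["outputs"]["power"] = str(out / "power_table.tsv")
        manifest["stages"].append("power")

        stage = "railway"
        gene = cfg.railway_gene
        if gene is None and pred_cfg.gene_set:
            gene = pred_cfg.gene_set[0]
        if gene is not None:
            slice_ = table[table["gene_name"] == gene]
            if len(slice_) == 0:
                raise PipelineError(f"railway: gene {gene!r} not in probe table")
            frame, thresholds = railway_table(slice_, mal)
            frame.to_csv(out / f"railway_{gene}.tsv", sep="\t", index=False)
            manifest["outputs"]["railway"] = str(out / f"railway_{gene}.tsv")
            manifest["outputs"]["railway_thresholds"] = {
                "nominal": thresholds.nominal,
                "corrected": thresholds.corrected,
            }
            manifest["stages"].append("railway")

    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    marker.unlink(missing_ok=True)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest
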