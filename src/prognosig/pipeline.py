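"""End-to-end orchestration of the signature discovery pipeline.

``run_full_pipeline`` wires the stages together — label assignment,
discovery split, correlation screen, LOOCV signature-size sweep, Cox
forward selection, and validation — writing each stage's outputs as TSV
(plus the signature JSON) under an output directory, and recording a run
manifest with parameters, SHA-256 digests of every output file, wall
times and warnings. One global seed governs all stochastic steps, so a
re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, prep, screen, signature as sig, validation
from .io import read_clinical, read_expression, reconcile_samples, write_expression
from .survstats import SurvivalComparison
from .synthetic import ConfigurationError, SimulationConfig, simulate_cohort, write_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_full_pipeline"]

FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Resolved settings for a full pipeline run.

    Either ``expression_path``/``clinical_path`` point at input TSVs, or
    ``simulation`` describes a synthetic cohort to generate in place.
    Discovery training-draw sizes default to 75% of each prognosis class
    when not given explicitly.
    """

    expression_path: str | None = None
    clinical_path: str | None = None
    simulation: SimulationConfig | None = None
    # phase I
    horizon_years: float = 3.0
    time_unit: str = "years"
    n_poor_train: int | None = None
    n_good_train: int | None = None
    train_fraction: float = 0.75
    r_threshold: float = 0.3
    n_permutations: int = 10_000
    size_select: str = "largest-min"
    #: screen/classify on log2(x+1) expression; sensible for RPKM-like data
    log2_screen: bool = False
    # phase II
    phase2_fraction: float = 0.5
    housekeeping_genes: tuple[str, ...] = sig.NormalizationConfig().housekeeping_genes
    max_k: int = 118
    endpoint: str = "dfs"
    balance_threshold: float = 0.05
    balance_retries: int = 100
    # validation
    strata: list = field(default_factory=list)
    validation_endpoints: tuple[str, ...] = ("dfs", "os")
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.expression_path is not None and self.clinical_path is not None
        if not has_files and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if has_files and self.simulation is not None:
            raise ConfigurationError("give input paths or a simulation config, not both")


@dataclass
class RunManifest:
    """Stage-by-stage record of a pipeline run."""

    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def add_stage(self, name: str, params: dict, outputs: dict, wall_time: float) -> None:
        self.stages[name] = {
            "params": params,
            "outputs": outputs,
            "wall_time_s": round(wall_time, 3),
        }

    def digests(self) -> dict[str, str]:
        return {
            path: meta
            for stage in self.stages.values()
            for path, meta in stage["outputs"].items()
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _comparison_row(c: SurvivalComparison) -> dict:
    return {
        "label": c.label,
        "endpoint": c.endpoint,
        "n_low": c.group_sizes.get("low", c.group_sizes.get("no-ACT", 0)),
        "n_high": c.group_sizes.get("high", c.group_sizes.get("ACT", 0)),
        "statistic": c.statistic,
        "p_value": c.p_value,
        "method": c.method,
    }


class StageError(RuntimeError):
    """A pipeline stage failed; the partial manifest was saved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_full_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute every stage in order; returns the saved manifest.

    A failing stage aborts the run: the partial manifest (with the
    completed stages) is still written and a :class:`StageError` naming
    the stage is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, config=_jsonable(dataclasses.asdict(config)))
    stage_tracker = {"current": "inputs"}
    try:
        _run_stages(config, out, manifest, stage_tracker)
    except Exception as exc:
        manifest.warnings.append(f"aborted in stage {stage_tracker['current']}: {exc}")
        manifest.save(out / "manifest.json")
        raise StageError(stage_tracker["current"], exc) from exc
    manifest.save(out / "manifest.json")
    return manifest


def _run_stages(config: PipelineConfig, out: Path, manifest: RunManifest,
                stage_tracker: dict) -> None:
    def finish_stage(name: str, params: dict, files: list[Path], t0: float) -> None:
        outputs = {str(p.relative_to(out)): _sha256(p) for p in files}
        manifest.add_stage(name, _jsonable(params), outputs, _time.perf_counter() - t0)

    # --- inputs ---------------------------------------------------------
    stage_tracker["current"] = "inputs"
    t0 = _time.perf_counter()
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation)
        paths = write_cohort(cohort, out / "cohort")
        expr, clinical = cohort.expression, cohort.clinical
        finish_stage(
            "simulate", dataclasses.asdict(config.simulation), list(paths.values()), t0
        )
    else:
        expr = read_expression(config.expression_path)
        clinical = read_clinical(config.clinical_path)
        expr, clinical, recon = reconcile_samples(expr, clinical)
        if recon.n_dropped:
            manifest.warnings.append(
                f"dropped {recon.n_dropped} unmatched sample(s) while reconciling inputs"
            )
        finish_stage(
            "load",
            {"expression": config.expression_path, "clinical": config.clinical_path},
            [],
            t0,
        )

    # --- prep -----------------------------------------------------------
    stage_tracker["current"] = "prep"
    t0 = _time.perf_counter()
    labels = prep.assign_prognosis_labels(
        clinical, config.horizon_years, time_unit=config.time_unit
    )
    n_poor = int((labels == prep.POOR).sum())
    n_good = int((labels == prep.GOOD).sum())
    n_poor_train = config.n_poor_train or max(1, int(config.train_fraction * n_poor))
    n_good_train = config.n_good_train or max(1, int(config.train_fraction * n_good))
    train_ids, test_ids = prep.split_phase1(
        labels, prep.SplitConfig(n_poor_train, n_good_train, seed=config.seed)
    )
    labels.to_frame().to_csv(out / "labels.tsv", sep="\t", index_label="sample_id")
    pd.Series(train_ids, name="sample_id").to_csv(out / "phase1_train.tsv", sep="\t", index=False)
    pd.Series(test_ids, name="sample_id").to_csv(out / "phase1_test.tsv", sep="\t", index=False)
    finish_stage(
        "prep",
        {"horizon_years": config.horizon_years, "n_poor_train": n_poor_train,
         "n_good_train": n_good_train, "n_poor": n_poor, "n_good": n_good},
        [out / "labels.tsv", out / "phase1_train.tsv", out / "phase1_test.tsv"],
        t0,
    )

    # --- screen ---------------------------------------------------------
    stage_tracker["current"] = "screen"
    t0 = _time.perf_counter()
    phase1_expr = np.log2(expr + 1.0) if config.log2_screen else expr
    screen_cfg = screen.ScreenConfig(
        r_threshold=config.r_threshold,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    result = screen.permutation_null(phase1_expr[train_ids], labels[train_ids], screen_cfg)
    ranked = pd.DataFrame(
        {"gene": result.retained, "r": result.r_values[result.retained].to_numpy()}
    )
    ranked.to_csv(out / "ranked_genes.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    pd.Series(result.null_counts, name="retained_count").to_csv(
        out / "null_counts.tsv", sep="\t", index=False
    )
    if result.n_retained < 2:
        manifest.warnings.append("screen retained fewer than 2 genes")
    finish_stage(
        "screen",
        {"r_threshold": config.r_threshold, "n_permutations": config.n_permutations,
         "n_retained": result.n_retained, "empirical_p": result.empirical_p},
        [out / "ranked_genes.tsv", out / "null_counts.tsv"],
        t0,
    )

    # --- loocv ----------------------------------------------------------
    stage_tracker["current"] = "loocv"
    t0 = _time.perf_counter()
    report = classifier.loocv_sweep(phase1_expr, labels[train_ids], result.retained)
    errors = pd.DataFrame(
        {"size": list(report.errors), "errors": list(report.errors.values())}
    )
    errors.to_csv(out / "loocv_errors.tsv", sep="\t", index=False)
    selected_size = classifier.select_signature_size(report, config.size_select)
    discovery_genes = result.retained[:selected_size]

    labeled = labels[labels != prep.EXCLUDED]
    scaled = classifier.zscore_genes(phase1_expr[list(labeled.index)])
    roc_rows = []
    for size in report.min_error_sizes:
        genes_s = result.retained[:size]
        templates = classifier.build_templates(scaled[train_ids], labels[train_ids], genes_s)
        risk = classifier.risk_coefs(scaled, templates)
        curve = classifier.roc_curve(risk, labeled)
        roc_rows.append(
            {"signature": f"{size}-gene", "AUC": curve.auc, "SE": curve.se,
             "ci_lower": curve.ci_lower, "ci_upper": curve.ci_upper}
        )
    pd.DataFrame(roc_rows).to_csv(
        out / "roc_table.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    finish_stage(
        "loocv",
        {"sizes": len(report.errors), "min_error": report.min_error,
         "min_error_sizes": report.min_error_sizes, "selected_size": selected_size,
         "size_select": config.size_select},
        [out / "loocv_errors.tsv", out / "roc_table.tsv"],
        t0,
    )

    # --- cox-select -----------------------------------------------------
    stage_tracker["current"] = "cox-select"
    t0 = _time.perf_counter()
    norm_cfg = sig.NormalizationConfig(housekeeping_genes=tuple(config.housekeeping_genes))
    normalized = sig.housekeeping_normalize(expr, norm_cfg)
    p2_train, p2_test, balance = prep.split_phase2(
        clinical,
        config.phase2_fraction,
        seed=config.seed,
        balance_threshold=config.balance_threshold,
        max_retries=config.balance_retries,
    )
    balance.rows.to_csv(out / "balance_report.tsv", sep="\t", index=False,
                        float_format=FLOAT_FORMAT)
    candidates = [g for g in discovery_genes if g in normalized.index]
    ranking = sig.univariate_rank(
        normalized.loc[candidates, p2_train],
        clinical.loc[p2_train, f"{config.endpoint}_time"],
        clinical.loc[p2_train, f"{config.endpoint}_event"],
    )
    if config.max_k > len(candidates):
        manifest.warnings.append(
            f"max_k={config.max_k} exceeds the {len(candidates)} screened genes; truncated"
        )
    weighted, trace = sig.forward_cox_select(
        ranking,
        normalized.loc[candidates, p2_train],
        normalized.loc[candidates, p2_test],
        clinical.loc[p2_train],
        clinical.loc[p2_test],
        max_k=min(config.max_k, len(candidates)),
        endpoint=config.endpoint,
        normalization=norm_cfg,
    )
    weighted.save(out / "signature.json")
    trace.to_csv(out / "selection_trace.tsv", sep="\t", index=False,
                 float_format=FLOAT_FORMAT)
    finish_stage(
        "cox-select",
        {"max_k": min(config.max_k, len(candidates)), "endpoint": config.endpoint,
         "selected_k": weighted.metadata["selected_k"],
         "housekeeping": list(config.housekeeping_genes)},
        [out / "balance_report.tsv", out / "signature.json", out / "selection_trace.tsv"],
        t0,
    )

    # --- validate -------------------------------------------------------
    stage_tracker["current"] = "validate"
    t0 = _time.perf_counter()
    risk = validation.score_cohort(expr[p2_test], weighted)
    rows = []
    for endpoint in config.validation_endpoints:
        if f"{endpoint}_time" in clinical.columns:
            rows.append(_comparison_row(
                validation.compare_endpoint(risk, clinical, endpoint)
            ))
    for res in validation.stratified_analysis(risk, clinical, config.strata, seed=config.seed):
        if res.comparison is not None:
            rows.append(_comparison_row(res.comparison))
        else:
            manifest.warnings.append(f"stratum {res.name!r} skipped: {res.skipped_reason}")
    pd.DataFrame(rows).to_csv(out / "validation.tsv", sep="\t", index=False,
                              float_format=FLOAT_FORMAT)
    enrich = validation.stage_enrichment(risk, clinical)
    enrich.table.assign(p_value=enrich.p_value).to_csv(
        out / "stage_enrichment.tsv", sep="\t", float_format=FLOAT_FORMAT
    )
    risk.scores.to_frame().assign(group=risk.groups).to_csv(
        out / "risk_scores.tsv", sep="\t", index_label="sample_id",
        float_format=FLOAT_FORMAT,
    )
    finish_stage(
        "validate",
        {"endpoints": list(config.validation_endpoints), "n_strata": len(config.strata)},
        [out / "validation.tsv", out / "stage_enrichment.tsv", out / "risk_scores.tsv"],
        t0,
    )

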