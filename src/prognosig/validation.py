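"""Applying a weighted signature to a cohort and validating it.

Given a serialized :class:`~prognosig.signature.WeightedSignature`, this
module scores any expression cohort (RNA-seq or microarray), splits it at
the median score, and runs the validation battery: Kaplan-Meier / log-rank
comparisons per survival endpoint, stratified analyses (stage, mismatch
repair status, adjuvant chemotherapy), and the stage-enrichment
contingency test between high- and low-score groups.

Microarray matrices with several probes per gene are first collapsed by
keeping, for each gene, the probe with the smallest univariate Cox p-value
on the validation cohort's own survival data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coxscan import cox_scan
from .io import DataError
from .screen import StatisticalError
from .signature import WeightedSignature
from .survstats import HIGH, LOW, MedianSplit, SurvivalComparison, km_logrank, median_split

__all__ = [
    "RiskScores",
    "ContingencyResult",
    "StratumResult",
    "collapse_probes",
    "score_cohort",
    "compare_endpoint",
    "stratified_analysis",
    "stage_enrichment",
]

EARLY_STAGES = ("I", "II")
ADVANCED_STAGES = ("III", "IV")
UNKNOWN_VALUES = {"", "na", "nan", "unknown", "none"}


@dataclass
class RiskScores:
    """Per-sample weighted risk scores with their median-split groups."""

    scores: pd.Series
    split: MedianSplit

    @property
    def groups(self) -> pd.Series:
        return self.split.groups


def collapse_probes(
    probe_matrix: pd.DataFrame,
    probe_map: pd.DataFrame,
    time: pd.Series,
    event: pd.Series,
    *,
    require: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One row per gene: the probe with the minimum univariate Cox p.

    ``probe_map`` has columns ``probe_id`` and ``gene_id``. Ties (and
    probes whose fit does not converge) are resolved by probe identifier.
    With ``require``, genes absent from the map (or without any probe in
    the matrix) raise an error listing them.

    Returns ``(gene_matrix, choices)`` where ``choices`` records the chosen
    probe and its Cox p per gene.
    """
    for col in ("probe_id", "gene_id"):
        if col not in probe_map.columns:
            raise DataError(f"probe map lacks column {col!r}")
    pmap = probe_map[probe_map["probe_id"].isin(probe_matrix.index)]
    if require is not None:
        covered = set(pmap["gene_id"])
        missing = sorted(set(require) - covered)
        if missing:
            raise DataError(f"no probe found for signature gene(s): {missing}")
    scan = cox_scan(
        probe_matrix.loc[pmap["probe_id"]],
        time[probe_matrix.columns].to_numpy(dtype=float),
        event[probe_matrix.columns].to_numpy(),
    )
    ranked = pmap.assign(
        p=scan.loc[pmap["probe_id"], "p"].to_numpy(),
        converged=scan.loc[pmap["probe_id"], "converged"].to_numpy(),
    )
    ranked["_p"] = np.where(ranked["converged"], ranked["p"], np.inf)
    ranked = ranked.sort_values(["gene_id", "_p", "probe_id"])
    chosen = ranked.groupby("gene_id", sort=True).first().reset_index()
    gene_matrix = probe_matrix.loc[chosen["probe_id"]].copy()
    gene_matrix.index = pd.Index(chosen["gene_id"], name="gene_id")
    choices = chosen[["gene_id", "probe_id", "p"]].rename(columns={"p": "cox_p"})
    return gene_matrix, choices


def score_cohort(expr: pd.DataFrame, signature: WeightedSignature) -> RiskScores:
    """Normalize, score and median-split a cohort with ``signature``.

    Scoring is deterministic and independent of sample order. A degenerate
    split (all scores identical) is flagged on the result rather than
    raised, since downstream analyses may still proceed groupwise.
    """
    scores = signature.scores(expr)
    return RiskScores(scores=scores, split=median_split(scores))


def compare_endpoint(
    risk: RiskScores,
    clinical: pd.DataFrame,
    endpoint: str = "dfs",
    *,
    method: str = "asymptotic",
    seed: int = 0,
    label: str = "",
) -> SurvivalComparison:
    """High-vs-low log-rank comparison for one survival endpoint."""
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for col in (tcol, ecol):
        if col not in clinical.columns:
            raise DataError(f"clinical table lacks column {col!r}")
    idx = risk.groups.index.intersection(clinical.index)
    return km_logrank(
        risk.groups[idx],
        clinical.loc[idx, tcol].astype(float),
        clinical.loc[idx, ecol].astype(int),
        endpoint,
        method=method,
        seed=seed,
        label=label or f"{endpoint}: high vs low score",
    )


@dataclass
class StratumResult:
    """Outcome of one stratified comparison (or the reason it was skipped)."""

    name: str
    filter_desc: str
    comparison: SurvivalComparison | None = None
    skipped_reason: str | None = None


def _apply_filter(clinical: pd.DataFrame, flt: dict) -> pd.Index:
    mask = pd.Series(True, index=clinical.index)
    for col, wanted in flt.items():
        if col not in clinical.columns:
            raise DataError(f"stratum filter references missing column {col!r}")
        values = wanted if isinstance(wanted, (list, tuple, set)) else [wanted]
        mask &= clinical[col].astype(str).isin([str(v) for v in values])
    return clinical.index[mask]


def stratified_analysis(
    risk: RiskScores,
    clinical: pd.DataFrame,
    strata_spec: list[dict],
    *,
    method: str = "asymptotic",
    seed: int = 0,
) -> list[StratumResult]:
    """Run a list of stratified survival comparisons.

    Each stratum is a mapping with keys:

    ``name``
        identifier for the report;
    ``filter``
        column -> value(s) restriction applied to the clinical table
        (e.g. ``{"stage": ["II", "III"], "mmr_status": "pMMR"}``);
    ``endpoint``
        survival endpoint (default ``"dfs"``);
    ``compare``
        ``"score"`` (default) compares the high- vs low-score groups of the
        cohort-wide median split within the stratum; ``"act"`` compares
        treated vs untreated patients *within* one score group, named by
        ``score_group`` (``"low"`` or ``"high"``) — the treatment-
        interaction analysis.

    Strata whose comparison cannot be formed (an empty arm, no events)
    are returned with a ``skipped_reason`` instead of failing the batch.
    """
    results: list[StratumResult] = []
    for spec in strata_spec:
        name = spec.get("name", "stratum")
        flt = spec.get("filter", {})
        endpoint = spec.get("endpoint", "dfs")
        compare = spec.get("compare", "score")
        desc = ", ".join(f"{k}={v}" for k, v in flt.items()) or "all samples"
        try:
            idx = _apply_filter(clinical, flt).intersection(risk.groups.index)
            if len(idx) == 0:
                raise StatisticalError("stratum matches no samples")
            if compare == "score":
                groups = risk.groups[idx]
                label = f"{name}: high vs low score [{desc}]"
            elif compare == "act":
                score_group = spec.get("score_group", LOW)
                idx = idx[risk.groups[idx] == score_group]
                if "act_flag" not in clinical.columns:
                    raise DataError("clinical table lacks column 'act_flag'")
                groups = pd.Series(
                    np.where(clinical.loc[idx, "act_flag"].astype(int) == 1, "ACT", "no-ACT"),
                    index=idx,
                )
                label = f"{name}: ACT vs no-ACT in {score_group}-score [{desc}]"
            else:
                raise DataError(f"unknown compare mode {compare!r}")
            if groups.nunique() < 2:
                raise StatisticalError("a comparison arm is empty")
            comparison = km_logrank(
                groups,
                clinical.loc[groups.index, f"{endpoint}_time"].astype(float),
                clinical.loc[groups.index, f"{endpoint}_event"].astype(int),
                endpoint,
                method=method,
                seed=seed,
                label=label,
            )
            results.append(StratumResult(name=name, filter_desc=desc, comparison=comparison))
        except (StatisticalError, DataError) as exc:
            results.append(
                StratumResult(name=name, filter_desc=desc, skipped_reason=str(exc))
            )
    return results


@dataclass
class ContingencyResult:
    """A contingency table with its two-sided exact test."""

    table: pd.DataFrame
    test: str
    p_value: float
    n_excluded: int = 0
    warning: str | None = None


def stage_enrichment(risk: RiskScores, clinical: pd.DataFrame) -> ContingencyResult:
    """Fisher test of advanced stage (III & IV) vs score group.

    Unknown stages are excluded (counted in the result). A zero margin
    (e.g. nobody in advanced stage) yields p = 1 with a warning.
    """
    if "stage" not in clinical.columns:
        raise DataError("clinical table lacks column 'stage'")
    stage = clinical.loc[risk.groups.index, "stage"].astype(str).str.strip()
    known = ~(stage.str.lower().isin(UNKNOWN_VALUES) | stage.isna())
    stage = stage[known]
    groups = risk.groups[stage.index]
    early = stage.isin(EARLY_STAGES)
    advanced = stage.isin(ADVANCED_STAGES)
    unknown_labels = stage[~(early | advanced)]
    if len(unknown_labels):
        keep = early | advanced
        stage, groups = stage[keep], groups[keep]
        early, advanced = early[keep], advanced[keep]
    table = pd.DataFrame(
        {
            "stage I & II": [
                int((early & (groups == HIGH)).sum()),
                int((early & (groups == LOW)).sum()),
            ],
            "stage III & IV": [
                int((advanced & (groups == HIGH)).sum()),
                int((advanced & (groups == LOW)).sum()),
            ],
        },
        index=["high score", "low score"],
    )
    n_excluded = int((~known).sum()) + len(unknown_labels)
    counts = table.to_numpy()
    warning = None
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        p = 1.0
        warning = "a zero margin makes the association untestable"
    else:
        _, p = stats.fisher_exact(counts, alternative="two-sided")
    return ContingencyResult(
        table=table, test="fisher_exact", p_value=float(p),
        n_excluded=n_excluded, warning=warning,
    )
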