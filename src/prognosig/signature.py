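"""Weighted Cox signature: normalization, ranking, forward selection.

Phase II condenses the discovery gene list into a compact weighted score:

1. expression is rescaled per sample to *relative* units by dividing each
   sample's column by the geometric mean of its housekeeping genes
   (defaults TFRC, GUSB, RPLP0 — reference genes chosen for stability);
2. genes are ranked by the p-value of a univariate Cox proportional-hazards
   fit on the training samples;
3. starting from the top gene, genes are added one at a time to a
   multivariate Cox fit; after each addition the candidate signature is
   scored on the held-out test samples, the test population is split at its
   median score, and the two-group log-rank p recorded. The signature size
   with the smallest test log-rank p wins (smallest k on ties).

The resulting signature assigns each sample the risk score

    score = sum_i  E_i * beta_i

with E_i the housekeeping-normalized expression of gene i and beta_i its
multivariate Cox coefficient. The signature serializes to JSON together
with its normalization rule, so scoring a new cohort is self-contained.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .coxscan import cox_scan
from .io import DataError
from .screen import StatisticalError
from .survstats import km_logrank, median_split
from .synthetic import HOUSEKEEPING_DEFAULT, ConfigurationError

__all__ = [
    "NormalizationConfig",
    "WeightedSignature",
    "housekeeping_normalize",
    "univariate_rank",
    "forward_cox_select",
]


@dataclass(frozen=True)
class NormalizationConfig:
    """Per-sample relative-expression rule.

    ``zero_policy`` is ``"pseudocount"`` (add ``pseudocount`` to every
    housekeeping value before the geometric mean; the default, 0.01
    expression units) or ``"error"`` (non-positive housekeeping values are
    a data error).
    """

    housekeeping_genes: tuple[str, ...] = HOUSEKEEPING_DEFAULT
    zero_policy: str = "pseudocount"
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if not self.housekeeping_genes:
            raise ConfigurationError("at least one housekeeping gene is required")
        if self.zero_policy not in ("pseudocount", "error"):
            raise ConfigurationError(f"unknown zero_policy {self.zero_policy!r}")


def housekeeping_normalize(
    expr: pd.DataFrame, config: NormalizationConfig = NormalizationConfig()
) -> pd.DataFrame:
    """Divide each sample's column by its housekeeping geometric mean.

    Housekeeping rows are retained in the output (their normalized values
    carry the residual variation). The operation is per sample, so
    multiplying a sample's whole column by a positive constant leaves its
    normalized profile unchanged.
    """
    hk = [g for g in config.housekeeping_genes if g in expr.index]
    if not hk:
        raise DataError(
            f"none of the housekeeping genes {config.housekeeping_genes} are present"
        )
    values = expr.loc[hk].to_numpy(dtype=float)
    if config.zero_policy == "pseudocount":
        values = values + config.pseudocount
    bad = (values <= 0).any(axis=0)
    if bad.any():
        sample = expr.columns[int(np.argmax(bad))]
        raise DataError(
            f"non-positive housekeeping value(s) in sample {sample!r}; "
            "geometric mean undefined under zero_policy='error'"
        )
    geomean = np.exp(np.log(values).mean(axis=0))
    return expr.div(pd.Series(geomean, index=expr.columns), axis=1)


def univariate_rank(
    expr: pd.DataFrame, time: pd.Series, event: pd.Series
) -> pd.DataFrame:
    """Rank genes by univariate Cox Wald p (ascending).

    Ties are broken by |coefficient| descending, then gene identifier.
    Genes whose fit does not converge (including constant genes) are placed
    last with ``converged = False``.
    """
    if int(pd.Series(event).sum()) == 0:
        raise StatisticalError("no events in the training data")
    scan = cox_scan(expr, np.asarray(time, dtype=float), np.asarray(event))
    scan = scan.copy()
    scan["gene"] = scan.index.astype(str)
    scan["_p"] = scan["p"].where(scan["converged"], np.inf).fillna(np.inf)
    scan = scan.sort_values(
        by=["_p", "coef", "gene"],
        key=lambda col: -col.abs() if col.name == "coef" else col,
    ).drop(columns=["_p", "gene"])
    return scan


@dataclass
class WeightedSignature:
    """Ordered gene list with multivariate Cox weights and its scoring rule."""

    genes: list[str]
    betas: list[float]
    normalization: NormalizationConfig
    endpoint: str = "dfs"
    metadata: dict = field(default_factory=dict)

    def scores(self, expr: pd.DataFrame, *, normalized: bool = False) -> pd.Series:
        """Risk score per sample column; missing signature genes are an error."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise DataError(f"expression lacks signature gene(s): {missing}")
        norm = expr if normalized else housekeeping_normalize(expr, self.normalization)
        E = norm.loc[self.genes].to_numpy(dtype=float)
        return pd.Series(
            np.asarray(self.betas, dtype=float) @ E, index=expr.columns, name="risk_score"
        )

    def save(self, path) -> None:
        payload = {
            "format": "prognosig-signature-v1",
            "genes": self.genes,
            "betas": list(map(float, self.betas)),
            "normalization": {
                "housekeeping_genes": list(self.normalization.housekeeping_genes),
                "zero_policy": self.normalization.zero_policy,
                "pseudocount": self.normalization.pseudocount,
            },
            "endpoint": self.endpoint,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "WeightedSignature":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "prognosig-signature-v1":
            raise DataError(f"{path} is not a signature file")
        norm = payload["normalization"]
        return cls(
            genes=list(payload["genes"]),
            betas=[float(b) for b in payload["betas"]],
            normalization=NormalizationConfig(
                housekeeping_genes=tuple(norm["housekeeping_genes"]),
                zero_policy=norm["zero_policy"],
                pseudocount=float(norm["pseudocount"]),
            ),
            endpoint=payload["endpoint"],
            metadata=payload.get("metadata", {}),
        )


def _fit_multivariate(
    df: pd.DataFrame, genes: list[str], duration_col: str, event_col: str
) -> tuple[pd.Series | None, str]:
    """Cox fit on ``genes``; ridge-stabilized retry on failure."""
    for penalizer, status in ((0.0, "ok"), (0.1, "ridge")):
        fitter = CoxPHFitter(penalizer=penalizer)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(
                    df[genes + [duration_col, event_col]],
                    duration_col=duration_col,
                    event_col=event_col,
                )
            coefs = fitter.params_[genes]
            if np.isfinite(coefs).all():
                return coefs, status
        except (ConvergenceError, np.linalg.LinAlgError, ValueError):
            continue
    return None, "failed"


def forward_cox_select(
    ranking: pd.DataFrame,
    expr_train: pd.DataFrame,
    expr_test: pd.DataFrame,
    survival_train: pd.DataFrame,
    survival_test: pd.DataFrame,
    max_k: int = 118,
    *,
    endpoint: str = "dfs",
    normalization: NormalizationConfig = NormalizationConfig(),
    split_median: str = "test",
) -> tuple[WeightedSignature, pd.DataFrame]:
    """Grow the signature gene-by-gene, minimizing the test log-rank p.

    ``ranking`` is the output of :func:`univariate_rank`; ``expr_train`` /
    ``expr_test`` are already housekeeping-normalized (the rule is recorded
    in the returned signature). ``survival_*`` need ``{endpoint}_time`` and
    ``{endpoint}_event`` columns. ``split_median`` chooses whose median
    splits the test set: the test population's own (``"test"``, default) or
    the training population's (``"train"``).

    Returns the selected :class:`WeightedSignature` and the selection
    trace (one row per candidate size k with the gene added, fit status and
    test KM log-rank p).
    """
    if split_median not in ("test", "train"):
        raise ConfigurationError(f"unknown split_median {split_median!r}")
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    for frame, name in ((survival_train, "train"), (survival_test, "test")):
        for col in (tcol, ecol):
            if col not in frame.columns:
                raise DataError(f"{name} survival table lacks column {col!r}")
    usable = ranking.index[ranking["converged"]].astype(str).tolist()
    if not usable:
        raise StatisticalError("no gene produced a converged univariate fit")
    max_k = min(max_k, len(usable))

    train_df = expr_train.loc[usable[:max_k]].T.copy()
    train_df[tcol] = survival_train.loc[train_df.index, tcol].astype(float)
    train_df[ecol] = survival_train.loc[train_df.index, ecol].astype(int)

    rows = []
    fits: dict[int, pd.Series] = {}
    for k in range(1, max_k + 1):
        genes_k = usable[:k]
        coefs, status = _fit_multivariate(train_df, genes_k, tcol, ecol)
        km_p = np.nan
        if coefs is not None:
            fits[k] = coefs
            test_scores = pd.Series(
                coefs.to_numpy() @ expr_test.loc[genes_k].to_numpy(dtype=float),
                index=expr_test.columns,
            )
            if split_median == "train":
                train_scores = pd.Series(
                    coefs.to_numpy() @ expr_train.loc[genes_k].to_numpy(dtype=float),
                    index=expr_train.columns,
                )
                med = float(np.median(train_scores))
                groups = pd.Series(
                    np.where(test_scores < med, "low", "high"), index=test_scores.index
                )
                degenerate = groups.nunique() < 2
            else:
                split = median_split(test_scores)
                groups, degenerate = split.groups, split.degenerate
            if degenerate:
                status = f"{status}+degenerate-split"
            else:
                km_p = km_logrank(
                    groups,
                    survival_test.loc[test_scores.index, tcol].astype(float),
                    survival_test.loc[test_scores.index, ecol].astype(int),
                    endpoint,
                ).p_value
        rows.append((k, genes_k[-1], status, km_p))

    trace = pd.DataFrame(rows, columns=["k", "gene_added", "status", "km_p"])
    valid = trace.dropna(subset=["km_p"])
    if valid.empty:
        raise StatisticalError("no candidate size produced a valid test split")
    best_k = int(valid.loc[valid["km_p"].idxmin(), "k"])  # idxmin: smallest k on ties
    trace["selected"] = trace["k"] == best_k

    coefs = fits[best_k]
    signature = WeightedSignature(
        genes=list(coefs.index),
        betas=[float(b) for b in coefs.to_numpy()],
        normalization=normalization,
        endpoint=endpoint,
        metadata={
            "selected_k": best_k,
            "test_km_p": float(valid.loc[valid["km_p"].idxmin(), "km_p"]),
            "n_train": int(len(train_df)),
            "n_test": int(expr_test.shape[1]),
            "max_k": max_k,
            "split_median": split_median,
        },
    )
    return signature, trace
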