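"""Gene-prognosis correlation screen with a Monte-Carlo permutation null.

Each gene's expression across the training samples is correlated (Pearson)
with the binary prognosis label (poor = 1, good = 0; point-biserial).
Genes whose correlation magnitude reaches a threshold are retained and
ranked by |r| descending. Chance expectation for the *number* of retained
genes is quantified by permuting the labels across samples many times and
recording the retained-set size of each trial; the empirical p-value for
the observed count uses the permutation-inclusive (add-one) estimator

    p = (#{trials with count >= observed} + 1) / (n_permutations + 1),

which can never return zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import ConfigurationError

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "gene_prognosis_correlation",
    "screen_genes",
    "permutation_null",
]

LABEL_CODING_DEFAULT = {"poor": 1.0, "good": 0.0}


class StatisticalError(ValueError):
    """Inputs do not support the requested statistic."""


@dataclass(frozen=True)
class ScreenConfig:
    """Correlation-screen settings (threshold compared inclusively, |r| >= t)."""

    r_threshold: float = 0.3
    n_permutations: int = 10_000
    seed: int = 0
    label_coding: tuple[tuple[str, float], ...] = (("poor", 1.0), ("good", 0.0))

    def __post_init__(self) -> None:
        if not 0.0 < self.r_threshold < 1.0:
            raise ConfigurationError("r_threshold must be in (0, 1)")
        if self.n_permutations < 0:
            raise ConfigurationError("n_permutations must be non-negative")

    @property
    def coding(self) -> dict[str, float]:
        return dict(self.label_coding)


@dataclass
class ScreenResult:
    """Outcome of the screen and its permutation null."""

    r_values: pd.Series  # per-gene Pearson r with the coded label
    retained: list[str]  # genes with |r| >= threshold, |r| descending
    r_threshold: float
    null_counts: np.ndarray | None = None  # retained-set size per permutation
    empirical_p: float | None = None
    zero_variance_genes: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _coded_labels(labels: pd.Series, coding: dict[str, float]) -> pd.Series:
    lab = labels[labels.isin(coding)]
    counts = lab.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise StatisticalError(
            "correlation screen needs at least two samples in each prognosis class"
        )
    return lab.map(coding).astype(float)


def _pearson_matrix(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r of X (genes x samples) against vector(s) y.

    ``y`` may be 1-D (one label vector) or 2-D (samples x trials); rows of
    X with zero variance yield r = 0 by convention.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    xsd = np.sqrt((Xc**2).sum(axis=1))
    y2 = y if y.ndim == 2 else y[:, None]
    yc = y2 - y2.mean(axis=0, keepdims=True)
    ysd = np.sqrt((yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / np.outer(xsd, ysd)
    r[~np.isfinite(r)] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return r if y.ndim == 2 else r[:, 0]


def gene_prognosis_correlation(
    expr: pd.DataFrame,
    labels: pd.Series,
    coding: dict[str, float] | None = None,
) -> pd.Series:
    """Per-gene Pearson correlation with the coded prognosis label.

    Only samples with a coded label are used; zero-variance genes get
    r = 0 (conventional, recorded via the result of :func:`screen_genes`).
    With the default coding, positive r means higher expression in poor
    prognosis; any affine recoding changes at most the global sign.
    """
    coding = LABEL_CODING_DEFAULT if coding is None else coding
    lab = _coded_labels(labels, coding)
    missing = [s for s in lab.index if s not in expr.columns]
    if missing:
        raise StatisticalError(f"labeled samples missing from expression: {missing[:5]}")
    X = expr[lab.index].to_numpy(dtype=float)
    r = _pearson_matrix(X, lab.to_numpy())
    return pd.Series(r, index=expr.index, name="r")


def screen_genes(r_values: pd.Series, config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Retain genes with |r| >= threshold, ordered by |r| descending.

    Ties in |r| are broken by gene identifier (lexicographic), which makes
    the ranking deterministic.
    """
    absr = r_values.abs()
    retained = absr[absr >= config.r_threshold]
    order = sorted(retained.index, key=lambda g: (-retained[g], str(g)))
    zero_var = list(r_values.index[r_values == 0.0])
    return ScreenResult(
        r_values=r_values,
        retained=order,
        r_threshold=config.r_threshold,
        zero_variance_genes=zero_var,
    )


def empirical_p_value(null_counts: np.ndarray, observed: int) -> float:
    """Add-one permutation p for observing ``observed`` retained genes or more."""
    n = len(null_counts)
    if n == 0:
        raise ConfigurationError("permutation null requires at least one trial")
    return (int((null_counts >= observed).sum()) + 1) / (n + 1)


def permutation_null(
    expr: pd.DataFrame,
    labels: pd.Series,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Run the screen and its label-permutation null in one pass.

    For every trial the labels are permuted across samples, all per-gene
    correlations recomputed, and the number of genes passing the threshold
    recorded. Trials are generated from ``config.seed``; identical seeds
    reproduce identical null counts.
    """
    if config.n_permutations < 1:
        raise ConfigurationError("n_permutations must be >= 1 for a permutation null")
    coding = config.coding
    lab = _coded_labels(labels, coding)
    X = expr[lab.index].to_numpy(dtype=float)
    y = lab.to_numpy()

    result = screen_genes(gene_prognosis_correlation(expr, labels, coding), config)

    rng = np.random.default_rng(config.seed)
    perms = np.empty((len(y), config.n_permutations))
    for j in range(config.n_permutations):
        perms[:, j] = rng.permutation(y)
    # chunk the trials to bound the genes x trials correlation matrix
    counts = np.empty(config.n_permutations, dtype=int)
    chunk = max(1, int(2_000_000 / max(1, X.shape[0])))
    for start in range(0, config.n_permutations, chunk):
        R = _pearson_matrix(X, perms[:, start : start + chunk])
        counts[start : start + chunk] = (np.abs(R) >= config.r_threshold).sum(axis=0)
    result.null_counts = counts
    result.empirical_p = empirical_p_value(counts, result.n_retained)
    return result
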