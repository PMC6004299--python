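"""Nearest-centroid correlation classifier with leave-one-out validation.

Phase I of the pipeline classifies a tumor by correlating its expression
profile (over a candidate gene signature) with the mean profile of the
good-prognosis training group and of the poor-prognosis group:

    risk_coef = r(profile, good template) - r(profile, poor template)

Low risk coefficients indicate poor-prognosis-like profiles. Rather than
thresholding at zero, the cohort is ranked by risk coefficient ascending
and the first ``n_high`` samples (the known number of poor-prognosis
patients) are called high genomic risk — the classifier therefore always
reproduces the cohort's class balance.

Leave-one-out cross-validation rebuilds the templates without the held-out
sample, ranks *all* samples (held-out included) and counts an error when
the held-out sample's genomic risk disagrees with its true status. The
sweep repeats this for nested signature prefixes of the correlation
ranking. A stricter "no information leak" variant recomputes the gene
screen itself inside every fold.

Expression is z-scored per gene across the cohort before template
correlation (the screening correlations are invariant to that affine
rescaling, but the centroids are not); pass ``scale=False`` for raw-scale
templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen import (
    ScreenConfig,
    StatisticalError,
    _pearson_matrix,
    gene_prognosis_correlation,
    screen_genes,
)
from .prep import GOOD, POOR

__all__ = [
    "PrognosisTemplates",
    "LoocvReport",
    "NoLeakReport",
    "RocCurve",
    "zscore_genes",
    "build_templates",
    "risk_coef",
    "risk_coefs",
    "rank_cut_classify",
    "signature_sizes",
    "loocv_sweep",
    "loocv_no_leak",
    "select_signature_size",
    "roc_curve",
    "roc_compare",
]

HIGH, LOW = "high", "low"


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each gene across samples; constant genes map to 0."""
    mu = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    out = expr.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return out.fillna(0.0)


@dataclass
class PrognosisTemplates:
    """Mean expression profiles of the two prognosis groups on a gene set."""

    good: pd.Series
    poor: pd.Series

    @property
    def genes(self) -> pd.Index:
        return self.good.index


def build_templates(
    expr: pd.DataFrame, labels: pd.Series, gene_subset
) -> PrognosisTemplates:
    """Per-gene arithmetic class means restricted to ``gene_subset``."""
    genes = list(gene_subset)
    if not genes:
        raise StatisticalError("empty gene subset")
    good_ids = labels.index[labels == GOOD]
    poor_ids = labels.index[labels == POOR]
    if len(good_ids) == 0 or len(poor_ids) == 0:
        raise StatisticalError("both prognosis classes must be non-empty")
    sub = expr.loc[genes]
    return PrognosisTemplates(
        good=sub[good_ids].mean(axis=1), poor=sub[poor_ids].mean(axis=1)
    )


def _corr_to_template(profiles: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``profiles`` (samples x genes) to a template."""
    return _pearson_matrix(profiles, template)


def risk_coefs(expr: pd.DataFrame, templates: PrognosisTemplates) -> pd.Series:
    """Risk coefficient for every sample column of ``expr``.

    Zero-variance profiles or templates contribute a correlation of 0
    (so a flat profile scores 0). Values lie in [-2, 2].
    """
    genes = templates.genes
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise StatisticalError(f"profile lacks signature genes: {missing[:5]}")
    if len(genes) < 2:
        raise StatisticalError("risk coefficient needs >= 2 genes")
    profiles = expr.loc[genes].to_numpy(dtype=float).T  # samples x genes
    r_good = _corr_to_template(profiles, templates.good.to_numpy())
    r_poor = _corr_to_template(profiles, templates.poor.to_numpy())
    return pd.Series(r_good - r_poor, index=expr.columns, name="risk_coef")


def risk_coef(sample_profile: pd.Series, templates: PrognosisTemplates) -> float:
    """Risk coefficient of a single sample profile."""
    frame = sample_profile.to_frame(name=getattr(sample_profile, "name", "sample"))
    return float(risk_coefs(frame, templates).iloc[0])


def rank_cut_classify(risk: pd.Series, n_high: int) -> pd.Series:
    """Call the ``n_high`` lowest-risk-coefficient samples high genomic risk.

    Ties at the cut are broken by sample identifier (deterministic).
    """
    if n_high > len(risk):
        raise StatisticalError("n_high exceeds the number of samples")
    order = sorted(risk.index, key=lambda s: (risk[s], str(s)))
    calls = pd.Series(LOW, index=risk.index, name="genomic_risk")
    calls[order[:n_high]] = HIGH
    return calls


def signature_sizes(n_ranked: int, step: int = 2, start: int = 2) -> list[int]:
    """The nested candidate sizes: ``start, start+step, ...`` up to ``n_ranked``."""
    return list(range(start, n_ranked + 1, step))


@dataclass
class LoocvReport:
    """Error counts of the leave-one-out sweep over nested signature sizes."""

    errors: dict[int, int]
    n_samples: int
    predictions: dict[int, pd.Series] = field(default_factory=dict)
    truncated: bool = False

    @property
    def min_error(self) -> int:
        return min(self.errors.values())

    @property
    def min_error_sizes(self) -> list[int]:
        m = self.min_error
        return sorted(k for k, v in self.errors.items() if v == m)


def _loocv_one_size(
    X: np.ndarray,  # genes x samples, already restricted to the signature
    is_poor: np.ndarray,
    is_good: np.ndarray,
    sample_ids: list[str],
    n_high: int,
) -> pd.Series:
    """Predicted genomic risk for each held-out sample at one signature size."""
    n = X.shape[1]
    sum_good = X[:, is_good].sum(axis=1)
    sum_poor = X[:, is_poor].sum(axis=1)
    n_good, n_poor = int(is_good.sum()), int(is_poor.sum())
    preds = {}
    profiles = X.T  # samples x genes
    for i in range(n):
        g_sum, p_sum = sum_good.copy(), sum_poor.copy()
        g_n, p_n = n_good, n_poor
        if is_good[i]:
            g_sum -= X[:, i]
            g_n -= 1
        elif is_poor[i]:
            p_sum -= X[:, i]
            p_n -= 1
        if g_n == 0 or p_n == 0:
            raise StatisticalError("a prognosis class empties when a sample is held out")
        good_t, poor_t = g_sum / g_n, p_sum / p_n
        rc = _corr_to_template(profiles, good_t) - _corr_to_template(profiles, poor_t)
        risk = pd.Series(rc, index=sample_ids)
        preds[sample_ids[i]] = rank_cut_classify(risk, n_high)[sample_ids[i]]
    return pd.Series(preds, name="genomic_risk")


def loocv_sweep(
    expr: pd.DataFrame,
    labels: pd.Series,
    ranked_genes: list[str],
    sizes: list[int] | None = None,
    *,
    n_high: int | None = None,
    scale: bool = True,
    keep_predictions: bool = False,
) -> LoocvReport:
    """Count LOOCV disagreements for each nested signature size.

    ``ranked_genes`` is the screen's |r|-descending ordering; each size s
    uses its first s genes. ``n_high`` defaults to the number of
    poor-prognosis samples. Error counts are invariant to the column order
    of ``expr``.
    """
    lab = labels[labels.isin([POOR, GOOD])]
    samples = sorted(lab.index)
    lab = lab[samples]
    sub = expr[samples]
    if scale:
        sub = zscore_genes(sub)
    if n_high is None:
        n_high = int((lab == POOR).sum())
    max_size = len(ranked_genes)
    if sizes is None:
        sizes = signature_sizes(max_size)
    truncated = any(s > max_size for s in sizes)
    sizes = [s for s in sizes if 2 <= s <= max_size]
    if not sizes:
        raise StatisticalError("no usable signature sizes (need >= 2 ranked genes)")

    is_poor = (lab == POOR).to_numpy()
    is_good = (lab == GOOD).to_numpy()
    real = pd.Series(np.where(is_poor, HIGH, LOW), index=samples)
    errors: dict[int, int] = {}
    predictions: dict[int, pd.Series] = {}
    for s in sizes:
        X = sub.loc[ranked_genes[:s]].to_numpy(dtype=float)
        preds = _loocv_one_size(X, is_poor, is_good, samples, n_high)
        errors[s] = int((preds[samples] != real).sum())
        if keep_predictions:
            predictions[s] = preds
    return LoocvReport(
        errors=errors, n_samples=len(samples), predictions=predictions, truncated=truncated
    )


def select_signature_size(report: LoocvReport, rule: str = "largest-min") -> int:
    """Pick a signature size from the sweep's minimum-error set.

    ``largest-min`` (default) and ``smallest-min`` select from the argmin
    set; ``fixed:<k>`` forces a size.
    """
    if rule.startswith("fixed:"):
        return int(rule.split(":", 1)[1])
    if rule == "largest-min":
        return report.min_error_sizes[-1]
    if rule == "smallest-min":
        return report.min_error_sizes[0]
    raise ValueError(f"unknown size-selection rule {rule!r}")


@dataclass
class NoLeakReport:
    """Per-fold screens and predictions of leak-free cross-validation."""

    fold_genes: dict[str, list[str]]  # held-out sample -> that fold's signature
    predictions: pd.Series  # held-out sample -> genomic risk call
    real: pd.Series
    full_data_genes: list[str]
    fallback_folds: list[str] = field(default_factory=list)

    @property
    def error_count(self) -> int:
        return int((self.predictions != self.real).sum())

    def fold_jaccard(self) -> pd.Series:
        """Jaccard overlap of each fold's gene list with the full-data list."""
        full = set(self.full_data_genes)
        out = {}
        for s, genes in self.fold_genes.items():
            gs = set(genes)
            union = full | gs
            out[s] = len(full & gs) / len(union) if union else 1.0
        return pd.Series(out, name="jaccard")


def loocv_no_leak(
    expr: pd.DataFrame,
    labels: pd.Series,
    config: ScreenConfig = ScreenConfig(),
    *,
    size_rule: int | None = None,
    scale: bool = True,
    n_high: int | None = None,
) -> NoLeakReport:
    """LOOCV in which the gene screen is recomputed inside every fold.

    Each fold screens genes on the remaining samples only (the held-out
    sample never influences feature selection), builds templates from the
    fold's own signature, and classifies the held-out sample by the rank
    cut over all samples. ``size_rule`` optionally truncates each fold's
    signature to its top-k genes. Folds whose screen retains fewer than two
    genes fall back to the all-genes signature (recorded).
    """
    lab = labels[labels.isin([POOR, GOOD])]
    samples = sorted(lab.index)
    lab = lab[samples]
    sub = expr[samples]
    scaled = zscore_genes(sub) if scale else sub
    if n_high is None:
        n_high = int((lab == POOR).sum())

    full_result = screen_genes(gene_prognosis_correlation(sub, lab, config.coding), config)
    real = pd.Series(
        np.where((lab == POOR).to_numpy(), HIGH, LOW), index=samples
    )
    fold_genes: dict[str, list[str]] = {}
    preds: dict[str, str] = {}
    fallback = []
    for held_out in samples:
        rest = [s for s in samples if s != held_out]
        r = gene_prognosis_correlation(sub[rest], lab[rest], config.coding)
        retained = screen_genes(r, config).retained
        if size_rule is not None:
            retained = retained[:size_rule]
        if len(retained) < 2:
            retained = list(sub.index)
            fallback.append(held_out)
        fold_genes[held_out] = retained
        templates = build_templates(scaled[rest], lab[rest], retained)
        risk = risk_coefs(scaled, templates)
        preds[held_out] = rank_cut_classify(risk, n_high)[held_out]
    return NoLeakReport(
        fold_genes=fold_genes,
        predictions=pd.Series(preds)[samples],
        real=real,
        full_data_genes=full_result.retained,
        fallback_folds=fallback,
    )


@dataclass
class RocCurve:
    """ROC of the risk coefficient as a poor-prognosis score."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    se: float  # Hanley-McNeil standard error
    ci_lower: float
    ci_upper: float
    n_pos: int
    n_neg: int


def roc_curve(risk: pd.Series, labels: pd.Series) -> RocCurve:
    """ROC from sweeping a cut on the negated risk coefficient.

    Poor prognosis is the positive class; lower risk coefficients mean
    more poor-like, so the score is ``-risk_coef``. Tied scores move both
    rates together (diagonal segments); AUC is the trapezoid integral and
    its standard error uses the Hanley-McNeil formula. The 95% CI is the
    normal approximation, clipped to [0, 1].
    """
    lab = labels[labels.isin([POOR, GOOD])]
    y = (lab == POOR).to_numpy()
    scores = -risk[lab.index].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatisticalError("ROC needs at least one sample of each class")

    order = np.argsort(-scores, kind="stable")
    y_sorted = y[order]
    s_sorted = scores[order]
    # group tied scores: thresholds are the distinct score values
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        se=se,
        ci_lower=max(0.0, auc - 1.959963984540054 * se),
        ci_upper=min(1.0, auc + 1.959963984540054 * se),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def roc_compare(
    risk_per_signature: dict[str, pd.Series], labels: pd.Series
) -> dict[str, RocCurve]:
    """ROC curve per candidate signature, keyed like the input."""
    return {name: roc_curve(risk, labels) for name, risk in risk_per_signature.items()}
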