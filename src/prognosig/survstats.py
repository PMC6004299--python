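"""Median risk split and two-group Kaplan-Meier / log-rank comparison.

Shared by the signature-selection stage (which minimizes the test-set
log-rank p over candidate signature sizes) and the validation stage. The
split rule follows the "below the median" convention: the median is the
linear-interpolated population median (for even n, the mean of the two
central order statistics); samples with scores strictly below it form the
low-risk group and the rest the high-risk group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .screen import StatisticalError

__all__ = ["MedianSplit", "SurvivalComparison", "median_split", "km_logrank"]

HIGH, LOW = "high", "low"


@dataclass
class MedianSplit:
    """High/low risk groups from a population median split."""

    groups: pd.Series  # sample -> "high" | "low"
    median: float
    degenerate: bool = False  # a group is empty (e.g. all scores equal)

    @property
    def sizes(self) -> dict[str, int]:
        return {g: int((self.groups == g).sum()) for g in (LOW, HIGH)}


def median_split(scores: pd.Series) -> MedianSplit:
    """Split at the population median; strictly-below scores are low risk."""
    if len(scores) == 0:
        raise StatisticalError("cannot split an empty score vector")
    med = float(np.median(scores.to_numpy(dtype=float)))
    groups = pd.Series(
        np.where(scores.to_numpy(dtype=float) < med, LOW, HIGH),
        index=scores.index,
        name="risk_group",
    )
    degenerate = groups.nunique() < 2
    return MedianSplit(groups=groups, median=med, degenerate=degenerate)


@dataclass
class SurvivalComparison:
    """Two-group log-rank comparison with the Kaplan-Meier curves."""

    endpoint: str
    group_sizes: dict[str, int]
    statistic: float  # log-rank chi-squared (df = 1)
    p_value: float
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    method: str = "asymptotic"
    label: str = ""  # provenance of the comparison (e.g. stratum filter)


def _km_curve(time: np.ndarray, event: np.ndarray) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    surv = kmf.survival_function_.iloc[:, 0]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "at_risk": at_risk.to_numpy()}
    )


def km_logrank(
    groups: pd.Series,
    time: pd.Series,
    event: pd.Series,
    endpoint: str = "dfs",
    *,
    method: str = "asymptotic",
    n_permutations: int = 2000,
    seed: int = 0,
    small_n: int = 20,
    label: str = "",
) -> SurvivalComparison:
    """Compare survival between the two groups of ``groups``.

    ``method``: ``"asymptotic"`` uses the chi-squared (df = 1)
    approximation; ``"permutation"`` permutes group labels (add-one
    estimator); ``"auto"`` switches to permutation below ``small_n``
    samples.
    """
    names = sorted(groups.dropna().unique())
    if len(names) != 2:
        raise StatisticalError(f"need exactly two non-empty groups, got {names}")
    idx = groups.dropna().index
    t = time[idx].to_numpy(dtype=float)
    e = event[idx].to_numpy(dtype=int)
    if e.sum() == 0:
        raise StatisticalError("no events in either group")
    g = groups[idx].to_numpy()
    mask_a = g == names[0]

    def _stat(mask: np.ndarray) -> float:
        res = logrank_test(t[mask], t[~mask], event_observed_A=e[mask],
                           event_observed_B=e[~mask])
        return float(res.test_statistic)

    observed = _stat(mask_a)
    from scipy.stats import chi2

    if method == "auto":
        method = "permutation" if len(idx) < small_n else "asymptotic"
    if method == "asymptotic":
        p = float(chi2.sf(observed, df=1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            if _stat(rng.permutation(mask_a)) >= observed:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown log-rank method {method!r}")

    curves = {
        name: _km_curve(t[g == name], e[g == name]) for name in names
    }
    return SurvivalComparison(
        endpoint=endpoint,
        group_sizes={name: int((g == name).sum()) for name in names},
        statistic=observed,
        p_value=p,
        curves=curves,
        method=method,
        label=label,
    )
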