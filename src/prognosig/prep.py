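"""Cohort preparation: prognosis dichotomization, train/test splits, balance.

Patients are dichotomized by relapse status at a fixed horizon (default
three years): relapse within the horizon is *poor* prognosis, relapse-free
with at least the horizon of follow-up is *good* prognosis, and
relapse-free patients censored before the horizon are *excluded* — their
status at the horizon is unknowable.

Two split strategies are provided. The discovery-phase split draws fixed
numbers of poor and good patients into the training set (the remainder is
the test set). The scoring-phase split is a random fraction split that is
re-drawn (bounded, seeded) until the clinicopathologic balance tests
between the two arms all exceed a p-value threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError
from .synthetic import ConfigurationError

__all__ = [
    "POOR",
    "GOOD",
    "EXCLUDED",
    "SplitConfig",
    "BalanceReport",
    "assign_prognosis_labels",
    "split_phase1",
    "split_phase2",
    "balance_tests",
]

POOR, GOOD, EXCLUDED = "poor", "good", "excluded"

DAYS_PER_YEAR = 365.25

#: covariates tested for balance when present, with their measurement type
DEFAULT_BALANCE_COLUMNS = {
    "age": "numeric",
    "gender": "categorical",
    "stage": "categorical",
    "mmr_status": "categorical",
    "act_flag": "categorical",
}
#: values treated as unknown and excluded from a characteristic's test
UNKNOWN_VALUES = {"", "na", "nan", "unknown", "none"}


def assign_prognosis_labels(
    clinical: pd.DataFrame,
    horizon_years: float = 3.0,
    *,
    time_unit: str = "years",
) -> pd.Series:
    """Label each sample poor/good/excluded by relapse status at the horizon.

    Requires ``dfs_event`` and ``dfs_time`` columns. ``time_unit`` may be
    ``"years"`` or ``"days"`` (converted at 365.25 days/year).
    """
    for col in ("dfs_event", "dfs_time"):
        if col not in clinical.columns:
            raise DataError(f"clinical table lacks required column {col!r}")
        bad = clinical.index[clinical[col].isna()]
        if len(bad):
            raise DataError(f"missing {col} for sample(s): {', '.join(map(str, bad[:5]))}")
    if time_unit not in ("years", "days"):
        raise ConfigurationError(f"unknown time unit {time_unit!r}")
    t = clinical["dfs_time"].astype(float)
    if time_unit == "days":
        t = t / DAYS_PER_YEAR
    event = clinical["dfs_event"].astype(int)

    labels = pd.Series(EXCLUDED, index=clinical.index, name="prognosis")
    labels[(event == 1) & (t < horizon_years)] = POOR
    labels[(event == 0) & (t >= horizon_years)] = GOOD
    # relapse at/after the horizon: relapse-free for the full horizon => good
    labels[(event == 1) & (t >= horizon_years)] = GOOD
    return labels


@dataclass(frozen=True)
class SplitConfig:
    """Discovery-phase training draw sizes (defaults follow a 32/39 design)."""

    n_poor_train: int = 32
    n_good_train: int = 39
    seed: int = 0


def split_phase1(
    labels: pd.Series, config: SplitConfig = SplitConfig()
) -> tuple[list[str], list[str]]:
    """Draw the discovery training set; the remaining labeled samples test.

    Sampling is without replacement within each prognosis class, seeded.
    Excluded samples belong to neither set.
    """
    poor = sorted(labels.index[labels == POOR])
    good = sorted(labels.index[labels == GOOD])
    if config.n_poor_train <= 0 and config.n_good_train <= 0:
        raise ConfigurationError("empty training set requested")
    if config.n_poor_train > len(poor) or config.n_good_train > len(good):
        raise ConfigurationError(
            f"requested {config.n_poor_train}/{config.n_good_train} "
            f"poor/good training samples but only {len(poor)}/{len(good)} available"
        )
    rng = np.random.default_rng(config.seed)
    train = sorted(
        list(rng.choice(poor, size=config.n_poor_train, replace=False))
        + list(rng.choice(good, size=config.n_good_train, replace=False))
    )
    in_train = set(train)
    test = [s for s in labels.index if labels[s] != EXCLUDED and s not in in_train]
    return train, test


@dataclass
class BalanceReport:
    """Per-characteristic balance tests between two cohort arms."""

    rows: pd.DataFrame  # characteristic, test, statistic, p_value, note
    threshold: float = 0.05

    @property
    def all_balanced(self) -> bool:
        p = self.rows["p_value"].dropna()
        return bool((p > self.threshold).all())

    def min_p(self) -> float:
        p = self.rows["p_value"].dropna()
        return float(p.min()) if len(p) else 1.0


def _is_unknown(values: pd.Series) -> pd.Series:
    return values.isna() | values.astype(str).str.strip().str.lower().isin(UNKNOWN_VALUES)


def balance_tests(
    clinical_train: pd.DataFrame,
    clinical_test: pd.DataFrame,
    columns: dict[str, str] | None = None,
    threshold: float = 0.05,
) -> BalanceReport:
    """Compare covariate distributions between two arms.

    Numeric characteristics get a Welch two-sample t-test; categorical
    characteristics with two observed levels get a two-sided Fisher exact
    test, with more levels a Pearson chi-squared test. Unknown values are
    excluded from that characteristic's test only.
    """
    if columns is None:
        columns = {
            c: k for c, k in DEFAULT_BALANCE_COLUMNS.items()
            if c in clinical_train.columns and c in clinical_test.columns
        }
    rows = []
    for col, kind in columns.items():
        a = clinical_train[col][~_is_unknown(clinical_train[col])]
        b = clinical_test[col][~_is_unknown(clinical_test[col])]
        n_unknown = (len(clinical_train) - len(a)) + (len(clinical_test) - len(b))
        note = f"{n_unknown} unknown excluded" if n_unknown else ""
        if kind == "numeric":
            stat, p = stats.ttest_ind(a.astype(float), b.astype(float), equal_var=False)
            rows.append((col, "welch_t", float(stat), float(p), note))
            continue
        levels = sorted(set(a.astype(str)) | set(b.astype(str)))
        if len(levels) < 2:
            rows.append((col, "skipped", np.nan, np.nan, "single observed level"))
            continue
        table = np.array(
            [
                [int((a.astype(str) == lev).sum()) for lev in levels],
                [int((b.astype(str) == lev).sum()) for lev in levels],
            ]
        )
        if len(levels) == 2:
            stat, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append((col, "fisher_exact", float(stat), float(p), note))
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            rows.append((col, "chi_squared", float(stat), float(p), note))
    report = pd.DataFrame(
        rows, columns=["characteristic", "test", "statistic", "p_value", "note"]
    )
    return BalanceReport(rows=report, threshold=threshold)


def split_phase2(
    clinical: pd.DataFrame,
    fraction: float = 0.5,
    seed: int = 0,
    *,
    balance_threshold: float = 0.05,
    max_retries: int = 100,
    balance_columns: dict[str, str] | None = None,
) -> tuple[list[str], list[str], BalanceReport]:
    """Random fraction split, re-drawn until the arms are balanced.

    Draws are seeded and bounded by ``max_retries``; if no draw achieves
    balance p-values above ``balance_threshold`` for every characteristic,
    the best-balanced split found (largest minimum p) is returned and the
    report carries a warning note.
    """
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must be in (0, 1)")
    samples = np.array(sorted(clinical.index))
    n_train = int(round(fraction * len(samples)))
    if n_train == 0 or n_train == len(samples):
        raise ConfigurationError("fraction leaves an empty arm")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, max_retries)):
        train_ids = sorted(rng.choice(samples, size=n_train, replace=False))
        test_ids = sorted(set(samples) - set(train_ids))
        report = balance_tests(
            clinical.loc[train_ids], clinical.loc[test_ids],
            columns=balance_columns, threshold=balance_threshold,
        )
        if best is None or report.min_p() > best[2].min_p():
            best = (train_ids, test_ids, report)
        if report.all_balanced:
            return train_ids, test_ids, report
    train_ids, test_ids, report = best
    report.rows = pd.concat(
        [report.rows, pd.DataFrame(
            [("_retries", "warning", np.nan, np.nan,
              f"retry budget {max_retries} exhausted; best split returned")],
            columns=report.rows.columns)],
        ignore_index=True,
    )
    return train_ids, test_ids, report
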