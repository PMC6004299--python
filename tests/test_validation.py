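"""Scoring, median split, KM/log-rank oracles, probe collapsing, enrichment."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from prognosig.screen import StatisticalError
from prognosig.signature import NormalizationConfig, WeightedSignature
from prognosig.survstats import km_logrank, median_split
from prognosig.synthetic import SimulationConfig, make_probe_matrix, simulate_cohort
from prognosig.validation import (
    collapse_probes,
    compare_endpoint,
    score_cohort,
    stage_enrichment,
    stratified_analysis,
)


def km_product_limit_oracle(time, event):
    """Direct O(n^2) evaluation of the product-limit estimator."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oracle(time_a, event_a, time_b, event_b):
    """Hand evaluation of the two-group log-rank O-E chi-squared."""
    time = np.r_[time_a, time_b]
    event = np.r_[event_a, event_b]
    group = np.r_[np.zeros(len(time_a)), np.ones(len(time_b))]
    O_minus_E = 0.0
    V = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 0)).sum()
        O_minus_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_minus_E**2 / V


class TestMedianSplit:
    def test_below_median_rule_even_n(self):
        split = median_split(pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd")))
        assert split.median == pytest.approx(2.5)
        assert list(split.groups) == ["low", "low", "high", "high"]

    def test_sample_exactly_at_median_goes_high(self):
        split = median_split(pd.Series([1.0, 2.0, 3.0], index=list("abc")))
        assert split.groups["b"] == "high"  # at the median -> "the rest"
        assert split.sizes == {"low": 1, "high": 2}

    def test_all_equal_scores_flagged_degenerate(self):
        split = median_split(pd.Series([0.0, 0.0, 0.0], index=list("abc")))
        assert split.degenerate
        assert (split.groups == "high").all()

    def test_groups_near_balanced_for_distinct_scores(self):
        rng = np.random.default_rng(0)
        split = median_split(pd.Series(rng.normal(size=101)))
        assert abs(split.sizes["low"] - split.sizes["high"]) <= 1


class TestKmLogrank:
    def make_groups(self, na, nb):
        idx = [f"s{i}" for i in range(na + nb)]
        return pd.Series(["A"] * na + ["B"] * nb, index=idx), idx

    def test_identical_groups_give_stat_zero_p_one(self):
        groups, idx = self.make_groups(4, 4)
        time = pd.Series([2.0, 4, 6, 8] * 2, index=idx)
        event = pd.Series([1, 0, 1, 1] * 2, index=idx)
        comp = km_logrank(groups, time, event)
        assert comp.statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0)

    def test_statistic_matches_hand_oracle(self):
        groups, idx = self.make_groups(4, 3)
        time = pd.Series([6.0, 7, 10, 15, 8, 12, 20], index=idx)
        event = pd.Series([1] * 7, index=idx)
        comp = km_logrank(groups, time, event)
        expected = logrank_oracle([6, 7, 10, 15], [1] * 4, [8, 12, 20], [1] * 3)
        assert comp.statistic == pytest.approx(expected, rel=1e-9)

    def test_km_curves_match_product_limit_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = int(rng.integers(10, 50))
            time = rng.exponential(5, size=n).round(1) + 0.1
            event = (rng.random(n) < 0.7).astype(int)
            groups = pd.Series(
                ["A"] * (n // 2) + ["B"] * (n - n // 2),
                index=[f"s{i}" for i in range(n)],
            )
            ts = pd.Series(time, index=groups.index)
            es = pd.Series(event, index=groups.index)
            if es[groups == "A"].sum() == 0 or es[groups == "B"].sum() == 0:
                continue
            comp = km_logrank(groups, ts, es)
            for g in ("A", "B"):
                oracle = km_product_limit_oracle(time[groups == g], event[groups == g])
                curve = comp.curves[g].set_index("time")["survival"]
                for t, s in oracle:
                    assert curve.loc[t] == pytest.approx(s, rel=1e-9)

    def test_group_relabeling_invariance(self):
        groups, idx = self.make_groups(5, 5)
        rng = np.random.default_rng(1)
        time = pd.Series(rng.exponential(3, 10), index=idx)
        event = pd.Series(np.ones(10, dtype=int), index=idx)
        a = km_logrank(groups, time, event)
        flipped = groups.map({"A": "Z", "B": "Y"})
        b = km_logrank(flipped, time, event)
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_permutation_method_close_to_asymptotic(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(30)]
        groups = pd.Series(["A"] * 15 + ["B"] * 15, index=idx)
        time = pd.Series(
            np.r_[rng.exponential(2, 15), rng.exponential(5, 15)], index=idx
        )
        event = pd.Series(np.ones(30, dtype=int), index=idx)
        asym = km_logrank(groups, time, event, method="asymptotic")
        perm = km_logrank(groups, time, event, method="permutation",
                          n_permutations=999, seed=0)
        assert perm.p_value == pytest.approx(asym.p_value, abs=0.05)

    def test_single_group_or_no_events_rejected(self):
        idx = ["a", "b"]
        groups = pd.Series(["A", "A"], index=idx)
        with pytest.raises(StatisticalError):
            km_logrank(groups, pd.Series([1.0, 2.0], index=idx),
                       pd.Series([1, 1], index=idx))
        groups2 = pd.Series(["A", "B"], index=idx)
        with pytest.raises(StatisticalError):
            km_logrank(groups2, pd.Series([1.0, 2.0], index=idx),
                       pd.Series([0, 0], index=idx))


class TestScoreCohort:
    def signature(self, genes, betas):
        return WeightedSignature(genes=genes, betas=betas,
                                 normalization=NormalizationConfig())

    def test_zero_signature_flagged_degenerate(self, small_cohort):
        sig = self.signature(small_cohort.prognostic_genes[:2], [0.0, 0.0])
        risk = score_cohort(small_cohort.expression, sig)
        assert risk.split.degenerate
        assert (risk.scores == 0).all()

    def test_deterministic_and_order_invariant(self, small_cohort):
        sig = self.signature(small_cohort.prognostic_genes[:3], [0.5, -1.0, 0.2])
        a = score_cohort(small_cohort.expression, sig)
        perm = np.random.default_rng(0).permutation(small_cohort.expression.columns)
        b = score_cohort(small_cohort.expression[perm], sig)
        common = a.scores.index
        np.testing.assert_allclose(a.scores[common], b.scores[common], rtol=1e-12)
        assert (a.groups[common] == b.groups[common]).all()

    def test_raw_scale_invariance_of_grouping(self, small_cohort):
        """Scaling any sample's raw column does not move it across groups."""
        sig = WeightedSignature(
            genes=small_cohort.prognostic_genes[:3], betas=[0.5, -1.0, 0.2],
            normalization=NormalizationConfig(zero_policy="error"),
        )
        expr = small_cohort.expression.copy()
        expr.iloc[:, 0] *= 37.0
        a = score_cohort(small_cohort.expression, sig)
        b = score_cohort(expr, sig)
        np.testing.assert_allclose(a.scores, b.scores, rtol=1e-9)
        assert (a.groups == b.groups).all()


class TestCollapseProbes:
    def test_single_probe_gene_passes_through(self, small_cohort):
        probes, pmap = make_probe_matrix(small_cohort, probes_per_gene=1)
        collapsed, choices = collapse_probes(
            probes, pmap,
            small_cohort.clinical["dfs_time"], small_cohort.clinical["dfs_event"],
        )
        assert collapsed.shape[0] == small_cohort.expression.shape[0]
        assert (choices["probe_id"].str.endswith("_p1")).all()

    def test_prognostic_probe_beats_noise_probe(self):
        hits = []
        for seed in range(10):
            c = simulate_cohort(
                SimulationConfig(n_samples=150, n_genes=30, n_prognostic=6,
                                 effect_size=1.2, seed=seed)
            )
            probes, pmap = make_probe_matrix(c, probes_per_gene=2, seed=seed + 500)
            _, choices = collapse_probes(
                probes, pmap, c.clinical["dfs_time"], c.clinical["dfs_event"]
            )
            chosen = choices.set_index("gene_id")["probe_id"]
            hits.extend(chosen[g].endswith("_p1") for g in c.prognostic_genes)
        assert np.mean(hits) >= 0.9

    def test_identical_probes_tie_break_by_id(self, small_cohort):
        gene = small_cohort.expression.index[0]
        probes = pd.DataFrame(
            [small_cohort.expression.loc[gene]] * 2,
            index=[f"{gene}_pB", f"{gene}_pA"],
        )
        pmap = pd.DataFrame({"probe_id": [f"{gene}_pB", f"{gene}_pA"],
                             "gene_id": [gene, gene]})
        _, choices = collapse_probes(
            probes, pmap,
            small_cohort.clinical["dfs_time"], small_cohort.clinical["dfs_event"],
        )
        assert choices["probe_id"].iloc[0] == f"{gene}_pA"

    def test_missing_required_gene_listed(self, small_cohort):
        probes, pmap = make_probe_matrix(small_cohort, probes_per_gene=1)
        from prognosig.io import DataError

        with pytest.raises(DataError, match="NOT_A_GENE"):
            collapse_probes(
                probes, pmap,
                small_cohort.clinical["dfs_time"], small_cohort.clinical["dfs_event"],
                require=["NOT_A_GENE"],
            )


@pytest.fixture(scope="module")
def scored():
    c = simulate_cohort(
        SimulationConfig(n_samples=300, n_genes=80, n_prognostic=10,
                         effect_size=1.0, seed=31)
    )
    signs = c.truth.set_index("gene_id")["sign"]
    sig = WeightedSignature(
        genes=list(signs.index[:6]),
        betas=[0.4 * s for s in signs.iloc[:6]],
        normalization=NormalizationConfig(),
    )
    return c, score_cohort(c.expression, sig)


class TestEndToEndValidation:
    def test_signature_separates_survival(self, scored):
        c, risk = scored
        comp = compare_endpoint(risk, c.clinical, "dfs")
        assert comp.p_value < 0.05
        for curve in comp.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] <= 1.0 and (np.diff(surv) <= 1e-12).all()

    def test_stage_enrichment_in_high_score_group(self, scored):
        c, risk = scored
        result = stage_enrichment(risk, c.clinical)
        assert result.table.to_numpy().sum() == len(risk.groups)
        adv = result.table["stage III & IV"]
        frac_high = adv["high score"] / result.table.loc["high score"].sum()
        frac_low = adv["low score"] / result.table.loc["low score"].sum()
        assert frac_high > frac_low
        assert result.p_value < 0.05

    def test_stage_enrichment_excludes_unknowns(self, scored):
        c, risk = scored
        clin = c.clinical.copy()
        clin.iloc[:5, clin.columns.get_loc("stage")] = "unknown"
        result = stage_enrichment(risk, clin)
        assert result.n_excluded == 5
        assert result.table.to_numpy().sum() == len(risk.groups) - 5

    def test_stratified_comparisons_and_skips(self, scored):
        c, risk = scored
        strata = [
            {"name": "stage23_dfs", "filter": {"stage": ["II", "III"]},
             "endpoint": "dfs", "compare": "score"},
            {"name": "pmmr_os", "filter": {"mmr_status": "pMMR"},
             "endpoint": "os", "compare": "score"},
            {"name": "empty", "filter": {"stage": "V"}, "compare": "score"},
        ]
        results = stratified_analysis(risk, c.clinical, strata)
        by_name = {r.name: r for r in results}
        assert by_name["stage23_dfs"].comparison is not None
        assert by_name["pmmr_os"].comparison.endpoint == "os"
        assert by_name["empty"].comparison is None
        assert "no samples" in by_name["empty"].skipped_reason

    def test_act_interaction_recovered(self):
        """Planted ACT benefit in low-risk patients shows up only there."""
        found_low, found_high = [], []
        for seed in range(6):
            c = simulate_cohort(
                SimulationConfig(n_samples=500, n_genes=40, n_prognostic=8,
                                 effect_size=1.0, seed=40 + seed,
                                 baseline_hazard=0.25,
                                 act_benefit=-2.0, act_benefit_low_risk_only=True)
            )
            signs = c.truth.set_index("gene_id")["sign"]
            sig = WeightedSignature(
                genes=list(signs.index), betas=[0.4 * s for s in signs],
                normalization=NormalizationConfig(),
            )
            risk = score_cohort(c.expression, sig)
            strata = [
                {"name": "act_low", "compare": "act", "score_group": "low",
                 "endpoint": "dfs"},
                {"name": "act_high", "compare": "act", "score_group": "high",
                 "endpoint": "dfs"},
            ]
            res = {r.name: r for r in stratified_analysis(risk, c.clinical, strata)}
            found_low.append(res["act_low"].comparison.p_value < 0.05)
            found_high.append(res["act_high"].comparison.p_value < 0.05)
        assert np.mean(found_low) >= 0.5
        assert np.mean(found_low) > np.mean(found_high)


class TestFisherOracle:
    def test_table3_style_counts_match_enumeration(self):
        from scipy import stats

        from tests.test_prep import fisher_two_sided_oracle

        for table in ([[19, 8], [13, 14]], [[3, 15], [9, 4]], [[10, 0], [5, 12]]):
            _, p = stats.fisher_exact(table)
            assert p == pytest.approx(fisher_two_sided_oracle(table), rel=1e-9)
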