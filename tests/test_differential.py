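"""Time-course tests, multiple-testing control, consolidation, anchor correlations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressomics import differential as de
from stressomics import multilevel as ml
from stressomics import simulate as sim
from stressomics.containers import DesignError

from conftest import make_matrix


def bh_bruteforce(p):
    """Step-up BH adjusted p-values, written independently of the package."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


class TestAdjust:
    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            assert de.adjust([0.031], method)[0] == pytest.approx(0.031)

    def test_bh_step_up_by_hand(self):
        adj = de.adjust([0.01, 0.02, 0.03], "BH")
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_bonferroni_closed_form(self):
        assert de.adjust([0.001] * 100, "bonferroni")[0] == pytest.approx(0.1)

    def test_bh_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            assert np.allclose(de.adjust(p, "BH"), bh_bruteforce(p), atol=1e-12)

    def test_nan_excluded_from_family(self):
        adj = de.adjust([0.01, np.nan, 0.04], "bonferroni")
        assert adj[0] == pytest.approx(0.02)  # m = 2, not 3
        assert np.isnan(adj[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust([1.2])


class TestRmAnova:
    def test_constant_in_time_gives_zero_F(self):
        # every animal flat over time, but animals differ
        values = np.repeat([[1.0], [5.0], [9.0]], 4, axis=0)
        m = make_matrix(values, n_times=4)
        res = de.rm_anova(m)
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_two_times_equals_paired_t_squared(self):
        rng = np.random.default_rng(22)
        values = rng.normal(size=(10, 1))
        m = make_matrix(values.repeat(2, axis=0) + rng.normal(size=(20, 1)), n_times=2)
        res = de.rm_anova(m)
        a = m.at_time(0).values[:, 0]
        b = m.at_time(1).values[:, 0]
        t = stats.ttest_rel(b, a).statistic
        assert res["F"].iloc[0] == pytest.approx(t**2, abs=1e-10)

    def test_matches_sums_of_squares_oracle(self):
        """F equals an explicit SS decomposition (and statsmodels AnovaRM)."""
        rng = np.random.default_rng(23)
        wide = rng.normal(size=(4, 3)) + np.array([0.0, 1.0, 0.5])
        m = make_matrix(wide.reshape(-1, 1), n_times=3)
        res = de.rm_anova(m)

        n, T = wide.shape
        grand = wide.mean()
        ss_time = n * ((wide.mean(axis=0) - grand) ** 2).sum()
        ss_subj = T * ((wide.mean(axis=1) - grand) ** 2).sum()
        ss_err = ((wide - grand) ** 2).sum() - ss_time - ss_subj
        F_oracle = (ss_time / (T - 1)) / (ss_err / ((n - 1) * (T - 1)))
        assert res["F"].iloc[0] == pytest.approx(F_oracle, rel=1e-10)

        from statsmodels.stats.anova import AnovaRM

        long = pd.DataFrame(
            {
                "y": wide.ravel(),
                "subject": np.repeat(np.arange(n), T),
                "time": np.tile(np.arange(T), n),
            }
        )
        sm_res = AnovaRM(long, "y", "subject", within=["time"]).fit()
        assert res["F"].iloc[0] == pytest.approx(
            sm_res.anova_table["F Value"].iloc[0], rel=1e-8
        )

    def test_too_few_animals_rejected(self):
        m = make_matrix(np.zeros((4, 1)), n_times=4)
        with pytest.raises(DesignError):
            de.rm_anova(m)


class TestSexAnova:
    def _matrix(self, values, sexes_per_animal):
        n_times = 4
        n = len(sexes_per_animal)
        sex = np.repeat(sexes_per_animal, n_times)
        return make_matrix(values, n_times=n_times, sex=sex)

    def test_mirrored_sexes_give_zero_statistic(self):
        rng = np.random.default_rng(24)
        block = rng.normal(size=(5 * 4, 1))
        values = np.vstack([block, block])  # identical data in both sexes
        m = self._matrix(values, ["F"] * 5 + ["M"] * 5)
        res = de.two_way_anova_sex(m)
        assert res["F"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_null_rejection_rate_near_nominal(self):
        """Randomly permuted sex labels reject at ~ the nominal 5% level."""
        rng = np.random.default_rng(25)
        n_animals, n_times, reps = 12, 4, 1000
        rejections = 0
        for _ in range(reps):
            values = (
                np.repeat(rng.normal(size=(n_animals, 1)), n_times, axis=0)
                + rng.normal(size=(n_animals * n_times, 1)) * 0.5
            )
            sexes = rng.permutation(["F"] * 6 + ["M"] * 6)
            m = self._matrix(values, list(sexes))
            res = de.two_way_anova_sex(m)
            rejections += res["p"].iloc[0] < 0.05
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo <= rejections <= hi

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(26)
        n_animals, n_times = 16, 4
        base = np.repeat(rng.normal(size=(n_animals, 1)), n_times, axis=0)
        shift = np.repeat([0.0] * 8 + [3.0] * 8, n_times)[:, None]  # 3 SD shift
        m = self._matrix(base + shift, ["F"] * 8 + ["M"] * 8)
        res = de.two_way_anova_sex(m)
        assert res["adj_p"].iloc[0] < 0.05

    def test_single_sex_rejected(self):
        m = self._matrix(np.zeros((8, 1)), ["F", "F"])
        with pytest.raises(DesignError):
            de.two_way_anova_sex(m)


class TestPairedTests:
    def test_closed_form_example(self):
        """Differences (1, 2, 3): t = 2 / (1/sqrt(3)) = 3.4641 on 2 df,
        two-sided p ~ 0.0742."""
        base = np.array([10.0, 20.0, 30.0])
        other = base + np.array([1.0, 2.0, 3.0])
        values = np.column_stack([base, other]).reshape(-1, 1)
        m = make_matrix(values, n_times=2)
        res = de.paired_tests(m)
        assert res["t"].iloc[0] == pytest.approx(2 * math.sqrt(3), rel=1e-6)
        assert res["p"].iloc[0] == pytest.approx(0.0742, abs=2e-4)

    def test_zero_differences_null(self):
        values = np.array([[5.0], [5.0], [8.0], [8.0], [2.0], [2.0]])
        m = make_matrix(values, n_times=2)
        res = de.paired_tests(m)
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(27)
        values = rng.normal(size=(12, 2))
        m_pos = make_matrix(values, n_times=4)
        m_neg = make_matrix(-values, n_times=4)
        a = de.paired_tests(m_pos)
        b = de.paired_tests(m_neg)
        assert np.allclose(a["t"].values, -b["t"].values, atol=1e-12)
        assert np.allclose(a["p"].values, b["p"].values, atol=1e-12)

    def test_constant_nonzero_difference_reported_na(self):
        base = np.array([1.0, 2.0, 3.0])
        values = np.column_stack([base, base + 5.0]).reshape(-1, 1)
        m = make_matrix(values, n_times=2)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = de.paired_tests(m)
        assert np.isnan(res["p"].iloc[0])

    def test_pooled_adjustment_scope(self):
        """All feature x contrast p-values form one adjustment family."""
        rng = np.random.default_rng(28)
        m = make_matrix(rng.normal(size=(20, 3)), n_times=4)
        res = de.paired_tests(m, adjust_method="bonferroni")
        valid = res["p"].notna()
        factor = (res.loc[valid, "adj_p"] / res.loc[valid, "p"]).round(6)
        clipped = res.loc[valid, "adj_p"] < 1
        assert (factor[clipped] == valid.sum()).all()


class TestConsolidation:
    def _results(self, probes, sig):
        rows = []
        for probe, s in zip(probes, sig):
            rows.append(
                {
                    "feature": probe,
                    "contrast": "0_vs_1",
                    "time": 1,
                    "diff": 1.0,
                    "t": 5.0,
                    "df": 9,
                    "p": 0.001 if s else 0.8,
                    "adj_p": (0.001 if s else 0.8),
                    "direction": "up" if s else "",
                }
            )
        return pd.DataFrame(rows)

    def _expression(self, probes, correlated=True, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=40)
        rows = []
        for j, _ in enumerate(probes):
            if correlated:
                rows.append(base + rng.normal(size=40) * 0.1)
            else:
                rows.append(rng.normal(size=40))
        return pd.DataFrame(rows, index=probes)

    def test_three_of_four_correlated_passes(self):
        probes = [f"p{j}" for j in range(4)]
        res = self._results(probes, [True, True, True, False])
        res.loc[res["feature"] == "p1", "adj_p"] = 0.0005  # most significant
        expr = self._expression(probes, correlated=True)
        probe_map = pd.DataFrame({"gene": ["G"] * 4}, index=probes)
        cons, _ = de.consolidate_probes(res, expr, probe_map)
        assert cons.loc["G", "passes"]
        assert cons.loc["G", "representative"] == "p1"

    def test_low_correlation_pair_fails(self):
        probes = [f"p{j}" for j in range(4)]
        res = self._results(probes, [True, True, True, False])
        expr = self._expression(probes, correlated=True, seed=1)
        expr.loc["p2"] = -expr.loc["p2"].values  # anti-correlated pair
        probe_map = pd.DataFrame({"gene": ["G"] * 4}, index=probes)
        cons, _ = de.consolidate_probes(res, expr, probe_map)
        assert not cons.loc["G", "passes"]

    def test_single_probe_gene_passes_on_de_alone(self):
        res = self._results(["p0"], [True])
        expr = self._expression(["p0"])
        probe_map = pd.DataFrame({"gene": ["G"]}, index=["p0"])
        cons, _ = de.consolidate_probes(res, expr, probe_map)
        assert cons.loc["G", "passes"]

    def test_unannotated_probes_reported_not_dropped(self):
        res = self._results(["p0", "p1"], [True, True])
        expr = self._expression(["p0", "p1"])
        probe_map = pd.DataFrame({"gene": ["G", ""]}, index=["p0", "p1"])
        cons, unannotated = de.consolidate_probes(res, expr, probe_map)
        assert "p1" in unannotated.index
        assert bool(unannotated.loc["p1", "is_de"])

    def test_matches_bruteforce_rule_oracle(self):
        """Pass/fail over 200 random genes equals an exhaustive re-evaluation
        of the rule."""
        rng = np.random.default_rng(29)
        probes, genes, sig = [], {}, {}
        for g in range(200):
            gene = f"G{g:03d}"
            n_probes = int(rng.integers(1, 6))
            for j in range(n_probes):
                p = f"{gene}.p{j}"
                probes.append(p)
                genes[p] = gene
                sig[p] = bool(rng.random() < 0.6)
        res = self._results(probes, [sig[p] for p in probes])
        res["adj_p"] = np.where(
            [sig[p] for p in probes], rng.random(len(probes)) * 0.04, 0.5
        )
        expr = pd.DataFrame(
            rng.normal(size=(len(probes), 30)), index=probes
        )
        # make a random half of genes internally correlated
        base = rng.normal(size=30)
        for p in probes:
            if hash(genes[p]) % 2 == 0:
                expr.loc[p] = base * rng.uniform(0.5, 2.0) + rng.normal(size=30) * 0.05
        probe_map = pd.DataFrame({"gene": [genes[p] for p in probes]}, index=probes)
        cons, _ = de.consolidate_probes(res, expr, probe_map)

        adj = res.set_index("feature")["adj_p"]
        for gene in cons.index:
            gp = [p for p in probes if genes[p] == gene]
            de_p = [p for p in gp if adj[p] < 0.05]
            if len(gp) == 1:
                expected = len(de_p) == 1
            else:
                ok_count = len(de_p) >= math.ceil(0.75 * len(gp))
                ok_corr = True
                for a in range(len(de_p)):
                    for b in range(a + 1, len(de_p)):
                        r = np.corrcoef(expr.loc[de_p[a]], expr.loc[de_p[b]])[0, 1]
                        ok_corr &= r >= 0.65
                expected = ok_count and (len(de_p) < 2 or ok_corr)
            assert cons.loc[gene, "passes"] == expected, gene


class TestAnchorCorrelation:
    def _within(self, n_animals=30, p=3, seed=0):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(n_animals * 4, p)), n_times=4)
        return ml.decompose(m).within_matrix, rng

    def test_anchor_with_itself(self):
        w, _ = self._within()
        anchor = w.at_time(1)["v0"]
        res = de.correlate_to_anchor(w, anchor)
        row = res[(res["feature"] == "v0") & (res["time"] == 1)]
        assert row["r"].iloc[0] == pytest.approx(1.0)

    def test_null_rejection_rate(self):
        """Independent noise features reject at ~5% before adjustment."""
        rng = np.random.default_rng(31)
        m = make_matrix(rng.normal(size=(50 * 4, 250)), n_times=4)
        w = ml.decompose(m).within_matrix
        anchor = pd.Series(rng.normal(size=50), index=np.arange(50))
        res = de.correlate_to_anchor(w, anchor)
        rate = (res["p"] < 0.05).mean()
        lo, hi = stats.binom.interval(0.999, len(res), 0.05)
        assert lo <= (res["p"] < 0.05).sum() <= hi, rate

    def test_known_population_correlation_recovered(self):
        """Feature = anchor + noise at an SNR giving r = 0.45: estimate within
        +/- 0.1 at n = 120."""
        rho = 0.45
        rng = np.random.default_rng(32)
        n = 120
        anchor_vals = rng.normal(size=n)
        noise_sd = math.sqrt(1 / rho**2 - 1)
        feature = anchor_vals + rng.normal(size=n) * noise_sd
        values = np.zeros((n * 4, 1))
        values[1::4, 0] = feature  # at time 1
        values[0::4, 0] = rng.normal(size=n)
        values[2::4, 0] = rng.normal(size=n)
        values[3::4, 0] = rng.normal(size=n)
        m = make_matrix(values, n_times=4)
        anchor = pd.Series(anchor_vals, index=np.arange(n))
        res = de.correlate_to_anchor(m, anchor)
        row = res[(res["time"] == 1)]
        assert row["r"].iloc[0] == pytest.approx(rho, abs=0.1)
        assert row["se"].iloc[0] < 0.1

    def test_zero_variance_feature_is_na(self):
        w, _ = self._within()
        vals = w.values.copy()
        vals.loc[w.time.values == 1, "v1"] = 0.0
        m = w.copy(values=vals)
        anchor = m.at_time(1)["v0"]
        with pytest.warns(UserWarning, match="zero-variance"):
            res = de.correlate_to_anchor(m, anchor)
        row = res[(res["feature"] == "v1") & (res["time"] == 1)]
        assert np.isnan(row["r"].iloc[0])
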