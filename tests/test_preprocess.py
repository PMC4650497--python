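"""Cleaning chain: imputation, transforms, batch alignment, normalization, filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stressomics import preprocess as pp
from stressomics import simulate as sim

from conftest import make_matrix


class TestImputeKnn:
    def test_no_missing_is_identity(self):
        m = make_matrix(np.arange(12.0).reshape(6, 2))
        out = pp.impute_knn(m, k=2)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_observed_cells_never_altered(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(10, 4))
        holes = rng.random(values.shape) < 0.2
        df = pd.DataFrame(values).mask(pd.DataFrame(holes))
        out = pp.impute_knn(make_matrix(df.values), k=3)
        observed = ~df.isna().values
        assert np.array_equal(out.values.values[observed], df.values[observed])
        assert not out.values.isna().values.any()

    def test_duplicate_row_forces_neighbour(self):
        values = np.array(
            [[1.0, 2.0, 3.0], [1.0, 2.0, np.nan], [50.0, 60.0, 70.0], [51.0, 61.0, 71.0]]
        )
        out = pp.impute_knn(make_matrix(values), k=1)
        assert out.values.iloc[1, 2] == pytest.approx(3.0)

    def test_matches_bruteforce_neighbour_oracle(self):
        """Imputed value equals the mean over the k nearest rows found by
        exhaustive distance enumeration."""
        rng = np.random.default_rng(1)
        values = rng.normal(size=(5, 3)) * np.array([1.0, 10.0, 0.1])
        hole_row, hole_col, k = 2, 1, 2
        values_h = values.copy()
        values_h[hole_row, hole_col] = np.nan

        sd = np.nanstd(values_h, axis=0, ddof=1)
        Z = values_h / sd
        dists = {}
        for i in range(5):
            if i == hole_row:
                continue
            shared = [j for j in range(3) if j != hole_col]
            d = np.sqrt(np.mean([(Z[i, j] - Z[hole_row, j]) ** 2 for j in shared]))
            dists[i] = d
        nearest = sorted(dists, key=lambda i: dists[i])[:k]
        expected = np.mean([values[i, hole_col] for i in nearest])

        m = make_matrix(values_h, animals=[0, 0, 1, 1, 2], times=[0, 1, 0, 1, 0])
        out = pp.impute_knn(m, k=k)
        assert out.values.iloc[hole_row, hole_col] == pytest.approx(expected, rel=1e-12)

    def test_entirely_missing_column_is_an_error(self):
        values = np.ones((4, 2))
        values[:, 1] = np.nan
        with pytest.raises(pp.ImputationError, match="v1"):
            pp.impute_knn(make_matrix(values), k=1)


class TestTransforms:
    def test_identity_spec_unchanged(self):
        m = make_matrix(np.arange(8.0).reshape(4, 2) + 1)
        out = pp.apply_transforms(m, pp.TransformSpec({"v0": "identity"}))
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_closed_forms(self):
        m = make_matrix([[100.0, 0.16], [100.0, 0.16]])
        out = pp.apply_transforms(
            m, pp.TransformSpec({"v0": "log10", "v1": "sqrt"})
        )
        assert out.values.iloc[0, 0] == pytest.approx(2.0)
        assert out.values.iloc[0, 1] == pytest.approx(0.4)

    def test_log_of_nonpositive_names_cell(self):
        m = make_matrix([[1.0], [-1.0]])
        with pytest.raises(pp.TransformError, match="v0"):
            pp.apply_transforms(m, pp.TransformSpec({"v0": "log10"}))

    def test_default_profile_targets(self):
        spec = pp.TransformSpec.acth_default()
        assert spec.transforms["cortisol"] == "log10"
        assert spec.transforms["ffa"] == "sqrt"


class TestBatchAlignment:
    def test_single_batch_unchanged(self):
        m = make_matrix(np.arange(8.0).reshape(4, 2))
        out = pp.align_batch_medians(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_pure_offset_removed_exactly(self):
        base = np.arange(8.0).reshape(8, 1)
        values = base.copy()
        values[4:] += 3.0
        m = make_matrix(values, batch=[0] * 4 + [1] * 4)
        out = pp.align_batch_medians(m)
        med0 = out.values.iloc[:4, 0].median()
        med1 = out.values.iloc[4:, 0].median()
        assert med0 == pytest.approx(med1, abs=1e-12)

    def test_random_offsets_aligned_and_idempotent(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(30, 4))
        batch = rng.integers(0, 3, size=30)
        values += batch[:, None] * rng.normal(size=4)
        m = make_matrix(values, batch=batch)
        out = pp.align_batch_medians(m)
        for b in range(3):
            block = out.values[batch == b]
            assert np.allclose(
                block.median(axis=0), m.values.median(axis=0), atol=1e-12
            )
        again = pp.align_batch_medians(out)
        assert np.allclose(again.values.values, out.values.values, atol=1e-12)


class TestQuantileNormalization:
    def test_identical_samples_unchanged(self):
        values = np.tile(np.array([1.0, 5.0, 2.0]), (4, 1))
        m = make_matrix(values, n_times=2)
        out = pp.quantile_normalize_within_group(m)
        assert np.allclose(out.values.values, values)

    def test_per_rank_mean_by_hand(self):
        values = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        m = make_matrix(values, n_times=2)
        out = pp.quantile_normalize_within_group(m)
        assert np.allclose(out.values.values, [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_ranks_preserved(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(6, 20))
        m = make_matrix(values, n_times=3)
        out = pp.quantile_normalize_within_group(m)
        for i in range(6):
            rho = stats.spearmanr(values[i], out.values.iloc[i].values).statistic
            assert rho == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(8, 10)), n_times=4)
        once = pp.quantile_normalize_within_group(m)
        twice = pp.quantile_normalize_within_group(once)
        assert np.allclose(once.values.values, twice.values.values, atol=1e-12)

    def test_singleton_group_warns(self):
        m = make_matrix(np.arange(6.0).reshape(3, 2), animals=[0, 0, 1], times=[0, 1, 0])
        with pytest.warns(UserWarning, match="single sample"):
            pp.quantile_normalize_within_group(m)

    def test_median_mode_aligns_medians(self):
        rng = np.random.default_rng(9)
        m = make_matrix(rng.normal(size=(4, 11)) + np.arange(4)[:, None] * 5, n_times=4)
        out = pp.quantile_normalize_within_group(m, mode="median")
        meds = np.median(out.values.values, axis=1)
        assert np.allclose(meds, meds[0], atol=1e-12)


class TestFilterProbes:
    def _dataset(self):
        design = sim.StudyDesign(n_animals=5, seed=10)
        truth = sim.ExpressionTruth(
            gene_clusters={f"G{j}": 0 for j in range(10)},
            probes_per_gene=1,
            n_controls=30,
        )
        return sim.generate_expression(design, truth)

    def test_mode_none_removes_only_controls(self):
        expr, _, probe_map = self._dataset()
        filtered, report = pp.filter_probes(expr, probe_map, threshold_mode="none")
        assert report["n_controls_removed"] == 30
        assert report["n_below_threshold"] == 0
        assert len(filtered) == 10

    def test_constructed_separation(self):
        """Probes planted 3 SD above the control distribution are kept; probes
        3 SD below are removed."""
        rng = np.random.default_rng(11)
        n_samples = 40
        ctrl = rng.normal(2.0, 0.3, size=(100, n_samples))
        hi = rng.normal(2.0 + 0.3 * 3 + 2.0, 0.1, size=(100, n_samples))
        lo = rng.normal(2.0 - 0.3 * 3, 0.1, size=(100, n_samples))
        probes = (
            [f"C{j}" for j in range(100)]
            + [f"HI{j}" for j in range(100)]
            + [f"LO{j}" for j in range(100)]
        )
        expr = pd.DataFrame(np.vstack([ctrl, hi, lo]), index=probes)
        probe_map = pd.DataFrame(
            {"is_control": [True] * 100 + [False] * 200}, index=probes
        )
        filtered, report = pp.filter_probes(expr, probe_map)
        assert set(filtered.index) == {f"HI{j}" for j in range(100)}
        assert report["n_below_threshold"] == 100

    def test_controls_required_for_control_mode(self):
        expr = pd.DataFrame(np.ones((3, 4)), index=["a", "b", "c"])
        probe_map = pd.DataFrame({"is_control": [False] * 3}, index=expr.index)
        with pytest.raises(ValueError, match="control"):
            pp.filter_probes(expr, probe_map, threshold_mode="control")


class TestOutlierMasking:
    def test_extreme_cell_masked_others_kept(self):
        rng = np.random.default_rng(12)
        values = rng.normal(0, 1, size=(40, 2))
        values[3, 0] = 100.0
        m = make_matrix(values, n_times=4)
        out = pp.mask_outliers(m, z_threshold=4.0)
        assert np.isnan(out.values.iloc[3, 0])
        # small-group MAD estimates may flag a few borderline cells too
        assert out.values.isna().values.sum() <= 4


class TestProvenance:
    def test_operations_logged_in_order(self, tmp_path):
        log = pp.ProvenanceLog()
        m = make_matrix(np.arange(16.0).reshape(8, 2) + 1, batch=[0] * 4 + [1] * 4)
        m = pp.impute_knn(m, k=2, log=log)
        m = pp.apply_transforms(m, pp.TransformSpec({"v0": "log10"}), log=log)
        m = pp.align_batch_medians(m, log=log)
        assert [e["operation"] for e in log.entries] == [
            "impute_knn",
            "apply_transforms",
            "align_batch_medians",
        ]
        assert log.entries[0]["params"]["k"] == 2
        log.write(tmp_path / "prov.jsonl")
        assert len((tmp_path / "prov.jsonl").read_text().splitlines()) == 3
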