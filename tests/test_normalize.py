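import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lymphomir as lm
from lymphomir.quantify import ExpressionMatrix


def _frame(arr, prefix="m"):
    arr = np.asarray(arr, float)
    return pd.DataFrame(
        arr, index=[f"s{i}" for i in range(arr.shape[0])],
        columns=[f"{prefix}{j}" for j in range(arr.shape[1])])


def _batch_sim(n_per_batch, n_mirnas, shifts, class_effect=0.0, seed=0,
               n_classes=2, shift_sd=0.3):
    """Gaussian matrix with per-batch additive shifts (per-miRNA effects
    drawn around the stated batch mean, matching the location/scale batch
    model) and an optional class effect on the first half of the miRNAs;
    classes are balanced within every batch so the design is not
    confounded."""
    rng = np.random.default_rng(seed)
    blocks, batches, classes = [], [], []
    for b, shift in enumerate(shifts):
        gamma = rng.normal(shift, shift_sd, n_mirnas)
        X = rng.normal(8.0, 1.0, (n_per_batch, n_mirnas)) + gamma
        cls = np.tile([f"c{k}" for k in range(n_classes)],
                      n_per_batch // n_classes + 1)[:n_per_batch]
        X[cls == "c1", : n_mirnas // 2] += class_effect
        blocks.append(X)
        batches += [f"b{b}"] * n_per_batch
        classes += list(cls)
    values = _frame(np.vstack(blocks))
    idx = values.index
    return (values, pd.Series(batches, index=idx),
            pd.Series(classes, index=idx))


class TestDetectionFilter:
    def test_boundary_inclusive_at_ten_percent(self):
        values = _frame(np.zeros((10, 2)))
        mask = values.astype(bool).copy()
        mask[:] = True
        mask.iloc[0, 0] = False            # 1/10 undetected: retained
        mask.iloc[0:2, 1] = False          # 2/10 undetected: removed
        out = lm.filter_detection(ExpressionMatrix(values, mask))
        assert list(out.values.columns) == ["m0"]

    def test_retained_count_matches_mask_recount(self, small_cohort,
                                                 small_quant):
        _, annotation, _ = small_cohort
        em, _ = small_quant
        disc = annotation.index[annotation["cohort"] == "discovery"]
        sub = ExpressionMatrix(em.values.loc[disc], em.mask.loc[disc])
        out = lm.filter_detection(sub)
        oracle = ((1 - sub.mask.mean(axis=0)) <= 0.10).sum()
        assert out.values.shape[1] == oracle

    def test_empty_result_raises(self):
        values = _frame(np.zeros((4, 2)))
        mask = values.astype(bool).copy()
        mask[:] = False
        with pytest.raises(ValueError, match="relax"):
            lm.filter_detection(ExpressionMatrix(values, mask))


class TestGlobalMeanNormalize:
    def test_constant_matrix_becomes_zero(self):
        out = lm.global_mean_normalize(_frame(np.full((3, 4), 7.5)))
        assert np.allclose(out, 0.0)

    def test_two_value_sample(self):
        out = lm.global_mean_normalize(_frame([[4.0, 6.0]]))
        assert np.allclose(out, [[-1.0, 1.0]])

    def test_matches_manual_subtraction(self):
        rng = np.random.default_rng(5)
        values = _frame(rng.normal(8, 2, (20, 50)))
        out = lm.global_mean_normalize(values)
        oracle = values.to_numpy() - values.to_numpy().mean(
            axis=1, keepdims=True)
        assert np.allclose(out.to_numpy(), oracle)
        assert np.abs(out.mean(axis=1)).max() < 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        values = _frame(rng.normal(0, 1, (10, 8)))
        once = lm.global_mean_normalize(values)
        twice = lm.global_mean_normalize(once)
        assert np.allclose(once, twice, atol=1e-9)


class TestZscore:
    def test_two_sample_values(self):
        out = lm.zscore_standardize(_frame([[1.0], [3.0]]))
        assert np.allclose(out.to_numpy().ravel(),
                           [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_moments_and_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        values = _frame(rng.normal(5, 3, (30, 40)))
        out = lm.zscore_standardize(values)
        assert np.abs(out.mean(axis=0)).max() < 1e-9
        assert np.abs(out.std(axis=0, ddof=1) - 1).max() < 1e-9
        X = values.to_numpy()
        oracle = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        assert np.allclose(out.to_numpy(), oracle)

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        once = lm.zscore_standardize(_frame(rng.normal(0, 1, (12, 6))))
        twice = lm.zscore_standardize(once)
        assert np.allclose(once, twice, atol=1e-9)

    def test_zero_variance_rejected(self):
        values = _frame(np.ones((5, 2)))
        values["m1"] = [1, 2, 3, 4, 5.0]
        with pytest.raises(ValueError, match="m0"):
            lm.zscore_standardize(values)


class TestHousekeepingNormalize:
    def test_all_mirnas_equals_global_normalization(self):
        rng = np.random.default_rng(9)
        values = _frame(rng.normal(8, 1, (10, 6)))
        hk = lm.housekeeping_normalize(values, values.columns)
        gl = lm.global_mean_normalize(values)
        assert np.allclose(hk, gl)

    def test_constant_housekeeping_preserves_differences(self):
        values = _frame([[5.0, 1.0], [7.0, 1.0], [6.0, 1.0]])
        out = lm.housekeeping_normalize(values, ["m1"])
        diffs = np.diff(out["m0"])
        assert np.allclose(diffs, np.diff(values["m0"]))

    def test_hand_computed_fixture(self):
        values = _frame([[4.0, 6.0, 10.0], [2.0, 4.0, 3.0]])
        out = lm.housekeeping_normalize(values, ["m0", "m1"])
        assert np.allclose(out.to_numpy(),
                           [[-1.0, 1.0, 5.0], [-1.0, 1.0, 0.0]])

    def test_missing_id_error(self):
        with pytest.raises(ValueError, match="absent"):
            lm.housekeeping_normalize(_frame(np.ones((2, 2))), ["zz"])


class TestCombat:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        values = _frame(rng.normal(0, 1, (10, 5)))
        out, _ = lm.combat_correct(
            values, pd.Series("b0", index=values.index))
        pd.testing.assert_frame_equal(out, values)

    def test_singleton_batch_rejected(self):
        values = _frame(np.random.default_rng(2).normal(0, 1, (5, 3)))
        batch = pd.Series(["a", "a", "a", "a", "b"], index=values.index)
        with pytest.raises(ValueError, match="single sample"):
            lm.combat_correct(values, batch)

    def test_confounded_design_rejected(self):
        values, batch, _ = _batch_sim(10, 5, [0, 0], seed=3)
        confounded = pd.DataFrame(
            {"dup": (batch == "b1").astype(float)}, index=values.index)
        with pytest.raises(ValueError, match="rank-deficient"):
            lm.combat_correct(values, batch, confounded)

    def test_near_identity_without_batch_effect(self):
        values, batch, _ = _batch_sim(100, 60, [0.0, 0.0], seed=4,
                                      shift_sd=0.0)
        out, _ = lm.combat_correct(values, batch)
        assert np.abs(out - values).to_numpy().mean() < 0.05

    def test_recovers_planted_site_shifts(self):
        """The planted +-0.8 site shifts are removed: the post-correction
        between-site offset (averaged over null miRNAs, in sd units) is
        within 0.05 of zero, and the reported additive estimates recover
        the planted shift magnitude."""
        values, batch, cls = _batch_sim(100, 60, [+0.8, -0.8], seed=5,
                                        shift_sd=0.4)
        out, report = lm.combat_correct(
            values, batch, pd.DataFrame({"cls": cls}))
        sd = out.std(axis=0, ddof=1)
        gap = (out[(batch == "b0").to_numpy()].mean(axis=0)
               - out[(batch == "b1").to_numpy()].mean(axis=0)) / sd
        assert abs(gap.mean()) < 0.05
        # per-miRNA residuals are bounded by EB sampling noise
        assert np.abs(gap).mean() < 0.10
        # reported additive estimates track the planted +-0.8 shifts
        gamma = report.batch_gamma.mean(axis=1)
        assert gamma["b0"] > 0.5 and gamma["b1"] < -0.5

    def test_preserves_class_effect(self):
        values, batch, cls = _batch_sim(
            100, 60, [+0.8, -0.8], class_effect=1.5, seed=6)
        out, _ = lm.combat_correct(values, batch,
                                   pd.DataFrame({"cls": cls}))
        informative = values.columns[:30]
        def gap(df):
            return (df.loc[(cls == "c1").to_numpy(), informative].mean()
                    - df.loc[(cls == "c0").to_numpy(), informative].mean())
        before, after = gap(values).mean(), gap(out).mean()
        assert abs(after - before) / abs(before) < 0.10

    def test_batch_f_test_rejection_rate_at_most_nominal(self):
        values, batch, _ = _batch_sim(60, 100, [+0.6, -0.6, 0.2], seed=7,
                                      n_classes=1)
        out, _ = lm.combat_correct(values, batch)
        groups = [out[(batch == b).to_numpy()] for b in ("b0", "b1", "b2")]
        rej = 0
        for m in out.columns:
            f = stats.f_oneway(*(g[m] for g in groups))
            rej += f.pvalue < 0.05
        assert rej / len(out.columns) <= 0.07

    def test_matches_reference_implementation(self):
        """Dual-route check against scanpy's ComBat on the same input."""
        anndata = pytest.importorskip("anndata")
        scanpy = pytest.importorskip("scanpy")
        values, batch, cls = _batch_sim(30, 20, [+0.5, -0.5], seed=8)
        cov = (cls == "c1").astype(float)
        adata = anndata.AnnData(values.to_numpy().copy())
        adata.obs["batch"] = pd.Categorical(batch.to_numpy())
        adata.obs["cov"] = cov.to_numpy()
        ref = scanpy.pp.combat(adata, key="batch", covariates=["cov"],
                               inplace=False)
        mine, _ = lm.combat_correct(values, batch,
                                    pd.DataFrame({"cov": cov}))
        assert np.abs(mine.to_numpy() - ref).max() < 0.01


class TestMergeCohorts:
    @staticmethod
    def _annotated(values, cohort, site, diagnosis, tissue):
        ann = pd.DataFrame({
            "diagnosis": diagnosis, "tissue_site": tissue,
            "collection_site": site, "cohort": cohort,
        }, index=values.index)
        return ann

    def _two_cohorts(self, shift=0.0, seed=0, n=80, g=24):
        rng = np.random.default_rng(seed)
        disc = _frame(rng.normal(8, 1, (n, g)))
        disc.index = [f"D{i}" for i in range(n)]
        val = _frame(rng.normal(8, 1, (n, g)) + shift)
        val.index = [f"V{i}" for i in range(n)]
        merged_idx = disc.index.append(val.index)
        lab_rng = np.random.default_rng(seed + 100)
        diagnosis = np.tile(["RL", "FL"], n)
        tissue = lab_rng.choice(["nodal", "extranodal"], 2 * n)
        site = ["NUH"] * n + list(lab_rng.choice(["NUH", "TTSH"], n))
        ann = pd.DataFrame({
            "diagnosis": diagnosis, "tissue_site": tissue,
            "collection_site": site,
            "cohort": ["discovery"] * n + ["validation"] * n,
        }, index=merged_idx)
        return disc, val, ann

    def test_cohort_shift_removed(self):
        """A 0.5 log2 cohort-level shift is removed: the residual
        between-cohort offset (averaged across miRNAs, sd units) is within
        0.05 of zero."""
        disc, val, ann = self._two_cohorts(shift=0.5, seed=1)
        hk = list(disc.columns[:3])
        merged = lm.merge_cohorts(disc, val, ann, hk)
        markers = [c for c in merged.columns if c.startswith("m")]
        sd = merged[markers].std(axis=0, ddof=1)
        gap = (merged.loc[disc.index, markers].mean()
               - merged.loc[val.index, markers].mean()) / sd
        assert abs(gap.mean()) < 0.05

    def test_alignment_by_id_not_position(self):
        disc, val, ann = self._two_cohorts(seed=2)
        scrambled = val[list(val.columns[::-1])]
        hk = list(disc.columns[:3])
        a = lm.merge_cohorts(disc, val, ann, hk)
        b = lm.merge_cohorts(disc, scrambled, ann, hk)
        pd.testing.assert_frame_equal(a, b)

    def test_tissue_indicator_appended(self):
        disc, val, ann = self._two_cohorts(seed=3)
        merged = lm.merge_cohorts(disc, val, ann, list(disc.columns[:2]))
        assert "tissue_site_numeric" in merged.columns
        assert set(merged["tissue_site_numeric"]) <= {0, 1}

    def test_disjoint_panels_rejected(self):
        disc, val, ann = self._two_cohorts(seed=4)
        val = val.rename(columns=lambda c: c + "_x")
        with pytest.raises(ValueError, match="no miRNAs"):
            lm.merge_cohorts(disc, val, ann, [])
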