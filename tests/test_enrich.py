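from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lymphomir as lm
from lymphomir.enrich import _score_pathways


def enumeration_pvalue(targets, pathway, universe):
    """Exhaustive oracle: over all draws of |targets| genes from the
    universe, the fraction with an overlap at least as large as observed."""
    k_obs = len(set(targets) & set(pathway))
    n_hits = total = 0
    for draw in combinations(sorted(universe), len(targets)):
        total += 1
        if len(set(draw) & set(pathway)) >= k_obs:
            n_hits += 1
    return n_hits / total


def running_sum_oracle(ranked_members, weights=None):
    """Step-by-step unweighted (or explicitly weighted) KS running sum."""
    n = len(ranked_members)
    n_mem = sum(ranked_members)
    if weights is None:
        weights = [1.0 if m else 0.0 for m in ranked_members]
    total_w = sum(w for w, m in zip(weights, ranked_members) if m)
    running, best = 0.0, 0.0
    for m, w in zip(ranked_members, weights):
        running += (w / total_w) if m else -1.0 / (n - n_mem)
        if abs(running) > abs(best):
            best = running
    return best


class TestTargetingPvalue:
    def test_no_overlap_is_one(self):
        u = {f"g{i}" for i in range(10)}
        assert lm.targeting_pvalue({"g0", "g1"}, {"g5", "g6"} - {"g0"},
                                   u) <= 1.0
        p = lm.targeting_pvalue({"g0"}, {"g5"}, u)
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        """Universe 10, pathway 5, targets 3, overlap 3:
        p = C(5,3)/C(10,3) = 10/120."""
        u = [f"g{i}" for i in range(10)]
        pathway = set(u[:5])
        targets = set(u[:3])
        p = lm.targeting_pvalue(targets, pathway, u)
        assert p == pytest.approx(10 / 120, rel=1e-12)

    def test_targets_equal_universe(self):
        u = {f"g{i}" for i in range(8)}
        assert lm.targeting_pvalue(u, set(list(u)[:3]), u) == (
            pytest.approx(1.0))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            lm.targeting_pvalue({"g0"}, {"g0"}, set())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        """Exact agreement with brute-force enumeration on universes of
        at most 12 genes."""
        rng = np.random.default_rng(seed)
        n_u = int(rng.integers(6, 13))
        u = [f"g{i}" for i in range(n_u)]
        pathway = set(rng.choice(u, rng.integers(2, n_u - 1), replace=False))
        targets = set(rng.choice(u, rng.integers(1, 5), replace=False))
        p = lm.targeting_pvalue(targets, pathway, u)
        assert p == pytest.approx(enumeration_pvalue(targets, pathway, u),
                                  rel=1e-9)


class TestPathwayScore:
    def test_single_member_ranked_first(self):
        ranked = pd.Series([3.0, 2.0, 1.0, 0.5],
                           index=["a", "b", "c", "d"])
        score = lm.pathway_score(ranked, {"a": 0.01})
        assert score == pytest.approx(1.0)

    def test_unit_weights_match_unweighted_oracle(self):
        """weight_exponent=0 reduces to the classical KS statistic,
        checked against a step-by-step running sum."""
        rng = np.random.default_rng(1)
        ids = [f"m{i}" for i in range(10)]
        ranked = pd.Series(np.sort(rng.normal(0, 1, 10))[::-1], index=ids)
        members = {ids[i]: 0.3 for i in (0, 3, 4, 8)}
        got = lm.pathway_score(ranked, members, weight_exponent=0.0)
        oracle = running_sum_oracle([i in members for i in ids])
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_weighted_score_matches_manual_sum(self):
        ids = ["a", "b", "c", "d", "e"]
        lfc = [2.0, 1.0, 0.5, -0.5, -2.0]
        ranked = pd.Series(lfc, index=ids)
        members = {"a": 0.01, "d": 0.5}
        w = {m: abs(ranked[m]) * -np.log10(members[m]) for m in members}
        weights = [w.get(i, 0.0) for i in ids]
        oracle = running_sum_oracle([i in members for i in ids], weights)
        got = lm.pathway_score(ranked, members, weight_exponent=1.0)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_interleaved_members_below_own_null(self):
        """Uniformly interleaved members score below the 95th percentile
        of their own permutation null."""
        n = 100
        ids = [f"m{i}" for i in range(n)]
        lfc_abs = np.abs(np.sort(np.random.default_rng(2).normal(0, 1, n)
                                 )[::-1])
        member = np.zeros(n, bool)
        member[::5] = True
        logp = np.where(member, 1.0, 0.0)[None, :]
        obs = _score_pathways(lfc_abs, logp, member[None, :], 1.0)
        _, null = lm.permutation_test(obs, lfc_abs, logp, member[None, :],
                                      n_permutations=500, seed=3)
        assert abs(obs[0]) < np.percentile(np.abs(null[0]), 95)

    def test_score_bounded_by_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            ids = [f"m{i}" for i in range(n)]
            ranked = pd.Series(np.sort(rng.normal(0, 1, n))[::-1],
                               index=ids)
            k = int(rng.integers(1, n))
            members = {ids[i]: float(rng.uniform(1e-4, 1))
                       for i in rng.choice(n, k, replace=False)}
            assert abs(lm.pathway_score(ranked, members)) <= 1.0 + 1e-12


class TestPermutationTest:
    def _null_setup(self, n_pathways=200, n_mirnas=120, seed=5):
        rng = np.random.default_rng(seed)
        lfc_abs = np.abs(np.sort(rng.normal(0, 1, n_mirnas))[::-1])
        member = rng.random((n_pathways, n_mirnas)) < 0.2
        member[~member.any(axis=1), 0] = True
        logp = np.where(member, rng.uniform(0.5, 3.0,
                                            (n_pathways, n_mirnas)), 0.0)
        return lfc_abs, logp, member

    def test_null_pvalues_uniform(self):
        """With membership independent of rank, permutation p-values over
        200 pathways pass a KS uniformity check."""
        lfc_abs, logp, member = self._null_setup()
        obs = _score_pathways(lfc_abs, logp, member, 1.0)
        p, _ = lm.permutation_test(obs, lfc_abs, logp, member,
                                   n_permutations=500, seed=6)
        ks = sps.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_pseudocount_floor(self):
        lfc_abs, logp, member = self._null_setup(n_pathways=3, n_mirnas=30)
        obs = _score_pathways(lfc_abs, logp, member, 1.0)
        p, _ = lm.permutation_test(obs, lfc_abs, logp, member,
                                   n_permutations=100, seed=7)
        assert (p >= 1 / 101).all()

    def test_deterministic(self):
        lfc_abs, logp, member = self._null_setup(n_pathways=5, n_mirnas=40)
        obs = _score_pathways(lfc_abs, logp, member, 1.0)
        p1, n1 = lm.permutation_test(obs, lfc_abs, logp, member, 200, seed=8)
        p2, n2 = lm.permutation_test(obs, lfc_abs, logp, member, 200, seed=8)
        assert np.array_equal(p1, p2) and np.array_equal(n1, n2)

    def test_too_few_permutations_rejected(self):
        lfc_abs, logp, member = self._null_setup(n_pathways=2, n_mirnas=20)
        obs = _score_pathways(lfc_abs, logp, member, 1.0)
        with pytest.raises(ValueError, match="100"):
            lm.permutation_test(obs, lfc_abs, logp, member, 50, seed=9)


class TestFdr:
    def test_null_scores_get_q_near_one(self):
        rng = np.random.default_rng(10)
        null = rng.normal(0, 0.3, 5000)
        observed = rng.normal(0, 0.3, 60)
        q = lm.fdr_correct(observed, null)
        assert np.median(q) > 0.5

    def test_planted_outlier_q_below_cutoff(self):
        rng = np.random.default_rng(11)
        null = rng.normal(0, 0.2, 5000)
        observed = np.append(rng.normal(0, 0.2, 40), 2.5)
        q = lm.fdr_correct(observed, null)
        assert q[-1] < 0.01

    def test_monotone_in_score(self):
        rng = np.random.default_rng(12)
        null = rng.normal(0, 0.3, 2000)
        observed = rng.normal(0, 0.5, 80)
        q = lm.fdr_correct(observed, null)
        pos = observed >= 0
        order = np.argsort(observed[pos])
        assert (np.diff(q[pos][order]) <= 1e-12).all()
        order = np.argsort(-observed[~pos])
        assert (np.diff(q[~pos][order]) <= 1e-12).all()

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lm.fdr_correct(np.array([0.5]), np.array([]))


class TestRunMirsea:
    def _diff_stats(self, ids, lfc):
        return pd.DataFrame({
            "mirna_id": ids, "contrast": "lymphoma_vs_RL",
            "mean_diff": lfc, "t": lfc, "p": 0.05,
            "direction": np.where(np.asarray(lfc) > 0, "up", "down")})

    def test_size_filter_bounds(self):
        """Pathways targeted by 5 / 50 / 600 miRNAs: only the 50 passes."""
        rng = np.random.default_rng(13)
        n_mirnas = 700
        ids = [f"m{i}" for i in range(n_mirnas)]
        genes = [f"g{i}" for i in range(3000)]
        rows = []
        targets = {}
        for m in ids:
            tg = set(rng.choice(genes, 4, replace=False))
            targets[m] = tg
            rows += [(m, g, "strong") for g in tg]
        # a dedicated gene targeted by exactly the first 5 miRNAs keeps
        # the tiny pathway below the lower size bound
        for m in ids[:5]:
            targets[m].add("g_tiny")
            rows.append((m, "g_tiny", "strong"))
        tmap = pd.DataFrame(rows, columns=["mirna_id", "gene_id",
                                           "evidence"])
        def pathway_with(k):
            genes_k = set()
            for m in ids[:k]:
                genes_k.add(next(iter(sorted(targets[m]))))
            return genes_k
        pathways = {"tiny": ("KEGG", {"g_tiny"}),
                    "mid": ("KEGG", pathway_with(50)),
                    "huge": ("KEGG", set().union(
                        *(targets[m] for m in ids[:600])))}
        stats_table = self._diff_stats(ids, rng.normal(0, 1, n_mirnas))
        res = lm.run_mirsea(stats_table, tmap, pathways,
                            n_permutations=100, seed=14)
        assert list(res.table["pathway"]) == ["mid"]

    def test_planted_pathways_recovered_exactly(self):
        """On a synthetic cohort with planted marker-targeted KEGG-tagged
        sets, a q<0.01 cutoff calls exactly the planted sets."""
        cfg = lm.SimulationConfig(
            n_mirnas=300, n_markers_per_class=12,
            n_samples_discovery={c: 16 for c in lm.CLASSES},
            n_samples_validation={c: 2 for c in lm.CLASSES}, seed=11)
        plates, annotation, truth = lm.simulate_cohort(cfg)
        planted_src = [m for m, d in
                       truth.true_markers["RL_vs_rest"].items() if d < 0]
        tmap, pathways = lm.simulate_pathway_resources(
            cfg, n_pathways=40, n_genes=4000, seed=3,
            true_markers=planted_src, n_enriched=3)
        em, _ = lm.quantify_plateset(plates)
        disc = annotation.index[annotation["cohort"] == "discovery"]
        dem = lm.filter_detection(
            lm.ExpressionMatrix(em.values.loc[disc], em.mask.loc[disc]))
        norm = lm.zscore_standardize(lm.global_mean_normalize(dem.values))
        st = lm.ttest_contrast(
            norm, annotation["diagnosis"].map(
                lambda c: "RL" if c == "RL" else "lymphoma"),
            "lymphoma_vs_RL")
        res = lm.run_mirsea(st, tmap, pathways, n_permutations=1000,
                            seed=1)
        called = set(res.significant(0.01)["pathway"])
        planted = {n for n in pathways if "PLANTED" in n}
        assert called == planted

    def test_deterministic(self):
        rng = np.random.default_rng(15)
        ids = [f"m{i}" for i in range(60)]
        genes = [f"g{i}" for i in range(400)]
        rows = []
        for m in ids:
            for g in rng.choice(genes, 8, replace=False):
                rows.append((m, g, "strong"))
        tmap = pd.DataFrame(rows, columns=["mirna_id", "gene_id",
                                           "evidence"])
        pathways = {f"p{k}": ("KEGG", set(rng.choice(genes, 100,
                                                     replace=False)))
                    for k in range(5)}
        stats_table = self._diff_stats(ids, rng.normal(0, 1, 60))
        r1 = lm.run_mirsea(stats_table, tmap, pathways, n_permutations=150,
                           seed=16)
        r2 = lm.run_mirsea(stats_table, tmap, pathways, n_permutations=150,
                           seed=16)
        pd.testing.assert_frame_equal(r1.table, r2.table)
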