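"""miRNA set enrichment analysis (miRSEA).

Links differentially expressed miRNAs to pathway regulation:

1. each miRNA's targeting of a pathway is scored by an upper-tail
   hypergeometric p-value on the overlap between its validated target
   genes and the pathway, within the universe of all targeted genes;
2. miRNAs ranked by descending log2 fold change (lymphoma vs reactive)
   are walked GSEA-style: a miRNA that targets the pathway advances a
   running sum by its weight w = |log2FC| * (-log10 targeting-p)
   (normalized to sum 1), a non-targeting miRNA retreats by
   1/(N - N_members); the enrichment score is the signed maximum
   excursion, so |ES| <= 1;
3. significance comes from permuting miRNA identities (severing the
   fold-change/membership linkage), with p = (1 + #{null as extreme,
   same sign}) / (1 + n_permutations);
4. FDR q-values use the null distribution pooled over all pathways:
   q(s) = [fraction of pooled null >= s] / [fraction of observed >= s]
   (mirrored for negative scores), clipped to [0, 1] and made monotone.

Pathways targeted by fewer than 10 or more than 500 miRNAs are excluded
before any scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "targeting_pvalue",
    "pathway_score",
    "permutation_test",
    "fdr_correct",
    "run_mirsea",
]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # pathway, source, n_mirnas, score, p, q
    pooled_null: np.ndarray

    def significant(self, q_cutoff: float = 0.01) -> pd.DataFrame:
        return self.table[self.table["q"] < q_cutoff]


def targeting_pvalue(mirna_targets, pathway, universe) -> float:
    """Upper-tail hypergeometric P(X >= k) for target/pathway overlap.

    Draws |targets| genes from a universe containing |pathway| successes;
    k is the observed overlap. No overlap gives p = 1.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    targets = set(mirna_targets) & universe
    path = set(pathway) & universe
    k = len(targets & path)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(path),
                                    len(targets)))


def _weights(lfc: np.ndarray, member_p: np.ndarray, member: np.ndarray,
             weight_exponent: float) -> np.ndarray:
    """Per-position hit weights (zero off-membership), normalized to sum 1."""
    base = np.abs(lfc) * (-np.log10(np.clip(member_p, 1e-300, 1.0)))
    w = np.where(member, base ** weight_exponent, 0.0)
    total = w.sum()
    if total <= 0:  # degenerate weights: fall back to equal steps
        w = member.astype(float)
        total = w.sum()
    return w / total


def _running_score(hit_w: np.ndarray, member: np.ndarray) -> float:
    """Signed maximum excursion of the GSEA-style running sum."""
    n = len(member)
    n_mem = int(member.sum())
    if n_mem == 0 or n_mem == n:
        return 0.0
    steps = hit_w - (~member) / (n - n_mem)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _score_pathways(lfc_abs: np.ndarray, logp_mat: np.ndarray,
                    member_mat: np.ndarray,
                    weight_exponent: float) -> np.ndarray:
    """Vectorized scores for P pathways over N ranked miRNAs.

    ``lfc_abs`` is fixed to rank positions; ``logp_mat``/``member_mat``
    carry the miRNA-linked targeting strength and membership (these are the
    columns the permutation test shuffles). Weights are renormalized per
    pathway so each row's hits sum to 1.
    """
    P, N = member_mat.shape
    w = np.where(member_mat,
                 (lfc_abs[None, :] * logp_mat) ** weight_exponent, 0.0)
    totals = w.sum(axis=1, keepdims=True)
    degenerate = (totals <= 0).ravel()
    if degenerate.any():
        w[degenerate] = member_mat[degenerate].astype(float)
        totals = w.sum(axis=1, keepdims=True)
    w = w / np.maximum(totals, 1e-300)
    n_mem = member_mat.sum(axis=1, keepdims=True)
    miss = (~member_mat) / np.maximum(N - n_mem, 1)
    running = np.cumsum(w - miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(P), idx]


def pathway_score(ranked_mirnas, membership, weight_exponent: float = 1.0
                  ) -> float:
    """Weighted KS-like enrichment score for one pathway.

    Parameters
    ----------
    ranked_mirnas
        Either a pandas Series of log2 fold changes indexed by miRNA id
        (sorted descending before use) or an ordered list of
        (mirna_id, log2fc) pairs.
    membership
        Mapping miRNA id -> targeting p-value, defined exactly for the
        miRNAs with at least one validated target in the pathway.
    weight_exponent
        0 recovers the classical unweighted KS/GSEA statistic.
    """
    if isinstance(ranked_mirnas, pd.Series):
        ranked = ranked_mirnas.sort_values(ascending=False, kind="mergesort")
        ids = ranked.index.to_numpy()
        lfc = ranked.to_numpy(float)
    else:
        ids = np.array([m for m, _ in ranked_mirnas])
        lfc = np.array([v for _, v in ranked_mirnas], float)
    member = np.array([m in membership for m in ids])
    member_p = np.array([membership.get(m, 1.0) for m in ids], float)
    w = _weights(lfc, member_p, member, weight_exponent)
    return _running_score(w, member)


def permutation_test(observed: np.ndarray, lfc_abs: np.ndarray,
                     logp_mat: np.ndarray, member_mat: np.ndarray,
                     n_permutations: int = 10000, seed: int = 0,
                     weight_exponent: float = 1.0):
    """Permutation p-values and the per-pathway null score matrix.

    Permutes miRNA identities over the ranked list: the fold-change
    magnitudes stay at their rank positions while each pathway's
    membership and targeting-strength columns are shuffled, severing the
    fold-change/membership linkage; every pathway is then rescored. The
    p-value counts permutation scores at least as extreme as the observed
    one with the matching sign, normalized by the same-sign null count
    (with a +1 pseudocount), so null p-values are uniform.
    """
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    rng = np.random.default_rng(seed)
    P, N = member_mat.shape
    null = np.empty((P, n_permutations))
    for b in range(n_permutations):
        perm = rng.permutation(N)
        null[:, b] = _score_pathways(lfc_abs, logp_mat[:, perm],
                                     member_mat[:, perm], weight_exponent)
    ge = (null >= observed[:, None]).sum(axis=1)
    le = (null <= observed[:, None]).sum(axis=1)
    n_pos = (null >= 0).sum(axis=1)
    n_neg = n_permutations - n_pos
    extreme = np.where(observed >= 0, ge, le)
    same_sign = np.where(observed >= 0, n_pos, n_neg)
    p = (1.0 + extreme) / (1.0 + same_sign)
    return np.minimum(p, 1.0), null


def fdr_correct(observed: np.ndarray, pooled_null: np.ndarray) -> np.ndarray:
    """GSEA-style FDR from the pooled permutation null.

    For a positive score s: q = [frac pooled null >= s] / [frac observed
    >= s]; negative scores mirror with <=. q is clipped to [0, 1] and made
    monotone non-increasing in |preference|, separately per sign.
    """
    pooled_null = np.asarray(pooled_null).ravel()
    if pooled_null.size == 0:
        raise ValueError("pooled null is empty")
    obs = np.asarray(observed, float)
    q = np.ones_like(obs)
    null_pos = pooled_null[pooled_null >= 0]
    null_neg = pooled_null[pooled_null < 0]
    pos = obs >= 0
    if pos.any():
        obs_pos = obs[pos]
        for i in np.flatnonzero(pos):
            s = obs[i]
            num = np.mean(null_pos >= s) if null_pos.size else 0.0
            den = np.mean(obs_pos >= s)
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        # monotone: a larger score never has a larger q — each pathway
        # takes the min of its raw q and every less-extreme pathway's
        order = np.argsort(obs[pos])  # least extreme first
        qp = q[pos]
        qp[order] = np.minimum.accumulate(qp[order])
        q[pos] = qp
    neg = ~pos
    if neg.any():
        obs_neg = obs[neg]
        for i in np.flatnonzero(neg):
            s = obs[i]
            num = np.mean(null_neg <= s) if null_neg.size else 0.0
            den = np.mean(obs_neg <= s)
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        order = np.argsort(-obs[neg])
        qn = q[neg]
        qn[order] = np.minimum.accumulate(qn[order])
        q[neg] = qn
    return q


def run_mirsea(diff_stats: pd.DataFrame, target_map: pd.DataFrame,
               pathways: dict, size_filter: tuple[int, int] = (10, 500),
               n_permutations: int = 10000, seed: int = 0,
               weight_exponent: float = 1.0) -> EnrichmentResult:
    """Full enrichment analysis for one differential contrast.

    Parameters
    ----------
    diff_stats
        Rows with ``mirna_id`` and ``mean_diff`` (log2 fold change,
        group of interest minus comparison) for a single contrast.
    target_map
        DataFrame with columns ``mirna_id``, ``gene_id`` (strong-evidence
        interactions).
    pathways
        Mapping pathway name -> (source_tag, gene set).
    """
    lfc = (diff_stats.set_index("mirna_id")["mean_diff"]
           .sort_values(ascending=False, kind="mergesort"))
    ids = lfc.index.to_numpy()
    universe = set(target_map["gene_id"])
    targets = {m: set(g["gene_id"])
               for m, g in target_map.groupby("mirna_id")}
    analyzed = [m for m in ids if m in targets]
    lfc = lfc.loc[analyzed]
    ids = lfc.index.to_numpy()
    N = len(ids)
    if N == 0:
        raise ValueError("no ranked miRNA has target annotations")

    names, sources, member_rows, logp_rows, n_targeting = [], [], [], [], []
    for name, (src, genes) in pathways.items():
        genes = set(genes) & universe
        member = np.array([bool(targets[m] & genes) for m in ids])
        k = int(member.sum())
        if not size_filter[0] <= k <= size_filter[1]:
            continue
        member_p = np.array([
            targeting_pvalue(targets[m], genes, universe) if mm else 1.0
            for m, mm in zip(ids, member)])
        names.append(name)
        sources.append(src)
        member_rows.append(member)
        logp_rows.append(-np.log10(np.clip(member_p, 1e-300, 1.0)))
        n_targeting.append(k)

    if not names:
        import warnings
        warnings.warn("no pathway passes the targeting-size filter")
        return EnrichmentResult(
            pd.DataFrame(columns=["pathway", "source", "n_mirnas", "score",
                                  "p", "q"]),
            np.empty(0))

    member_mat = np.vstack(member_rows)
    logp_mat = np.vstack(logp_rows)
    lfc_abs = np.abs(lfc.to_numpy(float))
    scores = _score_pathways(lfc_abs, logp_mat, member_mat, weight_exponent)
    p, null = permutation_test(scores, lfc_abs, logp_mat, member_mat,
                               n_permutations, seed,
                               weight_exponent=weight_exponent)
    q = fdr_correct(scores, null.ravel())
    table = pd.DataFrame({
        "pathway": names, "source": sources, "n_mirnas": n_targeting,
        "score": scores, "p": p, "q": q,
    }).sort_values(["q", "p", "pathway"]).reset_index(drop=True)
    return EnrichmentResult(table, null.ravel())
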