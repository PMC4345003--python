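"""Post-hoc refinement of significant interactions.

Significant pairs for one probe are often statistical echoes of a
single underlying interaction, because several SNPs tag the same
haplotype. Redundancy grouping merges two interactions when their SNPs
can be matched up in LD (or are identical) and the interaction
coefficients agree in sign; transitive closure of that relation
partitions the hits into groups. A stepwise AIC search over all main
and interaction terms then asks which interactions are mutually
independent, and a nested-model comparison quantifies the variance the
interaction term adds over the two main effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix
from .interaction import ld_r2
from .regression import RankDeficientError, design_with_intercept, ols_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelComparison:
    probe_id: str
    snp_a: str
    snp_b: str
    adj_r2_main: float
    adj_r2_full: float
    lrt_stat: float
    lrt_p: float

    @property
    def interaction_variance_share(self) -> float:
        return self.adj_r2_full - self.adj_r2_main


def _snps_match(
    s1: str, s2: str, genotypes: GenotypeMatrix, r2_min: float, cache: dict
) -> bool:
    if s1 == s2:
        return True
    key = (min(s1, s2), max(s1, s2))
    if key not in cache:
        cache[key] = ld_r2(genotypes.column(s1), genotypes.column(s2))
    return cache[key] >= r2_min


def group_redundant(
    significant_hits: pd.DataFrame,
    genotypes: GenotypeMatrix,
    group_r2_min: float = 0.5,
) -> pd.DataFrame:
    """Partition significant interactions into redundancy groups.

    Two hits on the same probe merge when their SNP pairs can be matched
    (in either orientation) with each matched pair identical or in LD at
    r2 >= ``group_r2_min``, and their interaction signs agree. Returns
    the input with ``group_id`` and ``sign`` columns added; group ids
    are dense integers per probe in stable order.
    """
    if significant_hits.empty:
        raise ValueError("no significant hits to group")
    hits = significant_hits.reset_index(drop=True).copy()
    hits["sign"] = np.where(hits["beta3"] >= 0, "positive", "negative")
    cache: dict = {}
    graph = nx.Graph()
    graph.add_nodes_from(hits.index)
    for pid, sub in hits.groupby("probe_id"):
        idx = list(sub.index)
        for pos, i in enumerate(idx):
            for j in idx[pos + 1:]:
                if hits.at[i, "sign"] != hits.at[j, "sign"]:
                    continue
                a1, b1 = hits.at[i, "snp_a"], hits.at[i, "snp_b"]
                a2, b2 = hits.at[j, "snp_a"], hits.at[j, "snp_b"]
                direct = _snps_match(a1, a2, genotypes, group_r2_min, cache) and \
                    _snps_match(b1, b2, genotypes, group_r2_min, cache)
                crossed = _snps_match(a1, b2, genotypes, group_r2_min, cache) and \
                    _snps_match(b1, a2, genotypes, group_r2_min, cache)
                if direct or crossed:
                    graph.add_edge(i, j)
    group_of = {}
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for gid, comp in enumerate(components):
        for i in comp:
            group_of[i] = gid
    hits["group_id"] = [group_of[i] for i in hits.index]
    return hits


def _aic(rss: float, n: int, k: int) -> float:
    # Gaussian ML up to an additive constant: n ln(RSS/n) + 2k
    return n * np.log(rss / n) + 2 * k


def stepwise_aic(
    expression_ranks: np.ndarray,
    mains: dict[str, np.ndarray],
    interactions: dict[str, tuple[str, str]],
    covariates: np.ndarray | None = None,
    hierarchy: bool = True,
) -> list[str]:
    """Bidirectional stepwise selection by AIC, starting from the full model.

    ``mains`` maps term name -> dosage vector; ``interactions`` maps
    term name -> the two main-term names whose product it is. At each
    step the single add or drop move with the largest AIC decrease is
    taken; the search stops when no move lowers the AIC. With
    ``hierarchy=True`` an interaction may only be present alongside both
    of its main effects. Aliased columns of the full model are dropped
    up-front (first-come order) and logged.
    """
    y = np.asarray(expression_ranks, dtype=float)
    term_vectors: dict[str, np.ndarray] = {k: np.asarray(v, float) for k, v in mains.items()}
    for name, (a, b) in interactions.items():
        term_vectors[name] = term_vectors[a] * term_vectors[b]

    mask = np.isfinite(y)
    for v in term_vectors.values():
        mask &= np.isfinite(v)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        mask &= np.isfinite(covariates).all(axis=1)
    y = y[mask]
    term_vectors = {k: v[mask] for k, v in term_vectors.items()}
    cov = covariates[mask] if covariates is not None else None
    n = y.size

    base_cols = [np.ones(n)]
    if cov is not None:
        base_cols.extend(cov.T)
    base = np.column_stack(base_cols)

    # de-alias the full design: keep terms that increase rank, in order
    order = list(mains) + list(interactions)
    kept: list[str] = []
    current_X = base
    for name in order:
        trial = np.column_stack([current_X, term_vectors[name]])
        if np.linalg.matrix_rank(trial) > np.linalg.matrix_rank(current_X):
            kept.append(name)
            current_X = trial
        else:
            logger.info("dropping aliased term %s from full model", name)
    all_terms = kept

    def fit_aic(terms: list[str]) -> float:
        X = base if not terms else np.column_stack(
            [base] + [term_vectors[t] for t in terms]
        )
        if n <= X.shape[1]:
            return np.inf
        fit = ols_fit(y, X)
        if fit.rss <= 0:
            return -np.inf
        return _aic(fit.rss, n, X.shape[1])

    def legal_drop(term: str, current: set[str]) -> bool:
        if not hierarchy or term not in mains:
            return True
        return not any(
            term in parents and iname in current
            for iname, parents in interactions.items()
        )

    def legal_add(term: str, current: set[str]) -> bool:
        if not hierarchy or term not in interactions:
            return True
        a, b = interactions[term]
        return a in current and b in current

    current = list(all_terms)
    current_aic = fit_aic(current)
    while True:
        best_move, best_aic = None, current_aic
        cur_set = set(current)
        for t in current:
            if legal_drop(t, cur_set):
                cand = [x for x in current if x != t]
                a = fit_aic(cand)
                if a < best_aic - 1e-10:
                    best_move, best_aic = cand, a
        for t in all_terms:
            if t not in cur_set and legal_add(t, cur_set):
                cand = current + [t]
                a = fit_aic(cand)
                if a < best_aic - 1e-10:
                    best_move, best_aic = cand, a
        if best_move is None:
            break
        current, current_aic = best_move, best_aic
    return [t for t in all_terms if t in set(current)]


def compare_models(
    expression_ranks: np.ndarray,
    geno_a: np.ndarray,
    geno_b: np.ndarray,
    covariates: np.ndarray | None = None,
    probe_id: str = "",
    snp_a: str = "",
    snp_b: str = "",
) -> ModelComparison:
    """Main-effects vs interaction model: adjusted R^2 and Gaussian-ML LRT.

    The LRT statistic is ``n ln(RSS_main / RSS_full)`` on 1 df; the
    interaction variance share is the difference of adjusted R^2.
    """
    y = np.asarray(expression_ranks, dtype=float)
    a = np.asarray(geno_a, dtype=float)
    b = np.asarray(geno_b, dtype=float)
    mask = np.isfinite(y) & np.isfinite(a) & np.isfinite(b)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        mask &= np.isfinite(covariates).all(axis=1)
    y, a, b = y[mask], a[mask], b[mask]
    cov = covariates[mask] if covariates is not None else None
    n = y.size

    def design(with_product: bool) -> np.ndarray:
        cols = [a, b] + ([a * b] if with_product else [])
        return (
            design_with_intercept(cov, *cols)
            if cov is not None
            else design_with_intercept(*cols)
        )

    fit_main = ols_fit(y, design(False))
    try:
        fit_full = ols_fit(y, design(True))
    except RankDeficientError:
        # product aliased to the mains: the models coincide
        fit_full = fit_main
    if fit_full.rss <= 0:
        logger.warning("perfect interaction fit: LRT undefined")
        lrt, lrt_p = float("nan"), float("nan")
    else:
        lrt = max(0.0, n * np.log(fit_main.rss / fit_full.rss))
        lrt_p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return ModelComparison(
        probe_id=probe_id, snp_a=snp_a, snp_b=snp_b,
        adj_r2_main=fit_main.adjusted_r2(),
        adj_r2_full=fit_full.adjusted_r2(),
        lrt_stat=lrt, lrt_p=lrt_p,
    )


def distance_distribution_test(
    significant_distances: np.ndarray, tested_distances: np.ndarray
) -> tuple[float, float]:
    """Two-sample KS test of significant-pair vs all-tested-pair distances."""
    sig = np.asarray(significant_distances, dtype=float)
    tested = np.asarray(tested_distances, dtype=float)
    sig = sig[np.isfinite(sig)]
    tested = tested[np.isfinite(tested)]
    if sig.size == 0 or tested.size == 0:
        raise ValueError("both distance sets must be non-empty")
    res = stats.ks_2samp(sig, tested, method="asymp")
    return float(res.statistic), float(res.pvalue)
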