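"""Population stratification: genotype PCA, Tracy-Widom component tests,
and iterative outlier removal.

The decomposition follows the usual eigenanalysis of genotype data:
each SNP column is mean-centred and divided by the binomial standard
deviation sqrt(p(1-p)) implied by its allele frequency, missing entries
are set to zero after centring (the column mean), and the eigenvalues /
eigenvectors of the individual x individual covariance are computed.

Significance of successive components uses the Tracy-Widom law for the
largest eigenvalue of a Wishart matrix: the lead eigenvalue of the
remaining spectrum is normalised with an effective marker number
estimated from the eigenvalue moments and compared with embedded TW1
quantiles. Outlier individuals (|score| beyond ``sd_threshold`` standard
deviations on any leading component) are removed over a fixed number of
refitting iterations, mirroring the defaults of standard eigenanalysis
software (6 SD, 5 iterations, 10 components).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Upper-tail quantiles of the Tracy-Widom (beta=1) distribution.
#: Keys are tail probabilities alpha; values x solve P(TW1 > x) = alpha.
TW1_QUANTILES = {
    0.10: 0.4501,
    0.05: 0.9793,
    0.01: 2.0234,
    0.001: 3.2724,
}


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # descending
    scores: np.ndarray               # individuals x components
    individuals: list[str]
    tw_stats: np.ndarray = field(default_factory=lambda: np.array([]))
    n_significant: int = 0
    outliers: list[str] = field(default_factory=list)


def _standardize(gm: GenotypeMatrix) -> np.ndarray:
    """Centre/scale columns; zero-fill missing; drop degenerate columns."""
    X = gm.values.astype(float).copy()
    cols = []
    for j in range(X.shape[1]):
        col = X[:, j]
        mask = np.isfinite(col)
        if mask.sum() == 0:
            continue
        p_hat = col[mask].mean() / 2.0
        denom = np.sqrt(p_hat * (1.0 - p_hat))
        if denom == 0.0 or np.allclose(col[mask], col[mask][0]):
            logger.warning("dropping zero-variance SNP column %s from PCA",
                           gm.snps[j].snp_id)
            continue
        out = np.zeros_like(col)
        out[mask] = (col[mask] - col[mask].mean()) / denom
        cols.append(out)
    if not cols:
        raise ValueError("no usable SNP columns for PCA")
    return np.column_stack(cols)


def genotype_pca(gm: GenotypeMatrix) -> PcaResult:
    """Eigendecomposition of the standardized-genotype covariance.

    Returns eigenvalues in descending order and PC scores (eigenvectors
    scaled by sqrt(eigenvalue)). The sign of each component is fixed so
    that its largest-magnitude entry is positive.
    """
    if gm.n_individuals < 2 or gm.n_snps < 2:
        raise ValueError("PCA needs at least 2 individuals and 2 SNPs")
    X = _standardize(gm)
    n, m = X.shape
    # eigendecompose the smaller Gram matrix; eigenvalues coincide
    if n <= m:
        C = X @ X.T / m
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        U = V[:, order]
    else:
        S = X.T @ X / m
        w, V = np.linalg.eigh(S)
        order = np.argsort(w)[::-1]
        w = np.clip(w[order], 0.0, None)
        V = V[:, order]
        with np.errstate(divide="ignore", invalid="ignore"):
            U = X @ V / np.sqrt(w * m)
        U[:, w <= 1e-12] = 0.0
        w = w[: min(n, m)]
        U = U[:, : min(n, m)]
    for k in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, k]))
        if U[i, k] < 0:
            U[:, k] = -U[:, k]
    scores = U * np.sqrt(w)
    return PcaResult(eigenvalues=w, scores=scores, individuals=list(gm.individuals))


def tracy_widom_test(
    eigenvalues: np.ndarray,
    n_individuals: int,
    n_snps: int,
    alpha: float = 0.05,
) -> tuple[int, np.ndarray]:
    """Count significant components by sequential Tracy-Widom testing.

    For each step the remaining eigenvalues are used to estimate an
    effective marker number from their first two moments; the lead
    eigenvalue is centred and scaled accordingly and compared with the
    TW1 upper quantile at ``alpha``. Testing stops at the first
    non-significant component. Returns (count, per-component statistics).
    """
    if alpha not in TW1_QUANTILES:
        raise ValueError(
            f"alpha must be one of {sorted(TW1_QUANTILES)} (embedded TW1 table)"
        )
    crit = TW1_QUANTILES[alpha]
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-12]
    stats_out: list[float] = []
    n_sig = 0
    while lam.size >= 2:
        m_eff = lam.size
        s1 = lam.sum()
        s2 = (lam**2).sum()
        denom = m_eff * s2 - s1 * s1
        if denom <= 1e-12:  # all remaining eigenvalues (nearly) equal
            break
        n_hat = (m_eff + 1) * s1 * s1 / denom
        if n_hat <= 1.0:
            break
        ell = m_eff * lam[0] / s1
        mu = (np.sqrt(n_hat - 1) + np.sqrt(m_eff)) ** 2 / n_hat
        sigma = (
            (np.sqrt(n_hat - 1) + np.sqrt(m_eff))
            / n_hat
            * (1.0 / np.sqrt(n_hat - 1) + 1.0 / np.sqrt(m_eff)) ** (1.0 / 3.0)
        )
        tw = (ell - mu) / sigma
        stats_out.append(float(tw))
        if tw > crit:
            n_sig += 1
            lam = lam[1:]
        else:
            break
    return n_sig, np.array(stats_out)


def detect_outliers(
    gm: GenotypeMatrix,
    sd_threshold: float = 6.0,
    n_iterations: int = 5,
    n_components: int = 10,
) -> list[str]:
    """Iteratively flag individuals extreme on any leading component.

    Each iteration refits the PCA on the remaining cohort and removes
    individuals with |score| > sd_threshold x SD on any of the top
    ``n_components`` PCs. Removal order is logged.
    """
    current = gm
    outliers: list[str] = []
    for it in range(n_iterations):
        res = genotype_pca(current)
        k = min(n_components, res.scores.shape[1])
        S = res.scores[:, :k]
        sd = S.std(axis=0, ddof=0)
        sd[sd == 0] = np.inf
        extreme = (np.abs(S) > sd_threshold * sd).any(axis=1)
        if not extreme.any():
            break
        flagged = [res.individuals[i] for i in np.where(extreme)[0]]
        logger.info("PCA outlier iteration %d: removing %s", it + 1, flagged)
        outliers.extend(flagged)
        keep = [ind for ind in current.individuals if ind not in set(flagged)]
        if not keep:
            raise ValueError("outlier removal eliminated every individual")
        current = current.subset_individuals(keep)
    return outliers


def run_pca_stage(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    sd_threshold: float = 6.0,
    n_iterations: int = 5,
    n_components: int = 10,
) -> PcaResult:
    """Outlier removal, final PCA on the clean cohort, and TW testing."""
    outliers = detect_outliers(gm, sd_threshold, n_iterations, n_components)
    clean = (
        gm.subset_individuals([i for i in gm.individuals if i not in set(outliers)])
        if outliers
        else gm
    )
    res = genotype_pca(clean)
    n_sig, tw = tracy_widom_test(res.eigenvalues, clean.n_individuals,
                                 clean.n_snps, alpha)
    res.tw_stats = tw
    res.n_significant = n_sig
    res.outliers = outliers
    return res
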