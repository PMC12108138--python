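"""Genotype PCA with Tracy–Widom selection of significant components.

PCA follows the population-genetics normalization: missing dosages are
mean-imputed, each variant is centred at twice its allele frequency and
divided by sqrt(2 p (1-p)), and the sample-sample covariance of the scaled
matrix is eigen-decomposed (via an economy SVD).

The number of components reflecting real structure is chosen by
sequentially testing the leading eigenvalues against the Tracy–Widom
(beta = 1) law for the largest eigenvalue of a null Wishart matrix, with
an effective marker count estimated from the eigenvalue moments so that
residual LD between markers does not inflate the test.  Testing stops at
the first non-significant eigenvalue.

The TW1 distribution itself is evaluated numerically as the Fredholm
determinant of the kernel Ai((x+y)/2)/2 on (s, infinity) with
Gauss–Legendre quadrature — a few-line spectral method accurate to ~1e-8
— and its quantiles are cached per significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.special import airy

from .containers import GenotypeMatrix, ParameterError


def tw1_cdf(s: float, n_nodes: int = 80, span: float = 14.0) -> float:
    """CDF of the Tracy–Widom distribution with beta = 1."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    t = s + (x + 1.0) * (span / 2.0)
    wt = w * (span / 2.0)
    kern = 0.5 * airy(np.add.outer(t, t) / 2.0)[0]
    sw = np.sqrt(wt)
    m = np.eye(n_nodes) - sw[:, None] * kern * sw[None, :]
    sign, logdet = np.linalg.slogdet(m)
    return float(sign * np.exp(logdet))


@lru_cache(maxsize=64)
def tw1_ppf(q: float) -> float:
    """Quantile function of TW1 (inverse CDF), cached per level."""
    if not (0.0 < q < 1.0):
        raise ParameterError("quantile level must be in (0, 1)")
    return brentq(lambda s: tw1_cdf(s) - q, -12.0, 8.0, xtol=1e-9)


@dataclass
class PCABasis:
    """Eigen-decomposition of the scaled genotype covariance.

    ``eigenvalues`` is the full non-negative spectrum in descending order;
    ``sample_loadings`` holds the orthonormal sample-space eigenvectors
    (samples x k); ``n_selected`` is the Tracy–Widom-selected number of
    significant components at level ``alpha``.
    """

    eigenvalues: np.ndarray
    sample_loadings: np.ndarray
    n_selected: int = 0
    tw_statistics: np.ndarray = field(default_factory=lambda: np.array([]))
    alpha: float = 0.05

    def pcs(self, k: int | None = None) -> np.ndarray:
        """Significant (or first-k) PC coordinates for regression covariates."""
        k = self.n_selected if k is None else k
        return self.sample_loadings[:, :k]


def _patterson_scaled(g: GenotypeMatrix, pruned: list[str] | None) -> np.ndarray:
    x = g.mean_imputed() if pruned is None else g.subset_by_variant_id(pruned).mean_imputed()
    p_hat = x.mean(axis=0) / 2.0
    poly = (p_hat > 0) & (p_hat < 1) & (x.std(axis=0) > 0)
    if not poly.any():
        raise ParameterError("zero-variance input: no polymorphic variants for PCA")
    x = x[:, poly]
    p_hat = p_hat[poly]
    return (x - 2.0 * p_hat) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))


def genotype_pca(
    g: GenotypeMatrix,
    pruned: list[str] | None = None,
    alpha: float = 0.05,
    max_pcs: int = 20,
) -> PCABasis:
    """PCA of the scaled dosage matrix restricted to ``pruned`` variants.

    Monomorphic variants are dropped (they carry no information and break
    the scaling); the full eigenvalue spectrum of the sample covariance is
    retained and the Tracy–Widom selection is applied immediately so the
    basis is ready to use as regression covariates.
    """
    if g.n_samples < 3:
        raise ParameterError("genotype_pca requires >= 3 samples")
    if pruned is not None and len(pruned) == 0:
        raise ParameterError("pruned variant list is empty")
    z = _patterson_scaled(g, pruned)
    n, m = z.shape
    # eigen-decompose the smaller Gram matrix; loadings only for the
    # components that can ever be used as covariates (max_pcs)
    from scipy.linalg import eigh

    if m < n:
        gram = (z.T @ z) / m
        w, v = eigh(gram)
        w, v = w[::-1], v[:, ::-1]
        eig = np.clip(w, 0.0, None)
        k = min(max_pcs + 1, m)
        s = np.sqrt(np.maximum(eig[:k] * m, 1e-300))
        u = (z @ v[:, :k]) / s
    else:
        gram = (z @ z.T) / m
        w, u_full = eigh(gram)
        eig = np.clip(w[::-1], 0.0, None)
        u = u_full[:, ::-1][:, : min(max_pcs + 1, n)]
    basis = PCABasis(eigenvalues=eig, sample_loadings=u, alpha=alpha)
    basis.n_selected, basis.tw_statistics = tracy_widom_select(
        eig, n_samples=n, n_variants=m, alpha=alpha, max_pcs=max_pcs, return_stats=True
    )
    return basis


def tracy_widom_select(
    eigenvalues: np.ndarray,
    n_samples: int,
    n_variants: int,
    alpha: float = 0.05,
    max_pcs: int = 20,
    return_stats: bool = False,
):
    """Count the consecutive leading eigenvalues significant under TW1.

    For each leading eigenvalue the remaining spectrum is renormalized to
    mean 1, an effective marker number is estimated from its first two
    moments, and the centred/scaled top eigenvalue is compared with the
    upper-``alpha`` TW1 quantile.  Testing stops at the first
    non-significant eigenvalue; at most ``max_pcs`` are returned.
    """
    if n_samples < 3:
        raise ParameterError("tracy_widom_select requires n_samples >= 3")
    eig = np.asarray(eigenvalues, dtype=float)
    if np.any(np.diff(eig) > 1e-9):
        raise ParameterError("eigenvalues must be sorted descending")
    eig = eig[eig > max(eig.max(initial=0.0) * 1e-9, 0.0)]
    crit = tw1_ppf(1.0 - alpha)

    n_sig = 0
    stats: list[float] = []
    limit = min(max_pcs, len(eig) - 1)
    for i in range(max(limit, 0)):
        tail = eig[i:]
        m_eff = len(tail)
        if m_eff < 3:
            break
        lam = m_eff * tail / tail.sum()  # renormalize to mean 1
        s2 = float(np.sum(lam**2))
        disp = (m_eff - 1) * s2 - m_eff**2
        if disp <= 0:  # spectrum flatter than any Wishart null: not significant
            stats.append(-np.inf)
            break
        # effective marker count from eigenvalue dispersion, with the exact
        # Wishart-moment correction E[disp] = m'(m'^2 - n' - 3)/n' so the
        # estimator stays unbiased when m'^2 is not >> n'
        n_eff = m_eff * (m_eff**2 - 3.0) / (disp + m_eff)
        if n_eff <= 1:
            stats.append(-np.inf)
            break
        mu = (np.sqrt(n_eff - 1) + np.sqrt(m_eff)) ** 2 / n_eff
        sigma = (
            (np.sqrt(n_eff - 1) + np.sqrt(m_eff))
            / n_eff
            * (1.0 / np.sqrt(n_eff - 1) + 1.0 / np.sqrt(m_eff)) ** (1.0 / 3.0)
        )
        x = (lam[0] - mu) / sigma
        stats.append(float(x))
        if x > crit:
            n_sig += 1
        else:
            break
    stats_arr = np.array(stats)
    if return_stats:
        return n_sig, stats_arr
    return n_sig
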