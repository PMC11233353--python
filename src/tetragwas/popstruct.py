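"""Population structure: tetraploid GRM, PCA, k-means/BIC cluster number, diagnostics.

The genomic relationship matrix is the ploidy-generalized VanRaden form:
with dosages ``x_ij`` (0..4) and alt-allele frequency ``p_j`` estimated as
mean dosage / 4, ``W = X - 4p`` column-centred and

    G = W W' / sum_j 4 p_j (1 - p_j).

Under tetraploid Hardy-Weinberg (dosage ~ Binomial(4, p)) the expected
diagonal is 1, which is the standard diagnostic for a well-behaved panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .genotypes import PLOIDY, DosageMatrix


@dataclass
class GRM:
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, clipped at 0
    scores: np.ndarray             # n x k, eigenvector * sqrt(eigenvalue)
    variance_fractions: np.ndarray
    samples: list[str]


@dataclass
class ClusterResult:
    bic_by_k: dict[int, float]
    chosen_k: int
    assignments: np.ndarray


def compute_grm(dm: DosageMatrix) -> GRM:
    """VanRaden-type GRM from tetraploid dosages (missing -> marker mean)."""
    if dm.n_samples < 2 or dm.n_markers < 1:
        raise ValueError("GRM needs >= 2 samples and >= 1 marker")
    all_missing = np.isnan(dm.values).all(axis=1)
    if all_missing.any():
        warnings.warn(f"excluding {all_missing.sum()} all-missing markers "
                      "from the GRM", stacklevel=2)
        dm = dm.take_markers(np.nonzero(~all_missing)[0])
    X = dm.imputed()
    p = X.mean(axis=1) / PLOIDY
    W = (X - PLOIDY * p[:, None]).T  # n x m
    denom = float(np.sum(PLOIDY * p * (1 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    G = W @ W.T / denom
    G = (G + G.T) / 2
    return GRM(G, list(dm.samples))


def pca(grm: GRM, n_components: int | None = None) -> PCAResult:
    """Eigendecomposition of the GRM; scores are eigenvectors scaled by sqrt(eigenvalue)."""
    n = grm.n
    k = n if n_components is None else int(n_components)
    if k > n:
        raise ValueError(f"n_components={k} exceeds {n} samples")
    evals, evecs = np.linalg.eigh(grm.values)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    if evals.min() < -1e-8 * max(np.trace(grm.values), 1.0):
        warnings.warn("GRM has materially negative eigenvalues; clipping at 0",
                      stacklevel=2)
    evals = np.clip(evals, 0, None)
    total = evals.sum()
    fracs = evals / total if total > 0 else np.zeros_like(evals)
    scores = evecs[:, :k] * np.sqrt(evals[:k])
    return PCAResult(evals[:k], scores, fracs[:k], list(grm.samples))


def scree_inflection(eigenvalues: np.ndarray) -> int:
    """Elbow heuristic: 1 + argmax of the drop in consecutive eigenvalue differences.

    On a panel with Q subpopulations the leading Q-1 eigenvalues separate
    from the bulk, so the largest second difference sits at index Q-1 and
    the heuristic returns Q.
    """
    ev = np.asarray(eigenvalues, float)
    if ev.size < 3:
        return 1
    d = -np.diff(ev)            # d[j] = ev[j] - ev[j+1]
    dd = d[:-1] - d[1:]
    return int(np.argmax(dd)) + 2


def choose_q_kmeans(pca_result: PCAResult, k_max: int = 10,
                    n_pcs: int | None = None,
                    n_starts: int = 50, seed: int = 0) -> ClusterResult:
    """Select the number of subpopulations by k-means + BIC on PC scores.

    BIC(k) = n ln(WSS_k / n) + k ln(n), minimized over k = 1..k_max
    (ties to the smaller k), the form used by adegenet's find.clusters.
    ``n_pcs=None`` (default) clusters on all score columns — retaining
    many PCs is what makes this BIC attain an interior minimum: on a few
    structure-bearing PCs alone the within-cluster sum of squares keeps
    shrinking multiplicatively with k and the criterion is monotone.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = pca_result.scores if n_pcs is None else pca_result.scores[:, :n_pcs]
    n = X.shape[0]
    eps = np.finfo(float).tiny
    bic, fits = {}, {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_starts, init="k-means++",
                    random_state=seed).fit(X)
        wss = max(km.inertia_, eps)
        bic[k] = n * np.log(wss / n) + k * np.log(n)
        fits[k] = km
    chosen = min(bic, key=lambda k: (round(bic[k], 12), k))
    return ClusterResult(bic, chosen, fits[chosen].labels_.copy())


def grm_diagnostics(grm: GRM, bins: int | np.ndarray = 50):
    """Mean diagonal, mean off-diagonal, and histograms of both."""
    G = grm.values
    diag = np.diag(G)
    off = G[~np.eye(grm.n, dtype=bool)]
    diag_hist = np.histogram(diag, bins=bins)
    off_hist = np.histogram(off, bins=bins)
    return float(diag.mean()), float(off.mean()), diag_hist, off_hist
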