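"""Dosage-based mixed-model association engine for autotetraploids.

Eight gene-action encodings map the 0..4 allele dosage onto design
columns (additive, a fully general 4-df model, simplex/duplex dominance of
either allele, and the two diploidized variants). Each encoding is tested
under four statistical models: Naive (no correction), Q (leading GRM
principal components as fixed covariates), K (polygenic random effect with
covariance proportional to the GRM) and QK (both).

The K/QK mixed model y = Xb + g + e with g ~ N(0, s2_g K) is fitted by
REML on the eigenbasis of K (EMMA-style 1-D optimization over the
variance ratio), once per trait (P3D); every marker is then tested by
generalized least squares in the rotated space with an F-test on the
encoding's degrees of freedom. Genome-wide significance uses an LD-aware
Bonferroni threshold: the effective number of tests

    M.eff = sum_chrom [ 1 + sum_{j>=2} sqrt(1 - r*_j^2) ]

where r*_j is the largest absolute correlation between marker j's encoded
design and any preceding marker within a sliding window
(Moskvina-Schmidt-type bound), and the threshold is -log10(alpha / M.eff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import qr as _qr
from scipy.optimize import minimize_scalar

from .genotypes import PLOIDY, DosageMatrix
from .popstruct import GRM, PCAResult

ENCODINGS = ("additive", "general", "1-dom-alt", "1-dom-ref",
             "2-dom-alt", "2-dom-ref", "diplo-general", "diplo-additive")
STAT_MODELS = ("Naive", "K", "Q", "QK")

_CHI2_NULL_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549364


def encode(dosages: np.ndarray, encoding: str,
           max_geno_freq: float = 0.98) -> np.ndarray | None:
    """Map a dosage vector onto design column(s) for one gene-action model.

    Missing dosages must already be imputed. Returns an (n, df) design, or
    ``None`` when the marker is dropped for this encoding because one
    encoded class exceeds ``max_geno_freq`` of samples (near-constant
    design) or a needed class is absent.
    """
    x = np.asarray(dosages, float)
    if np.nanmin(x) < 0 or np.nanmax(x) > PLOIDY:
        raise ValueError("dosages outside 0..4")
    cls = np.clip(np.rint(x), 0, PLOIDY).astype(int)
    if encoding == "additive":
        design = x[:, None]
        labels = cls
    elif encoding == "general":
        design = np.stack([(cls == k).astype(float) for k in range(1, 5)], axis=1)
        labels = cls
    elif encoding == "1-dom-alt":
        design = (x >= 1)[:, None].astype(float)
        labels = design[:, 0]
    elif encoding == "1-dom-ref":
        design = (x <= 3)[:, None].astype(float)
        labels = design[:, 0]
    elif encoding == "2-dom-alt":
        design = (x >= 2)[:, None].astype(float)
        labels = design[:, 0]
    elif encoding == "2-dom-ref":
        design = (x <= 2)[:, None].astype(float)
        labels = design[:, 0]
    elif encoding == "diplo-general":
        mid = ((cls >= 1) & (cls <= 3)).astype(float)
        design = np.stack([mid, (cls == 4).astype(float)], axis=1)
        labels = np.where(cls == 0, 0, np.where(cls == 4, 2, 1))
    elif encoding == "diplo-additive":
        mapped = np.where(cls == 0, 0.0, np.where(cls == 4, 2.0, 1.0))
        design = mapped[:, None]
        labels = mapped
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    _, counts = np.unique(labels, return_counts=True)
    if counts.max() / len(labels) > max_geno_freq or counts.size < 2:
        return None
    # drop indicator columns for absent classes (keeps the design full rank)
    if design.shape[1] > 1:
        design = design[:, design.any(axis=0)]
        if design.shape[1] == 0:
            return None
    return design


@dataclass(frozen=True)
class StatModelSpec:
    """One statistical model: which confounders are corrected."""

    name: str
    n_pcs: int = 3

    def __post_init__(self) -> None:
        if self.name not in STAT_MODELS:
            raise ValueError(f"unknown statistical model {self.name!r}")
        if self.name in ("Q", "QK") and self.n_pcs < 1:
            raise ValueError("Q/QK models need n_pcs >= 1")

    @property
    def uses_kinship(self) -> bool:
        return self.name in ("K", "QK")

    @property
    def uses_pcs(self) -> bool:
        return self.name in ("Q", "QK")


@dataclass
class NullModelFit:
    """P3D null fit: variance components plus the spectral rotation for fast GLS."""

    spec: StatModelSpec
    sigma2_g: float
    sigma2_e: float
    rot_y: np.ndarray        # whitened rotated phenotype
    rot_X: np.ndarray        # whitened rotated covariates (incl. intercept)
    rotate: np.ndarray       # n x n matrix: W^{-1/2} U' (identity weights if no kinship)
    sample_index: np.ndarray  # indices (into the panel) of the samples kept
    reml_loglik: float

    @property
    def h2(self) -> float:
        tot = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / tot if tot > 0 else 0.0

    @property
    def _xtx_pinv(self) -> np.ndarray:
        if not hasattr(self, "_xtx_pinv_cache"):
            self._xtx_pinv_cache = np.linalg.pinv(self.rot_X.T @ self.rot_X)
        return self._xtx_pinv_cache

    @property
    def _resid_y(self) -> np.ndarray:
        if not hasattr(self, "_resid_y_cache"):
            X, y = self.rot_X, self.rot_y
            self._resid_y_cache = y - X @ (self._xtx_pinv @ (X.T @ y))
        return self._resid_y_cache


def _reml_neg_loglik(log_lam: float, s: np.ndarray, yr: np.ndarray,
                     Xr: np.ndarray) -> float:
    lam = np.exp(log_lam)
    w = lam * s + 1.0
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return np.inf
    resid = yr - Xr @ beta
    n, p = Xr.shape
    rss = float(resid @ (resid / w))
    if rss <= 0:
        return np.inf
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    s2 = rss / (n - p)
    return 0.5 * ((n - p) * np.log(s2) + np.sum(np.log(w)) + logdet_xwx
                  + (n - p))


def fit_null(y: np.ndarray, spec: StatModelSpec, grm: GRM | None = None,
             pcs: np.ndarray | None = None) -> NullModelFit:
    """Fit the per-trait null model (no marker) for P3D scanning.

    ``y`` may contain NaN (those samples are dropped). For K/QK, REML over
    the variance ratio lambda = s2_g / s2_e is done on the eigenbasis of
    the GRM; Naive/Q fix s2_g = 0.
    """
    y = np.asarray(y, float)
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 non-missing phenotypes")
    idx = np.nonzero(keep)[0]
    yk = y[idx]
    if np.var(yk) == 0:
        raise ValueError("zero-variance trait")
    X = [np.ones((idx.size, 1))]
    if spec.uses_pcs:
        if pcs is None:
            raise ValueError(f"{spec.name} model needs PC scores")
        X.append(np.asarray(pcs)[idx, :spec.n_pcs])
    X = np.hstack(X)
    # drop collinear/degenerate covariate columns (keep the intercept)
    _, R, piv = _qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > 1e-10 * max(diag[0], 1e-30)).sum())
    if rank < X.shape[1]:
        X = X[:, np.sort(piv[:rank])]
    n, p = X.shape

    if not spec.uses_kinship:
        resid = yk - X @ np.linalg.lstsq(X, yk, rcond=None)[0]
        s2e = float(resid @ resid) / (n - p)
        rotate = np.eye(n)
        return NullModelFit(spec, 0.0, s2e, yk.copy(), X.copy(), rotate, idx,
                            reml_loglik=np.nan)

    if grm is None:
        raise ValueError(f"{spec.name} model needs a GRM")
    K = grm.values[np.ix_(idx, idx)]
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-8 * max(np.trace(K), 1.0):
        warnings.warn("GRM not PSD on the phenotyped subset; clipping "
                      "eigenvalues at 0", stacklevel=2)
    s = np.clip(s, 0, None)
    yr, Xr = U.T @ yk, U.T @ X

    grid = np.linspace(-10, 10, 41)
    vals = [_reml_neg_loglik(g, s, yr, Xr) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(_reml_neg_loglik, args=(s, yr, Xr),
                          bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
                          options={"xatol": 1e-8})
    lam = float(np.exp(res.x))
    w = lam * s + 1.0
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    resid = yr - Xr @ beta
    s2e = float(resid @ (resid / w)) / (n - p)
    s2g = lam * s2e
    if lam <= np.exp(-9.5):  # boundary: effectively no polygenic variance
        s2g = 0.0
    sqw = 1.0 / np.sqrt(w)
    rotate = sqw[:, None] * U.T
    return NullModelFit(spec, s2g, s2e, sqw * yr, sqw[:, None] * Xr, rotate,
                        idx, reml_loglik=float(-res.fun))


@dataclass
class MarkerTest:
    score: float
    effect: float | None
    df: int
    flagged: bool = False


def _gls_marker_test(null: NullModelFit, design: np.ndarray) -> MarkerTest:
    """F-test of the (rotated, whitened) marker design added to the null model."""
    Z = null.rotate @ design
    X = null.rot_X
    n, p = X.shape
    # residualize on covariates
    Zr = Z - X @ (null._xtx_pinv @ (X.T @ Z))
    yr = null._resid_y
    q, r = np.linalg.qr(Zr)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-8 * max(np.abs(np.diag(r)).max(), 1e-30)))
    if rank == 0:
        return MarkerTest(0.0, None, 0, flagged=True)
    rss0 = float(yr @ yr)
    coef, *_ = np.linalg.lstsq(Zr, yr, rcond=None)
    fit = Zr @ coef
    rss1 = rss0 - float(fit @ yr)
    df2 = n - p - rank
    if df2 <= 0 or rss1 <= 0:
        return MarkerTest(0.0, None, rank, flagged=True)
    F = ((rss0 - rss1) / rank) / (rss1 / df2)
    pval = float(stats.f.sf(F, rank, df2))
    effect = float(coef[0]) if design.shape[1] == 1 else None
    return MarkerTest(-np.log10(max(pval, np.finfo(float).tiny)), effect, rank)


def lambda_gc(pvalues: np.ndarray) -> float:
    """Genomic-control inflation factor from p-values via the 1-df chi-square quantile."""
    p = np.asarray(pvalues, float)
    if p.size < 100:
        raise ValueError("need >= 100 p-values for a stable lambda_GC")
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_NULL_MEDIAN)


def meff(designs: list[np.ndarray | None], chroms: np.ndarray,
         window: int = 100) -> float:
    """LD-adjusted effective number of tests over encoded marker designs.

    ``designs`` are per-marker (n, df) arrays in position order (``None``
    for markers dropped by the encoding); ``chroms`` aligns chromosomes.
    Per chromosome, M.eff = 1 + sum_{j>=2} sqrt(1 - r*_j^2) with r*_j the
    max |correlation| between any column of marker j and any column of the
    preceding ``window`` retained markers. Genome M.eff is the sum.
    """
    total = 0.0
    for chrom in pd.unique(chroms):
        std_cols: list[np.ndarray] = []
        meff_c = 0.0
        for j in np.nonzero(chroms == chrom)[0]:
            D = designs[j]
            if D is None:
                continue
            C = D - D.mean(axis=0)
            norms = np.linalg.norm(C, axis=0)
            good = norms > 1e-12
            C = C[:, good] / norms[good]
            if C.shape[1] == 0:
                continue
            if not std_cols:
                meff_c = 1.0
            else:
                prev = np.hstack(std_cols[-window:])
                r_star = min(float(np.abs(prev.T @ C).max()), 1.0)
                meff_c += np.sqrt(1.0 - r_star ** 2)
            std_cols.append(C)
        total += meff_c
    return total


def meff_threshold(designs: list[np.ndarray | None], chroms: np.ndarray,
                   alpha: float = 0.05, window: int = 100) -> float:
    """-log10 genome-wide significance threshold, alpha over M.eff."""
    m_eff = meff(designs, chroms, window=window)
    if m_eff < 1:
        m_eff = 1.0
    return float(-np.log10(alpha / m_eff))


class GwasModel:
    """Multi-trait, multi-encoding association model over a dosage panel.

    Parameters
    ----------
    dosages
        QC-filtered :class:`DosageMatrix`.
    phenotypes
        DataFrame of genotype-level trait values (one column per trait)
        indexed by sample id, e.g. across-environment BLUEs.
    grm
        Genomic relationship matrix (required for K/QK).
    pca_result
        PCA of the GRM (required for Q/QK); the leading ``n_pcs`` score
        columns form the Q matrix.
    """

    def __init__(self, dosages: DosageMatrix, phenotypes: pd.DataFrame,
                 grm: GRM | None = None, pca_result: PCAResult | None = None,
                 encodings=ENCODINGS, models=("K", "QK"), n_pcs: int = 3,
                 alpha: float = 0.05, meff_window: int = 100,
                 max_geno_freq: float = 0.98):
        missing = [s for s in dosages.samples if s not in phenotypes.index]
        if missing:
            raise ValueError(f"{len(missing)} panel samples absent from the "
                             "phenotype table")
        self.dosages = dosages
        self.phenotypes = phenotypes.loc[dosages.samples]
        self.grm = grm
        self.pcs = None if pca_result is None else pca_result.scores
        self.encodings = tuple(encodings)
        self.specs = tuple(StatModelSpec(m, n_pcs=n_pcs) for m in models)
        self.alpha = alpha
        self.meff_window = meff_window
        self.max_geno_freq = max_geno_freq

    def fit(self) -> "GwasResults":
        imputed = self.dosages.imputed()
        markers = self.dosages.markers
        chroms = markers["chrom"].to_numpy()

        designs = {enc: [encode(imputed[j], enc, self.max_geno_freq)
                         for j in range(len(markers))]
                   for enc in self.encodings}
        thresholds = {enc: meff_threshold(designs[enc], chroms,
                                          alpha=self.alpha,
                                          window=self.meff_window)
                      for enc in self.encodings}

        rows, lam_rows = [], []
        for trait in self.phenotypes.columns:
            y = self.phenotypes[trait].to_numpy(float)
            for spec in self.specs:
                null = fit_null(y, spec, grm=self.grm, pcs=self.pcs)
                for enc in self.encodings:
                    pvals = []
                    for j in range(len(markers)):
                        D = designs[enc][j]
                        if D is None:
                            continue
                        t = _gls_marker_test(null, D[null.sample_index])
                        pvals.append(10 ** (-t.score))
                        rows.append((trait, markers.at[j, "id"], chroms[j],
                                     int(markers.at[j, "pos"]), enc,
                                     spec.name, t.score, t.effect,
                                     thresholds[enc], t.flagged))
                    if len(pvals) >= 100:
                        lam_rows.append((trait, enc, spec.name,
                                         lambda_gc(np.array(pvals))))
        table = pd.DataFrame(rows, columns=["trait", "marker", "chrom", "pos",
                                            "encoding", "model", "score",
                                            "effect", "threshold", "flagged"])
        lam = pd.DataFrame(lam_rows, columns=["trait", "encoding", "model",
                                              "lambda_gc"])
        return GwasResults(self, table, thresholds, lam)


class GwasResults:
    """Long-format association results with thresholds and inflation diagnostics."""

    def __init__(self, model: GwasModel, table: pd.DataFrame,
                 thresholds: dict[str, float], lambda_table: pd.DataFrame):
        self.model = model
        self.table = table
        self.thresholds = thresholds
        self.lambda_table = lambda_table

    def scores(self, trait: str, encoding: str, model: str) -> pd.DataFrame:
        t = self.table
        return t[(t.trait == trait) & (t.encoding == encoding)
                 & (t.model == model)].reset_index(drop=True)

    def summary(self) -> str:
        lines = ["Dosage GWAS results",
                 f"  markers: {self.model.dosages.n_markers}, samples: "
                 f"{self.model.dosages.n_samples}",
                 f"  traits: {list(self.model.phenotypes.columns)}",
                 f"  models: {[s.name for s in self.model.specs]}",
                 "  -log10 thresholds by encoding "
                 f"(alpha={self.model.alpha}, M.eff):"]
        for enc, thr in self.thresholds.items():
            lines.append(f"    {enc:>15}: {thr:.2f}")
        if not self.lambda_table.empty:
            lines.append("  lambda_GC by (trait, encoding, model):")
            for _, r in self.lambda_table.iterrows():
                lines.append(f"    {r.trait:>10} {r.encoding:>15} "
                             f"{r.model:>5}: {r.lambda_gc:.3f}")
        return "\n".join(lines)

    def manhattan(self, trait: str, encoding: str, model: str, ax=None):
        """Manhattan plot of -log10 p along the genome for one scan."""
        import matplotlib.pyplot as plt

        df = self.scores(trait, encoding, model)
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        offset, ticks = 0.0, {}
        for chrom, grp in df.groupby("chrom", sort=True):
            ax.scatter(grp["pos"] + offset, grp["score"], s=6)
            ticks[chrom] = offset + grp["pos"].median()
            offset += grp["pos"].max() + 1e6
        ax.axhline(self.thresholds[encoding], ls="--", c="k", lw=0.8)
        ax.set_xticks(list(ticks.values()), list(ticks.keys()), rotation=45)
        ax.set_ylabel(r"$-\log_{10}(p)$")
        ax.set_title(f"{trait} | {encoding} | {model}")
        return ax
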