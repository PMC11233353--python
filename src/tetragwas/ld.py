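"""Dosage-based linkage disequilibrium and whole-chromosome decay estimation.

LD between two markers is the squared Pearson correlation of their dosage
vectors (0..4) over pairwise-complete samples. The chromosome-scale decay
of the upper envelope is summarized by fitting the hyperbolic curve

    r2(d) = a / (1 + b d)

to the 90th percentile of r2 versus distance by minimizing the pinball
(quantile) loss. Two decay estimators follow in closed form:
``LD_1/2max,90 = 1/b`` (distance where the curve halves its fitted maximum
``a``) and ``LD_1/10,90 = (a/0.1 - 1)/b`` (distance where it reaches 0.1,
defined only when a > 0.1). An exponential form ``a exp(-b d)`` is
available behind the ``form`` switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .genotypes import DosageMatrix

MIN_COMPLETE_SAMPLES = 10


@dataclass
class LDPairs:
    """Pairwise (distance, r2) records for one chromosome."""

    chrom: str
    distance_bp: np.ndarray
    r2: np.ndarray
    n_skipped: int = 0          # pairs with too few complete samples
    subsample_seed: int | None = None
    max_pairs: int | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom,
                             "distance_bp": self.distance_bp, "r2": self.r2})


@dataclass
class LDDecayFit:
    """Fitted decay curve and the derived distance estimators (Mb)."""

    chrom: str
    tau: float
    r2max90: float
    b_per_bp: float
    converged: bool
    n_pairs: int
    loss: float
    form: str = "hyperbolic"

    @property
    def ld_half_mb(self) -> float:
        if self.form == "hyperbolic":
            return 1.0 / self.b_per_bp / 1e6
        return np.log(2.0) / self.b_per_bp / 1e6

    @property
    def ld_tenth_mb(self) -> float | None:
        """Distance (Mb) where the fitted curve reaches r2 = 0.1; None if never above it."""
        if self.r2max90 <= 0.1:
            return None
        if self.form == "hyperbolic":
            return (self.r2max90 / 0.1 - 1.0) / self.b_per_bp / 1e6
        return np.log(self.r2max90 / 0.1) / self.b_per_bp / 1e6

    def predict(self, d_bp: np.ndarray) -> np.ndarray:
        return _curve(np.asarray(d_bp, float), self.r2max90, self.b_per_bp,
                      self.form)


def _pairwise_complete_r2(X: np.ndarray) -> np.ndarray:
    """All-pairs squared Pearson correlation over pairwise-complete samples.

    Returns (r2 matrix, complete-count matrix).
    """
    M = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    n = M @ M.T
    sx = X0 @ M.T
    sxx = (X0 ** 2) @ M.T
    sxy = X0 @ X0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        vx = sxx - sx ** 2 / n
        r2 = cov ** 2 / (vx * vx.T)
    return r2, n


def pairwise_r2(dm: DosageMatrix, chrom: str, max_pairs: int = 500_000,
                seed: int = 0) -> LDPairs:
    """Within-chromosome dosage r2 for all (or a seeded subsample of) marker pairs."""
    on = np.nonzero((dm.markers["chrom"] == chrom).to_numpy())[0]
    if on.size < 2:
        raise ValueError(f"need >= 2 markers on {chrom}")
    sub = dm.take_markers(on)
    pos = sub.markers["pos"].to_numpy()
    m = sub.n_markers
    iu, ju = np.triu_indices(m, k=1)
    n_all = iu.size
    if n_all > max_pairs:
        rng = np.random.default_rng(seed)
        pick = rng.choice(n_all, size=max_pairs, replace=False)
        iu, ju = iu[pick], ju[pick]
    r2_mat, n_mat = _pairwise_complete_r2(sub.values)
    r2 = r2_mat[iu, ju]
    n_complete = n_mat[iu, ju]
    ok = (n_complete >= MIN_COMPLETE_SAMPLES) & np.isfinite(r2)
    dist = (pos[ju] - pos[iu]).astype(float)
    return LDPairs(chrom, dist[ok], np.clip(r2[ok], 0, 1),
                   n_skipped=int((~ok).sum()),
                   subsample_seed=seed if n_all > max_pairs else None,
                   max_pairs=max_pairs)


def _curve(d, a, b, form):
    if form == "hyperbolic":
        return a / (1.0 + b * d)
    return a * np.exp(-b * d)


def _pinball(resid, tau):
    return np.where(resid >= 0, tau * resid, (tau - 1) * resid).mean()


class LDDecayModel:
    """Nonlinear quantile regression of r2 on distance (statsmodels-style).

    ``fit()`` minimizes the pinball loss at quantile ``tau`` over the
    curve parameters (a, b) via a coarse grid in (a, log b) followed by
    Nelder-Mead refinement from the best grid points.
    """

    def __init__(self, pairs: LDPairs, tau: float = 0.90,
                 form: str = "hyperbolic"):
        if pairs.r2.size < 100:
            raise ValueError("need >= 100 pairs to fit a decay curve")
        if form not in ("hyperbolic", "exponential"):
            raise ValueError(f"unknown form {form!r}")
        self.pairs = pairs
        self.tau = tau
        self.form = form

    def _loss(self, a: float, b: float) -> float:
        pred = _curve(self.pairs.distance_bp, a, b, self.form)
        return _pinball(self.pairs.r2 - pred, self.tau)

    def fit(self, n_starts: int = 5) -> LDDecayFit:
        d = self.pairs.distance_bp
        a_grid = np.linspace(0.05, 1.0, 20)
        logb_grid = np.linspace(np.log10(1.0 / (10 * d.max())),
                                np.log10(10.0 / max(d.min(), 1.0)), 40)
        losses = np.array([[self._loss(a, 10.0 ** lb) for lb in logb_grid]
                           for a in a_grid])
        flat = np.argsort(losses, axis=None)[:n_starts]
        best, best_loss, success = None, np.inf, False
        for f in flat:
            ai, bi = np.unravel_index(f, losses.shape)
            res = minimize(
                lambda th: self._loss(th[0], 10.0 ** th[1]),
                x0=[a_grid[ai], logb_grid[bi]],
                method="Nelder-Mead",
                bounds=[(1e-4, 1.0), (logb_grid[0] - 2, logb_grid[-1] + 2)],
                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
            if res.fun < best_loss:
                best, best_loss, success = res.x, res.fun, bool(res.success)
        a_hat, b_hat = float(best[0]), float(10.0 ** best[1])
        if not success:
            warnings.warn("LD decay fit did not converge cleanly", stacklevel=2)
        return LDDecayFit(self.pairs.chrom, self.tau, a_hat, b_hat,
                          converged=success, n_pairs=d.size,
                          loss=float(best_loss), form=self.form)


def fit_decay(pairs: LDPairs, tau: float = 0.90,
              form: str = "hyperbolic") -> LDDecayFit:
    """Convenience wrapper: fit the decay curve for one chromosome."""
    return LDDecayModel(pairs, tau=tau, form=form).fit()


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals, as printed tables do.

    Plain float rounding turns an exact x.xx5 (stored just below it) down;
    table summaries are compared at printed precision, so exact halves
    must round up.
    """
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(round(x, ndigits + 6))).quantize(q, ROUND_HALF_UP))


def fits_to_table(fits: dict[str, LDDecayFit]) -> pd.DataFrame:
    rows = [(c, f.r2max90, f.ld_half_mb, f.ld_tenth_mb)
            for c, f in fits.items()]
    return pd.DataFrame(rows, columns=["chrom", "r2max90", "ld_half_mb",
                                       "ld_tenth_mb"])


def decay_summary(table: pd.DataFrame | dict,
                  other: pd.DataFrame | dict | None = None) -> dict:
    """Per-chromosome decay table with genome averages and optional panel ratios.

    ``table`` is either a dict of :class:`LDDecayFit` or a frame with
    columns (chrom, r2max90, ld_half_mb, ld_tenth_mb). Averages are
    unweighted means across chromosomes rounded to 2 dp; chromosomes with
    undefined LD_1/10 are excluded from that mean (noted). With a second
    panel, per-chromosome larger/smaller fold ratios are reported (1 dp).
    """
    tab = fits_to_table(table) if isinstance(table, dict) else table.copy()
    if tab.empty:
        raise ValueError("no decay fits supplied")
    means = {c: round_half_up(float(tab[c].dropna().mean()), 2)
             for c in ("r2max90", "ld_half_mb", "ld_tenth_mb")}
    notes = []
    n_undef = tab["ld_tenth_mb"].isna().sum()
    if n_undef:
        notes.append(f"{n_undef} chromosome(s) excluded from the LD_1/10 "
                     "mean (fitted maximum <= 0.1)")
    out = {"table": tab, "means": means, "notes": notes}
    if other is not None:
        otab = fits_to_table(other) if isinstance(other, dict) else other
        merged = tab.merge(otab, on="chrom", suffixes=("_a", "_b"))
        for c in ("r2max90", "ld_half_mb", "ld_tenth_mb"):
            hi = merged[[f"{c}_a", f"{c}_b"]].max(axis=1)
            lo = merged[[f"{c}_a", f"{c}_b"]].min(axis=1)
            merged[f"{c}_ratio"] = (hi / lo).map(lambda v: round_half_up(v, 1))
        out["ratios"] = merged[["chrom"] +
                               [f"{c}_ratio" for c in
                                ("r2max90", "ld_half_mb", "ld_tenth_mb")]]
    return out
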