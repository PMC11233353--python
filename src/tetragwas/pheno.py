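"""Trait-data preparation: disease severity scores, genotype BLUEs,
Bonferroni-adjusted trait correlations and plot-basis heritability.

Disease incidence recorded as tuber counts per percent-surface-affected
category is converted to a plot severity score: the count-weighted mean of
the category midpoints. Genotype means per environment come from a
two-way fixed-effect fit (genotype + replicate); broad-sense heritability
on a plot basis is the genotypic variance fraction from a per-environment
one-way random-effects ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SeverityScheme:
    """Ordered, contiguous percent-surface categories with midpoints."""

    name: str
    bounds: tuple[tuple[float, float], ...]   # (low, high], first inclusive of 0
    midpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.bounds) != len(self.midpoints):
            raise ValueError("bounds/midpoints length mismatch")
        if list(self.midpoints) != sorted(self.midpoints):
            raise ValueError("midpoints must be strictly increasing")
        if self.bounds[0][0] != 0 or self.bounds[-1][1] != 100:
            raise ValueError("categories must cover 0-100")
        for (a, b), (c, _) in zip(self.bounds[:-1], self.bounds[1:]):
            if b != c:
                raise ValueError("categories must be contiguous")


# 7-category scheme for black scurf / common scab; 6-category for black dot.
# Midpoints are the arithmetic midpoints of the printed ranges.
SEVERITY_7 = SeverityScheme(
    "7-category",
    ((0, 1), (1, 5), (5, 10), (10, 25), (25, 50), (50, 75), (75, 100)),
    (0.5, 3.0, 7.5, 17.5, 37.5, 62.5, 87.5))
SEVERITY_6 = SeverityScheme(
    "6-category",
    ((0, 1), (1, 10), (10, 25), (25, 50), (50, 75), (75, 100)),
    (0.5, 5.5, 17.5, 37.5, 62.5, 87.5))


def severity_score(counts, scheme: SeverityScheme = SEVERITY_7) -> float:
    """Count-weighted mean of category midpoints: sum(n_c * mid_c) / sum(n_c)."""
    counts = np.asarray(counts, float)
    if counts.size != len(scheme.midpoints):
        raise ValueError(f"expected {len(scheme.midpoints)} category counts")
    if (counts < 0).any():
        raise ValueError("negative category counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("no tubers assessed")
    return float(counts @ np.asarray(scheme.midpoints) / total)


def blues(plots: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Per-environment genotype means from a genotype + replicate fixed-effect
    fit, plus the unweighted across-environment mean.

    Each environment is fitted separately by least squares; the genotype
    value is the fitted mean averaged over replicate levels, which equals
    the arithmetic genotype mean for balanced data with no block effect.
    Genotypes absent from an environment are missing there and excluded
    from the across-environment mean.
    """
    out = {}
    for env, grp in plots.groupby("environment", sort=True):
        grp = grp.dropna(subset=[trait])
        genos = pd.Categorical(grp["genotype"])
        reps = pd.Categorical(grp["replicate"])
        G = pd.get_dummies(genos, dtype=float).to_numpy()
        R = pd.get_dummies(reps, drop_first=True, dtype=float).to_numpy()
        X = np.hstack([G, R]) if R.shape[1] else G
        beta, *_ = np.linalg.lstsq(X, grp[trait].to_numpy(float), rcond=None)
        g_eff = beta[:G.shape[1]]
        rep_mean = beta[G.shape[1]:].sum() / len(reps.categories) \
            if R.shape[1] else 0.0
        out[env] = pd.Series(g_eff + rep_mean, index=genos.categories)
    table = pd.DataFrame(out)
    table["mean"] = table[list(out)].mean(axis=1, skipna=True)
    n_missing = int(table[list(out)].isna().sum().sum())
    if n_missing:
        warnings.warn(f"{n_missing} genotype x environment cells missing; "
                      "across-environment means use available environments",
                      stacklevel=2)
    table.index.name = "genotype"
    return table


def heritability(plots: pd.DataFrame, trait: str) -> tuple[pd.Series, float]:
    """Plot-basis broad-sense H2 per environment and its average.

    One-way random-effects ANOVA per environment: with genotype mean
    square MS_g, error mean square MS_e and (effective) replicate number
    r, sigma2_g = max(0, (MS_g - MS_e) / r) and
    H2 = sigma2_g / (sigma2_g + sigma2_e). Environments with a single
    replicate are undefined (NaN).
    """
    per_env = {}
    for env, grp in plots.groupby("environment", sort=True):
        grp = grp.dropna(subset=[trait])
        sizes = grp.groupby("genotype")[trait].count()
        sizes = sizes[sizes > 0]
        g = len(sizes)
        N = int(sizes.sum())
        if g < 2 or N <= g or sizes.max() < 2:
            per_env[env] = np.nan
            continue
        means = grp.groupby("genotype")[trait].mean()
        grand = grp[trait].mean()
        ss_between = float((sizes * (means - grand) ** 2).sum())
        ss_within = float(((grp[trait] - grp["genotype"].map(means)) ** 2).sum())
        ms_g = ss_between / (g - 1)
        ms_e = ss_within / (N - g)
        # effective replicate number for unbalanced one-way layouts
        r0 = (N - float((sizes ** 2).sum()) / N) / (g - 1)
        s2_g = max(0.0, (ms_g - ms_e) / r0)
        per_env[env] = s2_g / (s2_g + ms_e) if s2_g + ms_e > 0 else np.nan
    series = pd.Series(per_env, name=trait)
    return series, float(series.mean(skipna=True))


def trait_correlations(blue_table: pd.DataFrame) -> dict:
    """Pairwise-complete Pearson correlations with Bonferroni-adjusted p-values.

    Returns dict with ``r``, ``p``, ``p_adj`` (raw p times the number of
    tested pairs, capped at 1) and ``significant`` (p_adj < 0.05)
    DataFrames. Constant traits or pairs with < 3 complete observations
    are undefined (NaN) and not counted as tested pairs.
    """
    traits = list(blue_table.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.where(np.eye(k), 0.0, np.nan),
                     index=traits, columns=traits)
    tested = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = blue_table[[traits[i], traits[j]]].dropna()
            if len(sub) < 3 or sub.iloc[:, 0].nunique() < 2 \
                    or sub.iloc[:, 1].nunique() < 2:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(sub.iloc[:, 0], sub.iloc[:, 1])
            r.iloc[i, j] = r.iloc[j, i] = rr
            p.iloc[i, j] = p.iloc[j, i] = pp
            tested.append((i, j))
    n_pairs = len(tested)
    p_adj = (p * n_pairs).clip(upper=1.0)
    np.fill_diagonal(p_adj.values, 0.0)
    return {"r": r, "p": p, "p_adj": p_adj,
            "significant": p_adj < 0.05, "n_pairs_tested": n_pairs}
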