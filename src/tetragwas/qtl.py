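"""Post-GWAS filtering: significant MTAs, LD-window thinning, deduplication, hotspots.

A marker-trait association (MTA) is significant when its score exceeds the
encoding-specific M.eff threshold in the K or QK model. Within each
(trait, encoding, chromosome) the most significant marker per LD-derived
window is retained (greedy peak removal, the standard clumping semantics);
records for the same SNP under several gene-action models are then
collapsed to the single most significant one. Multi-trait hotspots are
single-linkage chains of retained associations within a maximum gap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MTA_COLUMNS = ["trait", "marker", "chrom", "pos", "encoding",
               "score_K", "effect_K", "score_QK", "effect_QK", "threshold"]

DEFAULT_WINDOW_BP = 1_520_000   # average LD_1/10,90 of the panel
DEFAULT_HOTSPOT_GAP_BP = 2_000_000


def significant_mtas(table: pd.DataFrame, models=("K", "QK")) -> pd.DataFrame:
    """Extract MTAs whose score exceeds the threshold in any requested model.

    ``table`` is the long-format :class:`~tetragwas.gwas.GwasResults`
    table. Returns one row per (trait, marker, encoding) carrying both
    models' scores/effects and the encoding threshold.
    """
    sub = table[table["model"].isin(models)]
    wide = sub.pivot_table(index=["trait", "marker", "chrom", "pos",
                                  "encoding", "threshold"],
                           columns="model", values=["score", "effect"],
                           aggfunc="first")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide = wide.reset_index()
    for m in models:
        for base in ("score", "effect"):
            col = f"{base}_{m}"
            if col not in wide:
                wide[col] = np.nan
    score_cols = [f"score_{m}" for m in models]
    best = wide[score_cols].max(axis=1, skipna=True)
    out = wide[best > wide["threshold"]]
    out = out.assign(best_score=best[out.index])
    return out.reset_index(drop=True)[MTA_COLUMNS + ["best_score"]]


def window_filter(mtas: pd.DataFrame,
                  window_bp: int = DEFAULT_WINDOW_BP) -> pd.DataFrame:
    """Greedy best-first thinning: keep the top-scoring MTA, drop neighbours
    within ``window_bp`` on the same chromosome, repeat (per trait x encoding).

    Score ties break toward the smaller position. Output rows gain a
    ``window_id`` and satisfy the spacing invariant exactly.
    """
    if mtas.empty:
        return mtas.assign(window_id=pd.Series(dtype=int))
    out = []
    for (trait, enc, chrom), grp in mtas.groupby(["trait", "encoding", "chrom"],
                                                 sort=True):
        grp = grp.sort_values(["best_score", "pos"],
                              ascending=[False, True], kind="mergesort")
        kept_pos: list[int] = []
        for _, row in grp.iterrows():
            if all(abs(row["pos"] - p) > window_bp for p in kept_pos):
                out.append(row.to_frame().T.assign(window_id=len(kept_pos)))
                kept_pos.append(row["pos"])
    res = pd.concat(out, ignore_index=True)
    res = res.astype({"pos": int, "window_id": int})
    _assert_spacing(res, window_bp)
    return res.sort_values(["trait", "encoding", "chrom", "pos"]
                           ).reset_index(drop=True)


def _assert_spacing(df: pd.DataFrame, window_bp: int) -> None:
    for _, grp in df.groupby(["trait", "encoding", "chrom"]):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size > 1 and np.diff(pos).min() <= window_bp:
            raise AssertionError("window_filter spacing invariant violated")


def dedup_encodings(qtl_mtas: pd.DataFrame) -> pd.DataFrame:
    """Per (trait, marker) keep the record with the highest best score.

    Ties break by lexicographically smallest encoding name. Records for
    the same SNP under different traits are deliberately retained.
    """
    if qtl_mtas.empty:
        return qtl_mtas.copy()
    df = qtl_mtas.sort_values(["trait", "marker", "best_score", "encoding"],
                              ascending=[True, True, False, True],
                              kind="mergesort")
    return df.groupby(["trait", "marker"], sort=True
                      ).head(1).reset_index(drop=True)


def hotspots(unique_qtl_mtas: pd.DataFrame,
             max_gap_bp: int = DEFAULT_HOTSPOT_GAP_BP) -> pd.DataFrame:
    """Multi-trait clusters: chain associations on a chromosome whose
    consecutive positions are <= ``max_gap_bp`` apart; report chains
    covering >= 2 distinct traits.
    """
    rows = []
    for chrom, grp in unique_qtl_mtas.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.nonzero(np.diff(pos) > max_gap_bp)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            cluster = grp.iloc[s:e]
            traits = sorted(cluster["trait"].unique())
            if len(traits) >= 2:
                rows.append((chrom, int(cluster["pos"].min()),
                             int(cluster["pos"].max()), len(traits),
                             ",".join(traits),
                             ",".join(cluster["marker"].astype(str))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_traits",
                                       "traits", "markers"])
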