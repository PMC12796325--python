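"""Virus and host abundance statistics.

Heterotroph accounting from flow-cytometry totals, percent-infected
statistics from polony/iPolony counts, depth fold changes with
Kruskal-Wallis / Dunn / Benjamini-Hochberg contrasts, and the monthly
Prochlorococcus-VLP log-log major-axis power law with a permutation null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .stats import GroupComparison, MajorAxisFit, bh_adjust, dunn_posthoc, major_axis_fit

logger = logging.getLogger(__name__)

__all__ = [
    "LAYERS",
    "PHAGE_COLUMNS",
    "heterotroph_counts",
    "percent_infected",
    "depth_fold_changes",
    "vlp_power_law",
]

LAYERS = ("SRF", "BML", "SOM", "DCM")

#: free-phage and infected-cell count columns of the polony table (per mL)
PHAGE_COLUMNS = ("free_t4", "free_t7", "infected_t4", "infected_t7")
CELL_COLUMNS = ("prochlorococcus", "synechococcus", "total_bacteria")


def heterotroph_counts(pt: pd.DataFrame) -> pd.DataFrame:
    """Heterotrophic bacteria = total SYBR counts minus cyanobacteria.

    Adds a ``heterotrophs`` column; negative differences are floored at 0
    with a warning; any missing component gives a missing output.
    """
    out = pt.copy()
    het = out["total_bacteria"] - (out["prochlorococcus"] + out["synechococcus"])
    neg = het < 0
    if neg.any():
        logger.warning("%d samples with cyanobacteria exceeding total counts; "
                       "heterotrophs floored at 0", int(neg.sum()))
        het = het.clip(lower=0.0)
    out["heterotrophs"] = het
    return out


def percent_infected(pt: pd.DataFrame) -> pd.DataFrame:
    """Per-sample percent of Prochlorococcus infected, by phage class.

    100 * infected / Prochlorococcus for T4- and T7-like classes and their
    sum; undefined (NaN) where the Prochlorococcus count is zero or
    missing.
    """
    pro = pt["prochlorococcus"]
    bad = ~(pro > 0)
    if bad.any():
        logger.warning("%d samples with zero/missing Prochlorococcus", int(bad.sum()))
    pro = pro.where(pro > 0)
    out = pt[[c for c in ("sample_id", "layer", "time_class") if c in pt.columns]].copy()
    out["pct_t4"] = 100.0 * pt["infected_t4"] / pro
    out["pct_t7"] = 100.0 * pt["infected_t7"] / pro
    out["pct_total"] = out["pct_t4"] + out["pct_t7"]
    return out


def depth_fold_changes(pt: pd.DataFrame, variable: str,
                       use_median: bool = False) -> tuple[pd.DataFrame, GroupComparison]:
    """SOM-vs-other-layer fold changes plus the rank-test group comparison.

    fold(SOM vs L) = mean(SOM) / mean(L) (medians by flag); day and night
    replicates are pooled.  The Kruskal-Wallis / Dunn machinery runs
    across all four layers and the Dunn p-values are BH-adjusted across
    the pairs.  Layers need >= 2 replicates.
    """
    groups, names = [], []
    for L in LAYERS:
        vals = pt.loc[pt["layer"] == L, variable].dropna().to_numpy(dtype=float)
        if vals.size:
            if vals.size < 2:
                raise ValueError(f"layer {L} has fewer than 2 replicates")
            groups.append(vals)
            names.append(L)
    gc = dunn_posthoc(groups)
    center = np.median if use_median else np.mean
    centers = {L: float(center(g)) for L, g in zip(names, groups)}

    som = centers.get("SOM", np.nan)
    adj = {tuple(sorted((names[p.group_i], names[p.group_j]))): p.dunn_p_adj
           for p in gc.pairs}
    rows = []
    for L in names:
        if L == "SOM":
            continue
        fold = som / centers[L] if centers[L] != 0 else np.nan
        rows.append({"contrast": f"SOM_vs_{L}", "fold": fold,
                     "p_adj": adj.get(tuple(sorted(("SOM", L))), np.nan)})
    return pd.DataFrame(rows), gc


def vlp_power_law(pa: pd.DataFrame, n_perm: int = 10_000,
                  seed=None) -> dict[int, MajorAxisFit]:
    """Monthly power-law exponents between Prochlorococcus and VLP counts.

    Major-axis (type-II) regression of log10 VLP on log10 Prochlorococcus
    per calendar month; the slope is the power-law exponent, its
    significance from ``n_perm`` permutations.  Months with fewer than 3
    pairs are skipped with a log entry; nonpositive abundances are an
    error (they cannot be log-transformed).
    """
    if (pa["prochlorococcus"] <= 0).any() or (pa["vlp"] <= 0).any():
        raise ValueError("abundances must be strictly positive for log transform")
    rng = np.random.default_rng(seed)
    out = {}
    for month, grp in pa.groupby("month"):
        if len(grp) < 3:
            logger.info("month %s skipped: fewer than 3 pairs", month)
            continue
        x = np.log10(grp["prochlorococcus"].to_numpy(dtype=float))
        y = np.log10(grp["vlp"].to_numpy(dtype=float))
        out[int(month)] = major_axis_fit(x, y, n_perm=n_perm,
                                         seed=rng.integers(2**31 - 1))
    return out


def power_law_frame(fits: dict[int, MajorAxisFit]) -> pd.DataFrame:
    return pd.DataFrame([
        {"month": m, "exponent": f.slope, "intercept": f.intercept,
         "perm_p": f.perm_p, "n": f.n}
        for m, f in sorted(fits.items())
    ])
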