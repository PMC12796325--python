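"""Multi-decadal CTD record processing.

Optode-vs-Winkler calibration QC, per-cast sub-mixed-layer oxygen
saturation, the climatological depth x season grid with the interannual
mixed-layer-depth curve and isopycnal-class seasonal series, and the
seasonal sinusoid fit of sub-MLD saturation.
"""

from __future__ import annotations

import calendar
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .ctd import CtdCast, MldError, MldResult, compute_mld
from .stats import LinearFit, SeasonalFit, nls_sinusoid_fit, ols_fit

logger = logging.getLogger(__name__)

__all__ = [
    "CalibrationRecord",
    "SubMldPoint",
    "ClimatologyGrid",
    "ClimatologyRun",
    "decimal_year",
    "calibrate_optode_qc",
    "submld_saturation",
    "seasonal_fit",
    "climatology_grid",
    "run_climatology",
]

SEASON_BIN_DAYS = 12.0  # 30 full bins + a final 5-6 day remainder bin
MLD_BIN_DAYS = 10.0
DEPTH_BIN_M = 5.0
ISOPYCNAL_BIN = 0.1


@dataclass
class CalibrationRecord:
    fit: LinearFit
    n_pairs: int
    rejected_cast_ids: set
    residual_threshold: float


@dataclass
class SubMldPoint:
    cast_id: str
    decimal_year: float
    date: datetime
    mld_m: float
    mean_saturation: float


@dataclass
class ClimatologyGrid:
    """Depth x season saturation grid plus MLD curve and isopycnal series.

    ``saturation``: DataFrame, rows = 5 m depth-bin centers, columns =
    12-day season-bin indices, values = interannual mean saturation (%).
    ``mld_curve``: Series indexed by 10-day season-bin center (day of
    year), mean MLD (m).  ``isopycnal``: per (0.1 kg/m^3 sigma-theta
    class, 12-day bin) mean depth and saturation.
    """

    saturation: pd.DataFrame
    mld_curve: pd.Series
    isopycnal: pd.DataFrame


@dataclass
class ClimatologyRun:
    calibration: CalibrationRecord
    points: pd.DataFrame
    fit: SeasonalFit
    grid: ClimatologyGrid
    n_casts_in: int = 0
    n_casts_retained: int = 0
    log: list = field(default_factory=list)


def decimal_year(ts: datetime) -> float:
    """Leap-aware decimal year in [0, 1): Jan 1 00:00 -> 0, Dec 31 -> ~1."""
    days = 366.0 if calendar.isleap(ts.year) else 365.0
    doy = ts.timetuple().tm_yday
    frac = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0) / 24.0
    return (doy - 1 + frac) / days


def calibrate_optode_qc(bottle_pairs: pd.DataFrame,
                        threshold: float = 3.0) -> CalibrationRecord:
    """OLS of optode on Winkler oxygen; reject casts with gross residuals.

    A cast is rejected when any of its pairs has an internally studentized
    residual of magnitude >= ``threshold``.  Requires >= 10 pairs; columns
    ``cast_id``, ``optode_uM``, ``winkler_uM``.
    """
    df = bottle_pairs.dropna(subset=["optode_uM", "winkler_uM"])
    if len(df) < 10:
        raise ValueError("need at least 10 optode/Winkler pairs")
    fit = ols_fit(df["winkler_uM"].to_numpy(), df["optode_uM"].to_numpy())
    bad = np.abs(fit.standardized_residuals) >= threshold
    rejected = set(df.loc[bad, "cast_id"].astype(str))
    return CalibrationRecord(fit=fit, n_pairs=len(df),
                             rejected_cast_ids=rejected,
                             residual_threshold=threshold)


def submld_saturation(cast: CtdCast, mld: MldResult,
                      window_m: float = 10.0) -> SubMldPoint | None:
    """Mean oxygen saturation in the (MLD, MLD + window] depth window.

    Returns None (with a log entry) when the window holds no saturation
    data or the MLD was not found.
    """
    if not mld.found:
        logger.info("cast %s: MLD not found, sub-MLD point skipped", cast.cast_id)
        return None
    sat = cast.var("oxygen_saturation")
    sel = (cast.depth > mld.mld_m) & (cast.depth <= mld.mld_m + window_m) & np.isfinite(sat)
    if not sel.any():
        logger.info("cast %s: no saturation data below the MLD", cast.cast_id)
        return None
    return SubMldPoint(
        cast_id=cast.cast_id,
        decimal_year=decimal_year(cast.timestamp),
        date=cast.timestamp,
        mld_m=float(mld.mld_m),
        mean_saturation=float(sat[sel].mean()),
    )


def points_frame(points) -> pd.DataFrame:
    return pd.DataFrame([
        {"cast_id": p.cast_id, "decimal_year": p.decimal_year,
         "date": p.date, "mld_m": p.mld_m,
         "mean_saturation": p.mean_saturation}
        for p in points if p is not None
    ])


def seasonal_fit(points) -> SeasonalFit:
    """Sinusoidal seasonal regression of sub-MLD saturation on decimal year.

    Requires >= 50 points whose phases span >= 200 days of the year.
    """
    df = points if isinstance(points, pd.DataFrame) else points_frame(points)
    if len(df) < 50:
        raise ValueError("need at least 50 sub-MLD points")
    t = df["decimal_year"].to_numpy(dtype=float)
    if np.ptp(t) * 365.25 < 200:
        raise ValueError("inadequate seasonal phase coverage (< 200 days)")
    return nls_sinusoid_fit(t, df["mean_saturation"].to_numpy(dtype=float))


def extremum_months(fit: SeasonalFit) -> tuple[str, str]:
    """Calendar months of the fitted minimum and maximum."""
    if not fit.phase_identifiable:
        return ("undefined", "undefined")
    def month(t):
        return calendar.month_name[int(t * 12) % 12 + 1]
    return month(fit.t_min), month(fit.t_max)


def _season_bin(doy0):
    return np.minimum((doy0 // SEASON_BIN_DAYS).astype(int), 30)


def climatology_grid(casts, mlds=None) -> ClimatologyGrid:
    """Interannual climatology: depth x 12-day saturation grid, 10-day MLD
    curve, and per-isopycnal-class seasonal mean depth / saturation.

    ``mlds`` may carry pre-computed :class:`MldResult` per cast (aligned
    with ``casts``); otherwise the MLD criterion is evaluated here, and
    casts without top-10 db data simply contribute no MLD.
    """
    casts = list(casts)
    if not casts:
        raise ValueError("no casts")
    depth_all, sat_all, sig_all, doy_all = [], [], [], []
    mld_vals, mld_doy = [], []
    for i, cast in enumerate(casts):
        doy0 = cast.timestamp.timetuple().tm_yday - 1
        sat = cast.var("oxygen_saturation")
        sig = cast.var("sigma_theta")
        depth_all.append(cast.depth)
        sat_all.append(sat)
        sig_all.append(sig)
        doy_all.append(np.full(cast.depth.shape, doy0, dtype=float))
        if mlds is not None:
            mld = mlds[i]
        else:
            try:
                mld = compute_mld(cast)
            except MldError:
                mld = None
        if mld is not None and mld.found:
            mld_vals.append(mld.mld_m)
            mld_doy.append(doy0)

    depth = np.concatenate(depth_all)
    sat = np.concatenate(sat_all)
    sig = np.concatenate(sig_all)
    doy = np.concatenate(doy_all)
    ok = np.isfinite(sat)

    cells = pd.DataFrame({
        "depth_bin": (np.floor(depth[ok] / DEPTH_BIN_M) * DEPTH_BIN_M + DEPTH_BIN_M / 2),
        "season_bin": _season_bin(doy[ok]),
        "saturation": sat[ok],
    })
    grid = cells.groupby(["depth_bin", "season_bin"])["saturation"].mean().unstack()

    if mld_vals:
        mc = pd.DataFrame({
            "bin": np.minimum((np.asarray(mld_doy) // MLD_BIN_DAYS).astype(int), 36),
            "mld": mld_vals,
        })
        mld_curve = mc.groupby("bin")["mld"].mean()
        mld_curve.index = mld_curve.index * MLD_BIN_DAYS + MLD_BIN_DAYS / 2
    else:
        mld_curve = pd.Series(dtype=float)

    ok2 = ok & np.isfinite(sig)
    iso = pd.DataFrame({
        "sigma_class": np.floor(sig[ok2] / ISOPYCNAL_BIN) * ISOPYCNAL_BIN,
        "season_bin": _season_bin(doy[ok2]),
        "depth": depth[ok2],
        "saturation": sat[ok2],
    })
    iso_series = (iso.groupby(["sigma_class", "season_bin"])
                  .agg(mean_depth=("depth", "mean"),
                       mean_saturation=("saturation", "mean"))
                  .reset_index())
    return ClimatologyGrid(saturation=grid, mld_curve=mld_curve, isopycnal=iso_series)


def run_climatology(casts, bottles: pd.DataFrame, qc_threshold: float = 3.0,
                    out_dir=None) -> ClimatologyRun:
    """Full record pipeline: QC -> per-cast MLD / sub-MLD means on retained
    casts -> seasonal fit -> climatology grid; optionally writes outputs."""
    casts = list(casts)
    log = []
    calib = calibrate_optode_qc(bottles, threshold=qc_threshold)
    log.append(f"calibration: {calib.n_pairs} pairs, "
               f"{len(calib.rejected_cast_ids)} casts rejected")
    retained = [c for c in casts if c.cast_id not in calib.rejected_cast_ids]

    points, kept_mlds, kept_casts = [], [], []
    for cast in retained:
        try:
            mld = compute_mld(cast)
        except MldError:
            continue
        kept_casts.append(cast)
        kept_mlds.append(mld)
        pt = submld_saturation(cast, mld)
        if pt is not None:
            points.append(pt)
    pts = points_frame(points)
    fit = seasonal_fit(pts)
    grid = climatology_grid(kept_casts, kept_mlds)
    run = ClimatologyRun(calibration=calib, points=pts, fit=fit, grid=grid,
                         n_casts_in=len(casts), n_casts_retained=len(retained),
                         log=log)
    if out_dir is not None:
        _write_outputs(run, Path(out_dir))
    return run


def _write_outputs(run: ClimatologyRun, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    f = run.calibration.fit
    (out / "calibration.json").write_text(json.dumps({
        "intercept": f.intercept, "slope": f.slope,
        "adj_r_squared": f.adj_r_squared, "n_pairs": run.calibration.n_pairs,
        "rejected_cast_ids": sorted(run.calibration.rejected_cast_ids),
        "residual_threshold": run.calibration.residual_threshold,
    }, indent=2))
    run.points.to_csv(out / "submld_points.csv", index=False)
    sf = run.fit
    (out / "seasonal_fit.json").write_text(json.dumps({
        "a": sf.a, "b": sf.b, "c": sf.c,
        "se_a": sf.se_a, "se_b": sf.se_b, "se_c": sf.se_c,
        "amplitude": sf.amplitude, "t_min": sf.t_min, "t_max": sf.t_max,
        "n": sf.n, "phase_identifiable": sf.phase_identifiable,
    }, indent=2))
    run.grid.saturation.to_csv(out / "grid.csv")
    run.grid.isopycnal.to_csv(out / "isopycnal.csv", index=False)
    (out / "run_log.json").write_text(json.dumps(run.log, indent=2))
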