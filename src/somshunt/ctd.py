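"""Per-cast CTD processing.

Ingestion of delimited cast tables, 0.5 m depth binning, Nadaraya-Watson
smoothing over pressure, thermodynamic derivation (sigma-theta, oxygen
solubility and saturation), the 0.125 kg/m^3 mixed-layer-depth criterion,
identification of the first 0.1 kg/m^3 isopycnal band below the mixed
layer (the operational subsurface-oxygen-maximum band), fixed-window layer
summaries and cruise-level layer contrasts, and extraction of 4-hourly
layer time series for diel rhythm testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from . import thermo
from .stats import nw_smooth

logger = logging.getLogger(__name__)

__all__ = [
    "CtdCast",
    "MldResult",
    "SomBand",
    "LayerSummary",
    "MldError",
    "CastList",
    "LAYER_WINDOWS",
    "read_casts",
    "write_casts",
    "bin_profile",
    "smooth_profile",
    "derive_thermo",
    "compute_mld",
    "identify_som_band",
    "layer_summaries",
    "layer_contrasts",
    "diel_series",
]

#: measured variables carried per depth bin
MEASURED_VARS = ("pressure", "temperature", "salinity", "oxygen",
                 "fluorescence", "beam_attenuation")
DERIVED_VARS = ("sigma_theta", "oxygen_solubility", "oxygen_saturation")

#: fixed depth windows (m) used for layer statistics
LAYER_WINDOWS = {"MIXED": (5.0, 40.0), "SOM": (50.0, 60.0), "DCM": (100.0, 120.0)}


@dataclass
class CtdCast:
    """One profile on an ordered depth grid (m, positive down)."""

    cast_id: str
    timestamp: datetime
    latitude: float
    longitude: float
    depth: np.ndarray
    variables: dict[str, np.ndarray] = field(default_factory=dict)
    qc_flags: set[str] = field(default_factory=set)

    def var(self, name: str) -> np.ndarray:
        v = self.variables.get(name)
        if v is None:
            return np.full(self.depth.shape, np.nan)
        return v

    def copy_with(self, depth=None, variables=None) -> "CtdCast":
        return CtdCast(
            cast_id=self.cast_id,
            timestamp=self.timestamp,
            latitude=self.latitude,
            longitude=self.longitude,
            depth=self.depth.copy() if depth is None else depth,
            variables={k: v.copy() for k, v in (self.variables if variables is None else variables).items()},
            qc_flags=set(self.qc_flags),
        )


@dataclass
class MldResult:
    mld_m: float | None
    reference_sigma: float
    threshold: float

    @property
    def found(self) -> bool:
        return self.mld_m is not None


@dataclass
class SomBand:
    sigma_lo: float
    sigma_hi: float
    depth_lo: float
    depth_hi: float
    representative_depth: float
    zero_thickness: bool = False


@dataclass
class LayerSummary:
    cast_id: str
    layer: str
    oxygen: float
    saturation: float
    fluorescence: float
    beam_attenuation: float


class MldError(ValueError):
    """Raised when the mixed-layer criterion cannot be evaluated."""

    def __init__(self, message, flag="MISSING_TOP_10DB"):
        super().__init__(message)
        self.flag = flag


class CastList(list):
    """List of casts; ``n_skipped`` counts unparseable input rows."""

    n_skipped: int = 0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REQUIRED = ("cast_id", "time", "depth", "oxygen", "fluorescence",
             "beam_attenuation")
_THERMO_ALTERNATIVES = (("temperature", "salinity"),
                        ("sigma_theta", "oxygen_saturation"))
_NUMERIC = ("depth", "pressure", "temperature", "salinity", "oxygen",
            "fluorescence", "beam_attenuation", "latitude", "longitude",
            "sigma_theta", "oxygen_solubility", "oxygen_saturation")


def read_casts(path, format_spec=None) -> CastList:
    """Read a delimited cast table (one row per cast x depth).

    Mandatory columns: cast_id, time, depth, temperature, salinity, oxygen,
    fluorescence, beam_attenuation.  Optional: pressure, latitude, longitude
    and pre-computed sigma_theta / oxygen_solubility / oxygen_saturation
    (pass-through mode).  Empty cells and "NA" are missing.  Rows whose depth
    or time cannot be parsed are skipped and counted on ``result.n_skipped``.
    """
    sep = (format_spec or {}).get("sep", ",") if isinstance(format_spec, dict) else ","
    df = pd.read_csv(path, sep=sep, na_values=["NA", ""], dtype=str,
                     skipinitialspace=True)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if not any(all(c in df.columns for c in alt) for alt in _THERMO_ALTERNATIVES):
        missing += [c for c in _THERMO_ALTERNATIVES[0] if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {', '.join(missing)}")
    for col in _NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    parsed_time = pd.to_datetime(df["time"], errors="coerce", format="mixed")
    bad = df["depth"].isna() | parsed_time.isna()
    n_skipped = int(bad.sum())
    if n_skipped:
        logger.warning("skipped %d unparseable rows in %s", n_skipped, path)
    df = df[~bad].copy()
    df["time"] = parsed_time[~bad]

    out = CastList()
    out.n_skipped = n_skipped
    for cast_id, grp in df.groupby("cast_id", sort=True):
        grp = grp.sort_values("depth")
        depth = grp["depth"].to_numpy(dtype=float)
        variables = {}
        for col in MEASURED_VARS + DERIVED_VARS:
            if col in grp.columns:
                variables[col] = grp[col].to_numpy(dtype=float)
        if "pressure" not in variables:
            # shallow-water equivalence: 1 db per metre
            variables["pressure"] = depth.copy()
        out.append(CtdCast(
            cast_id=str(cast_id),
            timestamp=grp["time"].iloc[0].to_pydatetime(),
            latitude=float(grp["latitude"].iloc[0]) if "latitude" in grp else np.nan,
            longitude=float(grp["longitude"].iloc[0]) if "longitude" in grp else np.nan,
            depth=depth,
            variables=variables,
        ))
    return out


def write_casts(casts, path):
    """Write casts back to the delimited format accepted by :func:`read_casts`."""
    frames = []
    for c in casts:
        d = {"cast_id": c.cast_id, "time": c.timestamp.isoformat(),
             "latitude": c.latitude, "longitude": c.longitude,
             "depth": c.depth}
        for k, v in c.variables.items():
            d[k] = v
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# binning / smoothing / thermodynamics
# ---------------------------------------------------------------------------


def bin_profile(cast: CtdCast) -> CtdCast:
    """Average samples to the nearest 0.5 m; empty bins are NaN.

    Idempotent: input already on the 0.5 m grid is returned unchanged.
    """
    if cast.depth.size == 0:
        return cast.copy_with()
    centers = np.round(cast.depth * 2.0) / 2.0
    lo, hi = centers.min(), centers.max()
    grid = np.round(np.arange(lo, hi + 0.25, 0.5) * 2) / 2
    idx = np.searchsorted(grid, centers)
    variables = {}
    for name, vals in cast.variables.items():
        sums = np.zeros(grid.size)
        cnts = np.zeros(grid.size)
        ok = np.isfinite(vals)
        np.add.at(sums, idx[ok], vals[ok])
        np.add.at(cnts, idx[ok], 1.0)
        with np.errstate(invalid="ignore"):
            variables[name] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return cast.copy_with(depth=grid, variables=variables)


def smooth_profile(cast: CtdCast, bandwidth_db: float = 5.0) -> CtdCast:
    """Nadaraya-Watson smooth of every variable along pressure.

    Missing bins are filled by the smoother (Gaussian weights are strictly
    positive).  An all-missing variable is left untouched and flagged.
    """
    pressure = cast.var("pressure")
    variables = {"pressure": pressure.copy()}
    flags = set(cast.qc_flags)
    for name, vals in cast.variables.items():
        if name == "pressure":
            continue
        if not np.isfinite(vals).any():
            variables[name] = vals.copy()
            flags.add(f"ALL_MISSING_{name.upper()}")
            continue
        variables[name] = nw_smooth(pressure, vals, bandwidth_db, pressure)
    out = cast.copy_with(variables=variables)
    out.qc_flags = flags
    return out


def derive_thermo(cast: CtdCast) -> CtdCast:
    """Attach sigma_theta, oxygen solubility and saturation.

    Casts already carrying sigma_theta and oxygen_saturation (synthetic
    pass-through mode) are returned untouched.  Otherwise sigma-theta and
    the Garcia-Gordon solubility are computed wherever temperature and
    salinity are defined, and saturation % = 100 * oxygen / solubility
    wherever both are defined.
    """
    if "sigma_theta" in cast.variables and "oxygen_saturation" in cast.variables:
        return cast
    out = cast.copy_with()
    t = out.var("temperature")
    s = out.var("salinity")
    p = out.var("pressure")
    ok = np.isfinite(t) & np.isfinite(s) & np.isfinite(p)
    sig = np.full(t.shape, np.nan)
    sol = np.full(t.shape, np.nan)
    if ok.any():
        sig[ok] = thermo.sigma_theta(s[ok], t[ok], p[ok])
        sol[ok] = thermo.o2_solubility(s[ok], t[ok])
    out.variables["sigma_theta"] = sig
    out.variables["oxygen_solubility"] = sol
    oxy = out.var("oxygen")
    with np.errstate(invalid="ignore", divide="ignore"):
        out.variables["oxygen_saturation"] = np.where(
            np.isfinite(oxy) & np.isfinite(sol), 100.0 * oxy / sol, np.nan)
    return out


# ---------------------------------------------------------------------------
# mixed layer and SOM band
# ---------------------------------------------------------------------------


def _interp_at(x, y, x0):
    """Linear interpolation of y at x0; NaN outside the sampled range."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 1:
        return np.nan
    xs, ys = x[ok], y[ok]
    if x0 < xs.min() or x0 > xs.max():
        return np.nan
    return float(np.interp(x0, xs, ys))


def compute_mld(cast: CtdCast, threshold: float = 0.125,
                reference_db: float = 10.0) -> MldResult:
    """Mixed layer depth: shallowest depth with sigma-theta >= ref + threshold.

    The reference is sigma-theta at 10 db; the crossing is linearly
    interpolated between the bracketing bins.  Casts without data in the
    top 10 db cannot supply the reference and raise :class:`MldError`
    (flagged MISSING_TOP_10DB), mirroring their removal from the record.
    """
    sig = cast.var("sigma_theta")
    pres = cast.var("pressure")
    ok = np.isfinite(sig) & np.isfinite(pres)
    if not ok.any() or pres[ok].min() > reference_db:
        cast.qc_flags.add("MISSING_TOP_10DB")
        raise MldError(
            f"cast {cast.cast_id}: no sigma-theta within the top {reference_db} db")
    ref = _interp_at(pres, sig, reference_db)
    if not np.isfinite(ref):
        cast.qc_flags.add("MISSING_TOP_10DB")
        raise MldError(f"cast {cast.cast_id}: reference sigma-theta undefined")

    depth = cast.depth[ok]
    excess = sig[ok] - ref
    # only search at/below the reference pressure
    below = pres[ok] >= reference_db
    depth_b, excess_b = depth[below], excess[below]
    hit = np.nonzero(excess_b >= threshold)[0]
    if hit.size == 0:
        return MldResult(None, ref, threshold)
    i = hit[0]
    if i == 0:
        mld = float(depth_b[0])
    else:
        d0, d1 = depth_b[i - 1], depth_b[i]
        e0, e1 = excess_b[i - 1], excess_b[i]
        mld = float(d0 + (threshold - e0) * (d1 - d0) / (e1 - e0))
    return MldResult(mld, ref, threshold)


def identify_som_band(cast: CtdCast, mld: MldResult,
                      isopycnal_width: float = 0.1) -> SomBand:
    """First isopycnal band below the mixed layer.

    The band is the depth range with sigma-theta in
    (sigma_theta(MLD), sigma_theta(MLD) + isopycnal_width]; its lower edge
    is interpolated.  The representative depth is the saturation-maximizing
    grid depth inside the band.  A density jump larger than the band width
    immediately below the MLD yields a zero-thickness band, flagged.
    """
    if not mld.found:
        raise ValueError("MLD not found; SOM band undefined")
    sig = cast.var("sigma_theta")
    ok = np.isfinite(sig)
    depth, sig_ok = cast.depth[ok], sig[ok]
    sigma_lo = mld.reference_sigma + mld.threshold
    sigma_hi = sigma_lo + isopycnal_width

    below = depth > mld.mld_m
    in_band = below & (sig_ok > sigma_lo) & (sig_ok <= sigma_hi)
    if not in_band.any():
        first = np.nonzero(below)[0]
        d = float(depth[first[0]]) if first.size else float(mld.mld_m)
        cast.qc_flags.add("SOM_BAND_EMPTY")
        return SomBand(sigma_lo, sigma_hi, d, d, d, zero_thickness=True)

    # lower edge: interpolate the sigma_hi crossing below the band
    idx = np.nonzero(in_band)[0]
    last = idx[-1]
    if last + 1 < depth.size and sig_ok[last + 1] > sigma_hi:
        d0, d1 = depth[last], depth[last + 1]
        s0, s1 = sig_ok[last], sig_ok[last + 1]
        depth_hi = float(d0 + (sigma_hi - s0) * (d1 - d0) / (s1 - s0))
    else:
        depth_hi = float(depth[last])
    depth_lo = float(mld.mld_m)

    sat = cast.var("oxygen_saturation")[ok]
    band_sat = sat[idx]
    if np.isfinite(band_sat).any():
        rep = float(depth[idx[np.nanargmax(band_sat)]])
    else:
        rep = 0.5 * (depth_lo + depth_hi)
    return SomBand(sigma_lo, sigma_hi, depth_lo, depth_hi, rep)


# ---------------------------------------------------------------------------
# layer statistics
# ---------------------------------------------------------------------------


def _layer_mean(cast, name, lo, hi):
    vals = cast.var(name)
    sel = (cast.depth >= lo) & (cast.depth <= hi) & np.isfinite(vals)
    return float(vals[sel].mean()) if sel.any() else np.nan


def layer_summaries(cast: CtdCast) -> list[LayerSummary]:
    """Per-layer means over the fixed windows ML 5-40, SOM 50-60, DCM 100-120 m."""
    out = []
    for layer, (lo, hi) in LAYER_WINDOWS.items():
        out.append(LayerSummary(
            cast_id=cast.cast_id,
            layer=layer,
            oxygen=_layer_mean(cast, "oxygen", lo, hi),
            saturation=_layer_mean(cast, "oxygen_saturation", lo, hi),
            fluorescence=_layer_mean(cast, "fluorescence", lo, hi),
            beam_attenuation=_layer_mean(cast, "beam_attenuation", lo, hi),
        ))
    return out


def summaries_frame(summaries) -> pd.DataFrame:
    rows = [{"cast_id": s.cast_id, "layer": s.layer, "oxygen": s.oxygen,
             "saturation": s.saturation, "fluorescence": s.fluorescence,
             "beam_attenuation": s.beam_attenuation} for s in summaries]
    return pd.DataFrame(rows)


def layer_contrasts(summaries) -> pd.DataFrame:
    """Cruise-level layer contrasts from per-cast layer summaries.

    Per-cast differences (SOM-ML, SOM-DCM) in oxygen (umol/kg, and as a
    percent of the reference layer) and saturation (percentage points),
    beam-attenuation ratios SOM/ML and SOM/DCM, and the chlorophyll-
    fluorescence SOM/DCM ratio expressed as a percentage; mean and sd
    across casts with all three layers.
    """
    df = summaries_frame(summaries)
    wide = df.pivot(index="cast_id", columns="layer")
    complete = wide.dropna(subset=[("oxygen", L) for L in ("MIXED", "SOM", "DCM")])
    if complete.empty:
        raise ValueError("no cast has all three layers populated")

    def col(v, L):
        return complete[(v, L)]

    per_cast = pd.DataFrame({
        "oxygen_som_minus_ml": col("oxygen", "SOM") - col("oxygen", "MIXED"),
        "oxygen_som_minus_ml_pct": 100.0 * (col("oxygen", "SOM") - col("oxygen", "MIXED")) / col("oxygen", "MIXED"),
        "oxygen_som_minus_dcm": col("oxygen", "SOM") - col("oxygen", "DCM"),
        "oxygen_som_minus_dcm_pct": 100.0 * (col("oxygen", "SOM") - col("oxygen", "DCM")) / col("oxygen", "DCM"),
        "saturation_som_minus_ml": col("saturation", "SOM") - col("saturation", "MIXED"),
        "saturation_som_minus_dcm": col("saturation", "SOM") - col("saturation", "DCM"),
        "beam_som_over_ml": col("beam_attenuation", "SOM") / col("beam_attenuation", "MIXED"),
        "beam_som_over_dcm": col("beam_attenuation", "SOM") / col("beam_attenuation", "DCM"),
        "chl_som_over_dcm_pct": 100.0 * col("fluorescence", "SOM") / col("fluorescence", "DCM"),
    })
    return pd.DataFrame({"mean": per_cast.mean(), "sd": per_cast.std(ddof=1)})


def diel_series(casts, layer: str, variable: str):
    """Layer-mean time series (elapsed hours, values) across time-ordered casts."""
    if layer not in LAYER_WINDOWS:
        raise ValueError(f"unknown layer {layer!r}")
    lo, hi = LAYER_WINDOWS[layer]
    casts = sorted(casts, key=lambda c: c.timestamp)
    t0 = casts[0].timestamp
    t_hours, values = [], []
    for c in casts:
        v = _layer_mean(c, variable, lo, hi)
        if np.isfinite(v):
            t_hours.append((c.timestamp - t0).total_seconds() / 3600.0)
            values.append(v)
    return np.asarray(t_hours), np.asarray(values)
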