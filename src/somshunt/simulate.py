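"""Synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one observed data
stream -- stratified density profiles with a sub-mixed-layer oxygen bump,
a seasonal sinusoid in sub-MLD saturation with optode calibration bias and
a handful of grossly contaminated casts, overdispersed taxon x KO
transcript counts with SOM-specific planted effects, lognormal phage and
cell abundances with depth fold structure, and log-log power-law coupled
virus/host pairs.  The documented defaults are the study's reported
effect sizes, so downstream estimators run against known ground truth.

Every generator is a pure function of its config (seed included): same
config, same output.  Setting ``noise_scale = 0`` on a config gives the
noiseless limit in which downstream estimators return the planted
parameters exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import thermo
from .ctd import CtdCast
from .enrichment import CountMatrix

__all__ = [
    "CruiseConfig",
    "ClimatologyConfig",
    "CountsConfig",
    "PolonyConfig",
    "VlpConfig",
    "gen_cruise_casts",
    "gen_climatology",
    "gen_count_matrix",
    "gen_polony_table",
    "gen_vlp_pairs",
]


def _lognormal_factor(rng, cv, size=None):
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


# ---------------------------------------------------------------------------
# cruise casts
# ---------------------------------------------------------------------------


@dataclass
class CruiseConfig:
    """4-hourly Lagrangian cruise profiles, 0-200 m at 0.5 m resolution.

    Layer-contrast defaults are the observed cruise means; their sd fields
    are the observed between-cast spreads applied as Gaussian noise on the
    per-cast layer deltas (scaled by ``noise_scale``).
    """

    seed: int = 0
    n_casts: int = 36                # 6 days of 4-hourly casts
    cast_interval_hours: float = 4.0
    start: datetime = field(default_factory=lambda: datetime(2019, 10, 12, 20, 0))
    max_depth_m: float = 200.0
    # density structure: uniform sigma-theta above the pycnocline, MLD ~ 52 m
    sigma_surface: float = 24.0
    pycnocline_top_m: float = 50.0
    pycnocline_gradient: float = 0.0625   # kg/m^3 per m down to 60 m
    deep_gradient: float = 0.02
    # oxygen (umol/kg) and saturation (%) layer structure
    ml_oxygen: float = 191.4
    som_minus_ml_oxygen: float = 22.14
    som_minus_ml_oxygen_sd: float = 4.20
    som_minus_dcm_oxygen: float = 17.43
    som_minus_dcm_oxygen_sd: float = 5.66
    ml_saturation: float = 100.5
    som_minus_ml_saturation: float = 6.47
    som_minus_ml_saturation_sd: float = 1.22
    som_minus_dcm_saturation: float = 13.9
    som_minus_dcm_saturation_sd: float = 1.93
    ml_level_sd: float = 1.0              # cast-to-cast baseline wobble
    # particulates: beam attenuation (1/m) ratios and the 24 h SOM cycle
    som_beam: float = 0.50
    beam_som_over_ml: float = 1.09
    beam_som_over_ml_sd: float = 0.04
    beam_som_over_dcm: float = 1.52
    beam_som_over_dcm_sd: float = 0.14
    beam_cast_cv: float = 0.02
    beam_diel_amplitude: float = 0.05     # fractional 24 h modulation at the SOM
    beam_diel_peak_hour: float = 18.0     # local hour of the beam maximum
    # chlorophyll fluorescence (mg/m^3)
    dcm_chl: float = 0.45
    chl_som_over_dcm: float = 0.269
    chl_som_over_dcm_sd: float = 0.0447
    surface_chl: float = 0.05
    salinity: float = 36.6
    latitude: float = 31.67
    longitude: float = -64.17
    mode: str = "passthrough"             # "passthrough" or "raw"
    noise_scale: float = 1.0


def _piecewise(depth, nodes):
    xs, ys = zip(*nodes)
    return np.interp(depth, xs, ys)


def _cruise_sigma_profile(cfg: CruiseConfig, depth):
    sig = np.full(depth.shape, cfg.sigma_surface)
    below = depth > cfg.pycnocline_top_m
    z = depth[below]
    upper = cfg.sigma_surface + cfg.pycnocline_gradient * np.minimum(
        z - cfg.pycnocline_top_m, 10.0)
    deep = cfg.deep_gradient * np.maximum(z - cfg.pycnocline_top_m - 10.0, 0.0)
    sig[below] = upper + deep
    return sig


def _invert_temperature(sigma_target, salinity, pressure):
    """Temperature profile whose EOS-80 sigma-theta matches the target."""
    out = np.empty_like(sigma_target)
    for i, (sg, p) in enumerate(zip(sigma_target, pressure)):
        out[i] = brentq(lambda t: thermo.sigma_theta(salinity, t, p) - sg, -2.0, 40.0)
    return out


def gen_cruise_casts(cfg: CruiseConfig | None = None) -> list[CtdCast]:
    """Simulate the 6-day 4-hourly cruise CTD record.

    Pass-through mode emits sigma_theta / oxygen_saturation directly; raw
    mode emits (temperature, salinity) consistent with the same density
    structure, with oxygen set from the target saturation so the derived
    saturation matches.
    """
    cfg = cfg or CruiseConfig()
    rng = np.random.default_rng(cfg.seed)
    ns = cfg.noise_scale
    depth = np.arange(0.0, cfg.max_depth_m + 0.25, 0.5)
    sigma = _cruise_sigma_profile(cfg, depth)
    if cfg.mode == "raw":
        temp = _invert_temperature(sigma, cfg.salinity, depth)
        sol = thermo.o2_solubility(np.full_like(depth, cfg.salinity), temp)
    elif cfg.mode != "passthrough":
        raise ValueError(f"unknown mode {cfg.mode!r}")

    casts = []
    for k in range(cfg.n_casts):
        t_hours = k * cfg.cast_interval_hours
        ts = cfg.start + timedelta(hours=t_hours)

        ml_oxy = cfg.ml_oxygen + ns * cfg.ml_level_sd * rng.standard_normal()
        som_oxy = ml_oxy + cfg.som_minus_ml_oxygen + ns * cfg.som_minus_ml_oxygen_sd * rng.standard_normal()
        dcm_oxy = som_oxy - cfg.som_minus_dcm_oxygen - ns * cfg.som_minus_dcm_oxygen_sd * rng.standard_normal()
        ml_sat = cfg.ml_saturation + ns * 0.5 * cfg.ml_level_sd * rng.standard_normal()
        som_sat = ml_sat + cfg.som_minus_ml_saturation + ns * cfg.som_minus_ml_saturation_sd * rng.standard_normal()
        dcm_sat = som_sat - cfg.som_minus_dcm_saturation - ns * cfg.som_minus_dcm_saturation_sd * rng.standard_normal()

        diel = 1.0 + cfg.beam_diel_amplitude * np.cos(
            2 * np.pi * (t_hours + cfg.start.hour - cfg.beam_diel_peak_hour) / 24.0)
        som_beam_base = cfg.som_beam * _lognormal_factor(rng, ns * cfg.beam_cast_cv)
        som_beam = som_beam_base * diel
        ml_beam = som_beam / (cfg.beam_som_over_ml + ns * cfg.beam_som_over_ml_sd * rng.standard_normal())
        dcm_beam = som_beam / (cfg.beam_som_over_dcm + ns * cfg.beam_som_over_dcm_sd * rng.standard_normal())

        dcm_chl = cfg.dcm_chl * _lognormal_factor(rng, ns * 0.05)
        som_chl = dcm_chl * (cfg.chl_som_over_dcm + ns * cfg.chl_som_over_dcm_sd * rng.standard_normal())

        oxy = _piecewise(depth, [(0, ml_oxy), (40, ml_oxy), (50, som_oxy),
                                 (60, som_oxy), (100, dcm_oxy), (120, dcm_oxy),
                                 (200, dcm_oxy - 30.0)])
        sat = _piecewise(depth, [(0, ml_sat), (40, ml_sat), (50, som_sat),
                                 (60, som_sat), (100, dcm_sat), (120, dcm_sat),
                                 (200, dcm_sat - 10.0)])
        beam = _piecewise(depth, [(0, ml_beam), (40, ml_beam), (50, som_beam),
                                  (60, som_beam), (100, dcm_beam), (120, dcm_beam),
                                  (200, dcm_beam * 0.8)])
        chl = _piecewise(depth, [(0, cfg.surface_chl), (40, cfg.surface_chl),
                                 (50, som_chl), (60, som_chl), (100, dcm_chl),
                                 (120, dcm_chl), (200, 0.02)])
        variables = {
            "pressure": depth.copy(),
            "fluorescence": chl,
            "beam_attenuation": beam,
        }
        if cfg.mode == "passthrough":
            variables["sigma_theta"] = sigma.copy()
            variables["oxygen"] = oxy
            variables["oxygen_saturation"] = sat
            variables["oxygen_solubility"] = 100.0 * oxy / sat
        else:
            variables["temperature"] = temp.copy()
            variables["salinity"] = np.full_like(depth, cfg.salinity)
            variables["oxygen"] = sat * sol / 100.0
        casts.append(CtdCast(
            cast_id=f"AE-{k:03d}", timestamp=ts,
            latitude=cfg.latitude, longitude=cfg.longitude,
            depth=depth.copy(), variables=variables,
        ))
    return casts


# ---------------------------------------------------------------------------
# climatological record
# ---------------------------------------------------------------------------


@dataclass
class ClimatologyConfig:
    """Multi-decadal record: seasonal sub-MLD saturation law, seasonal MLD
    cycle, optode/Winkler bottle pairs and planted gross contamination."""

    seed: int = 0
    n_casts: int = 5270
    year_start: int = 1989
    year_end: int = 2019
    # seasonal law y = a + b sin(2 pi (c + t)) for sub-MLD saturation (%)
    law_a: float = 102.0
    law_b: float = -2.993
    law_c: float = 0.5924
    residual_sd: float = 1.5          # percentage points
    # seasonal MLD cycle (m): deep winter mixing, shallow summer
    mld_mean: float = 125.0
    mld_amplitude: float = 75.0
    mld_phase: float = 0.35
    sigma_surface: float = 24.0
    sigma_gradient: float = 0.05      # kg/m^3 per m below the mixed layer
    max_depth_m: float = 250.0
    grid_step_m: float = 2.0
    reference_solubility: float = 210.0   # umol/kg, to back out concentrations
    # bottle calibration block: optode = cal_intercept + cal_slope * winkler
    n_bottle_pairs: int = 1000
    cal_intercept: float = 7.85
    cal_slope: float = 0.964
    bottle_noise_sd: float = 2.0      # uM
    n_contaminated: int = 26
    contamination_offset: float = 60.0    # uM, gross optode bias
    noise_scale: float = 1.0


def _seasonal_mld(cfg: ClimatologyConfig, t):
    return cfg.mld_mean - cfg.mld_amplitude * np.sin(2 * np.pi * (t - cfg.mld_phase))


def gen_climatology(cfg: ClimatologyConfig | None = None):
    """Simulate the multi-decadal cast record and its bottle table.

    Returns ``(casts, bottles)``; ``bottles`` is a DataFrame with columns
    cast_id, depth, optode_uM, winkler_uM and carries the planted
    contaminated cast ids in ``bottles.attrs["contaminated_cast_ids"]``.
    Contaminated casts get the same gross offset on their profile oxygen,
    so discarding them protects the seasonal fit.
    """
    cfg = cfg or ClimatologyConfig()
    rng = np.random.default_rng(cfg.seed)
    ns = cfg.noise_scale
    depth = np.arange(0.0, cfg.max_depth_m + cfg.grid_step_m / 2, cfg.grid_step_m)

    years = rng.integers(cfg.year_start, cfg.year_end + 1, size=cfg.n_casts)
    tfrac = rng.uniform(0.0, 1.0, size=cfg.n_casts)

    # bottle block: which casts get pairs, which are contaminated
    pair_idx = rng.choice(cfg.n_casts, size=min(cfg.n_bottle_pairs, cfg.n_casts),
                          replace=False)
    contam_idx = set(rng.choice(pair_idx, size=cfg.n_contaminated, replace=False).tolist())

    casts, bottle_rows = [], []
    for i in range(cfg.n_casts):
        t = tfrac[i]
        year = int(years[i])
        days = 366 if (year % 4 == 0 and (year % 100 != 0 or year % 400 == 0)) else 365
        ts = datetime(year, 1, 1) + timedelta(days=float(t * days))
        mld = float(np.clip(_seasonal_mld(cfg, t), 20.0, cfg.max_depth_m - 30.0))

        # uniform above (mld - 0.125/gradient), linear crossing at mld
        ramp_top = mld - 0.125 / cfg.sigma_gradient
        sigma = cfg.sigma_surface + cfg.sigma_gradient * np.maximum(depth - ramp_top, 0.0)

        sat_sub = cfg.law_a + cfg.law_b * np.sin(2 * np.pi * (cfg.law_c + t)) \
            + ns * cfg.residual_sd * rng.standard_normal()
        sat = np.full(depth.shape, cfg.law_a)
        in_win = (depth > mld) & (depth <= mld + 10.0)
        sat[in_win] = sat_sub
        deep = depth > mld + 10.0
        sat[deep] = sat_sub - 0.15 * (depth[deep] - (mld + 10.0))

        oxy = sat * cfg.reference_solubility / 100.0
        if i in contam_idx:
            oxy = oxy + cfg.contamination_offset

        cast_id = f"B{i:05d}"
        casts.append(CtdCast(
            cast_id=cast_id, timestamp=ts, latitude=31.67, longitude=-64.17,
            depth=depth.copy(),
            variables={
                "pressure": depth.copy(),
                "sigma_theta": sigma,
                "oxygen": oxy,
                "oxygen_saturation": 100.0 * oxy / cfg.reference_solubility,
                "oxygen_solubility": np.full(depth.shape, cfg.reference_solubility),
            },
        ))
        if i in set(pair_idx.tolist()):
            winkler = rng.uniform(180.0, 250.0)
            optode = cfg.cal_intercept + cfg.cal_slope * winkler \
                + ns * cfg.bottle_noise_sd * rng.standard_normal()
            if i in contam_idx:
                optode += cfg.contamination_offset
            bottle_rows.append({"cast_id": cast_id, "depth": 10.0,
                                "optode_uM": optode, "winkler_uM": winkler})
    bottles = pd.DataFrame(bottle_rows)
    bottles.attrs["contaminated_cast_ids"] = {f"B{i:05d}" for i in contam_idx}
    return casts, bottles


# ---------------------------------------------------------------------------
# transcript count matrix
# ---------------------------------------------------------------------------

_DEFAULT_TAXA = {
    "Prochlorococcus": "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Prochloraceae;Prochlorococcus",
    "Rhodobacterales": "Bacteria;Proteobacteria;Alphaproteobacteria;Rhodobacterales;Rhodobacteraceae;Ruegeria",
    "Flavobacteriales": "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Polaribacter",
    "Oceanospirillales": "Bacteria;Proteobacteria;Gammaproteobacteria;Oceanospirillales;Oceanospirillaceae;Oceanospirillum",
    "Dinophyceae": "Eukaryota;Dinoflagellata;Dinophyceae;Gymnodiniales;Gymnodiniaceae;Gymnodinium",
}


@dataclass
class CountsConfig:
    """Negative-binomial taxon x KO transcript counts with planted effects.

    The planted effect is the Prochlorococcus ammonium transporter (amt,
    K03320) whose KO:rpoB ratio is raised at the SOM (default 2.5, the
    highest observed Prochlorococcus ratio) plus a dusk (night) increase
    in the mixed layer and SOM but not the DCM.  Null KOs share one
    baseline ratio across layers.  Effects are planted on the normalized
    log2 scale so the planted ratio is the expected value of the ratio
    statistic the pipeline computes.
    """

    seed: int = 0
    n_per_layer: int = 12             # 6 day + 6 night samples per layer
    n_null_kos: int = 20
    rpob_base_count: int = 63         # log2(63+1) = 6 on the normalized scale
    null_ratio: float = 1.2
    amt_ratio_som: float = 2.5
    amt_ratio_other: float = 1.5
    amt_dusk_factor: float = 1.15     # night multiplier on amt ratio, SRF/BML/SOM
    dispersion: float = 50.0          # NB size parameter; larger = less noise
    libsize_cv: float = 0.2
    sag_genome_genes: int = 100
    sag_detected_genes: int = 9       # < 10% => the genome is filtered out
    taxa: dict = field(default_factory=lambda: dict(_DEFAULT_TAXA))
    noise_scale: float = 1.0


def _nb_draw(rng, mean, size_param, noise_scale):
    mean = np.asarray(mean, dtype=float)
    if noise_scale == 0 or size_param == np.inf:
        return np.round(mean).astype(int)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def gen_count_matrix(cfg: CountsConfig | None = None) -> CountMatrix:
    """Simulate the annotated gene x sample transcript count matrix."""
    cfg = cfg or CountsConfig()
    rng = np.random.default_rng(cfg.seed)
    layers = ("SRF", "BML", "SOM", "DCM")

    # sample metadata: alternating day/night across 6 days
    sample_ids, meta_rows = [], []
    for L in layers:
        for r in range(cfg.n_per_layer):
            tc = "day" if r % 2 == 0 else "night"
            sid = f"{L}_{r:02d}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "layer": L, "time_class": tc,
                              "date": (datetime(2019, 10, 12) + timedelta(days=r % 6)).date().isoformat()})
    samples = pd.DataFrame(meta_rows).set_index("sample_id")
    layer_of = samples["layer"]
    time_of = samples["time_class"]

    libsize = _lognormal_factor(rng, cfg.noise_scale * cfg.libsize_cv,
                                size=len(sample_ids))
    v_rpob = np.log2(cfg.rpob_base_count + 1)

    gene_ids, ann_rows, count_rows = [], [], []

    def add_gene(gene_id, taxon_path, ko, genome_id, mean_per_sample):
        gene_ids.append(gene_id)
        ann_rows.append({"taxon_path": taxon_path, "ko": ko, "genome_id": genome_id})
        count_rows.append(_nb_draw(rng, mean_per_sample * libsize,
                                   cfg.dispersion if cfg.noise_scale else np.inf,
                                   cfg.noise_scale))

    for taxon, path in cfg.taxa.items():
        rpob_ko = "K03006" if path.startswith("Eukaryota") else "K04043"
        add_gene(f"{taxon}_rpoB", path, rpob_ko, "",
                 np.full(len(sample_ids), float(cfg.rpob_base_count)))
        for j in range(cfg.n_null_kos):
            ko = f"K{90000 + j:05d}"
            mean = 2.0 ** (cfg.null_ratio * v_rpob) - 1.0
            add_gene(f"{taxon}_{ko}", path, ko, "",
                     np.full(len(sample_ids), mean))
        if taxon == "Prochlorococcus":
            targets = np.where(layer_of.to_numpy() == "SOM",
                               cfg.amt_ratio_som, cfg.amt_ratio_other)
            # dusk effect in the mixed layer and SOM, not the DCM; day and
            # night planted so the day/night average equals the layer target
            has_dusk = layer_of.to_numpy() != "DCM"
            day_ratio = np.where(has_dusk,
                                 targets * 2.0 / (1.0 + cfg.amt_dusk_factor),
                                 targets)
            ratios = np.where(has_dusk & (time_of.to_numpy() == "night"),
                              day_ratio * cfg.amt_dusk_factor, day_ratio)
            mean = 2.0 ** (ratios * v_rpob) - 1.0
            add_gene("Prochlorococcus_amt", path, "K03320", "", mean)

    # genome-linked rows exercising the SAG detection filters
    pro_path = cfg.taxa.get("Prochlorococcus", next(iter(cfg.taxa.values())))
    for g in range(cfg.sag_genome_genes):
        mean = 30.0 if g < cfg.sag_detected_genes else 0.0
        add_gene(f"SAG1_g{g:03d}", pro_path, "", "SAG1",
                 np.full(len(sample_ids), mean))

    counts = pd.DataFrame(np.vstack(count_rows), index=gene_ids, columns=sample_ids)
    annotations = pd.DataFrame(ann_rows, index=gene_ids)
    return CountMatrix(counts=counts, annotations=annotations, samples=samples)


# ---------------------------------------------------------------------------
# polony / flow-cytometry table
# ---------------------------------------------------------------------------


@dataclass
class PolonyConfig:
    """Lognormal abundances by layer with the observed fold structure.

    Free-phage and infected-cell defaults reproduce the reported SOM
    contrasts (free T4: 3.12x vs SRF, 5.54x vs BML; free T7: 19.62x /
    15.42x / 2.79x vs SRF / BML / DCM; T4-infected: 11.70x vs SRF, 3.44x
    vs BML; T7-infected: 11.26x / 5.42x) and infected fractions (T4 2.8%,
    T7 4.1% at the SOM).  Cell counts encode the heterotroph:Prochlorococcus
    ratios 4.4 (SOM) and 8.2 (mixed layer).  Replicates: SRF 10, BML 6,
    SOM 14, DCM 10; infected-cell columns are missing on 4 SOM rows
    (the infection assay ran 10 there).
    """

    seed: int = 0
    n_replicates: dict = field(default_factory=lambda: {
        "SRF": 10, "BML": 6, "SOM": 14, "DCM": 10})
    n_ipolony_som: int = 10
    # Prochlorococcus / Synechococcus / heterotroph means (cells per mL)
    pro_mean: dict = field(default_factory=lambda: {
        "SRF": 1.0e5, "BML": 1.0e5, "SOM": 2.0e5, "DCM": 5.0e4})
    syn_mean: dict = field(default_factory=lambda: {
        "SRF": 1.0e4, "BML": 1.0e4, "SOM": 8.0e3, "DCM": 2.0e3})
    het_to_pro_som: float = 4.4
    het_to_pro_ml: float = 8.2
    het_mean_dcm: float = 4.0e5
    # free phages per mL at the SOM and SOM-vs-layer folds
    free_t4_som: float = 1.0e5
    free_t4_folds: dict = field(default_factory=lambda: {
        "SRF": 3.12, "BML": 5.54, "DCM": 1.5})
    free_t7_som: float = 6.0e4
    free_t7_folds: dict = field(default_factory=lambda: {
        "SRF": 19.62, "BML": 15.42, "DCM": 2.79})
    # infected fractions of Prochlorococcus at the SOM and SOM-vs-layer
    # folds of infected-cell concentrations
    frac_t4_som: float = 0.028
    t4_infected_folds: dict = field(default_factory=lambda: {
        "SRF": 11.70, "BML": 3.44, "DCM": 2.0})
    frac_t7_som: float = 0.041
    t7_infected_folds: dict = field(default_factory=lambda: {
        "SRF": 11.26, "BML": 5.42, "DCM": 1.0})
    phage_cv: float = 0.35
    cell_cv: float = 0.2
    noise_scale: float = 1.0


def _infected_fraction(cfg, phage, layer):
    """Back out the per-layer infected fraction from the planted folds."""
    frac_som = cfg.frac_t4_som if phage == "t4" else cfg.frac_t7_som
    if layer == "SOM":
        return frac_som
    folds = cfg.t4_infected_folds if phage == "t4" else cfg.t7_infected_folds
    infected_som = cfg.pro_mean["SOM"] * frac_som
    return infected_som / folds[layer] / cfg.pro_mean[layer]


def gen_polony_table(cfg: PolonyConfig | None = None) -> pd.DataFrame:
    """Simulate the per-sample polony / iPolony / flow-cytometry table."""
    cfg = cfg or PolonyConfig()
    rng = np.random.default_rng(cfg.seed)
    ns = cfg.noise_scale
    rows = []
    for layer, n in cfg.n_replicates.items():
        het_mean = (cfg.het_to_pro_som * cfg.pro_mean["SOM"] if layer == "SOM"
                    else cfg.het_to_pro_ml * cfg.pro_mean[layer]
                    if layer in ("SRF", "BML") else cfg.het_mean_dcm)
        t4_mean = cfg.free_t4_som / cfg.free_t4_folds.get(layer, 1.0) \
            if layer != "SOM" else cfg.free_t4_som
        t7_mean = cfg.free_t7_som / cfg.free_t7_folds.get(layer, 1.0) \
            if layer != "SOM" else cfg.free_t7_som
        f_t4 = _infected_fraction(cfg, "t4", layer)
        f_t7 = _infected_fraction(cfg, "t7", layer)
        for r in range(n):
            pro = cfg.pro_mean[layer] * _lognormal_factor(rng, ns * cfg.cell_cv)
            syn = cfg.syn_mean[layer] * _lognormal_factor(rng, ns * cfg.cell_cv)
            het = het_mean * _lognormal_factor(rng, ns * cfg.cell_cv)
            if ns == 0:
                inf_t4 = f_t4 * pro
                inf_t7 = f_t7 * pro
            else:
                inf_t4 = float(rng.binomial(int(round(pro)), f_t4))
                inf_t7 = float(rng.binomial(int(round(pro)), f_t7))
            ipolony_missing = layer == "SOM" and r >= cfg.n_ipolony_som
            rows.append({
                "sample_id": f"{layer}_{r:02d}",
                "layer": layer,
                "time_class": "day" if r % 2 == 0 else "night",
                "replicate": r,
                "free_t4": t4_mean * _lognormal_factor(rng, ns * cfg.phage_cv),
                "free_t7": t7_mean * _lognormal_factor(rng, ns * cfg.phage_cv),
                "infected_t4": np.nan if ipolony_missing else inf_t4,
                "infected_t7": np.nan if ipolony_missing else inf_t7,
                "prochlorococcus": pro,
                "synechococcus": syn,
                "total_bacteria": pro + syn + het,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# paired Prochlorococcus / VLP abundances
# ---------------------------------------------------------------------------


@dataclass
class VlpConfig:
    """Monthly log-log power-law coupled virus/host pairs (104 total)."""

    seed: int = 0
    n_total: int = 104
    exponent: dict = field(default_factory=lambda: {m: 1.5 for m in range(1, 13)})
    log10_intercept: float = -0.5
    pro_log10_mean: float = 5.0
    pro_log10_sd: float = 0.3
    noise_log10_sd: float = 0.15
    noise_scale: float = 1.0


def gen_vlp_pairs(cfg: VlpConfig | None = None) -> pd.DataFrame:
    """Simulate monthly paired Prochlorococcus and VLP abundances.

    A latent log10 host abundance u drives both observations:
    log10 Pro = u + e_x and log10 VLP = intercept + exponent * u + e_y,
    with e_x, e_y iid N(0, noise_log10_sd^2).  Both counts carry equal
    measurement error -- the regime in which the major-axis slope is a
    consistent estimator of the exponent, and the reason a type-II fit is
    used on such data in the first place.  Noiseless mode collapses to the
    exact power law VLP = 10^intercept * Pro^exponent.
    """
    cfg = cfg or VlpConfig()
    if any(v <= 0 for v in (10**cfg.pro_log10_mean, 10**cfg.log10_intercept)):
        raise ValueError("config abundances must be positive")
    rng = np.random.default_rng(cfg.seed)
    base, extra = divmod(cfg.n_total, 12)
    rows = []
    for m in range(1, 13):
        n = base + (1 if m <= extra else 0)
        latent = cfg.pro_log10_mean + cfg.pro_log10_sd * rng.standard_normal(n)
        err = cfg.noise_scale * cfg.noise_log10_sd
        log_pro = latent + err * rng.standard_normal(n)
        log_vlp = cfg.log10_intercept + cfg.exponent[m] * latent \
            + err * rng.standard_normal(n)
        for lp, lv in zip(log_pro, log_vlp):
            rows.append({"month": m, "prochlorococcus": 10**lp, "vlp": 10**lv})
    return pd.DataFrame(rows)


def config_provenance(cfg) -> dict:
    """Serializable record of the generator configuration for run manifests."""
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, datetime):
            d[k] = v.isoformat()
    return d


def with_overrides(cfg, **kw):
    """Replace selected config fields (dataclasses.replace convenience)."""
    return replace(cfg, **kw)
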