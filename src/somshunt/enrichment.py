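"""KO : rpoB transcript-ratio enrichment across depth layers.

A gene x sample count matrix with taxonomy, KEGG-orthology and genome
annotations is filtered, normalized with a variance-stabilizing surrogate
(median-of-ratios size factors + shifted log2), aggregated to taxon
aggregates (order level for heterotrophic bacteria, genus for
cyanobacteria, class for eukaryotes), and expressed as the ratio of each
KO's normalized signal to the taxon's summed rpoB/RPB1 (K04043/K03006)
housekeeping signal.  Per-feature Kruskal-Wallis + Dunn contrasts across
the four depth layers with a single Benjamini-Hochberg family decide
whether a (taxon, KO) feature is ELEVATED or DEPLETED at the subsurface
oxygen maximum relative to all other layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bh_adjust, dunn_posthoc, kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "RatioTable",
    "DepthComparisonResult",
    "LAYERS",
    "RPOB_KOS",
    "read_counts",
    "apply_detection_filters",
    "vst_normalize",
    "aggregate_and_ratio",
    "depth_enrichment",
    "diel_contrast",
]

LAYERS = ("SRF", "BML", "SOM", "DCM")
RPOB_KOS = frozenset({"K04043", "K03006"})


@dataclass
class CountMatrix:
    """Gene x sample counts plus row annotations and sample metadata.

    ``counts``: DataFrame (genes x samples, nonnegative integers).
    ``annotations``: DataFrame indexed like ``counts`` with columns
    taxon_path (semicolon path domain;phylum;class;order;family;genus),
    ko (KEGG id or empty), genome_id (for genome-linked rows, else empty).
    ``samples``: DataFrame indexed by sample id with columns layer
    (SRF/BML/SOM/DCM), time_class (day/night), date.
    """

    counts: pd.DataFrame
    annotations: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def is_rpob(self) -> pd.Series:
        return self.annotations["ko"].isin(RPOB_KOS)


@dataclass
class RatioTable:
    """(taxon aggregate, KO) x sample matrix of KO:rpoB ratios."""

    ratios: pd.DataFrame  # MultiIndex (taxon, ko) rows
    samples: pd.DataFrame


@dataclass
class DepthComparisonResult:
    taxon: str
    ko: str
    group_means: dict
    kw_statistic: float
    kw_p: float
    pairs: list = field(default_factory=list)  # (layer_i, layer_j, z, p_raw, p_adj)
    call: str = "NONE"


def read_counts(counts_path, meta_path) -> CountMatrix:
    """Load the counts TSV (gene_id, taxon_path, ko, genome_id, samples...)
    and the sample metadata TSV (sample_id, layer, time_class, date)."""
    df = pd.read_csv(counts_path, sep="\t", dtype={"gene_id": str})
    df = df.set_index("gene_id")
    ann_cols = ["taxon_path", "ko", "genome_id"]
    annotations = df[ann_cols].fillna("")
    counts = df.drop(columns=ann_cols).astype(float).round().astype(int)
    samples = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return CountMatrix(counts=counts, annotations=annotations, samples=samples)


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def apply_detection_filters(cm: CountMatrix, min_mean_reads: float = 10.0,
                            sag_min_gene_frac: float = 0.10,
                            min_gene_reads: int = 20) -> CountMatrix:
    """Detection filters, each evaluated on the input matrix.

    1. ORFs with dataset-mean count < ``min_mean_reads`` are dropped.
    2. Genome-linked genes with fewer than ``min_gene_reads`` total reads
       are dropped.
    3. Genomes with fewer than ``sag_min_gene_frac`` of their genes
       detected (total reads > 0) are dropped entirely.

    All three rules are computed from the original counts, so the survivor
    set does not depend on the order of application.
    """
    counts = cm.counts
    mean_ok = counts.mean(axis=1) >= min_mean_reads

    genome = cm.annotations["genome_id"].fillna("")
    has_genome = genome != ""
    totals = counts.sum(axis=1)
    gene_reads_ok = ~has_genome | (totals >= min_gene_reads)

    detected = totals > 0
    frac = detected.groupby(genome).mean()
    genome_ok = ~has_genome | genome.map(frac).ge(sag_min_gene_frac)

    keep = mean_ok & gene_reads_ok & genome_ok
    if not keep.any():
        logger.warning("detection filters removed every gene")
    return CountMatrix(counts=counts.loc[keep],
                       annotations=cm.annotations.loc[keep],
                       samples=cm.samples)


def vst_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Variance-stabilizing surrogate: median-of-ratios size factors
    followed by a shifted log2 transform, log2(count / sf + 1).

    Size factors are medians of per-sample ratios to the gene-wise
    geometric mean, over genes with nonzero counts in every sample.  When
    no such gene exists, total-count size factors (scaled to geometric
    mean 1) are used instead, with a log entry.  Zeros map to 0.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_nonzero = (counts > 0).all(axis=1)
    if all_nonzero.any():
        sub = counts[all_nonzero]
        log_geomean = np.log(sub).mean(axis=1)
        sf = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    else:
        logger.info("no gene nonzero in all samples; total-count size factors")
        tot = counts.sum(axis=0)
        if (tot == 0).any():
            raise ValueError("a sample has zero total counts")
        sf = tot / np.exp(np.mean(np.log(tot)))
    norm = np.log2(counts / sf + 1.0)
    return pd.DataFrame(norm, index=cm.counts.index, columns=cm.counts.columns)


# ---------------------------------------------------------------------------
# taxon aggregation and the ratio statistic
# ---------------------------------------------------------------------------

_PATH_LEVELS = ("domain", "phylum", "class", "order", "family", "genus")


def taxon_aggregate(taxon_path: str) -> str:
    """Aggregation label: order for heterotrophic bacteria (Bacteria minus
    Cyanobacteria) and archaea, genus for cyanobacteria, class for
    eukaryotes."""
    parts = [p.strip() for p in str(taxon_path).split(";")]
    parts += [""] * (len(_PATH_LEVELS) - len(parts))
    domain, phylum, cls, order, _family, genus = parts[:6]
    if domain == "Eukaryota":
        return cls or domain
    if phylum == "Cyanobacteria":
        return genus or phylum
    return order or domain


def aggregate_and_ratio(norm: pd.DataFrame, annotations: pd.DataFrame,
                        samples: pd.DataFrame) -> RatioTable:
    """Sum normalized values per (taxon aggregate, KO, sample) and divide
    by the taxon's summed rpoB/RPB1 normalized value in the same sample.

    Ratios are NaN wherever the denominator is zero; taxa without any
    rpoB/RPB1 row get all-NaN ratios (logged).
    """
    agg = annotations["taxon_path"].map(taxon_aggregate)
    ko = annotations["ko"].fillna("")
    is_rpob = ko.isin(RPOB_KOS)

    denom = norm[is_rpob.to_numpy()].groupby(agg[is_rpob]).sum()
    has_ko = (ko != "") & ~is_rpob
    num = norm[has_ko.to_numpy()].groupby([agg[has_ko], ko[has_ko]]).sum()
    num.index.names = ["taxon", "ko"]

    taxa = num.index.get_level_values("taxon")
    missing = sorted(set(taxa) - set(denom.index))
    if missing:
        logger.warning("taxa without rpoB/RPB1 rows: %s", missing)
    den_aligned = denom.reindex(taxa)
    den_aligned.index = num.index
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = num / den_aligned.where(den_aligned > 0)
    return RatioTable(ratios=ratios, samples=samples)


# ---------------------------------------------------------------------------
# depth enrichment and diel contrast
# ---------------------------------------------------------------------------


def depth_enrichment(rt: RatioTable, alpha: float = 0.1,
                     mode: str = "pooled") -> list[DepthComparisonResult]:
    """SOM elevated/depleted calls per (taxon, KO) feature.

    Per feature: Kruskal-Wallis across the four layers, Dunn pairwise
    z / p, then one Benjamini-Hochberg family over all (feature, pair)
    raw p-values of the run.  ELEVATED requires the SOM mean to exceed
    every other layer's mean AND all three SOM-vs-other adjusted p <=
    ``alpha``; DEPLETED is symmetric; otherwise NONE.  ``mode`` pools day
    and night ("pooled") or restricts to one time class ("day"/"night").
    Features with fewer than 2 samples in any populated layer are skipped.
    """
    if mode == "pooled":
        meta = rt.samples
    elif mode in ("day", "night"):
        meta = rt.samples[rt.samples["time_class"] == mode]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    layer_samples = {L: meta.index[meta["layer"] == L].tolist() for L in LAYERS}

    results = []
    raw_record = []  # (result_idx, pair_idx)
    raw_ps = []
    for (taxon, ko), row in rt.ratios.iterrows():
        groups, names = [], []
        for L in LAYERS:
            vals = row[[s for s in layer_samples[L] if s in row.index]].dropna().to_numpy()
            if vals.size:
                groups.append(vals)
                names.append(L)
        if len(names) < 2 or any(g.size < 2 for g in groups):
            continue
        gc = dunn_posthoc(groups)
        res = DepthComparisonResult(
            taxon=taxon, ko=ko,
            group_means=dict(zip(names, gc.group_means)),
            kw_statistic=gc.kw_statistic, kw_p=gc.kw_p,
        )
        for pr in gc.pairs:
            res.pairs.append([names[pr.group_i], names[pr.group_j],
                              pr.dunn_z, pr.dunn_p_raw, np.nan])
            raw_record.append((len(results), len(res.pairs) - 1))
            raw_ps.append(pr.dunn_p_raw)
        results.append(res)

    adj = bh_adjust(raw_ps) if raw_ps else np.array([])
    for (ri, pi), pa in zip(raw_record, adj):
        results[ri].pairs[pi][4] = float(pa)

    for res in results:
        means = res.group_means
        others = [L for L in means if L != "SOM"]
        if "SOM" not in means or len(others) < 3:
            continue
        som_pairs = {tuple(sorted((a, b))): p_adj
                     for a, b, _z, _p, p_adj in res.pairs}
        sig = all(som_pairs.get(tuple(sorted(("SOM", L))), 1.0) <= alpha
                  for L in others)
        if sig and all(means["SOM"] > means[L] for L in others):
            res.call = "ELEVATED"
        elif sig and all(means["SOM"] < means[L] for L in others):
            res.call = "DEPLETED"
    return results


def enrichment_frame(results) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"taxon": r.taxon, "ko": r.ko, "kw_statistic": r.kw_statistic,
               "kw_p": r.kw_p, "call": r.call}
        for L, m in r.group_means.items():
            row[f"mean_{L}"] = m
        for a, b, z, p, pa in r.pairs:
            row[f"p_adj_{a}_{b}"] = pa
        rows.append(row)
    return pd.DataFrame(rows)


def diel_contrast(rt: RatioTable, taxon: str, ko: str) -> pd.DataFrame:
    """Night/day mean-ratio contrast of one feature per layer, with a
    two-group rank test p (Kruskal-Wallis on two groups = Mann-Whitney)."""
    row = rt.ratios.loc[(taxon, ko)]
    meta = rt.samples
    out = []
    for L in LAYERS:
        day = row[meta.index[(meta["layer"] == L) & (meta["time_class"] == "day")]].dropna()
        night = row[meta.index[(meta["layer"] == L) & (meta["time_class"] == "night")]].dropna()
        if day.empty or night.empty:
            continue
        h, p = kruskal_wallis([night.to_numpy(), day.to_numpy()])
        out.append({"layer": L, "mean_day": day.mean(), "mean_night": night.mean(),
                    "night_over_day": night.mean() / day.mean() if day.mean() != 0 else np.nan,
                    "p": p})
    return pd.DataFrame(out)
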