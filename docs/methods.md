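# Methods

This note documents the models and procedures implemented in `somshunt`,
the defaults that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was open.

## Profile processing

Casts are averaged to the nearest 0.5 m depth bin, then every variable is
smoothed along pressure with a Nadaraya–Watson estimator using a Gaussian
kernel, `exp(-d²/2h²)` with h = 5 db by default.  The Gaussian (rather
than a compact-support) kernel was chosen because its strictly positive
weights fill isolated missing bins without empty-window failures; "bandwidth"
is the Gaussian scale parameter.  Smoothing runs on pressure, binning and
layer statistics on depth; in the shallow (< 250 m) regime treated here
the two coordinates are interchangeable at the 1 db ≈ 1 m level and the
generators emit both.

Thermodynamics: sigma-theta is computed from the UNESCO 1983 (EOS-80)
surface-density polynomial evaluated at the potential temperature obtained
by the standard 4th-order Runge–Kutta integration of the Fofonoff
adiabatic lapse rate; oxygen solubility (µmol/kg) uses the Garcia–Gordon
combined fit.  All three routines are pinned to published check values
(σ(35, 5, 0) = 27.67547 kg/m³; θ(40, 40, 10000 db) = 36.89073 °C;
O₂sol(35, 10 °C) = 274.61 µmol/kg) at 1e-4 absolute tolerance.  For the
near-surface differences this pipeline measures, EOS-80 and the full
TEOS-10 stack differ negligibly (≲0.01 kg/m³ in σθ).  A pass-through mode
accepts pre-computed σθ/saturation so the pipeline runs without any
thermodynamic input.

**Mixed-layer depth.**  σθ at the 10 db reference is linearly
interpolated; the MLD is the shallowest depth where σθ exceeds the
reference by 0.125 kg/m³ (default), linearly interpolated between the
bracketing bins to avoid grid-resolution bias.  Casts with no data in the
top 10 db cannot supply the reference and are rejected with a QC flag.
The SOM band is the depth range with σθ in (σθ(MLD), σθ(MLD)+0.1]; its
reported scalar depth is the saturation-argmax inside the band, a
reproducible summary of a band definition.  If density jumps by more than
the band width immediately below the MLD the band degenerates to zero
thickness and is flagged rather than silently extended.

**Layers.**  Fixed windows (mixed layer 5–40 m, SOM 50–60 m,
DCM 100–120 m) are used for all layer statistics; the base of the mixed
layer is treated as part of the mixed layer.  Contrasts are means and
standard deviations of per-cast differences (oxygen, saturation) and
per-cast ratios (beam attenuation, chlorophyll).

## Climatology

Calibration regresses optode oxygen on Winkler oxygen (OLS).  Residuals
are internally studentized, `e/(s√(1−h))` — the conventional statistic for
an outlying calibration point; a cast is discarded if *any* of its pairs
reaches |residual| ≥ 3.  The regression is deliberately fit once on all
pairs: rejection is a QC sweep, not an iterative robust fit, and
re-running the sweep on the retained pairs of a clean record rejects
nothing further.

The seasonal model is y = a + b·sin(2π(c+t)) with t ∈ [0, 1) a leap-aware
decimal year.  It is estimated by the exact linear reparameterization
a + B₁sin(2πt) + B₂cos(2πt), so there is no initialization, convergence
tolerance, or local-optimum issue; (b, c) are recovered from (B₁, B₂) and
standard errors follow from the OLS covariance by the delta method.  The
pair (b, c) is only identified up to (b, c) ↔ (−b, c+½); output is
canonicalized to c ∈ [0.5, 1.0), a fixed convention that makes the
reported parameterization unique.  When the Wald test of amplitude > 0
has p > 0.05 the phase is declared unidentifiable and c and the extrema
are reported as NaN.  The fitted extrema are always half a year apart by
the symmetry of the sine.

The climatology grid bins saturation into 5 m × 12-day cells (30 full
bins plus a 5–6 day remainder bin closing the year), the MLD curve into
10-day bins, and the isopycnal series into 0.1 kg/m³ σθ classes with
edges at multiples of 0.1.

## Rhythm detection

Layer time series (4-hourly, detrended by OLS) are pooled into
m = period/interval phase classes.  For each candidate peak class the
Mack–Wolfe umbrella statistic — the sum of Mann–Whitney pair counts
consistent with a monotone rise to the peak and fall after it, with the
trough fixed half a period away — is compared to its exact null mean and
variance under a normal approximation; the best ordering is
Bonferroni-corrected over the m candidates.  The correction is
conservative (the m orderings are positively dependent), which the null
calibration test confirms (~4 % rejections at α = 0.05).  Ties enter the
statistic as half-counts and the variance through the Kruskal–Wallis-style
tie factor; the variance formula is exact only for continuous data, an
approximation that is irrelevant for the continuous series treated here.
The test depends on the data only through ranks and is invariant to
monotone transforms.

## Transcript enrichment

Detection filters: ORFs need a dataset-mean count ≥ 10; genome-linked
genes need ≥ 20 total reads; genomes need ≥ 10 % of their genes detected.
Each rule is evaluated on the input matrix, making the combined filter
the order-independent intersection of the three rules.

Normalization is a variance-stabilizing surrogate: size factors by
median-of-ratios over genes nonzero in every sample, then
log₂(count/sf + 1).  This preserves the structure the enrichment rule
depends on — cross-sample ranks within a feature — for moderate counts,
without a dispersion model; zeros map to zero, and two proportionally
scaled samples become identical.  An external variance-stabilizing
transform can be substituted at this interface for real-data runs.

The ratio statistic divides each taxon aggregate's summed normalized KO
signal by the same aggregate's summed rpoB/RPB1 (K04043/K03006) signal in
the same sample, correcting gene signal for taxon activity; aggregates
are order-level for heterotrophic bacteria (Bacteria minus Cyanobacteria),
genus-level for cyanobacteria, class-level for eukaryotes.  Ratios are
undefined where the housekeeping denominator is zero.

Depth calls: per feature, Kruskal–Wallis across the four layers and
Dunn's pairwise z with midranks and tie correction; *all* (feature, pair)
raw p-values of a run form one Benjamini–Hochberg family — the most
conservative plausible family.  ELEVATED requires the SOM mean to exceed
every other layer with all three SOM contrasts at adjusted p ≤ 0.1;
DEPLETED is symmetric.  Day and night samples are pooled by default; a
day- or night-only mode is available since the sampling design resolves
both (the choice between pooling and splitting is genuinely open; pooling
is the default because it uses all replicates).

## Virus/host statistics

Percent infected is 100 × infected cells / *Prochlorococcus* per phage
class, with the total the exact sum of classes.  Heterotrophs are total
SYBR-positive counts minus cyanobacteria, floored at zero with a warning.
Fold changes are ratios of layer means (medians by flag), pooled over
day/night, with the same KW/Dunn/BH machinery.  The monthly power law
fits a major-axis (type-II) line to (log₁₀ Pro, log₁₀ VLP); the slope is
the power-law exponent.  Significance comes from permuting y against x;
exceedance is measured on |r| rather than the slope because the MA slope
magnitude is minimized, not maximized, by strong association (for fixed
marginal variances, any permutation that weakens the covariance inflates
the slope toward ±∞), so the absolute-correlation tail is the one that
corresponds to a significant fit.  The add-one estimator keeps
permutation p-values in [1/(B+1), 1]; B = 10 000 by default.

## Synthetic generators

The generators reproduce the *statistical structure* of each input
stream with the study's reported effect sizes as defaults, so the
estimators run against known ground truth:

* **Cruise** (36 casts, 4-hourly, 0–200 m at 0.5 m): uniform σθ above a
  ~50 m pycnocline (MLD 52 m), piecewise-linear oxygen/saturation
  profiles encoding SOM−ML = +22.14 µmol/kg and +6.47 pp saturation,
  SOM−DCM = +17.43 µmol/kg and +13.9 pp, beam-attenuation ratios
  SOM/ML = 1.09 and SOM/DCM = 1.52 with a 5 % 24 h modulation peaking at
  18:00, and chlorophyll SOM/DCM = 26.9 % — each with the reported
  between-cast sd as Gaussian noise on the per-cast deltas.  The raw
  (T, S) variant inverts the EOS-80 density polynomial at constant
  salinity so derived σθ matches the pass-through field.
* **Climatology** (5270 casts over 31 years): sub-MLD saturation follows
  a + b·sin(2π(c+t)) with (a, b, c) = (102.0, −2.993, 0.5924) and 1.5 pp
  residual noise; the MLD cycles smoothly between ~200 m (winter) and
  ~50 m (summer); 1000 bottle pairs lie on optode = 7.85 + 0.964·Winkler
  with 2 µM noise, and 26 casts carry a +60 µM gross optode offset on
  both their pairs and their profiles.
* **Counts**: negative-binomial counts for 5 taxa × 20 null KOs plus one
  rpoB row each and a 100-gene genome block exercising the detection
  filters; 12 samples per layer (6 day + 6 night over 6 days, the cruise
  metatranscriptome design).  The planted effect is *amt* (K03320) in
  *Prochlorococcus* with a SOM ratio of 2.5 versus 1.5 elsewhere and a
  ×1.15 dusk factor outside the DCM, planted on the normalized log₂
  scale so the planted ratio is the expected value of the statistic the
  pipeline computes.
* **Polony** (SRF 10, BML 6, SOM 14, DCM 10 replicates; infected-cell
  columns missing on 4 SOM rows where the infection assay ran 10):
  mean-preserving lognormal abundances with the reported fold structure
  (free T4 3.12×/5.54× vs SRF/BML; free T7 19.62×/15.42×/2.79×;
  T4-infected 11.70×/3.44×; T7-infected 11.26×/5.42×), binomial infected
  cells at SOM fractions 2.8 % (T4) and 4.1 % (T7), and cell counts
  encoding heterotroph:*Prochlorococcus* = 4.4 (SOM) vs 8.2 (mixed
  layer).  Abundance noise is lognormal (cv 0.35 phages, 0.2 cells) —
  positive and right-skewed, matching plankton/phage count behaviour —
  matched to the reported spreads on the natural scale.
* **VLP pairs** (104 over 12 months): a latent log₁₀ host abundance
  drives both observations with equal N(0, 0.15²) measurement error —
  the regime in which the major-axis slope is a consistent estimator of
  the exponent, and the reason a type-II fit is appropriate for such
  data.  Default exponent 1.5 per month.

Every generator is a pure function of its config (seed included), and
every config has a `noise_scale`; at `noise_scale = 0` downstream
estimators return the planted parameters exactly, which the tests assert.

What the generators do **not** emulate: vertical covariance structure
beyond the piecewise layer means, sensor drift and despiking artifacts,
year-to-year trends in the climatology, taxon co-occurrence and
compositional coupling in the count matrix, or any mechanistic
virus–host dynamics.  Passing tests therefore demonstrate that the
estimators recover known effects under realistic noise and sampling
designs — not that real-data complications (autocorrelation, batch
effects, annotation error) are handled.

A documented inconsistency carried as-is: the seasonal-law default
constants place the sub-MLD saturation maximum in late winter and
minimum in August; the reported narrative of an August maximum is not
arithmetically consistent with those printed constants, and no
reconciliation is attempted — the generator encodes the constants, and
recovery is asserted against them.

## Numerical choices and degenerate inputs

* Ties: midranks everywhere; Kruskal–Wallis on all-identical data is
  defined as H = 0, p = 1.
* Permutation p-values use the add-one estimator; seeds are explicit
  arguments, never global state.
* A noiseless calibration line yields studentized residuals defined as 0.
* Empty SOM bands, missing layers, casts without top-10 db data, taxa
  without housekeeping rows, and zero-*Prochlorococcus* samples all
  produce flagged/NaN outputs rather than exceptions, except where the
  operation is meaningless (no casts, constant x in a regression).
* Problem sizes in the test suite and the acceptance script (full
  5270-cast record; 100–200 polony replicate cruises; 1000-series null
  calibration) were chosen to give stable Monte-Carlo estimates on a
  single CPU in seconds.

## Known limitations

The VST surrogate is not a dispersion-based variance-stabilizing
transform; heavily overdispersed low-count features will stabilize less
well.  The umbrella test's Bonferroni correction over peak phases is
conservative.  The EOS-80 port omits the full pressure-dependent equation
of state (only surface-referenced potential density is needed here).
Fold changes are ratios of means; back-transformed log-scale means would
differ for highly skewed data and are available only via the median flag.
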