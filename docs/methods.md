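# Methods

`pamox` quantifies cerebral hemodynamics and oxygen metabolism from
multi-parametric photoacoustic microscopy (PAM) data, and mitochondrial
bioenergetics from Clark-electrode and fluorometer traces.  Because the
workflow is normally driven by animal experiments, the package ships a
synthetic-data generator that emulates every input with known ground
truth, so each stage — and the full chain — is validated by parameter
recovery rather than by comparison to a dataset it cannot ship.

## The metabolic model

Regional oxygen metabolism follows the standard microvascular formulation:

* **Per-vessel flux.** A vessel with lumen diameter `d` and peak axial flow
  speed `v` carries the volumetric flux of a parabolic (Poiseuille) velocity
  profile, `F = π v d² / 8` — mean speed `v/2` times cross-section
  `π d²/4`.  The denominator 8 is therefore part of the model, not a typo.
* **Regional CBF.** The fluxes of the feeding arteries of a hemicortical
  region are summed and normalized by the region mass, giving cerebral blood
  flow in mL/100 g/min.  The default region mass is 0.002 g, representing
  one hemicortical imaging region of a neonatal mouse; it is a configuration
  input because a projected 2-D image cannot measure the perfused mass.
* **OEF.** The oxygen extraction fraction is
  `OEF = (s_aO2 − s_vO2) / s_aO2`, where `s_aO2` and `s_vO2` are the
  oxygen saturations of the feeding arteries and draining veins.  Per-vessel
  saturations are aggregated flow-weighted by default (a mass-balance
  argument: a large artery contributes proportionally to its flux); a
  uniform mean is available for sensitivity checks.  A venous saturation
  above the arterial one produces a flagged, unclipped negative OEF rather
  than a silent correction.
* **CMRO2.** `CMRO2 = ξ · C_Hb · s_aO2 · OEF · CBF`, with
  ξ = 0.014 L O2 per gram hemoglobin (the oxygen-binding capacity) and
  `C_Hb` the total hemoglobin concentration in g/L.  `ξ·C_Hb` is
  dimensionless as mL O2 per mL blood, so CMRO2 carries CBF's
  per-100-g-per-minute units.

Percent-of-baseline values are rounded half-up to integers, matching the
convention of the hemodynamic literature this package serves.

## PAM signal chain

**Envelope and projection.**  Each A-line is reduced to the magnitude of
its analytic signal (Hilbert transform); an image pixel is the maximum of
its A-line envelope.  Envelope values within about one carrier period of
the record ends carry the usual analytic-signal edge artifact and are
excluded from accuracy assertions.

**Concentration channel.**  Relative total hemoglobin is taken
proportional to the 532 nm (near-isosbestic) envelope amplitude with one
user-supplied calibration constant `k_chb` (g/L per a.u.); absolute
calibration is an instrument property, not something the analysis can
derive.  The pipeline samples the amplitude along the vessel centerline
interior, which keeps the estimate insensitive to the point-spread
function for vessels wider than a few PSF widths.

**Segmentation.**  Vessels of interest are segmented inside a bounding-box
ROI padded by a factor 1.2 ("slightly larger than the vessel").  The
threshold maximizes the between-class variance over a 256-bin histogram of
min-max-normalized ROI values, with ties broken to the lowest bin edge;
this binning/tie-break contract is implemented in-package and verified
against an exhaustive brute-force maximizer (and, coarsely, against
scikit-image's implementation).  8-connected components smaller than
`min_fragment_px = 10` are removed as spurious fragments; the largest
component always survives.  The centerline is the morphological skeleton
pruned to its longest path; the diameter is the mean mask chord
perpendicular to the local path direction over interior path points
(two trimmed at each end), measured by sub-pixel ray marching in physical
coordinates — so anisotropic pixel spacing is handled.  Full-width at
half-maximum of the amplitude profile would be a defensible alternative
diameter estimator; the mask chord was chosen because it is defined by the
same segmentation the rest of the pipeline uses.

**Oximetry.**  At each pixel the two amplitudes form a 2×2 linear system
in the oxy- and deoxy-hemoglobin concentrations through their molar
extinction coefficients; sO2 is the oxy fraction.  The default extinction
table (532 nm: 44 480 / 40 584; 558 nm: 32 620 / 53 412 M⁻¹cm⁻¹ for
HbO2/Hb) comes from the standard tabulated hemoglobin compilation and is a
configuration input; every closure test uses the same table for generation
and inversion, so nothing depends on the compilation chosen.  Negative
unmixed concentrations (noise) are clipped to zero before forming sO2,
which guarantees sO2 ∈ [0,1].  Per-vessel sO2 is the amplitude-weighted
mean over mask pixels (weight: 532 nm amplitude).  Artery/vein labels come
either from user labels or from a threshold heuristic
(artery iff sO2 ≥ 0.8) that is explicitly a placeholder — phantom tests
with well-separated saturations (0.95 vs 0.65) classify perfectly, but the
threshold is not a physiological claim.

**Flowmetry.**  The inter-line correlation of an A-line ensemble at lag τ
is modeled as `exp(−(τ/τc)²)`, a single-parameter Gaussian decay, with the
decorrelation time inversely proportional to the peak speed:
`v = k_flow / τc`.  `k_flow` (default 0.002 mm, i.e. τc = 2 ms at
1 mm/s) is of the order of the optical focal-spot size and is a
calibration input.  The fit is initialized at the lag where the
correlation first drops below 1/e (deterministic, no restarts) and uses
lags below `max_lag_s` (default 2 ms).  A fitted τc exceeding ten times
the maximum lag means no decorrelation is detectable and the speed is
reported as zero — this prevents divergent speeds on static vessels.

## The synthetic phantom

The generator emulates a scaled-down version of the 5×3 mm² two-hemicortex
imaging field: by default a 2.5×1.5 mm field at 5 µm isotropic pixels with
six near-vertical vessels (per hemicortex: two feeding arteries,
sO2 0.95/0.93, diameters 100/80 µm, peak speeds 1.6/1.2 mm/s; one draining
vein, sO2 0.65, 150 µm, 0.8 mm/s; hemoglobin 120 g/L).  These values are
physiologically plausible for the neonatal mouse cortex and put the
ground-truth regional CBF in the tens of mL/100 g/min.  A seed jitters
positions and parameters within small ranges so Monte-Carlo sweeps explore
scene variability; the same (config, seed) always reproduces the same
scene bit-for-bit.

The forward optical model is deliberately minimal and exactly invertible:
amplitude ∝ total hemoglobin × the wavelength's extinction mixture,
Gaussian PSF blur (8 µm FWHM default), additive Gaussian noise with a
standard deviation set by an SNR in dB relative to the RMS vessel
amplitude of the 532 nm channel (default 25 dB).  No speckle, fluence,
depth-coloring or acoustic effects are modeled.  A-line ensembles are
constructed from an orthonormal zero-mean signal basis combined through
the Cholesky factor of the target lag-correlation matrix, so the noiseless
empirical correlation equals the Gaussian-decay model at machine precision
(a 1e-9 diagonal jitter regularizes the near-singular kernel matrix);
zero speed yields identical lines.

Instrument traces are generated with the event structure of the assay
protocols: piecewise-linear Clark-electrode O2 with substrate/ADP/DNP
events (State-3 → State-4 slope change at a configurable ADP-exhaustion
time; defaults: 0.05 mg protein, 0.5 mL chamber, slopes −12/−3
nmol/mL/min → OCR 120/30 nmol O2/mg/min, RCR 4); Amplex UltraRed traces
with rate changes at rotenone (400 s) and antimycin A (600 s); MitoSOX
traces exactly linear up to the saturation time (25 min) then rolling off
through a C1 exponential; RH-123 traces with a 300 s baseline plateau, an
exponential settle to the quenched plateau after the substrate addition,
and partial recovery after CCCP.

What passing recovery tests on these phantoms shows — and does not show:
they validate the mathematics and the implementation of every estimator
under the generator's idealized physics.  They do not validate the
forward model against a real instrument (real PAM has speckle, depth-
dependent fluence, skull aberration, and an unknown decorrelation family),
so absolute in-vivo accuracy is outside what this package can claim.

## Bioenergetics estimators

State windows start 10 s after their triggering event (settling buffer)
and end at the next event.  When no ADP-exhaustion annotation exists, the
State-3 → State-4 boundary is the time maximizing the drop in slope
magnitude between two adjacent 60 s regression windows.  OCR is the
negated least-squares O2 slope scaled by chamber volume over protein mass;
rising O2 (a physically impossible negative consumption) reports 0 with a
warning rather than a negative rate.  The H2O2 calibration regression
includes an intercept because the dye background is nonzero.  The MitoSOX
initial-rate window is 300 s, well inside the kinetics saturation.  RH-123
plateaus are means over the last third of their segment, robust to the
settling transient; both the substrate quench depth and the CCCP-released
amplitude are reported because figure conventions differ on which is "the"
ΔRH-123.

## Statistics

The t-test is the pooled-variance two-sided Student test (df = n₁+n₂−2),
with conventions for degenerate inputs (zero pooled variance: p = 1 if the
means agree, a flagged divergent statistic otherwise).  One-way ANOVA is
the classical between/within F.  Two-way ANOVA uses type-II sums of
squares (equal to the classical decomposition when balanced) via
statsmodels; designs with singleton cells drop the interaction.
Summaries report mean ± sample SD (n−1) with n.  Holm-adjusted pairwise
t-tests are available as an optional post-hoc extra and labeled as such.

## Numerical choices and known limitations

* **Clipping bias at high saturation.**  Clipping unmixed concentrations
  at zero and sO2 to [0,1] makes the per-pixel estimator biased where the
  minority species is small compared to the noise: at 25 dB SNR the
  per-pixel sO2 scatter is ≈0.1 (the 532/558 extinction vectors are fairly
  collinear), which biases arterial sO2 down by ≈0.02–0.03 and hence OEF
  by ≈−7%.  Per-vessel averaging removes the variance but not the bias.
  This is the dominant error term in end-to-end CMRO2 recovery (≈−9.5% at
  the default phantom conditions) and is intrinsic to the clipped
  estimator, not a defect of the inversion.
* **Problem sizes.**  The shipped test suite and the acceptance script use
  the scaled-down field (500×300 px), 100-seed oximetry and 4×50-seed
  flowmetry sweeps, 20-seed end-to-end recovery, and 2000-rep null
  simulations — sizes chosen to keep full verification runs interactive on
  one CPU while leaving Monte-Carlo errors well below the tolerances they
  gate.
* **Scope.**  No 3-D reconstruction, no flow direction, no fluence
  correction, no acoustic simulation, no whole-field vessel discovery
  (ROIs follow the per-vessel workflow), no dynamic time-course modeling,
  and no absolute membrane potential in mV — the RH-123 read-out is
  relative by construction.
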