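# Methods

## Sensing model

The probe P and glutathione G form a 1:1 adduct A by reversible Michael
addition.  At equilibrium the adduct solves the mass balance

    A² − (P_T + G_T + Kd)·A + P_T·G_T = 0,

and the physical (smaller) root is evaluated in the cancellation-free
form `A = 2c / (b + √(b² − 4c))`.  This matters because the operating
regime is micromolar probe against millimolar GSH, where the naive
quadratic formula loses most of its significant digits.  The solver is
cross-checked in the tests against an independent bisection root of the
mass-action residual at 1e-10 relative tolerance.

The readout model assigns each species a brightness per unit
concentration in each excitation channel (`s405_free`, `s405_bound`,
`s488_free`, `s488_bound`, plus additive backgrounds), with the adduct
dominating the 405-nm channel and the free probe the 488-nm channel:

    R = (s405_bound·A + s405_free·P + bg405) / (s488_bound·A + s488_free·P + bg488).

Two limiting ratios follow: Rmin = s405_free/s488_free (no GSH) and
Rmax = s405_bound/s488_bound (saturating GSH).  For a dilute probe the
ratio reduces exactly to the hyperbolic calibration form

    (R − Rmin)/(Rmax − R) = k·C,     k = (s488_bound/s488_free)/Kd,

which is the identity the calibration module inverts.  (Note the 488
brightness ratio enters in the numerator: substituting A/P = C/Kd into
the quotient gives (R−Rmin)/(Rmax−R) = (s488_bound/s488_free)·C/Kd.)

## Photophysics fixtures

Two brightness fixtures ship with the package, reflecting that in-vitro
fluorimeter titrations and intracellular FACS calibrations are acquired
on different instruments with different gains and spectral windows:

* `FLUORIMETER_PHOTOPHYSICS` (Rmin = 0.02, Rmax = 25,
  w = s488_bound/s488_free = 0.04): the free probe is nearly dark under
  405-nm excitation and the adduct nearly dark under 488-nm excitation.
  With Kd = 3.7 mM this produces the wide, near-linear ratio response
  over 1–10 mM (model R² ≈ 0.999) characteristic of cuvette titrations.
  This is the default for titration simulation and Kd fitting.
* `HELA_FACS_PHOTOPHYSICS` (Rmin = 1.65, Rmax = 2.98, w = 0.7):
  anchored to the fitted HeLa flow-cytometry calibration.  Used for
  imaging and cytometry generation and calibration.

The two regimes are mathematically incompatible within a single fixture:
the channel-dominance constraints force w > Rmin/Rmax, so a response
anchored at 1.65/2.98 (w > 0.554) is necessarily saturating over
1–10 mM at a millimolar Kd, while near-linearity requires w ≲ 0.05 and
hence a small Rmin/Rmax.  Keeping one fixture per instrument class
resolves this without distorting either context.

For synthetic FACS and imaging data the calibration constant is fixed at
k = w/Kd = 0.7/3.7 ≈ 0.189 mM⁻¹, tying the calibration midpoint
(C = 1/k) to the titration Kd.  The published calibrations report only
Rmin and Rmax, never k, so k is always treated as a free parameter when
fitting.

## Kd estimation and identifiability

For a dilute probe the ratio titration constrains only the combination
w/Kd — Kd and the 488 brightness ratio are exactly confounded.  `fit_kd`
therefore takes the photophysics as known (the practical situation:
channel brightnesses are characterized once per instrument), pins Rmin
from the zero-concentration point when present, and fits Kd alone by
Levenberg–Marquardt on log-Kd.  A `fit_limits` flag frees Rmin and Rmax
as well (keeping w fixed); in that mode the data must bracket the
response midpoint C = Kd/w or the fit is flagged ill-conditioned.
Standard errors come from the Gauss–Newton covariance with a delta-method
transform off the log scale.

## Kinetics

The reversible rate law dA/dt = kf(P_T−A)(G_T−A) − kr·A is quadratic
with constant coefficients, hence a Riccati equation with the exact
solution

    (A−A1)/(A−A2) = ((a0−A1)/(a0−A2))·exp(−kf(A2−A1)·t),

where A1 < A2 are the roots of the equilibrium quadratic (A1 is the
physical equilibrium, shared exactly with the binding module at
Kd = kr/kf).  The exact relaxation rate kf·(A2−A1) reduces to the
pseudo-first-order kobs = kf·G_T + kr when GSH is in large excess.  The
closed form is the default simulation path; an adaptive LSODA
integration at rtol 1e-9 (atol 1e-15, stiff-capable for kf·G_T ≫ kr) is
kept as an independent numerical route and the two are required to agree
to 1e-6 in the tests.  The textbook single-exponential PFO formula is
deliberately not used for simulation: at G_T/P_T = 100 its
ligand-depletion error is ~P_T/(G_T+Kd) ≈ 4×10⁻³, far above the
agreement tolerance.

Rate-constant estimation follows the experimental logic: each trace is
fit to y(t) = y∞ + (y0−y∞)e^(−kobs·t) (initialized from a
log-linearized approach to the terminal value), and kobs is regressed on
G_T — slope kf, intercept kr — with inverse-variance weights.  An
optional joint refinement re-fits all traces (including
dilution-relaxation traces, the experiment that isolates kr) against the
closed-form model with residuals normalized per trace, which keeps
μM-scale signals from triggering absolute convergence tolerances.

The rate constants (kf = 7.5 M⁻¹ s⁻¹, kr = 20.3×10⁻³ s⁻¹) imply
kr/kf ≈ 2.7 mM, whereas the titration-derived Kd is 3.7 mM.  The package
does not force these to agree: each constant is used in its own context
(kinetic simulation uses kr/kf; binding and calibration use the
titration Kd), mirroring how the quantities are measured.

## Calibration fitting

`fit_calibration` minimizes residuals in R-space rather than in the
linearizing transform, because (R−Rmin)/(Rmax−R) diverges as samples
approach Rmax and would dominate the loss.  Rmin is bounded below the
smallest observation and Rmax above the largest; a fit that pins Rmax at
its bound is retried with the bound expanded and a warning.  Ratios
outside (Rmin, Rmax) invert to 0 or ∞ with `below-range`/`saturated`
flags rather than errors, since live-cell pixels and events routinely
stray past fitted limits; flags propagate to all per-cell and per-sample
outputs.

## Imaging pipeline

Background is a per-channel scalar.  The default estimator is the median
of pixels below the channel's Otsu threshold ("mode" method): with cells
covering a minority of the field this is an unbiased estimate of a
shot-noise-limited background, whereas a low percentile systematically
undershoots it (a 5th-percentile estimate of a Poisson(30) background is
low by ~9 counts, which propagates to a multi-percent concentration
bias after ratio inversion).  Percentile and explicit dark-region
estimators remain available.

Segmentation thresholds the channel-sum image by Otsu, labels 8-connected
components and drops those below `min_area_px`; touching cells merge
into one label (known limitation).  The ratio map divides the channels
pixel-wise where the 488 signal exceeds a floor (default 3× the
background standard deviation) and is NaN elsewhere.  Each cell is
reduced to its median valid-pixel ratio — robust to floor-adjacent and
saturated pixels — and that single median is converted to concentration,
because inverting a nonlinear calibration pixel-by-pixel and then
averaging would be biased.  Time-lapse tracking is greedy
nearest-centroid matching with a displacement bound defaulting to 20% of
the mean equivalent cell diameter per frame; unmatched cells open new
tracks and track ids are never reused.

## Cytometry pipeline

The gating chain is scatter → singlets → fluorescence outliers, with a
report recording counts into and out of every stage (the chain is
required to be contiguous, so no event is lost or duplicated
unaccounted).  The default scatter gate is a median ± 4·MAD box on
log10(FSC-A) and log10(SSC-A): a percentile box computed on the sample
itself would absorb a planted debris population into its lower bound,
while the robust box tolerates ~15% contamination.  A 2nd–98th
percentile box from a clean reference sample, or explicit bounds, can be
supplied instead.  Singlet gating keeps events whose area/height ratio
(FSC and SSC independently) lies within a factor-1.3 band around the
median singlet ratio; doublets carry roughly twice the area per unit
height and fall outside.  The 4-s.d. fluorescence exclusion is computed
once per channel on raw intensities of the post-singlet set (not
iterated); raw-vs-log is a config choice and raw is the default.
Samples are summarized by their median event ratio, since the event
distributions are right-skewed.

## Lysate assays

The recycling-assay readout is the OLS slope of 412-nm absorbance over a
2-minute window read every 30 s; slopes convert to lysate concentration
through a linear standard curve, with sub-blank responses clamped to
zero and flagged.  Intracellular concentration divides the molar amount
by counted cells × 4,000 μm³ per cell.  LC-MS quantification inverts
per-ion standard curves (GSH and cysteine maleimide adducts) with an
explicit dilution factor (default 100×).  All dilution bookkeeping is
explicit parameters, never inferred; standards are assumed measured at
the same dilution as samples unless configured otherwise.

## Synthetic data

Generators use exactly the forward models the estimators invert — no
hidden mismatch — unless the `gain_drift` switch (default 0) is set,
which scales the 405 channel for robustness experiments.  One global
seed fans out to fixed per-generator streams
(`default_rng([seed, stream_id])`), so consuming one data type never
perturbs another and identical configurations are byte-identical.

Default conditions: titrations of 10 μM probe over a 12-point 0–50 mM
grid with 1% multiplicative noise; kinetic traces at post-mixing probe
5 μM and GSH 2.5/5/10 mM, 0–120 s sampled at 1 s, 2% additive noise
relative to amplitude, plus two-fold dilution-relaxation traces from
pre-equilibrated 20 μM probe with 10 or 5 mM GSH; image frames of 46
non-overlapping elliptical cells (radii 8–14 px on 512×512) at a photon
budget of 500 counts/pixel over a flat background of 30 counts with
3-count read noise, cell-to-cell concentration spread 3% CV, and a
population schedule holding 5.0 mM, stepping to 4.1 mM within 90 s of an
oxidative insult at t = 120 s, then ramping back after ester rescue;
cytometry samples of 10,000 events at 10% ratio CV with 5% debris, 5%
dead cells, 5% doublets and 1% planted per-channel outliers, in a
10-sample dose series spanning 8 → 1 mM and a 3-point ferroptosis time
course (4.5/4.2/1.2 mM at 0/6/24 h — the published time course shows
GSH holding near baseline at 6 h and collapsing by 24 h; absolute levels
are not printed, so representative values were fixed once); recycling
assays at 2% multiplicative noise (3% in the cross-pipeline comparison)
with 10⁶ cells lysed per mL.

What the generators do not emulate: microscope point-spread functions,
flat-field or bleaching effects, spectral bleed-through, cytometer
transforms (logicle etc.), probe loading/efflux kinetics, or
subcellular heterogeneity.  Passing tests therefore demonstrate that the
estimation chain is correct and well-conditioned under the assumed noise
structure, not that any particular instrument is free of systematic
effects outside that structure.

## Numerical choices

* Equilibrium quadratic: cancellation-free root; bisection oracle
  agreement 1e-10.
* ODE integration: LSODA, rtol 1e-9 / atol 1e-15.
* Exponential fits: `curve_fit` with log-linearized initialization;
  constant traces flagged unidentifiable rather than fit.
* Calibration round trip: forward∘inverse identity to 1e-12 inside
  (Rmin, Rmax).
* Competitive partition: dilute-probe formula f_i ∝ C_i/Kd_i, exact
  (to solver tolerance) against the full coupled mass balance when
  reactivities are equal; O(P_free/Kd) deviation otherwise, with the
  full solve available via `full_solve=True` (bracketed Brent on the
  free-probe balance).
* Problem sizes in the acceptance script (12-point titrations, 3×121
  kinetic samples, 10×10,000 events, one 512×512 frame, 100-seed Monte
  Carlo in the test suite) were chosen as the smallest sizes at which
  the estimators' sampling error is clearly inside the stated
  tolerances.

## Known limitations

* Kd′ (a secondary equilibrium constant referenced alongside Kd in the
  source protocols) is not implemented; its definition is not given in
  the material this package models.
* The empirical 90%/10% partition of reacted probe between GSH and
  protein thiols is stored as constants (`GPC_GSH_FRACTION`,
  `GPC_PROTEIN_FRACTION`); no protein-thiol Kd exists from which to
  derive it.
* Touching cells merge under Otsu segmentation; no watershed splitting.
* No FCS binary ingestion; cytometry input is CSV with named channels.
* Absolute agreement with any specific published image set is not
  claimable, because the original image-processing settings (thresholds,
  background handling) are not specified; agreement is asserted against
  synthetic ground truth only.
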