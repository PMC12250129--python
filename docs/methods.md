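# Methods

This note documents the models implemented in `rltkit`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Units and decay conventions

All internal times are hours, activities MBq; configuration files may
declare half-lives in days. The decay factor is `2^(-Δt/T½)`; negative
elapsed times are permitted (back-correction). Lu-177 constants
(T½ = 6.73 d; mean β energy 0.1335 MeV per decay; photons 208 keV at 11%
and 113 keV at 6%) live in `src/rltkit/data/nuclides.csv` and are external
standard constants: the mean β energy in particular is the standard
evaluated value, not the ~0.5 MeV spectral endpoint sometimes quoted for
this nuclide.

The decisive convention is the **decay seam** between biodistribution and
dosimetry. %IA/g values produced by the worksheet pipeline are
decay-referenced to injection time: they describe the *biological*
distribution, which keeps tumor-to-normal ratios time-consistent and
matches the usual %ID/g reading. The dosimetry stage multiplies the
extrapolated human curves back by the physical decay factor before
fitting, so the integrals it forms count physical disintegrations, as a
residence time must.

## Radiochemical QC

Purity is a window fraction: counts inside an explicit half-open interval
`[lo, hi)` over total counts. Windows are operator-supplied, never
auto-detected — with an EDTA mobile phase the product sits at the origin
and free radiometal at the solvent front, so the default product window is
the origin half of the strip. Half-open intervals tile the axis without
double counting, which makes "fractions over a partition sum to 100%" an
exact invariant rather than an approximation. A labelling run is
releasable at ≥90% purity. Serum-stability records pivot to a
temperature × time table; missing cells stay absent (never imputed) and
duplicate keys are rejected.

## Binding assays

Uptake per million cells is
`%IA = 100 · counts / (standard_counts / f_std)` scaled by `10⁶/cells`,
assuming same-session counting (no decay term; cross-session work belongs
to the worksheet pipeline, which has one).

Both binding fits are one-site models with Hill slope fixed at 1, solved
by bounded least squares (`scipy.optimize.least_squares`, tolerances
1e-15) from a deterministic log-spaced multi-start grid (5×5; candidate
starts sorted so that sum-of-squares ties resolve toward the smaller
Kd/IC50). Standard errors come from the Jacobian at the solution.
Saturation fitting uses specific binding = total − nonspecific computed
pointwise, flooring negative values at zero with a warning (design points
are kept and flagged, not silently dropped). Competition fitting
parameterises log₁₀ IC50; a curve whose dynamic range is under 5% of its
maximum is declared unidentifiable, and a fitted IC50 outside the measured
concentration range is rejected as an unbracketed transition. The
Cheng-Prusoff conversion `Ki = IC50/(1 + [L]/Kd)` is an exact formula
evaluation; its `[L] → 0` limit (Ki → IC50) and monotonicity are tested
properties.

## Biodistribution

For each organ record the nearest-in-time counting standard in the same
worksheet is used (error if the gap exceeds 24 h — a deliberate pairing
rule, since gamma counting sessions are short relative to that). Sample
and standard counts are both decay-referenced to injection, so
cross-session decay cancels out of the ratio exactly when they share a
session. Summaries are arithmetic mean and sample SD (n−1); a cell with
one animal reports no SD, and empty cells are absent rather than zero.
Ratios divide tumor mean %IA/g by organ mean %IA/g per timepoint; a zero
denominator yields an absent cell with a warning.

## Dosimetry

Mouse-to-human extrapolation is relative organ-mass scaling:
`(%IA/organ)_human = (%IA/g)_animal × (kg TB)_animal × (g_organ/kg TB)_human`.
The default animal body mass is 0.025 kg (typical adult mouse,
config-overridable); phantom masses are an editable 70-kg reference-adult
table of standard constants. Organs without a phantom entry (the
xenograft tumor) are excluded from dosimetry and reported — tumor
dosimetry is out of scope.

Biokinetic fits are sums of exponentials with every rate bounded below by
the physical decay constant λ (total disappearance can never be slower
than physical decay). For a candidate rate set the coefficients are first
solved by non-negative least squares, then jointly refined; `model="auto"`
compares mono vs bi by corrected AIC with ties to mono, and the
bi-exponential is only eligible for selection when n−k−1 > 0 (with four
timepoints that means auto mode fits mono; an explicit `model="bi"`
honours the four-point minimum). Residence time is the analytic integral
τ = Σ (cᵢ/100)/rateᵢ; a trapezoid-plus-physical-tail fallback covers
unfittable curves, and an all-zero curve yields τ = 0. The remainder of
body is whole-body τ minus the organ sum, clamped at zero with a warning.
The demo pipeline takes the whole-body τ as the physical-decay bound
T½/ln 2 ≈ 233.0 h (no excretion model — conservative and reproducible;
supply a measured whole-body curve to refine it).

Organ doses are the MIRD sum `D(target) = Σ_source τ_s · S(target←source)`
in mGy/MBq. The S-matrix is an input file. The packaged matrix is a toy
fixture: self-dose terms from the closed form
`S_self = 0.5767 · E_β(MeV)/m(kg)` (3.6×10⁹ decays per MBq·h with full
local absorption of the mean β energy) plus a uniform nominal photon cross
term; `build_smatrix` constructs such matrices for arbitrary organ sets
with user-supplied photon absorbed fractions. Phantom Monte-Carlo S-value
tables are deliberately out of scope — the engine's contract is the sum,
not the geometry. With radiation weighting 1 for β/γ the equivalent dose
equals the absorbed dose numerically, and the effective dose is the
ICRP-60-weighted sum (weights shipped as an editable table; the remainder
weight applies to the mass-weighted mean dose of organs not explicitly
weighted, and weighted tissues absent from a report inherit that remainder
dose so normalisation is preserved).

## Survival

Humane-endpoint animals (weight ≤ 80% of the inoculation-day baseline,
boundary inclusive) are events, not censored; survivors are censored at
last observation. The Kaplan–Meier estimator and the two-group log-rank
test are computed from their defining sums — risk sets over pooled event
times, hypergeometric variance with tie multiplicities, death before
censoring at a tie — and cross-checked in the tests against lifelines and
against a brute-force oracle that enumerates every way tied deaths could
fall in the risk set. Median survival is the smallest time with
S(t) ≤ 0.5 (this equals the conventional KM median whenever S crosses 0.5
strictly). Lifespan increase is `100·(median_treated − median_control)/
median_control`, reported to one decimal, round-half-even.

## Synthetic data: what it emulates, and what it does not

The generators are forward models written independently of the analysis
code (an AST-level test enforces that only container classes and decay
arithmetic cross the boundary), so generator → pipeline round-trips are
genuine inversions.

* **Biodistribution preset** (`LNCAP_BIODIST`): per-organ anchor curves in
  decay-corrected %IA/g, log-linearly interpolated (piecewise
  exponential) and extrapolated with the nearest segment's slope. Tumor
  (13.149 → 23.31 → 12.88 %IA/g at 1/4/24 h) and kidney (43.83 %IA/g at
  1 h) carry the measured anchors; blood and muscle are back-derived from
  the tumor-to-normal ratios (69.5/434.4 and 60.2/857.4); the 48 h tumor
  value extrapolates the 4→24 h slope and the 48 h kidney value follows
  the tumor/kidney ratio maximum of 26.3. Liver, spleen and lung are
  nominal low-uptake fixtures (1.0/0.8/0.9 %IA/g at 1 h, mono-exponential
  decline with a 20 h biological half-time) — placeholders, not
  measurements.
* **Worksheets**: counts = %IA/g·mass/100 × A₀ × calibration × decay,
  with a same-session 1%-aliquot standard; organ sample masses are a
  declared fixture table; calibration 10⁴ CPM/MBq puts zero-noise counts
  in a realistic gamma-counter range. Noise models: none (default),
  Poisson counting noise, or Gaussian with configurable CV.
* **Binding**: one-site forward curves (Bmax 5000 CPM; competition Top
  4000 / Bottom 200 CPM; nonspecific binding a fixed 10% of total).
* **Survival**: Weibull event times per arm with shape k = 6 (realistic
  spread; medians are shape-robust), scale = median/(ln 2)^(1/k), rounded
  *up* to whole days — which can move a sample median at most one day
  above the continuous preset median. Arms: control n = 6 (median 26 d)
  and two treated arms n = 8/9 (medians 34/40 d).

What passing round-trips show is that the pipeline exactly inverts a
self-consistent forward model under the declared conventions. They do not
validate the biology of the presets, detector effects absent from the
forward model (dead time, geometry, background), inter-animal biological
variability beyond the chosen noise models, or the unpublished quantities
(blood/muscle uptake, late timepoints) that are derived rather than
measured.

## Numerical choices and degenerate inputs

Fits: tolerances 1e-15, deterministic start grids, SSE ties toward the
smaller binding constant / the simpler model. Empty stability input gives
an empty table; zero-count profiles are an analysis error; all-censored
survival data gives a flat S ≡ 1 and an undefined log-rank (error);
all-zero activity curves give τ = 0. Residence-time sets respect
Σ τ ≤ T½/ln 2 by construction (every decay happens at most once).
Problem sizes throughout (8/10-point assays, 7 organs × 4 timepoints × 3
animals, arms of 6–9 animals, ≤300-replicate noise studies in the tests)
mirror a realistic single preclinical study and keep every check fast.

## Known limitations

* The packaged S-matrix and phantom are demonstration-grade; organ doses
  from the demo pipeline are not clinical estimates.
* No excretion model: the demo whole-body residence time is the physical
  upper bound, which inflates the remainder term.
* One-site binding only (no Hill-slope estimation beyond the config
  switch, no kinetic on/off-rate models).
* No Cox regression, multi-arm simultaneous testing, or confidence bands
  on survival curves.
* Decay-chain daughters are not modelled (single-nuclide bookkeeping).
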