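# Methods

## Scientific problem

The redox state of a couple like glutathione (reduced GSH, with a thiol
S–H; oxidized GSSG, with a disulfide S–S) is hard to read out
non-invasively. The premise of this package is that the *hydration shell*
of the redox-active sulfur carries the signal: a thiol sulfur both accepts
hydrogen bonds from water and donates its S–H proton to water, while a
disulfide sulfur can only accept. That asymmetry shows up in two
observable domains:

1. **NIR difference spectra.** In the water first-overtone region
   (1300–1600 nm), subtracting the PBS background spectrum from a solution
   spectrum isolates the solute-plus-hydration signal. Reduced species
   show positive solvation-shell bands near 1362 and 1381 nm; oxidized
   species lack them and displace more bulk water (a deeper negative band
   near 1450 nm). Multivariate calibration on these difference spectra
   both quantifies concentration and, through the regression vector,
   localizes the discriminating bands.
2. **Trajectory statistics.** Around a thiol sulfur, the sulfur–water-oxygen
   radial distribution function has a higher first peak than around a
   disulfide sulfur, and the directional hydrogen-bond tallies differ: the
   sulfur-donates direction (S–H···O) is a structural zero for a disulfide.

The package implements both analysis chains over synthetic generators with
exact ground truth, so every claim the pipelines make is checkable against
construction.

## Synthetic spectra generator

Each spectrum is a Beer–Lambert mixture

    A(λ) = g · (B(λ) + c · S(λ)) + o + m·(λ − λ_mid) + ε(λ)

with background `B` (Gaussians at 1450 nm, σ 70 nm, 0.55 AU and 1940 nm,
σ 90 nm, 1.10 AU, over a 0.08 AU offset), molar signature `S` (sum of
Gaussian bands), concentration `c` in mM, multiplicative scatter gain
`g ~ N(1, 0.01)`, baseline offset `o ~ N(0, 5e-4 AU)`, slope
`m ~ N(0, 1e-7 AU/nm)` and white noise `ε ~ N(0, 1e-3 AU)` per channel.
The default design is 1–10 mM in 1 mM steps, 25 replicates per level, on a
1100–2400 nm grid at 2 nm spacing (651 channels).

Default signatures (amplitudes in AU per mM; tunable model parameters, not
measured molar absorptivities — chosen so 10 mM bands are a few percent of
the background):

| analyte | bands (center nm / σ nm / amplitude·1e3) |
|---|---|
| GSH  | 1362/6/+2.0, 1381/6/+1.6, 1450/35/−1.2, 2175/15/+1.0, 2279/15/+1.0 |
| GSSG | 1450/35/−2.4, 2175/15/+1.0, 2279/15/+1.0 |
| NADH | 1363/6/+2.0, 1450/35/−1.2, 2175/15/+1.0, 2279/15/+1.0 |
| NAD+ | 1383/6/+1.4, 1450/35/−2.0, 2175/15/+1.0, 2279/15/+1.0 |

The 6 nm band width is a deliberate choice: with the 1362/1381 nm centers
19 nm apart and amplitudes 2.0/1.6, widths of ~8 nm or more merge the two
Gaussians into a single analytic maximum, which would make "two distinct
peaks" untestable. At σ = 6 nm the doublet is resolvable in the noiseless
signature and survives the default smoothing.

Outlier injection adds a constant offset, a smooth full-grid sinusoidal
ripple (period 200 nm, random phase) and a narrow spike, all of amplitude
`magnitude`. The ripple matters: a pure offset is removed exactly by SNV
and a lone spike can land in the masked 1850–2050 nm region, so only a
shape-distorting artifact is guaranteed to remain screenable after
preprocessing.

What the generator does *not* emulate: wavelength-dependent instrument
noise, temperature-driven water-band shifts, band overlap between analyte
and background beyond simple addition, detector nonlinearity, or any
radiative-transfer physics. Passing tests therefore demonstrate that the
*chemometric machinery* recovers what was put in under realistic noise
magnitudes — not that real instrument spectra would behave this way.

## Preprocessing chain

Default quantification pipeline (each step logged in provenance):

1. `mask_regions` to 1100–1850 nm and 2050–2400 nm (552 channels on the
   default grid) — the excluded stretch is noisy/saturated on real
   instruments.
2. `snv` per spectrum ((x − mean)/sd, sd with n−1) — removes scatter gain
   and offset. Row-wise SNV was chosen as the default reading of
   "standardization"; column autoscaling exists as a separate operation
   with a returned scaler for held-out data.
3. `savitzky_golay`, window 9 channels (18 nm), polyorder 2, derivative 0.
   The window is narrower than a typical 15-channel default because a
   30 nm quadratic window demonstrably merges the 19-nm-spaced doublet;
   9 channels smooths white noise while reproducing any global quadratic
   exactly ('interp' edge handling).
4. PCA + Mahalanobis screen (below), on the preprocessed spectra.
5. `difference_spectra` against the channel-wise mean PBS background.
6. OSC + PLS calibration (below).

Whether SNV precedes or follows background subtraction is genuinely open;
the default (SNV first, subtraction of an identically preprocessed
background) is a documented choice, and the order is configurable.

The mixture branch deliberately uses none of steps 2–4: it masks
1300–1600 nm, subtracts PBS and fits PCR directly.

## Chemometrics

**PCA** is mean-centered SVD with a fixed sign convention (largest-|element|
loading positive). The **Mahalanobis screen** computes
d² = Σⱼ tⱼ²/λⱼ over k components (k = smallest count explaining ≥95%
variance, capped at 10) and flags d² above a chi-square(k) quantile
(default 0.975; the closed-loop test uses 0.999, where the expected
false-flag count at n = 250 is ≈0.25 — at 0.975 roughly 2.5% of *clean*
Gaussian-noise spectra exceed the threshold by construction, which is the
expected behavior of the screen, not a defect).

**OSC** (orthogonal signal correction, Wold-style): per component, seed a
score with the first principal component, alternate projection onto the
orthogonal complement of y with regression back onto X until stationary,
then deflate X by the rank-one score/loading product. Each removed score
satisfies |tᵀy| ≤ 1e-8·‖t‖‖y‖ (asserted, not assumed). One component is
removed by default. OSC uses the response, so it is refit inside every
cross-validation training fold; a y-shuffle leakage test guards this.

**PLS1** is NIPALS with deflation: w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt,
q = yᵀt/tᵀt, deflate, repeat; b = W(PᵀW)⁻¹q. The latent-variable count is
selected by leave-one-out RMSECV (capped at 10), computed cheaply from one
nested NIPALS fit per fold since the models are nested in LV count. At
full rank, PLS, PCR and ordinary least squares on centered data coincide;
the tests hold all three (and sklearn's PLSRegression as an external
cross-check) to that identity.

**PCR** regresses each response on the first k PCA scores and maps
coefficients back to channel space. For the paired mixture design
(1 mM GSH : 4.5 mM GSSG … 9 mM GSH : 0.5 mM GSSG) the two responses are
perfectly anti-correlated — the centered noiseless spectra have rank 1 —
so both regression vectors localize the same 1362/1381 nm bands with
opposite signs, and exact noiseless recovery needs only k = 1. The
component count on noisy data is chosen by leave-five-spectra-out CV.

**Metrics** are pooled held-out RMSE = √(mean squared residual) and
R² = 1 − SSres/SStot; reported R² is cross-validated unless labelled
"calibration".

**Peak localization** finds local maxima of |b(λ)| in 1300–1600 nm with a
prominence floor of 5% of the window's max |b| (suppresses noise wiggles
without touching designed bands), sorted by magnitude.

## Synthetic trajectories

A thiol-like solute (S + bonded H) or disulfide-like solute (S–S, bond
length 2.05 Å, no S-bonded H) sits fixed at the center of a 30×30×30 Å
orthorhombic box with 200 rigid waters (O–H 0.9572 Å, H–O–H 104.52°) over
2,000 frames — a desk-scale stand-in for a production box (a full-size run
remains configurable). There is **no integrator**: waters are re-placed
independently every frame. The generator realizes a known
`BondSchedule` of directed intervals:

* during an interval, the scheduled pair satisfies the detection criteria
  with margin (donor–acceptor distance U(3.0, 3.6) Å for O···S, D–H···A
  angle within U(0°, 20°) of linear);
* outside it, the water is in bulk, ≥6 Å from every sulfur — at least 1 Å
  beyond the cutoff + margin;
* rejection sampling guarantees that no *unscheduled*
  hydrogen/sulfur combination comes within 1 Å / 10° of the criteria
  (the second sulfur of a disulfide sits only 2.05 Å from the first, so
  this is a real hazard, not a formality).

Auto-schedules draw geometric interval lengths (mean 20 frames) at target
occupancy 0.6 simultaneous bonds per frame per direction and per sulfur;
the single thiol hydrogen donates serially. Bulk waters are mutually
unconstrained (their overlap is irrelevant to H-bond bookkeeping). Frame
spacing (10 ps) is metadata only and never enters scoring.

This artifact tests *bookkeeping* — interval recovery, residence-time
weighting, per-sulfur normalization — not water physics: there are no
forces, no dynamics, no realistic residence-time distributions.

## Hydration analysis

**H-bond criteria** (configurable per element pair): donor–acceptor
distance ≤ 3.5 Å for O···O and ≤ 4.0 Å for O···S (just beyond the ~3.8 Å
first RDF peak of sulfur–water), D–H···A angle within 30° of linear.
Directions are labelled O–H···S (water donates to sulfur), S–H···O (thiol
donates to water) and O–H···O.

**RDF**: minimum-image distances under orthorhombic periodic boundaries,
g(r) = ⟨pair count in shell⟩/(N_ref·ρ·V_shell) averaged over frames,
r_max ≤ half the smallest box edge. The first peak is the first local
maximum in 2–5 Å above a height floor; the workflow additionally requires
the peak bin to exceed the bulk Poisson expectation by ≥5σ (or g ≥ 1.5)
before calling it structure, because sparse ideal-gas fixtures produce
ripple maxima. The coordination number is 4πρ∫g(r)r²dr (trapezoid), cut
at the first minimum after the peak; it matches direct per-frame counting
within 2% on every fixture.

**Interaction score**: per directed pair, maximal runs of consecutive
bonded frames are extracted; the score is Σ L^(1+w) over runs with
L ≥ min_persistence. The defaults (min_persistence 1, w 0) make the score
the total number of bonded frames — each hydrogen bond counted once per
frame it persists, i.e. bonds weighted by their residence time. Stricter
readings (persistence filters, superlinear weighting) are exposed as
parameters; an exact published weighting formula does not exist to pin
down, and magnitudes of a few thousand over 10,000 frames are consistent
with the default reading. Per-sulfur normalization divides by the sulfur
count, the comparison that puts one disulfide on the same footing as two
thiols; with matched per-direction occupancy the thiol:disulfide combined
per-sulfur ratio is 2 by construction (donor + acceptor vs acceptor only),
and the S–H···O score of any disulfide trajectory is exactly 0.

## Numerical and degenerate-input choices

* Sign conventions fixed everywhere (largest-|element| positive) for
  backend-independent reproducibility; seeded `numpy.random.Generator`
  throughout; identical (config, seed) reruns are bit-identical.
* SNV errors on constant rows naming the sample; column autoscaling leaves
  zero-variance channels centered-only with a flag.
* Grid mismatches in subtraction/prediction are errors (no interpolation).
* NIPALS raises when deflation exhausts covariance (n_lv above effective
  rank); OSC raises on non-convergence with the residual.
* Triclinic boxes are rejected; only orthorhombic minimum image is
  implemented.
* first_peak errors on monotone profiles; empty CV windows, empty masks,
  zero-variance responses all raise with context.

## Problem sizes

Defaults used by the tests and the analysis scripts: 250 spectra per
series (10 × 25), 552 channels after masking; 2,000 frames × 200 waters
(602 atoms) per trajectory; ten full-size trajectory fixtures in the
oracle-equivalence test. The full suite runs in a few minutes on one CPU.

## Known limitations

* Band amplitudes and widths are free parameters; nothing here claims
  physical molar absorptivities, and the calibration numbers (RMSE ≈
  0.15–0.22 mM, R² ≈ 0.995 at these noise settings) characterize the
  synthetic conditions only.
* The trajectory generator's residence statistics are geometric by fiat;
  autocorrelation-based residence analyses would be inappropriate on it.
* The mixture design's collinearity means mixture models cannot be used to
  *independently* quantify both species from one sample family; the
  single-series workflow is the quantification claim.
* No real-instrument file formats (JCAMP-DX/SPC) and no real-trajectory
  importers are wired into the core; the CSV/XYZ/JSON formats are the
  supported surface.
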