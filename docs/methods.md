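# Model and methods

`takolv` is a reduced-order, desk-scale re-creation of a multiscale
simulation study of Takotsubo-like apical ballooning: a cell-level
contraction model driven by prescribed calcium transients, embedded in
a simplified left ventricle coupled to a Windkessel afterload, with
apex-base gradients in β-adrenergic end points and a scalar ballooning
metric on top.  This note records the model equations, the calibration
constants and why they have the values they do, the numerical choices,
and what the surrogate can and cannot be expected to reproduce.

## Calcium transients

Cytosolic calcium is prescribed, not simulated.  One cycle at 6-Hz
pacing (166.7 ms) is the product-of-exponentials pulse

    c(t) = c_dia + c_amp · k · (1 − e^(−t/τ_rise)) · e^(−t/τ_decay),

normalised (k) so the peak increment equals `c_amp` exactly; the peak
falls at `τ_rise · ln(1 + τ_decay/τ_rise)`.  Defaults
(`takolv/defaults.yaml`):

| trace      | c_dia (μM) | c_amp (μM) | τ_rise (ms) | τ_decay (ms) |
|------------|-----------|-----------|-------------|--------------|
| control    | 0.10      | 0.90      | 8           | 28           |
| stimulated | 0.10      | 2.20      | 6           | 18           |

Only the orderings are experimentally anchored (the stimulated
transient has a higher peak and relaxes faster; both return to within
5 % of the diastolic level by the end of the cycle).  The stimulated
amplitude sits in the 2–3× range typical of a saturating isoproterenol
response.  Absolute micromolar levels are plausibility choices, fixed
once: no tabulated amplitudes exist for these traces.

## Contraction model

A deliberately minimal two-state surrogate exposes exactly the four
handles the organ-level experiments manipulate (maximal tension
`T_ref`, calcium sensitivity `Ca_T50`, cycling rate `k_xb`, length
dependence `β₁`):

    d(trpn)/dt = k_trpn [ (c/Ca_T50(λ))^n_trpn (1 − trpn) − trpn ]
    d(xb)/dt   = k_xb ( trpn^n_xb − xb ),        T_a = T_ref · xb
    Ca_T50(λ)  = Ca_T50_ref · max(0.1, 1 + β₁ (λ − 1))

`trpn` lumps troponin-C binding together with the cooperative
tropomyosin dynamics of richer models, which is why its effective Hill
coefficient is large (n_trpn = 12 after calibration; the steady
force–calcium relation then has Hill slope ≈ n_trpn · n_xb-corrected
≈ 12–14, at the steep end of intact-muscle measurements).  By
construction, relative changes in `Ca_T50` map to identical relative
changes in the steady-state tension EC50 — the property the original
model class states — and the plateau tension is exactly `T_ref`.

**Twitch calibration.**  With `k_xb` fixed at 0.02 /ms, a Nelder–Mead
search over (k_trpn, n_trpn, n_xb) fits the control twitch to
time-to-peak 39 ms and 50 %-relaxation 31 ms.  A structural constraint
matters here: cross-bridge decay cannot be faster than `k_xb`, so RT50
has a floor of ln 2 / 0.02 ≈ 34.7 ms.  The calibrated model therefore
sits at TTP 39.0 ms (dead on) and RT50 35.2 ms — inside the
experimental 31 ± 5 ms spread, but pinned near its upper edge by the
model structure, not by data.  Calibrated values: k_trpn = 0.8 /ms,
n_trpn = 12, n_xb = 1.

`Ca_T50_ref = 0.55 μM` for the unstimulated cell is inferred from the
constraint that the extreme apical desensitization explored organ-level
(3 μM) is 5–6× the unstimulated level.

**Integration.**  Exponential (exact-for-frozen-coefficients) updates
for both states, with the calcium sampled at step midpoints and a
trapezoidal cross-bridge source: unconditionally stable and
second-order accurate for smooth inputs.  Default dt = 0.05 ms;
trajectories at dt = 0.1 ms match dt = 0.001 ms to better than 1e-4 in
peak tension.

## Ventricle surrogate

The 3-D ventricle is collapsed to 12 axisymmetric thick-walled slices
(apex z≈0 to base z≈1) plus a hemispherical apical cap.  Reference
endocardial radii follow a truncated-ellipsoid profile
`r(z) = R √(1 − (1−z)² κ)` with κ = 0.35; the wall thickness is a fixed
fraction (0.85) of the local radius at both ends, which makes the
pressure capacity σ·h/r of a homogeneously activated wall uniform along
the axis — the slice-stack analogue of a homogeneously contracting
ventricle (an absolute thickness profile instead puts the largest slice
on the unstable Laplace branch and makes even the *control* run
balloon basally).

Each slice obeys a quasi-static force balance with the shared cavity
pressure,

    (σ_p(λ(r)) + T_ref·xb) · h(r) = p · r,

with conserved wall cross-sectional area (incompressible wall: h(r)
thins as the cavity dilates), midwall circumferential stretch λ, and a
tension–compression symmetric exponential passive law
`σ_p = ±a (e^(b|λ−1|) − 1)`, a = 1 kPa, b = 12.5 after calibration.
Slices interact only through pressure and the volume constraint; there
is no axial coupling and no long-axis shortening.

**Stretch reference for LDA.**  Length-dependent activation uses
stretch measured *relative to the end-diastolic configuration*
(λ_cell = λ/λ_ED), the analogue of the image-derived reference state of
organ models.  Two further choices stabilise the coupling:

* Residual diastolic cross-bridge tension (~5 kPa at 6 Hz, an
  unavoidable consequence of `k_xb = 0.02`) is included when the
  geometry is scaled to its target EDV, so the beat really starts at
  125 μl; relative to the unloaded reference the end-diastolic state is
  mildly compressed.
* The linear LDA law is not extrapolated below λ_cell = 0.9.  The
  surrogate shortens circumferentially to λ ≈ 0.6–0.7 at end systole —
  far beyond the sarcomere-length range over which the linear relation
  means anything — and extrapolating it there makes global
  shortening-deactivation swamp the stretch-side Frank–Starling
  compensation these experiments probe.

**Cardiac cycle.**  Starting at end diastole (p = EDP = 0.5 kPa, cell
states paced 12 cycles to periodicity at λ_cell = 1): isovolumic
contraction (volume pinned, pressure solved) until p reaches the
ejection-onset pressure p_a; ejection coupled to a three-element
Windkessel (`C·dp_wk/dt = q − p_wk/R`, chamber sees `p_wk + z_c·q`;
aortic pressure initialised to p_a at onset) until flow reverses;
isovolumic relaxation (the valve reopens if cavity pressure exceeds the
decaying aortic pressure again); then refilling at EDP.  The beat is
analysed in isolation; because the cells are paced isometrically, the
late-diastolic volume can overshoot EDV by a few percent — a known
periodicity error of the single-beat convention that does not touch
EDV, ESV, EF or the end-systolic shape.

**Hemodynamic calibration.**  Compliance (0.0144 ml/mmHg) and p_a
(9 kPa) are printed values and stay fixed.  Peripheral resistance and
characteristic impedance are free constants (the cited source gives no
numbers; dimensional analysis of a 6-Hz rat circulation at ~0.6 μl/ms
mean flow and ~12 kPa mean pressure puts R at tens of kPa·ms/μl):
defaults r_per = 20 kPa·ms/μl, z_c = 0.4 kPa·ms/μl, set together with
(a, b, κ) so the homogeneous control beat gives EF 77 % (target
70–80 %), peak pressure 15.1 kPa (target 13.5–16.5) and EDV 125 μl
(target 100–150).

## Mechanisms, sweeps and the A:B index

The activation fraction β(z) is 0 for z ≤ z_a, 1 for z ≥ 1 − z_b and
linear between; the nine gradient shapes are (z_a, z_b) ∈ {0, 0.25,
0.5}².  The three mechanisms assign per-slice cell inputs exactly as in
the study design: blended transients with homogeneous desensitization
(72 configs, Ca_T50 0.6–1.5 μM); graded sensitivity under the
stimulated transient everywhere (90 configs, apical Ca_T50 1–4 μM,
basal 1 μM); graded maximal tension (216 configs, apical T_ref
30/60/90 kPa, Ca_T50 0.6–1.3 μM).  The tension mechanism also applies
the stimulated transient throughout (a catecholamine-overload context;
configurable).  Every configuration can be re-run under
β₁ ∈ {−1.5, −0.75, 0} and p_a ∈ {9, 11.25, 13.5} kPa.

A:B is the maximal apical over minimal basal endocardial radius at end
systole (minimum-volume instant); slices with z ∈ [0.1, 0.4] form the
apical band and z ∈ [0.7, 0.95] the basal band (cap and valve-plane
slice excluded; both bands configurable).  A:B ≥ 1.3 counts as
significant.  Sweep tables carry one row per run; configurations whose
quasi-static equilibrium genuinely disappears (cavity collapse under
extreme tension) are recorded as `aborted`, not dropped.

## Numerical solvers

All inner solvers are deterministic, derivative-based and bracketed:

* per-slice radii: vectorised safeguarded Newton with per-slice
  bisection brackets (residual → +∞ with radius via the exponential
  passive term guarantees a bracket whenever a root exists), warm
  started from the previous time step to track the physical branch;
* isovolumic pressure and the ejection coupling: scalar bracketed
  Newton on monotone residuals.  When the target volume falls inside a
  fold of V(p) (a branch snap of the slice stack), the nearest branch
  is taken and the transient volume mismatch logged — the quasi-static
  idealisation has no exact solution there.

Discretisation defaults: 12 slices, dt = 0.05 ms.  Halving dt changes
the baseline EF by < 0.1 percentage points.  A full 378-run sweep takes
roughly half an hour on one CPU; the test-suite and the acceptance
script therefore exercise sharp-gradient sub-grids (16–24 runs), which
contain every configuration the headline analysis selects.

## Known limitations

* **No force–velocity or filament-overlap effects.**  Tension during
  ejection is quasi-isometric, so ejection proceeds as a fast
  "dump" limited by the compression response of the wall rather than by
  relaxation; ejection and systole are correspondingly short (~20–35 ms
  to end systole).  Pressure–volume *end points* (EF, peak p, EDV) are
  calibrated; trajectories between them are not quantitative.
* **EF distribution is lumpier than a finite-element model's**: with
  mechanically independent slices, configurations tend to cluster into
  "everything ejects", "base alone ejects" and "nothing ejects" rungs,
  with narrow transition bands in between.  The 30–60 % EF analysis
  window is populated, but more sparsely than in a continuum model.
* **Length-dependent activation phenomenology is partial.**  Halving
  the LDA coefficient (β₁ −1.5 → −0.75) raises mean end-systolic A:B
  over ballooning configurations (measured 1.48 → 1.52 over a
  19-configuration sharp-gradient panel), reproducing the impaired-
  Frank–Starling direction.  *Fully removing* LDA (β₁ = 0) instead
  collapses marginal configurations to EF ≈ 0 — without stretch
  sensitization their apex never reaches the ejection threshold — so
  the full-removal re-run does not show the across-the-board A:B
  increase a continuum model does.  Conclusions about β₁ = 0 should not
  be drawn from this surrogate.
* **Raw vs in-window significance.**  At a sharp gradient the 50 %
  -inhibition case (apical T_ref 60 kPa) can show raw A:B slightly
  above 1.3 at EF ≈ 70–76 %, outside the 30–60 % analysis window;
  within the window only the 75 %-inhibition case is significant, and
  the raw index is strictly ordered 30 > 60 > 90 kPa.
* Absolute A:B values inherit the missing long-axis shortening and the
  circular-cross-section idealisation; orderings and threshold
  crossings, not third decimal places, are the meaningful output.
* Single-beat analysis: no beat-to-beat Windkessel state carry-over, no
  baroreflex, no atria, synchronous activation only.
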