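# Package default configuration: every calibration constant of the model
# lives here.  Numbers marked (calibrated) were set by the package's own
# calibration routines (calibrate_rates, calibrate_hemodynamics, geometry
# scaling) against the printed physiological targets: twitch time-to-peak
# 39 +/- 6 ms, 50%-relaxation time 31 +/- 5 ms, peak pressure ~15 kPa,
# EDV 100-150 ul, ejection fraction ~75%.

transients:
  # 6-Hz rat myocyte calcium transients (synthetic stand-ins; uM, ms).
  control:
    c_dia: 0.10
    c_amp: 0.90
    tau_rise: 8.0
    tau_decay: 28.0
    t_cycle: 166.66666666666666
  stimulated:
    # Beta-adrenergic stimulation: higher peak, faster relaxation.
    c_dia: 0.10
    c_amp: 2.20
    tau_rise: 6.0
    tau_decay: 18.0
    t_cycle: 166.66666666666666

contraction:
  t_ref: 120.0        # kPa, maximal active tension at saturating calcium
  ca_t50_ref: 0.55    # uM, troponin-C half-activation at reference stretch
                      # (nonstimulated level; ~1/5 of the 3 uM extreme)
  k_xb: 0.02          # 1/ms, cross-bridge cycling rate (fixed)
  k_trpn: 0.8         # 1/ms (calibrated)
  n_trpn: 12.0        # lumped activation cooperativity (calibrated)
  n_xb: 1.0           # cross-bridge recruitment exponent (calibrated)
  beta1: -1.5         # length-dependent activation coefficient

geometry:
  n_slices: 12
  base_radius: 2.5    # mm, endocardial radius at the valve plane (pre-scaling)
  length: 11.0        # mm, apex-to-base cavity length (pre-scaling)
  taper: 0.35         # ellipsoidal taper kappa in r(z) = R*sqrt(1-(1-z)^2*kappa)
  wall_ratio_base: 0.85   # wall thickness / endocardial radius at the base
  wall_ratio_apex: 0.85   # same ratio at the apex (uniform pressure capacity)
  passive_a: 1.0      # kPa, passive stiffness scale (calibrated)
  passive_b: 12.5     # exponential steepness (calibrated)
  target_edv: 125.0   # ul, cavity volume at end-diastolic pressure

hemodynamics:
  c_art_ml_per_mmhg: 0.0144   # ml/mmHg, aortic compliance (printed value)
  r_per: 20.0                 # kPa*ms/ul, peripheral resistance (calibrated)
  z_c: 0.4                    # kPa*ms/ul, characteristic impedance (calibrated)
  p_a: 9.0                    # kPa, minimal aortic (ejection-onset) pressure
  edp: 0.5                    # kPa, end-diastolic pressure

discretization:
  dt: 0.05            # ms, explicit integration step
  n_pacing_cycles: 12 # cell-state pacing cycles before the analysed beat

metrics:
  apical_band: [0.1, 0.4]   # z range of "apical" slices for the A:B index
  basal_band: [0.7, 0.95]   # z range of "basal" slices (valve plane excluded)
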