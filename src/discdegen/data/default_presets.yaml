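# Default degeneration presets and phantom parameters.
#
# The preset table encodes, per treatment and sacrifice week, the "true"
# degeneration state of a disc; the synthetic generator draws noisy raw data
# around these truths and the analysis pipeline is expected to recover them.
#
# Calibration sources (see README for the scientific context):
#   * dhi_trajectory_pct: radiographic %DHI means reported for weeks 4 and 12
#     (MIA 0.01: 87/81, MIA 0.1: 75/61, MIA 1.0: 66/56); intermediate biweekly
#     values are monotone interpolations — ASSUMPTION, only the week-4/12
#     values are reported. CA/NI controls are reported only as "no significant
#     change vs baseline": a flat 100% trajectory is an ASSUMPTION.
#   * zone_gap_scale: posterior-zone 3D-DHI 68.8% (w2) -> 38.2% (w12) and NP
#     87.4% -> 61.3% for MIA 0.1; posterior 56.4% -> 41.7% for MIA 1.0;
#     CA all zones >=90% except posterior at week 2. Weeks 4 and 8 are linear
#     interpolations; anterior/lateral scales and all MIA 0.01 scales are
#     inferred from the reported <90% / >=90% bin memberships — ASSUMPTION.
#   * cell_survival_fraction at week 12: 40.6% / 19.1% / 2.5% of CA control
#     for MIA 0.01 / 0.1 / 1.0; earlier weeks interpolated — ASSUMPTION.
#   * clone_probability: 2/6 discs at weeks 2 and 4 and 3/6 at week 12
#     (MIA 0.01); 2/6 at weeks 4 and 12 (MIA 0.1); none for MIA 1.0.
#   * severity drives T2 decline (t2_scale = 1 - 0.5*severity) and histology
#     category means; absolute T2 baselines (NP 120 ms / AF 40 ms) are
#     literature-scale ASSUMPTIONS — only relative change is calibrated.

geometry:
  a_mm: 7.5              # anteroposterior semi-axis of the elliptical footprint
  b_mm: 5.0              # lateral semi-axis
  base_gap_mm: 1.2       # control disc height (physiologic rabbit lumbar scale)
  points_per_endplate: 2000
  surface_roughness_sd_mm: 0.05
  np_fraction: 0.5       # NP ellipse semi-axis fraction (25% of footprint area)
  blend_mm: 0.5          # smooth blend width across zone boundaries

noise:
  radiograph_sd_mm: 0.05     # i.i.d. measurement noise per height reading
  mr_noise_frac: 0.02        # MR noise sd as a fraction of S0
  mr_noise_model: gaussian
  t2_disc_jitter_frac: 0.05  # per-disc biological T2 variability

baseline:
  np_t2_ms: 120.0
  af_t2_ms: 40.0
  control_alive_per_field: 120   # NP cells per x200 field of view
  anterior_height_mm: 3.8        # radiographic Ha of a healthy disc
  middle_height_mm: 4.2          # Hm
  posterior_height_mm: 3.6       # Hp
  marker_mm: 10.0                # calibration wire length
  marker_px: 200.0               # its projected pixel length (0.05 mm/px)
  te_first_ms: 20.0
  te_last_ms: 400.0
  n_echoes: 20
  tr_ms: 2500.0

# Per-category histology mean = weight * severity, truncated to the score
# range (default 0..2). The endplate is weakly coupled to NP-driven
# degeneration, matching its weaker reported correlation with T2.
histology_category_weights:
  np_shape: 2.0
  np_area: 2.0
  np_matrix: 2.0
  np_cellularity: 2.0
  af_np_border: 2.0
  af: 1.8
  endplate: 0.8

histology_score_range: [0, 2]

# Radiographic %DHI truth per biweekly timepoint (percent of baseline).
dhi_trajectory_pct:
  CA:       {0: 100.0, 2: 100.0, 4: 100.0, 6: 100.0, 8: 100.0, 10: 100.0, 12: 100.0}
  NI:       {0: 100.0, 2: 100.0, 4: 100.0, 6: 100.0, 8: 100.0, 10: 100.0, 12: 100.0}
  MIA_0.01: {0: 100.0, 2: 93.0, 4: 87.0, 6: 85.0, 8: 83.5, 10: 82.0, 12: 81.0}
  MIA_0.1:  {0: 100.0, 2: 85.0, 4: 75.0, 6: 70.0, 8: 66.0, 10: 63.0, 12: 61.0}
  MIA_1.0:  {0: 100.0, 2: 80.0, 4: 66.0, 6: 62.0, 8: 60.0, 10: 58.0, 12: 56.0}

# zone_gap_scale order: posterior, anterior, l_lateral, r_lateral, np
presets:
  NI:
    2:  {zone_gap_scale: {posterior: 1.0, anterior: 1.0, l_lateral: 1.0, r_lateral: 1.0, np: 1.0}, severity: 0.0, cell_survival_fraction: 1.0, clone_probability: 0.0}
    4:  {zone_gap_scale: {posterior: 1.0, anterior: 1.0, l_lateral: 1.0, r_lateral: 1.0, np: 1.0}, severity: 0.0, cell_survival_fraction: 1.0, clone_probability: 0.0}
    8:  {zone_gap_scale: {posterior: 1.0, anterior: 1.0, l_lateral: 1.0, r_lateral: 1.0, np: 1.0}, severity: 0.0, cell_survival_fraction: 1.0, clone_probability: 0.0}
    12: {zone_gap_scale: {posterior: 1.0, anterior: 1.0, l_lateral: 1.0, r_lateral: 1.0, np: 1.0}, severity: 0.0, cell_survival_fraction: 1.0, clone_probability: 0.0}
  CA:
    2:  {zone_gap_scale: {posterior: 0.88, anterior: 0.97, l_lateral: 0.97, r_lateral: 0.97, np: 0.96}, severity: 0.05, cell_survival_fraction: 1.0, clone_probability: 0.0}
    4:  {zone_gap_scale: {posterior: 0.93, anterior: 0.97, l_lateral: 0.97, r_lateral: 0.97, np: 0.96}, severity: 0.05, cell_survival_fraction: 1.0, clone_probability: 0.0}
    8:  {zone_gap_scale: {posterior: 0.92, anterior: 0.97, l_lateral: 0.97, r_lateral: 0.97, np: 0.96}, severity: 0.05, cell_survival_fraction: 1.0, clone_probability: 0.0}
    12: {zone_gap_scale: {posterior: 0.91, anterior: 0.97, l_lateral: 0.97, r_lateral: 0.97, np: 0.96}, severity: 0.05, cell_survival_fraction: 1.0, clone_probability: 0.0}
  MIA_0.01:
    2:  {zone_gap_scale: {posterior: 0.88, anterior: 0.95, l_lateral: 0.96, r_lateral: 0.96, np: 0.92}, severity: 0.15, cell_survival_fraction: 0.75, clone_probability: 0.333}
    4:  {zone_gap_scale: {posterior: 0.86, anterior: 0.93, l_lateral: 0.95, r_lateral: 0.95, np: 0.89}, severity: 0.25, cell_survival_fraction: 0.62, clone_probability: 0.333}
    8:  {zone_gap_scale: {posterior: 0.83, anterior: 0.92, l_lateral: 0.94, r_lateral: 0.94, np: 0.86}, severity: 0.30, cell_survival_fraction: 0.50, clone_probability: 0.333}
    12: {zone_gap_scale: {posterior: 0.80, anterior: 0.91, l_lateral: 0.93, r_lateral: 0.93, np: 0.84}, severity: 0.35, cell_survival_fraction: 0.406, clone_probability: 0.50}
  MIA_0.1:
    2:  {zone_gap_scale: {posterior: 0.688, anterior: 0.93, l_lateral: 0.94, r_lateral: 0.94, np: 0.874}, severity: 0.35, cell_survival_fraction: 0.55, clone_probability: 0.167}
    4:  {zone_gap_scale: {posterior: 0.627, anterior: 0.91, l_lateral: 0.92, r_lateral: 0.92, np: 0.822}, severity: 0.50, cell_survival_fraction: 0.40, clone_probability: 0.333}
    8:  {zone_gap_scale: {posterior: 0.504, anterior: 0.88, l_lateral: 0.89, r_lateral: 0.89, np: 0.717}, severity: 0.60, cell_survival_fraction: 0.28, clone_probability: 0.167}
    12: {zone_gap_scale: {posterior: 0.382, anterior: 0.85, l_lateral: 0.86, r_lateral: 0.86, np: 0.613}, severity: 0.70, cell_survival_fraction: 0.191, clone_probability: 0.333}
  MIA_1.0:
    2:  {zone_gap_scale: {posterior: 0.564, anterior: 0.89, l_lateral: 0.89, r_lateral: 0.89, np: 0.85}, severity: 0.55, cell_survival_fraction: 0.30, clone_probability: 0.0}
    4:  {zone_gap_scale: {posterior: 0.535, anterior: 0.85, l_lateral: 0.86, r_lateral: 0.86, np: 0.76}, severity: 0.70, cell_survival_fraction: 0.15, clone_probability: 0.0}
    8:  {zone_gap_scale: {posterior: 0.476, anterior: 0.80, l_lateral: 0.81, r_lateral: 0.81, np: 0.65}, severity: 0.80, cell_survival_fraction: 0.06, clone_probability: 0.0}
    12: {zone_gap_scale: {posterior: 0.417, anterior: 0.75, l_lateral: 0.76, r_lateral: 0.76, np: 0.55}, severity: 0.90, cell_survival_fraction: 0.025, clone_probability: 0.0}
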