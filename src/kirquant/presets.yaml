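# Default simulation presets.
#
# Ephys presets are calibrated so the true group-mean Ba2+-sensitive current
# density at -150 mV equals the target cd_mean (pA/pF) with between-cell SD
# cd_sd; the Kir conductance density is solved from those targets given the
# shared biophysical parameters.  Blot presets fix the per-lane target
# abundance and the mature-band fraction; the mutant lane carries 0.40x the
# wild-type abundance.  Cell-field presets fix expression level and the
# membrane-localised fraction of the target channel.

ephys:
  shared:
    e_rev_mv: -5.0            # K+ reversal for 115 mM out / 140 mM in at 22 C
    rect_vhalf_mv: -10.0
    rect_slope_mv: 25.0
    g_leak_ns_per_pf: 0.05
    ba_block_frac: 0.95
    capacitance_pf: 12.0
    capacitance_jitter_frac: 0.10
    noise_sd_pa: 10.0
  groups:
    WT:     {cd_mean_pa_per_pf: -147.7, cd_sd_pa_per_pf: 23.1, n_cells: 5}
    MT:     {cd_mean_pa_per_pf: -8.4,   cd_sd_pa_per_pf: 2.3,  n_cells: 7}
    WT+MT:  {cd_mean_pa_per_pf: -19.1,  cd_sd_pa_per_pf: 3.2,  n_cells: 5}

blot:
  shared:
    tubulin_amount: 200.0
    abundance_cv: 0.08        # lane-to-lane biological/loading variability
    background_level: 30.0
    background_tilt: 0.02     # a.u. per px along the migration axis
    band_sigma_px: 1.5
    noise_sd: 1.5
    lane_length_px: 900
    lane_width_px: 40
    upper_mw_kda: 45.0
    lower_mw_kda: 43.0
    loading_mw_kda: 50.0
    ladder_kda: [250, 130, 100, 70, 55, 35, 25, 15, 10]
  lanes:
    NT:          {abundance: 0.0,   upper_frac: 0.70}
    WT:          {abundance: 300.0, upper_frac: 0.70}
    MT:          {abundance: 120.0, upper_frac: 0.70}   # 0.40 x WT
    WT_PNGaseF:  {abundance: 300.0, upper_frac: 0.05}
    MT_PNGaseF:  {abundance: 120.0, upper_frac: 0.05}
    WT_EndoH:    {abundance: 300.0, upper_frac: 0.25}
    MT_EndoH:    {abundance: 120.0, upper_frac: 0.25}

cells:
  shared:
    nucleus_radius_px: 12.0
    cell_radius_px: 28.0
    membrane_width_px: 3
    marker_intensity: 120.0
    nucleus_intensity: 150.0
    nucleoli_count: 2
    nucleoli_radius_px: 2.5
    nucleoli_contrast: 0.6
    noise_gaussian_sd: 2.0
    noise_poisson_scale: 0.0
    image_shape: [512, 512]
  groups:
    WT: {n_cells: 12, membrane_fraction: 0.6, total_expression: 50000.0}
    MT: {n_cells: 12, membrane_fraction: 0.4, total_expression: 20000.0}
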