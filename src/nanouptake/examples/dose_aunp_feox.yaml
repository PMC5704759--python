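# Administered-dose and deposition parameters for the two model particles:
# polymer-shelled gold (AuNP) and iron oxide (FeOx) nanoparticles in
# serum-containing medium at 37 C, four-chamber slide geometry.
species:
  - name: AuNP
    d_core_mean_nm: 4.7
    d_core_sd_nm: 2.0
    d_h_mean_nm: 11.0
    d_h_sd_nm: 3.0
    core_density_g_cm3: 19.2
    shell_density_g_cm3: 1.0
    conc_ug_ml: 38.6
    channel: NP1
  - name: FeOx
    d_core_mean_nm: 13.6
    d_core_sd_nm: 4.0
    d_h_mean_nm: 28.0
    d_h_sd_nm: 9.0
    core_density_g_cm3: 5.24
    shell_density_g_cm3: 1.0
    conc_ug_ml: 54.8
    channel: NP2
setup:
  area_cm2: 1.7
  volume_ml: 0.4
  temp_K: 310.0
  viscosity_Pa_s: 6.9e-4
  medium_density_g_cm3: 1.00
times:
  start: 0
  stop: 86400
  n: 97
  spacing: linear
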