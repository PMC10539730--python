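# Benchtop (1 T) single-cryptophane Z-spectrum with the strong saturation
# normally used at high field -- shows the baseline collapse caused by the
# small free/bound frequency splitting at low field.
larmor_mhz: 12.09
gamma_bar_mhz_t: 11.79
gamma_sign: -1
delta_a_ppm: 196
r1a_s: 0.01
r2a_s: 50
m0a: 1.0
pool1_f: 0.04
pool1_kout_s: 50
pool1_delta_ppm: 52
omega1_rad_s: 521.4
offset_ppm: 52
tsat_s: 1
offsets_ppm: "0:100:201"
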