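# Benchtop (1 T) mixture of two cryptophanes (bound xenon at 52 and 42 ppm,
# 10 ppm apart) with the UFZ gradient pair of the benchtop instrument.
# The rf saturation sits between the two caged-xenon resonances.
larmor_mhz: 12.09
gamma_bar_mhz_t: 11.79
gamma_sign: -1
delta_a_ppm: 196
r1a_s: 0.1
r2a_s: 10
m0a: 1.0
pool1_f: 0.037
pool1_kout_s: 50
pool1_delta_ppm: 52
pool2_f: 0.025
pool2_kout_s: 100
pool2_delta_ppm: 42
omega1_rad_s: 100
offset_ppm: 47
tsat_s: 3
offsets_ppm: "0:100:201"
tube_diameter_m: 0.0043
gsat_t_m: 0.021
gacq_t_m: 0.084
n_positions: 512
noise_sigma: 0.0
off_scale: 1.0
seed: 0
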