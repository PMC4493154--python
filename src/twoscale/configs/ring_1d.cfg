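# 1D ring experiment: a rectangular pulse of height 1 and support 2*R_l
# (total mass 1.5) develops a long-lived double-peak (ring) profile.
name = ring_1d
simulator = continuum
dim = 1
D0 = 1e-4
a = 1.0
b = 3.33
c = 2.67
R_s = 0.4
R_l = 0.75
L = 6.0
grid = 600
t_end = 6e5
pulse_height = 1.0
initial = pulse1d
seed = 1
analyses = ring1d
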