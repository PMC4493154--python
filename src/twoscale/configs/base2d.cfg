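# Shared 2D setup: N = 1e4 individuals on the unit periodic square,
# short radius 0.05, long radius 0.1, maximal diffusivity 1e-4.
D0 = 1e-4
a = 1.0
R_s = 0.05
R_l = 0.1
L = 1.0
N = 10000
dim = 2
seed = 1
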