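# Continuum labyrinth pattern (type-B instability, slower saturation).
include = base2d.cfg
name = continuum_labyrinth
simulator = continuum
b = 8.5e-4
c = 7.0e-4
grid = 256
t_end = 400
snapshot_every = 20
perturbation = 0.01
analyses = structure_function
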