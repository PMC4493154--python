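# Continuum spot pattern: 256^2 grid, perturbed uniform start.
include = base2d.cfg
name = continuum_spots
simulator = continuum
b = 4.3e-4
c = 3.9e-4
grid = 256
t_end = 80
snapshot_every = 4
perturbation = 0.01
analyses = structure_function,diffusivity
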