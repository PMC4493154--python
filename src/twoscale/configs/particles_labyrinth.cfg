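# Labyrinth regime of the particle model.
include = base2d.cfg
name = particles_labyrinth
simulator = particle
b = 8.5e-4
c = 7.0e-4
t_end = 400
snapshot_every = 10
analyses = structure_function
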