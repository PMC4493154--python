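# Spot regime of the particle model: hexagonally arranged hollow clusters.
include = base2d.cfg
name = particles_spots
simulator = particle
b = 4.3e-4
c = 3.9e-4
t_end = 400
snapshot_every = 10
analyses = structure_function,profile
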