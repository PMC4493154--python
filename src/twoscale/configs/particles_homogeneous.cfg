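# Stable regime: long-range dispersal dominates, no pattern forms.
include = base2d.cfg
name = particles_homogeneous
simulator = particle
b = 3.5e-4
c = 7.0e-4
t_end = 200
snapshot_every = 10
analyses = structure_function
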