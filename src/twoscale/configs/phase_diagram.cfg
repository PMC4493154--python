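# Instability classification over the (b, c) plane.
include = base2d.cfg
name = phase_diagram
simulator = stability
b = 4.3e-4
c = 3.9e-4
analyses = phase_diagram
b_range = 0:1.2e-3:25
c_range = 0:1.2e-3:25
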