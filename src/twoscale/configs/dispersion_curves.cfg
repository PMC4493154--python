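# Dispersion relation of the spot regime (type-A instability).
include = base2d.cfg
name = dispersion_curves
simulator = stability
b = 4.3e-4
c = 3.9e-4
analyses = dispersion
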