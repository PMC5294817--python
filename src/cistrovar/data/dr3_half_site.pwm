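>DR3_half_site
A [   0.4250   0.0500   0.0750   0.0500   0.0750   0.8500 ]
C [   0.0750   0.0500   0.0750   0.0500   0.4250   0.0500 ]
G [   0.4250   0.8500   0.4250   0.0500   0.4250   0.0500 ]
T [   0.0750   0.0500   0.4250   0.8500   0.0750   0.0500 ]
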