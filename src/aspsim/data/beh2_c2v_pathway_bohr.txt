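# Be + H2 C2v insertion pathway: H-atom coordinates in bohr.
# Be at the origin; H atoms at (0, +y, z) and (0, -y, z).
# point    y        z
A        2.540    0.000
B        2.080    1.000
C        1.620    2.000
D        1.390    2.500
E        1.275    2.750
F        1.160    3.000
G        0.930    3.500
H        0.700    4.000
I        0.700    6.000
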