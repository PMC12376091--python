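# Default 2:2 primitive model for a divalent metal sulfate:
# sulfate diameter fixed at 4.6 A, water permittivity 78.36 at 25 C.
# The cation diameter is the quantity usually fitted; 4.6 A here is a
# neutral placeholder giving the restricted (equal-diameter) PM.

[model]
epsilon_r = 78.36
temperature_K = 298.15

[[species]]
name = "M"
charge = 2.0
diameter_A = 4.6

[[species]]
name = "X"
charge = -2.0
diameter_A = 4.6
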