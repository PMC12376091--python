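# Nonbonded force-field parameters of the sulfate / divalent-metal MD
# models that the synthetic generators emulate.  Stored as metadata only:
# the primitive model itself is strictly hard-core + Coulomb and never uses
# the Lennard-Jones entries.
#
# sigma_A: LJ sigma (A); epsilon_kJ_mol: LJ epsilon; q_e: charge (e);
# alpha_prime_A3: polarizability volume carried by a Drude shell on the
# sulfur site.  The sulfate ion is rigid-tetrahedral with S-O = 1.52 A and
# O-O = 2.49 A.  The two cation entries are the lambda-mixing end points
# ("small ions" A-state, "large ions" B-state).

[[particle]]
name = "SO4_S"
sigma_A = 3.55
epsilon_kJ_mol = 1.0465
q_e = 0.0

[[particle]]
name = "SO4_S_shell"
sigma_A = 0.0
epsilon_kJ_mol = 0.0
q_e = 2.0
alpha_prime_A3 = 5.0

[[particle]]
name = "SO4_O_mamatkulov"
sigma_A = 3.916
epsilon_kJ_mol = 0.1
q_e = -1.0

[[particle]]
name = "SO4_O_cannon"
sigma_A = 3.15
epsilon_kJ_mol = 0.8368
q_e = -1.0

[[particle]]
name = "M2+_A_state"
sigma_A = 2.6
epsilon_kJ_mol = 0.1
q_e = 2.0

[[particle]]
name = "M2+_B_state"
sigma_A = 3.6
epsilon_kJ_mol = 0.1
q_e = 2.0

[geometry]
S_O_distance_A = 1.52
O_O_distance_A = 2.49
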