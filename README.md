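# ionpair

Primitive-model electrolytes for studying ion pairing in divalent metal
sulfate solutions: an Ornstein–Zernike/HNC integral-equation solver and a
Metropolis Monte Carlo engine for osmotic coefficients, a cation-size
fitter, and configuration statistics for contact / solvent-shared ion pairs
and solvent-shell polarization.

## The problem

Divalent cations such as Mg²⁺ or Zn²⁺ pair with sulfate either in direct
contact (CIP, contact ion pair) or with one water molecule between the ions
(SIP, solvent-shared ion pair). How much of each occurs is controlled by a
competition between the bare Coulomb attraction at contact and the energetic
cost of stripping strongly polarized water from the cation's first shell.
Two experimental/thermodynamic handles on this competition are the osmotic
coefficient φ(m) of the salt solution and, in simulations, the population
N_contact of the cation–sulfate contact peak and the excess induced dipole
Δμ_ind of first-shell waters.

`ionpair` implements the implicit-solvent side of this analysis:

* **Primitive model (PM).** Ions are charged hard spheres in a dielectric
  continuum, u_ij(r) = ∞ for r < d_ij and q_i q_j e²/(4πε ε₀ r) outside, with
  ε = 78.36 (water, 25 °C) and additive radii d₊₋ = (d₊₊ + d₋₋)/2. In the
  package's reduced units βu_ij(r) = q_i q_j l_B / r with the Bjerrum length
  l_B ≈ 7.15 Å.
* **HNC solver.** The multicomponent Ornstein–Zernike equation with the
  hypernetted-chain closure g = exp(−βu + h − c), solved with Ng long-range
  renormalization and Anderson-accelerated Picard iteration; φ by the virial
  route, φ = 1 + contact term + βE_el/3N.
* **Monte Carlo.** Canonical Metropolis sampling of the same PM with plain
  Ewald electrostatics — an independent route to φ used to validate HNC.
* **Cation-size fitting.** With the sulfate diameter fixed at d₋₋ = 4.6 Å,
  the cation diameter d₊₊ is fitted to an osmotic-coefficient curve by
  weighted least squares; d₊₋ follows from additivity.
* **Pairing and polarization statistics.** RDFs, first-peak/CIP–SIP-minimum
  detection, N_contact as the RDF integral up to the CIP/SIP minimum, radial
  CIP/SIP classification, 3.2 Å shell membership, Δμ_ind from per-water
  induced dipoles, Drude-displacement dipoles (μ = q·d), the
  point-polarizability energies U = −(α/2)E² and U = −α′q²/(4πε₀r⁴), and the
  λ-mixed Hamiltonian U = (1−λ)U_A + λU_B with its Metropolis exchange rule.
* **Synthetic data.** Deterministic generators for PM configurations, paired
  configurations with a planted CIP/SIP census, field-polarized water
  dipoles, and synthetic φ(m) curves — everything the pipeline consumes,
  with known ground truth.

## Worked example

```python
import numpy as np
from ionpair import (Species, build_model, bjerrum_length, molality_to_state,
                     solve_hnc, osmotic_coefficient, predict_curve,
                     fit_cation_diameter, RadialGrid)

# restricted 2:2 primitive model of a metal sulfate
pm = build_model([Species("M", +2, 4.6), Species("X", -2, 4.6)],
                 epsilon_r=78.36, temperature=298.15)
print(f"l_B = {bjerrum_length(pm):.4f} A")

state = molality_to_state(pm, 0.5, {"M": 1, "X": 1})
corr = solve_hnc(pm, state)
print(f"phi(0.5 mol/kg) = {osmotic_coefficient(corr):.4f}")

# recover a planted cation diameter from a synthetic curve
template = build_model([Species("M", +2, 3.0), Species("X", -2, 4.6)],
                       78.36, 298.15)
grid = RadialGrid(2**12, 0.02)
curve = predict_curve(template, 2.4, [0.1, 0.5, 1.0, 1.5, 2.0], grid=grid)
fit = fit_cation_diameter(curve, template, grid=grid)
print(f"recovered d_++ = {fit.d_plus_plus:.3f} A (planted 2.4 A)")
```

prints

```
l_B = 7.1524 A
phi(0.5 mol/kg) = 0.6517
recovered d_++ = 2.382 A (planted 2.4 A)
```

The Bjerrum length is the distance at which two unit charges interact with
thermal energy; φ < 1 signals the strong cation–anion attraction of a 2:2
electrolyte; and the fit recovers the cation diameter that generated the
curve to within 0.02 Å (the dilute 0.1 mol/kg point sits at the edge of the
HNC solution region for this small ion and is dropped during part of the
search, which costs the fit its last few thousandths of an angstrom).

A command-line interface mirrors the workflow (`ionpair model show`,
`ionpair hnc`, `ionpair mc`, `ionpair fit`, `ionpair analyze`,
`ionpair generate`); run `ionpair --help` for details.

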