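"""Primitive-model electrolyte definitions and unit conventions.

The primitive model (PM) represents an electrolyte as charged hard spheres in
a structureless dielectric continuum: the pair potential is infinite inside
the distance of closest approach ``d_ij`` and Coulombic,
``u_ij(r) = q_i q_j e^2 / (4 pi eps0 eps_r r)``, outside it.  The solvent
enters only through the relative permittivity ``eps_r``.

Internal unit system
--------------------
lengths in angstrom (A), charges in elementary charges (e), energies in units
of k_B*T at the model temperature, dipole moments in debye (D).  With these
conventions the Coulomb interaction is ``beta*u = q_i q_j l_B / r`` where
``l_B`` is the Bjerrum length in A.

Number densities are in A^-3.  Molality (mol solute per kg solvent) is mapped
to number density assuming a pure-water solvent of density 997.0 kg/m^3 and
zero solute partial volume; the constant is overridable.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import constants as _const

__all__ = [
    "Species",
    "PMModel",
    "IonicState",
    "build_model",
    "load_model",
    "pair_potential",
    "bjerrum_length",
    "scale_charges",
    "molality_to_state",
    "state_to_molality",
    "molality_from_counts",
    "box_edge_from_composition",
    "HARD_CORE",
    "WATER_DENSITY_KG_M3",
    "WATER_MOLAR_MASS_KG_MOL",
    "EA_TO_DEBYE",
]

#: sentinel returned inside the hard core (callers can test with np.isinf)
HARD_CORE = math.inf

#: pure-water solvent mass density used for molality -> number density, kg/m^3
WATER_DENSITY_KG_M3 = 997.0

#: molar mass of water, kg/mol
WATER_MOLAR_MASS_KG_MOL = 0.018015

#: 1 e*A in debye (e * 1e-10 m / (1e-21/c) C m)
EA_TO_DEBYE = _const.e * 1e-10 / (1e-21 / _const.c)

#: Bjerrum length prefactor e^2/(4 pi eps0 k_B) in A*K; divide by (eps_r * T)
_BJERRUM_PREFACTOR_A_K = (
    _const.e**2 / (4.0 * math.pi * _const.epsilon_0 * _const.k) * 1e10
)


class ModelValidationError(ValueError):
    """Raised when a model definition violates a physical constraint."""


@dataclass(frozen=True)
class Species:
    """One particle type of the primitive model.

    Parameters
    ----------
    name : str
        Unique label within a model.
    charge : float
        Charge in elementary charges; fractional values (e.g. +-1.5) are
        allowed to express charge-scaled model variants.
    diameter : float
        Hard-sphere diameter d_ii in A.
    polarizability_volume : float, optional
        alpha' in A^3 for dipole-carrying sites; 0 means nonpolarizable.
    """

    name: str
    charge: float
    diameter: float
    polarizability_volume: float = 0.0

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ModelValidationError(
                f"species {self.name!r}: diameter must be > 0, got {self.diameter}"
            )
        if self.polarizability_volume < 0:
            raise ModelValidationError(
                f"species {self.name!r}: polarizability_volume must be >= 0"
            )


@dataclass(frozen=True)
class PMModel:
    """Immutable primitive-model definition.

    ``closest_approach[i, j]`` holds d_ij in A.  When built through
    :func:`build_model` the table follows the additivity rule
    d_ij = (d_ii + d_jj) / 2.
    """

    species: tuple[Species, ...]
    epsilon_r: float
    temperature: float
    closest_approach: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.epsilon_r > 1.0:
            raise ModelValidationError(
                f"epsilon_r must be > 1, got {self.epsilon_r}"
            )
        if not self.temperature > 0:
            raise ModelValidationError(
                f"temperature must be > 0 K, got {self.temperature}"
            )
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ModelValidationError(f"duplicate species names in {names}")
        d = np.asarray(self.closest_approach, dtype=float)
        if d.shape != (len(names), len(names)):
            raise ModelValidationError("closest_approach table has wrong shape")
        if not np.allclose(d, d.T):
            raise ModelValidationError("closest_approach table must be symmetric")
        if not (d > 0).all():
            raise ModelValidationError("all d_ij must be > 0")
        d.setflags(write=False)
        object.__setattr__(self, "closest_approach", d)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.species])

    def index(self, species: int | str) -> int:
        """Resolve a species given by index or name to its index."""
        if isinstance(species, str):
            try:
                return self.names.index(species)
            except ValueError:
                raise KeyError(
                    f"unknown species {species!r}; model has {self.names}"
                ) from None
        i = int(species)
        if not 0 <= i < self.n_species:
            raise KeyError(f"species index {i} out of range for {self.n_species}")
        return i


@dataclass(frozen=True)
class IonicState:
    """Per-species number densities (A^-3) of an electroneutral solution."""

    model: PMModel
    number_densities: np.ndarray
    molality: float | None = None

    def __post_init__(self) -> None:
        rho = np.asarray(self.number_densities, dtype=float)
        if rho.shape != (self.model.n_species,):
            raise ModelValidationError(
                "number_densities must have one entry per species"
            )
        if (rho < 0).any():
            raise ModelValidationError("number densities must be >= 0")
        q = self.model.charges
        scale = float(np.abs(q) @ rho)
        if scale > 0 and abs(float(q @ rho)) > 1e-12 * scale:
            raise ModelValidationError(
                f"state is not electroneutral: sum q_i rho_i = {float(q @ rho):g}"
            )
        rho.setflags(write=False)
        object.__setattr__(self, "number_densities", rho)

    @property
    def total_density(self) -> float:
        return float(self.number_densities.sum())


def build_model(
    species: Sequence[Species],
    epsilon_r: float,
    temperature: float = 298.15,
) -> PMModel:
    """Build a primitive model with the additive closest-approach rule.

    d_ij = (d_ii + d_jj)/2 for every pair, as for hard spheres taken at
    face value.
    """
    if len(species) < 1:
        raise ModelValidationError("at least one species is required")
    d = np.array([s.diameter for s in species], dtype=float)
    table = 0.5 * (d[:, None] + d[None, :])
    return PMModel(
        species=tuple(species),
        epsilon_r=float(epsilon_r),
        temperature=float(temperature),
        closest_approach=table,
    )


def bjerrum_length(model: PMModel) -> float:
    """Bjerrum length l_B = e^2/(4 pi eps0 eps_r k_B T) in A.

    Two unit charges a Bjerrum length apart interact with energy k_B*T;
    about 7.15 A in water at 25 C.
    """
    return _BJERRUM_PREFACTOR_A_K / (model.epsilon_r * model.temperature)


def pair_potential(
    model: PMModel, i: int | str, j: int | str, r: float | np.ndarray
) -> float | np.ndarray:
    """Pair energy beta*u_ij(r) in units of k_B*T.

    Returns the ``HARD_CORE`` (+inf) sentinel for r < d_ij and
    q_i q_j l_B / r outside the core.  ``r`` may be an array; r > 0 required.
    """
    ii, jj = model.index(i), model.index(j)
    r_arr = np.asarray(r, dtype=float)
    if (r_arr <= 0).any():
        raise ValueError("pair_potential requires r > 0")
    d_ij = model.closest_approach[ii, jj]
    qq = model.species[ii].charge * model.species[jj].charge
    coul = qq * bjerrum_length(model) / r_arr
    out = np.where(r_arr < d_ij, HARD_CORE, coul)
    if np.isscalar(r) or r_arr.ndim == 0:
        return float(out)
    return out


def scale_charges(model: PMModel, factor: float) -> PMModel:
    """Return a new model with every charge multiplied by ``factor``.

    Emulates charge-scaled model variants (e.g. factor 0.5 turns a +-2 salt
    into a +-1 salt, 0.75 into +-1.5); diameters, eps_r and T are untouched.
    """
    if not factor > 0:
        raise ModelValidationError(f"charge scale factor must be > 0, got {factor}")
    scaled = tuple(replace(s, charge=s.charge * factor) for s in model.species)
    return PMModel(
        species=scaled,
        epsilon_r=model.epsilon_r,
        temperature=model.temperature,
        closest_approach=np.array(model.closest_approach),
    )


def molality_to_state(
    model: PMModel,
    molality: float,
    stoichiometry: Mapping[str, float],
    solvent_density: float = WATER_DENSITY_KG_M3,
) -> IonicState:
    """Convert molality (mol salt / kg solvent) to per-species densities.

    rho_i = nu_i * m * N_A * rho_solvent * 1e-30  [A^-3], i.e. the solute is
    assumed to occupy no volume and the solvent to stay at ``solvent_density``.
    Species absent from ``stoichiometry`` get zero density.
    """
    if molality < 0:
        raise ModelValidationError("molality must be >= 0")
    nu = np.zeros(model.n_species)
    for name, count in stoichiometry.items():
        nu[model.index(name)] = count
    q = model.charges
    if abs(float(nu @ q)) > 1e-9 * max(1.0, float(np.abs(nu * q).sum())):
        raise ModelValidationError(
            f"stoichiometry {dict(stoichiometry)} is not electroneutral"
        )
    rho = nu * molality * _const.N_A * solvent_density * 1e-30
    return IonicState(model=model, number_densities=rho, molality=molality)


def state_to_molality(
    state: IonicState,
    stoichiometry: Mapping[str, float],
    solvent_density: float = WATER_DENSITY_KG_M3,
) -> float:
    """Inverse of :func:`molality_to_state` for a state built from a salt."""
    model = state.model
    for name, count in stoichiometry.items():
        if count > 0:
            i = model.index(name)
            rho = state.number_densities[i]
            return float(rho / (count * _const.N_A * solvent_density * 1e-30))
    raise ModelValidationError("stoichiometry has no positive entries")


def molality_from_counts(n_salt: int, n_waters: int) -> float:
    """Molality of a simulation box with ``n_salt`` formula units per
    ``n_waters`` water molecules (12 per 665 gives ~1.00 mol/kg)."""
    if n_waters <= 0:
        raise ModelValidationError("n_waters must be > 0")
    return n_salt / (n_waters * WATER_MOLAR_MASS_KG_MOL)


def box_edge_from_composition(
    n_waters: int,
    n_salt: int,
    salt_molar_mass: float,
    solution_density: float,
    water_molar_mass: float = WATER_MOLAR_MASS_KG_MOL,
) -> float:
    """Cubic box edge (A) for a composition at a given solution density.

    ``salt_molar_mass`` and ``water_molar_mass`` in kg/mol, density in kg/m^3.
    For 665 waters + 12 MgSO4 at ~1100 kg/m^3 this gives ~27.3 A (2.73 nm).
    """
    mass = (n_waters * water_molar_mass + n_salt * salt_molar_mass) / _const.N_A
    volume_m3 = mass / solution_density
    return float(volume_m3 ** (1.0 / 3.0) * 1e10)


def load_model(path) -> PMModel:
    """Read a model definition from a TOML file.

    Expected layout::

        [model]
        epsilon_r = 78.36
        temperature_K = 298.15

        [[species]]
        name = "M"
        charge = 2.0
        diameter_A = 4.6
        alpha_prime_A3 = 0.0   # optional
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    try:
        mblock = doc["model"]
        sblocks = doc["species"]
    except KeyError as exc:
        raise ModelValidationError(f"model file missing section {exc}") from None
    species = [
        Species(
            name=str(b["name"]),
            charge=float(b["charge"]),
            diameter=float(b["diameter_A"]),
            polarizability_volume=float(b.get("alpha_prime_A3", 0.0)),
        )
        for b in sblocks
    ]
    return build_model(
        species,
        epsilon_r=float(mblock["epsilon_r"]),
        temperature=float(mblock.get("temperature_K", 298.15)),
    )
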