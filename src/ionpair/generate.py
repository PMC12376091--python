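"""Synthetic inputs: configurations, planted ion pairs, induced dipoles,
and osmotic-coefficient curves.

These generators produce everything the analysis pipeline consumes without
external data: random hard-core configurations, paired-ion configurations
with a known (planted) CIP/SIP census, water-like dipole carriers polarized
by the Coulomb field of the ions, and phi(m) curves from a primitive model
of known cation diameter.  Every generator is deterministic for a fixed
seed.

The generated structures are static stand-ins for simulation snapshots, not
dynamics: dipoles are single-pass linear response (no self-consistent
polarization) and waters are point dipole carriers without hydrogen
geometry, which is all the downstream statistics consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import Configuration
from .fit import OsmoticCurve, predict_curve
from .hnc import RadialGrid
from .model import EA_TO_DEBYE, IonicState, PMModel

__all__ = [
    "PairedSystemSpec",
    "DipoleFieldSpec",
    "gen_random_config",
    "gen_paired_config",
    "gen_dipole_field",
    "gen_osmotic_curve",
    "SULFATE_SO_DISTANCE",
]

#: rigid S-O bond length of the tetrahedral sulfate geometry, A
SULFATE_SO_DISTANCE = 1.52

#: unit tetrahedron vertices
_TETRAHEDRON = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)


@dataclass(frozen=True)
class PairedSystemSpec:
    """Recipe for a configuration with a planted CIP/SIP census.

    ``n_cip`` cation-anion pairs are placed in direct contact at separation
    ``r_contact``; ``n_sip`` cation-water-anion arrangements put one water
    between the ions, each bond at ``r_sip_gap`` (so the cation-anion
    separation is 2*r_sip_gap).  Remaining particles are dispersed with all
    unplanned cation-anion distances kept beyond the SIP window.
    """

    n_cations: int
    n_anions: int
    n_waters: int
    box_length: float
    n_cip: int = 0
    n_sip: int = 0
    r_contact: float = 3.5
    r_sip_gap: float = 2.9
    seed: int = 0
    tetrahedral_anions: bool = False

    def __post_init__(self) -> None:
        if self.n_cip + self.n_sip > min(self.n_cations, self.n_anions):
            raise ValueError(
                "planted pair counts exceed available cations or anions"
            )
        if self.n_sip > self.n_waters:
            raise ValueError("not enough waters for the requested SIP count")
        if not 0 < self.r_contact < 2 * self.r_sip_gap:
            raise ValueError("need 0 < r_contact < 2*r_sip_gap")


@dataclass(frozen=True)
class DipoleFieldSpec:
    """Linear-response dipole assignment: polarizability volume per
    water-like site (A^3) and whether anion charges contribute to the field."""

    alpha_prime: float = 1.0
    include_anions: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_prime < 0:
            raise ValueError("alpha_prime must be >= 0")


def _min_image(delta: np.ndarray, L: float) -> np.ndarray:
    return delta - L * np.rint(delta / L)


def gen_random_config(
    model: PMModel,
    state: IonicState,
    box_length: float,
    seed: int = 0,
    max_attempts: int = 1_000_000,
) -> Configuration:
    """Uniform non-overlapping placement of a state's particles in a box.

    Counts are densities rounded to integers; hard cores (the model's d_ij
    table) are respected by rejection.  Deterministic per seed.
    """
    from .mc import counts_from_state, place_random

    counts = counts_from_state(state, box_length)
    rng = np.random.Generator(np.random.PCG64(seed))
    pos = place_random(model, counts, box_length, rng, max_attempts)
    names: list[str] = []
    for sp in model.species:
        names.extend([sp.name] * counts.get(sp.name, 0))
    return Configuration(
        positions=pos,
        species=np.array(names, dtype=object),
        box_length=box_length,
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_paired_config(
    spec: PairedSystemSpec,
    cation_species: str = "M",
    anion_species: str = "X",
    water_species: str = "W",
) -> tuple[Configuration, list[dict]]:
    """Build a configuration with an exactly known CIP/SIP census.

    Returns the configuration and a truth record listing every planted pair
    as ``{"kind": "CIP"|"SIP", "cation": i, "anion": j}`` (particle indices).
    Unplanned cation-anion distances are kept beyond 2.2*r_sip_gap so a
    distance-window classifier recovers exactly the planted counts.  With
    ``tetrahedral_anions`` each anion becomes a central S site plus four O
    sites at 1.52 A (labels ``<anion>`` and ``<anion>_O``); pair distances
    refer to the central site.
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    L = spec.box_length
    exclusion = 2.2 * spec.r_sip_gap

    cat_pos: list[np.ndarray] = []
    an_pos: list[np.ndarray] = []
    wat_pos: list[np.ndarray] = []
    truth: list[dict] = []

    def far_from(p: np.ndarray, others: list[np.ndarray], rmin: float) -> bool:
        return all(
            float(np.linalg.norm(_min_image(p - o, L))) >= rmin for o in others
        )

    def place(constraint, max_attempts: int = 200_000) -> np.ndarray:
        for _ in range(max_attempts):
            p = rng.random(3) * L
            if constraint(p):
                return p
        raise RuntimeError(
            "placement failed; box too small for the requested counts"
        )

    # planted CIP: anion at r_contact from its cation, both away from others
    for _ in range(spec.n_cip):
        c = place(lambda p: far_from(p, cat_pos + an_pos, exclusion * 2))
        a = np.mod(c + spec.r_contact * _random_unit(rng), L)
        truth.append({"kind": "CIP", "cation": len(cat_pos), "anion": len(an_pos)})
        cat_pos.append(c)
        an_pos.append(a)

    # planted SIP: cation - water - anion, collinear, r_sip_gap per bond
    for _ in range(spec.n_sip):
        c = place(lambda p: far_from(p, cat_pos + an_pos, exclusion * 2))
        u = _random_unit(rng)
        w = np.mod(c + spec.r_sip_gap * u, L)
        a = np.mod(c + 2.0 * spec.r_sip_gap * u, L)
        truth.append({"kind": "SIP", "cation": len(cat_pos), "anion": len(an_pos)})
        cat_pos.append(c)
        an_pos.append(a)
        wat_pos.append(w)

    # dispersed remainder: keep unplanned cation-anion pairs out of the window
    for _ in range(spec.n_cations - spec.n_cip - spec.n_sip):
        cat_pos.append(place(lambda p: far_from(p, an_pos, exclusion)
                             and far_from(p, cat_pos, 1.0)))
    for _ in range(spec.n_anions - spec.n_cip - spec.n_sip):
        an_pos.append(place(lambda p: far_from(p, cat_pos, exclusion)
                            and far_from(p, an_pos, 1.0)))
    for _ in range(spec.n_waters - spec.n_sip):
        wat_pos.append(place(lambda p: far_from(p, wat_pos, 1.0)))

    positions: list[np.ndarray] = []
    species: list[str] = []
    cation_index: list[int] = []
    anion_index: list[int] = []
    for p in cat_pos:
        cation_index.append(len(positions))
        positions.append(p)
        species.append(cation_species)
    for p in an_pos:
        anion_index.append(len(positions))
        positions.append(p)
        species.append(anion_species)
        if spec.tetrahedral_anions:
            # random rigid orientation of the SO4 tetrahedron
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w0, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w0 * z), 2 * (x * z + w0 * y)],
                [2 * (x * y + w0 * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w0 * x)],
                [2 * (x * z - w0 * y), 2 * (y * z + w0 * x), 1 - 2 * (x * x + y * y)],
            ])
            for vertex in _TETRAHEDRON @ rot.T:
                positions.append(np.mod(p + SULFATE_SO_DISTANCE * vertex, L))
                species.append(anion_species + "_O")
    for p in wat_pos:
        positions.append(p)
        species.append(water_species)

    # remap truth records to final particle indices
    for rec in truth:
        rec["cation"] = cation_index[rec["cation"]]
        rec["anion"] = anion_index[rec["anion"]]

    conf = Configuration(
        positions=np.array(positions),
        species=np.array(species, dtype=object),
        box_length=L,
    )
    return conf, truth


def gen_dipole_field(
    configuration: Configuration,
    dipole_spec: DipoleFieldSpec,
    model: PMModel,
    water_species: str = "W",
) -> Configuration:
    """Assign induced dipoles to water-like sites by linear response.

    Each water site gets mu = alpha' * E_perm, where E_perm is the
    minimum-image Coulomb field (superposition over all ion charges from the
    model; anions optional).  With alpha' in A^3, charges in e and distances
    in A, alpha'*q/r^2 is a dipole in e*A, converted to debye.  Single-pass:
    induced dipoles do not feed back into the field.
    """
    iw = configuration.select(water_species)
    if len(iw) == 0:
        raise ValueError(f"no {water_species!r} sites in the configuration")
    charges: dict[str, float] = {}
    for sp in model.species:
        if sp.charge > 0 or (dipole_spec.include_anions and sp.charge < 0):
            charges[sp.name] = sp.charge
    L = configuration.box_length
    mu = np.zeros_like(configuration.positions)
    wpos = configuration.positions[iw]
    field = np.zeros((len(iw), 3))
    for name, q in charges.items():
        idx = configuration.select(name)
        if len(idx) == 0:
            continue
        delta = _min_image(wpos[:, None, :] - configuration.positions[idx][None, :, :], L)
        r = np.linalg.norm(delta, axis=-1)
        field += (q * delta / r[:, :, None] ** 3).sum(axis=1)
    mu[iw] = dipole_spec.alpha_prime * field * EA_TO_DEBYE
    return Configuration(
        positions=configuration.positions.copy(),
        species=configuration.species.copy(),
        box_length=L,
        induced_dipoles=mu,
    )


def gen_osmotic_curve(
    model_template: PMModel,
    d_plus_plus: float,
    molalities,
    noise_sigma: float = 0.0,
    seed: int = 0,
    grid: RadialGrid | None = None,
    label: str = "synthetic",
) -> OsmoticCurve:
    """Synthetic experimental phi(m) curve: HNC prediction of a primitive
    model with known cation diameter plus i.i.d. Gaussian noise.

    Stands in for measured osmotic-coefficient tables; with noise_sigma = 0
    the curve equals :func:`ionpair.fit.predict_curve` exactly.  HNC failures
    propagate as NaN points.
    """
    base = predict_curve(model_template, d_plus_plus, molalities, grid=grid,
                         label=label)
    if noise_sigma == 0.0:
        return base
    rng = np.random.Generator(np.random.PCG64(seed))
    noisy = base.phi + rng.normal(0.0, noise_sigma, size=len(base))
    return OsmoticCurve(molality=base.molality, phi=noisy, label=label,
                        sigma_phi=np.full(len(base), noise_sigma))
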