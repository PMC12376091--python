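"""Configuration and trajectory statistics for ion pairing and polarization.

Covers radial distribution functions (RDFs), first-peak and CIP/SIP-minimum
detection, coordination numbers (N_contact), contact / solvent-shared ion
pair classification, solvation-shell membership, induced-dipole statistics
(delta mu_ind), point-polarizability energies, and the lambda-mixed
Hamiltonian arithmetic used by Hamiltonian replica exchange.

Conventions: cubic periodic boxes with the minimum-image convention, lengths
in A, dipoles in debye, energies in k_B*T.  CIP = contact ion pair (cation
and anion in direct contact), SIP = solvent-shared ion pair (one water
between them); operationally both are distance windows on the cation-anion
separation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import constants as _const

from .model import EA_TO_DEBYE

__all__ = [
    "Configuration",
    "RDFResult",
    "PairingSummary",
    "MixingState",
    "read_xyz",
    "write_xyz",
    "compute_rdf",
    "find_first_peak",
    "find_cip_sip_minimum",
    "coordination_number",
    "classify_pairs",
    "shell_membership",
    "delta_mu_ind",
    "induced_dipole_from_drude",
    "polarizability_from_volume",
    "upol_field",
    "upol_point_charge",
    "mixed_energy",
    "exchange_acceptance",
    "DEFAULT_SHELL_CUTOFF",
]

#: metal--water-oxygen distance defining first-shell membership, A
DEFAULT_SHELL_CUTOFF = 3.2

#: e^2/(4 pi eps0 k_B T) at T in vacuum, in A: the scale of bare Coulomb
#: energies when charges are in e and lengths in A
def _vacuum_bjerrum(temperature: float) -> float:
    return _const.e**2 / (4 * math.pi * _const.epsilon_0 * _const.k * temperature) * 1e10


@dataclass
class Configuration:
    """One particle configuration in a cubic periodic box.

    positions (N, 3) in A (wrapped into [0, L) on construction); ``species``
    is a length-N label array; ``induced_dipoles`` is an optional (N, 3)
    array in debye, meaningful for dipole-carrying species only.
    """

    positions: np.ndarray
    species: np.ndarray
    box_length: float
    induced_dipoles: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not self.box_length > 0:
            raise ValueError("box_length must be > 0")
        self.positions = np.mod(pos, self.box_length)
        self.species = np.asarray(self.species, dtype=object)
        if self.species.shape != (pos.shape[0],):
            raise ValueError("species must have one label per particle")
        if self.induced_dipoles is not None:
            mu = np.asarray(self.induced_dipoles, dtype=float)
            if mu.shape != pos.shape:
                raise ValueError("induced_dipoles must be (N, 3)")
            self.induced_dipoles = mu

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def select(self, species: str) -> np.ndarray:
        """Indices of all particles with the given species label."""
        return np.flatnonzero(self.species == species)


@dataclass(frozen=True)
class RDFResult:
    """Radial distribution function g_AB(r) for one species pair.

    ``counts`` are raw pair counts per half-open bin [lo, hi); ``rho_B`` is
    the partner number density used in the normalization (A^-3), as needed by
    :func:`coordination_number`.
    """

    bin_edges: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    rho_B: float
    species_A: str = ""
    species_B: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class PairingSummary:
    """Headline ion-pairing numbers for one system."""

    n_contact: float
    r_first_peak: float | None
    r_cip_sip_min: float | None
    n_cip: int
    n_sip: int
    used_fallback_minimum: bool = False

    def __post_init__(self) -> None:
        if self.n_contact < 0:
            raise ValueError("n_contact must be >= 0")
        if (
            self.r_first_peak is not None
            and self.r_cip_sip_min is not None
            and not self.r_first_peak < self.r_cip_sip_min
        ):
            raise ValueError("first peak must precede the CIP/SIP minimum")


@dataclass(frozen=True)
class MixingState:
    """Energies of the two end-point Hamiltonians and the mixing parameter."""

    lam: float
    U_A: float
    U_B: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")


# ---------------------------------------------------------------------------
# extended-XYZ I/O
# ---------------------------------------------------------------------------

def write_xyz(configurations: Sequence[Configuration] | Configuration, path) -> None:
    """Write configurations in the extended-XYZ dialect used throughout.

    Per frame: the atom count, a comment line ``box=<L>``, then one row per
    particle ``species x y z [mux muy muz]``.  Floats use repr precision so a
    read/write round trip is bit-stable.
    """
    if isinstance(configurations, Configuration):
        configurations = [configurations]
    with open(path, "w") as fh:
        for conf in configurations:
            fh.write(f"{conf.n_particles}\n")
            fh.write(f"box={float(conf.box_length)!r}\n")
            has_mu = conf.induced_dipoles is not None
            for k in range(conf.n_particles):
                x, y, z = (float(v) for v in conf.positions[k])
                row = f"{conf.species[k]} {x!r} {y!r} {z!r}"
                if has_mu:
                    mx, my, mz = (float(v) for v in conf.induced_dipoles[k])
                    row += f" {mx!r} {my!r} {mz!r}"
                fh.write(row + "\n")


def read_xyz(path) -> list[Configuration]:
    """Read all frames written by :func:`write_xyz`."""
    frames: list[Configuration] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i])
        comment = lines[i + 1]
        box = None
        for token in comment.split():
            if token.startswith("box="):
                box = float(token[4:])
        if box is None:
            raise ValueError(f"frame comment {comment!r} lacks box=L")
        species, pos, mus = [], [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            species.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
            if len(parts) >= 7:
                mus.append([float(v) for v in parts[4:7]])
        frames.append(
            Configuration(
                positions=np.array(pos),
                species=np.array(species, dtype=object),
                box_length=box,
                induced_dipoles=np.array(mus) if mus else None,
            )
        )
        i += 2 + n
    return frames


# ---------------------------------------------------------------------------
# distances and RDFs
# ---------------------------------------------------------------------------

def minimum_image_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box_length: float
) -> np.ndarray:
    """Pairwise minimum-image distance matrix (len(a), len(b)) in a cubic box."""
    delta = pos_a[:, None, :] - pos_b[None, :, :]
    delta -= box_length * np.rint(delta / box_length)
    return np.sqrt((delta**2).sum(axis=-1))


def compute_rdf(
    configurations: Sequence[Configuration] | Configuration,
    species_A: str,
    species_B: str,
    bin_width: float = 0.05,
    r_max: float | None = None,
) -> RDFResult:
    """Radial distribution function between two species over a trajectory.

    Uses minimum-image distances in the cubic box and normalizes by the
    ideal-gas expectation so that g -> 1 for uncorrelated particles.  For
    A == B self-pairs are excluded and each unordered pair is counted once.
    """
    if isinstance(configurations, Configuration):
        configurations = [configurations]
    if not configurations:
        raise ValueError("need at least one configuration")
    L = configurations[0].box_length
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-9:
        raise ValueError(f"r_max {r_max} exceeds half the box length {L / 2}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    counts = np.zeros(len(edges) - 1)
    ideal_weight = 0.0
    rho_B = 0.0
    same = species_A == species_B
    for conf in configurations:
        ia, ib = conf.select(species_A), conf.select(species_B)
        if len(ia) == 0 or len(ib) == 0:
            continue
        dmat = minimum_image_distances(
            conf.positions[ia], conf.positions[ib], conf.box_length
        )
        if same:
            iu = np.triu_indices(len(ia), k=1)
            dists = dmat[iu]
            n_pairs = len(ia) * (len(ia) - 1) / 2.0
        else:
            dists = dmat.ravel()
            n_pairs = float(len(ia) * len(ib))
        c, _ = np.histogram(dists, bins=edges)
        counts += c
        V = conf.box_length**3
        ideal_weight += n_pairs / V
        rho_B += len(ib) / V
    n_frames = len(configurations)
    rho_B /= n_frames
    shell = 4.0 * math.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal_weight > 0, counts / (shell * ideal_weight), 0.0)
    return RDFResult(
        bin_edges=edges,
        g=g,
        counts=counts,
        rho_B=rho_B,
        species_A=species_A,
        species_B=species_B,
    )


def _smooth5(y: np.ndarray) -> np.ndarray:
    """5-point moving average with edge truncation."""
    kernel = np.ones(5) / 5.0
    padded = np.pad(y, 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _parabolic_refine(x: np.ndarray, y: np.ndarray, k: int) -> float:
    """Vertex of the parabola through points k-1, k, k+1 (clamped at edges)."""
    if k <= 0 or k >= len(x) - 1:
        return float(x[k])
    denom = y[k - 1] - 2 * y[k] + y[k + 1]
    if denom == 0:
        return float(x[k])
    shift = 0.5 * (y[k - 1] - y[k + 1]) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    return float(x[k] + shift * (x[k + 1] - x[k]))


def _local_maxima(y: np.ndarray) -> list[int]:
    return [
        k
        for k in range(1, len(y) - 1)
        if y[k] >= y[k - 1] and y[k] > y[k + 1]
    ]


def _significant_peaks(ys: np.ndarray) -> list[int]:
    """Local maxima of the smoothed curve that rise meaningfully above the
    uncorrelated baseline g = 1: at least 10% of the tallest excess, so bin
    noise on the baseline does not register as structure."""
    excess = float(ys.max()) - 1.0
    if excess <= 0:
        return []
    threshold = 1.0 + 0.1 * excess
    return [k for k in _local_maxima(ys) if ys[k] > threshold]


def find_first_peak(rdf: RDFResult) -> float | None:
    """Position (A) of the first RDF maximum with g > 1, or None.

    The curve is smoothed with a 5-point moving average to locate the peak,
    then the position is refined by a 3-point parabola on the raw curve.
    """
    if int((rdf.g > 0).sum()) < 5:
        raise ValueError("need at least 5 bins with g > 0")
    x = rdf.bin_centers
    ys = _smooth5(rdf.g)
    for k in _significant_peaks(ys):
        lo, hi = max(k - 2, 0), min(k + 3, len(x))
        kraw = lo + int(np.argmax(rdf.g[lo:hi]))
        return _parabolic_refine(x, rdf.g, kraw)
    return None


def find_cip_sip_minimum(rdf: RDFResult) -> float | None:
    """Position (A) of the minimum separating the first two RDF peaks.

    Detects peaks on the smoothed curve; returns None when fewer than two
    peaks with g > 1 exist (single-peak curves have no CIP/SIP boundary).
    """
    x = rdf.bin_centers
    ys = _smooth5(rdf.g)
    peaks = _significant_peaks(ys)
    if len(peaks) < 2:
        return None
    k1, k2 = peaks[0], peaks[1]
    interior = np.arange(k1 + 1, k2)
    if len(interior) == 0:
        return None
    kmin = interior[int(np.argmin(ys[interior]))]
    # least-squares parabola on the raw curve over a window around the
    # smoothed minimum; averages bin noise instead of chasing single bins
    lo, hi = max(kmin - 3, k1 + 1), min(kmin + 4, k2)
    if hi - lo < 3:
        return float(x[kmin])
    coef = np.polyfit(x[lo:hi], rdf.g[lo:hi], 2)
    if coef[0] <= 0:
        return float(x[kmin])
    vertex = -coef[1] / (2.0 * coef[0])
    return float(np.clip(vertex, x[lo], x[hi - 1]))


def first_minimum_after_peak(rdf: RDFResult) -> float | None:
    """First local minimum after the first peak; fallback integration bound
    for N_contact when no second peak exists."""
    x = rdf.bin_centers
    ys = _smooth5(rdf.g)
    peaks = _significant_peaks(ys)
    if not peaks:
        return None
    k1 = peaks[0]
    # first point after the peak where the curve stops decreasing (a flat
    # tail that has relaxed back to the baseline counts as the minimum)
    for k in range(k1 + 1, len(ys) - 1):
        if ys[k + 1] >= ys[k]:
            return _parabolic_refine(x, rdf.g, k)
    return None


def coordination_number(rdf: RDFResult, r_cut: float) -> float:
    """Running coordination number N(r_cut) = 4 pi rho_B int_0^rcut g r^2 dr.

    Trapezoid rule on bin centers; the segment from the last center below
    ``r_cut`` to ``r_cut`` itself is added with a linearly interpolated
    integrand.  With r_cut at the CIP/SIP minimum of a cation-anion RDF this
    is the contact-pair population N_contact.
    """
    x = rdf.bin_centers
    if not 0 < r_cut <= rdf.bin_edges[-1]:
        raise ValueError(f"r_cut {r_cut} outside the binned range")
    integrand = 4.0 * math.pi * rdf.rho_B * rdf.g * x**2
    mask = x <= r_cut
    xs, ys = x[mask], integrand[mask]
    total = float(np.trapezoid(ys, xs)) if len(xs) > 1 else 0.0
    if len(xs) and xs[-1] < r_cut:
        y_cut = float(np.interp(r_cut, x, integrand))
        total += 0.5 * (ys[-1] + y_cut) * (r_cut - xs[-1])
    # leading sliver [0, first center]
    if len(xs):
        total += 0.5 * ys[0] * xs[0]
    return total


# ---------------------------------------------------------------------------
# pair classification and shells
# ---------------------------------------------------------------------------

def classify_pairs(
    configuration: Configuration,
    r_cip: float,
    r_sip: float,
    cation_species: str = "M",
    anion_species: str = "X",
):
    """Label every cation-anion pair as CIP, SIP or unpaired by distance.

    A pair is CIP when r < r_cip, SIP when r_cip <= r < r_sip.  An anion may
    be in contact with several cations simultaneously (aggregates), so counts
    are per pair, not per anion.  Returns ``(labels, n_cip, n_sip)`` where
    ``labels`` is a (n_cation, n_anion) array of strings.
    """
    if not 0 < r_cip < r_sip:
        raise ValueError(f"need 0 < r_cip < r_sip, got {r_cip}, {r_sip}")
    ic = configuration.select(cation_species)
    ia = configuration.select(anion_species)
    d = minimum_image_distances(
        configuration.positions[ic], configuration.positions[ia],
        configuration.box_length,
    )
    labels = np.full(d.shape, "unpaired", dtype=object)
    labels[d < r_sip] = "SIP"
    labels[d < r_cip] = "CIP"
    n_cip = int((labels == "CIP").sum())
    n_sip = int((labels == "SIP").sum())
    return labels, n_cip, n_sip


def shell_membership(
    configuration: Configuration,
    center_species: str,
    partner_species: str,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
) -> np.ndarray:
    """Boolean mask over partner particles: in the first shell of any center.

    A partner is in-shell iff its minimum-image distance to at least one
    center is below ``cutoff`` (3.2 A for metal--water-oxygen by default).
    Membership is counted once per partner regardless of how many centers it
    is close to.
    """
    if not cutoff > 0:
        raise ValueError("cutoff must be > 0")
    centers = configuration.select(center_species)
    partners = configuration.select(partner_species)
    if len(centers) == 0 or len(partners) == 0:
        return np.zeros(len(partners), dtype=bool)
    d = minimum_image_distances(
        configuration.positions[partners], configuration.positions[centers],
        configuration.box_length,
    )
    return (d < cutoff).any(axis=1)


def delta_mu_ind(
    configurations: Sequence[Configuration] | Configuration,
    cutoff: float = DEFAULT_SHELL_CUTOFF,
    cation_species: str = "M",
    water_species: str = "W",
) -> float:
    """Excess induced-dipole magnitude of first-shell waters, in debye.

    delta mu_ind = <|mu|> over waters within ``cutoff`` of any cation minus
    <|mu|> over all other waters, averaged over frames.  Frames where either
    class is empty are skipped.  Magnitudes (not vector components) are
    averaged.
    """
    if isinstance(configurations, Configuration):
        configurations = [configurations]
    diffs = []
    for conf in configurations:
        if conf.induced_dipoles is None:
            raise ValueError("configuration carries no induced dipoles")
        iw = conf.select(water_species)
        if len(iw) == 0:
            continue
        in_shell = shell_membership(conf, cation_species, water_species, cutoff)
        mags = np.linalg.norm(conf.induced_dipoles[iw], axis=1)
        if in_shell.sum() == 0 or (~in_shell).sum() == 0:
            continue
        diffs.append(float(mags[in_shell].mean() - mags[~in_shell].mean()))
    if not diffs:
        raise ValueError("no frame had both shell and bulk waters")
    return float(np.mean(diffs))


# ---------------------------------------------------------------------------
# polarization energetics
# ---------------------------------------------------------------------------

def induced_dipole_from_drude(
    shell_displacement: np.ndarray, shell_charge: float
) -> np.ndarray:
    """Induced dipole mu = q * d of a Drude shell particle, in debye.

    ``shell_displacement`` is the shell-core separation vector in A and
    ``shell_charge`` the shell charge in e; 1 e*A = 4.8032 D.
    """
    return np.asarray(shell_displacement, dtype=float) * shell_charge * EA_TO_DEBYE


def polarizability_from_volume(
    alpha_prime: float, temperature: float = 298.15
) -> float:
    """Convert a polarizability volume alpha' (A^3) to the reduced
    polarizability used by :func:`upol_field`.

    With fields expressed as the reduced Coulomb field E = q/r^2 (e/A^2), the
    SI relation alpha = 4 pi eps0 alpha' becomes alpha_red = alpha' *
    e^2/(4 pi eps0 k_B T) in k_B T A^4 / e^2."""
    if alpha_prime < 0:
        raise ValueError("alpha_prime must be >= 0")
    return alpha_prime * _vacuum_bjerrum(temperature)


def upol_field(alpha: float, field) -> float:
    """Polarization energy of a point polarizability in a field:
    U = -(alpha/2) |E|^2, always <= 0.

    ``field`` may be a vector or a magnitude, in reduced units of e/A^2
    (i.e. q/r^2 for a bare point charge); ``alpha`` in k_B T A^4/e^2, see
    :func:`polarizability_from_volume`.  Returns k_B T.
    """
    if alpha < 0:
        raise ValueError("polarizability must be >= 0")
    e2 = float(np.sum(np.asarray(field, dtype=float) ** 2))
    return -0.5 * alpha * e2


def upol_point_charge(
    alpha_prime: float,
    charge: float,
    distance: float,
    temperature: float = 298.15,
    half_consistent: bool = False,
) -> float:
    """Polarization energy of a polarizability volume near a point charge:
    U = -alpha' q^2 / (4 pi eps0 r^4), in k_B T.

    Strictly negative for q != 0; scales as q^2 and 1/r^4 (small, highly
    charged ions polarize their surroundings disproportionately).  With
    ``half_consistent=True`` the extra factor 1/2 that follows from
    U = -(alpha/2) E^2 with E = q/(4 pi eps0 r^2) is included; the default
    omits it (the two conventions differ by exactly a factor of two).
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    if alpha_prime < 0:
        raise ValueError("alpha_prime must be >= 0")
    u = -alpha_prime * charge**2 * _vacuum_bjerrum(temperature) / distance**4
    return 0.5 * u if half_consistent else u


# ---------------------------------------------------------------------------
# lambda mixing / replica exchange arithmetic
# ---------------------------------------------------------------------------

def mixed_energy(mixing_state: MixingState) -> float:
    """Total energy of a lambda-mixed Hamiltonian:
    U = (1 - lambda) U_A + lambda U_B."""
    s = mixing_state
    return (1.0 - s.lam) * s.U_A + s.lam * s.U_B


def exchange_acceptance(delta_beta_U: float) -> float:
    """Metropolis acceptance probability min(1, exp(-delta_beta_U)) for a
    replica-exchange (or displacement) move with total-energy change
    ``delta_beta_U`` in k_B T."""
    if not np.isfinite(delta_beta_U):
        raise ValueError("delta_beta_U must be finite")
    if delta_beta_U <= 0:
        return 1.0
    return float(math.exp(-delta_beta_U))
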