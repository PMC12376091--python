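"""Canonical Metropolis Monte Carlo of the primitive model with Ewald sums.

Single-particle displacement moves with the Metropolis rule
min(1, exp(-beta dU)); hard-core overlaps are always rejected.  Periodic
Coulomb energies use a plain (non-mesh) Ewald decomposition with tin-foil
boundary conditions — adequate for the few hundred particles used here.
The engine serves as the simulation oracle against which the HNC osmotic
coefficients are validated.

All energies are in k_B*T, lengths in A, charges in e; the dielectric
continuum enters through the Bjerrum length, exactly as in the pair
potential of the model.

The inner loop is JIT-compiled with numba; reproducibility is per-seed and
per-platform (numba's Mersenne-Twister is seeded inside the kernel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .analysis import Configuration, RDFResult
from .model import IonicState, PMModel, bjerrum_length

__all__ = [
    "EwaldParams",
    "MCConfig",
    "MCResult",
    "run_mc",
    "ewald_energy",
    "mc_osmotic_coefficient",
    "metropolis_acceptance",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Initial non-overlapping placement failed; lower the density."""


@dataclass(frozen=True)
class EwaldParams:
    """Ewald splitting parameter alpha (A^-1), reciprocal cutoff kmax
    (integer shells), and real-space cutoff (A)."""

    alpha: float
    kmax: int
    real_cutoff: float

    @staticmethod
    def auto(box_length: float, kmax: int = 8) -> "EwaldParams":
        """Conventional choice alpha = 5.6/L with real cutoff L/2."""
        return EwaldParams(alpha=5.6 / box_length, kmax=kmax,
                           real_cutoff=box_length / 2.0)


@dataclass(frozen=True)
class MCConfig:
    """Run parameters for one canonical MC simulation."""

    counts: dict  # species name -> particle count
    box_length: float
    max_displacement: float = 1.0
    n_equilibration: int = 100_000
    n_production: int = 1_000_000
    seed: int = 0
    ewald: EwaldParams | None = None  # None -> EwaldParams.auto(box_length)
    rdf_bin_width: float = 0.05
    n_blocks: int = 20
    sample_interval: int = 0  # moves between samples; 0 -> one sweep (N moves)
    recompute_interval: int = 10_000
    n_snapshots: int = 10


@dataclass
class MCResult:
    """Outputs of one MC run; errors are block-averaged standard errors."""

    acceptance_rate: float
    mean_beta_energy_per_particle: float
    energy_stderr: float
    block_energies: np.ndarray
    rdf: dict
    block_rdf_counts: dict
    n_rdf_samples_per_block: np.ndarray
    snapshots: list
    phi: float | None = None
    phi_stderr: float | None = None
    max_bookkeeping_drift: float = 0.0
    config: MCConfig | None = None
    model: PMModel | None = None
    counts: dict = field(default_factory=dict)


def metropolis_acceptance(delta_beta_u: float) -> float:
    """min(1, exp(-beta dU)); detailed balance requires
    p(fwd)/p(rev) = exp(-beta dU) which this rule satisfies exactly."""
    if delta_beta_u <= 0:
        return 1.0
    return math.exp(-delta_beta_u)


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _axis_table(x: float, L: float, kmax: int, cr: np.ndarray, ci: np.ndarray):
    """cos/sin of 2*pi*n*x/L for n = 0..kmax via the angle-addition recurrence."""
    cr[0] = 1.0
    ci[0] = 0.0
    c1 = math.cos(2.0 * math.pi * x / L)
    s1 = math.sin(2.0 * math.pi * x / L)
    for n in range(1, kmax + 1):
        cr[n] = cr[n - 1] * c1 - ci[n - 1] * s1
        ci[n] = ci[n - 1] * c1 + cr[n - 1] * s1


@njit(cache=False)
def _eikr(kvecs: np.ndarray, cr: np.ndarray, ci: np.ndarray,
          out_re: np.ndarray, out_im: np.ndarray):
    """exp(i k.r) for all half-space k-vectors from per-axis tables."""
    for m in range(kvecs.shape[0]):
        nx, ny, nz = kvecs[m, 0], kvecs[m, 1], kvecs[m, 2]
        re = cr[0, nx]
        im = ci[0, nx]
        ay = abs(ny)
        cy = cr[1, ay]
        sy = ci[1, ay] if ny >= 0 else -ci[1, ay]
        re, im = re * cy - im * sy, re * sy + im * cy
        az = abs(nz)
        cz = cr[2, az]
        sz = ci[2, az] if nz >= 0 else -ci[2, az]
        out_re[m] = re * cz - im * sz
        out_im[m] = re * sz + im * cz


@njit(cache=False)
def _real_energy_particle(pos: np.ndarray, x: float, y: float, z: float,
                          skip: int, qi: float, q: np.ndarray,
                          spp: np.ndarray, dmat: np.ndarray, L: float,
                          lB: float, alpha: float, rcut: float, si: int):
    """erfc-screened real-space energy of one particle of charge ``qi`` and
    species ``si`` at (x,y,z) with all others; returns (energy, overlap_flag)."""
    u = 0.0
    rcut2 = rcut * rcut
    for j in range(pos.shape[0]):
        if j == skip:
            continue
        dx = x - pos[j, 0]
        dy = y - pos[j, 1]
        dz = z - pos[j, 2]
        dx -= L * round(dx / L)
        dy -= L * round(dy / L)
        dz -= L * round(dz / L)
        r2 = dx * dx + dy * dy + dz * dz
        d = dmat[si, spp[j]]
        if r2 < d * d:
            return 0.0, True
        if r2 < rcut2 and qi != 0.0 and q[j] != 0.0:
            r = math.sqrt(r2)
            u += qi * q[j] * lB * math.erfc(alpha * r) / r
    return u, False


@njit(cache=False)
def _full_energy(pos: np.ndarray, q: np.ndarray, spp: np.ndarray,
                 dmat: np.ndarray, L: float, lB: float, use_ewald: int,
                 alpha: float, rcut: float, kvecs: np.ndarray, Ak: np.ndarray,
                 Sre: np.ndarray, Sim: np.ndarray):
    """Total beta-energy (real + reciprocal + self); fills S(k) in place.
    Returns (energy, overlap_flag)."""
    N = pos.shape[0]
    u_real = 0.0
    rcut2 = rcut * rcut
    for i in range(N):
        for j in range(i + 1, N):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r2 = dx * dx + dy * dy + dz * dz
            d = dmat[spp[i], spp[j]]
            if r2 < d * d:
                return 0.0, True
            if use_ewald and r2 < rcut2 and q[i] != 0.0 and q[j] != 0.0:
                r = math.sqrt(r2)
                u_real += q[i] * q[j] * lB * math.erfc(alpha * r) / r
    if not use_ewald:
        return 0.0, False
    M = kvecs.shape[0]
    kmax = 0
    for m in range(M):
        for a in range(3):
            if abs(kvecs[m, a]) > kmax:
                kmax = abs(kvecs[m, a])
    cr = np.empty((3, kmax + 1))
    ci = np.empty((3, kmax + 1))
    ere = np.empty(M)
    eim = np.empty(M)
    for m in range(M):
        Sre[m] = 0.0
        Sim[m] = 0.0
    for i in range(N):
        if q[i] == 0.0:
            continue
        for a in range(3):
            _axis_table(pos[i, a], L, kmax, cr[a], ci[a])
        _eikr(kvecs, cr, ci, ere, eim)
        for m in range(M):
            Sre[m] += q[i] * ere[m]
            Sim[m] += q[i] * eim[m]
    u_recip = 0.0
    for m in range(M):
        u_recip += Ak[m] * (Sre[m] * Sre[m] + Sim[m] * Sim[m])
    q2 = 0.0
    for i in range(N):
        q2 += q[i] * q[i]
    u_self = -lB * alpha / math.sqrt(math.pi) * q2
    return u_real + u_recip + u_self, False


@njit(cache=False)
def _mc_kernel(pos, q, spp, dmat, L, lB, use_ewald, alpha, rcut, kvecs, Ak,
               kmax, n_eq, n_prod, max_disp, seed, n_blocks, sample_interval,
               recompute_interval, rdf_interval, nbins, bin_w, pair_index,
               n_pair_types, n_snapshots):
    np.random.seed(seed)
    N = pos.shape[0]
    M = kvecs.shape[0]
    Sre = np.zeros(M)
    Sim = np.zeros(M)
    U, overlap = _full_energy(pos, q, spp, dmat, L, lB, use_ewald, alpha,
                              rcut, kvecs, Ak, Sre, Sim)
    cr = np.empty((3, kmax + 1))
    ci = np.empty((3, kmax + 1))
    e_old_re = np.empty(M)
    e_old_im = np.empty(M)
    e_new_re = np.empty(M)
    e_new_im = np.empty(M)

    n_acc = 0
    block_E = np.zeros(n_blocks)
    block_nE = np.zeros(n_blocks)
    rdf_counts = np.zeros((n_blocks, n_pair_types, nbins))
    rdf_nsamp = np.zeros(n_blocks)
    snapshots = np.zeros((n_snapshots, N, 3))
    snap_interval = max(n_prod // n_snapshots, 1)
    max_drift = 0.0

    total_moves = n_eq + n_prod
    for move in range(total_moves):
        i = int(np.random.random() * N)
        if i == N:
            i = N - 1
        xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
        xn = (xo + (np.random.random() * 2.0 - 1.0) * max_disp) % L
        yn = (yo + (np.random.random() * 2.0 - 1.0) * max_disp) % L
        zn = (zo + (np.random.random() * 2.0 - 1.0) * max_disp) % L
        si = spp[i]
        u_new, ov = _real_energy_particle(pos, xn, yn, zn, i, q[i], q, spp,
                                          dmat, L, lB, alpha, rcut, si)
        accepted = False
        if not ov:
            u_old, _ = _real_energy_particle(pos, xo, yo, zo, i, q[i], q, spp,
                                             dmat, L, lB, alpha, rcut, si)
            dU = u_new - u_old
            if use_ewald and q[i] != 0.0:
                for a in range(3):
                    _axis_table(pos[i, a], L, kmax, cr[a], ci[a])
                _eikr(kvecs, cr, ci, e_old_re, e_old_im)
                _axis_table(xn, L, kmax, cr[0], ci[0])
                _axis_table(yn, L, kmax, cr[1], ci[1])
                _axis_table(zn, L, kmax, cr[2], ci[2])
                _eikr(kvecs, cr, ci, e_new_re, e_new_im)
                for m in range(M):
                    dre = q[i] * (e_new_re[m] - e_old_re[m])
                    dim = q[i] * (e_new_im[m] - e_old_im[m])
                    dU += Ak[m] * (
                        (Sre[m] + dre) ** 2 + (Sim[m] + dim) ** 2
                        - Sre[m] ** 2 - Sim[m] ** 2
                    )
            if dU <= 0.0 or np.random.random() < math.exp(-min(dU, 700.0)):
                accepted = True
                U += dU
                pos[i, 0], pos[i, 1], pos[i, 2] = xn, yn, zn
                if use_ewald and q[i] != 0.0:
                    for m in range(M):
                        Sre[m] += q[i] * (e_new_re[m] - e_old_re[m])
                        Sim[m] += q[i] * (e_new_im[m] - e_old_im[m])
        if accepted:
            n_acc += 1

        if (move + 1) % recompute_interval == 0:
            U_full, _ = _full_energy(pos, q, spp, dmat, L, lB, use_ewald,
                                     alpha, rcut, kvecs, Ak, Sre, Sim)
            drift = abs(U - U_full) / max(1.0, abs(U_full))
            if drift > max_drift:
                max_drift = drift
            U = U_full

        if move >= n_eq:
            p = move - n_eq
            b = p * n_blocks // n_prod
            if (p + 1) % sample_interval == 0:
                block_E[b] += U
                block_nE[b] += 1.0
            if (p + 1) % rdf_interval == 0:
                rdf_nsamp[b] += 1.0
                for ii in range(N):
                    for jj in range(ii + 1, N):
                        dx = pos[ii, 0] - pos[jj, 0]
                        dy = pos[ii, 1] - pos[jj, 1]
                        dz = pos[ii, 2] - pos[jj, 2]
                        dx -= L * round(dx / L)
                        dy -= L * round(dy / L)
                        dz -= L * round(dz / L)
                        r = math.sqrt(dx * dx + dy * dy + dz * dz)
                        kb = int(r / bin_w)
                        if kb < nbins:
                            rdf_counts[b, pair_index[spp[ii], spp[jj]], kb] += 1.0
            if (p + 1) % snap_interval == 0:
                s = (p + 1) // snap_interval - 1
                if s < n_snapshots:
                    for ii in range(N):
                        for a in range(3):
                            snapshots[s, ii, a] = pos[ii, a]

    return (n_acc, U, block_E, block_nE, rdf_counts, rdf_nsamp, snapshots,
            max_drift)


# ---------------------------------------------------------------------------
# setup helpers
# ---------------------------------------------------------------------------


def _half_space_kvectors(kmax: int) -> np.ndarray:
    """Integer k-vectors with 0 < |n|^2 <= kmax^2, one of each +-k pair."""
    out = []
    for nx in range(0, kmax + 1):
        for ny in range(-kmax, kmax + 1):
            for nz in range(-kmax, kmax + 1):
                if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                    continue
                n2 = nx * nx + ny * ny + nz * nz
                if 0 < n2 <= kmax * kmax:
                    out.append((nx, ny, nz))
    return np.array(out, dtype=np.int64)


def _ewald_coefficients(kvecs: np.ndarray, L: float, lB: float,
                        alpha: float) -> np.ndarray:
    """A_k = (2 pi lB / V) * 2 * exp(-k^2/4 alpha^2)/k^2 (half-space weight 2)."""
    V = L**3
    k2 = (2.0 * math.pi / L) ** 2 * (kvecs**2).sum(axis=1)
    return 4.0 * math.pi * lB / V * np.exp(-k2 / (4.0 * alpha**2)) / k2


def _species_arrays(model: PMModel, counts: dict):
    names = []
    spp = []
    for si, sp in enumerate(model.species):
        n = int(counts.get(sp.name, 0))
        names.extend([sp.name] * n)
        spp.extend([si] * n)
    spp = np.array(spp, dtype=np.int64)
    q = model.charges[spp] if len(spp) else np.zeros(0)
    net = float((model.charges * np.array(
        [counts.get(s.name, 0) for s in model.species])).sum())
    if abs(net) > 1e-9:
        raise ValueError(f"particle counts are not electroneutral (net {net:g} e)")
    return np.array(names, dtype=object), spp, q


def place_random(model: PMModel, counts: dict, box_length: float,
                 rng: np.random.Generator,
                 max_attempts: int = 1_000_000) -> np.ndarray:
    """Random sequential insertion respecting all hard cores (min image)."""
    _, spp, _ = _species_arrays(model, counts)
    N = len(spp)
    pos = np.zeros((N, 3))
    dmat = model.closest_approach
    placed = 0
    attempts = 0
    while placed < N:
        trial = rng.random(3) * box_length
        ok = True
        for j in range(placed):
            delta = trial - pos[j]
            delta -= box_length * np.rint(delta / box_length)
            if (delta**2).sum() < dmat[spp[placed], spp[j]] ** 2:
                ok = False
                break
        if ok:
            pos[placed] = trial
            placed += 1
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place particle {placed + 1}/{N} after "
                f"{max_attempts} attempts; lower the density"
            )
    return pos


def counts_from_state(state: IonicState, box_length: float) -> dict:
    """Round per-species densities to particle counts for a given box."""
    V = box_length**3
    return {
        s.name: int(round(rho * V))
        for s, rho in zip(state.model.species, state.number_densities)
    }


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def ewald_energy(configuration: Configuration, model: PMModel,
                 ewald: EwaldParams | None = None) -> float:
    """Total periodic Coulomb energy (k_B*T) of a configuration.

    Real-space + reciprocal + self terms under tin-foil boundary conditions.
    The configuration must be electroneutral; for a fixed electroneutral
    configuration the result is independent of the splitting parameter
    within the truncation accuracy of ``kmax`` and the real-space cutoff.
    """
    L = configuration.box_length
    if ewald is None:
        ewald = EwaldParams.auto(L)
    if ewald.real_cutoff > L / 2.0 + 1e-9:
        raise ValueError("real_cutoff must be <= box_length/2")
    spp = np.array([model.index(s) for s in configuration.species],
                   dtype=np.int64)
    q = model.charges[spp]
    if abs(q.sum()) > 1e-9:
        raise ValueError("configuration is not electroneutral")
    lB = bjerrum_length(model)
    kvecs = _half_space_kvectors(ewald.kmax)
    Ak = _ewald_coefficients(kvecs, L, lB, ewald.alpha)
    Sre = np.zeros(len(kvecs))
    Sim = np.zeros(len(kvecs))
    # zero-size core table: overlap rejection is not this function's job
    tiny = np.full_like(model.closest_approach, 1e-12)
    u, _ = _full_energy(np.ascontiguousarray(configuration.positions, dtype=float),
                        q.astype(float), spp, tiny, L, lB, 1,
                        ewald.alpha, ewald.real_cutoff, kvecs, Ak, Sre, Sim)
    return float(u)


def run_mc(model: PMModel, state_or_counts, mc_config: MCConfig) -> MCResult:
    """Run canonical Metropolis MC and collect energies, RDFs and phi.

    ``state_or_counts`` is either an :class:`IonicState` (densities rounded
    to counts in the configured box) or a dict of per-species counts.  The
    trajectory is bit-reproducible for a fixed seed on one platform.
    """
    cfg = mc_config
    L = cfg.box_length
    if isinstance(state_or_counts, IonicState):
        counts = counts_from_state(state_or_counts, L)
    else:
        counts = dict(state_or_counts)
    names, spp, q = _species_arrays(model, counts)
    N = len(spp)
    if N == 0:
        raise ValueError("no particles requested")
    if L <= 2.0 * model.closest_approach.max():
        raise ValueError("box_length must exceed twice the largest d_ij")
    use_ewald = int(np.any(q != 0.0))
    ewald = cfg.ewald or EwaldParams.auto(L)
    if ewald.real_cutoff > L / 2.0 + 1e-9:
        raise ValueError("real_cutoff must be <= box_length/2")
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    pos = place_random(model, counts, L, rng)

    kvecs = _half_space_kvectors(ewald.kmax) if use_ewald else np.zeros(
        (1, 3), dtype=np.int64)
    lB = bjerrum_length(model)
    Ak = _ewald_coefficients(kvecs, L, lB, ewald.alpha) if use_ewald else \
        np.zeros(1)

    ns = model.n_species
    pair_index = np.zeros((ns, ns), dtype=np.int64)
    p = 0
    for i in range(ns):
        for j in range(i, ns):
            pair_index[i, j] = pair_index[j, i] = p
            p += 1
    n_pair_types = p
    nbins = int((L / 2.0) / cfg.rdf_bin_width)
    sample_interval = cfg.sample_interval or N
    rdf_interval = sample_interval

    (n_acc, _, block_E, block_nE, rdf_counts, rdf_nsamp, snaps,
     max_drift) = _mc_kernel(
        pos, q.astype(float), spp, model.closest_approach, L, lB, use_ewald,
        ewald.alpha, ewald.real_cutoff, kvecs, Ak, ewald.kmax,
        cfg.n_equilibration, cfg.n_production, cfg.max_displacement,
        cfg.seed % 2**31, cfg.n_blocks, sample_interval,
        cfg.recompute_interval, rdf_interval, nbins, cfg.rdf_bin_width,
        pair_index, n_pair_types, cfg.n_snapshots)

    with np.errstate(invalid="ignore", divide="ignore"):
        blocks = np.where(block_nE > 0, block_E / np.maximum(block_nE, 1), 0.0)
    blocks_per_particle = blocks / N
    mean_E = float(blocks_per_particle.mean())
    err_E = float(blocks_per_particle.std(ddof=1) / math.sqrt(cfg.n_blocks))

    edges = np.arange(nbins + 1) * cfg.rdf_bin_width
    V = L**3
    rdf = {}
    block_rdf = {}
    shell = 4.0 * math.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    for i in range(ns):
        for j in range(i, ns):
            na = counts.get(model.names[i], 0)
            nb = counts.get(model.names[j], 0)
            if na == 0 or nb == 0:
                continue
            n_pairs = na * (na - 1) / 2.0 if i == j else float(na * nb)
            if n_pairs == 0:
                continue
            cts = rdf_counts[:, pair_index[i, j], :]
            total = cts.sum(axis=0)
            nsamp = rdf_nsamp.sum()
            g = total / (nsamp * n_pairs * shell / V)
            rdf[(model.names[i], model.names[j])] = RDFResult(
                bin_edges=edges, g=g, counts=total, rho_B=nb / V,
                species_A=model.names[i], species_B=model.names[j])
            block_rdf[(model.names[i], model.names[j])] = cts

    snapshots = [
        Configuration(positions=snaps[s].copy(),
                      species=np.array(names, dtype=object), box_length=L)
        for s in range(cfg.n_snapshots)
    ]
    result = MCResult(
        acceptance_rate=n_acc / (cfg.n_equilibration + cfg.n_production),
        mean_beta_energy_per_particle=mean_E,
        energy_stderr=err_E,
        block_energies=blocks_per_particle,
        rdf=rdf,
        block_rdf_counts=block_rdf,
        n_rdf_samples_per_block=rdf_nsamp,
        snapshots=snapshots,
        max_bookkeeping_drift=float(max_drift),
        config=cfg,
        model=model,
        counts=counts,
    )
    try:
        result.phi, result.phi_stderr = mc_osmotic_coefficient(result)
    except ValueError:
        pass
    return result


def _contact_from_counts(cts: np.ndarray, edges: np.ndarray, n_pairs: float,
                         nsamp: float, V: float, d: float, bu_contact) -> float:
    """g(d+) from binned counts via the cavity function y = g exp(beta u).

    ln y is smooth and slowly varying across a charged contact, so a
    count-weighted linear fit over the first five bins outside the core
    extrapolates it to contact with low variance; g = y exp(-beta u) there.
    Falls back to the nearest-bin value if the fit misbehaves on sparse
    histograms."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell = 4.0 * math.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = cts / (nsamp * n_pairs * shell / V)
    usable = np.flatnonzero(edges[:-1] >= d - 1e-9)
    usable = usable[g[usable] > 0][:5]
    if len(usable) < 3:
        raise ValueError(
            "contact region has fewer than 3 populated bins; cannot "
            "extrapolate g at contact")
    y = np.log(g[usable]) + bu_contact(centers[usable])
    anchor = float(y[0])
    weights = np.sqrt(cts[usable])
    coef = np.polyfit(centers[usable], y, 1, w=weights)
    val = float(np.polyval(coef, d))
    if not np.isfinite(val) or abs(val - anchor) > math.log(10.0):
        val = anchor
    return float(math.exp(val - bu_contact(d)))


def mc_osmotic_coefficient(result: MCResult) -> tuple[float, float]:
    """Osmotic coefficient from an MC run, by the virial route.

    Per block: phi_b = 1 + (2 pi/3 rho) sum_ij rho_i rho_j d_ij^3 g_ij(d+)
    + beta<E_el>_b/(3N), with contact values extrapolated from the block RDF
    histograms.  Returns (mean, standard error over blocks).
    """
    model, cfg, counts = result.model, result.config, result.counts
    if model is None or cfg is None:
        raise ValueError("result lacks model/config metadata")
    L = cfg.box_length
    V = L**3
    N = sum(counts.values())
    lB = bjerrum_length(model)
    edges = np.arange(int((L / 2.0) / cfg.rdf_bin_width) + 1) * cfg.rdf_bin_width
    rho_tot = N / V
    n_blocks = cfg.n_blocks
    phis = np.zeros(n_blocks)
    for b in range(n_blocks):
        nsamp = result.n_rdf_samples_per_block[b]
        if nsamp == 0:
            raise ValueError("a block has no RDF samples")
        contact = 0.0
        for (a_name, b_name), cts in result.block_rdf_counts.items():
            i, j = model.index(a_name), model.index(b_name)
            na, nb = counts[a_name], counts[b_name]
            n_pairs = na * (na - 1) / 2.0 if i == j else float(na * nb)
            d = model.closest_approach[i, j]
            qq = model.species[i].charge * model.species[j].charge

            def bu(r, qq=qq):
                return qq * lB / np.asarray(r, dtype=float)

            gc = _contact_from_counts(cts[b], edges, n_pairs, nsamp, V, d, bu)
            mult = 1.0 if i == j else 2.0  # ordered-pair double count
            contact += (mult * (na / V) * (nb / V) * d**3 * gc)
        phi_hc = 2.0 * math.pi / (3.0 * rho_tot) * contact
        phis[b] = 1.0 + phi_hc + result.block_energies[b] / 3.0
    return float(phis.mean()), float(phis.std(ddof=1) / math.sqrt(n_blocks))
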