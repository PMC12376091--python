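"""Multicomponent Ornstein-Zernike / hypernetted-chain (HNC) solver.

Solves the OZ relation ``h = c + c * rho * h`` (matrix form, in Fourier
space) together with the HNC closure ``g = exp(-beta*u + h - c)`` for a
primitive-model electrolyte, and evaluates the osmotic coefficient by the
virial route.

Long-range handling (Ng renormalization): the Coulomb tail is split with an
error function,

    beta*u_ij(r) = beta*u_short,ij(r) + q_i q_j l_B erf(kappa_s r)/r,

and the iteration works with the short-ranged functions
``c_s = c + beta*u_long`` and ``gamma_s = h - c_s``.  In these variables the
closure is simply ``g = exp(-beta*u_short + gamma_s)`` and every function that
is Fourier transformed is absolutely integrable; the Fourier transform of the
long-range part is analytic, ``-4 pi l_B q_i q_j exp(-q^2/4 kappa_s^2)/q^2``.

Iteration is Picard with adaptive mixing, optionally accelerated by Anderson
(DIIS) extrapolation, with geometric density ramping as a fallback for
strongly coupled (2:2) states.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import dst
from scipy.special import erf, erfc

from .model import IonicState, PMModel, bjerrum_length

__all__ = [
    "RadialGrid",
    "CorrelationGrid",
    "HNCConvergenceError",
    "solve_hnc",
    "osmotic_coefficient",
    "excess_coulomb_energy",
    "charge_sum_rule_error",
]


class HNCConvergenceError(RuntimeError):
    """HNC iteration failed to converge; carries the last residual and the
    number of iterations spent."""

    def __init__(self, message: str, residual: float, iterations: int = 0):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid r_k = (k+1)*dr, k = 0..n_points-1.

    The reciprocal grid is q_n = (n+1)*dq with dq = pi/((n_points+1)*dr),
    matching the type-I discrete sine transform.
    """

    n_points: int = 2**14
    dr: float = 0.02

    def __post_init__(self) -> None:
        if self.n_points < 2**12:
            raise ValueError("n_points must be >= 4096")
        if self.n_points & (self.n_points - 1):
            raise ValueError("n_points must be a power of two")
        if not 0 < self.dr <= 0.05:
            raise ValueError("dr must be in (0, 0.05] A")

    @property
    def r(self) -> np.ndarray:
        return (np.arange(self.n_points) + 1.0) * self.dr

    @property
    def dq(self) -> float:
        return math.pi / ((self.n_points + 1) * self.dr)

    @property
    def q(self) -> np.ndarray:
        return (np.arange(self.n_points) + 1.0) * self.dq

    @property
    def r_max(self) -> float:
        return self.n_points * self.dr

    def fourier(self, f: np.ndarray) -> np.ndarray:
        """3D Fourier transform of a radial function sampled on ``r``."""
        return 2.0 * math.pi * self.dr / self.q * dst(self.r * f, type=1)

    def inverse(self, fhat: np.ndarray) -> np.ndarray:
        """Inverse 3D Fourier transform back onto ``r``."""
        return self.dq / (4.0 * math.pi**2 * self.r) * dst(self.q * fhat, type=1)


@dataclass(frozen=True)
class CorrelationGrid:
    """Converged pair correlations h_ij(r), c_ij(r) for one thermodynamic state.

    Arrays have shape (n_species, n_species, n_points) and are symmetric in
    the species indices.  ``c`` is the full direct correlation function
    (including the Coulomb asymptote -beta*u)."""

    grid: RadialGrid
    model: PMModel
    state: IonicState
    h: np.ndarray
    c: np.ndarray
    converged: bool
    residual: float
    n_iterations: int
    gamma_s: np.ndarray | None = None
    sum_rule_error: float | None = None

    @property
    def g(self) -> np.ndarray:
        return self.h + 1.0


def _debye_kappa(model: PMModel, state: IonicState) -> float:
    """Inverse Debye length in A^-1 (0 for an uncharged state)."""
    lB = bjerrum_length(model)
    s = float((model.charges**2 * state.number_densities).sum())
    return math.sqrt(4.0 * math.pi * lB * s)


def _attempt(
    model: PMModel,
    state: IonicState,
    grid: RadialGrid,
    tolerance: float,
    max_iter: int,
    gamma_s0: np.ndarray | None,
    mixing0: float,
    anderson_depth: int,
):
    """One HNC solve at fixed densities.  Returns (h, c, gamma_s, residual, n_iter)
    or raises HNCConvergenceError."""
    ns = model.n_species
    r, q = grid.r, grid.q
    N = grid.n_points
    lB = bjerrum_length(model)
    rho = state.number_densities
    z = model.charges
    kappa_s = 1.0  # A^-1, erf splitting parameter

    zz = np.einsum("i,j->ij", z, z)
    # fractional occupancy of each radial bin outside the hard core: 0 inside,
    # 1 outside, volume fraction for the cell straddling contact.  A smooth
    # (in d_ij) discretization of the core avoids staircase artifacts when
    # diameters are varied continuously, e.g. during fitting.
    d_tab = model.closest_approach[:, :, None]
    hi = (r + 0.5 * grid.dr)[None, None, :]
    lo = (r - 0.5 * grid.dr)[None, None, :]
    occupancy = np.clip((hi**3 - d_tab**3) / (hi**3 - lo**3), 0.0, 1.0)
    # short-range potential: hard core handled by occupancy, erfc-screened
    # Coulomb outside
    bu_short = zz[:, :, None] * lB * erfc(kappa_s * r)[None, None, :] / r
    bu_long = zz[:, :, None] * lB * (1.0 - erfc(kappa_s * r))[None, None, :] / r
    # analytic FT of -beta*u_long
    phi_hat = (
        -4.0 * math.pi * lB * zz[:, :, None]
        * np.exp(-(q**2) / (4.0 * kappa_s**2))[None, None, :] / q**2
    )

    gamma_s = np.zeros((ns, ns, N)) if gamma_s0 is None else gamma_s0.copy()

    # batched OZ solve: for each q, H = (I - C R)^-1 C with R = diag(rho)
    R = np.diag(rho)
    eye = np.eye(ns)

    def oz_step(gs):
        # cap far above any physical contact value to stop overflow cascades
        expo = np.clip(-bu_short + gs, -np.inf, 50.0)
        gpair = occupancy * np.exp(expo)
        h = gpair - 1.0
        c_s = h - gs
        c_s_hat = np.empty_like(c_s)
        for i in range(ns):
            for j in range(i, ns):
                c_s_hat[i, j] = grid.fourier(c_s[i, j])
                c_s_hat[j, i] = c_s_hat[i, j]
        c_hat = c_s_hat + phi_hat
        # (N, ns, ns) batched linear solve
        C = np.moveaxis(c_hat, 2, 0)
        A = eye[None, :, :] - C @ R[None, :, :]
        H = np.linalg.solve(A, C)
        gs_hat = np.moveaxis(H, 0, 2) - c_s_hat
        gs_new = np.empty_like(gs)
        for i in range(ns):
            for j in range(i, ns):
                gs_new[i, j] = grid.inverse(gs_hat[i, j])
                gs_new[j, i] = gs_new[i, j]
        return gs_new, h, c_s

    mix = mixing0
    anderson_damping = 0.5
    anderson_on = anderson_depth > 1
    stall_window = 150
    stall_res = np.inf
    hist_g: list[np.ndarray] = []
    hist_f: list[np.ndarray] = []
    best_res = np.inf
    best_g = gamma_s.copy()
    for it in range(1, max_iter + 1):
        gs_new, h, c_s = oz_step(gamma_s)
        F = gs_new - gamma_s
        res = float(np.max(np.abs(F)))
        if res < tolerance:
            c = c_s - bu_long
            return h, c, gamma_s, res, it
        # safeguard: on blowup restart from the best iterate with less mixing
        if not np.isfinite(res) or res > 100.0 * best_res + 100.0:
            mix = max(mix / 4.0, 1e-3)
            gamma_s = best_g.copy()
            hist_g, hist_f = [], []
            continue
        if res < best_res:
            best_res = res
            best_g = gamma_s.copy()
        # near-critical states make Anderson oscillate where damped Picard
        # still converges: on stall, fall back to Picard for good
        if anderson_on and it % stall_window == 0:
            if best_res > 0.5 * stall_res:
                anderson_on = False
                gamma_s = best_g.copy()
                hist_g, hist_f = [], []
                gs_new, h, c_s = oz_step(gamma_s)
                F = gs_new - gamma_s
                res = float(np.max(np.abs(F)))
            stall_res = best_res
        hist_g.append(gamma_s.ravel().copy())
        hist_f.append(F.ravel().copy())
        if len(hist_g) > anderson_depth:
            hist_g.pop(0)
            hist_f.pop(0)
        # Anderson (type-II / DIIS) extrapolation once the iteration is in
        # the basin; plain damped Picard otherwise
        stepped = False
        if anderson_on and len(hist_g) >= 2 and res < 10.0:
            Fm = np.stack(hist_f, axis=1)
            dF = Fm[:, 1:] - Fm[:, :-1]
            try:
                theta, *_ = np.linalg.lstsq(dF, hist_f[-1], rcond=None)
                if np.abs(theta).max() < 1e3:
                    Gm = np.stack(hist_g, axis=1)
                    dG = Gm[:, 1:] - Gm[:, :-1]
                    gnew = (hist_g[-1] - dG @ theta
                            + anderson_damping * (hist_f[-1] - dF @ theta))
                    gamma_s = gnew.reshape(gamma_s.shape)
                    stepped = True
            except np.linalg.LinAlgError:
                pass
        if not stepped:
            gamma_s = gamma_s + mix * F
            mix = min(mix * 1.02, 0.3)
    raise HNCConvergenceError(
        f"HNC did not converge in {max_iter} iterations (residual {best_res:.3e})",
        best_res,
        max_iter,
    )


def solve_hnc(
    model: PMModel,
    state: IonicState,
    grid: RadialGrid | None = None,
    tolerance: float = 1e-8,
    max_iter: int = 500,
    mixing: float = 0.1,
    anderson_depth: int = 5,
    n_ramp_steps: int = 20,
    initial_gamma: np.ndarray | None = None,
    iteration_budget: int | None = None,
) -> CorrelationGrid:
    """Solve the OZ equation with the HNC closure for a PM state.

    A direct solve is attempted first (warm-started from ``initial_gamma``
    when given).  If it fails, all charges are ramped up geometrically at the
    target density (robust for strongly coupled 2:2 states, since it never
    crosses the dilute regime where HNC is known to lack solutions); as a
    last resort densities are ramped geometrically from 1% of the target in
    at most ``n_ramp_steps`` steps, each solve seeding the next.  Raises
    :class:`HNCConvergenceError` when every path is exhausted.

    ``iteration_budget`` caps the total iterations across all attempts so a
    state with no reachable solution fails in bounded time.

    States so dilute that less than ~10^-3 particles fall inside the whole
    grid volume are solved analytically: at zero density HNC reduces to
    h = c = exp(-beta*u) - 1 exactly, and the numerical transforms lose
    accuracy there because nothing screens the Coulomb tail.
    """
    if grid is None:
        grid = RadialGrid()
    if state.total_density * (4.0 / 3.0) * math.pi * grid.r_max**3 < 1e-3:
        return _zero_density_solution(model, state, grid)
    budget = [iteration_budget if iteration_budget is not None else 10**9]

    def attempt(mdl, st, gam):
        if budget[0] <= 0:
            raise HNCConvergenceError("iteration budget exhausted", math.inf, 0)
        cap = min(max_iter, budget[0])
        try:
            out = _attempt(mdl, st, grid, tolerance, cap, gam, mixing,
                           anderson_depth)
            budget[0] -= out[4]
            return out
        except HNCConvergenceError as exc:
            budget[0] -= exc.iterations
            raise
    kappa = _debye_kappa(model, state)
    if kappa > 0 and grid.r_max < 40.0 / kappa:
        warnings.warn(
            f"grid extent {grid.r_max:.0f} A is below 40 Debye lengths "
            f"({40.0 / kappa:.0f} A); tails may be truncated",
            stacklevel=2,
        )
    def finish(h, c, res, it, gam):
        corr = CorrelationGrid(grid, model, state, h, c, True, res, it, gam)
        err = charge_sum_rule_error(corr)
        return CorrelationGrid(grid, model, state, h, c, True, res, it, gam,
                               err)

    try:
        h, c, gam, res, it = attempt(model, state, initial_gamma)
        return finish(h, c, res, it, gam)
    except HNCConvergenceError:
        pass

    # coupling ramp: scale all charges up geometrically at the target density
    from .model import scale_charges

    try:
        gamma = None
        total_it = 0
        for s in np.geomspace(0.3, 1.0, 8):
            sub_model = scale_charges(model, s)
            sub = IonicState(
                model=sub_model, number_densities=state.number_densities,
                molality=None,
            )
            h, c, gamma, res, it = attempt(sub_model, sub, gamma)
            total_it += it
        return finish(h, c, res, total_it, gamma)
    except HNCConvergenceError:
        pass

    # density ramp: geometric from 1% of target
    gamma = None
    total_it = 0
    for frac in np.geomspace(0.01, 1.0, n_ramp_steps):
        sub = IonicState(
            model=model,
            number_densities=state.number_densities * frac,
            molality=None,
        )
        try:
            h, c, gamma, res, it = attempt(model, sub, gamma)
            total_it += it
        except HNCConvergenceError as exc:
            raise HNCConvergenceError(
                f"HNC failed on charge and density ramps (density fraction "
                f"{frac:.3g}, residual {exc.residual:.3e})",
                exc.residual,
            ) from exc
    return finish(h, c, res, total_it, gamma)


def charge_sum_rule_error(corr: CorrelationGrid) -> float:
    """Worst relative violation of the local-electroneutrality sum rule.

    For each species i the charge of the screening cloud must cancel q_i:
    sum_j q_j rho_j int g_ij 4 pi r^2 dr = -q_i.  Converged physical HNC
    solutions satisfy this to high accuracy; spurious near-critical
    solutions (2:2 electrolytes close to the HNC solution boundary) violate
    it badly, which makes the sum rule a cheap reliability diagnostic.
    Returns 0 for an uncharged system.
    """
    model, state, grid = corr.model, corr.state, corr.grid
    r = grid.r
    z = model.charges
    rho = state.number_densities
    if float((np.abs(z) * rho).sum()) == 0.0:
        return 0.0
    worst = 0.0
    for i in range(model.n_species):
        if z[i] == 0.0:
            continue
        cloud = 0.0
        for j in range(model.n_species):
            if z[j] == 0.0 or rho[j] == 0.0:
                continue
            cloud += z[j] * rho[j] * float(
                np.trapezoid(corr.g[i, j] * 4.0 * math.pi * r**2, r)
            )
        worst = max(worst, abs(cloud + z[i]) / abs(z[i]))
    return worst


def _zero_density_solution(model: PMModel, state: IonicState,
                           grid: RadialGrid) -> CorrelationGrid:
    """Exact zero-density limit: g = exp(-beta*u), h = c = Mayer f-function."""
    ns = model.n_species
    r = grid.r
    lB = bjerrum_length(model)
    z = model.charges
    zz = np.einsum("i,j->ij", z, z)
    d_tab = model.closest_approach[:, :, None]
    hi = (r + 0.5 * grid.dr)[None, None, :]
    lo = (r - 0.5 * grid.dr)[None, None, :]
    occupancy = np.clip((hi**3 - d_tab**3) / (hi**3 - lo**3), 0.0, 1.0)
    bu = zz[:, :, None] * lB / r[None, None, :]
    g = occupancy * np.exp(np.clip(-bu, -np.inf, 50.0))
    h = g - 1.0
    bu_long = zz[:, :, None] * lB * erf(1.0 * r)[None, None, :] / r
    gamma_s = -bu_long
    return CorrelationGrid(grid, model, state, h, h.copy(), True, 0.0, 0,
                           gamma_s, 0.0)


def _contact_values(corr: CorrelationGrid) -> np.ndarray:
    """g_ij(d_ij+) by 3-point parabolic extrapolation to contact.

    The extrapolation acts on the log of the cavity function,
    ln y = ln g + beta*u_Coul, which stays smooth and slowly varying even
    where g itself rises exponentially toward a charged contact; the first
    three grid nodes whose bins lie fully outside the core are used (the
    boundary bin carries fractional occupancy and is skipped).
    """
    model, grid = corr.model, corr.grid
    r = grid.r
    ns = model.n_species
    lB = bjerrum_length(model)
    out = np.zeros((ns, ns))
    g = corr.g
    for i in range(ns):
        for j in range(ns):
            d = model.closest_approach[i, j]
            qq = model.species[i].charge * model.species[j].charge
            k0 = int(np.searchsorted(r, d + 0.5 * grid.dr - 1e-12, side="left"))
            if k0 + 3 > grid.n_points:
                raise ValueError("contact lies beyond the grid")
            xs = r[k0 : k0 + 3]
            gs = np.maximum(g[i, j, k0 : k0 + 3], 1e-300)
            ys = np.log(gs) + qq * lB / xs
            val = np.polyval(np.polyfit(xs, ys, 2), d)
            out[i, j] = float(np.exp(val - qq * lB / d))
    return out


def _require_converged(corr: CorrelationGrid) -> None:
    if not corr.converged:
        raise ValueError(
            "correlation grid is not converged "
            f"(residual {corr.residual:.3e}); refusing to compute thermodynamics"
        )


def excess_coulomb_energy(corr: CorrelationGrid) -> float:
    """Excess Coulomb energy per particle, beta*E_el/N.

    beta*E_el/N = (2 pi l_B / rho_tot) sum_ij rho_i rho_j q_i q_j
                  int_0^inf r h_ij(r) dr;
    electroneutrality removes the divergent g -> 1 background, and the
    screened tail of h decays exponentially so plain truncation at r_max is
    exact to the solver tolerance.  Zero for an uncharged system.
    """
    _require_converged(corr)
    model, state, grid = corr.model, corr.state, corr.grid
    rho = state.number_densities
    rho_tot = state.total_density
    if rho_tot == 0:
        return 0.0
    z = model.charges
    lB = bjerrum_length(model)
    r = grid.r
    integrals = np.trapezoid(r[None, None, :] * corr.h, r, axis=2)
    total = float(np.einsum("i,j,ij->", rho * z, rho * z, integrals))
    return 2.0 * math.pi * lB * total / rho_tot


def osmotic_coefficient(corr: CorrelationGrid) -> float:
    """Osmotic coefficient by the virial (pressure) route.

    phi = 1 + (2 pi / 3 rho_tot) sum_ij rho_i rho_j d_ij^3 g_ij(d_ij+)
            + beta*E_el/(3N),
    the first term being the hard-core contact contribution and the second
    exact for a 1/r potential.  phi = 1 in the ideal (zero-density) limit
    and < 1 when Coulomb attractions dominate.
    """
    _require_converged(corr)
    model, state = corr.model, corr.state
    rho = state.number_densities
    rho_tot = state.total_density
    if rho_tot == 0:
        return 1.0
    gc = _contact_values(corr)
    d3 = corr.model.closest_approach**3
    contact = (
        2.0 * math.pi / (3.0 * rho_tot)
        * float(np.einsum("i,j,ij,ij->", rho, rho, d3, gc))
    )
    return 1.0 + contact + excess_coulomb_energy(corr) / 3.0
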