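"""Fitting the cation hard-sphere diameter to an osmotic-coefficient curve.

The anion diameter d_-- is held fixed (4.6 A for sulfate) and the cation
diameter d_++ is the single fit parameter; the cation-anion closest approach
follows from additivity, d_+- = (d_++ + d_--)/2, and controls the Coulomb
energy at contact and hence the degree of ion pairing.  A larger d_++ gives
more repulsive interactions and a larger osmotic coefficient, so the weighted
sum of squared residuals is unimodal in d_++ over physically sensible ranges.

Model curves come from the HNC solver; molalities are solved from the most
concentrated state downward with warm starting, which keeps phi(m) on the
solution branch continued from the well-behaved concentrated regime.  Points
where HNC fails to converge are flagged and excluded from the objective,
never fabricated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .hnc import HNCConvergenceError, RadialGrid, osmotic_coefficient, solve_hnc
from .model import PMModel, build_model, molality_to_state

__all__ = [
    "OsmoticCurve",
    "FitResult",
    "predict_curve",
    "fit_cation_diameter",
    "read_curve",
    "write_curve",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OsmoticCurve:
    """An osmotic-coefficient curve phi(m) for one salt."""

    molality: np.ndarray
    phi: np.ndarray
    label: str = ""
    sigma_phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.molality, dtype=float)
        p = np.asarray(self.phi, dtype=float)
        if m.shape != p.shape or m.ndim != 1:
            raise ValueError("molality and phi must be 1-D arrays of equal length")
        if len(m) and ((np.diff(m) <= 0).any() or (m <= 0).any()):
            raise ValueError("molalities must be strictly increasing and > 0")
        if len(p) and (p[np.isfinite(p)] <= 0).any():
            raise ValueError("phi values must be > 0")
        if self.sigma_phi is not None:
            s = np.asarray(self.sigma_phi, dtype=float)
            if s.shape != m.shape:
                raise ValueError("sigma_phi must match molality in length")
            object.__setattr__(self, "sigma_phi", s)
        object.__setattr__(self, "molality", m)
        object.__setattr__(self, "phi", p)

    def __len__(self) -> int:
        return len(self.molality)


@dataclass(frozen=True)
class FitResult:
    """Best-fit cation diameter and goodness-of-fit diagnostics."""

    d_plus_plus: float
    d_plus_minus: float
    objective: float
    residuals: np.ndarray
    molalities_used: np.ndarray
    points_skipped: list
    n_objective_evaluations: int
    converged: bool


def _cation_anion(model: PMModel):
    cats = [s for s in model.species if s.charge > 0]
    ans = [s for s in model.species if s.charge < 0]
    if len(cats) != 1 or len(ans) != 1:
        raise ValueError(
            "model template must contain exactly one cation and one anion"
        )
    return cats[0], ans[0]


def _with_cation_diameter(model: PMModel, d_plus_plus: float) -> PMModel:
    cat, _ = _cation_anion(model)
    species = tuple(
        replace(s, diameter=d_plus_plus) if s.name == cat.name else s
        for s in model.species
    )
    return build_model(species, model.epsilon_r, model.temperature)


def predict_curve(
    model_template: PMModel,
    d_plus_plus: float,
    molalities,
    grid: RadialGrid | None = None,
    label: str = "",
    iteration_budget: int = 1000,
    sum_rule_tol: float = 1e-4,
) -> OsmoticCurve:
    """Osmotic coefficients phi(m) of the PM with the given cation diameter.

    Solves HNC at each molality in descending order, warm-starting each
    state from the previous one and bisecting molality gaps on failure.
    Solutions violating the local-electroneutrality sum rule beyond
    ``sum_rule_tol`` (spurious near-critical 2:2 solutions) are treated as
    failures.  Failed points carry phi = NaN.  ``d_plus_plus`` must lie in
    [0.5, 10] A.
    """
    if not 0.5 <= d_plus_plus <= 10.0:
        raise ValueError(f"d_plus_plus {d_plus_plus} outside [0.5, 10] A")
    molalities = np.asarray(molalities, dtype=float)
    if len(molalities) == 0:
        return OsmoticCurve(molality=np.array([]), phi=np.array([]), label=label)
    model = _with_cation_diameter(model_template, d_plus_plus)
    cat, an = _cation_anion(model)
    # stoichiometry from charge neutrality: nu+ q+ + nu- q- = 0
    g = math.gcd(int(round(abs(cat.charge) * 2)), int(round(abs(an.charge) * 2)))
    nu_plus = int(round(abs(an.charge) * 2)) // g
    nu_minus = int(round(abs(cat.charge) * 2)) // g
    stoich = {cat.name: nu_plus, an.name: nu_minus}
    grid = grid or RadialGrid()
    # Align the grid so the cation-anion contact d_+- falls exactly on a
    # node.  The discretized hard core otherwise changes in steps of dr as
    # d_++ varies, which makes phi(d_++) a staircase and the fit objective
    # non-smooth; node alignment removes the dominant (+-) staircase.
    d_pm = 0.5 * (d_plus_plus + an.diameter)
    k = max(int(round(d_pm / grid.dr)), 1)
    grid = RadialGrid(grid.n_points, d_pm / k)
    phis = np.full(len(molalities), np.nan)
    # Solve from the most concentrated state downward, each solution seeding
    # the next: HNC for 2:2 electrolytes loses solutions in the dilute
    # regime, and continuing the branch from high concentration both
    # converges where cold starts stall and keeps phi(m) on the physical
    # branch.  Failed gaps are bisected in molality before giving up.
    order = np.argsort(molalities)[::-1]
    gamma = None
    m_prev = None
    def reliable(corr):
        return (corr.sum_rule_error is None
                or corr.sum_rule_error <= sum_rule_tol)

    for k in order:
        m = float(molalities[k])
        state = molality_to_state(model, m, stoich)
        corr = None
        try:
            corr = solve_hnc(model, state, grid=grid, initial_gamma=gamma,
                             iteration_budget=iteration_budget)
        except HNCConvergenceError:
            pass
        if corr is None or not reliable(corr):
            # retry along a finer continuation path from the previous state
            gamma2 = _substep(model, stoich, grid, gamma, m_prev, m)
            corr = None
            if gamma2 is not None:
                try:
                    corr = solve_hnc(model, state, grid=grid,
                                     initial_gamma=gamma2,
                                     iteration_budget=iteration_budget)
                except HNCConvergenceError:
                    pass
        if corr is None or not reliable(corr):
            logger.warning(
                "HNC gave no reliable solution at m=%.3g for d_++=%.3g "
                "(dropped)", m, d_plus_plus)
            continue
        phis[k] = osmotic_coefficient(corr)
        gamma = corr.gamma_s
        m_prev = m
    return OsmoticCurve(molality=molalities, phi=phis, label=label)


def _substep(model, stoich, grid, gamma, m_hi, m_lo, max_solves: int = 5,
             iteration_budget: int = 300):
    """Continue the HNC solution branch from m_hi down to m_lo with adaptive
    molality steps; returns a warm-start gamma at m_lo, or None."""
    if gamma is None or m_hi is None or m_hi <= m_lo:
        return None
    current = m_hi
    step = 0.5 * (m_hi - m_lo)
    solves = 0
    while current > m_lo + 1e-12 and solves < max_solves:
        target = max(current - step, m_lo)
        solves += 1
        try:
            corr = solve_hnc(
                model, molality_to_state(model, target, stoich),
                grid=grid, initial_gamma=gamma,
                iteration_budget=iteration_budget,
            )
            gamma = corr.gamma_s
            current = target
        except HNCConvergenceError:
            step *= 0.5
            if step < 5e-3:
                return None
    return gamma if current <= m_lo + 1e-12 else None


def fit_cation_diameter(
    curve: OsmoticCurve,
    model_template: PMModel,
    bounds: tuple[float, float] = (1.5, 6.5),
    grid: RadialGrid | None = None,
    coarse_step: float = 0.5,
    xatol: float = 1e-3,
) -> FitResult:
    """Least-squares fit of d_++ to an osmotic-coefficient curve.

    Minimizes sum_k w_k (phi_model(m_k) - phi_k)^2 with w_k = 1 (or 1/sigma^2
    when per-point uncertainties are given).  A coarse scan over ``bounds``
    brackets the minimum first; bounded scalar minimization (golden-section /
    Brent) then refines it to ``xatol``.  Deterministic for fixed inputs.
    Molalities where HNC fails are dropped from the objective with a warning.
    """
    mask0 = np.isfinite(curve.phi)
    if int(mask0.sum()) < 3:
        raise ValueError("need at least 3 usable curve points to fit")
    weights = (
        1.0 / np.asarray(curve.sigma_phi, dtype=float) ** 2
        if curve.sigma_phi is not None
        else np.ones(len(curve))
    )
    n_eval = 0
    skipped: set[float] = set()

    def objective(d: float) -> float:
        nonlocal n_eval
        n_eval += 1
        pred = predict_curve(model_template, d, curve.molality, grid=grid)
        ok = np.isfinite(pred.phi) & mask0
        skipped.update(curve.molality[~np.isfinite(pred.phi)].tolist())
        if int(ok.sum()) < 3:
            return np.inf
        return float(
            np.sum(weights[ok] * (pred.phi[ok] - curve.phi[ok]) ** 2)
        )

    lo, hi = bounds
    ds = np.arange(lo, hi + 1e-9, coarse_step)
    vals = np.array([objective(d) for d in ds])
    if not np.isfinite(vals).any():
        raise RuntimeError(
            f"HNC failed at every scanned diameter; skipped molalities "
            f"{sorted(skipped)}"
        )
    kbest = int(np.nanargmin(vals))
    blo = ds[max(kbest - 1, 0)]
    bhi = ds[min(kbest + 1, len(ds) - 1)]
    res = minimize_scalar(
        objective, bounds=(blo, bhi), method="bounded",
        options={"xatol": xatol},
    )
    d_best = float(res.x)
    pred = predict_curve(model_template, d_best, curve.molality, grid=grid)
    ok = np.isfinite(pred.phi) & mask0
    _, an = _cation_anion(model_template)
    return FitResult(
        d_plus_plus=d_best,
        d_plus_minus=0.5 * (d_best + an.diameter),
        objective=float(res.fun),
        residuals=np.where(ok, pred.phi - curve.phi, np.nan),
        molalities_used=curve.molality[ok],
        points_skipped=sorted(curve.molality[~np.isfinite(pred.phi)].tolist()),
        n_objective_evaluations=n_eval,
        converged=bool(res.success),
    )


def read_curve(path, label: str = "") -> OsmoticCurve:
    """Read a curve from CSV with header ``molality,phi[,sigma]``."""
    df = pd.read_csv(path)
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return OsmoticCurve(
        molality=df["molality"].to_numpy(),
        phi=df["phi"].to_numpy(),
        label=label,
        sigma_phi=sigma,
    )


def write_curve(curve: OsmoticCurve, path) -> None:
    """Write a curve as CSV (``molality,phi[,sigma]``)."""
    data = {"molality": curve.molality, "phi": curve.phi}
    if curve.sigma_phi is not None:
        data["sigma"] = curve.sigma_phi
    pd.DataFrame(data).to_csv(path, index=False)
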