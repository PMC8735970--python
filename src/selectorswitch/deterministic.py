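"""Mass-action ODE analysis of the switch: fixed points, stability, steady states.

The deterministic model treats promoter occupancies as continuous fractions
(mean field).  At a fixed point the promoter-binding sub-network is at
equilibrium given the free protein level C, which reduces the fixed-point
problem to a one-dimensional root search in C: the net production-decay
balance of the free pool, ``g(C) = fC * M(C) - bC * C``, with ``M(C)``
following from the equilibrium occupancy of the productive promoter states.

The non-cooperative model has the ON fixed point plus the origin; the origin
is a boundary equilibrium (no molecules) that is stochastically absorbing but
deterministically repelling, tagged ``half-stable``.  The cooperative model
is bistable over part of parameter space, with a genuinely stable OFF state
and an unstable intermediate point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .network import Protocol, ReactionNetwork, build_network
from .parameters import ParameterSet

__all__ = ["FixedPoint", "LifetimeRequirement", "ode_rhs", "find_fixed_points",
           "steady_state_observables", "required_on_lifetime",
           "on_initial_state", "integrate"]


@dataclass
class FixedPoint:
    """A fixed point of the deterministic system (continuous species values)."""

    state: dict
    stability: str            # 'stable' | 'unstable' | 'half-stable'
    leading_eigenvalue: float
    C_free: float
    C_total: float
    M: float
    theta_O: float
    nT_bound: float


@dataclass
class LifetimeRequirement:
    """Bound on the ON-state lifetime for a Poisson loss process.

    If spontaneous OFF switches occur at rate r, the fraction of animals that
    lose the state within a lifetime T stays below phi iff
    r < -ln(1 - phi) / T, i.e. the mean ON lifetime 1/r must exceed
    T / (-ln(1 - phi)); for small phi this is approximately T / phi.
    """

    phi: float
    T: float
    min_mean_lifetime: float
    small_phi_approx: float


def ode_rhs(state: np.ndarray, params: ParameterSet, variant: str,
            network: Optional[ReactionNetwork] = None,
            t: float = 0.0, protocol: Optional[Protocol] = None) -> np.ndarray:
    """Mass-action time derivatives for the given variant at continuous state."""
    net = network if network is not None else build_network(variant, params)
    rates = net.rate_vector(t, protocol)
    a = rates.copy()
    for k in range(len(net.channels)):
        for j in range(2):
            idx = net.reactant_idx[k, j]
            if idx >= 0:
                a[k] *= state[idx]
    return net.stoich.T @ a


def _promoter_equilibrium(C: float, H: float, params: ParameterSet,
                          variant: str) -> dict:
    """Stationary promoter-state fractions of the binding sub-network at
    clamped free protein C (and free HD-TF H for the co-factor variants)."""
    fO = params.fO
    if variant == "noncoop":
        w = fO * C / params.bO
        z = 1.0 + w
        return {"O": 1 / z, "OC": w / z}
    if variant == "coop":
        w1 = fO * C / params.b1
        w2 = w1 * fO * C / params.b2
        z = 1.0 + w1 + w2
        return {"O": 1 / z, "OC": w1 / z, "OC2": w2 / z}
    # HD variants: states O, OC, OH (+ OHC for model 1)
    fOC, fOH, bO = params.get("fO_C"), params.get("fO_H"), params.bO
    if variant.startswith("hd1"):
        bOs = params.get("bO_s")
        # 4-state CTMC; solve stationary distribution
        Q = np.zeros((4, 4))  # order O, OC, OH, OHC
        def add(i, j, r):
            Q[i, j] += r
            Q[i, i] -= r
        add(0, 1, fOC * C); add(1, 0, bO)
        add(0, 2, fOH * H); add(2, 0, bO)
        add(2, 3, fOC * C); add(3, 2, bOs)
        add(1, 3, fOH * H); add(3, 1, bOs)
        A = np.vstack([Q.T, np.ones(4)])
        b = np.zeros(5); b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        pi = pi / pi.sum()
        return {"O": pi[0], "OC": pi[1], "OH": pi[2], "OHC": pi[3]}
    # hd2: 3 states, detailed balance
    wC = fOC * C / bO
    wH = fOH * H / bO
    z = 1.0 + wC + wH
    return {"O": 1 / z, "OC": wC / z, "OH": wH / z}


def _reduced_residual(C: float, params: ParameterSet, variant: str,
                      return_aux: bool = False):
    """g(C) = fC*M(C) - bC*C with promoters (and HD-TF) equilibrated at C."""
    if variant in ("hd1b", "hd2b"):
        H = params.get("fH") * C / params.get("bH")
    elif variant in ("hd1a", "hd2a"):
        H = float(params.get("H0"))
    else:
        H = 0.0
    occ = _promoter_equilibrium(C, H, params, variant)
    production = 0.0
    if variant == "coop":
        production += params.fM * occ["OC2"]
    else:
        production += params.fM * occ["OC"]
    if variant.startswith("hd1"):
        production += params.fM * occ["OHC"]
    if variant.startswith("hd2"):
        production += params.get("fM_H") * occ["OH"]
    if params.fM0 is not None:
        production += params.fM0
    M = production / params.bM
    g = params.fC * M - params.bC * C
    if return_aux:
        thetaT = params.fO * C / (params.fO * C + params.bT)
        return g, occ, M, H, thetaT
    return g


def _fixed_point_from_C(C: float, params: ParameterSet,
                        variant: str) -> FixedPoint:
    _, occ, M, H, thetaT = _reduced_residual(C, params, variant, return_aux=True)
    nT = params.NT * thetaT
    state = dict(occ)
    state.update({"OT": params.NT * (1 - thetaT), "OTC": nT, "M": M, "C": C})
    if variant.startswith("hd"):
        state["H"] = H
    # theta_O: probability the che-1 promoter is CHE-1-bound (productive states
    # for noncoop/hd; for coop report the doubly bound, productive fraction)
    if variant == "coop":
        theta_O = occ["OC2"]
        own_bound = occ["OC"] + 2 * occ["OC2"]
    elif variant.startswith("hd1"):
        theta_O = occ["OC"] + occ["OHC"]
        own_bound = theta_O
    else:
        theta_O = occ["OC"]
        own_bound = occ["OC"]
    C_total = C + own_bound + nT
    net = build_network(variant, params)
    x = np.array([state.get(sp, 0.0) for sp in net.species], dtype=float)
    lead, stab = _classify(x, params, variant, net)
    if (C == 0.0 and M == 0.0 and stab == "unstable"
            and (params.fM0 or 0.0) == 0.0):
        # boundary equilibrium, approached one-sidedly; stochastically absorbing
        stab = "half-stable"
    return FixedPoint(state=state, stability=stab, leading_eigenvalue=lead,
                      C_free=C, C_total=C_total, M=M, theta_O=theta_O,
                      nT_bound=nT)


def _classify(x: np.ndarray, params: ParameterSet, variant: str,
              net: ReactionNetwork, tol: float = 1e-8) -> tuple[float, str]:
    """Leading Jacobian eigenvalue on the reduced manifold, plus stability tag.

    Promoter ledgers are exactly conserved, so the full Jacobian always
    carries zero eigenvalues along the conservation directions; stability is
    judged after eliminating the dependent species (free promoters, clamped
    pools) via the conservation laws.
    """
    dependent = {"O", "OT", "PO"} | set(net.clamped)
    free_idx = [i for i, sp in enumerate(net.species) if sp not in dependent]
    own_states = [sp for sp in ("OC", "OCd", "OC2", "OH", "OHC")
                  if sp in net.index]
    tgt_states = [sp for sp in ("OTC", "OTCd") if sp in net.index]

    def full_from_reduced(y: np.ndarray) -> np.ndarray:
        z = x.copy().astype(float)
        z[free_idx] = y
        if "O" in net.index:
            z[net.index["O"]] = 1.0 - sum(z[net.index[s]] for s in own_states)
        if "OT" in net.index:
            z[net.index["OT"]] = params.NT - sum(z[net.index[s]] for s in tgt_states)
        if "PO" in net.index:
            z[net.index["PO"]] = 1.0 - z[net.index["POC"]]
        return z

    def reduced_rhs(y: np.ndarray) -> np.ndarray:
        return ode_rhs(full_from_reduced(y), params, variant,
                       network=net)[free_idx]

    y0 = x[free_idx].astype(float)
    n = len(y0)
    J = np.empty((n, n))
    for j in range(n):
        h = 1e-6 * max(1.0, abs(y0[j]))
        yp = y0.copy(); yp[j] += h
        ym = y0.copy(); ym[j] -= h
        J[:, j] = (reduced_rhs(yp) - reduced_rhs(ym)) / (2 * h)
    lead = float(np.max(np.linalg.eigvals(J).real))
    if lead < -tol:
        return lead, "stable"
    if lead > tol:
        return lead, "unstable"
    return lead, "half-stable"


def find_fixed_points(params: ParameterSet, variant: str = "noncoop",
                      n_grid: int = 400) -> list[FixedPoint]:
    """All fixed points, via sign changes of the reduced 1-D residual in C.

    Scans a log-spaced grid of free-protein levels (plus the origin), brackets
    every sign change, and polishes each root with Brent's method; stability
    comes from the Jacobian of the full system.
    """
    prod_max = params.fM
    if params.fM_H is not None:
        prod_max += params.fM_H
    if params.fM0 is not None:
        prod_max += params.fM0
    C_max = 1.5 * params.fC * prod_max / (params.bM * params.bC) + 10.0

    fps: list[FixedPoint] = []
    if (params.fM0 or 0.0) == 0.0:
        fps.append(_fixed_point_from_C(0.0, params, variant))

    grid = np.logspace(-6, math.log10(C_max), n_grid)
    vals = np.array([_reduced_residual(c, params, variant) for c in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(_reduced_residual, grid[i], grid[i + 1],
                                args=(params, variant), xtol=1e-12, rtol=1e-10))
    for r in roots:
        if not any(abs(r - fp.C_free) <= 1e-6 * max(1.0, r) for fp in fps):
            fps.append(_fixed_point_from_C(r, params, variant))
    fps.sort(key=lambda fp: fp.C_free)
    if not fps:
        raise RuntimeError("no fixed point found; residual grid: "
                           f"min={vals.min():.3g} max={vals.max():.3g}")
    return fps


def steady_state_observables(params: ParameterSet, variant: str = "noncoop",
                             branch: str = "ON",
                             protocol: Optional[Protocol] = None
                             ) -> tuple[float, float, float, float]:
    """(M_ss, C_total_ss, theta_O, nT_bound) at the requested branch.

    With a protocol given, every override's in-window value is applied,
    yielding the quasi-steady state under (e.g.) depletion conditions.
    """
    p = params
    if protocol is not None:
        for (_t0, _t1, name, val) in protocol.overrides:
            p = p.replace(**{name: val})
    fps = find_fixed_points(p, variant)
    if branch == "ON":
        fp = max(fps, key=lambda f: f.C_free)
        if fp.C_free <= 0:
            raise ValueError("no ON fixed point exists for these parameters")
    elif branch == "OFF":
        fp = min(fps, key=lambda f: f.C_free)
    elif branch == "unstable":
        cands = [f for f in fps if f.stability == "unstable" and f.C_free > 0]
        if not cands:
            raise ValueError("no interior unstable fixed point")
        fp = cands[0]
    else:
        raise ValueError(f"unknown branch {branch!r}")
    return fp.M, fp.C_total, fp.theta_O, fp.nT_bound


def on_initial_state(params: ParameterSet, variant: str = "noncoop",
                     network: Optional[ReactionNetwork] = None) -> np.ndarray:
    """ON-state initial condition: deterministic ON fixed point, rounded.

    The single che-1 promoter is set to its most likely state; mRNA, free
    protein, and bound-target counts are rounded to integers.  In FRAP or
    reporter networks the extra species start dark-free/unbound as
    appropriate.
    """
    fps = find_fixed_points(params, variant)
    fp = max(fps, key=lambda f: f.C_free)
    net = network if network is not None else build_network(variant, params)
    counts: dict = {"M": round(fp.M), "C": round(fp.C_free),
                    "OTC": round(fp.nT_bound)}
    promoter_states = [sp for sp in ("O", "OC", "OC2", "OH", "OHC")
                       if sp in net.index]
    best = max(promoter_states, key=lambda sp: fp.state.get(sp, 0.0))
    for sp in promoter_states:
        if sp != "O":
            counts[sp] = 1 if sp == best else 0
    if "H" in net.index:
        counts["H"] = round(fp.state.get("H", 0.0))
    if "POC" in net.index:
        # reporter promoter bound with its equilibrium probability, rounded
        thetaT = fp.nT_bound / params.NT
        counts["POC"] = 1 if thetaT >= 0.5 else 0
        counts["P"] = round(params.get("fP") * thetaT / params.get("bP")) \
            if params.fP is not None else 0
    return net.initial_state(**counts)


def integrate(params: ParameterSet, variant: str, x0: np.ndarray,
              t_span: tuple[float, float], protocol: Optional[Protocol] = None,
              n_eval: int = 200):
    """Integrate the mass-action ODEs (stiff solver); returns (t, states)."""
    from scipy.integrate import solve_ivp
    net = build_network(variant, params)

    def rhs(t, x):
        return ode_rhs(x, params, variant, network=net, t=t, protocol=protocol)

    t_eval = np.linspace(*t_span, n_eval)
    sol = solve_ivp(rhs, t_span, x0, method="LSODA", t_eval=t_eval,
                    rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, sol.y.T


def required_on_lifetime(phi: float, T: float) -> LifetimeRequirement:
    """Minimum mean ON lifetime so that at most a fraction phi of animals
    lose the state within lifetime T (Poisson switching)."""
    if not 0 < phi < 1:
        raise ValueError("phi must be in (0, 1)")
    if T <= 0:
        raise ValueError("T must be positive")
    return LifetimeRequirement(
        phi=phi, T=T,
        min_mean_lifetime=T / (-math.log1p(-phi)),
        small_phi_approx=T / phi,
    )
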