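"""Rate constants of the CHE-1 switch and their derivation from measured observables.

The switch model is parameterized by a small set of measured quantities
(copy numbers, lifetimes, nuclear volume) from which every kinetic rate is
derived: the diffusion-limited binding rate ``fO`` from the reaction cross
section and nuclear volume, the mRNA decay rate ``bM`` from the measured mean
lifetime, and the expression rates ``fM``, ``fC``, ``bC`` from the steady-state
balance at the measured mRNA and protein copy numbers, given the (free)
promoter dissociation rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ParameterSet",
    "ObservableSet",
    "EquilibriumSolution",
    "diffusion_limited_rate",
    "rate_from_mean_lifetime",
    "solve_binding_equilibrium",
    "derive_expression_rates",
    "calibrate_protein_rates_to_frap",
    "derive_parameter_set",
]

#: molecules per (nM * um^3); 1 nM = 0.6022 molecules/um^3
MOLECULES_PER_NM_UM3 = 0.6022

VARIANTS = ("noncoop", "coop", "hd1a", "hd1b", "hd2a", "hd2b")


@dataclass
class ParameterSet:
    """All kinetic rates of the switch models, in s^-1, plus copy-number constants.

    ``fO`` is the volume-scaled association rate (per free molecule, free site
    pair); ``bO`` (or ``b1``/``b2`` in the cooperative model) is dissociation
    from the *che-1* promoter; ``bT`` dissociation from target promoters.
    ``fM``/``bM`` are mRNA production/decay, ``fC``/``bC`` protein
    production/decay (only *free* protein is degraded).  Optional rates cover
    the reporter target (``fP``/``bP``) and the homeodomain co-factor models
    (``fO_C``, ``fO_H``, ``bO_s``, ``fM_H``, ``fM0``, ``fH``, ``bH``, ``H0``).
    """

    fO: float = 0.03
    bO: float = 100.0
    b1: Optional[float] = None
    b2: Optional[float] = None
    bT: float = 100.0
    fM: float = 0.0302
    bM: float = 1.0 / 1200.0
    fC: float = 0.0274
    bC: float = 0.00024
    NT: int = 500
    # reporter target gene (depletion panels)
    fP: Optional[float] = None
    bP: Optional[float] = None
    # HD-TF co-factor models
    fO_C: Optional[float] = None
    fO_H: Optional[float] = None
    bO_s: Optional[float] = None
    fM_H: Optional[float] = None
    fM0: Optional[float] = None
    fH: Optional[float] = None
    bH: Optional[float] = None
    H0: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("fO", "bO", "bT", "fM", "bM", "fC", "bC"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"rate {name} must be >= 0, got {v}")
        if self.NT < 1:
            raise ValueError(f"NT must be >= 1, got {self.NT}")
        if self.bO_s is not None and self.bO_s >= self.bO:
            raise ValueError("bO_s must be < bO (slow complex dissociation)")

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"missing required rate(s): {', '.join(missing)}")

    def get(self, name: str) -> float:
        v = getattr(self, name)
        if v is None:
            raise ValueError(f"rate {name} is not set")
        return v

    def replace(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


@dataclass
class ObservableSet:
    """Measured quantities from which the kinetic rates are derived.

    Defaults are the measured values in ASER neurons: ~900 CHE-1 proteins and
    ~7 che-1 mRNAs per cell at steady state, a mean mRNA lifetime of 20 min,
    a protein half-life of 83 min from FRAP, and a diffusion-limited binding
    rate from cross-section sigma = 0.01 um, D = 1 um^2/s in a 4 um^3 nucleus.
    """

    C_total: float = 900.0
    M_ss: float = 7.0
    mRNA_mean_lifetime: float = 1200.0  # s
    protein_half_life_target: float = 83.0 * 60.0  # s
    sigma: float = 0.01  # um
    D: float = 1.0  # um^2/s
    V_C: float = 4.0  # um^3
    NT: int = 500

    def __post_init__(self) -> None:
        for name in ("C_total", "M_ss", "mRNA_mean_lifetime",
                     "protein_half_life_target", "sigma", "D", "V_C", "NT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"observable {name} must be positive")

    def scaled(self, factor: float) -> "ObservableSet":
        """Copy-number/volume scaled observables (factor < 1 shrinks the cell).

        Copy numbers and nuclear volume scale together so concentrations, and
        hence promoter occupancies, are preserved.  mRNA copy number is kept
        (it is already O(10)); lifetimes are physical and unchanged.
        """
        return replace(
            self,
            C_total=self.C_total * factor,
            V_C=self.V_C * factor,
            NT=max(1, int(round(self.NT * factor))),
        )


@dataclass
class EquilibriumSolution:
    """Partition of total CHE-1 over free pool, own promoter, and targets."""

    C_free: float
    theta_O: float          # che-1 promoter occupancy in [0, 1]
    nT_bound_mean: float    # mean number of CHE-1-occupied target promoters
    own_bound_mean: float   # mean CHE-1 copies sequestered on the che-1 promoter
    residual: float


def diffusion_limited_rate(sigma: float, D: float, V_C: float) -> float:
    """Diffusion-limited promoter association rate 4*pi*sigma*D / V_C (s^-1).

    ``sigma`` is the reaction cross section (binding-site size, um), ``D`` the
    diffusion coefficient (um^2/s), ``V_C`` the nuclear volume (um^3).
    """
    if sigma <= 0 or D <= 0 or V_C <= 0:
        raise ValueError("sigma, D and V_C must all be positive")
    return 4.0 * math.pi * sigma * D / V_C


def rate_from_mean_lifetime(tau: float) -> float:
    """First-order decay rate from a *mean* lifetime: 1/tau (not ln2/t_half)."""
    if tau <= 0:
        raise ValueError(f"mean lifetime must be positive, got {tau}")
    return 1.0 / tau


def _own_promoter_weights(x: float, params: ParameterSet, variant: str):
    """Return (occupancy of productive state, mean CHE-1 bound on own promoter,
    theta_O reported) at free-CHE-1 level x, from binding equilibrium."""
    fO = params.fO
    if variant == "noncoop":
        theta = fO * x / (fO * x + params.bO) if x > 0 or params.bO > 0 else 0.0
        return theta, theta, theta
    if variant == "coop":
        params.require("b1", "b2")
        # sequential equilibrium: OC/O = fO x / b1, OC2/OC = fO x / b2
        w1 = fO * x / params.b1
        w2 = w1 * fO * x / params.b2
        z = 1.0 + w1 + w2
        theta_oc2 = w2 / z
        bound = (w1 + 2.0 * w2) / z
        return theta_oc2, bound, theta_oc2
    raise ValueError(f"unknown variant for equilibrium solve: {variant!r}")


def solve_binding_equilibrium(
    C_total: float, params: ParameterSet, variant: str = "noncoop"
) -> EquilibriumSolution:
    """Solve the CHE-1 conservation equation for the free pool at equilibrium.

    Finds the unique ``x = C_free`` with
    ``x + NT * fO x / (fO x + bT) + <bound on own promoter>(x) = C_total``.
    The left side is strictly increasing in x, so the root is unique in
    ``[0, C_total]``; it is polished by Brent's method to ~1e-12 relative.
    """
    fO, bT, NT = params.fO, params.bT, params.NT

    def excess(x: float) -> float:
        thetaT = fO * x / (fO * x + bT)
        _, own_bound, _ = _own_promoter_weights(x, params, variant)
        return x + NT * thetaT + own_bound - C_total

    lo, hi = 0.0, C_total
    if excess(lo) > 0 or excess(hi) < 0:
        raise ValueError("no equilibrium root in [0, C_total]")
    x = brentq(excess, lo, hi, xtol=1e-14, rtol=1e-12)
    theta_prod, own_bound, theta_O = _own_promoter_weights(x, params, variant)
    thetaT = fO * x / (fO * x + bT)
    return EquilibriumSolution(
        C_free=x,
        theta_O=theta_O,
        nT_bound_mean=NT * thetaT,
        own_bound_mean=own_bound,
        residual=excess(x),
    )


def derive_expression_rates(
    obs: ObservableSet, eq: EquilibriumSolution, fC_given: float
) -> tuple[float, float]:
    """(fM, bC) from steady-state balance at the measured copy numbers.

    mRNA balance at the ON state gives ``fM = bM * M_ss / theta_O`` (the
    promoter transcribes only while occupied); protein balance of the free
    pool gives ``bC = fC * M_ss / C_free``.  ``bM`` is the unrounded
    1/mean-lifetime.
    """
    if eq.theta_O <= 0:
        raise ValueError("theta_O = 0: promoter never productive, cannot derive fM")
    bM = rate_from_mean_lifetime(obs.mRNA_mean_lifetime)
    fM = bM * obs.M_ss / eq.theta_O
    bC = fC_given * obs.M_ss / eq.C_free
    return fM, bC


def _frap_half_time(params: ParameterSet, obs: ObservableSet,
                    bC: float, fC: float, bleach_fraction: float = 0.2) -> float:
    """Recovery half-time of the visible pool in the deterministic two-pool model.

    After a bleach leaving ``bleach_fraction`` of the protein visible, visible
    protein is produced at ``fC * M_ss`` while the free visible pool decays at
    ``bC``.  Free and bound pools exchange on the (fast) binding timescale; the
    visible total V relaxes as dV/dt = fC*M - bC * free_fraction * V, assuming
    proportional partitioning of visible protein over free and bound pools.
    """
    eq = solve_binding_equilibrium(obs.C_total, params, "noncoop")
    free_frac = eq.C_free / obs.C_total
    b_eff = bC * free_frac
    # V(t) = V_ss + (V0 - V_ss) exp(-b_eff t): half-time is ln2 / b_eff
    if b_eff <= 0:
        return math.inf
    return math.log(2.0) / b_eff


def calibrate_protein_rates_to_frap(
    params: ParameterSet,
    target_half_life: float,
    obs: Optional[ObservableSet] = None,
    tol: float = 0.01,
) -> tuple[float, float]:
    """Find (fC, bC) reproducing a FRAP recovery half-time.

    The pair is constrained by the steady state ``fC * M_ss = bC * C_free`` and
    searched one-dimensionally in ``bC`` until the two-pool recovery half-time
    matches ``target_half_life`` to within ``tol`` (relative).
    """
    if target_half_life <= 0:
        raise ValueError("target half-life must be positive")
    if obs is None:
        obs = ObservableSet(NT=params.NT)
    eq = solve_binding_equilibrium(obs.C_total, params, "noncoop")

    def mismatch(bC: float) -> float:
        fC = bC * eq.C_free / obs.M_ss
        return _frap_half_time(params, obs, bC, fC) - target_half_life

    lo, hi = 1e-14, 10.0
    if mismatch(hi) > 0:
        raise ValueError(
            "target half-life shorter than the binding-limited bound")
    if mismatch(lo) < 0:
        raise ValueError("target half-life too long to calibrate")
    bC = brentq(mismatch, lo, hi, rtol=1e-10)
    fC = bC * eq.C_free / obs.M_ss
    achieved = _frap_half_time(params, obs, bC, fC)
    if abs(achieved - target_half_life) > tol * target_half_life:
        raise RuntimeError("FRAP calibration did not converge to tolerance")
    return fC, bC


def derive_parameter_set(
    obs: ObservableSet,
    bO: float,
    bT: float,
    variant: str = "noncoop",
    fC: Optional[float] = None,
    b1: Optional[float] = None,
    b2: Optional[float] = None,
) -> ParameterSet:
    """Full derivation chain: observables + dissociation rates -> ParameterSet.

    ``fO`` comes from the diffusion limit (applied at its one-significant-
    figure presentation, as in the published derivation), ``bM`` from the
    mRNA mean lifetime, and (``fM``, ``bC``) from the steady-state balance.
    If ``fC`` is not given it is calibrated (with ``bC``) against the
    protein-half-life target via the two-pool FRAP model.
    """
    fO = round_sig(diffusion_limited_rate(obs.sigma, obs.D, obs.V_C), 1)
    bM = rate_from_mean_lifetime(obs.mRNA_mean_lifetime)
    base = ParameterSet(fO=fO, bO=bO, b1=b1, b2=b2, bT=bT, bM=bM, NT=obs.NT)
    eq = solve_binding_equilibrium(obs.C_total, base, variant)
    if fC is None:
        fC, _ = calibrate_protein_rates_to_frap(
            base, obs.protein_half_life_target, obs)
    fM, bC = derive_expression_rates(obs, eq, fC)
    return base.replace(fM=fM, fC=fC, bC=bC)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (table presentation)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))
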