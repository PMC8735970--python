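"""End-to-end simulation panels: lifetime scans, depletion ensembles, and the
HD-TF co-factor experiments.

Every panel runs at one of two presets: ``full`` (measured copy numbers; scans
and lifetimes can take hours to days) or ``smoke`` (copy numbers and nuclear
volume scaled to one tenth, reduced trial counts; minutes).  Results carry a
manifest (preset, seeds, parameter hash) so tables are reproducible.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .deterministic import on_initial_state, steady_state_observables
from .ffs import characterize_on_basin, ffs_run, place_interfaces
from .network import Protocol, build_network
from .parameters import ParameterSet, derive_parameter_set
from .presets import OBSERVABLES, hd_params, scaled_observables
from .ssa import derive_seed, gillespie_run, recovery_fraction, run_protocol

__all__ = ["PRESETS", "lifetime_scan", "depletion_panel", "hdtf_panel"]

PRESETS = ("smoke", "full")


def _preset_setup(preset: str):
    if preset == "full":
        return OBSERVABLES, dict(step=20.0, trials=1000, n_flux=500,
                                 n_excursions=500, min_interfaces=20,
                                 max_interfaces=35)
    if preset == "smoke":
        return scaled_observables(0.1), dict(step=8.0, trials=100, n_flux=60,
                                             n_excursions=150,
                                             min_interfaces=5,
                                             max_interfaces=35)
    raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")


def _lifetime_for(params: ParameterSet, variant: str, seed: int,
                  ffs_opts: dict) -> dict:
    basin = characterize_on_basin(params, variant, t_burn=1000.0,
                                  t_sample=10000.0, seed=seed)
    cfg = place_interfaces(params, variant, basin, step=ffs_opts["step"],
                           seed=seed, n_excursions=ffs_opts["n_excursions"],
                           trials=ffs_opts["trials"],
                           min_interfaces=ffs_opts["min_interfaces"],
                           max_interfaces=ffs_opts["max_interfaces"])
    cfg.n_flux = ffs_opts["n_flux"]
    res = ffs_run(params, variant, cfg)
    return {"lifetime_s": res.lifetime, "lifetime_err_s": res.lifetime_err,
            "lower_bound_only": res.lower_bound_only, "phi0": res.phi0,
            "result": res}


def lifetime_scan(bO_values, bT_values, variant: str = "noncoop",
                  preset: str = "smoke", seed: int = 0,
                  fC: Optional[float] = 0.0274):
    """FFS lifetimes over a grid of dissociation rates (scan-panel table).

    For each (bO, bT) cell the expression rates are re-derived from the
    measured observables at that binding strength, then the ON-state lifetime
    is estimated by FFS.  In the cooperative variant the pair is applied as
    b1 = b2 = bO.  Returns a DataFrame; the qualitative signature is longer
    lifetimes at smaller bO, maximal when bO << bT.
    """
    import pandas as pd
    obs, ffs_opts = _preset_setup(preset)
    rows = []
    for i, bO in enumerate(bO_values):
        for j, bT in enumerate(bT_values):
            if variant == "coop":
                p = derive_parameter_set(obs, bO=bO, bT=bT, variant="coop",
                                         fC=fC, b1=bO, b2=bO)
            else:
                p = derive_parameter_set(obs, bO=bO, bT=bT, fC=fC)
            cell_seed = derive_seed(seed, i, j)
            try:
                life = _lifetime_for(p, variant, cell_seed, ffs_opts)
                rows.append({"bO": bO, "bT": bT,
                             "lifetime_s": life["lifetime_s"],
                             "lifetime_err_s": life["lifetime_err_s"],
                             "lower_bound_only": life["lower_bound_only"]})
            except RuntimeError as exc:
                rows.append({"bO": bO, "bT": bT, "lifetime_s": float("nan"),
                             "lifetime_err_s": float("nan"),
                             "lower_bound_only": False, "note": str(exc)})
    df = pd.DataFrame(rows)
    df.attrs["manifest"] = {"preset": preset, "variant": variant, "seed": seed,
                            "NT": obs.NT, "C_total": obs.C_total}
    return df


def depletion_panel(stable_params: ParameterSet,
                    unstable_params: ParameterSet,
                    depletion_bC_stable: float,
                    depletion_bC_unstable: float,
                    duration: float = 24 * 3600.0,
                    recovery_durations=(12 * 3600.0, 24 * 3600.0, 48 * 3600.0),
                    n_runs: int = 8, n_recovery_runs: int = 30,
                    seed: int = 0, variant: str = "noncoop",
                    sample_dt: float = 300.0,
                    recovery_observation: float = 48 * 3600.0) -> dict:
    """Transient-depletion ensembles for a stable and an unstable switch.

    Each run starts at the ON state and experiences a depletion window in
    which the free-protein degradation rate is raised to the given value.
    The summary reports mean che-1 mRNA (and reporter mRNA, if configured)
    during depletion relative to before, plus recovery fractions as a
    function of depletion duration.
    """
    out: dict = {"duration_s": duration, "panels": {}}
    for tag_idx, (tag, params, bC_dep) in enumerate(
            (("stable", stable_params, depletion_bC_stable),
             ("unstable", unstable_params, depletion_bC_unstable))):
        protocol = Protocol.depletion(duration, duration, bC_dep)
        # depletion starts after an equilibration window of equal length
        t_max = 3 * duration
        M_pre, M_dep, P_pre, P_dep, traj0 = [], [], [], [], None
        for r in range(n_runs):
            traj = run_protocol(params, variant, protocol, t_max,
                                derive_seed(seed, tag_idx, r),
                                sample_dt=sample_dt)
            pre = (traj.times >= 0.5 * duration) & (traj.times < duration)
            dep = (traj.times >= 1.5 * duration) & (traj.times < 2 * duration)
            M_pre.append(traj.column("M")[pre].mean())
            M_dep.append(traj.column("M")[dep].mean())
            if "P" in traj.species:
                P_pre.append(traj.column("P")[pre].mean())
                P_dep.append(traj.column("P")[dep].mean())
            if traj0 is None:
                traj0 = traj
        rec = {}
        for d in recovery_durations:
            rec[d] = recovery_fraction(params, variant, d, bC_dep,
                                       n_recovery_runs,
                                       derive_seed(seed, 77, int(d)),
                                       observation_window=recovery_observation)
        out["panels"][tag] = {
            "M_before": float(np.mean(M_pre)),
            "M_during_depletion": float(np.mean(M_dep)),
            "M_se_before": float(np.std(M_pre, ddof=1) / math.sqrt(n_runs)),
            "M_se_during": float(np.std(M_dep, ddof=1) / math.sqrt(n_runs)),
            "P_before": float(np.mean(P_pre)) if P_pre else None,
            "P_during_depletion": float(np.mean(P_dep)) if P_dep else None,
            "recovery_fraction_by_duration": {
                f"{d:.0f}": rec[d]["fraction"] for d in recovery_durations},
            "example_trajectory": traj0,
        }
    return out


def _score_expression(traj, window_mask, M_on: float) -> float:
    """Mean che-1 mRNA in the window, as a fraction of the ON-state mean."""
    return float(traj.column("M")[window_mask].mean() / M_on)


def hdtf_panel(scale: float = 0.1, constitutive: bool = True,
               n_runs: int = 8, seed: int = 0,
               induction_duration: float = 2 * 3600.0,
               observation: float = 6 * 3600.0,
               depletion_duration: float = 2 * 3600.0,
               depletion_factor: float = 10.0,
               maintain_threshold: float = 0.5,
               loss_threshold: float = 0.25) -> dict:
    """The three in-silico HD-TF experiments for both co-factor models.

    Per model (1: HD-TF as CHE-1 co-factor on the che-1 promoter; 2: HD-TF
    induces che-1 independently), runs ensembles of

    * transient induction — start with no CHE-1/mRNA, basal transcription on
      for a window; scores whether expression is *maintained* afterwards;
    * motif deletion — start ON, CHE-1 binding to its own promoter removed
      (fO_C = 0); scores whether expression is *lost*;
    * transient depletion — start ON, protein degradation raised by
      ``depletion_factor`` for a window; scores whether expression *recovers*.

    The co-factor model passes all three; the independent-induction model
    maintains expression even with the motif deleted, failing that
    experiment.  ``scale`` < 1 runs the copy-number-scaled preset (the
    depletion factor is scaled with it so the depleted copy number matches
    the full-scale depth).
    """
    out: dict = {"scale": scale, "models": {}}
    for model in (1, 2):
        variant = f"hd{model}{'a' if constitutive else 'b'}"
        params = hd_params(model, constitutive=constitutive, scale=scale)
        M_on, C_on, _th, _nT = steady_state_observables(
            params.replace(fM0=0.0) if params.fM0 else params, variant)
        results: dict = {}

        # 1) transient induction from the unexpressed state; the basal
        # channel exists with base rate 0 and is switched on by the protocol
        net_ind = build_network(variant, params.replace(fM0=0.0))
        init_off = net_ind.initial_state(M=0, C=0)
        induction = Protocol.induction(0.0, induction_duration,
                                       params.fM0 or 0.005)
        frac = []
        for r in range(n_runs):
            traj = gillespie_run(net_ind, init_off,
                                 induction_duration + observation,
                                 derive_seed(seed, model, 1, r),
                                 protocol=induction, sample_dt=120.0)
            late = traj.times >= induction_duration + 0.5 * observation
            frac.append(_score_expression(traj, late, M_on))
        results["induction_maintained"] = float(np.mean(
            [f >= maintain_threshold for f in frac]))
        results["induction_expression_level"] = float(np.mean(frac))

        # 2) motif deletion: ON animal loses CHE-1 binding to its own promoter
        p_del = params.replace(fO_C=0.0, fM0=None)
        init_on = on_initial_state(params.replace(fM0=None), variant)
        net_del = build_network(variant, p_del)
        frac = []
        for r in range(n_runs):
            traj = gillespie_run(net_del, init_on, observation,
                                 derive_seed(seed, model, 2, r),
                                 sample_dt=120.0)
            late = traj.times >= 0.5 * observation
            frac.append(_score_expression(traj, late, M_on))
        results["deletion_lost"] = float(np.mean(
            [f < loss_threshold for f in frac]))
        results["deletion_expression_level"] = float(np.mean(frac))

        # 3) transient depletion of CHE-1 protein
        p_base = params.replace(fM0=None)
        net_dep = build_network(variant, p_base)
        frac = []
        for r in range(n_runs):
            prot = Protocol.depletion(0.0, depletion_duration,
                                      params.bC * depletion_factor)
            traj = gillespie_run(net_dep, init_on,
                                 depletion_duration + observation,
                                 derive_seed(seed, model, 3, r),
                                 protocol=prot, sample_dt=120.0)
            late = traj.times >= depletion_duration + 0.5 * observation
            frac.append(_score_expression(traj, late, M_on))
        results["depletion_recovered"] = float(np.mean(
            [f >= maintain_threshold for f in frac]))
        results["depletion_expression_level"] = float(np.mean(frac))

        results["passes_all_three"] = (
            results["induction_maintained"] >= 0.75
            and results["deletion_lost"] >= 0.75
            and results["depletion_recovered"] >= 0.75)
        out["models"][f"model{model}"] = results
    return out
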