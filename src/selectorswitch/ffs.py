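"""Direct forward flux sampling (FFS) of spontaneous ON -> OFF transitions.

The order parameter is total CHE-1 protein (free plus promoter- and
target-bound), decreasing toward the OFF state; interfaces are placed at
descending protein thresholds, by default 20 molecules apart, with the first
interface chosen from pilot excursion statistics so that ~5-10% of basin
excursions reach it.  The ON-state lifetime is ``1 / (Phi_0 * prod p_i)``
where ``Phi_0`` is the flux through the first interface and ``p_i`` the
conditional probability of advancing one interface before falling back into
the basin.  Direct FFS, no pruning.  Transition-path statistics (promoter
occupancy, target occupancy, mRNA binned by total protein) are accumulated
time-weighted along every shot and composed over branch ancestries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from ._kernel import ssa_kernel
from .deterministic import on_initial_state
from .network import ReactionNetwork, build_network
from .parameters import ParameterSet
from .ssa import derive_seed

__all__ = ["FFSConfig", "FFSResult", "characterize_on_basin",
           "place_interfaces", "ffs_run", "average_transition_path"]

_MAX_EVENTS = 200_000_000
_NO_SAMPLES = np.empty(0)

SECONDS_PER_YEAR = 365.25 * 24 * 3600.0


@dataclass
class FFSConfig:
    """Interface layout and sampling budget for one FFS run.

    ``c_interfaces`` are total-protein thresholds, strictly decreasing, ending
    at 0 (the OFF boundary, which additionally requires zero mRNA);
    ``c_basin`` is the basin-return boundary, one interface step inside the
    basin mean.
    """

    c_interfaces: list
    c_basin: float
    trials: int = 1000
    n_flux: Optional[int] = None      # first-interface crossings to collect
    max_store: int = 500
    seed: int = 0
    t_burn: float = 2000.0
    shot_t_max: float = 1.0e5
    on_mean: float = float("nan")
    on_var: float = float("nan")
    step: float = 20.0
    path_bin_width: Optional[float] = None
    notes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        c = np.asarray(self.c_interfaces, dtype=float)
        if len(c) < 2 or np.any(np.diff(c) >= 0):
            raise ValueError("interfaces must be strictly decreasing toward OFF")
        if c[-1] != 0.0:
            raise ValueError("last interface must be the OFF boundary (0)")
        if self.c_basin <= c[0]:
            raise ValueError("basin boundary must lie above the first interface")

    @property
    def n_interfaces(self) -> int:
        return len(self.c_interfaces)


@dataclass
class FFSResult:
    """Flux, conditional probabilities, lifetime, and harvested paths."""

    config: FFSConfig
    phi0: float                      # crossings of the first interface per second
    phi0_n: int
    p: np.ndarray                    # conditional crossing probabilities
    p_err: np.ndarray
    n_trials: np.ndarray
    lifetime: float                  # s
    lifetime_err: float              # s (delta method on log tau)
    lower_bound_only: bool
    transition_paths: list           # composed path records (complete ON->OFF)
    partial_paths: list = field(default_factory=list)  # deepest-interface paths
    off_during_flux: int = 0

    @property
    def lifetime_years(self) -> float:
        return self.lifetime / SECONDS_PER_YEAR

    def to_dict(self) -> dict:
        return {
            "interfaces": list(map(float, self.config.c_interfaces)),
            "c_basin": self.config.c_basin,
            "phi0": self.phi0, "phi0_n": self.phi0_n,
            "p": self.p.tolist(), "p_err": self.p_err.tolist(),
            "lifetime_s": self.lifetime, "lifetime_err_s": self.lifetime_err,
            "lifetime_years": self.lifetime_years,
            "lower_bound_only": self.lower_bound_only,
            "n_transition_paths": len(self.transition_paths),
        }


def _kernel_args(net: ReactionNetwork):
    return dict(w_prot=net.protein_weights, w_own=net.own_occupancy_weights,
                m_idx=net.index["M"], tgt_idx=net.index["OTC"])


def _run_until(net, state, rates, t, t_max, seed, c_lo, c_hi, require_m_zero,
               acc=None, binw=1.0, kw=None):
    """Advance ``state`` until the order parameter leaves (c_lo, c_hi)."""
    kw = kw or _kernel_args(net)
    acc_arr = acc if acc is not None else np.zeros((1, 4))
    samples = np.zeros((0, len(net.species)), dtype=np.int64)
    chunk = 0
    while True:
        t, status, _ev, _k, min_p = ssa_kernel(
            state, rates, net.reactant_idx, net.stoich, t, t_max,
            derive_seed(seed, chunk), _NO_SAMPLES, 0, samples,
            kw["w_prot"], kw["m_idx"], 1, c_lo, c_hi, require_m_zero,
            acc_arr, 1 if acc is not None else 0, binw,
            kw["w_own"], kw["tgt_idx"], _MAX_EVENTS)
        if status != _kernel.MAX_EVENTS:
            return t, status, min_p
        chunk += 1


def characterize_on_basin(params: ParameterSet, variant: str,
                          t_burn: float = 2000.0, t_sample: float = 20000.0,
                          seed: int = 0, sample_dt: float = 5.0,
                          n_replicas: int = 5) -> dict:
    """Time-averaged mean and variance of total CHE-1 in the ON basin.

    The sampling budget is split over independent replicas started from the
    ON state; replicas that leave the basin (total CHE-1 reaching zero — a
    spontaneous OFF switch) are excluded so marginally stable parameter sets
    still yield basin moments.  Burn-in is discarded per replica.
    """
    from .ssa import derive_seed as _ds, gillespie_run
    net = build_network(variant, params)
    init = on_initial_state(params, variant, network=net)
    t_rep = t_sample / n_replicas
    chunks = []
    for r in range(n_replicas):
        traj = gillespie_run(net, init, t_burn + t_rep, _ds(seed, 700, r),
                             sample_dt=sample_dt)
        prot = traj.total_protein(net)
        if prot.min() <= 0:
            continue  # switched OFF: not a basin sample
        chunks.append(prot[traj.times >= t_burn])
    if not chunks:
        raise RuntimeError(
            "ON state not metastable on the sampling window: every replica "
            "switched OFF; shorten t_sample or stabilize parameters")
    per_rep_mean = np.array([c.mean() for c in chunks])
    prot = np.concatenate(chunks)
    mean, var = float(prot.mean()), float(prot.var(ddof=1))
    se = (float(per_rep_mean.std(ddof=1) / math.sqrt(len(chunks)))
          if len(chunks) > 1 else float("nan"))
    return {"mean": mean, "var": var, "sd": math.sqrt(var), "se": se,
            "n_samples": len(prot), "n_replicas_kept": len(chunks)}


def place_interfaces(params: ParameterSet, variant: str, basin_stats: dict,
                     step: float = 20.0,
                     target_first_prob: tuple = (0.05, 0.10),
                     seed: int = 0, n_excursions: int = 300,
                     min_interfaces: int = 20, max_interfaces: int = 35,
                     trials: int = 1000, adjust_step: bool = True,
                     pilot_t_max: float = 2.0e5) -> FFSConfig:
    """Choose the first interface from pilot excursion statistics.

    Simulates basin excursions below the return boundary ``c_basin = mean -
    step`` and records each excursion's minimum total protein; the first
    interface is the threshold (on the step grid) that ~5-10% of excursions
    reach.  Subsequent interfaces descend by ``step`` to the OFF boundary;
    the interface count is clamped to [min_interfaces, max_interfaces] by
    adjusting the step only if necessary (recorded in ``notes``).
    """
    mean = basin_stats["mean"]
    if step >= 0.5 * mean:
        raise ValueError(
            f"interface step {step} too large for a basin at mean {mean:.1f}")
    c_pilot = mean - step          # excursion-detection boundary for the pilot
    net = build_network(variant, params)
    kw = _kernel_args(net)
    init = on_initial_state(params, variant, network=net)
    state = init.copy()
    rates = net.rate_vector()
    notes: list = []

    minima = []
    t = 0.0
    for i in range(n_excursions):
        # wait in the basin until the trajectory dips below the pilot boundary
        t, status, _ = _run_until(net, state, rates, t, t + pilot_t_max,
                                  derive_seed(seed, 2, i), c_pilot, np.inf, 0,
                                  kw=kw)
        if status != _kernel.HIT_LOW:
            break
        # follow the excursion until it returns (or reaches OFF)
        t, status, min_p = _run_until(net, state, rates, t, t + pilot_t_max,
                                      derive_seed(seed, 3, i), 0.0,
                                      c_pilot + 1.0, 1, kw=kw)
        if status == _kernel.HIT_LOW:        # reached OFF during the pilot
            minima.append(0.0)
            state = init.copy()
        elif status == _kernel.HIT_HIGH:
            minima.append(min_p)
        else:
            break
    if len(minima) < 20:
        raise RuntimeError(
            "pilot runs never left the basin often enough; increase "
            "pilot_t_max or n_excursions")
    minima = np.asarray(minima)

    lo_p, hi_p = target_first_prob
    c_pilot = math.floor(c_pilot)
    candidates = np.arange(c_pilot - step, -0.5 * step, -step)
    candidates = candidates[candidates > 0]
    chosen = None
    for c0 in candidates:  # highest (closest to basin) first
        frac = float(np.mean(minima <= c0))
        if lo_p <= frac <= hi_p:
            chosen = c0
            break
    if chosen is None:
        # fallback: snap the mid-target quantile of excursion depths to grid
        q = float(np.quantile(minima, 0.5 * (lo_p + hi_p)))
        chosen = max(step, math.floor(q / step) * step)
        chosen = min(chosen, c_pilot - step)
        notes.append(f"first-interface fallback: quantile placement at {chosen}")

    def ladder(c0: float, st: float) -> list:
        cs = [float(round(c)) for c in np.arange(c0, 0.5 * st, -st)]
        return cs + [0.0]

    st = step
    cs = ladder(chosen, st)
    if adjust_step and len(cs) < min_interfaces:
        st = max(1.0, math.floor(chosen / (min_interfaces - 1)))
        cs = ladder(chosen, st)
        notes.append(f"step reduced to {st} to reach >= {min_interfaces} interfaces")
    if adjust_step and len(cs) > max_interfaces:
        st = math.ceil(chosen / (max_interfaces - 1))
        cs = ladder(chosen, st)
        notes.append(f"step increased to {st} to stay <= {max_interfaces} interfaces")
    if len(cs) < 2:
        raise ValueError("interface ladder degenerate; step too large for basin")
    # basin-return boundary one interface step inside the basin from the
    # first interface: failed shots terminate quickly, and the flux stage
    # re-arms at the same boundary, keeping the rate estimate consistent
    c_basin = cs[0] + st
    return FFSConfig(c_interfaces=cs, c_basin=c_basin, trials=trials,
                     seed=seed, on_mean=mean, on_var=basin_stats["var"],
                     step=st, notes=notes)


def ffs_run(params: ParameterSet, variant: str, config: FFSConfig) -> FFSResult:
    """Direct FFS: flux stage plus one shooting stage per interface gap."""
    net = build_network(variant, params)
    kw = _kernel_args(net)
    rates = net.rate_vector()
    rng = np.random.default_rng(derive_seed(config.seed, 11))
    cs = list(map(float, config.c_interfaces))
    binw = config.path_bin_width or max(1.0, config.step / 2.0)
    n_bins = int(math.ceil((config.c_basin + 4 * config.step) / binw)) + 1

    # ---- stage 0: initial flux through the first interface -----------------
    init = on_initial_state(params, variant, network=net)
    state = init.copy()
    t, _status, _ = _run_until(net, state, rates, 0.0, config.t_burn,
                               derive_seed(config.seed, 0), -1.0, np.inf, 0,
                               kw=kw)
    t_flux_start = t
    stored0: list = []
    off_during_flux = 0
    n_cross = 0
    target_cross = config.n_flux or min(config.trials, config.max_store)
    i_cross = 0
    while n_cross < target_cross:
        t, status, _ = _run_until(net, state, rates, t, t + 1e12,
                                  derive_seed(config.seed, 20, i_cross),
                                  cs[0], np.inf, 0, kw=kw)
        if status != _kernel.HIT_LOW:
            raise RuntimeError("flux stage failed to reach the first interface")
        n_cross += 1
        if len(stored0) < config.max_store:
            stored0.append(state.copy())
        # must return to the basin boundary before the next crossing counts
        t, status, _ = _run_until(net, state, rates, t, t + 1e12,
                                  derive_seed(config.seed, 21, i_cross),
                                  0.0, config.c_basin, 1, kw=kw)
        if status == _kernel.HIT_LOW:       # spontaneous full transition
            off_during_flux += 1
            state = init.copy()
        i_cross += 1
    t_total = t - t_flux_start
    phi0 = n_cross / t_total

    # ---- shooting stages ---------------------------------------------------
    stages = []  # per stage: dict(stored=[states], parents=[int], accs=[arr])
    stored = stored0
    parents_of_stored = [None] * len(stored0)
    accs_of_stored = [None] * len(stored0)
    p_list, perr_list, ntrials_list = [], [], []
    lower_bound_only = False
    for i in range(len(cs) - 1):
        c_next = cs[i + 1]
        require_m0 = 1 if c_next == 0.0 else 0
        succ_states, succ_parents, succ_accs = [], [], []
        n_succ = 0
        n_timeout = 0
        n_shot = config.trials
        for j in range(n_shot):
            pick = int(rng.integers(len(stored)))
            shot_state = stored[pick].copy()
            acc = np.zeros((n_bins, 4))
            _t, status, _ = _run_until(
                net, shot_state, rates, 0.0, config.shot_t_max,
                derive_seed(config.seed, 30 + i, j), c_next, config.c_basin,
                require_m0, acc=acc, binw=binw, kw=kw)
            if status == _kernel.HIT_LOW:
                n_succ += 1
                if len(succ_states) < config.max_store:
                    succ_states.append(shot_state)
                    succ_parents.append(pick)
                    succ_accs.append(acc)
            elif status != _kernel.HIT_HIGH:
                n_timeout += 1   # time-capped shot scored as a failure
        if n_timeout:
            config.notes.append(
                f"stage {i}: {n_timeout}/{n_shot} shots hit shot_t_max "
                "(scored as failures)")
        p = n_succ / n_shot
        p_list.append(p)
        perr_list.append(math.sqrt(max(p * (1 - p), 1.0 / n_shot) / n_shot))
        ntrials_list.append(n_shot)
        stages.append({"stored": stored, "parents": parents_of_stored,
                       "accs": accs_of_stored})
        if n_succ == 0:
            lower_bound_only = True
            # upper bound p_i <= 1/trials gives a lifetime lower bound
            p_list[-1] = 1.0 / n_shot
            break
        stored = succ_states
        parents_of_stored = succ_parents
        accs_of_stored = succ_accs

    p = np.asarray(p_list)
    p_err = np.asarray(perr_list)
    n_trials = np.asarray(ntrials_list)
    rate = phi0 * float(np.prod(p))
    lifetime = 1.0 / rate
    var_log = 1.0 / n_cross + float(np.sum((1 - p) / (p * n_trials)))
    lifetime_err = lifetime * math.sqrt(var_log)

    # ---- compose transition paths via branch ancestry ----------------------
    def _compose(stage_list, final_states, final_parents, final_accs):
        out = []
        for j in range(len(final_states)):
            if final_accs[j] is None:
                continue
            acc_total = final_accs[j].copy()
            crossing_states = [final_states[j]]
            parent = final_parents[j]
            for s in range(len(stage_list) - 1, 0, -1):
                st = stage_list[s]
                crossing_states.append(st["stored"][parent])
                if st["accs"][parent] is not None:
                    acc_total += st["accs"][parent]
                parent = st["parents"][parent]
            crossing_states.append(stage_list[0]["stored"][parent])
            out.append({"acc": acc_total,
                        "states": list(reversed(crossing_states))})
        return out

    # partial paths reach the deepest interface with stored configurations;
    # they enrich occupancy profiles where complete OFF paths are scarce
    if lower_bound_only:
        paths = []
        partial = _compose(stages[:-1], stages[-1]["stored"],
                           stages[-1]["parents"], stages[-1]["accs"]) \
            if len(stages) > 1 else []
    else:
        paths = _compose(stages, stored, parents_of_stored, accs_of_stored)
        partial = _compose(stages[:-1], stages[-1]["stored"],
                           stages[-1]["parents"], stages[-1]["accs"]) \
            if len(stages) > 1 else []
    return FFSResult(config=config, phi0=phi0, phi0_n=n_cross, p=p,
                     p_err=p_err, n_trials=n_trials, lifetime=lifetime,
                     lifetime_err=lifetime_err,
                     lower_bound_only=lower_bound_only,
                     transition_paths=paths,
                     partial_paths=partial,
                     off_during_flux=off_during_flux)


def average_transition_path(result: FFSResult, NT: int,
                            bin_width: Optional[float] = None,
                            include_partial: bool = False):
    """Average che-1 promoter occupancy, target occupancy, and mRNA along
    harvested ON->OFF transition paths, binned by descending total protein.

    Complete paths (traced through the branch ancestry back to the first
    interface) are weighted equally; empty bins are dropped per path.  When
    the run produced no complete OFF path (lifetime lower bound only),
    ``include_partial=True`` falls back to paths reaching the deepest
    interface that was sampled.
    Returns a DataFrame with columns C_total, theta_O, target_occupancy, M,
    n_paths.
    """
    import pandas as pd
    import warnings as _warnings
    records = list(result.transition_paths)
    if include_partial:
        records += list(result.partial_paths)
    if not records:
        raise ValueError("no complete transition paths harvested")
    binw = bin_width or (result.config.path_bin_width
                         or max(1.0, result.config.step / 2.0))
    accs = [p["acc"] for p in records]
    n_bins = accs[0].shape[0]
    prof = np.full((len(accs), n_bins, 3), np.nan)
    for k, acc in enumerate(accs):
        occupied = acc[:, 0] > 0
        prof[k, occupied, 0] = acc[occupied, 1] / acc[occupied, 0]
        prof[k, occupied, 1] = acc[occupied, 2] / (acc[occupied, 0] * NT)
        prof[k, occupied, 2] = acc[occupied, 3] / acc[occupied, 0]
    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        mean_prof = np.nanmean(prof, axis=0)
    n_paths = np.sum(~np.isnan(prof[:, :, 0]), axis=0)
    centers = (np.arange(n_bins) + 0.5) * binw
    keep = n_paths > 0
    return pd.DataFrame({
        "C_total": centers[keep],
        "theta_O": mean_prof[keep, 0],
        "target_occupancy": mean_prof[keep, 1],
        "M": mean_prof[keep, 2],
        "n_paths": n_paths[keep],
    })
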