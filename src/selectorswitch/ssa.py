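"""Exact stochastic simulation (Gillespie direct method) of the switch models.

Thin, protocol-aware Python layer over the jitted kernel: piecewise-constant
parameter overrides are handled by splitting the run at window boundaries (a
step never crosses a boundary), FRAP bleach events re-label visible protein
as dark instantaneously, and every ensemble member gets an independently
derived sub-seed so runs are reproducible and order-independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from ._kernel import ssa_kernel
from .deterministic import on_initial_state, steady_state_observables
from .network import Protocol, ReactionNetwork, build_network
from .parameters import ParameterSet

__all__ = ["Trajectory", "gillespie_run", "run_protocol",
           "first_passage_to_off", "recovery_fraction", "mean_first_passage",
           "derive_seed"]

_MAX_EVENTS = 200_000_000


def derive_seed(master: int, *indices: int) -> int:
    """Deterministic sub-seed below 2^31 from a master seed and indices."""
    h = hashlib.sha256(("/".join(map(str, (master,) + indices))).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31 - 1)


@dataclass
class Trajectory:
    """Sampled stochastic time series of the full state vector."""

    times: np.ndarray                  # uniform grid, strictly increasing
    states: np.ndarray                 # (n_samples, n_species) int64
    species: list
    seed: int
    events: int
    variant: str
    protocol: Optional[Protocol] = None
    config_hash: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")

    def column(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    def total_protein(self, network: ReactionNetwork) -> np.ndarray:
        return self.states @ network.protein_weights

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.states, columns=self.species)
        df.insert(0, "t", self.times)
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            meta = {"seed": self.seed, "events": self.events,
                    "variant": self.variant, "config_hash": self.config_hash,
                    "species": self.species}
            with open(str(path) + ".json", "w") as fh:
                json.dump(meta, fh, indent=1)


def _config_hash(network: ReactionNetwork, protocol: Optional[Protocol]) -> str:
    payload = {
        "variant": network.variant,
        "params": network.params.to_dict(),
        "species": network.species,
        "overrides": protocol.overrides if protocol else [],
        "bleach": protocol.bleach_events if protocol else [],
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _apply_bleach(network: ReactionNetwork, state: np.ndarray,
                  visible_fraction: float, rng: np.random.Generator) -> None:
    """Binomially re-label visible protein as dark, pool by pool (FRAP)."""
    pairs = [("C", "Cd"), ("OC", "OCd"), ("OTC", "OTCd")]
    for vis, dark in pairs:
        if vis in network.index and dark in network.index:
            iv, idk = network.index[vis], network.index[dark]
            keep = rng.binomial(int(state[iv]), visible_fraction)
            state[idk] += state[iv] - keep
            state[iv] = keep


def gillespie_run(network: ReactionNetwork, init: np.ndarray, t_max: float,
                  seed: int, protocol: Optional[Protocol] = None,
                  sample_dt: float = 10.0) -> Trajectory:
    """Statistically exact SSA of ``network`` from ``init`` on [0, t_max].

    Samples the state on a uniform grid of spacing ``sample_dt`` (the state at
    t=0 is the first sample).  Identical (network, protocol, seed) yields an
    identical trajectory.  Absorbing states simply persist until ``t_max``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    network.validate_state(init)
    state = init.astype(np.int64).copy()
    n_sp = len(network.species)
    sample_times = np.arange(0.0, t_max + 0.5 * sample_dt, sample_dt)
    samples = np.zeros((len(sample_times), n_sp), dtype=np.int64)
    samples[0] = state
    k_samp = 1

    boundaries = [0.0, t_max]
    if protocol is not None:
        boundaries += [b for b in protocol.boundaries() if 0.0 < b < t_max]
    boundaries = sorted(set(boundaries))

    bleach_by_t = {}
    if protocol is not None:
        for (tb, frac) in protocol.bleach_events:
            bleach_by_t.setdefault(tb, []).append(frac)

    w_prot = network.protein_weights
    w_own = network.own_occupancy_weights
    m_idx = network.index["M"]
    tgt_idx = network.index["OTC"]
    dummy_acc = np.zeros((1, 4))
    rng = np.random.default_rng(derive_seed(seed, 987))
    events_total = 0
    t = 0.0
    for si in range(len(boundaries) - 1):
        t0, t1 = boundaries[si], boundaries[si + 1]
        for frac in bleach_by_t.get(t0, []):
            _apply_bleach(network, state, frac, rng)
        rates = network.rate_vector(0.5 * (t0 + t1), protocol)
        chunk = 0
        while True:
            t, status, ev, k_samp, _ = ssa_kernel(
                state, rates, network.reactant_idx, network.stoich,
                t0 if chunk == 0 else t, t1, derive_seed(seed, si, chunk),
                sample_times, k_samp, samples,
                w_prot, m_idx, 0, -1.0, np.inf, 0,
                dummy_acc, 0, 1.0, w_own, tgt_idx, _MAX_EVENTS)
            events_total += ev
            chunk += 1
            if status != _kernel.MAX_EVENTS:
                break
    return Trajectory(times=sample_times, states=samples,
                      species=network.species, seed=seed, events=events_total,
                      variant=network.variant, protocol=protocol,
                      config_hash=_config_hash(network, protocol))


def run_protocol(params: ParameterSet, variant: str, protocol: Protocol,
                 t_max: float, seed: int, sample_dt: float = 60.0,
                 frap: bool = False) -> Trajectory:
    """Build the network, start at the rounded deterministic ON state, run."""
    network = build_network(variant, params, frap=frap)
    init = on_initial_state(params, variant, network=network)
    return gillespie_run(network, init, t_max, seed, protocol=protocol,
                         sample_dt=sample_dt)


def first_passage_to_off(params: ParameterSet, variant: str, seed: int,
                         t_max: float,
                         init: Optional[np.ndarray] = None,
                         network: Optional[ReactionNetwork] = None
                         ) -> Optional[float]:
    """First time total CHE-1 and che-1 mRNA both hit zero, else None (censored).

    The OFF criterion (no protein anywhere, no mRNA) is absorbing in the
    non-cooperative model without basal transcription.
    """
    net = network if network is not None else build_network(variant, params)
    state = (init.copy() if init is not None
             else on_initial_state(params, variant, network=net)).astype(np.int64)
    w_prot = net.protein_weights
    w_own = net.own_occupancy_weights
    m_idx = net.index["M"]
    tgt_idx = net.index["OTC"]
    no_samples = np.empty(0)
    samples = np.zeros((0, len(net.species)), dtype=np.int64)
    dummy_acc = np.zeros((1, 4))
    rates = net.rate_vector()
    if float(w_prot @ state) == 0 and state[m_idx] == 0:
        return 0.0
    t, chunk = 0.0, 0
    while True:
        t, status, _ev, _k, _m = ssa_kernel(
            state, rates, net.reactant_idx, net.stoich, t, t_max,
            derive_seed(seed, chunk), no_samples, 0, samples,
            w_prot, m_idx, 1, 0.0, np.inf, 1,
            dummy_acc, 0, 1.0, w_own, tgt_idx, _MAX_EVENTS)
        if status == _kernel.HIT_LOW:
            return t
        if status == _kernel.ABSORBED:
            # absorbing but not OFF (cannot happen in these models); censored
            return None
        if status != _kernel.MAX_EVENTS:
            return None
        chunk += 1


def mean_first_passage(params: ParameterSet, variant: str, n_runs: int,
                       seed: int, t_max: float) -> dict:
    """Brute-force ensemble of ON->OFF first-passage times.

    Returns mean, standard error, the individual times, and the number of
    runs censored at ``t_max`` (censoring biases the mean low; keep t_max
    generous relative to the expected lifetime).
    """
    net = build_network(variant, params)
    init = on_initial_state(params, variant, network=net)
    times, censored = [], 0
    for r in range(n_runs):
        fpt = first_passage_to_off(params, variant, derive_seed(seed, r),
                                   t_max, init=init, network=net)
        if fpt is None:
            censored += 1
        else:
            times.append(fpt)
    times = np.asarray(times)
    mean = float(times.mean()) if len(times) else float("nan")
    se = float(times.std(ddof=1) / np.sqrt(len(times))) if len(times) > 1 else float("nan")
    return {"mean": mean, "se": se, "times": times, "censored": censored,
            "n_runs": n_runs}


def recovery_fraction(params: ParameterSet, variant: str,
                      depletion_duration: float, depletion_bC: float,
                      n_runs: int, seed: int,
                      observation_window: float = 48 * 3600.0,
                      sample_dt: float = 300.0) -> dict:
    """Fraction of runs that regain CHE-1 after transient depletion.

    Depletion raises the free-protein degradation rate to ``depletion_bC``
    for ``depletion_duration`` seconds; a run counts as recovered if total
    CHE-1 returns above half its ON-state mean at any sampled time within the
    post-depletion observation window.  Non-recovery reflects stochastic loss
    of every CHE-1 molecule (and mRNA) during depletion, after which the OFF
    state is absorbing.  Returns the fraction with a 95% binomial CI.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    net = build_network(variant, params)
    _M, C_on, _th, _nT = steady_state_observables(params, variant)
    threshold = 0.5 * C_on
    init = on_initial_state(params, variant, network=net)
    if depletion_duration > 0:
        protocol = Protocol.depletion(0.0, depletion_duration, depletion_bC)
    else:
        protocol = None
    t_max = depletion_duration + observation_window
    n_rec = 0
    for r in range(n_runs):
        traj = gillespie_run(net, init, t_max, derive_seed(seed, r),
                             protocol=protocol, sample_dt=sample_dt)
        prot = traj.total_protein(net)
        post = traj.times >= depletion_duration
        if np.any(prot[post] >= threshold):
            n_rec += 1
    from scipy.stats import binomtest
    ci = binomtest(n_rec, n_runs).proportion_ci(confidence_level=0.95)
    return {"fraction": n_rec / n_runs, "n_recovered": n_rec, "n_runs": n_runs,
            "ci_low": ci.low, "ci_high": ci.high}
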