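"""Reaction networks for the CHE-1 switch model variants.

State space and mass-action channels for:

* ``noncoop`` — CHE-1 binds its own promoter as a monomer and induces
  transcription from the singly bound promoter;
* ``coop`` — two CHE-1 molecules bind sequentially; only the doubly bound
  promoter transcribes;
* ``hd1a``/``hd1b`` — a homeodomain co-factor (HD-TF) binds the *che-1*
  promoter and stabilizes CHE-1 on it (slow dissociation from the joint
  complex); transcription fires from both the CHE-1-bound and the joint
  complex;
* ``hd2a``/``hd2b`` — HD-TF induces *che-1* independently of CHE-1.

``a`` variants hold free HD-TF clamped at a constant copy number; ``b``
variants produce HD-TF from CHE-1 and degrade it.  The *che-1* promoter is a
single copy; the ``NT`` identical target promoters are lumped into one bound
counter (exact, since they share association and dissociation rates).  An
optional reporter target promoter with its own mRNA supports the depletion
panels, and an optional FRAP mode mirrors every protein channel for a
bleached (dark) pool which is never produced, only degraded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .parameters import ParameterSet

__all__ = ["Channel", "ReactionNetwork", "Protocol", "build_network",
           "propensity_vector"]

VARIANTS = ("noncoop", "coop", "hd1a", "hd1b", "hd2a", "hd2b")


@dataclass(frozen=True)
class Channel:
    """One reaction channel: propensity = rate(param) * product of reactant counts."""

    name: str
    rate_param: str
    reactants: tuple[str, ...]      # 0-2 species whose counts multiply
    stoich: dict                    # species name -> integer change


@dataclass
class Protocol:
    """Timed, piecewise-constant parameter overrides plus bleach events.

    ``overrides`` is a list of ``(t_start, t_end, param, value)``; outside all
    windows the base ParameterSet applies.  ``bleach_events`` is a list of
    ``(t, visible_fraction)``: at time t every visible protein (free or bound)
    is independently retained as visible with the given probability, the rest
    re-labeled dark (FRAP mode only).
    """

    overrides: list = field(default_factory=list)
    bleach_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for (t0, t1, name, _val) in self.overrides:
            if t0 > t1:
                raise ValueError(f"override window for {name} has t_start > t_end")

    def add(self, t_start: float, t_end: float, param: str, value: float) -> "Protocol":
        self.overrides.append((t_start, t_end, param, value))
        return self

    def boundaries(self) -> list[float]:
        out = set()
        for (t0, t1, _n, _v) in self.overrides:
            out.update((t0, t1))
        for (t, _f) in self.bleach_events:
            out.add(t)
        return sorted(out)

    def value(self, param: str, t: float, base: float) -> float:
        """Parameter value at time t (last matching window wins)."""
        v = base
        for (t0, t1, name, val) in self.overrides:
            if name == param and t0 <= t < t1:
                v = val
        return v

    @classmethod
    def depletion(cls, t_start: float, duration: float, bC_depleted: float) -> "Protocol":
        """Transient protein depletion: raised degradation inside the window."""
        return cls(overrides=[(t_start, t_start + duration, "bC", bC_depleted)])

    @classmethod
    def induction(cls, t_start: float, duration: float, fM0: float = 0.005) -> "Protocol":
        """Transient CHE-1-independent *che-1* induction (basal transcription on)."""
        return cls(overrides=[(t_start, t_start + duration, "fM0", fM0)])


class ReactionNetwork:
    """Channel list of one model variant, compiled to arrays for simulation."""

    def __init__(self, variant: str, params: ParameterSet,
                 species: Sequence[str], channels: Sequence[Channel],
                 clamped: Sequence[str] = ()) -> None:
        self.variant = variant
        self.params = params
        self.species = list(species)
        self.channels = list(channels)
        self.clamped = tuple(clamped)
        self.index = {s: i for i, s in enumerate(self.species)}
        n_ch, n_sp = len(self.channels), len(self.species)
        self.reactant_idx = np.full((n_ch, 2), -1, dtype=np.int64)
        self.stoich = np.zeros((n_ch, n_sp), dtype=np.int64)
        for k, ch in enumerate(self.channels):
            if len(ch.reactants) > 2:
                raise ValueError("at most bimolecular channels supported")
            for j, r in enumerate(ch.reactants):
                self.reactant_idx[k, j] = self.index[r]
            for sp, d in ch.stoich.items():
                if sp in self.clamped:
                    continue  # clamped species: read in propensities, never changed
                self.stoich[k, self.index[sp]] = d

    # -- weights for derived observables ------------------------------------
    @property
    def protein_weights(self) -> np.ndarray:
        """w such that w . state = total CHE-1 (free + all bound, incl. dark)."""
        w = np.zeros(len(self.species))
        for sp, wt in (("C", 1), ("Cd", 1), ("OC", 1), ("OCd", 1), ("OC2", 2),
                       ("OTC", 1), ("OTCd", 1), ("OHC", 1), ("POC", 1)):
            if sp in self.index:
                w[self.index[sp]] = wt
        return w

    @property
    def own_occupancy_weights(self) -> np.ndarray:
        """w such that w . state = 1 iff the che-1 promoter is productively bound."""
        w = np.zeros(len(self.species))
        for sp in ("OC", "OCd", "OC2", "OHC"):
            if sp in self.index:
                w[self.index[sp]] = 1.0
        return w

    def rate_vector(self, t: float = 0.0,
                    protocol: Optional[Protocol] = None) -> np.ndarray:
        rates = np.empty(len(self.channels))
        for k, ch in enumerate(self.channels):
            base = self.params.get(ch.rate_param)
            if protocol is not None:
                base = protocol.value(ch.rate_param, t, base)
            rates[k] = base
        return rates

    # -- state helpers ------------------------------------------------------
    def initial_state(self, **counts) -> np.ndarray:
        """Build a valid state from partial counts, filling free promoters.

        Unspecified bound species default to 0; ``O`` and ``OT`` (and ``PO``)
        are inferred from promoter conservation.
        """
        s = np.zeros(len(self.species), dtype=np.int64)
        for name, v in counts.items():
            if name not in self.index:
                raise KeyError(f"unknown species {name!r} for variant {self.variant}")
            s[self.index[name]] = int(v)
        own = sum(s[self.index[sp]] for sp in ("OC", "OCd", "OC2", "OH", "OHC")
                  if sp in self.index)
        if "O" not in counts:
            s[self.index["O"]] = 1 - own
        tgt = sum(s[self.index[sp]] for sp in ("OTC", "OTCd") if sp in self.index)
        if "OT" not in counts:
            s[self.index["OT"]] = self.params.NT - tgt
        if "PO" in self.index and "PO" not in counts:
            s[self.index["PO"]] = 1 - s[self.index["POC"]]
        if "H" in self.index and "H" not in counts and self.params.H0 is not None:
            s[self.index["H"]] = self.params.H0
        self.validate_state(s)
        return s

    def validate_state(self, state: np.ndarray) -> None:
        if np.any(state < 0):
            raise ValueError("negative species count")
        own = sum(state[self.index[sp]]
                  for sp in ("O", "OC", "OCd", "OC2", "OH", "OHC")
                  if sp in self.index)
        if own != 1:
            raise ValueError(f"che-1 promoter ledger sums to {own}, expected 1")
        tgt = sum(state[self.index[sp]] for sp in ("OT", "OTC", "OTCd")
                  if sp in self.index)
        if tgt != self.params.NT:
            raise ValueError(f"target promoter ledger sums to {tgt}, expected NT={self.params.NT}")
        if "PO" in self.index:
            if state[self.index["PO"]] + state[self.index["POC"]] != 1:
                raise ValueError("reporter promoter ledger must sum to 1")

    def value(self, state: np.ndarray, name: str) -> int:
        return int(state[self.index[name]])


def _expression_channels(fM_species: list[str]) -> list[Channel]:
    chs = [Channel(f"transcription_{sp}", "fM", (sp,), {"M": +1})
           for sp in fM_species]
    chs += [
        Channel("mrna_decay", "bM", ("M",), {"M": -1}),
        Channel("translation", "fC", ("M",), {"C": +1}),
        Channel("protein_decay", "bC", ("C",), {"C": -1}),
    ]
    return chs


def _reporter_channels() -> list[Channel]:
    return [
        Channel("rep_bind", "fO", ("PO", "C"), {"PO": -1, "POC": +1, "C": -1}),
        Channel("rep_unbind", "bT", ("POC",), {"POC": -1, "PO": +1, "C": +1}),
        Channel("rep_transcription", "fP", ("POC",), {"P": +1}),
        Channel("rep_mrna_decay", "bP", ("P",), {"P": -1}),
    ]


def build_network(variant: str, params: ParameterSet,
                  frap: bool = False) -> ReactionNetwork:
    """Assemble the reaction channel set for one model variant.

    Raises a configuration error naming the missing rate symbol if the
    variant requires a rate that is unset.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")
    reporter = params.fP is not None and params.bP is not None
    basal = params.fM0 is not None

    if variant == "noncoop":
        species = ["O", "OC", "OT", "OTC", "M", "C"]
        chs = [
            Channel("own_bind", "fO", ("O", "C"), {"O": -1, "OC": +1, "C": -1}),
            Channel("own_unbind", "bO", ("OC",), {"OC": -1, "O": +1, "C": +1}),
            Channel("tgt_bind", "fO", ("OT", "C"), {"OT": -1, "OTC": +1, "C": -1}),
            Channel("tgt_unbind", "bT", ("OTC",), {"OTC": -1, "OT": +1, "C": +1}),
        ]
        chs += _expression_channels(["OC"])
        if frap:
            species += ["OCd", "OTCd", "Cd"]
            chs += [
                Channel("own_bind_dark", "fO", ("O", "Cd"),
                        {"O": -1, "OCd": +1, "Cd": -1}),
                Channel("own_unbind_dark", "bO", ("OCd",),
                        {"OCd": -1, "O": +1, "Cd": +1}),
                Channel("tgt_bind_dark", "fO", ("OT", "Cd"),
                        {"OT": -1, "OTCd": +1, "Cd": -1}),
                Channel("tgt_unbind_dark", "bT", ("OTCd",),
                        {"OTCd": -1, "OT": +1, "Cd": +1}),
                # a dark-bound promoter still transcribes; translation makes
                # only visible protein; dark protein is only degraded
                Channel("transcription_OCd", "fM", ("OCd",), {"M": +1}),
                Channel("protein_decay_dark", "bC", ("Cd",), {"Cd": -1}),
            ]
    elif variant == "coop":
        params.require("b1", "b2")
        if frap:
            raise ValueError("FRAP mode is implemented for the noncoop variant only")
        species = ["O", "OC", "OC2", "OT", "OTC", "M", "C"]
        chs = [
            Channel("own_bind1", "fO", ("O", "C"), {"O": -1, "OC": +1, "C": -1}),
            Channel("own_unbind1", "b1", ("OC",), {"OC": -1, "O": +1, "C": +1}),
            Channel("own_bind2", "fO", ("OC", "C"), {"OC": -1, "OC2": +1, "C": -1}),
            Channel("own_unbind2", "b2", ("OC2",), {"OC2": -1, "OC": +1, "C": +1}),
            Channel("tgt_bind", "fO", ("OT", "C"), {"OT": -1, "OTC": +1, "C": -1}),
            Channel("tgt_unbind", "bT", ("OTC",), {"OTC": -1, "OT": +1, "C": +1}),
        ]
        chs += _expression_channels(["OC2"])
    else:  # HD-TF variants
        if frap:
            raise ValueError("FRAP mode is implemented for the noncoop variant only")
        params.require("fO_C", "fO_H")
        model1 = variant.startswith("hd1")
        controlled = variant.endswith("b")
        species = ["O", "OC", "OH", "OT", "OTC", "M", "C", "H"]
        if model1:
            species.insert(3, "OHC")
        chs = [
            Channel("own_bind", "fO_C", ("O", "C"), {"O": -1, "OC": +1, "C": -1}),
            Channel("own_unbind", "bO", ("OC",), {"OC": -1, "O": +1, "C": +1}),
            Channel("h_bind", "fO_H", ("O", "H"), {"O": -1, "OH": +1, "H": -1}),
            Channel("h_unbind", "bO", ("OH",), {"OH": -1, "O": +1, "H": +1}),
            Channel("tgt_bind", "fO", ("OT", "C"), {"OT": -1, "OTC": +1, "C": -1}),
            Channel("tgt_unbind", "bT", ("OTC",), {"OTC": -1, "OT": +1, "C": +1}),
        ]
        fM_species = ["OC"]
        if model1:
            params.require("bO_s")
            chs += [
                Channel("joint_bind_c", "fO_C", ("OH", "C"),
                        {"OH": -1, "OHC": +1, "C": -1}),
                Channel("joint_unbind_c", "bO_s", ("OHC",),
                        {"OHC": -1, "OH": +1, "C": +1}),
                Channel("joint_bind_h", "fO_H", ("OC", "H"),
                        {"OC": -1, "OHC": +1, "H": -1}),
                Channel("joint_unbind_h", "bO_s", ("OHC",),
                        {"OHC": -1, "OC": +1, "H": +1}),
            ]
            fM_species.append("OHC")
        else:
            params.require("fM_H")
            chs.append(Channel("transcription_OH", "fM_H", ("OH",), {"M": +1}))
        chs += _expression_channels(fM_species)
        if controlled:
            params.require("fH", "bH")
            chs += [
                Channel("h_production", "fH", ("C",), {"H": +1}),
                Channel("h_decay", "bH", ("H",), {"H": -1}),
            ]
        else:
            if params.H0 is None:
                raise ValueError("missing required rate(s): H0 (constitutive HD-TF copy number)")

    if basal:
        chs.append(Channel("basal_transcription", "fM0", (), {"M": +1}))
    if reporter:
        species += ["PO", "POC", "P"]
        chs += _reporter_channels()

    clamped = ("H",) if variant in ("hd1a", "hd2a") else ()
    return ReactionNetwork(variant, params, species, chs, clamped=clamped)


def propensity_vector(network: ReactionNetwork, state: np.ndarray,
                      t: float = 0.0,
                      protocol: Optional[Protocol] = None) -> np.ndarray:
    """Mass-action propensities of every channel at ``state`` and time ``t``.

    A total of zero is a valid return: the state is absorbing.
    """
    rates = network.rate_vector(t, protocol)
    a = rates.copy()
    for k in range(len(network.channels)):
        for j in range(2):
            idx = network.reactant_idx[k, j]
            if idx >= 0:
                a[k] *= state[idx]
    return a
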