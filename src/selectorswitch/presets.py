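"""Published parameter sets for the CHE-1 switch models.

These are the printed simulation parameter tables: the unstable reference
switch (ON-state lifetime ~10 days), the highly stable switch (slow CHE-1
unbinding from its own promoter), the two depletion-panel sets (with a
reporter target gene), and the homeodomain co-factor (HD-TF) model sets.
All rates in s^-1.
"""

from __future__ import annotations

from .parameters import ParameterSet, ObservableSet

__all__ = [
    "UNSTABLE_4B", "STABLE_4B", "STABLE_DEPLETION", "UNSTABLE_DEPLETION",
    "hd_params", "OBSERVABLES", "scaled_observables",
]

#: Measured observables underlying every derivation (ASER neuron).
OBSERVABLES = ObservableSet()

#: Unstable reference switch: equal, fast dissociation everywhere.
UNSTABLE_4B = ParameterSet(
    fO=0.03, bO=100.0, bT=100.0,
    fM=0.0302, bM=0.00083, fC=0.0274, bC=0.00024, NT=500,
)

#: Highly stable switch: CHE-1 unbinds its own promoter 1000x slower.
STABLE_4B = UNSTABLE_4B.replace(bO=0.1, fM=0.0059, fC=0.0261, bC=0.00023)

#: Stable switch for the depletion panel (depleted to ~100 CHE-1), with a
#: reporter target gene whose promoter binds like any target.
STABLE_DEPLETION = UNSTABLE_4B.replace(
    bO=0.1, fM=0.0059, bC=0.0019, fC=0.024, fP=0.09, bP=0.0008,
)

#: Unstable switch for the depletion panel.
UNSTABLE_DEPLETION = UNSTABLE_4B.replace(
    bO=10.0, bT=10.0, bC=0.00076, fC=0.026, fP=0.016, bP=0.0004,
)


def hd_params(model: int = 1, constitutive: bool = True,
              scale: float = 1.0) -> ParameterSet:
    """Parameters for the HD-TF co-factor models.

    Model 1: HD-TF raises CHE-1 affinity for the *che-1* promoter (slow
    dissociation ``bO_s`` from the joint complex).  Model 2: HD-TF induces
    *che-1* independently of CHE-1 (rate ``fM_H`` from the HD-bound promoter).
    ``constitutive=True`` holds free HD-TF clamped at ``H0`` (models 1A/2A);
    otherwise HD-TF is produced from CHE-1 at ``fH`` and decays at ``bH``
    (models 1B/2B).  ``scale`` < 1 yields a copy-number-scaled variant:
    association rates are divided by the volume factor (so occupancies are
    preserved) and protein decay is sped up to shrink the protein pool.
    """
    if model not in (1, 2):
        raise ValueError("model must be 1 or 2")
    fO = 0.03 / scale
    p = ParameterSet(
        fO=fO, bO=100.0, bT=100.0,
        fM=0.0085, bM=0.00083, fC=0.0198, bC=0.00032 / scale,
        NT=max(1, int(round(500 * scale))),
        fO_C=fO, fO_H=fO, fM0=0.005,
        fH=0.0001, bH=0.000015,
    )
    if model == 1:
        p = p.replace(bO_s=0.1)
    else:
        p = p.replace(fM=0.01, fM_H=0.015)
    # constitutive free HD-TF level matching the production/decay balance of
    # the CHE-1-controlled variant at the ON-state protein count
    H0 = int(round(p.fH * 900 * scale / p.bH))
    if constitutive:
        p = p.replace(H0=H0, fH=None, bH=None)
    return p


def scaled_observables(factor: float = 0.1) -> ObservableSet:
    """Copy-number/volume scaled observables for fast test fixtures."""
    return OBSERVABLES.scaled(factor)
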