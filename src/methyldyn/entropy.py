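"""Conformational entropy from order parameters via the cone model.

A methyl symmetry axis diffusing freely in a cone has a closed-form
relation between its order parameter and the configurational entropy of
the axis orientation:

    S/k_B = ln[ π·(3 − √(1 + 8·O_axis)) ],   O_axis = √O²_axis

At O² = 0 this gives ln(2π) (the full sphere of orientations); it
decreases strictly with O² and diverges to −∞ as O² → 1 (a perfectly
rigid axis has vanishing orientational freedom). This mapping is an
interpretation layer — order parameters report motional amplitude, and
the cone model is one defensible calibration of amplitude into entropy
among several; the function is kept separate so alternative calibrations
can be swapped in.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import GAS_CONSTANT
from .exceptions import InsufficientDataError, MethylDynError, PairingError
from .probes import OrderParameterSet

__all__ = ["EntropyEstimate", "cone_entropy", "ensemble_entropy", "delta_entropy"]


def cone_entropy(o2_axis: float) -> float:
    """Entropy (in units of k_B) of a methyl axis with order parameter O².

    Raises for O² ≥ 1 (the entropy diverges to −∞) and for negative O²
    (outside the model's domain).
    """
    o2 = float(o2_axis)
    if o2 < 0.0:
        raise MethylDynError(f"O2_axis must be >= 0, got {o2}")
    if o2 >= 1.0:
        raise MethylDynError(
            f"O2_axis = {o2} >= 1: cone entropy diverges at the rigid limit"
        )
    o_axis = math.sqrt(o2)
    return math.log(math.pi * (3.0 - math.sqrt(1.0 + 8.0 * o_axis)))


def cone_entropy_J_per_mol_K(o2_axis: float) -> float:
    """Same as :func:`cone_entropy`, in J mol⁻¹ K⁻¹."""
    return cone_entropy(o2_axis) * GAS_CONSTANT


@dataclass
class EntropyEstimate:
    """Per-probe and total conformational entropy of a set."""

    per_probe: dict  #: probe -> entropy in k_B units
    total_kB: float
    total_J_per_mol_K: float
    mean_kB: float
    n_probes: int
    n_skipped: int


def ensemble_entropy(opset: OrderParameterSet) -> EntropyEstimate:
    """Cone entropy per probe, plus the total and mean over the set.

    Entries with O² ≥ 1 or O² < 0 are skipped with a warning rather than
    clipped: the divergence near 1 makes clipping unsafe.
    """
    if len(opset) == 0:
        raise InsufficientDataError("cannot compute entropy of an empty set")
    per_probe = {}
    skipped = 0
    for e in opset.entries:
        if not (0.0 <= e.O2_axis < 1.0):
            skipped += 1
            continue
        per_probe[e.probe] = cone_entropy(e.O2_axis)
    if skipped:
        warnings.warn(
            f"{skipped} entries with O2 outside [0, 1) skipped in entropy sum",
            stacklevel=2,
        )
    if not per_probe:
        raise MethylDynError("all entries fell outside the cone-entropy domain")
    vals = np.array(list(per_probe.values()))
    total = float(vals.sum())
    return EntropyEstimate(
        per_probe=per_probe,
        total_kB=total,
        total_J_per_mol_K=total * GAS_CONSTANT,
        mean_kB=float(vals.mean()),
        n_probes=len(per_probe),
        n_skipped=skipped,
    )


def delta_entropy(set_a: OrderParameterSet, set_b: OrderParameterSet):
    """Per-probe and total entropy change S(b) − S(a) over shared probes.

    Probes outside the entropy domain in either set are dropped from the
    pairing. Returns ``(per_probe_delta: dict, total_kB: float)``.
    """
    pairs = set_a.pair_with(set_b)
    per_probe = {}
    for ea, eb in pairs:
        if not (0.0 <= ea.O2_axis < 1.0 and 0.0 <= eb.O2_axis < 1.0):
            continue
        per_probe[ea.probe] = cone_entropy(eb.O2_axis) - cone_entropy(ea.O2_axis)
    if not per_probe:
        raise PairingError("no paired probes inside the entropy domain")
    return per_probe, float(sum(per_probe.values()))
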