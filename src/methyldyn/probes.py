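"""Domain types: methyl probes, relaxation records, build-up series,
order-parameter sets, and the tumbling-time estimate.

A *methyl probe* is one ¹³CH₃ group of an Ile/Leu/Val/Met side chain,
identified by chain, author residue number, and methyl label (d1, g2, ...).
Order parameters refer to the methyl three-fold symmetry axis: 1 means the
axis is rigid in the molecular frame, 0 means isotropic disorder on the
sub-nanosecond timescale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .exceptions import MethylDynError, PairingError

#: methyl labels allowed for each residue type
ALLOWED_METHYLS = {
    "ILE": frozenset({"d1", "g2"}),
    "LEU": frozenset({"d1", "d2"}),
    "VAL": frozenset({"g1", "g2"}),
    "MET": frozenset({"e"}),
}

#: environments an order-parameter set may be tagged with
ENVIRONMENTS = frozenset({"micelle", "bicelle", "md"})


@dataclass(frozen=True, order=True)
class MethylProbe:
    """Identity of one methyl group (author numbering)."""

    residue_number: int
    residue_type: str
    methyl_id: str
    chain_id: str = "A"

    def __post_init__(self):
        if self.residue_type not in ALLOWED_METHYLS:
            raise MethylDynError(
                f"residue_type {self.residue_type!r} is not one of "
                f"{sorted(ALLOWED_METHYLS)}"
            )
        if self.methyl_id not in ALLOWED_METHYLS[self.residue_type]:
            raise MethylDynError(
                f"methyl_id {self.methyl_id!r} is not valid for "
                f"{self.residue_type} (allowed: "
                f"{sorted(ALLOWED_METHYLS[self.residue_type])})"
            )

    @property
    def key(self) -> tuple:
        """Identity used for pairing across datasets."""
        return (self.chain_id, self.residue_number, self.methyl_id)

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_type}{self.residue_number}-{self.methyl_id}"


@dataclass(frozen=True)
class RelaxationRecord:
    """Per-residue backbone ¹⁵N R1/R2 at a stated field and temperature."""

    residue_number: int
    R1: float
    R1_err: float
    R2: float
    R2_err: float
    field_MHz: float
    temperature_K: float

    def __post_init__(self):
        for name in ("R1", "R2", "field_MHz", "temperature_K"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise MethylDynError(f"{name} must be finite and positive, got {v!r}")
        for name in ("R1_err", "R2_err"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise MethylDynError(f"{name} must be finite and >= 0, got {v!r}")
        # R2 < R1 is possible for fast tumbling; only flag, never reject
        if self.R2 < self.R1:
            warnings.warn(
                f"residue {self.residue_number}: R2 < R1 — inconsistent with "
                "slow tumbling (tau_m > ~1 ns)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class BuildupSeries:
    """Cross-correlated relaxation build-up for one methyl probe.

    ``ratios`` are the dimensionless intensity ratios of the
    cross-correlation-filtered experiment at each relaxation delay.
    """

    probe: MethylProbe
    delays: tuple
    ratios: tuple
    ratio_errs: tuple
    temperature_K: float

    def __post_init__(self):
        object.__setattr__(self, "delays", tuple(float(t) for t in self.delays))
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        object.__setattr__(self, "ratio_errs", tuple(float(e) for e in self.ratio_errs))
        n = len(self.delays)
        if n < 2:
            raise MethylDynError("build-up series needs at least 2 delay points")
        if len(self.ratios) != n or len(self.ratio_errs) != n:
            raise MethylDynError("delays, ratios and ratio_errs must have equal length")
        if any(b <= a for a, b in zip(self.delays, self.delays[1:])):
            raise MethylDynError("delays must be strictly increasing")
        if any(not (-1.0 < r < 1.0) for r in self.ratios):
            raise MethylDynError("intensity ratios must lie in (-1, 1)")
        if any(e < 0 for e in self.ratio_errs):
            raise MethylDynError("ratio errors must be >= 0")

    def __len__(self) -> int:
        return len(self.delays)


@dataclass(frozen=True)
class OrderParameterEntry:
    """One probe's symmetry-axis order parameter in one environment."""

    probe: MethylProbe
    O2_axis: float
    error: float
    temperature_K: float
    environment: str

    def __post_init__(self):
        if not math.isfinite(self.O2_axis):
            raise MethylDynError(f"O2_axis must be finite, got {self.O2_axis!r}")
        if not math.isfinite(self.error) or self.error < 0:
            raise MethylDynError(f"error must be finite and >= 0, got {self.error!r}")
        if self.temperature_K <= 0:
            raise MethylDynError("temperature_K must be positive")
        if self.environment not in ENVIRONMENTS:
            raise MethylDynError(
                f"environment {self.environment!r} must be one of {sorted(ENVIRONMENTS)}"
            )


class OrderParameterSet:
    """A collection of per-methyl O²_axis values with shared provenance.

    Values are stored unclipped: conversion from cross-correlated relaxation
    can legitimately return values slightly above 1 or below 0 within noise.

    Parameters
    ----------
    entries : iterable of OrderParameterEntry
    tau_m_ns : float
        The global tumbling time used in the η → O²_axis conversion
        (environment specific; NaN when not applicable, e.g. MD sets).
    """

    def __init__(self, entries: Iterable[OrderParameterEntry], tau_m_ns: float = float("nan")):
        self.entries: list[OrderParameterEntry] = list(entries)
        self.tau_m_ns = float(tau_m_ns)
        seen = set()
        for e in self.entries:
            k = (e.probe.key, e.environment, round(e.temperature_K, 6))
            if k in seen:
                raise MethylDynError(
                    f"duplicate entry for probe {e.probe} in environment "
                    f"{e.environment} at {e.temperature_K} K"
                )
            seen.add(k)

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[OrderParameterEntry]:
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, OrderParameterSet):
            return NotImplemented
        tau_eq = (self.tau_m_ns == other.tau_m_ns) or (
            math.isnan(self.tau_m_ns) and math.isnan(other.tau_m_ns)
        )
        return tau_eq and self.entries == other.entries

    # -- views --------------------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        return np.array([e.O2_axis for e in self.entries], dtype=float)

    @property
    def errors(self) -> np.ndarray:
        return np.array([e.error for e in self.entries], dtype=float)

    @property
    def probes(self) -> list[MethylProbe]:
        return [e.probe for e in self.entries]

    def temperature(self) -> float:
        """The single temperature of the set; error if mixed."""
        temps = {e.temperature_K for e in self.entries}
        if len(temps) != 1:
            raise MethylDynError(f"set contains multiple temperatures: {sorted(temps)}")
        return temps.pop()

    def by_key(self) -> dict:
        return {e.probe.key: e for e in self.entries}

    def pair_with(self, other: "OrderParameterSet") -> list[tuple]:
        """Match entries by exact (chain, residue_number, methyl_id) identity."""
        mine = self.by_key()
        pairs = [
            (mine[e.probe.key], e) for e in other.entries if e.probe.key in mine
        ]
        if not pairs:
            raise PairingError("no probes shared between the two sets")
        return pairs


@dataclass(frozen=True)
class TumblingEstimate:
    """Global rotational correlation time τ_m from backbone R2/R1 ratios."""

    tau_m_ns: float
    tau_m_err_ns: float
    n_residues_used: int
    method: str = "R2/R1"

    def __post_init__(self):
        if self.tau_m_ns <= 0:
            raise MethylDynError("tau_m_ns must be positive")
        if not (0 <= self.tau_m_err_ns < self.tau_m_ns):
            raise MethylDynError("tau_m_err_ns must satisfy 0 <= err < tau_m")
        if self.n_residues_used < 1:
            raise MethylDynError("n_residues_used must be >= 1")
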