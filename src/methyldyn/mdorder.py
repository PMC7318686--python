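"""Order parameters from bond-vector time series (MD comparison).

Two estimators for O² of a unit bond vector e(t) in the molecular frame
(overall tumbling assumed removed upstream):

* the ensemble-average ("isotropic") formula
      O² = (3/2)·Σ_{i≤j} w_ij·⟨e_i e_j⟩² − 1/2,   w_ii = 1, w_{i<j} = 2,
* the long-time plateau of the P₂ autocorrelation function
      C(t) = ⟨P₂(e(τ)·e(τ+t))⟩_τ,   P₂(x) = (3x²−1)/2.

For a stationary trajectory the two agree. Bond-vector conventions
(e.g. Arg Nϵ–Hϵ, Thr Cβ–Cγ2, Tyr/Trp Cδ1–Hδ1, methyl C–C symmetry axis)
are carried as explicit labels so that any novel choice is auditable.
The methyl-axis O² from MD is directly comparable to the experimental
O²_axis — no ³-site-jump factor applies because the axis vector itself
is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import MethylDynError

__all__ = [
    "VectorTrajectory",
    "order_parameter_iso",
    "p2_autocorrelation",
    "plateau_estimate",
    "read_vector_trajectory",
    "write_vector_trajectory",
]


@dataclass
class VectorTrajectory:
    """Time-ordered unit bond vectors for one probe."""

    vectors: np.ndarray  #: (n_frames, 3), unit norm within 1e-6
    dt_ps: float
    probe: str = ""
    vector_convention: str = ""

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MethylDynError("vectors must be an (n, 3) array")
        if len(v) < 2:
            raise MethylDynError("trajectory needs at least 2 frames")
        norms = np.linalg.norm(v, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise MethylDynError(
                f"vectors must be unit norm within 1e-6 "
                f"(max deviation {np.abs(norms - 1.0).max():.2e})"
            )
        self.vectors = v

    def __len__(self) -> int:
        return len(self.vectors)


def _product_series(v: np.ndarray):
    """The 6 unique e_i·e_j product time series and their weights."""
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    series = np.stack([x * x, y * y, z * z, x * y, x * z, y * z])
    weights = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
    return series, weights


def order_parameter_iso(traj: VectorTrajectory) -> float:
    """Ensemble-average order parameter of the trajectory.

    Equals 1 for a constant vector and 0 in expectation for isotropic
    sampling; finite-sample values can dip slightly below 0 (bounded by
    −1/2).
    """
    series, weights = _product_series(traj.vectors)
    means = series.mean(axis=1)
    return float(1.5 * np.dot(weights, means**2) - 0.5)


def p2_autocorrelation(traj: VectorTrajectory, max_lag: int) -> np.ndarray:
    """C(t) = ⟨P₂(e(τ)·e(τ+t))⟩_τ for t = 0 … max_lag, FFT-accelerated.

    Uses the identity (e·e′)² = Σ w_c·s_c(τ)·s_c(τ+t) over the six
    quadratic product series, so the lag average reduces to six linear
    autocorrelations. C(0) = 1 exactly.
    """
    n = len(traj)
    if max_lag >= n // 2:
        raise MethylDynError(f"max_lag={max_lag} must be < n_frames/2 = {n // 2}")
    series, weights = _product_series(traj.vectors)
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    acf = np.zeros(max_lag + 1)
    counts = n - np.arange(max_lag + 1)
    for s, w in zip(series, weights):
        f = np.fft.rfft(s, nfft)
        corr = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
        acf += w * corr / counts
    return 1.5 * acf - 0.5


def plateau_estimate(C: np.ndarray, window_fraction: float = 0.25) -> float:
    """Mean of C(t) over the final ``window_fraction`` of computed lags."""
    C = np.asarray(C, dtype=float)
    if not (0.0 < window_fraction <= 1.0):
        raise MethylDynError("window_fraction must be in (0, 1]")
    start = int(round(len(C) * (1.0 - window_fraction)))
    window = C[start:]
    if window.size == 0:
        raise MethylDynError("plateau window is empty")
    return float(window.mean())


# ---------------------------------------------------------------------------
# trajectory I/O: plain TSV of t, x, y, z


def read_vector_trajectory(
    path, probe: str = "", vector_convention: str = ""
) -> VectorTrajectory:
    """Read a (t, x, y, z) TSV; vectors are normalized on read.

    A warning is emitted if any norm deviates from 1 by more than 1e-3
    (suggesting the file does not actually contain unit bond vectors).
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] != 4:
        raise MethylDynError(f"{path}: expected 4 columns (t, x, y, z)")
    data = df.to_numpy(dtype=float)
    t, v = data[:, 0], data[:, 1:]
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms <= 0):
        raise MethylDynError(f"{path}: zero-length vector encountered")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn(
            f"{path}: vector norms deviate from 1 by up to "
            f"{np.abs(norms - 1.0).max():.2e}; normalizing",
            stacklevel=2,
        )
    v = v / norms[:, None]
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return VectorTrajectory(vectors=v, dt_ps=dt, probe=probe, vector_convention=vector_convention)


def write_vector_trajectory(traj: VectorTrajectory, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# probe={traj.probe} convention={traj.vector_convention}\n")
        fh.write("t_ps\tx\ty\tz\n")
        for i, v in enumerate(traj.vectors):
            fh.write(
                f"{float(i * traj.dt_ps)!r}\t{float(v[0])!r}\t{float(v[1])!r}\t{float(v[2])!r}\n"
            )
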