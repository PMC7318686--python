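"""Synthetic datasets with known ground truth.

The study data these generators emulate are per-methyl order-parameter
tables for two membrane proteins (an α-helical rhodopsin-like protein and
a β-barrel outer-membrane protein) in micelles and bicelles: 50–150 ILVM
methyl probes, O²_axis drawn from a three-band motional-class mixture
(J′/J/α, centers near 0.21/0.36–0.42/0.55–0.66), per-probe errors of
0.02–0.04, and micelle/bicelle replicates correlated at R² ≈ 0.8–0.96.
The backbone generator emulates the ¹⁵N R1/R2 tables used for tumbling
time estimation. Every generator is a deterministic function of its
parameters and seed.

Presets are data, not code: dictionaries naming the class structure,
tumbling times, and noise levels of the two study-like conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .exceptions import MethylDynError
from .mdorder import VectorTrajectory
from .modelfree import ModelFreeParams, buildup_ratio, o2_axis_to_eta, predict_n15_rates
from .probes import (
    BuildupSeries,
    MethylProbe,
    OrderParameterEntry,
    OrderParameterSet,
    RelaxationRecord,
)
from .spatial import SpatialDataset, slab_pseudo_cloud

__all__ = [
    "PSRII_LIKE",
    "OMPW_LIKE",
    "PRESETS",
    "SyntheticMethylDataset",
    "make_backbone_dataset",
    "make_methyl_dataset",
    "make_cone_trajectory",
    "make_sphere_trajectory",
    "make_spatial_dataset",
    "cone_order_parameter",
    "write_ground_truth_json",
]

#: α-helical membrane-protein-like condition (micelle data at 50 °C)
PSRII_LIKE = {
    "name": "psrii_like",
    "class_centers": (0.21, 0.36, 0.55),
    "class_weights": (1 / 3, 1 / 3, 1 / 3),
    "class_sigma": 0.05,
    "n_probes": 90,
    "tau_m_ns": {"micelle": 21.9, "bicelle": 28.9},
    "temperature_K": 323.15,
    "env_target_r2": 0.81,
    "jprime_mli_fraction": 0.75,
    "other_mli_fraction": 0.50,
    "sigma_ratio": 0.01,
}

#: β-barrel membrane-protein-like condition (micelle data at 40 °C)
OMPW_LIKE = {
    "name": "ompw_like",
    "class_centers": (0.21, 0.42, 0.66),
    "class_weights": (1 / 3, 1 / 3, 1 / 3),
    "class_sigma": 0.05,
    "n_probes": 55,
    "tau_m_ns": {"micelle": 24.0, "bicelle": 29.9},
    "temperature_K": 313.15,
    "env_target_r2": 0.96,
    "jprime_mli_fraction": 0.75,
    "other_mli_fraction": 0.50,
    "sigma_ratio": 0.01,
}

PRESETS = {"psrii_like": PSRII_LIKE, "ompw_like": OMPW_LIKE}

#: delay schedule for synthetic build-up series, s
DEFAULT_DELAYS = tuple(t * 1e-3 for t in (4, 8, 12, 16, 20, 24))

_MLI = ("MET", "LEU", "ILE")
_DEFAULT_METHYL = {"ILE": "d1", "LEU": "d1", "VAL": "g1", "MET": "e"}


# ---------------------------------------------------------------------------
# backbone relaxation tables


def make_backbone_dataset(
    tau_m_ns: float = 21.9,
    n_residues: int = 20,
    field_MHz: float = 600.0,
    temperature_K: float = 323.15,
    noise_frac: float = 0.02,
    rex_fraction: float = 0.0,
    rex_value: float = 8.0,
    seed: int = 0,
):
    """Per-residue ¹⁵N R1/R2 records from the forward model.

    Per-residue S² is drawn U(0.8, 0.9) (a rigid scaffold); multiplicative
    Gaussian noise of fractional size ``noise_frac`` is applied to both
    rates, and a fraction ``rex_fraction`` of residues receives a planted
    exchange contribution ``rex_value`` (s⁻¹) to R2. Returns
    ``(records, truth)`` where truth records the planted τ_m, S² values
    and outlier indices.
    """
    rng = np.random.default_rng(seed)
    s2 = rng.uniform(0.8, 0.9, size=n_residues)
    n_out = int(round(rex_fraction * n_residues))
    outliers = rng.choice(n_residues, size=n_out, replace=False) if n_out else np.array([], int)
    records = []
    for i in range(n_residues):
        rex = rex_value if i in outliers else 0.0
        params = ModelFreeParams(S2=float(s2[i]), tau_m=tau_m_ns * 1e-9, R_ex=rex)
        r1, r2 = predict_n15_rates(params, field_MHz)
        if noise_frac > 0:
            r1_obs = r1 * (1.0 + noise_frac * rng.standard_normal())
            r2_obs = r2 * (1.0 + noise_frac * rng.standard_normal())
            r1_err, r2_err = noise_frac * r1, noise_frac * r2
        else:
            r1_obs, r2_obs, r1_err, r2_err = r1, r2, 0.0, 0.0
        records.append(
            RelaxationRecord(
                residue_number=i + 1,
                R1=float(r1_obs),
                R1_err=float(r1_err),
                R2=float(r2_obs),
                R2_err=float(r2_err),
                field_MHz=field_MHz,
                temperature_K=temperature_K,
            )
        )
    truth = {
        "tau_m_ns": tau_m_ns,
        "S2": s2.tolist(),
        "rex_outliers": sorted(int(i) for i in outliers),
        "rex_value": rex_value,
        "noise_frac": noise_frac,
        "field_MHz": field_MHz,
        "seed": seed,
    }
    return records, truth


# ---------------------------------------------------------------------------
# methyl build-up datasets


@dataclass
class SyntheticMethylDataset:
    """Build-up series per environment, with the generating ground truth."""

    buildups: dict  #: environment -> list[BuildupSeries]
    truth_sets: dict  #: environment -> OrderParameterSet (true O², error 0)
    truth: dict  #: generating parameters, assignments and seed


def _draw_probes(rng, n_probes, weights, jprime_mli, other_mli):
    """Class assignment and residue-type per probe."""
    comps = rng.choice(len(weights), size=n_probes, p=np.asarray(weights) / np.sum(weights))
    types = []
    for c in comps:
        frac = jprime_mli if c == 0 else other_mli
        if rng.random() < frac:
            types.append(_MLI[rng.integers(len(_MLI))])
        else:
            types.append("VAL")
    probes = [
        MethylProbe(
            residue_number=i + 1,
            residue_type=t,
            methyl_id=_DEFAULT_METHYL[t],
            chain_id="A",
        )
        for i, t in enumerate(types)
    ]
    return comps, probes


def make_methyl_dataset(
    preset: dict = PSRII_LIKE,
    n_probes: int | None = None,
    sigma_ratio: float | None = None,
    delays=DEFAULT_DELAYS,
    environments=("micelle", "bicelle"),
    seed: int = 0,
) -> SyntheticMethylDataset:
    """Generate per-methyl build-up series with known true O²_axis.

    True micelle O² values are drawn from the preset's class mixture
    (clipped to [0.02, 0.95] to stay inside the physical conversion
    domain); the bicelle replicate adds a perturbation whose variance is
    calibrated so the expected micelle/bicelle R² matches the preset
    target. Each probe's η follows from the inverse of the η → O²
    conversion at the environment's τ_m, and intensity ratios follow the
    forward build-up model with Gaussian noise ``sigma_ratio``.
    """
    rng = np.random.default_rng(seed)
    n = n_probes if n_probes is not None else preset["n_probes"]
    sr = sigma_ratio if sigma_ratio is not None else preset["sigma_ratio"]
    centers = np.asarray(preset["class_centers"])
    weights = np.asarray(preset["class_weights"])
    sigma = preset["class_sigma"]
    comps, probes = _draw_probes(
        rng, n, weights, preset["jprime_mli_fraction"], preset["other_mli_fraction"]
    )
    o2_mic = np.clip(centers[comps] + sigma * rng.standard_normal(n), 0.02, 0.95)

    o2_by_env = {"micelle": o2_mic}
    if "bicelle" in environments:
        target_r2 = preset["env_target_r2"]
        if target_r2 >= 1.0:
            sigma_env = 0.0
        else:
            sigma_env = float(np.sqrt(o2_mic.var() * (1.0 / target_r2 - 1.0)))
        o2_by_env["bicelle"] = np.clip(
            o2_mic + sigma_env * rng.standard_normal(n), 0.02, 0.95
        )

    delays = np.asarray(delays, dtype=float)
    buildups: dict = {}
    truth_sets: dict = {}
    for env in environments:
        tau_ns = preset["tau_m_ns"][env]
        o2_true = o2_by_env[env]
        series_list = []
        entries = []
        for i, probe in enumerate(probes):
            eta = o2_axis_to_eta(float(o2_true[i]), tau_ns * 1e-9)
            clean = buildup_ratio(delays, eta)
            noisy = clean + sr * rng.standard_normal(len(delays)) if sr > 0 else clean
            noisy = np.clip(noisy, -0.999, 0.999)
            series_list.append(
                BuildupSeries(
                    probe=probe,
                    delays=tuple(delays),
                    ratios=tuple(noisy),
                    ratio_errs=tuple(np.full(len(delays), sr)),
                    temperature_K=preset["temperature_K"],
                )
            )
            entries.append(
                OrderParameterEntry(
                    probe=probe,
                    O2_axis=float(o2_true[i]),
                    error=0.0,
                    temperature_K=preset["temperature_K"],
                    environment=env,
                )
            )
        buildups[env] = series_list
        truth_sets[env] = OrderParameterSet(entries, tau_m_ns=tau_ns)

    truth = {
        "preset": preset["name"],
        "n_probes": n,
        "class_centers": centers.tolist(),
        "class_weights": weights.tolist(),
        "class_sigma": sigma,
        "class_assignments": comps.tolist(),
        "sigma_ratio": sr,
        "tau_m_ns": dict(preset["tau_m_ns"]),
        "true_O2": {env: o2_by_env[env].tolist() for env in environments if env in o2_by_env},
        "seed": seed,
    }
    return SyntheticMethylDataset(buildups=buildups, truth_sets=truth_sets, truth=truth)


# ---------------------------------------------------------------------------
# bond-vector trajectories


def cone_order_parameter(theta0_deg: float) -> float:
    """Closed-form O² for free diffusion in a cone of semi-angle θ₀:
    O² = [cos θ₀ (1 + cos θ₀)/2]²."""
    c = np.cos(np.radians(theta0_deg))
    return float((c * (1.0 + c) / 2.0) ** 2)


def make_cone_trajectory(
    theta0_deg: float, n_frames: int, dt_ps: float = 1.0, seed: int = 0
) -> VectorTrajectory:
    """Reflecting random walk inside a cone about +z.

    The walk acts on (u = cos θ, φ): u performs a Gaussian walk reflected
    into [cos θ₀, 1] (triangle-wave folding of a free walk), φ a periodic
    Gaussian walk — a process whose stationary density is uniform in
    (u, φ), i.e. uniform on the spherical cap, the assumption behind the
    closed-form cone order parameter. Step sizes are set so the
    orientational decorrelation time is of order 50 frames.
    """
    if not (0.0 < theta0_deg < 90.0):
        raise MethylDynError("theta0 must lie in (0, 90) degrees")
    rng = np.random.default_rng(seed)
    u_min = float(np.cos(np.radians(theta0_deg)))
    width = 1.0 - u_min
    # reflected-Brownian relaxation time ~ width^2 / (pi^2 D), D = step^2/2
    step_u = width * np.sqrt(2.0 / 50.0) / np.pi
    step_phi = np.sqrt(2.0 / 50.0) * np.pi / 2.0

    u_raw = rng.uniform(u_min, 1.0) + np.concatenate(
        [[0.0], np.cumsum(step_u * rng.standard_normal(n_frames - 1))]
    )
    # fold into [u_min, 1] by reflection (period 2*width triangle wave)
    y = np.mod(u_raw - u_min, 2.0 * width)
    u = u_min + np.where(y <= width, y, 2.0 * width - y)

    phi = rng.uniform(0.0, 2.0 * np.pi) + np.concatenate(
        [[0.0], np.cumsum(step_phi * rng.standard_normal(n_frames - 1))]
    )
    s = np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    vectors = np.column_stack([s * np.cos(phi), s * np.sin(phi), u])
    return VectorTrajectory(
        vectors=vectors,
        dt_ps=dt_ps,
        probe="cone",
        vector_convention=f"cone theta0={theta0_deg} deg",
    )


def make_sphere_trajectory(n_frames: int, dt_ps: float = 1.0, seed: int = 0) -> VectorTrajectory:
    """Independent uniform directions on the full sphere (isotropic limit)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_frames, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return VectorTrajectory(vectors=v, dt_ps=dt_ps, probe="sphere", vector_convention="isotropic")


# ---------------------------------------------------------------------------
# spatial datasets


def make_spatial_dataset(
    clustered: bool, n: int = 80, k_classes: int = 3, seed: int = 0
) -> SpatialDataset:
    """Gaussian probe cloud in a 40 Å box with class labels.

    Labels are either random (null condition) or assigned by spatial
    octant (clustered condition). A pseudo-lipid cloud sits on the two
    z = ±20 Å slab surfaces.
    """
    if n < 10:
        raise MethylDynError("spatial dataset needs n >= 10")
    rng = np.random.default_rng(seed)
    coords = np.clip(10.0 * rng.standard_normal((n, 3)), -20.0, 20.0)
    if clustered:
        octant = (
            (coords[:, 0] > 0).astype(int)
            + 2 * (coords[:, 1] > 0).astype(int)
            + 4 * (coords[:, 2] > 0).astype(int)
        )
        labels = octant % k_classes
    else:
        labels = rng.integers(0, k_classes, size=n)
    # O2 values loosely tied to class (low class = most dynamic)
    base = np.linspace(0.21, 0.55, k_classes)
    o2 = np.clip(base[labels] + 0.05 * rng.standard_normal(n), 0.02, 0.95)
    cloud = slab_pseudo_cloud(coords, z_min=-20.0, z_max=20.0, spacing=5.0)
    return SpatialDataset(
        probes=list(range(n)),
        coords=coords,
        o2_values=o2,
        class_labels=labels,
        cloud=cloud,
    )


# ---------------------------------------------------------------------------


def write_ground_truth_json(truth: dict, path) -> None:
    """Emit the ground-truth sidecar alongside generated tables."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
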