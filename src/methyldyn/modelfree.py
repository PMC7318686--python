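"""Model-free relaxation analysis.

This module implements the Lipari–Szabo ("model-free") machinery used to
turn NMR relaxation observables into side-chain order parameters:

* the two-term model-free spectral density J(ω),
* the standard dipolar + CSA forward model for backbone ¹⁵N R1/R2,
* estimation of the global tumbling time τ_m from R2/R1 ratios,
* the R1·R2 product screen for µs–ms exchange broadening,
* extraction of the intra-methyl ¹H–¹H cross-correlated relaxation rate η
  from intensity-ratio build-up curves,
* conversion of η to the squared order parameter of the methyl symmetry
  axis, O²_axis = (10/9)·η·r⁶_HH / ([P₂(cosθ)]²·(μ₀/4π)²·γ_H⁴·ħ²·τ_m),
* aggregate comparisons: temperature slopes and micelle/bicelle
  environment correlations.

Uncertainties are propagated by seeded Monte-Carlo resampling throughout;
the number of draws and the seed are recorded on every result object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .exceptions import ConvergenceError, InsufficientDataError, MethylDynError
from .probes import OrderParameterSet, RelaxationRecord, TumblingEstimate

__all__ = [
    "ModelFreeParams",
    "EtaFit",
    "spectral_density",
    "predict_n15_rates",
    "estimate_tau_m",
    "r1r2_exchange_screen",
    "buildup_ratio",
    "fit_eta",
    "eta_to_o2_axis",
    "o2_axis_to_eta",
    "temperature_slope",
    "compare_environments",
    "summarize_set",
]


@dataclass(frozen=True)
class ModelFreeParams:
    """Lipari–Szabo parameters: amplitude S², overall tumbling τ_m,
    internal correlation time τ_e, and chemical-exchange rate R_ex."""

    S2: float
    tau_m: float
    tau_e: float = 0.0
    R_ex: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.S2 <= 1.0):
            raise MethylDynError(f"S2 must lie in [0, 1], got {self.S2}")
        if self.tau_m <= 0:
            raise MethylDynError("tau_m must be positive")
        if self.tau_e < 0 or self.R_ex < 0:
            raise MethylDynError("tau_e and R_ex must be >= 0")
        if self.tau_e > 0 and self.tau_e >= self.tau_m:
            raise MethylDynError("tau_e must be smaller than tau_m")


def spectral_density(omega, params: ModelFreeParams):
    """Model-free spectral density J(ω), s rad⁻¹.

    J(ω) = (2/5)·[S²·τ_m/(1+(ωτ_m)²) + (1−S²)·τ/(1+(ωτ)²)]
    with 1/τ = 1/τ_m + 1/τ_e; the internal term vanishes for τ_e = 0.
    Accepts scalar or array ω (rad s⁻¹); J is even in ω.
    """
    omega = np.asarray(omega, dtype=float)
    tm = params.tau_m
    J = params.S2 * tm / (1.0 + (omega * tm) ** 2)
    if params.tau_e > 0.0 and params.S2 < 1.0:
        tau = 1.0 / (1.0 / tm + 1.0 / params.tau_e)
        J = J + (1.0 - params.S2) * tau / (1.0 + (omega * tau) ** 2)
    return 0.4 * J


def predict_n15_rates(
    params: ModelFreeParams,
    field_MHz: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
):
    """Backbone ¹⁵N (R1, R2) in s⁻¹ from dipolar + CSA relaxation.

    Uses the standard expressions with d² the N–H dipolar coupling constant
    squared and c² = (Δσ·ω_N)²/3; R_ex adds to R2 only.
    """
    if field_MHz <= 0:
        raise MethylDynError("field_MHz must be positive")
    wH = constants.omega_H(field_MHz)
    wN = abs(constants.omega_N(field_MHz))
    d2 = constants.dipolar_NH_squared()
    c2 = constants.csa_N_squared(field_MHz)

    def J(w):
        return float(spectral_density(w, params))

    R1 = (d2 / 4.0) * (J(wH - wN) + 3.0 * J(wN) + 6.0 * J(wH + wN)) + c2 * J(wN)
    R2 = (
        (d2 / 8.0)
        * (4.0 * J(0.0) + J(wH - wN) + 3.0 * J(wN) + 6.0 * J(wH) + 6.0 * J(wH + wN))
        + (c2 / 6.0) * (4.0 * J(0.0) + 3.0 * J(wN))
        + params.R_ex
    )
    return R1, R2


# ---------------------------------------------------------------------------
# tumbling time from R2/R1


def _r2_over_r1(tau_m_s: float, field_MHz: float, constants: PhysicalConstants) -> float:
    # ratio is independent of S2 under the tau_e=0, R_ex=0 model
    p = ModelFreeParams(S2=1.0, tau_m=tau_m_s)
    r1, r2 = predict_n15_rates(p, field_MHz, constants)
    return r2 / r1


def r1r2_exchange_screen(records, k: float = 3.0) -> np.ndarray:
    """Flag residues whose R1·R2 product exceeds median + k·MAD.

    Elevated R1·R2 indicates a chemical-exchange (R_ex) contribution to R2;
    the median/MAD form makes the screen robust to the flagged outliers
    themselves. Returns a boolean array aligned with ``records``. Strict
    inequality, so a degenerate spread (MAD = 0) flags nothing.
    """
    if len(records) < 5:
        raise InsufficientDataError("exchange screen needs at least 5 records")
    products = np.array([r.R1 * r.R2 for r in records])
    med = np.median(products)
    mad = np.median(np.abs(products - med))
    return products > med + k * mad


def estimate_tau_m(
    records,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    trim: bool = True,
    k_mad: float = 3.0,
    mobile_percentile: float = 10.0,
    bracket_ns: tuple = (0.5, 200.0),
) -> TumblingEstimate:
    """Estimate the global tumbling time τ_m from backbone R2/R1 ratios.

    Each residue's ratio is inverted numerically (Brent root search on the
    τ_e=0, R_ex=0 forward model, under which the ratio does not depend on
    S²). With ``trim``, residues flagged by the R1·R2 exchange screen and
    residues in the lowest ``mobile_percentile`` of R2/R1 (mobile tails,
    where the rigid-ratio model is biased) are excluded. The estimate is
    the mean of the retained per-residue values, with the standard
    deviation as its error.
    """
    if len(records) < 5:
        raise InsufficientDataError("tau_m estimation needs at least 5 records")
    records = list(records)
    keep = np.ones(len(records), dtype=bool)
    if trim:
        keep &= ~r1r2_exchange_screen(records, k=k_mad)
        ratios = np.array([r.R2 / r.R1 for r in records])
        keep &= ratios >= np.percentile(ratios, mobile_percentile)
    lo, hi = bracket_ns[0] * 1e-9, bracket_ns[1] * 1e-9
    per_residue = []
    for rec, use in zip(records, keep):
        if not use:
            continue
        target = rec.R2 / rec.R1
        f = lambda tm: _r2_over_r1(tm, rec.field_MHz, constants) - target
        try:
            if f(lo) * f(hi) > 0:
                raise ValueError("no sign change in bracket")
            tm = optimize.brentq(f, lo, hi, xtol=1e-15, rtol=1e-13)
        except ValueError:
            warnings.warn(
                f"residue {rec.residue_number}: R2/R1 = {target:.3g} has no "
                f"solution in [{bracket_ns[0]}, {bracket_ns[1]}] ns; excluded",
                stacklevel=2,
            )
            continue
        per_residue.append(tm * 1e9)
    if len(per_residue) < 5:
        raise InsufficientDataError(
            f"only {len(per_residue)} usable residues after trimming (need >= 5)"
        )
    arr = np.array(per_residue)
    return TumblingEstimate(
        tau_m_ns=float(arr.mean()),
        tau_m_err_ns=float(arr.std(ddof=1)),
        n_residues_used=len(arr),
        method="R2/R1",
    )


# ---------------------------------------------------------------------------
# cross-correlated relaxation build-up


def buildup_ratio(T, eta, delta=0.0):
    """Forward model for the cross-correlation build-up intensity ratio.

    ratio(T) = (3/4)·η·tanh(√(η²+δ²)·T) / (√(η²+δ²) − δ·tanh(√(η²+δ²)·T))

    δ is the nuisance cross-relaxation term; for δ = 0 this reduces to
    (3/4)·tanh(η·T). The η → 0, δ → 0 limit is 0.
    """
    T = np.asarray(T, dtype=float)
    s = math.hypot(eta, delta)
    if s < 1e-300:
        return np.zeros_like(T)
    th = np.tanh(s * T)
    return 0.75 * eta * th / (s - delta * th)


@dataclass(frozen=True)
class EtaFit:
    """Result of fitting one build-up series."""

    eta: float
    eta_err: float
    delta: float
    residual_rms: float
    n_points: int
    fixed_delta: bool
    n_mc: int
    seed: int

    def __post_init__(self):
        if not math.isfinite(self.eta):
            raise MethylDynError("eta must be finite")
        if self.eta_err < 0:
            raise MethylDynError("eta_err must be >= 0")


def fit_eta(
    series,
    fix_delta_zero: bool | None = None,
    n_mc: int = 500,
    seed: int = 0,
) -> EtaFit:
    """Fit (η, δ) to a build-up series by nonlinear least squares.

    ``fix_delta_zero=None`` (the default) fits δ when the series has at
    least 4 points and fixes δ=0 otherwise, to avoid overparameterization.
    ``eta_err`` comes from ``n_mc`` seeded Monte-Carlo resamples of the
    ratios with their stated errors (falling back on the fit residual RMS
    when all stated errors are zero).
    """
    T = np.array(series.delays)
    y = np.array(series.ratios)
    errs = np.array(series.ratio_errs)
    n = len(T)
    if fix_delta_zero is None:
        fix_delta_zero = n < 4

    # initial guess from the last point of the delta=0 model
    r_last = float(np.clip(y[-1] * 4.0 / 3.0, -0.999, 0.999))
    eta0 = math.atanh(r_last) / T[-1]

    weights = 1.0 / errs if np.all(errs > 0) else np.ones(n)

    def solve(y_obs, x0):
        if fix_delta_zero:
            fun = lambda p: (buildup_ratio(T, p[0], 0.0) - y_obs) * weights
            x0 = x0[:1]
        else:
            fun = lambda p: (buildup_ratio(T, p[0], p[1]) - y_obs) * weights
        res = optimize.least_squares(fun, x0, method="lm", xtol=1e-14, ftol=1e-14)
        return res

    res = solve(y, np.array([eta0, 0.0]))
    if not res.success:
        raise ConvergenceError(
            "build-up fit did not converge",
            diagnostics={"status": res.status, "cost": res.cost, "message": res.message},
        )
    eta_hat = float(res.x[0])
    delta_hat = 0.0 if fix_delta_zero else float(res.x[1])
    unweighted = buildup_ratio(T, eta_hat, delta_hat) - y
    residual_rms = float(np.sqrt(np.mean(unweighted**2)))

    # Monte-Carlo error propagation
    sigma = errs if np.all(errs > 0) else np.full(n, residual_rms)
    eta_err = 0.0
    if n_mc > 0 and np.any(sigma > 0):
        rng = np.random.default_rng(seed)
        x0 = res.x.copy()
        draws = np.empty(n_mc)
        for i in range(n_mc):
            y_mc = np.clip(y + rng.normal(0.0, sigma), -0.999999, 0.999999)
            draws[i] = solve(y_mc, x0).x[0]
        eta_err = float(draws.std(ddof=1))

    return EtaFit(
        eta=eta_hat,
        eta_err=eta_err,
        delta=delta_hat,
        residual_rms=residual_rms,
        n_points=n,
        fixed_delta=bool(fix_delta_zero),
        n_mc=n_mc,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# eta <-> O2_axis conversion


def _conversion_factor(tau_m_s: float, constants: PhysicalConstants) -> float:
    """O²_axis per unit η, i.e. O² = η · factor."""
    p2sq = constants.p2_axis_HH() ** 2
    num = (10.0 / 9.0) * constants.r_HH_methyl**6
    den = p2sq * constants.mu0_over_4pi**2 * constants.gamma_H**4 * constants.hbar**2 * tau_m_s
    return num / den


def eta_to_o2_axis(
    eta: float, tau_m_s: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Convert the cross-correlated relaxation rate η (s⁻¹) to O²_axis.

    O²_axis = (10/9)·η·r⁶_HH / ([P₂(cosθ_axis,HH)]²·(μ₀/4π)²·γ_H⁴·ħ²·τ_m)

    The value is returned unclipped; a warning is emitted when it falls
    outside [0, 1] (negative η or noise pushing past the rigid limit) and
    interpretation is left to the caller.
    """
    if tau_m_s <= 0:
        raise MethylDynError("tau_m must be positive")
    o2 = eta * _conversion_factor(tau_m_s, constants)
    if not (0.0 <= o2 <= 1.0):
        warnings.warn(
            f"O2_axis = {o2:.4g} falls outside [0, 1]; returned unclipped",
            stacklevel=2,
        )
    return o2


def o2_axis_to_eta(
    o2_axis: float, tau_m_s: float, constants: PhysicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Algebraic inverse of :func:`eta_to_o2_axis`."""
    if tau_m_s <= 0:
        raise MethylDynError("tau_m must be positive")
    return o2_axis / _conversion_factor(tau_m_s, constants)


# ---------------------------------------------------------------------------
# aggregate comparisons


@dataclass(frozen=True)
class TemperatureSlope:
    mean_delta: float  #: mean O²(T_low) − O²(T_high) over paired probes
    slope_per_K: float  #: dO²/dT
    n_paired: int


def temperature_slope(set_a: OrderParameterSet, set_b: OrderParameterSet) -> TemperatureSlope:
    """Mean paired O² change between two temperatures and the slope dO²/dT.

    Probes are paired by identity; order of the arguments does not matter
    (the low/high temperature roles are read off the sets themselves).
    """
    Ta, Tb = set_a.temperature(), set_b.temperature()
    if Ta == Tb:
        raise MethylDynError("the two sets must be at different temperatures")
    low, high = (set_a, set_b) if Ta < Tb else (set_b, set_a)
    pairs = low.pair_with(high)
    deltas = np.array([el.O2_axis - eh.O2_axis for el, eh in pairs])
    mean_delta = float(deltas.mean())
    dT = high.temperature() - low.temperature()
    return TemperatureSlope(
        mean_delta=mean_delta,
        slope_per_K=-mean_delta / dT,
        n_paired=len(pairs),
    )


@dataclass(frozen=True)
class EnvironmentComparison:
    r_squared: float
    slope: float
    intercept: float
    n_paired: int


def compare_environments(
    set_a: OrderParameterSet, set_b: OrderParameterSet
) -> EnvironmentComparison:
    """Ordinary least squares of set_b's O² on set_a's over shared probes.

    R² is the squared Pearson correlation. Used for the micelle/bicelle
    comparison, where a high R² indicates that fast side-chain dynamics are
    insensitive to the membrane mimetic.
    """
    pairs = set_a.pair_with(set_b)
    if len(pairs) < 3:
        raise InsufficientDataError(
            f"environment comparison needs >= 3 paired probes, got {len(pairs)}"
        )
    x = np.array([ea.O2_axis for ea, _ in pairs])
    y = np.array([eb.O2_axis for _, eb in pairs])
    fit = stats.linregress(x, y)
    return EnvironmentComparison(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_paired=len(pairs),
    )


def fit_order_parameter_set(
    series_list,
    tau_m_ns: float,
    environment: str,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_mc: int = 500,
    seed: int = 0,
    fix_delta_zero: bool | None = None,
) -> OrderParameterSet:
    """Fit every build-up series and convert to an order-parameter set.

    Per-probe errors are the Monte-Carlo η uncertainties propagated through
    the (linear) η → O² conversion; the τ_m uncertainty is not folded in,
    since it is a common-mode scale shared by every probe in the set.
    Each series gets its own derived seed so the set is reproducible as a
    whole.
    """
    from .probes import OrderParameterEntry

    tau_m_s = tau_m_ns * 1e-9
    factor = _conversion_factor(tau_m_s, constants)
    entries = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-probe out-of-range O2 is summarized below
        for i, series in enumerate(series_list):
            fit = fit_eta(
                series, fix_delta_zero=fix_delta_zero, n_mc=n_mc, seed=(seed + 7919 * i) % (2**31)
            )
            entries.append(
                OrderParameterEntry(
                    probe=series.probe,
                    O2_axis=fit.eta * factor,
                    error=fit.eta_err * factor,
                    temperature_K=series.temperature_K,
                    environment=environment,
                )
            )
    n_out = sum(1 for e in entries if not (0.0 <= e.O2_axis <= 1.0))
    if n_out:
        warnings.warn(
            f"{n_out} of {len(entries)} converted O2_axis values fall outside [0, 1]",
            stacklevel=2,
        )
    return OrderParameterSet(entries, tau_m_ns=tau_m_ns)


def summarize_set(opset: OrderParameterSet) -> tuple[float, float, int]:
    """Unweighted mean O²_axis, mean reported error, and entry count."""
    if len(opset) == 0:
        raise InsufficientDataError("cannot summarize an empty set")
    return float(opset.values.mean()), float(opset.errors.mean()), len(opset)
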