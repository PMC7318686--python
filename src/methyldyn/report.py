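"""End-to-end summary report over one or more order-parameter tables.

Aggregates, per table: probe count, mean O² and mean reported error, the
error-filtered motional-class model with residue-type composition, and
cone-entropy totals. Across tables it computes the temperature slope
(same environment, two temperatures) and the environment correlation
(same temperature, micelle vs bicelle). The result is a plain dict, JSON
serializable, plus a human-readable text rendering.
"""

from __future__ import annotations

import json
import warnings

import numpy as np

from .classify import class_composition, classify_set
from .entropy import ensemble_entropy
from .exceptions import InsufficientDataError, MethylDynError, PairingError
from .modelfree import compare_environments, summarize_set, temperature_slope
from .probes import OrderParameterSet

__all__ = ["run_report", "render_text"]


def _set_block(name: str, opset: OrderParameterSet, max_error: float, k, seed: int) -> dict:
    mean_o2, mean_err, n = summarize_set(opset)
    block = {
        "n_probes": n,
        "mean_O2_axis": mean_o2,
        "mean_error": mean_err,
        "temperature_K": opset.temperature(),
        "environment": sorted({e.environment for e in opset.entries}),
        "tau_m_ns": opset.tau_m_ns if np.isfinite(opset.tau_m_ns) else None,
        "class_model": None,
        "composition": None,
        "entropy": None,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model, filtered = classify_set(opset, k=k, max_error=max_error, seed=seed)
        comp = class_composition(model, filtered.probes)
        block["class_model"] = {
            "k": model.k,
            "labels": list(model.labels),
            "centers": model.centers.tolist(),
            "boundaries": model.boundaries.tolist(),
            "class_sizes": model.class_sizes().tolist(),
            "n_filtered": len(filtered),
            "selection_scores": {str(kk): v for kk, v in model.selection_scores.items()},
        }
        block["composition"] = {
            "per_class": comp.reset_index().to_dict(orient="records"),
            "overall_frac_MLI": comp.attrs["overall_frac_MLI"],
            "overall_frac_V": comp.attrs["overall_frac_V"],
        }
    except (InsufficientDataError, MethylDynError) as exc:
        block["class_model_absent_reason"] = str(exc)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ent = ensemble_entropy(opset)
        block["entropy"] = {
            "total_kB": ent.total_kB,
            "total_J_per_mol_K": ent.total_J_per_mol_K,
            "mean_kB": ent.mean_kB,
            "n_probes": ent.n_probes,
            "n_skipped": ent.n_skipped,
        }
    except MethylDynError as exc:
        block["entropy_absent_reason"] = str(exc)
    return block


def run_report(
    tables: dict,
    max_error: float = 0.1,
    k: int | None = None,
    seed: int = 0,
) -> dict:
    """Build the report over named order-parameter sets.

    Parameters
    ----------
    tables : dict of name -> OrderParameterSet
    max_error : error-filter threshold for the class analysis.
    k : fixed class count, or None for BIC-based selection.
    seed : seed for the clustering and mixture fits.
    """
    if not tables:
        raise InsufficientDataError("report needs at least one order-parameter table")
    report: dict = {"options": {"max_error": max_error, "k": k, "seed": seed}, "sets": {}}
    for name, opset in tables.items():
        report["sets"][name] = _set_block(name, opset, max_error, k, seed)

    names = list(tables)
    report["comparisons"] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = tables[names[i]], tables[names[j]]
            envs_a = {e.environment for e in a.entries}
            envs_b = {e.environment for e in b.entries}
            entry = {"a": names[i], "b": names[j]}
            try:
                if envs_a == envs_b and a.temperature() != b.temperature():
                    ts = temperature_slope(a, b)
                    entry.update(
                        kind="temperature",
                        mean_delta=ts.mean_delta,
                        slope_per_K=ts.slope_per_K,
                        n_paired=ts.n_paired,
                    )
                elif envs_a != envs_b and a.temperature() == b.temperature():
                    cmp_ = compare_environments(a, b)
                    entry.update(
                        kind="environment",
                        r_squared=cmp_.r_squared,
                        slope=cmp_.slope,
                        intercept=cmp_.intercept,
                        n_paired=cmp_.n_paired,
                    )
                else:
                    continue
            except PairingError:
                keys_a = {e.probe.key for e in a.entries}
                keys_b = {e.probe.key for e in b.entries}
                raise PairingError(
                    f"probe identities of {names[i]} and {names[j]} do not "
                    f"reconcile; only-in-a: {sorted(keys_a - keys_b)[:10]}, "
                    f"only-in-b: {sorted(keys_b - keys_a)[:10]}"
                )
            except (InsufficientDataError, MethylDynError) as exc:
                entry.update(kind="failed", reason=str(exc))
            report["comparisons"].append(entry)
    return report


def render_text(report: dict) -> str:
    """Human-readable rendering of :func:`run_report` output."""
    lines = []
    for name, blk in report["sets"].items():
        lines.append(f"== {name} ==")
        lines.append(
            f"  n={blk['n_probes']}  <O2_axis>={blk['mean_O2_axis']:.3f}  "
            f"<err>={blk['mean_error']:.3f}  T={blk['temperature_K']:.1f} K"
        )
        cm = blk.get("class_model")
        if cm:
            centers = ", ".join(f"{c:.3f}" for c in cm["centers"])
            lines.append(
                f"  classes (k={cm['k']}): {'/'.join(cm['labels'])} "
                f"centered at {centers} (n_filtered={cm['n_filtered']})"
            )
        ent = blk.get("entropy")
        if ent:
            lines.append(
                f"  entropy: total {ent['total_kB']:.1f} kB over "
                f"{ent['n_probes']} probes (mean {ent['mean_kB']:.3f} kB)"
            )
    for cmp_ in report.get("comparisons", []):
        if cmp_.get("kind") == "temperature":
            lines.append(
                f"{cmp_['a']} vs {cmp_['b']}: dO2/dT = {cmp_['slope_per_K']:.4f} K^-1 "
                f"(mean paired change {cmp_['mean_delta']:+.3f}, n={cmp_['n_paired']})"
            )
        elif cmp_.get("kind") == "environment":
            lines.append(
                f"{cmp_['a']} vs {cmp_['b']}: R^2 = {cmp_['r_squared']:.2f} "
                f"(slope {cmp_['slope']:.2f}, n={cmp_['n_paired']})"
            )
    return "\n".join(lines)


def write_report_json(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
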