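"""Shared fixtures: small domain objects and one fitted synthetic dataset.

The pSRII-like end-to-end fit (90 probes, two environments) is expensive
relative to the rest of the suite, so it is computed once per session and
shared by the pipeline and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from methyldyn.modelfree import fit_order_parameter_set
from methyldyn.probes import MethylProbe, OrderParameterEntry, OrderParameterSet
from methyldyn.synth import OMPW_LIKE, PSRII_LIKE, make_methyl_dataset


def make_probe(i: int, residue_type: str = "LEU") -> MethylProbe:
    methyl = {"ILE": "d1", "LEU": "d1", "VAL": "g1", "MET": "e"}[residue_type]
    return MethylProbe(residue_number=i, residue_type=residue_type, methyl_id=methyl)


def make_set(values, errors=None, temperature_K=323.15, environment="micelle", tau_m_ns=21.9):
    values = np.atleast_1d(values)
    errors = np.zeros_like(values) if errors is None else np.atleast_1d(errors)
    entries = [
        OrderParameterEntry(
            probe=make_probe(i + 1),
            O2_axis=float(v),
            error=float(e),
            temperature_K=temperature_K,
            environment=environment,
        )
        for i, (v, e) in enumerate(zip(values, errors))
    ]
    return OrderParameterSet(entries, tau_m_ns=tau_m_ns)


@pytest.fixture(scope="session")
def psrii_synthetic():
    """pSRII-like synthetic dataset: build-ups + ground truth, seed fixed."""
    return make_methyl_dataset(preset=PSRII_LIKE, seed=11)


def _fit_all(dataset, n_mc=25, seed=11):
    fitted = {}
    for env, series in dataset.buildups.items():
        fitted[env] = fit_order_parameter_set(
            series,
            tau_m_ns=dataset.truth_sets[env].tau_m_ns,
            environment=env,
            n_mc=n_mc,
            seed=seed,
        )
    return fitted


@pytest.fixture(scope="session")
def psrii_fitted(psrii_synthetic):
    """Order-parameter sets fitted from the synthetic build-up curves."""
    return _fit_all(psrii_synthetic)


@pytest.fixture(scope="session")
def ompw_synthetic():
    """OmpW-like synthetic dataset (55 probes, tighter replicate R²)."""
    return make_methyl_dataset(preset=OMPW_LIKE, seed=17)


@pytest.fixture(scope="session")
def ompw_fitted(ompw_synthetic):
    return _fit_all(ompw_synthetic, seed=17)
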