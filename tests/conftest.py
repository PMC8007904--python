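"""Shared fixtures: synthetic interval tables and one reference simulation.

The expensive fixture (`low80`) is the reference experiment — the calibrated
80-neuron circuit simulated for 1000 s under low uncertainty and encoded as
an interval table — built once per session and shared by the evaluation,
workflow, and acceptance tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from spiketree import c5tree as ct
from spiketree import intervals as iv
from spiketree import netsim as ns

REFERENCE_SEED = 1
REFERENCE_DURATION = 1000.0


def make_interval_table(codes, y, units=None) -> iv.IntervalTable:
    """Build a small in-memory interval table from explicit codes/classes."""
    codes = np.array(codes, dtype=object)
    if codes.ndim == 1:
        codes = codes[:, None]
    units = list(units) if units is not None else [f"U{i + 1}" for i in range(codes.shape[1])]
    df = pd.DataFrame({"timestamp_s": np.arange(len(y)) * 0.05 + 0.05})
    for j, u in enumerate(units):
        df[u] = codes[:, j]
    df["R"] = np.asarray(y, dtype=np.int8)
    return iv.IntervalTable(df, units, target="T")


def random_interval_table(rng, n_rows=60, n_units=3, informative=None):
    """Random categorical table; `informative` unit index forces class coupling."""
    cats = np.array(["0", "A", "B", "AB", "C"], dtype=object)
    codes = rng.choice(cats, size=(n_rows, n_units))
    if informative is None:
        y = rng.integers(0, 2, n_rows)
    else:
        y = (codes[:, informative] != "0").astype(int)
    return make_interval_table(codes, y)


@dataclass
class ReferenceExperiment:
    params: ns.CircuitParams
    circuit: ns.Circuit
    labels: dict
    mono: set
    spikes: ns.SpikeTrainSet
    table: iv.IntervalTable
    encoded: ct.EncodedTable


def build_reference(seed: int, duration: float = REFERENCE_DURATION) -> ReferenceExperiment:
    """Calibrate, simulate, and encode one low-uncertainty experiment."""
    params = ns.CircuitParams(seed=seed, duration=duration)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = ns.calibrate(params, "low")
        circuit = ns.build_circuit(params, rng_seed=seed)
        level = ns.uncertainty_level(circuit, "low")
        spikes = ns.simulate(circuit, level, params, rng_seed=seed)
    labels = ns.ground_truth(circuit)
    table = iv.extract_intervals(spikes, circuit.target)
    return ReferenceExperiment(
        params=params,
        circuit=circuit,
        labels=labels,
        mono=ns.excitatory_monosynaptic(circuit, labels),
        spikes=spikes,
        table=table,
        encoded=ct.EncodedTable(table),
    )


@pytest.fixture(scope="session")
def low80() -> ReferenceExperiment:
    """The reference 80-neuron, 1000 s, low-uncertainty experiment."""
    return build_reference(REFERENCE_SEED)
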