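"""Dynamic evolving SNN output layer: rank-order initial weights, spike-driven
synaptic plasticity, and per-sample feature vectors.

One output neuron is materialized per sample as the vector of its synaptic
weights.  Each synapse connects a reservoir or input neuron to the output:
its initial weight is mod^order, where order is the (0-based, competition)
rank of that neuron's first spike among all connected neurons' first spikes,
and never-spiking neurons stay at 0.  From the synapse's first spike onward
each step drifts the weight up (presynaptic spike) or down (silence); once a
weight touches w_high or w_low it is frozen there (bi-stability).

Connection strategies:
  ALL32_FULL  reservoir + 32 input-channel synapses (length 1471+32)
  ALL32_IO    only the 32 input-channel synapses (length 32)
  TOP5_FULL   5-channel-trained cube, reservoir + 5 inputs (length 1471+5)
  TOP5_IO     only the 5 input-channel synapses (length 5)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from ._kernels import sdsp_kernel
from .encoding import SpikeTrains
from .reservoir import ReservoirCube, SubtractedCube, simulate

__all__ = [
    "Strategy",
    "DeSNNConfig",
    "FeatureVector",
    "ro_init",
    "sdsp_tune",
    "build_feature_vector",
    "feature_vector_from_record",
    "first_spike_orders",
    "ABSENT",
]

ABSENT = -1  # first-spike order sentinel for never-spiking neurons


class Strategy(str, Enum):
    ALL32_FULL = "all32_full"
    ALL32_IO = "all32_io"
    TOP5_FULL = "top5_full"
    TOP5_IO = "top5_io"

    @property
    def io_only(self) -> bool:
        return self in (Strategy.ALL32_IO, Strategy.TOP5_IO)

    @property
    def n_inputs(self) -> int:
        return 32 if self in (Strategy.ALL32_FULL, Strategy.ALL32_IO) else 5


@dataclass(frozen=True)
class DeSNNConfig:
    """Rank-order modulation factor and SDSP drift parameters."""

    mod: float = 0.9
    drift_up: float = 0.08
    drift_down: float = 0.08
    # bi-stable bounds: at ±0.08 per step the net drift of a synapse with
    # spike probability p is ≈ 0.08·T·(2p−1) per window (≈ ±8 for a balanced
    # 1000-step train), so bounds tighter than that absorb nearly every
    # synapse and erase the vector; ±20 keeps ordinary channels in the
    # drifting regime while strongly rate-biased ones still freeze
    w_high: float = 20.0
    w_low: float = -20.0
    strategy: Strategy = Strategy.ALL32_IO

    def __post_init__(self) -> None:
        if not (0 < self.mod < 1):
            raise ValueError("mod must be in (0, 1)")
        if self.drift_up < 0 or self.drift_down < 0:
            raise ValueError("drift parameters must be nonnegative")
        if self.w_low >= self.w_high:
            raise ValueError("w_low must be below w_high")


@dataclass
class FeatureVector:
    """Output-neuron connection weights for one sample."""

    values: np.ndarray
    feature_names: list[str]
    strategy: Strategy
    label: str | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.feature_names) != self.values.shape[0]:
            raise ValueError("feature_names must match values length")


def first_spike_orders(records: np.ndarray) -> np.ndarray:
    """Competition (1-2-2-4 style) 0-based ranks of first-spike times.

    records: (n_synapses, T) with nonzero entries marking spikes.  Ties share
    the lower rank and the following rank is skipped; never-spiking rows get
    ABSENT.
    """
    n, T = records.shape
    first = np.full(n, T, dtype=np.int64)
    any_spike = (records != 0).any(axis=1)
    first[any_spike] = np.argmax(records[any_spike] != 0, axis=1)
    order = np.full(n, ABSENT, dtype=np.int64)
    spiking = np.flatnonzero(any_spike)
    if spiking.size:
        times = first[spiking]
        # competition ranking: rank = number of strictly earlier first spikes
        order[spiking] = (times[:, None] > times[None, :]).sum(axis=1)
    return order


def ro_init(orders: np.ndarray, mod: float) -> np.ndarray:
    """Rank-order initial weights mod^order; ABSENT → 0."""
    if not (0 < mod < 1):
        raise ValueError("mod must be in (0, 1)")
    orders = np.asarray(orders)
    w = np.where(orders == ABSENT, 0.0, np.power(mod, np.maximum(orders, 0)))
    return w.astype(np.float64)


def sdsp_tune(
    w_init: float | np.ndarray,
    spike_steps: np.ndarray,
    cfg: DeSNNConfig,
) -> float | np.ndarray:
    """Bi-stable spike-driven drift of one or more synapses.

    ``spike_steps`` is a binary/ternary sequence (nonzero = presynaptic spike),
    one row per synapse; drift starts at each synapse's first spike step.
    """
    arr = np.atleast_2d(np.asarray(spike_steps, dtype=np.int8))
    w0 = np.atleast_1d(np.asarray(w_init, dtype=np.float64))
    if w0.shape[0] != arr.shape[0]:
        raise ValueError("w_init must match number of synapse rows")
    out = sdsp_kernel(
        w0, arr, cfg.drift_up, cfg.drift_down, cfg.w_high, cfg.w_low
    )
    return float(out[0]) if np.isscalar(w_init) or np.ndim(w_init) == 0 else out


def build_feature_vector(
    cube: ReservoirCube | SubtractedCube,
    sample: SpikeTrains,
    cfg: DeSNNConfig,
    label: str | int | None = None,
) -> FeatureVector:
    """Parse a sample through the cube and emit its deSNN weight vector.

    The synapse set is the strategy's input channels (their own event trains)
    plus, for FULL strategies, every reservoir neuron (its firing record).
    Rank-order initialization ranks first spikes jointly across the whole
    synapse set, then SDSP drift tunes each synapse.
    """
    chans = cube.template.channels
    if len(chans) != cfg.strategy.n_inputs:
        raise ValueError(
            f"strategy {cfg.strategy.value} expects {cfg.strategy.n_inputs} "
            f"channels but the cube has {len(chans)}"
        )
    if list(sample.channels) != list(chans):
        sample = sample.select(chans)
    rec = simulate(cube, sample)
    return feature_vector_from_record(cube, rec, sample, cfg, label)


def feature_vector_from_record(
    cube: ReservoirCube | SubtractedCube,
    rec: np.ndarray,
    sample: SpikeTrains,
    cfg: DeSNNConfig,
    label: str | int | None = None,
) -> FeatureVector:
    """As :func:`build_feature_vector`, reusing an existing firing record
    (lets parameter grids over mod/drift share one simulation)."""
    chans = cube.template.channels
    if cfg.strategy.io_only:
        synapse_rec = np.ascontiguousarray(sample.events)
        names = list(chans)
    else:
        synapse_rec = np.concatenate([sample.events, rec], axis=0)
        names = list(chans) + [f"n{i:04d}" for i in range(cube.n_neurons)]
    orders = first_spike_orders(synapse_rec)
    w0 = ro_init(orders, cfg.mod)
    w = sdsp_tune(w0, synapse_rec, cfg)
    return FeatureVector(np.asarray(w), names, cfg.strategy, label)
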