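"""Step-Forward (SF) spike encoding of continuous signals.

SF tracks a running ``base`` value per channel.  At each sample after the
first, the signal is compared against two moving cutoffs, ``base + threshold``
(excitatory) and ``base - threshold`` (inhibitory).  Crossing the excitatory
cutoff emits a +1 event and raises the base by one threshold step; crossing the
inhibitory cutoff emits a -1 event and lowers it.  Otherwise no event is
emitted and the base is unchanged.  The resulting ternary event sequence is the
reservoir's input representation of the channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from ._kernels import sf_encode_kernel

__all__ = [
    "SFConfig",
    "SpikeTrains",
    "sf_encode",
    "sf_reconstruct",
    "spike_count",
    "encode_recording",
]

Base0Policy = Literal["first_sample", "zero", "explicit"]


@dataclass(frozen=True)
class SFConfig:
    """Step-Forward encoder configuration.

    threshold
        Cutoff step, in signal units.  Must be positive.
    base0_policy
        How the initial base is chosen: the first sample of each channel
        (default), zero, or an explicit value (``base0_value``).
    """

    threshold: float
    base0_policy: Base0Policy = "first_sample"
    base0_value: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.threshold) or self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")

    def base0(self, signal: np.ndarray) -> float:
        if self.base0_policy == "first_sample":
            return float(signal[0])
        if self.base0_policy == "zero":
            return 0.0
        return float(self.base0_value)


@dataclass
class SpikeTrains:
    """Per-channel ternary event sequences over {-1, 0, +1}.

    events has shape (n_channels, n_samples), int8.
    """

    channels: list[str]
    events: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.events = np.asarray(self.events, dtype=np.int8)
        if self.events.ndim != 2:
            raise ValueError("events must be 2-D (channels x time)")
        if len(self.channels) != self.events.shape[0]:
            raise ValueError("channel list does not match event rows")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        bad = np.setdiff1d(np.unique(self.events), [-1, 0, 1])
        if bad.size:
            raise ValueError(f"events contain values outside {{-1,0,1}}: {bad}")

    @property
    def length(self) -> int:
        return int(self.events.shape[1])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def select(self, channels: Sequence[str]) -> "SpikeTrains":
        """Restrict to a channel subset, preserving the given order."""
        idx = [self.channels.index(c) for c in channels]
        return SpikeTrains(list(channels), self.events[idx], self.rate)


def _validate_signal(signal: np.ndarray) -> np.ndarray:
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D series")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return x


def sf_encode(signal: Sequence[float], cfg: SFConfig) -> np.ndarray:
    """Encode one channel into a ternary event sequence (same length, t=0 is 0)."""
    x = _validate_signal(np.asarray(signal))
    return sf_encode_kernel(x, cfg.threshold, cfg.base0(x))


def sf_reconstruct(events: np.ndarray, cfg: SFConfig, base0: float = 0.0) -> np.ndarray:
    """Running base path implied by an event sequence.

    Element ``t`` is the base value after processing event ``t``: cumulative
    ±threshold steps from ``base0``.
    """
    ev = np.asarray(events)
    bad = np.setdiff1d(np.unique(ev), [-1, 0, 1]) if ev.size else np.array([])
    if ev.ndim != 1 or bad.size:
        raise ValueError("events must be a 1-D ternary sequence")
    return base0 + cfg.threshold * np.cumsum(ev.astype(np.float64))


@dataclass
class SpikeCounts:
    """Per-channel event counts, total and split by polarity."""

    channels: list[str]
    total: np.ndarray
    positive: np.ndarray
    negative: np.ndarray


def spike_count(trains: SpikeTrains) -> SpikeCounts:
    """Count nonzero events per channel, reported total and by polarity."""
    pos = (trains.events == 1).sum(axis=1)
    neg = (trains.events == -1).sum(axis=1)
    return SpikeCounts(list(trains.channels), pos + neg, pos, neg)


def encode_recording(
    data: np.ndarray,
    channels: Sequence[str],
    rate: float,
    cfg: SFConfig | None = None,
    threshold_sd_fraction: float = 0.5,
) -> SpikeTrains:
    """SF-encode a multichannel recording (channels x samples).

    When ``cfg`` is None, a per-channel threshold of
    ``threshold_sd_fraction`` x the channel's standard deviation is used
    (scale-free across channels); channels with zero variance emit no events.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[0] != len(channels):
        raise ValueError("data rows must match channel count")
    events = np.zeros(data.shape, dtype=np.int8)
    for i in range(data.shape[0]):
        if cfg is None:
            sd = float(np.std(data[i]))
            if sd == 0.0:
                continue
            ch_cfg = SFConfig(threshold=threshold_sd_fraction * sd)
        else:
            ch_cfg = cfg
        events[i] = sf_encode(data[i], ch_cfg)
    return SpikeTrains(list(channels), events, rate)
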