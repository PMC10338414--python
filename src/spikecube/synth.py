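"""Synthetic two-class EEG + RR-interval cohorts with planted ground truth.

The generator emulates the study design the pipeline targets: two groups
(one susceptible to the induced state, one control), 32-channel EEG with a
2-min resting baseline followed by a 2-min stimulus period, and a per-subject
RR-interval series.  Class differences are planted and fully recorded:

* EEG — every channel is pink (1/f) background noise plus a shared-source
  field mixed by electrode distance, normalized to unit variance.  Affected
  subjects additionally carry a band-limited 10 Hz oscillation of amplitude
  ``effect_size`` × the background SD on ``effect_channels`` inside
  ``effect_windows`` (whole recording by default), so the planted channels'
  variance ratio between classes is 1 + effect_size².
* onset markers — affected subjects report state onset at a log-normal time
  with median ``onset_median`` s after stimulus start, clipped to the
  stimulus window.
* RR — AR(1)-correlated Gaussian intervals; the affected class has its mean
  shortened by ``rr_mean_shift`` ms and its variability scaled by
  ``rr_var_shift`` (a sympathetic-shift analogue).

Recordings are generated deterministically per subject on demand (a full
64-subject cohort at 500 samples/s would not fit comfortably in memory), so
the dataset object is light and bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hrv import RRSeries
from .template import build_template

__all__ = ["SynthSpec", "Recording", "SynthDataset", "gen_eeg", "gen_rr", "generate"]

CONTROL, AFFECTED = 0, 1
DEFAULT_EFFECT_CHANNELS = ("Cz", "O2", "F7", "P4", "Fz")


@dataclass(frozen=True)
class SynthSpec:
    n_per_class: int = 32
    channels: tuple[str, ...] = ()          # empty → the packaged 32-channel set
    rate: float = 500.0
    baseline_len: float = 120.0
    stim_len: float = 120.0
    effect_channels: tuple[str, ...] = DEFAULT_EFFECT_CHANNELS
    effect_size: float = 2.0
    effect_windows: tuple[tuple[float, float], ...] | None = None
    onset_median: float = 39.0
    rr_mean: float = 850.0                  # control-class mean RR (ms)
    rr_sd: float = 50.0                     # control-class stationary SD (ms)
    rr_ar: float = 0.6                      # AR(1) coefficient
    rr_mean_shift: float = 60.0             # affected class: mean RR shortened (ms)
    rr_var_shift: float = 0.7               # affected class: SD multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.channels and not set(self.effect_channels) <= set(self.channels):
            raise ValueError("effect_channels must be a subset of channels")

    @property
    def duration(self) -> float:
        return self.baseline_len + self.stim_len


@dataclass
class Recording:
    """One subject's multichannel recording with event markers."""

    subject: str
    data: np.ndarray            # (n_channels, n_samples)
    channels: list[str]
    rate: float
    markers: dict               # baseline_start / stimulus_start / onset (s)
    label: int

    def window(self, start: float, length: float) -> np.ndarray:
        i0 = int(round(start * self.rate))
        i1 = i0 + int(round(length * self.rate))
        if i0 < 0 or i1 > self.data.shape[1]:
            raise ValueError(f"window [{start}, {start + length}) s outside recording")
        return self.data[:, i0:i1]


def _pink(rng: np.random.Generator, n_rows: int, n: int) -> np.ndarray:
    """Rows of 1/f-shaped Gaussian noise, each normalized to unit SD."""
    nf = n // 2 + 1
    f = np.arange(nf, dtype=np.float64)
    f[0] = 1.0
    spec = (rng.standard_normal((n_rows, nf)) + 1j * rng.standard_normal((n_rows, nf)))
    spec /= np.sqrt(f)[None, :]
    x = np.fft.irfft(spec, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


class SynthDataset:
    """Lazy, seed-deterministic synthetic cohort.

    Subjects 0..n-1 are controls, n..2n-1 the affected class.  ``ground_truth``
    records the planted structure for recovery tests only; pipeline stages
    consume recordings and RR series, never the ground truth.
    """

    def __init__(self, spec: SynthSpec):
        self.spec = spec
        if spec.channels:
            self.channels = list(spec.channels)
            self._chan_pos = None
        else:
            tpl = build_template()
            self.channels = list(tpl.channels)
            self._chan_pos = tpl.channel_pos
        self.n_subjects = 2 * spec.n_per_class
        self.labels = [CONTROL] * spec.n_per_class + [AFFECTED] * spec.n_per_class
        self._onsets = self._draw_onsets()
        self.ground_truth = {
            "effect_channels": list(spec.effect_channels),
            "effect_size": spec.effect_size,
            "effect_windows": self._windows(),
            "onsets": dict(self._onsets),
            "rr_mean_shift": spec.rr_mean_shift,
            "rr_var_shift": spec.rr_var_shift,
        }

    # -- EEG ---------------------------------------------------------------

    def _windows(self) -> list[tuple[float, float]]:
        if self.spec.effect_windows is None:
            return [(0.0, self.spec.duration)]
        return [tuple(w) for w in self.spec.effect_windows]

    def _draw_onsets(self) -> dict[int, float]:
        rng = np.random.default_rng([self.spec.seed, 7919])
        out = {}
        for i in range(self.spec.n_per_class, self.n_subjects):
            t = float(np.exp(rng.normal(np.log(self.spec.onset_median), 0.5)))
            out[i] = float(np.clip(t, 1.0, self.spec.stim_len - 1.0))
        return out

    def recording(self, subject: int) -> Recording:
        """Generate subject's full recording (deterministic in seed+subject)."""
        spec = self.spec
        rng = np.random.default_rng([spec.seed, 1009, subject])
        n = int(round(spec.duration * spec.rate))
        n_ch = len(self.channels)
        data = _pink(rng, n_ch, n)
        # shared sources mixed by electrode distance give spatial correlation
        sources = _pink(rng, 4, n)
        if self._chan_pos is not None:
            src_pos = np.array(
                [[0, 8, 2], [0, -9, 2], [-7, 0, 2], [7, 0, 2]], dtype=float
            )
            dist = np.sqrt(
                ((self._chan_pos[:, None, :] - src_pos[None, :, :]) ** 2).sum(-1)
            )
            mix = np.exp(-dist / 5.0)
        else:
            mix = rng.random((n_ch, 4))
        data = data + 0.5 * (mix @ sources)
        data /= data.std(axis=1, keepdims=True)

        label = self.labels[subject]
        if label == AFFECTED and spec.effect_size > 0:
            t = np.arange(n) / spec.rate
            phases = rng.uniform(0, 2 * np.pi, size=len(spec.effect_channels))
            for k, ch in enumerate(spec.effect_channels):
                row = self.channels.index(ch)
                osc = np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t + phases[k])
                mask = np.zeros(n)
                for w0, w1 in self._windows():
                    i0, i1 = int(round(w0 * spec.rate)), int(round(w1 * spec.rate))
                    mask[i0:i1] = 1.0
                data[row] += spec.effect_size * osc * mask
        markers = {"baseline_start": 0.0, "stimulus_start": spec.baseline_len}
        if subject in self._onsets:
            markers["onset"] = spec.baseline_len + self._onsets[subject]
        return Recording(
            f"s{subject:03d}", data, list(self.channels), spec.rate, markers, label
        )

    def eeg_window(self, subject: int, start: float, length: float) -> np.ndarray:
        return self.recording(subject).window(start, length)

    # -- RR ----------------------------------------------------------------

    def rr(self, subject: int) -> RRSeries:
        spec = self.spec
        rng = np.random.default_rng([spec.seed, 2003, subject])
        label = self.labels[subject]
        mean = spec.rr_mean - (spec.rr_mean_shift if label == AFFECTED else 0.0)
        sd = spec.rr_sd * (spec.rr_var_shift if label == AFFECTED else 1.0)
        n = int(np.ceil(spec.duration * 1000.0 / max(mean - 4 * sd, 300.0))) + 4
        eps = rng.standard_normal(n) * sd * np.sqrt(max(1.0 - spec.rr_ar**2, 0.0))
        x = np.empty(n)
        x[0] = mean + rng.standard_normal() * sd
        for t in range(1, n):
            x[t] = mean + spec.rr_ar * (x[t - 1] - mean) + eps[t]
        x = np.maximum(x, 1.0)  # positivity clip; outliers flagged downstream
        return RRSeries(x, t0=0.0, subject=f"s{subject:03d}", label=label)


def gen_eeg(spec: SynthSpec) -> SynthDataset:
    """Synthetic cohort (EEG part; RR series also available on the dataset)."""
    return SynthDataset(spec)


def gen_rr(spec: SynthSpec) -> SynthDataset:
    """Synthetic cohort (RR part; EEG also available on the dataset)."""
    return SynthDataset(spec)


def generate(spec: SynthSpec) -> SynthDataset:
    return SynthDataset(spec)
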