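"""End-to-end glue: windows → spike trains → class cubes → subtracted cube →
deSNN feature vectors → LOOCV classification, plus top-k feature discovery."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import CVResult, KNNParams, loocv
from .desnn import DeSNNConfig, FeatureVector, Strategy, feature_vector_from_record
from .encoding import SpikeTrains, encode_recording
from .knowledge import cluster_by_weight, neuron_proportion, select_top_k
from .reservoir import (
    LIFConfig,
    ReservoirCube,
    STDPConfig,
    SubtractedCube,
    SWCConfig,
    init_reservoir,
    simulate,
    stdp_train,
    subtract,
)
from .synth import SynthDataset
from .template import BrainTemplate

__all__ = [
    "PipelineConfig",
    "encode_windows",
    "train_class_cubes",
    "feature_matrix",
    "classify_samples",
    "discover_top_k",
]


@dataclass(frozen=True)
class PipelineConfig:
    swc: SWCConfig = SWCConfig()
    lif: LIFConfig = LIFConfig()
    stdp: STDPConfig = STDPConfig()
    desnn: DeSNNConfig = DeSNNConfig()
    knn: KNNParams = KNNParams(k=3, feature_weighting="snr")
    threshold_sd_fraction: float = 0.5


def encode_windows(
    dataset: SynthDataset,
    start: float,
    length: float,
    channels: Sequence[str] | None = None,
    threshold_sd_fraction: float = 0.5,
) -> tuple[list[SpikeTrains], list[int]]:
    """SF-encode one time window for every subject of a synthetic cohort."""
    trains, labels = [], []
    for i in range(dataset.n_subjects):
        rec = dataset.recording(i)
        data = rec.window(start, length)
        chans = rec.channels
        if channels is not None:
            idx = [chans.index(c) for c in channels]
            data, chans = data[idx], list(channels)
        trains.append(
            encode_recording(
                data, chans, rec.rate, threshold_sd_fraction=threshold_sd_fraction
            )
        )
        labels.append(rec.label)
    return trains, labels


def train_class_cubes(
    samples: Sequence[SpikeTrains],
    labels: Sequence[int],
    template: BrainTemplate,
    cfg: PipelineConfig,
) -> tuple[dict[int, ReservoirCube], SubtractedCube]:
    """Train one cube per class from a shared initialization and subtract.

    The subtraction order is descending class label (affected − control when
    labels are 1/0), matching the convention of a state-specific cube.
    """
    base = init_reservoir(template, cfg.swc, cfg.lif)
    y = np.asarray(labels)
    classes = sorted(set(y.tolist()), reverse=True)
    if len(classes) != 2:
        raise ValueError("train_class_cubes expects exactly two classes")
    cubes = {}
    for c in classes:
        cls_samples = [s for s, l in zip(samples, y) if l == c]
        cubes[c] = stdp_train(base, cls_samples, cfg.stdp, label=str(c))
    sub = subtract(cubes[classes[0]], cubes[classes[1]])
    return cubes, sub


def feature_matrix(
    cube: ReservoirCube | SubtractedCube,
    samples: Sequence[SpikeTrains],
    desnn_cfgs: Sequence[DeSNNConfig],
    labels: Sequence[int] | None = None,
) -> list[list[FeatureVector]]:
    """Feature vectors for every sample under each deSNN configuration,
    simulating each sample through the cube only once."""
    labels = list(labels) if labels is not None else [None] * len(samples)
    chans = cube.template.channels
    out: list[list[FeatureVector]] = [[] for _ in desnn_cfgs]
    for s, lab in zip(samples, labels):
        if list(s.channels) != list(chans):
            s = s.select(chans)
        rec = simulate(cube, s)
        for j, cfg in enumerate(desnn_cfgs):
            out[j].append(feature_vector_from_record(cube, rec, s, cfg, lab))
    return out


def stack(fvs: Sequence[FeatureVector]) -> np.ndarray:
    return np.stack([fv.values for fv in fvs])


def classify_samples(
    cube: ReservoirCube | SubtractedCube,
    samples: Sequence[SpikeTrains],
    labels: Sequence[int],
    cfg: PipelineConfig,
) -> tuple[CVResult, list[FeatureVector]]:
    """Feature vectors under cfg.desnn, evaluated by LOOCV with cfg.knn."""
    fvs = feature_matrix(cube, samples, [cfg.desnn], labels)[0]
    res = loocv(stack(fvs), list(labels), cfg.knn)
    return res, fvs


def discover_top_k(cube: SubtractedCube, k: int = 5) -> list[str]:
    """Top-k channels by neuron proportion of the subtracted cube's clusters."""
    cm = cluster_by_weight(cube)
    return select_top_k(neuron_proportion(cm), k)
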