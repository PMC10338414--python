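"""Exhaustive time-segment optimization over the resting baseline.

The baseline is partitioned into windows of 2/5/10 s (non-overlapping by
default); every (segment × channel mode × connection strategy × SDSP grid
point) cell trains class cubes, subtracts them, derives deSNN feature
vectors, and scores them by LOOCV.  When the drift constraint is on, only
grid points with drift_up > drift_down are evaluated (stronger weight
increases than decreases, boosting frequently firing inputs).  Cells are
independent; rows are emitted in canonical enumeration order so the result
table is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import loocv
from .desnn import DeSNNConfig, Strategy
from .pipeline import PipelineConfig, encode_windows, feature_matrix, stack, train_class_cubes
from .synth import SynthDataset
from .template import BrainTemplate

__all__ = ["ScanSpec", "enumerate_segments", "run_scan", "best_io_subset"]

SUBSET_GUARD = 10  # exhaustive subset search is refused above this many features


@dataclass(frozen=True)
class ScanSpec:
    lengths: tuple[float, ...] = (2.0, 5.0, 10.0)
    stride: float | None = None             # None → segment length (partition)
    channel_modes: tuple[str, ...] = ("all32",)   # and/or "top5"
    strategies: tuple[Strategy, ...] = (Strategy.ALL32_IO,)
    mod_grid: tuple[float, ...] = (0.9,)
    drift_grid: tuple[tuple[float, float], ...] = ((0.08, 0.08),)
    constraint_up_gt_down: bool = False
    top_k: int = 5

    def __post_init__(self) -> None:
        if self.stride is not None and self.stride <= 0:
            raise ValueError("stride must be positive")
        if not self.mod_grid or not self.drift_grid:
            raise ValueError("parameter grids must be non-empty")

    def valid_drifts(self) -> list[tuple[float, float]]:
        if not self.constraint_up_gt_down:
            return list(self.drift_grid)
        return [(u, d) for u, d in self.drift_grid if u > d]


def enumerate_segments(
    total: float, length: float, stride: float | None = None
) -> list[tuple[float, float]]:
    """(start, length) windows from 0, stepping by stride, fully inside total."""
    if length <= 0 or length > total:
        raise ValueError(f"invalid segment length {length} for total {total}")
    stride = length if stride is None else stride
    if stride <= 0:
        raise ValueError("stride must be positive")
    out = []
    start = 0.0
    while start + length <= total + 1e-9:
        out.append((round(start, 9), length))
        start += stride
    return out


def best_io_subset(
    X: np.ndarray,
    feature_names: Sequence[str],
    labels: Sequence[int],
    cfg: PipelineConfig,
    allow_large: bool = False,
) -> tuple[list[str], float]:
    """Exhaustive non-empty feature-subset search by LOOCV.

    Ties prefer higher accuracy, then smaller subsets, then canonical feature
    order.  Refuses more than SUBSET_GUARD features unless ``allow_large``
    (2^32 subsets is not a desk-scale search).
    """
    names = list(feature_names)
    if len(names) > SUBSET_GUARD and not allow_large:
        raise ValueError(
            f"{len(names)} features → {2 ** len(names) - 1} subsets; "
            "pass allow_large=True to override"
        )
    y = list(labels)
    best: tuple | None = None
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(range(len(names)), r):
            acc = loocv(X[:, list(combo)], y, cfg.knn).accuracy
            key = (acc, -r, tuple(-c for c in combo))
            if best is None or key > best[0]:
                best = (key, combo, acc)
    assert best is not None
    return [names[c] for c in best[1]], best[2]


def run_scan(
    dataset: SynthDataset,
    spec: ScanSpec,
    cfg: PipelineConfig,
    template: BrainTemplate,
    subset_search: bool = True,
) -> pd.DataFrame:
    """Evaluate every scan cell; returns the full result table.

    Columns: start, length, channel_mode, strategy, mod, drift_up, drift_down,
    accuracy, best_subset, best_subset_accuracy, error.  Failed cells keep
    their row with the error message recorded.
    """
    from .encoding import encode_recording

    total = dataset.spec.baseline_len
    rows = []
    desnn_grid = [
        (m, u, d)
        for m in spec.mod_grid
        for (u, d) in spec.valid_drifts()
    ]
    # one recording pass per subject; every window is encoded from it
    segs = {
        length: enumerate_segments(total, length, spec.stride)
        for length in spec.lengths
    }
    cache: dict[tuple[float, float], list] = {
        (length, start): [] for length in segs for (start, _) in segs[length]
    }
    labels: list[int] = []
    chan_idx = None
    for i in range(dataset.n_subjects):
        rec = dataset.recording(i)
        labels.append(rec.label)
        if chan_idx is None:
            chan_idx = [rec.channels.index(c) for c in template.channels]
        for length in segs:
            for start, _ in segs[length]:
                data = rec.window(start, length)[chan_idx]
                cache[(length, start)].append(
                    encode_recording(
                        data, template.channels, rec.rate,
                        threshold_sd_fraction=cfg.threshold_sd_fraction,
                    )
                )
    for length in spec.lengths:
        for start, _ in segs[length]:
            samples32 = cache[(length, start)]
            for mode in spec.channel_modes:
                try:
                    rows.extend(
                        _scan_cell(
                            mode, samples32, labels, template, cfg, spec,
                            desnn_grid, start, length, subset_search,
                        )
                    )
                except Exception as e:  # record, keep scanning
                    rows.append(
                        {
                            "start": start, "length": length, "channel_mode": mode,
                            "strategy": None, "mod": None, "drift_up": None,
                            "drift_down": None, "accuracy": np.nan,
                            "best_subset": None, "best_subset_accuracy": np.nan,
                            "error": str(e),
                        }
                    )
    df = pd.DataFrame(rows)
    return df.reset_index(drop=True)


def _scan_cell(
    mode, samples32, labels, template, cfg, spec, desnn_grid, start, length,
    subset_search,
):
    if mode == "all32":
        tpl, samples = template, samples32
        strategies = [s for s in spec.strategies if s.n_inputs == 32]
    elif mode == "top5":
        _, sub32 = train_class_cubes(samples32, labels, template, cfg)
        from .pipeline import discover_top_k

        top = discover_top_k(sub32, spec.top_k)
        tpl = template.restrict(top)
        samples = [s.select(top) for s in samples32]
        strategies = [s for s in spec.strategies if s.n_inputs == 5]
    else:
        raise ValueError(f"unknown channel mode {mode!r}")
    if not strategies:
        return []
    _, sub = train_class_cubes(samples, labels, tpl, cfg)
    cfgs = [
        DeSNNConfig(
            mod=m, drift_up=u, drift_down=d,
            w_high=cfg.desnn.w_high, w_low=cfg.desnn.w_low, strategy=strat,
        )
        for strat in strategies
        for (m, u, d) in desnn_grid
    ]
    fv_sets = feature_matrix(sub, samples, cfgs, labels)
    out = []
    for dcfg, fvs in zip(cfgs, fv_sets):
        X = stack(fvs)
        acc = loocv(X, labels, cfg.knn).accuracy
        best_sub, best_acc = None, np.nan
        if subset_search and dcfg.strategy.io_only and X.shape[1] <= SUBSET_GUARD:
            best_sub, best_acc = best_io_subset(
                X, fvs[0].feature_names, labels, cfg
            )
        out.append(
            {
                "start": start, "length": length, "channel_mode": mode,
                "strategy": dcfg.strategy.value, "mod": dcfg.mod,
                "drift_up": dcfg.drift_up, "drift_down": dcfg.drift_down,
                "accuracy": acc,
                "best_subset": "+".join(best_sub) if best_sub else None,
                "best_subset_accuracy": best_acc,
                "error": None,
            }
        )
    return out
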