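"""Brain-shaped reservoir template: 1471 neuron coordinates + 32-channel input map.

The packaged coordinate asset is a synthetic stand-in for the Talairach-atlas
neuron table: all integer-cm grid points inside an ellipsoid fitted to adult
brain dimensions (the semi-axes were chosen so the count is exactly 1471, one
neuron per cm³), together with 32 scalp electrode positions of the 10-10
system.  Each EEG channel is assigned to the nearest reservoir neuron by
Euclidean distance, ties broken by lowest neuron index; if two channels would
collide on one neuron, later channels (canonical order) take their next
nearest free neuron so the 32 input neurons are distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["BrainTemplate", "build_template", "N_NEURONS", "N_CHANNELS"]

N_NEURONS = 1471
N_CHANNELS = 32


@dataclass
class BrainTemplate:
    """Reservoir geometry: neuron coordinates plus the channel → neuron map."""

    coords: np.ndarray                # (n_neurons, 3) cm
    channels: list[str]               # canonical channel order
    input_indices: np.ndarray         # (n_channels,) neuron index per channel
    channel_pos: np.ndarray | None = None  # (n_channels, 3) electrode positions

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.input_indices = np.asarray(self.input_indices, dtype=np.int64)
        n = self.coords.shape[0]
        if len(np.unique(self.coords, axis=0)) != n:
            raise ValueError("template coordinates must be distinct")
        if len(set(self.input_indices.tolist())) != len(self.channels):
            raise ValueError("input neurons must be distinct")
        if self.input_indices.min(initial=0) < 0 or self.input_indices.max(initial=0) >= n:
            raise ValueError("input neuron index out of range")

    @property
    def n_neurons(self) -> int:
        return int(self.coords.shape[0])

    @property
    def input_map(self) -> dict[str, int]:
        return {c: int(i) for c, i in zip(self.channels, self.input_indices)}

    def restrict(self, channels: list[str]) -> "BrainTemplate":
        """Same neuron grid, inputs restricted to a channel subset (used when
        retraining a cube on the top-k discovered channels)."""
        missing = [c for c in channels if c not in self.channels]
        if missing:
            raise KeyError(f"unknown channels: {missing}")
        sel = [self.channels.index(c) for c in channels]
        pos = None if self.channel_pos is None else self.channel_pos[sel]
        return BrainTemplate(self.coords, list(channels), self.input_indices[sel], pos)

    def subsample(self, spacing: int = 2) -> "BrainTemplate":
        """Reduced reservoir: keep grid points on a coarser (``spacing`` cm)
        lattice and re-map the inputs.  Used for fast exhaustive scans."""
        keep = np.all(np.mod(self.coords, spacing) == 0, axis=1)
        coords = self.coords[keep]
        pos = self.channel_pos
        if pos is None:
            pos = self.coords[self.input_indices]
        idx = _assign_nearest(pos, coords)
        return BrainTemplate(coords, list(self.channels), idx, pos)


def _assign_nearest(targets: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Nearest-coordinate assignment with distinctness: ties and collisions
    resolved by lowest available neuron index, channels processed in order."""
    d2 = ((targets[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    taken: set[int] = set()
    out = np.empty(targets.shape[0], dtype=np.int64)
    for c in range(targets.shape[0]):
        order = np.argsort(d2[c], kind="stable")  # stable → lowest index on ties
        for j in order:
            if int(j) not in taken:
                out[c] = int(j)
                taken.add(int(j))
                break
    return out


def _asset(name: str) -> pd.DataFrame:
    ref = resources.files("spikecube.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def build_template(
    grid_asset: str | None = None, channel_asset: str | None = None
) -> BrainTemplate:
    """Load the packaged template: 1471 neurons, 32 mapped input channels.

    Alternative assets may be given as CSV paths (grid: ``x,y,z``; channels:
    ``channel,x,y,z``).
    """
    grid = (
        pd.read_csv(grid_asset)
        if grid_asset
        else _asset("synthetic_brain_grid_1471.csv")
    )
    chan = (
        pd.read_csv(channel_asset)
        if channel_asset
        else _asset("channels_1010_32.csv")
    )
    for col in ("x", "y", "z"):
        if col not in grid.columns:
            raise ValueError(f"grid asset missing column {col!r}")
    coords = grid[["x", "y", "z"]].to_numpy(dtype=np.float64)
    if grid_asset is None and coords.shape[0] != N_NEURONS:
        raise ValueError(
            f"packaged grid asset corrupt: {coords.shape[0]} points, expected {N_NEURONS}"
        )
    channels = chan["channel"].astype(str).tolist()
    pos = chan[["x", "y", "z"]].to_numpy(dtype=np.float64)
    if channel_asset is None and len(channels) != N_CHANNELS:
        raise ValueError(
            f"packaged channel asset corrupt: {len(channels)} channels, expected {N_CHANNELS}"
        )
    idx = _assign_nearest(pos, coords)
    return BrainTemplate(coords, channels, idx, pos)
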