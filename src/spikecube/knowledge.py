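"""Knowledge discovery on (subtracted) reservoir cubes.

A trained or class-subtracted cube is summarized into interpretable
structures: every reservoir neuron is assigned to the input channel with the
strongest weighted-path connection to it (a "cluster"), cluster sizes become
per-channel neuron proportions, cross-cluster weight mass becomes a feature
interaction network (FIN), and the top-k channels by proportion drive feature
selection for retraining.

Cluster assignment spreads from each input neuron over directed paths of up to
``hops`` connections, multiplying |w| along a path and attenuating each hop
beyond the first by ``attenuation``; a neuron joins the channel with maximal
accumulated strength, input neurons always belong to their own channel, and
neurons with zero strength from every input stay UNASSIGNED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reservoir import ReservoirCube, SubtractedCube

__all__ = [
    "UNASSIGNED",
    "ClusterMap",
    "cluster_by_weight",
    "neuron_proportion",
    "feature_interaction_network",
    "select_top_k",
    "export_node_edge",
]

UNASSIGNED = ""


@dataclass
class ClusterMap:
    """Per-neuron winning input channel ('' = unassigned) and its strength."""

    assignment: np.ndarray   # (n_neurons,) object array of channel names
    strength: np.ndarray     # (n_neurons,) winning accumulated |w|
    channels: list[str]
    meta: dict

    def cluster_sizes(self) -> pd.Series:
        vals = pd.Series(self.assignment)
        return vals[vals != UNASSIGNED].value_counts().reindex(
            self.channels, fill_value=0
        )


def cluster_by_weight(
    cube: ReservoirCube | SubtractedCube,
    hops: int = 2,
    attenuation: float = 0.5,
    strength_quantile: float | None = 0.75,
) -> ClusterMap:
    """Assign each reservoir neuron to the input channel that reaches it with
    the greatest accumulated absolute connection strength.

    For subtracted cubes the magnitude |Δw| is used: sign encodes direction of
    the class difference, not strength.  Neurons whose winning strength falls
    below the ``strength_quantile`` of all positive winning strengths are left
    UNASSIGNED (``None`` disables the cutoff): cluster sizes then count only
    strongly connected neurons rather than everything merely *reachable*,
    which would make them a map of local neuron density instead of weight.
    """
    tpl = cube.template
    n = tpl.n_neurons
    a = np.abs(cube.weights.toarray())
    score = a[tpl.input_indices, :].copy()           # 1-hop direct strength
    reach = score
    for _ in range(hops - 1):
        reach = reach @ a
        score = score + attenuation * reach
    assignment = np.full(n, UNASSIGNED, dtype=object)
    strength = np.zeros(n)
    any_pos = score.max(axis=0) > 0
    winner = score.argmax(axis=0)
    keep = any_pos
    if strength_quantile is not None and any_pos.any():
        cut = np.quantile(score.max(axis=0)[any_pos], strength_quantile)
        keep = any_pos & (score.max(axis=0) >= cut)
    assignment[keep] = np.array(tpl.channels, dtype=object)[winner[keep]]
    strength[keep] = score[winner[keep], np.flatnonzero(keep)]
    # input neurons always belong to their own channel
    for c, i in tpl.input_map.items():
        assignment[i] = c
        strength[i] = max(strength[i], score[:, i].max(initial=0.0))
    return ClusterMap(
        assignment, strength, list(tpl.channels),
        meta={
            "hops": hops,
            "attenuation": attenuation,
            "strength_quantile": strength_quantile,
        },
    )


def neuron_proportion(cm: ClusterMap) -> pd.Series:
    """Percentage of reservoir neurons belonging to each channel's cluster."""
    sizes = cm.cluster_sizes()
    return 100.0 * sizes / len(cm.assignment)


def feature_interaction_network(
    cube: ReservoirCube | SubtractedCube, cm: ClusterMap
) -> pd.DataFrame:
    """Channel × channel summed |w| over cross-cluster connections, symmetric
    with zero diagonal."""
    chans = cm.channels
    pos = {c: k for k, c in enumerate(chans)}
    n_ch = len(chans)
    fin = np.zeros((n_ch, n_ch))
    coo = cube.weights.tocoo()
    for i, j, w in zip(coo.row, coo.col, coo.data):
        ci, cj = cm.assignment[i], cm.assignment[j]
        if ci == UNASSIGNED or cj == UNASSIGNED or ci == cj:
            continue
        fin[pos[ci], pos[cj]] += abs(w)
    fin = fin + fin.T  # symmetrize (each directed edge counted once per side)
    return pd.DataFrame(fin, index=chans, columns=chans)


def select_top_k(pt: pd.Series, k: int) -> list[str]:
    """Top-k channels by descending proportion; ties broken by the canonical
    channel order of the table's index."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(pt):
        raise ValueError(f"k={k} exceeds {len(pt)} channels")
    order = {c: i for i, c in enumerate(pt.index)}
    ranked = sorted(pt.index, key=lambda c: (-pt[c], order[c]))
    return ranked[:k]


def export_node_edge(
    cube: ReservoirCube | SubtractedCube,
    cm: ClusterMap,
    node_path: str,
    edge_path: str,
) -> None:
    """Write brain-network-viewer text files: per-channel nodes
    (name x y z size) and the square FIN edge matrix."""
    pt = neuron_proportion(cm)
    tpl = cube.template
    with open(node_path, "w") as f:
        for c, i in tpl.input_map.items():
            x, y, z = tpl.coords[i]
            f.write(f"{c} {x:g} {y:g} {z:g} {pt[c]:.4f}\n")
    fin = feature_interaction_network(cube, cm)
    np.savetxt(edge_path, fin.to_numpy(), fmt="%.6g")
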