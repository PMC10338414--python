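"""Spiking neural network reservoir: small-world initialization, delayed LIF
dynamics, STDP training, and class-cube subtraction.

The reservoir is a population of leaky integrate-and-fire neurons at the
template coordinates.  Ordered neuron pairs (i, j) are connected independently
with probability

    P_ij = C · exp(-(d_norm / λ)²)   if d_norm ≤ d_thresh, else 0

where d_norm is the pair's Euclidean distance divided by the template's
maximum pairwise distance.  Connected pairs carry a signed weight (negative
when the presynaptic neuron is inhibitory) and an integer synaptic delay that
grows with distance.  Unsupervised training applies spike-timing-dependent
plasticity: a presynaptic spike shortly before a postsynaptic one potentiates
the synapse, the reverse order depresses it, with exponentially decaying
magnitude in the spike-time gap.  Two reservoirs trained from the *same*
random initialization on two classes of data are subtracted element-wise to
localize class-discriminative connectivity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import sparse

from ._kernels import lif_simulate_kernel, stdp_delta_kernel
from .encoding import SpikeTrains
from .template import BrainTemplate

__all__ = [
    "SWCConfig",
    "LIFConfig",
    "STDPConfig",
    "ReservoirCube",
    "SubtractedCube",
    "init_reservoir",
    "simulate",
    "stdp_train",
    "subtract",
    "connection_probabilities",
]


@dataclass(frozen=True)
class SWCConfig:
    """Small-world connectivity parameters (distances are normalized)."""

    C: float = 0.7             # max connection probability, at distance 0
    lam: float = 0.15          # small-world radius
    d_thresh: float = 0.2      # no connections beyond this distance
    p_inhibitory: float = 0.2  # per-presynaptic-neuron inhibition probability
    w_init_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.C <= 1):
            raise ValueError("C must be in (0, 1]")
        if self.lam <= 0 or self.d_thresh <= 0:
            raise ValueError("lam and d_thresh must be positive")
        if not (0 <= self.p_inhibitory < 1):
            raise ValueError("p_inhibitory must be in [0, 1)")
        if self.w_init_scale <= 0:
            raise ValueError("w_init_scale must be positive")


@dataclass(frozen=True)
class LIFConfig:
    """Leaky integrate-and-fire neuron and synaptic-delay parameters.

    ``leak`` is the per-step fractional potential decay (v ← v·(1−leak));
    delays are 1 + floor(d_norm · delay_max) steps.
    """

    v_threshold: float = 0.5
    leak: float = 0.1
    refractory: int = 2
    delay_max: int = 5

    def __post_init__(self) -> None:
        if self.v_threshold <= 0:
            raise ValueError("v_threshold must be positive")
        if not (0 <= self.leak < 1):
            raise ValueError("leak must be in [0, 1)")
        if self.refractory < 0 or self.delay_max < 0:
            raise ValueError("refractory and delay_max must be nonnegative")


@dataclass(frozen=True)
class STDPConfig:
    """STDP amplitudes and (single) time constant, in simulation steps."""

    A_plus: float = 0.002
    A_minus: float = 0.002
    t_plus: float = 3.0
    t_minus: float | None = None  # hook for a distinct anti-causal constant
    iterations: int = 1

    def __post_init__(self) -> None:
        if self.A_plus <= 0 or self.A_minus <= 0 or self.t_plus <= 0:
            raise ValueError("A_plus, A_minus, t_plus must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class ReservoirCube:
    """A (trainable) reservoir: CSR connectivity over the template.

    ``indptr``/``indices`` index presynaptic rows; ``w`` and ``d`` are the
    aligned weight and delay arrays.  The sparsity pattern is fixed at
    initialization; training changes only ``w``.
    """

    template: BrainTemplate
    indptr: np.ndarray
    indices: np.ndarray
    w: np.ndarray
    d: np.ndarray
    swc: SWCConfig
    lif: LIFConfig
    init_id: str
    trained_on: str | None = None

    @property
    def n_neurons(self) -> int:
        return self.template.n_neurons

    @property
    def weights(self) -> sparse.csr_matrix:
        n = self.n_neurons
        return sparse.csr_matrix((self.w, self.indices, self.indptr), shape=(n, n))

    @property
    def delays(self) -> sparse.csr_matrix:
        n = self.n_neurons
        return sparse.csr_matrix((self.d, self.indices, self.indptr), shape=(n, n))

    def copy(self) -> "ReservoirCube":
        return ReservoirCube(
            self.template, self.indptr, self.indices, self.w.copy(), self.d,
            self.swc, self.lif, self.init_id, self.trained_on,
        )


@dataclass
class SubtractedCube:
    """Element-wise weight difference of two identically initialized cubes."""

    template: BrainTemplate
    indptr: np.ndarray
    indices: np.ndarray
    w: np.ndarray              # dweights = A.w − B.w
    d: np.ndarray
    lif: LIFConfig
    init_id: str
    class_order: tuple[str, str]

    n_neurons = ReservoirCube.n_neurons
    weights = ReservoirCube.weights
    delays = ReservoirCube.delays

    @property
    def dweights(self) -> sparse.csr_matrix:
        return self.weights


def _normalized_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    dmax = dist.max()
    return dist / dmax if dmax > 0 else dist


def connection_probabilities(template: BrainTemplate, cfg: SWCConfig) -> np.ndarray:
    """Dense P_ij matrix of the small-world rule (zero diagonal)."""
    dn = _normalized_distances(template.coords)
    p = cfg.C * np.exp(-((dn / cfg.lam) ** 2))
    p[dn > cfg.d_thresh] = 0.0
    np.fill_diagonal(p, 0.0)
    return p


def init_reservoir(
    template: BrainTemplate, cfg: SWCConfig, lif: LIFConfig | None = None
) -> ReservoirCube:
    """Randomly initialize a reservoir with small-world connectivity.

    Weight magnitudes are uniform on (0, w_init_scale]; a neuron is inhibitory
    (all outgoing weights negative) with probability p_inhibitory.  Fully
    reproducible from ``cfg.seed``.
    """
    lif = lif or LIFConfig()
    rng = np.random.default_rng(cfg.seed)
    p = connection_probabilities(template, cfg)
    n = template.n_neurons
    conn = rng.random((n, n)) < p
    mag = cfg.w_init_scale * (1.0 - rng.random((n, n)))  # uniform on (0, scale]
    sign = np.where(rng.random(n) < cfg.p_inhibitory, -1.0, 1.0)
    dn = _normalized_distances(template.coords)
    delay = 1 + np.floor(dn * lif.delay_max).astype(np.int64)

    wmat = sparse.csr_matrix(np.where(conn, sign[:, None] * mag, 0.0))
    wmat.sort_indices()
    rows = np.repeat(np.arange(n), np.diff(wmat.indptr))
    dvals = delay[rows, wmat.indices]
    digest = hashlib.sha256(
        repr((cfg, lif.delay_max, n)).encode() + wmat.indices.tobytes()
    ).hexdigest()[:16]
    return ReservoirCube(
        template, wmat.indptr, wmat.indices, wmat.data.astype(np.float64),
        dvals, cfg, lif, init_id=digest,
    )


def _input_arrays(cube, inputs: SpikeTrains) -> tuple[np.ndarray, np.ndarray]:
    imap = cube.template.input_map
    missing = [c for c in inputs.channels if c not in imap]
    if missing:
        raise KeyError(f"channels not in template input map: {missing}")
    idx = np.array([imap[c] for c in inputs.channels], dtype=np.int64)
    return idx, np.ascontiguousarray(inputs.events)


def simulate(cube: ReservoirCube | SubtractedCube, inputs: SpikeTrains) -> np.ndarray:
    """Run spike trains through the cube; returns the signed firing record
    (neurons × time int8; input neurons carry their event signs)."""
    idx, events = _input_arrays(cube, inputs)
    lif = cube.lif
    return lif_simulate_kernel(
        cube.indptr, cube.indices, cube.w, cube.d, cube.n_neurons,
        idx, events, lif.v_threshold, lif.leak, int(lif.refractory),
        int(max(cube.d.max(initial=1), 1)),
    )


def stdp_train(
    cube: ReservoirCube,
    samples: Sequence[SpikeTrains],
    cfg: STDPConfig | None = None,
    label: str | None = None,
) -> ReservoirCube:
    """Train a copy of the cube with STDP over the given samples.

    Nearest-spike pairing within a window of 3·t_plus steps; weights are
    clipped to ±10·w_init_scale.  One pass per iteration, samples in order.
    """
    if len(samples) == 0:
        raise ValueError("stdp_train requires at least one sample")
    cfg = cfg or STDPConfig()
    out = cube.copy()
    window = int(np.ceil(3.0 * cfg.t_plus))
    w_max = 10.0 * cube.swc.w_init_scale
    for _ in range(cfg.iterations):
        for s in samples:
            rec = simulate(out, s)
            dw = stdp_delta_kernel(
                out.indptr, out.indices, rec,
                cfg.A_plus, cfg.A_minus, float(cfg.t_plus), window,
            )
            np.clip(out.w + dw, -w_max, w_max, out=out.w)
    out.trained_on = label
    return out


def subtract(cubeA: ReservoirCube, cubeB: ReservoirCube) -> SubtractedCube:
    """Class-difference cube: A.weights − B.weights on the shared pattern."""
    if cubeA.init_id != cubeB.init_id:
        raise ValueError(
            "cubes have different initializations "
            f"({cubeA.init_id} vs {cubeB.init_id}); subtraction is undefined"
        )
    return SubtractedCube(
        cubeA.template, cubeA.indptr, cubeA.indices, cubeA.w - cubeB.w,
        cubeA.d, cubeA.lif, cubeA.init_id,
        (cubeA.trained_on or "A", cubeB.trained_on or "B"),
    )
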