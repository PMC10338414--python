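"""Numba-compiled inner loops: SF encoding, delayed LIF simulation, STDP, SDSP.

All kernels are deterministic and operate on plain numpy arrays so the calling
modules stay free of compilation concerns.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "sf_encode_kernel",
    "lif_simulate_kernel",
    "stdp_delta_kernel",
    "sdsp_kernel",
]


@njit(cache=False)
def sf_encode_kernel(x: np.ndarray, threshold: float, base0: float) -> np.ndarray:
    n = x.shape[0]
    out = np.zeros(n, dtype=np.int8)
    base = base0
    for t in range(1, n):
        if x[t] > base + threshold:
            out[t] = 1
            base += threshold
        elif x[t] < base - threshold:
            out[t] = -1
            base -= threshold
    return out


@njit(cache=False)
def lif_simulate_kernel(
    indptr: np.ndarray,      # CSR over presynaptic rows
    indices: np.ndarray,
    weights: np.ndarray,
    delays: np.ndarray,      # int64, >= 1, aligned with weights
    n_neurons: int,
    input_idx: np.ndarray,   # reservoir indices of the input neurons
    input_events: np.ndarray,  # (n_inputs, T) int8 in {-1,0,1}
    v_threshold: float,
    leak: float,
    refractory: int,
    delay_max: int,
) -> np.ndarray:
    """Discrete-time LIF with per-connection integer delays.

    Input neurons are clamped to their event trains (signed spikes); all other
    neurons integrate delayed weighted input, fire at threshold, reset, and sit
    out `refractory` steps.  Returns the signed firing record (neurons x T).
    """
    T = input_events.shape[1]
    nbuf = delay_max + 1
    buf = np.zeros((nbuf, n_neurons))
    v = np.zeros(n_neurons)
    refr = np.zeros(n_neurons, dtype=np.int64)
    is_input = np.zeros(n_neurons, dtype=np.uint8)
    for a in range(input_idx.shape[0]):
        is_input[input_idx[a]] = 1
    rec = np.zeros((n_neurons, T), dtype=np.int8)

    for t in range(T):
        slot = t % nbuf
        for j in range(n_neurons):
            if is_input[j]:
                buf[slot, j] = 0.0
                continue
            if refr[j] > 0:
                refr[j] -= 1
                v[j] = 0.0
                buf[slot, j] = 0.0
                continue
            v[j] = v[j] * (1.0 - leak) + buf[slot, j]
            buf[slot, j] = 0.0
            if v[j] >= v_threshold:
                rec[j, t] = 1
                v[j] = 0.0
                refr[j] = refractory
        for a in range(input_idx.shape[0]):
            ev = input_events[a, t]
            if ev != 0:
                rec[input_idx[a], t] = ev
        # propagate this step's spikes to future buffer slots
        for jj in range(n_neurons):
            s = rec[jj, t]
            if s == 0:
                continue
            for k in range(indptr[jj], indptr[jj + 1]):
                buf[(t + delays[k]) % nbuf, indices[k]] += s * weights[k]
    return rec


@njit(cache=False)
def _spike_bounds(rec: np.ndarray):
    """Per neuron: previous-spike-at-or-before[t] (-1 if none) and
    next-spike-at-or-after[t] (T if none)."""
    n, T = rec.shape
    prev = np.empty((n, T), dtype=np.int64)
    nxt = np.empty((n, T), dtype=np.int64)
    for i in range(n):
        last = -1
        for t in range(T):
            if rec[i, t] != 0:
                last = t
            prev[i, t] = last
        nx = T
        for t in range(T - 1, -1, -1):
            if rec[i, t] != 0:
                nx = t
            nxt[i, t] = nx
    return prev, nxt


@njit(cache=False)
def stdp_delta_kernel(
    indptr: np.ndarray,
    indices: np.ndarray,
    rec: np.ndarray,        # signed firing record (neurons x T)
    a_plus: float,
    a_minus: float,
    t_plus: float,
    window: int,
) -> np.ndarray:
    """Weight increments per connection from nearest-spike STDP pairing.

    Each postsynaptic spike pairs with the nearest presynaptic spike within
    `window` steps; a causal pair (pre first) potentiates by
    A+·exp(-gap/t+), an anti-causal one depresses by A-·exp(-gap/t+).
    Simultaneous spikes (gap 0) and equidistant ties favour the causal branch.
    """
    n, T = rec.shape
    prev, nxt = _spike_bounds(rec)
    nnz = indices.shape[0]
    dw = np.zeros(nnz)
    for i in range(n):
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            acc = 0.0
            for t in range(T):
                if rec[j, t] == 0:
                    continue
                a = prev[i, t]
                b = nxt[i, t]
                ga = t - a if a >= 0 else T + 1
                gb = b - t if b < T else T + 1
                if ga <= gb:
                    if 0 < ga <= window:
                        acc += a_plus * np.exp(-ga / t_plus)
                else:
                    if 0 < gb <= window:
                        acc -= a_minus * np.exp(-gb / t_plus)
            dw[k] = acc
    return dw


@njit(cache=False)
def sdsp_kernel(
    w_init: np.ndarray,     # per-synapse RO initial weights
    rec: np.ndarray,        # (n_synapses, T) int8, nonzero = presynaptic spike
    drift_up: float,
    drift_down: float,
    w_high: float,
    w_low: float,
) -> np.ndarray:
    """Bi-stable spike-driven drift from each synapse's first spike onward."""
    S, T = rec.shape
    out = np.empty(S)
    for s in range(S):
        # first spike step; synapses that never spike keep w = 0 (RO ABSENT)
        fs = -1
        for t in range(T):
            if rec[s, t] != 0:
                fs = t
                break
        w = w_init[s]
        if fs < 0:
            out[s] = w
            continue
        for t in range(fs, T):
            if rec[s, t] != 0:
                w += drift_up
            else:
                w -= drift_down
            if w >= w_high:
                w = w_high
                break
            if w <= w_low:
                w = w_low
                break
        out[s] = w
    return out
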