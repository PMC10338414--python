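import numpy as np
import pytest

from spikecube.encoding import SpikeTrains
from spikecube.reservoir import LIFConfig, ReservoirCube, SWCConfig
from spikecube.template import BrainTemplate, build_template


@pytest.fixture(scope="session")
def template():
    return build_template()


@pytest.fixture(scope="session")
def reduced_template(template):
    return template.subsample(2)


def make_line_template(n: int = 3, frac: float = 0.5, channels=("A",)) -> BrainTemplate:
    """Collinear template: points at 0, frac·D and D so the (0,1) pair has
    normalized distance `frac`."""
    coords = np.array([[0.0, 0, 0], [10.0 * frac, 0, 0], [10.0, 0, 0]])[:n]
    idx = np.arange(len(channels))
    return BrainTemplate(coords, list(channels), idx)


def make_manual_cube(
    template: BrainTemplate,
    edges: list[tuple[int, int, float, int]],
    lif: LIFConfig | None = None,
    init_id: str = "manual",
) -> ReservoirCube:
    """Cube with an explicit edge list (pre, post, weight, delay)."""
    n = template.n_neurons
    dense_w = np.zeros((n, n))
    dense_d = np.zeros((n, n), dtype=np.int64)
    for i, j, w, d in edges:
        dense_w[i, j] = w
        dense_d[i, j] = d
    from scipy import sparse

    mask = dense_w != 0
    csr = sparse.csr_matrix(np.where(mask, dense_w, 0.0))
    csr.sort_indices()
    rows = np.repeat(np.arange(n), np.diff(csr.indptr))
    dvals = dense_d[rows, csr.indices]
    return ReservoirCube(
        template, csr.indptr, csr.indices, csr.data.astype(float), dvals,
        SWCConfig(), lif or LIFConfig(leak=0.0, refractory=0), init_id,
    )


def trains_from_events(events, channels=None, rate=500.0) -> SpikeTrains:
    events = np.atleast_2d(np.asarray(events, dtype=np.int8))
    channels = channels or [f"ch{i}" for i in range(events.shape[0])]
    return SpikeTrains(list(channels), events, rate)
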