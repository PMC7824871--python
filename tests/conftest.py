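import numpy as np
import pytest

from arisnn.encoding import SpikeSample
from arisnn.reservoir import (
    InputMapping,
    LIFParams,
    NeuronTemplate,
    ReservoirModel,
    STDPParams,
    SWCParams,
)


def make_toy_model(
    coords,
    edges,
    input_channels,
    lif=LIFParams(),
    stdp=STDPParams(),
    w_init=0.0,
):
    """Hand-wired reservoir for dynamics tests.

    ``edges`` is a list of (src, dst, signed_weight); ``input_channels`` maps
    channel label -> neuron index.
    """
    coords = np.asarray(coords, dtype=float)
    template = NeuronTemplate(coords=coords)
    if edges:
        src, dst, w = (np.asarray(a) for a in zip(*edges))
    else:
        src = dst = np.array([], dtype=np.int64)
        w = np.array([])
    order = np.lexsort((dst, src))
    mapping = InputMapping(
        channel_to_neuron=dict(input_channels),
        electrode_coords={k: coords[v] for k, v in input_channels.items()},
    )
    return ReservoirModel(
        template=template,
        mapping=mapping,
        src=src[order].astype(np.int64),
        dst=dst[order].astype(np.int64),
        sign=np.sign(np.asarray(w, dtype=float))[order] if len(w) else np.array([]),
        mag=np.abs(np.asarray(w, dtype=float))[order] if len(w) else np.array([]),
        swc=SWCParams(radius=1000.0, seed=0, w_init_max=max(w_init, 1e-9)),
        lif=lif,
        stdp=stdp,
    )


def spikes_from_matrix(matrix, channels, thresholds=None):
    """SpikeSample from an explicit channel x time matrix of {-1,0,+1}."""
    matrix = np.asarray(matrix, dtype=np.int8)
    if thresholds is None:
        thresholds = np.ones(matrix.shape[0])
    return SpikeSample(
        spikes=matrix,
        thresholds=np.asarray(thresholds, dtype=float),
        channels=tuple(channels),
    )


@pytest.fixture(scope="session")
def bundled_template():
    from arisnn.reservoir import load_talairach_template

    return load_talairach_template()


@pytest.fixture(scope="session")
def bundled_mapping(bundled_template):
    from arisnn.reservoir import default_input_mapping

    return default_input_mapping(bundled_template)


@pytest.fixture(scope="session")
def lattice_template():
    """27-neuron cubic lattice, 10 mm spacing."""
    axis = np.array([0.0, 10.0, 20.0])
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    return NeuronTemplate(coords=np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]))
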