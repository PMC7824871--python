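"""3D spiking reservoir: template, input mapping, SWC wiring, LIF dynamics, STDP.

The reservoir is a set of neurons at the centres of 1-cm^3 voxels of a
brain-shaped volume (1471 for the bundled template).  EEG channels are mapped
to their nearest neurons; connections are created by a distance-dependent
small-world rule and carry signed weights (excitatory >= 0, inhibitory <= 0)
whose magnitudes are shaped by spike-timing-dependent plasticity while the
network is driven by encoded EEG.  The connection *structure* is fixed at
initialization; learning only moves weight magnitudes within [0, w_max].
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .channels import electrode_positions_mm, fit_electrodes_to_extent
from .encoding import SpikeSample

BUNDLED_TEMPLATE_NEURONS = 1471


class TemplateIntegrityError(ValueError):
    pass


@dataclass(frozen=True)
class NeuronTemplate:
    """Reservoir neuron coordinates (mm)."""

    coords: np.ndarray  # (n, 3)

    @property
    def n_neurons(self) -> int:
        return self.coords.shape[0]

    def bounding_box_diagonal(self) -> float:
        span = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(np.sqrt((span**2).sum()))


@dataclass(frozen=True)
class InputMapping:
    """channel label -> reservoir neuron index, plus the coordinates used."""

    channel_to_neuron: dict[str, int]
    electrode_coords: dict[str, np.ndarray]

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_to_neuron)

    def neuron_indices(self) -> np.ndarray:
        return np.array(list(self.channel_to_neuron.values()), dtype=np.int64)


@dataclass(frozen=True)
class SWCParams:
    """Small-world connectivity initialization.

    Connection probability for an ordered pair at distance d is
    ``p0 * (1 - d / radius)`` for d <= radius, 0 beyond.  ``radius=None``
    defaults to one quarter of the template bounding-box diagonal.
    """

    radius: float | None = None
    p0: float = 0.15
    inhibitory_fraction: float = 0.2
    w_init_max: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius is not None and self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not 0 < self.p0 <= 1:
            raise ValueError("p0 must be in (0, 1]")
        if not 0 <= self.inhibitory_fraction < 1:
            raise ValueError("inhibitory_fraction must be in [0, 1)")
        if self.w_init_max < 0:
            raise ValueError("w_init_max must be >= 0")


@dataclass(frozen=True)
class LIFParams:
    """Discrete-time leaky integrate-and-fire constants."""

    threshold: float = 0.5
    decay: float = 0.9
    refractory: int = 1
    input_gain: float = 0.5

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0, 1)")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")


@dataclass(frozen=True)
class STDPParams:
    """Nearest-spike additive STDP.

    A connection i->j is potentiated by ``a_plus`` when j fires at t and i
    fired within the ``window`` steps before t (causal pre-then-post), and
    depressed by ``a_minus`` when a pre spike goes unanswered: i fired at
    t - window and j did not fire anywhere in (t - window, t].  Magnitudes
    are clipped to [0, w_max]; synapse sign never changes.  A single causal
    pairing therefore changes the weight by exactly +a_plus.
    """

    a_plus: float = 0.01
    a_minus: float = 0.01
    window: int = 1
    w_max: float = 1.0

    def __post_init__(self) -> None:
        if min(self.a_plus, self.a_minus, self.w_max) <= 0 or self.window <= 0:
            raise ValueError("STDP parameters must be positive")


@dataclass
class ReservoirModel:
    """Wired reservoir: coordinates, directed weighted connections, parameters.

    ``src``/``dst`` give the fixed connection structure (sorted by ``src``);
    ``sign`` is +1/-1 per connection (synapse type), ``mag`` the current
    weight magnitude.  Signed weights are ``sign * mag``.
    """

    template: NeuronTemplate
    mapping: InputMapping | None
    src: np.ndarray
    dst: np.ndarray
    sign: np.ndarray
    mag: np.ndarray
    swc: SWCParams
    lif: LIFParams = LIFParams()
    stdp: STDPParams = STDPParams()
    trained_on: dict = field(default_factory=dict)

    @property
    def n_connections(self) -> int:
        return self.src.shape[0]

    @property
    def weights(self) -> np.ndarray:
        return self.sign * self.mag

    def copy(self) -> "ReservoirModel":
        out = copy.copy(self)
        out.mag = self.mag.copy()
        out.trained_on = dict(self.trained_on)
        return out


@dataclass(frozen=True)
class ConnectivityDelta:
    """Signed elementwise weight difference between two structurally
    identical models (first minus second)."""

    template: NeuronTemplate
    mapping: InputMapping | None
    src: np.ndarray
    dst: np.ndarray
    delta: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return self.delta

    @property
    def n_connections(self) -> int:
        return self.src.shape[0]


def load_talairach_template(path=None) -> NeuronTemplate:
    """Load a reservoir template from CSV (columns x, y, z; mm).

    With no path the bundled synthetic 1471-neuron template is loaded (1-cm
    voxel centres inside a brain-sized ellipsoid, a stand-in for the
    atlas-derived coordinate list) and its neuron count is enforced.
    """
    expected = None
    if path is None:
        path = resources.files("arisnn.data") / "talairach_1471_synthetic.csv"
        expected = BUNDLED_TEMPLATE_NEURONS
    df = pd.read_csv(str(path))
    if list(df.columns) != ["x", "y", "z"]:
        raise TemplateIntegrityError(f"template {path}: expected columns x,y,z")
    coords = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise TemplateIntegrityError(f"template {path}: non-finite coordinates")
    if expected is not None and coords.shape[0] != expected:
        raise TemplateIntegrityError(
            f"template {path}: expected {expected} neurons, found {coords.shape[0]}"
        )
    if np.unique(coords, axis=0).shape[0] != coords.shape[0]:
        raise TemplateIntegrityError(f"template {path}: duplicate coordinates")
    return NeuronTemplate(coords=coords)


def map_inputs(
    template: NeuronTemplate, electrode_coords: dict[str, np.ndarray]
) -> InputMapping:
    """Map each channel to its nearest template neuron (Euclidean distance).

    Ties break toward the lowest neuron index.  Distinct electrode positions
    mapping onto the same neuron raise an error (the template is too coarse
    for the montage in that case).
    """
    mapping: dict[str, int] = {}
    coords = template.coords
    for label, pos in electrode_coords.items():
        pos = np.asarray(pos, dtype=float)
        if pos.shape != (3,):
            raise ValueError(f"electrode {label!r}: expected a 3-vector")
        d2 = ((coords - pos) ** 2).sum(axis=1)
        mapping[label] = int(np.argmin(d2))  # argmin takes the lowest index on ties
    taken: dict[int, str] = {}
    for label, idx in mapping.items():
        if idx in taken:
            other = taken[idx]
            if not np.allclose(electrode_coords[label], electrode_coords[other]):
                raise ValueError(
                    f"channels {other!r} and {label!r} map to the same neuron {idx}"
                )
        taken[idx] = label
    return InputMapping(
        channel_to_neuron=mapping,
        electrode_coords={k: np.asarray(v, float) for k, v in electrode_coords.items()},
    )


def default_input_mapping(template: NeuronTemplate) -> InputMapping:
    """Map the canonical 64-channel montage onto a template.

    Standard montage positions are rescaled onto the template extent before
    nearest-neighbour assignment.
    """
    elec = fit_electrodes_to_extent(electrode_positions_mm(), template.coords)
    return map_inputs(template, elec)


def _swc_probabilities(d: np.ndarray, radius: float, p0: float) -> np.ndarray:
    if radius <= 0:
        return np.zeros_like(d)
    p = np.where(d <= radius, p0 * (1.0 - d / radius), 0.0)
    np.fill_diagonal(p, 0.0)
    return p


def swc_radius(template: NeuronTemplate, params: SWCParams) -> float:
    if params.radius is not None:
        return params.radius
    return template.bounding_box_diagonal() / 4.0


def init_swc(
    template: NeuronTemplate,
    params: SWCParams,
    mapping: InputMapping | None = None,
    lif: LIFParams = LIFParams(),
    stdp: STDPParams = STDPParams(),
) -> ReservoirModel:
    """Wire a reservoir with the distance-dependent small-world rule.

    Every ordered pair (i, j), i != j, within ``radius`` receives a directed
    connection with probability ``p0 * (1 - d/radius)``.  Each connection is
    inhibitory with probability ``inhibitory_fraction``; initial magnitude is
    Uniform(0, w_init_max).  Deterministic given ``params.seed``.
    """
    coords = template.coords
    n = coords.shape[0]
    radius = swc_radius(template, params)
    rng = np.random.default_rng(params.seed)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    p = _swc_probabilities(d, radius, params.p0)
    connect = rng.random((n, n)) < p
    src, dst = np.nonzero(connect)
    e = src.shape[0]
    sign = np.where(
        rng.random(e) < params.inhibitory_fraction, -1.0, 1.0
    )
    mag = rng.uniform(0.0, params.w_init_max, size=e)
    order = np.lexsort((dst, src))
    return ReservoirModel(
        template=template,
        mapping=mapping,
        src=src[order].astype(np.int64),
        dst=dst[order].astype(np.int64),
        sign=sign[order],
        mag=mag[order],
        swc=replace(params, radius=radius),
        lif=lif,
        stdp=stdp,
    )


def expected_swc_edges(template: NeuronTemplate, params: SWCParams) -> tuple[float, float]:
    """Analytic mean and SD of the realized directed edge count."""
    coords = template.coords
    radius = swc_radius(template, params)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    p = _swc_probabilities(d, radius, params.p0)
    return float(p.sum()), float(np.sqrt((p * (1 - p)).sum()))


def _check_channels(model: ReservoirModel, spikes: SpikeSample) -> np.ndarray:
    if model.mapping is None:
        raise ValueError("model has no input mapping")
    if tuple(spikes.channels) != model.mapping.channels:
        raise ValueError("spike sample channels do not match the model input mapping")
    return model.mapping.neuron_indices()


def _simulate(
    model: ReservoirModel,
    spikes: SpikeSample,
    learn: bool,
) -> np.ndarray:
    """Run LIF dynamics over one sample; optionally apply STDP in place.

    Returns the binary reservoir firing raster (neurons x time).
    """
    input_neurons = _check_channels(model, spikes)
    n = model.template.n_neurons
    t_steps = spikes.n_steps
    lif, stdp = model.lif, model.stdp
    src, dst, sign = model.src, model.dst, model.sign
    mag = model.mag
    inp = spikes.spikes.astype(np.float64)

    v = np.zeros(n)
    refr = np.zeros(n, dtype=np.int64)
    raster = np.zeros((n, t_steps), dtype=np.uint8)
    fired = np.zeros(n, dtype=bool)
    # fired history, most recent first, for the STDP window and propagation
    history = [np.zeros(n, dtype=bool) for _ in range(stdp.window)]

    for t in range(t_steps):
        fired_prev = history[0]
        syn = np.zeros(n)
        if fired_prev.any():
            active = np.flatnonzero(fired_prev[src])
            if active.size:
                syn = np.bincount(
                    dst[active], weights=sign[active] * mag[active], minlength=n
                )
        drive = np.zeros(n)
        np.add.at(drive, input_neurons, lif.input_gain * inp[:, t])
        v = lif.decay * v + syn + drive
        eligible = refr == 0
        fired = (v >= lif.threshold) & eligible
        v[fired] = 0.0
        refr[refr > 0] -= 1
        refr[fired] = lif.refractory
        raster[:, t] = fired

        if learn:
            # potentiate: pre fired in the last `window` steps, post fires now
            pre_recent = history[0]
            for h in history[1:]:
                pre_recent = pre_recent | h
            # depress: pre fired `window` steps ago with no post spike since
            pre_old = history[-1]
            post_window = fired.copy()
            for h in history[:-1]:
                post_window |= h
            pot = pre_recent[src] & fired[dst]
            dep = pre_old[src] & ~post_window[dst]
            if pot.any():
                mag[pot] = np.minimum(mag[pot] + stdp.a_plus, stdp.w_max)
            if dep.any():
                mag[dep] = np.maximum(mag[dep] - stdp.a_minus, 0.0)

        history.insert(0, fired)
        history.pop()

    return raster


def run_sample(model: ReservoirModel, spikes: SpikeSample) -> np.ndarray:
    """Drive the reservoir with one spike sample (no learning).

    Returns the binary firing raster (neurons x time).  State starts from
    rest, so rasters are independent of presentation order.
    """
    return _simulate(model, spikes, learn=False)


def train_stdp(
    model: ReservoirModel, samples: list[SpikeSample], epochs: int = 1
) -> ReservoirModel:
    """Train connection magnitudes with STDP over the given samples.

    Neuron state resets between samples; weight updates accumulate in
    presentation order.  Returns a new model; the input is unmodified.
    """
    if not samples:
        raise ValueError("train_stdp requires at least one sample")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    out = model.copy()
    for _ in range(epochs):
        for s in samples:
            _simulate(out, s, learn=True)
    out.trained_on = dict(model.trained_on)
    out.trained_on["n_samples"] = len(samples) * epochs
    return out


def subtract_models(m_a: ReservoirModel, m_b: ReservoirModel) -> ConnectivityDelta:
    """Elementwise signed weight difference (A minus B) on the shared
    connection set; the two models must have identical structure."""
    if m_a.template.coords.shape != m_b.template.coords.shape or not np.array_equal(
        m_a.template.coords, m_b.template.coords
    ):
        raise ValueError("models use different templates")
    if not (np.array_equal(m_a.src, m_b.src) and np.array_equal(m_a.dst, m_b.dst)):
        raise ValueError("models have different connection structures")
    return ConnectivityDelta(
        template=m_a.template,
        mapping=m_a.mapping,
        src=m_a.src,
        dst=m_a.dst,
        delta=m_a.weights - m_b.weights,
    )


def activation_level(model: ReservoirModel | ConnectivityDelta) -> float:
    """Mean absolute connection weight of a model (or of a subtraction)."""
    if model.n_connections == 0:
        raise ValueError("model has no connections")
    return float(np.abs(model.weights).mean())


def save_model(model: ReservoirModel | ConnectivityDelta, path) -> None:
    """Write the connection list as CSV (i, j, weight, type) with a JSON
    metadata sidecar ``<path>.meta.json``."""
    w = model.weights
    kind = np.where(w >= 0, "excitatory", "inhibitory")
    pd.DataFrame({"i": model.src, "j": model.dst, "weight": w, "type": kind}).to_csv(
        path, index=False
    )
    meta = {"n_neurons": model.template.n_neurons, "n_connections": int(model.n_connections)}
    if isinstance(model, ReservoirModel):
        meta["trained_on"] = model.trained_on
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
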