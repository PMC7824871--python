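import numpy as np
import pytest

from arisnn.encoding import encode_tbr
from arisnn.reservoir import (
    LIFParams,
    STDPParams,
    SWCParams,
    TemplateIntegrityError,
    activation_level,
    expected_swc_edges,
    init_swc,
    load_talairach_template,
    map_inputs,
    run_sample,
    subtract_models,
    train_stdp,
)
from conftest import make_toy_model, spikes_from_matrix


class TestTemplate:
    def test_bundled_template_has_1471_unique_neurons(self, bundled_template):
        assert bundled_template.n_neurons == 1471
        assert (
            np.unique(bundled_template.coords, axis=0).shape[0]
            == bundled_template.n_neurons
        )

    def test_all_pairwise_distances_positive(self, bundled_template):
        c = bundled_template.coords
        d2 = ((c[:100, None] - c[None, :100]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        assert d2.min() > 0

    def test_duplicate_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("x,y,z\n0,0,0\n0,0,0\n1,1,1\n")
        with pytest.raises(TemplateIntegrityError, match="duplicate"):
            load_talairach_template(path)

    def test_malformed_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n0,0\n")
        with pytest.raises(TemplateIntegrityError):
            load_talairach_template(path)


class TestInputMapping:
    def test_exact_coordinate_maps_to_that_neuron(self, lattice_template):
        m = map_inputs(lattice_template, {"A": lattice_template.coords[13]})
        assert m.channel_to_neuron["A"] == 13

    def test_64_channels_give_64_distinct_neurons(self, bundled_mapping):
        idx = bundled_mapping.neuron_indices()
        assert idx.shape == (64,)
        assert len(set(idx.tolist())) == 64

    def test_small_perturbation_keeps_mapping(self, lattice_template):
        """Brute-force nearest-neighbour oracle: perturbing an electrode by
        less than half the lattice spacing never changes its neuron."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            base = lattice_template.coords[rng.integers(27)]
            shift = rng.uniform(-1, 1, 3)
            shift *= 4.9 / np.linalg.norm(shift)  # < half of 10 mm spacing
            pos = base + shift
            d2 = ((lattice_template.coords - pos) ** 2).sum(1)
            assert map_inputs(lattice_template, {"A": pos}).channel_to_neuron[
                "A"
            ] == int(np.argmin(d2))

    def test_missing_electrode_errors_by_name(self, lattice_template):
        with pytest.raises(ValueError, match="Bad"):
            map_inputs(lattice_template, {"Bad": np.zeros(2)})


class TestSWC:
    def test_radius_zero_gives_no_connections(self, lattice_template):
        model = init_swc(lattice_template, SWCParams(radius=0.0, seed=0))
        assert model.n_connections == 0

    def test_close_pair_connects_with_probability_one(self):
        model = make_toy_model([[0, 0, 0], [0.01, 0, 0]], [], {"A": 0})
        template = model.template
        got = init_swc(template, SWCParams(radius=1000.0, p0=1.0, seed=3))
        assert got.n_connections == 2  # both directed edges

    def test_edge_count_within_3sd_of_analytic_expectation(self, lattice_template):
        params = SWCParams(radius=25.0, p0=0.5, seed=7)
        mean, sd = expected_swc_edges(lattice_template, params)
        model = init_swc(lattice_template, params)
        assert abs(model.n_connections - mean) <= 3 * sd

    def test_weight_signs_match_synapse_type(self, lattice_template):
        model = init_swc(lattice_template, SWCParams(radius=30.0, seed=1))
        w = model.weights
        assert ((w >= 0) | (model.sign < 0)).all()
        assert (model.mag >= 0).all() and (model.mag <= model.swc.w_init_max).all()

    def test_deterministic_given_seed(self, lattice_template):
        a = init_swc(lattice_template, SWCParams(radius=30.0, seed=5))
        b = init_swc(lattice_template, SWCParams(radius=30.0, seed=5))
        assert np.array_equal(a.src, b.src) and np.allclose(a.mag, b.mag)


class TestDynamics:
    def test_no_input_no_firing(self):
        model = make_toy_model(
            [[0, 0, 0], [10, 0, 0]], [(0, 1, 0.9)], {"A": 0}
        )
        raster = run_sample(model, spikes_from_matrix(np.zeros((1, 20)), ["A"]))
        assert raster.sum() == 0

    def test_driven_input_neuron_fires_alone(self):
        model = make_toy_model([[0, 0, 0], [10, 0, 0]], [], {"A": 0})
        sp = spikes_from_matrix([[1, 1, 1, 1]], ["A"])
        raster = run_sample(model, sp)
        assert raster[0].sum() > 0
        assert raster[1].sum() == 0

    def test_two_neuron_chain_fires_one_step_later(self):
        """Hand simulation of the membrane recursion: with input gain 0.5 and
        threshold 0.5 the input neuron fires at t=1; a weight of 0.6 then
        drives the downstream neuron over threshold at t=2."""
        model = make_toy_model(
            [[0, 0, 0], [10, 0, 0]],
            [(0, 1, 0.6)],
            {"A": 0},
            lif=LIFParams(threshold=0.5, decay=0.9, refractory=0, input_gain=0.5),
        )
        sp = spikes_from_matrix([[0, 1, 0, 0, 0]], ["A"])
        raster = run_sample(model, sp)
        assert raster[0].tolist() == [0, 1, 0, 0, 0]
        assert raster[1].tolist() == [0, 0, 1, 0, 0]

    def test_firing_rate_monotone_in_input_gain(self, bundled_template, bundled_mapping):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(64, 64)).cumsum(axis=0)
        sp = encode_tbr(x, channels=bundled_mapping.channels)
        rates = []
        for gain in (0.1, 0.5, 1.0):
            model = init_swc(
                bundled_template,
                SWCParams(seed=4),
                bundled_mapping,
                lif=LIFParams(input_gain=gain),
            )
            rates.append(run_sample(model, sp).mean())
        assert rates[0] <= rates[1] <= rates[2]


class TestSTDP:
    def test_single_pre_post_pairing_adds_a_plus(self):
        """One causal pre->post pairing potentiates by exactly a_plus."""
        stdp = STDPParams(a_plus=0.01, a_minus=0.004, w_max=1.0)
        model = make_toy_model(
            [[0, 0, 0], [10, 0, 0]],
            [(0, 1, 0.6)],
            {"A": 0, "B": 1},
            lif=LIFParams(threshold=0.5, decay=0.9, refractory=0, input_gain=0.6),
            stdp=stdp,
        )
        # pre fires at t=1; its 0.6 weight drives post over threshold at t=2,
        # inside the plasticity window, so the pairing nets exactly +a_plus
        sp = spikes_from_matrix([[0, 1, 0], [0, 0, 0]], ["A", "B"])
        trained = train_stdp(model, [sp])
        assert trained.mag[0] == pytest.approx(0.6 + stdp.a_plus)

    def test_unanswered_pre_spike_depresses_by_a_minus(self):
        """A pre spike with no post response within the window loses a_minus."""
        stdp = STDPParams(a_plus=0.01, a_minus=0.004, w_max=1.0)
        model = make_toy_model(
            [[0, 0, 0], [10, 0, 0]],
            [(0, 1, 0.2)],  # too weak to fire the downstream neuron
            {"A": 0, "B": 1},
            lif=LIFParams(threshold=0.5, decay=0.9, refractory=0, input_gain=0.6),
            stdp=stdp,
        )
        sp = spikes_from_matrix([[0, 1, 0, 0], [0, 0, 0, 0]], ["A", "B"])
        trained = train_stdp(model, [sp])
        assert trained.mag[0] == pytest.approx(0.2 - stdp.a_minus)

    def test_no_firing_leaves_weights_unchanged(self):
        model = make_toy_model(
            [[0, 0, 0], [10, 0, 0]], [(0, 1, 0.3)], {"A": 0}
        )
        trained = train_stdp(model, [spikes_from_matrix(np.zeros((1, 30)), ["A"])])
        assert np.array_equal(trained.mag, model.mag)

    def test_training_returns_new_model_and_is_deterministic(
        self, bundled_template, bundled_mapping
    ):
        rng = np.random.default_rng(5)
        sp = encode_tbr(
            rng.normal(size=(96, 64)).cumsum(axis=0), channels=bundled_mapping.channels
        )
        model = init_swc(bundled_template, SWCParams(seed=6), bundled_mapping)
        before = model.mag.copy()
        t1 = train_stdp(model, [sp])
        t2 = train_stdp(model, [sp])
        assert np.array_equal(model.mag, before)  # input untouched
        assert np.array_equal(t1.mag, t2.mag)
        assert not np.array_equal(t1.mag, before)

    def test_weights_bounded_and_structure_fixed_after_long_training(self):
        rng = np.random.default_rng(8)
        stdp = STDPParams(a_plus=0.05, a_minus=0.02, w_max=0.3)
        model = make_toy_model(
            [[0, 0, 0], [10, 0, 0], [20, 0, 0]],
            [(0, 1, 0.2), (1, 2, -0.1), (0, 2, 0.25)],
            {"A": 0, "B": 1, "C": 2},
            lif=LIFParams(input_gain=0.6),
            stdp=stdp,
        )
        sp = spikes_from_matrix(rng.integers(-1, 2, size=(3, 50)), ["A", "B", "C"])
        trained = train_stdp(model, [sp], epochs=100)
        assert (trained.mag <= stdp.w_max + 1e-12).all()
        assert (trained.mag >= 0).all()
        assert np.array_equal(trained.src, model.src)
        assert np.array_equal(trained.sign, model.sign)  # synapse type never flips

    def test_empty_sample_list_rejected(self):
        model = make_toy_model([[0, 0, 0]], [], {"A": 0})
        with pytest.raises(ValueError):
            train_stdp(model, [])


class TestSubtractionAndActivation:
    def _pair(self):
        m = make_toy_model(
            [[0, 0, 0], [10, 0, 0]],
            [(0, 1, 0.4), (1, 0, 0.1)],
            {"A": 0},
        )
        other = m.copy()
        other.mag = np.array([0.1, 0.3])
        return m, other

    def test_self_subtraction_is_zero(self):
        m, _ = self._pair()
        assert np.allclose(subtract_models(m, m).delta, 0)

    def test_toy_subtraction_values_and_antisymmetry(self):
        m, other = self._pair()
        d = subtract_models(m, other)
        assert np.allclose(sorted(d.delta), sorted([0.3, -0.2]))
        assert np.allclose(
            subtract_models(other, m).delta, -d.delta
        )

    def test_structure_mismatch_rejected(self):
        m, _ = self._pair()
        other = make_toy_model([[0, 0, 0], [10, 0, 0]], [(0, 1, 0.4)], {"A": 0})
        with pytest.raises(ValueError):
            subtract_models(m, other)

    def test_activation_level_is_mean_magnitude(self):
        m = make_toy_model(
            [[0, 0, 0], [10, 0, 0]],
            [(0, 1, 0.2), (1, 0, -0.4)],
            {"A": 0},
        )
        assert activation_level(m) == pytest.approx(0.3)
        with pytest.raises(ValueError):
            activation_level(make_toy_model([[0, 0, 0]], [], {"A": 0}))
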