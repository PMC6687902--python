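import numpy as np
import pytest
from scipy.linalg import expm

from erpdcm.network import (
    ModelParameters,
    NetworkSpec,
    Population,
    linearized_jacobian,
    state_index,
)
from erpdcm.simulate import (
    SensorData,
    TimeGrid,
    apply_lead_field,
    exogenous_input,
    integrate,
    load_sensor_data,
    load_sensor_data_hdf5,
    predict_erp,
    save_sensor_data,
    save_sensor_data_hdf5,
)


def expm_response(J, forcing_vec, u_times, u_vals, sample_times):
    """Closed-form solution of x' = Jx + f*u(t) by piecewise-constant input.

    Independent linear-systems oracle: propagates the state with matrix
    exponentials on a fine grid, never touching the RK4 path under test.
    """
    x = np.zeros(J.shape[0])
    dt = u_times[1] - u_times[0]
    Phi = expm(J * dt)
    Jinv_f = np.linalg.solve(J, forcing_vec)
    out = []
    sample_iter = iter(sample_times)
    next_t = next(sample_iter, None)
    for t, u in zip(u_times, u_vals):
        if next_t is not None and t >= next_t - 1e-12:
            out.append(x.copy())
            next_t = next(sample_iter, None)
        # x(t+dt) = Phi x + (Phi - I) J^-1 f u   (u constant on the step)
        x = Phi @ x + (Phi @ Jinv_f - Jinv_f) * u
    while next_t is not None:
        out.append(x.copy())
        next_t = next(sample_iter, None)
    return np.array(out)


class TestTimeGrid:
    def test_default_matches_study_window(self):
        g = TimeGrid()
        assert g.n_samples == 150
        assert g.rate == 600.0
        assert np.isclose(g.times[-1], 0.25 - 1 / 600.0)


class TestExogenousInput:
    def test_peak_value(self):
        assert np.isclose(exogenous_input(0.06, 0.06, 0.016, 2.5), 2.5)

    def test_zero_amplitude(self):
        t = np.linspace(0, 0.25, 50)
        assert np.all(exogenous_input(t, 0.06, 0.016, 0.0) == 0.0)

    def test_even_symmetry(self):
        d = 0.013
        assert np.isclose(exogenous_input(0.06 + d, 0.06, 0.016),
                          exogenous_input(0.06 - d, 0.06, 0.016))

    def test_nonpositive_dispersion_fails(self):
        with pytest.raises(ValueError):
            exogenous_input(0.1, 0.06, 0.0)


class TestIntegrate:
    def test_zero_input_gives_zero(self, spec, template_params):
        p = template_params.copy()
        p.input_amplitude = 0.0
        resp = integrate(spec, p)
        assert np.all(resp.voltages == 0.0)

    def test_deterministic(self, spec, template_params):
        a = integrate(spec, template_params).voltages
        b = integrate(spec, template_params).voltages
        assert np.array_equal(a, b)

    def test_self_convergence_under_refinement(self, spec, template_params):
        coarse = integrate(spec, template_params, substeps=4).voltages
        fine = integrate(spec, template_params, substeps=8).voltages
        rel = np.linalg.norm(fine - coarse) / np.linalg.norm(fine)
        assert rel < 0.005

    def test_matches_matrix_exponential_oracle(self, spec, template_params):
        # small-amplitude regime: nonlinear response ~ linearised system
        p = template_params.copy()
        p.input_amplitude = 1e-3
        grid = TimeGrid()
        resp = integrate(spec, p, grid, substeps=8)
        J = linearized_jacobian(p, spec)
        from erpdcm.network import flow_matrices, N_POPULATIONS

        W, C, kappa = flow_matrices(p, spec, 0)
        f = np.zeros(spec.n_states)
        f[1::2] = kappa * C  # drive enters conductance equations
        n_fine = 20 * grid.n_samples
        tt = np.linspace(grid.start, grid.stop, n_fine, endpoint=False)
        uu = exogenous_input(tt, p.input_onset, p.input_dispersion,
                             p.input_amplitude)
        xs = expm_response(J, f, tt, uu, grid.times)
        v_oracle = xs[:, 0::2].T.reshape(spec.n_sources, N_POPULATIONS,
                                         grid.n_samples)
        rel = np.linalg.norm(resp.voltages - v_oracle) / np.linalg.norm(v_oracle)
        assert rel < 0.01

    def test_blow_up_raises(self, spec, template_params):
        p = template_params.copy()
        p.kappa = np.full(4, 3.5)  # absurd rate constants destabilise RK4
        with pytest.raises(FloatingPointError):
            integrate(spec, p)

    def test_kappa_doubling_halves_time_constants(self):
        # single isolated source, intrinsic coupling switched off: doubling
        # all rate constants compresses the impulse response in time
        # (v_2k(t) = v_k(2t)/2 once the input is compressed in step)
        spec = NetworkSpec(sources=("s",), forward_edges=(), backward_edges=(),
                           input_targets=("s",), modulated_edges=(),
                           design=(0.0,))
        base = ModelParameters(spec=spec, n_channels=1)
        base.g = np.full(3, -30.0)  # exp(-30) ~ 0: pure synaptic kernels
        base.input_onset = 0.02
        base.input_dispersion = 0.004
        slow = integrate(spec, base, TimeGrid(0.0, 0.25, 600.0), substeps=8)
        fast_p = base.copy()
        fast_p.kappa = np.full(4, np.log(2.0))
        fast_p.input_onset = base.input_onset / 2
        fast_p.input_dispersion = base.input_dispersion / 2
        fast = integrate(spec, fast_p, TimeGrid(0.0, 0.125, 1200.0), substeps=8)
        v_slow = slow.trace("s", Population.SPINY_STELLATE)
        v_fast = fast.trace("s", Population.SPINY_STELLATE)
        # fast sample k is at t_k/2 relative to slow trace sampled at t_k
        assert v_fast.shape == v_slow.shape
        rel = (np.linalg.norm(v_fast - v_slow / 2.0)
               / np.linalg.norm(v_slow / 2.0))
        assert rel < 0.01


class TestLeadField:
    def test_zero_response_gives_zero_sensors(self, spec, template_params):
        p = template_params.copy()
        p.input_amplitude = 0.0
        y = apply_lead_field(integrate(spec, p), p)
        assert np.all(y == 0.0)

    def test_identity_lead_selects_source_traces(self, spec, template_params):
        p = template_params.copy()
        p.lead_gain = np.eye(spec.n_sources)
        resp = integrate(spec, p)
        y = apply_lead_field(resp, p)
        for i, s in enumerate(spec.sources):
            assert np.allclose(y[i], resp.trace(s, Population.SUPERFICIAL_PYRAMIDAL))

    def test_homogeneity(self, spec, template_params):
        resp = integrate(spec, template_params)
        y1 = apply_lead_field(resp, template_params)
        resp.voltages = 2.0 * resp.voltages
        y2 = apply_lead_field(resp, template_params)
        assert np.allclose(y2, 2.0 * y1)


class TestPredictErp:
    def test_no_modulation_means_identical_conditions(self, spec, template_params):
        sd = predict_erp(spec, template_params)
        assert np.array_equal(sd.data[0], sd.data[1])

    def test_output_dimensions(self, scenario):
        spec, params, _ = scenario
        sd = predict_erp(spec, params)
        assert sd.data.shape == (2, 4, 150)

    def test_backward_disinhibition_raises_late_tpj_amplitude(self, spec,
                                                              template_params):
        p = template_params.copy()
        p.b = np.array([0.0, 0.0, -0.5, -0.5])
        early = integrate(spec, p, condition_index=0)
        late = integrate(spec, p, condition_index=1)
        amp = lambda r: np.abs(
            r.trace("rTPJ", Population.SUPERFICIAL_PYRAMIDAL)).max()
        assert amp(late) > amp(early)


class TestSensorDataIO:
    def test_csv_json_round_trip(self, noisy_dataset, tmp_path):
        data, _ = noisy_dataset
        save_sensor_data(data, tmp_path)
        back = load_sensor_data(tmp_path)
        assert np.allclose(back.data, data.data)
        assert back.grid == data.grid
        assert back.condition_labels == data.condition_labels
        assert back.design == data.design

    def test_hdf5_round_trip(self, noisy_dataset, tmp_path):
        data, _ = noisy_dataset
        path = tmp_path / "erp.h5"
        save_sensor_data_hdf5(data, path)
        back = load_sensor_data_hdf5(path)
        assert np.array_equal(back.data, data.data)
        assert back.grid == data.grid

    def test_mismatched_metadata_rejected(self, noisy_dataset):
        data, _ = noisy_dataset
        with pytest.raises(ValueError):
            SensorData(data=data.data, grid=data.grid,
                       condition_labels=("only_one",),
                       channel_labels=data.channel_labels,
                       design=data.design)
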