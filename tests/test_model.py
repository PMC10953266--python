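import numpy as np
import pytest
from scipy import signal

from sgm.connectome import Connectome
from sgm.model import (
    INITIAL_GUESSES,
    PARAM_BOUNDS,
    PARAM_NAMES,
    SGMParams,
    default_freq_grid,
    euler_local_simulation,
    gamma_response_ft,
    is_stable,
    local_transfer,
    model_spectrum,
    stability_polynomial,
)
from tests.conftest import draw_stable_uniform


class TestGammaResponse:
    def test_dc_is_unity(self):
        assert gamma_response_ft(0.01, 0.0) == 1.0 + 0.0j

    def test_omega_tau_one(self):
        # omega*tau = 1  ->  1/(1+i)^2 = -0.5i
        tau = 0.01
        f = 1.0 / (2.0 * np.pi * tau)
        val = gamma_response_ft(tau, f)
        assert abs(val - (-0.5j)) < 1e-12
        assert abs(abs(val) - 0.5) < 1e-12

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            gamma_response_ft(0.0, 5.0)

    def test_against_numeric_fourier_transform(self):
        # direct integration of the unit-area kernel (t/tau^2) e^{-t/tau}
        tau = 0.010
        dt = 1e-5
        t = np.arange(0, 0.5, dt)
        kernel = (t / tau**2) * np.exp(-t / tau)
        grid = default_freq_grid()
        for f in grid[::10]:
            numeric = np.trapezoid(kernel * np.exp(-2j * np.pi * f * t), dx=dt)
            exact = gamma_response_ft(tau, f)
            assert abs(numeric - exact) / abs(exact) < 1e-3


class TestLocalTransfer:
    def test_decoupled_dc_gain(self):
        p = SGMParams(tau_e=10, tau_i=10, g_ei=0.001, g_ii=0.5)
        xe, xi, h = local_transfer(p, 0.0)
        # with g_ei ~ 0, X_e ~ tau_e (a = F_e/tau_e at DC)
        assert abs(xe - 0.010) < 1e-4

    def test_block_diagonal_limit(self):
        p = SGMParams(tau_e=12, tau_i=40, g_ei=0.001, g_ii=0.7)
        f = np.array([3.0, 11.0, 27.0])
        omega = 2 * np.pi * f
        fe = gamma_response_ft(p.tau_e_s, f)
        fi = gamma_response_ft(p.tau_i_s, f)
        expected = 1.0 / (1j * omega + fe / p.tau_e_s) + 1.0 / (
            1j * omega + p.g_ii * fi / p.tau_i_s
        )
        _, _, h = local_transfer(p, f)
        # g_ei = 0.001 is not exactly zero; tolerance reflects the coupling
        assert np.abs(h - expected).max() < 2e-4

    def test_euler_simulation_psd_matches_transfer(self, table1_params):
        p = table1_params
        dt = 1e-4
        x = euler_local_simulation(p, duration=40.0, dt=dt, rng=np.random.default_rng(3))
        fs = 1.0 / dt
        freqs, pxx = signal.welch(x, fs=fs, nperseg=2**15)
        grid = default_freq_grid()
        emp = np.interp(grid, freqs, pxx)
        _, _, h = local_transfer(p, grid)
        r = np.corrcoef(emp, np.abs(h) ** 2)[0, 1]
        assert r > 0.95


class TestModelSpectrum:
    def test_uniform_graph_gives_identical_regions(self):
        n = 6
        w = np.ones((n, n)) - np.eye(n)
        conn = Connectome(w, np.zeros((n, n)), [f"r{i}" for i in range(n)])
        p = SGMParams(alpha=0.1)
        spec = model_spectrum(p, conn)
        assert np.abs(spec.psd_db - spec.psd_db[0]).max() < 1e-10

    def test_eigen_equals_direct_solve(self, conn10, table1_params):
        a = model_spectrum(table1_params, conn10, method="eigen").response
        b = model_spectrum(table1_params, conn10, method="solve").response
        assert np.abs(a - b).max() < 1e-8

    def test_table1_initials_finite_on_86_nodes(self, conn86, table1_params):
        spec = model_spectrum(table1_params, conn86, method="solve")
        assert np.all(np.isfinite(spec.psd_db[conn86.cortical_mask]))

    def test_psd_db_definition(self, conn10, table1_params):
        spec = model_spectrum(table1_params, conn10)
        assert np.abs(spec.psd_db - 20 * np.log10(np.abs(spec.response))).max() < 1e-12

    def test_mode_truncation_runs_and_differs(self, conn10, table1_params):
        full = model_spectrum(table1_params, conn10, method="eigen")
        trunc = model_spectrum(table1_params, conn10, method="eigen", n_modes=3)
        assert np.all(np.isfinite(trunc.psd_db))
        assert np.abs(full.psd_db - trunc.psd_db).max() > 1e-6

    def test_hermitian_modes_flag(self, conn10, table1_params):
        spec = model_spectrum(table1_params, conn10, method="eigen", hermitian_modes=True)
        assert np.all(np.isfinite(spec.psd_db))

    def test_conjugate_symmetry(self, conn10, table1_params):
        f = np.array([4.0, 9.0, 21.0])
        pos = model_spectrum(table1_params, conn10, f).response
        neg = model_spectrum(table1_params, conn10, -f[::-1]).response[:, ::-1]
        assert np.abs(pos.conj() - neg).max() < 1e-12

    def test_equivalence_over_random_draws(self, conn10):
        rng = np.random.default_rng(11)
        grid = default_freq_grid()[::4]
        for _ in range(50):
            p = draw_stable_uniform(rng)
            a = model_spectrum(p, conn10, grid, method="eigen").response
            b = model_spectrum(p, conn10, grid, method="solve").response
            assert np.abs(a - b).max() < 1e-8

    def test_psd_continuity_under_tiny_perturbation(self, conn10, table1_params):
        base = model_spectrum(table1_params, conn10).psd_db
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            val = getattr(table1_params, name)
            step = 1e-6 * (hi - lo)
            bumped = table1_params.replace(
                **{name: val - step if val + step > hi else val + step}
            )
            pert = model_spectrum(bumped, conn10).psd_db
            assert np.abs(pert - base).max() < 0.1


class TestModelSpectrumIO:
    def test_hdf5_and_csv_serialization(self, conn10, table1_params, tmp_path):
        import h5py
        import pandas as pd

        spec = model_spectrum(table1_params, conn10, method="solve")
        h5 = tmp_path / "spec.h5"
        spec.save_hdf5(h5)
        with h5py.File(h5) as fh:
            resp = fh["response_real"][()] + 1j * fh["response_imag"][()]
            assert np.array_equal(resp, spec.response)
            assert np.array_equal(fh["psd_db"][()], spec.psd_db)
        csv = tmp_path / "spec.csv"
        spec.save_csv(csv, labels=list(conn10.labels))
        back = pd.read_csv(csv, index_col=0)
        assert np.allclose(back.to_numpy(float), spec.psd_db)


class TestGraphResponseMonotonicity:
    def test_fg_magnitude_strictly_decreasing(self):
        f = default_freq_grid()
        mags = np.abs(gamma_response_ft(0.010, f))
        assert np.all(np.diff(mags) < 0)


class TestStability:
    def test_decoupled_always_stable(self):
        for g_ii in (0.1, 0.5, 1.0, 2.0):
            assert is_stable(SGMParams(g_ei=0.001, g_ii=g_ii))

    def test_table1_initials_stable(self):
        for guess in INITIAL_GUESSES:
            assert is_stable(SGMParams.from_vector(np.array(guess)))

    def test_polynomial_degree_six(self, table1_params):
        assert stability_polynomial(table1_params).size == 7

    def test_agreement_with_euler_boundedness(self):
        rng = np.random.default_rng(5)
        agree = 0
        n = 12
        for _ in range(n):
            p = SGMParams(**{nm: rng.uniform(*PARAM_BOUNDS[nm]) for nm in PARAM_NAMES})
            x = euler_local_simulation(p, duration=2.0, dt=2e-5, drive="impulse")
            fs = 1.0 / 2e-5
            m1 = np.max(np.abs(x[int(0.4 * fs) : int(1.0 * fs)]))
            m2 = np.max(np.abs(x[int(1.4 * fs) : int(2.0 * fs)]))
            bounded = (m2 < m1) or (m2 < 1e-10)
            agree += bounded == is_stable(p)
        assert agree >= n - 1

    def test_known_unstable_draw_detected(self):
        p = SGMParams(
            tau_e=20.9, tau_i=57.6, alpha=0.137, v=5.2, g_ei=0.57, g_ii=1.83, tau_G=20.2
        )
        assert not is_stable(p)

    def test_bad_method_and_truncation_args(self, conn10, table1_params):
        with pytest.raises(ValueError, match="method"):
            model_spectrum(table1_params, conn10, method="magic")
        with pytest.raises(ValueError, match="n_modes"):
            model_spectrum(table1_params, conn10, method="eigen", n_modes=0)
        with pytest.raises(ValueError, match="n_modes"):
            model_spectrum(table1_params, conn10, method="solve", n_modes=3)
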