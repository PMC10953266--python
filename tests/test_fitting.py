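import numpy as np
import pytest

from sgm.features import RegionalPSD
from sgm.fitting import (
    FitConfig,
    FitResult,
    GAIN_STAGES,
    _FastForward,
    alpha_band_power,
    fit_subject,
    progressive_refit,
    spatial_correlation,
    spectral_correlation,
)
from sgm.model import ModelSpectrum, SGMParams, default_freq_grid, model_spectrum

QUICK = dict(maxiter=20, maxfun=250, initial_guesses=(FitConfig().initial_guesses[0],))


def make_subject(params, conn, noise_db=0.0, seed=0, subject_id="s"):
    spec = model_spectrum(params, conn, method="solve")
    psd = spec.psd_db[conn.cortical_mask]
    if noise_db:
        psd = psd + noise_db * np.random.default_rng(seed).standard_normal(psd.shape)
    return RegionalPSD(spec.frequencies, psd, subject_id=subject_id)


class TestSpectralCorrelation:
    def test_self_is_one(self):
        x = np.random.default_rng(0).standard_normal((4, 20))
        assert spectral_correlation(x, x) == pytest.approx(1.0)

    def test_negated_is_minus_one(self):
        x = np.random.default_rng(0).standard_normal((4, 20))
        assert spectral_correlation(x, -x) == pytest.approx(-1.0)

    def test_hand_two_region_case(self):
        # region A: r = 1 exactly; region B: r = 0.5 by construction
        model = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        emp = np.array([[2.0, 4.0, 6.0], [0.0, -2.0, 2.0]])
        assert spectral_correlation(model, emp) == pytest.approx(0.75, abs=1e-12)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal((3, 30)), rng.standard_normal((3, 30))
        assert spectral_correlation(a, b) == pytest.approx(
            spectral_correlation(a, b + 17.3), abs=1e-12
        )

    def test_zero_variance_region_errors(self):
        a = np.ones((2, 5))
        with pytest.raises(ValueError, match="zero-variance"):
            spectral_correlation(a, np.random.default_rng(0).standard_normal((2, 5)))


class TestSpatialCorrelation:
    def test_identity_matrix_reduces_to_pearson(self):
        x = np.array([1.0, 4.0, 2.0, 7.0])
        c = np.zeros((4, 4))
        assert spatial_correlation(x, x, c) == pytest.approx(1.0, abs=1e-12)
        assert spatial_correlation(x, -x, c) == pytest.approx(-1.0, abs=1e-12)
        y = np.array([3.0, 1.0, 5.0, 2.0])
        assert spatial_correlation(x, y, c) == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-12
        )

    def test_three_region_hand_matrix_evaluation(self):
        # independent evaluation with explicit loops
        c = np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
        w = 10.0
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([3.0, 2.0, 1.0])
        m = c + w * np.eye(3)
        m = np.array([row / row.sum() for row in m])
        xz = (x - x.mean()) / x.std()
        yz = (y - y.mean()) / y.std()
        expected = 0.0
        for i in range(3):
            for j in range(3):
                expected += xz[i] * m[i, j] * yz[j]
        expected /= 3.0
        assert spatial_correlation(x, y, c, w) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            spatial_correlation(np.ones(3), np.arange(3.0), np.zeros((3, 3)))


class TestAlphaBandPower:
    def test_flat_model_spectrum(self):
        grid = default_freq_grid()
        resp = np.full((1, grid.size), 2.0 + 0j)
        spec = ModelSpectrum(grid, resp, 20 * np.log10(np.abs(resp)))
        # nine 0.5 Hz points in [8, 12], |X|^2 = 4 each
        assert alpha_band_power(spec) == pytest.approx([36.0])

    def test_band_outside_grid_errors(self):
        grid = default_freq_grid()
        with pytest.raises(ValueError, match="band"):
            alpha_band_power(np.zeros((1, grid.size)), (40.0, 50.0), grid)

    def test_delog_roundtrip(self):
        power = np.array([[1.5, 2.5, 4.0]])
        db = 10.0 * np.log10(power)
        back = alpha_band_power(db, (0.5, 3.5), np.array([1.0, 2.0, 3.0]))
        assert back == pytest.approx(power.sum(), abs=1e-12)


class TestFitConfig:
    def test_default_has_three_guesses_and_three_stages(self):
        cfg = FitConfig()
        assert len(cfg.initial_guesses) == 3
        assert len(cfg.gain_stages) == 3

    def test_stages_non_expanding(self):
        for prev, cur in zip(GAIN_STAGES, GAIN_STAGES[1:]):
            for (plo, phi), (clo, chi) in zip(prev, cur):
                assert clo >= plo and chi <= phi

    def test_expanding_stages_rejected(self):
        with pytest.raises(ValueError, match="non-expanding"):
            FitConfig(gain_stages=(((0.001, 0.4), (0.001, 1.5)), ((0.001, 0.7), (0.001, 2.0))))


class TestFastForward:
    def test_matches_model_spectrum(self, conn12):
        ff = _FastForward(conn12, default_freq_grid())
        rng = np.random.default_rng(3)
        from tests.conftest import draw_stable_uniform

        for _ in range(5):
            p = draw_stable_uniform(rng)
            a = ff.response(p)
            b = model_spectrum(p, conn12, method="solve").response
            assert np.abs(a - b).max() < 1e-12


class TestFitSubject:
    def test_determinism(self, conn12, table1_params):
        emp = make_subject(table1_params, conn12)
        cfg = FitConfig(seed=9, **QUICK)
        r1 = fit_subject(emp, conn12, cfg)
        r2 = fit_subject(emp, conn12, cfg)
        assert r1.params == r2.params
        assert r1.objective == r2.objective
        assert (r1.stage_used, r1.start_index) == (r2.stage_used, r2.start_index)

    def test_noiseless_recovery_tau_g(self, conn20):
        truth = SGMParams(tau_e=14, tau_i=50, alpha=0.6, v=10, g_ei=0.3, g_ii=0.5, tau_G=12)
        truth.validate()
        emp = make_subject(truth, conn20)
        res = fit_subject(emp, conn20, FitConfig(seed=2, maxiter=20, maxfun=250))
        assert abs(res.params.tau_G - truth.tau_G) / truth.tau_G < 0.15
        assert res.spectral_corr > 0.99

    def test_objective_consistency(self, conn12, table1_params):
        emp = make_subject(table1_params, conn12, noise_db=1.0, seed=3)
        res = fit_subject(emp, conn12, FitConfig(seed=5, **QUICK))
        assert res.objective == pytest.approx(
            res.spectral_corr + res.spatial_corr, abs=1e-12
        )
        assert -1 <= res.spectral_corr <= 1

    def test_accepted_result_is_stable(self, conn12, table1_params):
        from sgm.model import is_stable

        emp = make_subject(table1_params, conn12, noise_db=2.0, seed=4)
        res = fit_subject(emp, conn12, FitConfig(seed=6, **QUICK))
        assert is_stable(res.params)

    def test_region_count_mismatch_errors(self, conn12, table1_params):
        spec = model_spectrum(table1_params, conn12)
        emp = RegionalPSD(spec.frequencies, spec.psd_db)  # all regions, not masked
        with pytest.raises(ValueError, match="mask"):
            fit_subject(emp, conn12, FitConfig(**QUICK))

    def test_json_roundtrip(self, conn12, table1_params, tmp_path):
        import json

        emp = make_subject(table1_params, conn12)
        res = fit_subject(emp, conn12, FitConfig(seed=1, **QUICK))
        path = tmp_path / "fit.json"
        res.save_json(path)
        data = json.loads(path.read_text())
        assert data["params"]["tau_G"] == pytest.approx(res.params.tau_G)
        assert data["stage_used"] == res.stage_used


class TestProgressiveRefit:
    def test_tau_g_step_dominates(self, conn12):
        base = dict(tau_e=14.0, tau_i=50.0, alpha=0.6, v=10.0, g_ei=0.3, g_ii=0.5)
        tau_gs = [6.0, 10.0, 16.0]
        subjects, fits = [], []
        for i, tg in enumerate(tau_gs):
            p = SGMParams(**base, tau_G=tg)
            subjects.append(make_subject(p, conn12, subject_id=f"s{i}"))
            fits.append(
                FitResult(
                    params=p,
                    spectral_corr=1.0,
                    spatial_corr=1.0,
                    objective=2.0,
                    per_region_r=np.ones(conn12.n_cortical),
                    stage_used=0,
                    start_index=0,
                )
            )
        cfg = FitConfig(seed=3, maxiter=15, maxfun=150)
        order = ("tau_G", "tau_e", "g_ii")
        curve = progressive_refit(fits, subjects, conn12, cfg, order=order)
        assert len(curve) == len(order) + 1
        # nothing optimized can not beat the full fit of matched spectra
        assert curve[0] <= 1.0 + 1e-9
        gains = np.diff(curve)
        assert np.argmax(gains) == 0  # freeing tau_G gives the largest jump
        assert curve[1] > curve[0]

    def test_empty_cohort_errors(self, conn12):
        with pytest.raises(ValueError, match="empty"):
            progressive_refit([], [], conn12, FitConfig(**QUICK))

    def test_unknown_order_name_errors(self, conn12, table1_params):
        emp = make_subject(table1_params, conn12)
        fit = FitResult(
            params=table1_params,
            spectral_corr=1.0,
            spatial_corr=1.0,
            objective=2.0,
            per_region_r=np.ones(conn12.n_cortical),
            stage_used=0,
            start_index=0,
        )
        with pytest.raises(ValueError, match="unknown parameter"):
            progressive_refit([fit], [emp], conn12, FitConfig(**QUICK), order=("tau_X",))
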