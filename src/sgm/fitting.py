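"""Per-subject parameter inference against empirical regional spectra.

The objective is the sum of the spectral correlation (mean over regions
of Pearson r between model and data dB spectra) and the spatial
correlation (connectome-smoothed correlation of regional alpha-band raw
power maps). Optimization runs dual annealing from three starting
points, with up to three successively tighter gain-bound stages to land
inside the stability region.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import dual_annealing

from sgm.connectome import Connectome, degree_normalize
from sgm.features import RegionalPSD
from sgm.model import (
    INITIAL_GUESSES,
    PARAM_BOUNDS,
    PARAM_NAMES,
    ModelSpectrum,
    SGMParams,
    default_freq_grid,
    is_stable,
    model_spectrum,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "FitError",
    "spectral_correlation",
    "spatial_correlation",
    "alpha_band_power",
    "fit_subject",
    "progressive_refit",
]

#: Successively tighter (g_ei, g_ii) bounds used to steer the optimizer
#: back inside the stability region.
GAIN_STAGES: tuple[tuple[tuple[float, float], tuple[float, float]], ...] = (
    ((0.001, 0.7), (0.001, 2.0)),
    ((0.001, 0.5), (0.001, 1.5)),
    ((0.001, 0.4), (0.001, 1.5)),
)

_UNSTABLE_PENALTY = 10.0


class FitError(RuntimeError):
    """Raised when no stable parameter set is found across all stages."""


@dataclass(frozen=True)
class FitConfig:
    """Settings for per-subject inference."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PARAM_BOUNDS)
    )
    gain_stages: tuple = GAIN_STAGES
    initial_guesses: tuple = INITIAL_GUESSES
    maxiter: int = 500
    maxfun: int = int(1e7)
    spatial_weight: float = 10.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    seed: int = 0
    n_modes: int | None = None
    normalization: str = "row"

    def __post_init__(self) -> None:
        if self.maxiter < 1:
            raise ValueError("maxiter must be >= 1")
        if len(self.initial_guesses) < 1:
            raise ValueError("at least one initial guess required")
        prev = None
        for stage in self.gain_stages:
            for i, (lo, hi) in enumerate(stage):
                if prev is not None and (lo < prev[i][0] or hi > prev[i][1]):
                    raise ValueError("gain stages must be non-expanding")
            prev = stage


@dataclass(frozen=True)
class FitResult:
    """Accepted parameter estimate with goodness-of-fit provenance."""

    params: SGMParams
    spectral_corr: float
    spatial_corr: float
    objective: float
    per_region_r: np.ndarray
    stage_used: int
    start_index: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "spectral_corr": self.spectral_corr,
            "spatial_corr": self.spatial_corr,
            "objective": self.objective,
            "per_region_r": [float(r) for r in self.per_region_r],
            "stage_used": self.stage_used,
            "start_index": self.start_index,
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r between two equal-shape matrices."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        bad = int(np.argmin(np.minimum(na, nb)))
        raise ValueError(f"zero-variance spectrum in region index {bad}")
    return (a * b).sum(axis=1) / (na * nb)


def spectral_correlation(model_psd_db: np.ndarray, emp_psd_db: np.ndarray) -> float:
    """Mean over regions of Pearson r between dB spectra across frequencies."""
    model_psd_db = np.asarray(model_psd_db, dtype=float)
    emp_psd_db = np.asarray(emp_psd_db, dtype=float)
    if model_psd_db.shape != emp_psd_db.shape:
        raise ValueError(
            f"shape mismatch: {model_psd_db.shape} vs {emp_psd_db.shape}"
        )
    return float(_pearson_rows(model_psd_db, emp_psd_db).mean())


def _smoothing_matrix(c_rownorm: np.ndarray, w: float) -> np.ndarray:
    m = np.asarray(c_rownorm, dtype=float) + w * np.eye(c_rownorm.shape[0])
    return m / m.sum(axis=1, keepdims=True)


def spatial_correlation(
    x: np.ndarray, y: np.ndarray, c_rownorm: np.ndarray, w: float = 10.0
) -> float:
    """Connectome-smoothed correlation of two regional power maps.

    Both maps are z-scored (population convention) and combined as
    ``x~^T M y~ / N`` with ``M`` the row-normalized ``C + w I``. With
    zero connectivity (M = I) this is exactly the Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant regional power vector")
    xz = (x - x.mean()) / sx
    yz = (y - y.mean()) / sy
    m = _smoothing_matrix(c_rownorm, w)
    return float(xz @ m @ yz / x.size)


def alpha_band_power(
    spectrum: ModelSpectrum | RegionalPSD | np.ndarray,
    band: tuple[float, float] = (8.0, 12.0),
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Regional raw power summed over grid points inside ``band``.

    Model spectra contribute ``|X(f)|^2``; empirical dB spectra are
    de-logged with ``10**(dB/10)`` before summation.
    """
    lo, hi = band
    if hi <= lo:
        raise ValueError(f"empty band {band}")
    if isinstance(spectrum, ModelSpectrum):
        freqs = spectrum.frequencies
        power = np.abs(spectrum.response) ** 2
    elif isinstance(spectrum, RegionalPSD):
        freqs = spectrum.frequencies
        power = 10.0 ** (spectrum.psd_db / 10.0)
    else:
        if freqs is None:
            raise ValueError("freqs required for raw-array input")
        power = 10.0 ** (np.asarray(spectrum, dtype=float) / 10.0)
    freqs = np.asarray(freqs, dtype=float)
    sel = (freqs >= lo) & (freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"band {band} outside frequency grid")
    return power[:, sel].sum(axis=1)


def _anneal_seed(base_seed: int, subject_id: str, stage: int, start: int) -> int:
    key = f"{base_seed}|{subject_id}|{stage}|{start}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little")


class _FastForward:
    """Batched direct-solve forward model with precomputed phase bases.

    Numerically identical to ``model_spectrum(..., method='solve')`` but
    amortizes everything that does not depend on the parameter vector;
    used inside the annealing objective where it is the hot path.
    """

    def __init__(self, conn: Connectome, freqs: np.ndarray, mode: str = "row"):
        from sgm.model import gamma_response_ft, local_transfer  # cycle-free

        self._gamma = gamma_response_ft
        self._local = local_transfer
        self.freqs = np.asarray(freqs, dtype=float)
        self.omega = 2.0 * np.pi * self.freqs
        self.cnorm = degree_normalize(conn.weights, mode=mode)
        # phase per unit (1/v): omega * d / 1000, shape F x N x N
        self.phase_base = self.omega[:, None, None] * (conn.distances / 1000.0)
        n = conn.n_regions
        self.eye = np.eye(n)
        self.ones = np.ones((self.freqs.size, n, 1))
        self.iwI = (1j * self.omega)[:, None, None] * self.eye[None, :, :]

    def response(self, params: SGMParams) -> np.ndarray:
        """Regions x frequencies complex response under unit drive."""
        tg = params.tau_G_s
        fg = self._gamma(tg, self.freqs)
        _, _, h_local = self._local(params, self.freqs)
        L = self.eye[None, :, :] - params.alpha * self.cnorm[None, :, :] * np.exp(
            (-1j / params.v) * self.phase_base
        )
        A = self.iwI + (fg / tg)[:, None, None] * L
        x = np.linalg.solve(A, self.ones)
        return (x[..., 0] * h_local[:, None]).T


class _Objective:
    """Negative (spectral + spatial) correlation for a fixed subject."""

    def __init__(self, emp: RegionalPSD, conn: Connectome, cfg: FitConfig):
        self.conn = conn
        self.cfg = cfg
        self.freqs = np.asarray(emp.frequencies, dtype=float)
        self.emp_db = np.asarray(emp.psd_db, dtype=float)
        self.mask = conn.cortical_mask
        if self.emp_db.shape[0] != int(self.mask.sum()):
            raise ValueError(
                f"empirical PSD has {self.emp_db.shape[0]} regions, "
                f"connectome mask selects {int(self.mask.sum())}"
            )
        self.emp_alpha = alpha_band_power(self.emp_db, cfg.alpha_band, self.freqs)
        self.c_rownorm = degree_normalize(conn.weights, mode="row")[self.mask][
            :, self.mask
        ]
        self.alpha_sel = (self.freqs >= cfg.alpha_band[0]) & (
            self.freqs <= cfg.alpha_band[1]
        )
        self._fast = (
            _FastForward(conn, self.freqs, mode=cfg.normalization)
            if cfg.n_modes is None
            else None
        )

    def _response(self, params: SGMParams) -> np.ndarray:
        if self._fast is not None:
            return self._fast.response(params)
        spec = model_spectrum(
            params,
            self.conn,
            self.freqs,
            mode=self.cfg.normalization,
            method="eigen",
            n_modes=self.cfg.n_modes,
        )
        return spec.response

    def evaluate(self, params: SGMParams) -> tuple[float, float, np.ndarray]:
        """Return (spectral_corr, spatial_corr, per-region r)."""
        response = self._response(params)[self.mask]
        mag = np.abs(response)
        if not np.all(np.isfinite(mag)) or np.any(mag <= 0):
            raise FloatingPointError("non-finite model response")
        model_db = 20.0 * np.log10(mag)
        per_region = _pearson_rows(model_db, self.emp_db)
        model_alpha = (mag[:, self.alpha_sel] ** 2).sum(axis=1)
        s = spatial_correlation(
            model_alpha, self.emp_alpha, self.c_rownorm, self.cfg.spatial_weight
        )
        return float(per_region.mean()), s, per_region

    def __call__(self, x: np.ndarray) -> float:
        try:
            r, s, _ = self.evaluate(SGMParams.from_vector(x))
        except (FloatingPointError, ValueError):
            return _UNSTABLE_PENALTY
        if not np.isfinite(r + s):
            return _UNSTABLE_PENALTY
        return -(r + s)


def _stage_bounds(cfg: FitConfig, stage: int) -> list[tuple[float, float]]:
    gei_b, gii_b = cfg.gain_stages[stage]
    bounds = dict(cfg.bounds)
    bounds["g_ei"] = gei_b
    bounds["g_ii"] = gii_b
    return [bounds[name] for name in PARAM_NAMES]


def _clip_to_bounds(x: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def fit_subject(
    emp_psd: RegionalPSD,
    conn: Connectome,
    cfg: FitConfig | None = None,
    subject_id: str | None = None,
) -> FitResult:
    """Infer SGM parameters for one subject.

    For each gain stage in order, dual annealing runs from every initial
    guess (deterministically seeded from ``cfg.seed``, subject id, stage
    and start index); the best-objective candidate is accepted if stable,
    otherwise the next, tighter stage runs. If no stage's winner is
    stable, the best stable candidate seen anywhere is accepted; with
    none at all a :class:`FitError` is raised.
    """
    cfg = cfg or FitConfig()
    sid = subject_id if subject_id is not None else getattr(emp_psd, "subject_id", "")
    obj = _Objective(emp_psd, conn, cfg)
    best_stable: tuple[float, SGMParams, int, int] | None = None

    for stage in range(len(cfg.gain_stages)):
        bounds = _stage_bounds(cfg, stage)
        stage_best: tuple[float, SGMParams, int] | None = None
        for start, guess in enumerate(cfg.initial_guesses):
            x0 = _clip_to_bounds(np.asarray(guess, dtype=float), bounds)
            res = dual_annealing(
                obj,
                bounds=bounds,
                x0=x0,
                maxiter=cfg.maxiter,
                maxfun=cfg.maxfun,
                seed=_anneal_seed(cfg.seed, str(sid), stage, start),
            )
            cand = SGMParams.from_vector(_clip_to_bounds(res.x, bounds))
            val = float(res.fun)
            if stage_best is None or val < stage_best[0]:
                stage_best = (val, cand, start)
            if is_stable(cand) and (best_stable is None or val < best_stable[0]):
                best_stable = (val, cand, stage, start)
        assert stage_best is not None
        if is_stable(stage_best[1]):
            return _make_result(obj, stage_best[1], stage, stage_best[2])

    if best_stable is None:
        raise FitError(
            f"no stable parameter set found for subject {sid!r} "
            f"across {len(cfg.gain_stages)} stages"
        )
    _, params, stage, start = best_stable
    return _make_result(obj, params, stage, start)


def _make_result(
    obj: _Objective, params: SGMParams, stage: int, start: int
) -> FitResult:
    r, s, per_region = obj.evaluate(params)
    return FitResult(
        params=params,
        spectral_corr=r,
        spatial_corr=s,
        objective=r + s,
        per_region_r=per_region,
        stage_used=stage,
        start_index=start,
    )


def progressive_refit(
    cohort_fits: list[FitResult],
    emp_psds: list[RegionalPSD],
    conn: Connectome,
    cfg: FitConfig | None = None,
    order: tuple[str, ...] = ("tau_G", "tau_e", "g_ii", "g_ei", "tau_i", "alpha", "v"),
) -> list[float]:
    """Mean spectral correlation as parameters are progressively freed.

    Step 0 fixes every parameter at the grand mean of the cohort's
    fitted values (no optimization). Step m frees the first m names in
    ``order`` and refits each subject over those dimensions only, the
    rest pinned at the grand means. Returns one mean spectral
    correlation per step (length ``len(order) + 1``).
    """
    cfg = cfg or FitConfig()
    if not cohort_fits:
        raise ValueError("empty cohort")
    unknown = set(order) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter names in order: {sorted(unknown)}")
    grand = np.mean([f.params.to_vector() for f in cohort_fits], axis=0)
    grand_params = SGMParams.from_vector(grand)
    curve: list[float] = []

    # step 0: nothing free
    step0 = []
    for emp in emp_psds:
        obj = _Objective(emp, conn, cfg)
        r, _, _ = obj.evaluate(grand_params)
        step0.append(r)
    curve.append(float(np.mean(step0)))

    for m in range(1, len(order) + 1):
        free = order[:m]
        free_idx = [PARAM_NAMES.index(n) for n in free]
        rs = []
        for si, emp in enumerate(emp_psds):
            obj = _Objective(emp, conn, cfg)
            bounds = [_stage_bounds(cfg, 0)[i] for i in free_idx]

            def sub_obj(xfree: np.ndarray) -> float:
                x = grand.copy()
                x[free_idx] = xfree
                return obj(x)

            x0 = _clip_to_bounds(grand[free_idx], bounds)
            res = dual_annealing(
                sub_obj,
                bounds=bounds,
                x0=x0,
                maxiter=cfg.maxiter,
                maxfun=cfg.maxfun,
                seed=_anneal_seed(cfg.seed, f"prog{si}", m, 0),
            )
            x = grand.copy()
            x[free_idx] = res.x
            r, _, _ = obj.evaluate(SGMParams.from_vector(_clip_to_bounds(x, _stage_bounds(cfg, 0))))
            rs.append(r)
        curve.append(float(np.mean(rs)))
    return curve
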