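"""Closed-form forward model of regional steady-state frequency response.

Each region holds excitatory and inhibitory subpopulations whose
interactions define a local transfer function ``H_local(w)``; long-range
excitatory populations couple through the connectome via the complex
Laplacian. The network response at angular frequency ``w`` is

    X(w) = U(w) diag( 1 / (j w + tau_G^-1 lambda_k(w) F_G(w)) ) U(w)^-1
           * H_local(w) * 1

with ``F_G`` the Fourier transform of the Gamma-shaped ensemble response
and unit white-noise drive. PSD in dB is ``20 log10 |X|``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from sgm.connectome import Connectome, complex_laplacian, degree_normalize, eigensystem

__all__ = [
    "SGMParams",
    "ModelSpectrum",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "INITIAL_GUESSES",
    "default_freq_grid",
    "gamma_response_ft",
    "local_transfer",
    "model_spectrum",
    "network_transfer_matrix",
    "is_stable",
    "stability_polynomial",
    "euler_local_simulation",
]

#: Optimizer parameter order (time constants in ms, speed in m/s).
PARAM_NAMES: tuple[str, ...] = ("tau_e", "tau_i", "alpha", "v", "g_ei", "g_ii", "tau_G")

#: Outer optimization bounds, same order and units as PARAM_NAMES.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "tau_e": (5.0, 30.0),
    "tau_i": (5.0, 200.0),
    "alpha": (0.1, 1.0),
    "v": (5.0, 20.0),
    "g_ei": (0.001, 0.7),
    "g_ii": (0.001, 2.0),
    "tau_G": (5.0, 30.0),
}

#: Three optimizer starting points, same order as PARAM_NAMES.
INITIAL_GUESSES: tuple[tuple[float, ...], ...] = (
    (15.0, 10.0, 1.0, 5.0, 0.3, 0.6, 6.0),
    (25.0, 8.0, 0.5, 10.0, 0.2, 0.1, 15.0),
    (6.0, 150.0, 0.1, 18.0, 0.1, 1.2, 25.0),
)


def default_freq_grid(start: float = 1.0, stop: float = 35.0, step: float = 0.5) -> np.ndarray:
    """Analysis frequency grid in Hz (default 1-35 Hz at 0.5 Hz)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


@dataclass(frozen=True)
class SGMParams:
    """The seven free biophysical parameters (plus fixed ``g_ee = 1``).

    Time constants are expressed in ms, speed in m/s; gains and coupling
    are dimensionless. Computations convert to SI internally.
    """

    tau_e: float = 15.0  # local excitatory time constant, ms
    tau_i: float = 10.0  # local inhibitory time constant, ms
    alpha: float = 1.0  # long-range coupling
    v: float = 5.0  # transmission speed, m/s
    g_ei: float = 0.3  # excitatory-inhibitory alternating gain
    g_ii: float = 0.6  # inhibitory gain
    tau_G: float = 6.0  # long-range (graph) excitatory time constant, ms

    g_ee: float = field(default=1.0, init=False, repr=False)

    def validate(self) -> "SGMParams":
        """Raise ValueError if any parameter is outside the outer bounds."""
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            val = getattr(self, name)
            if not np.isfinite(val) or not (lo <= val <= hi):
                raise ValueError(f"{name}={val} outside bounds [{lo}, {hi}]")
        return self

    # seconds for internal math
    @property
    def tau_e_s(self) -> float:
        return self.tau_e * 1e-3

    @property
    def tau_i_s(self) -> float:
        return self.tau_i * 1e-3

    @property
    def tau_G_s(self) -> float:
        return self.tau_G * 1e-3

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "SGMParams":
        return cls(**dict(zip(PARAM_NAMES, (float(v) for v in x))))

    def replace(self, **kwargs) -> "SGMParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class ModelSpectrum:
    """Modeled regional frequency response on a grid.

    ``response`` is regions x frequencies (complex); ``psd_db`` is
    ``20 log10 |response|``.
    """

    frequencies: np.ndarray
    response: np.ndarray
    psd_db: np.ndarray

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("frequencies", data=self.frequencies)
            fh.create_dataset("response_real", data=self.response.real)
            fh.create_dataset("response_imag", data=self.response.imag)
            fh.create_dataset("psd_db", data=self.psd_db)

    def save_csv(self, path: str | Path, labels: list[str] | None = None) -> None:
        idx = labels if labels is not None else [f"r{i}" for i in range(self.psd_db.shape[0])]
        pd.DataFrame(self.psd_db, index=idx, columns=self.frequencies).to_csv(path)


def gamma_response_ft(tau: float, f: float | np.ndarray) -> complex | np.ndarray:
    """Fourier transform of the Gamma-shaped ensemble response kernel.

    The unit-area kernel ``f(t) = (t / tau^2) exp(-t/tau)`` transforms to
    ``F(w) = 1 / (1 + j w tau)^2`` with ``w = 2 pi f``. ``tau`` in seconds.
    """
    if tau <= 0:
        raise ValueError(f"time constant must be positive, got {tau}")
    f_arr = np.asarray(f, dtype=float)
    omega = 2.0 * np.pi * np.atleast_1d(f_arr)
    out = 1.0 / (1.0 + 1j * omega * tau) ** 2
    return complex(out[0]) if f_arr.ndim == 0 else out


def local_transfer(
    params: SGMParams, f: float | np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local E-I frequency response under unit white-noise drive.

    Solves the 2x2 balance with ``P_e = P_i = 1``:

        a = jw + (g_ee/tau_e) F_e     b = (g_ei/tau_e) F_e
        c = (g_ei/tau_i) F_i          d = jw + (g_ii/tau_i) F_i
        Det = a d + b c

    and returns ``(X_e, X_i, H_local)`` with ``X_e = (d - b)/Det``,
    ``X_i = (c + a)/Det``, ``H_local = X_e + X_i``.
    """
    te, ti = params.tau_e_s, params.tau_i_s
    omega = 2.0 * np.pi * np.asarray(f, dtype=float)
    fe = gamma_response_ft(te, f)
    fi = gamma_response_ft(ti, f)
    a = 1j * omega + (params.g_ee / te) * fe
    b = (params.g_ei / te) * fe
    c = (params.g_ei / ti) * fi
    d = 1j * omega + (params.g_ii / ti) * fi
    det = a * d + b * c
    if np.any(np.abs(det) < 1e-15):
        raise FloatingPointError(
            "local transfer singular (|Det| < 1e-15): parameters at instability"
        )
    return (d - b) / det, (c + a) / det, (d - b + c + a) / det


def network_transfer_matrix(
    params: SGMParams,
    conn: Connectome,
    freqs: np.ndarray,
    mode: str = "row",
) -> np.ndarray:
    """Full network frequency-response matrix ``A(w) H_local(w)``.

    ``A(w) = (jw I + tau_G^-1 F_G(w) L(w))^-1``. Returns an F x N x N
    complex array; applying it to a drive vector gives the regional
    response. Used by the time-series generator and the direct solver.
    """
    freqs = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * freqs
    tg = params.tau_G_s
    fg = gamma_response_ft(tg, freqs)
    L = complex_laplacian(conn, params.v, params.alpha, freqs, mode=mode)
    n = conn.n_regions
    A = (1j * omega)[:, None, None] * np.eye(n)[None, :, :] + (fg / tg)[
        :, None, None
    ] * L
    _, _, h_local = local_transfer(params, freqs)
    return np.linalg.inv(A) * h_local[:, None, None]


def model_spectrum(
    params: SGMParams,
    conn: Connectome,
    freqs: np.ndarray | None = None,
    n_modes: int | None = None,
    mode: str = "row",
    method: str = "eigen",
    hermitian_modes: bool = False,
) -> ModelSpectrum:
    """Forward-model the regional spectrum on a frequency grid.

    ``method='eigen'`` evaluates the exact eigenmode expansion (columns
    of U with unit norm, inverse-based reconstruction); ``'solve'`` uses
    an equivalent batched direct linear solve and is preferred inside
    optimization loops. ``n_modes`` truncates the expansion to the
    smallest-|lambda| modes (eigen method only). ``hermitian_modes``
    replaces ``U^-1`` rows with ``u_k^H`` for comparison with the
    rank-one-sum form.
    """
    params.validate()
    if freqs is None:
        freqs = default_freq_grid()
    freqs = np.asarray(freqs, dtype=float)
    omega = 2.0 * np.pi * freqs
    tg = params.tau_G_s
    fg = gamma_response_ft(tg, freqs)
    _, _, h_local = local_transfer(params, freqs)
    n = conn.n_regions
    ones = np.ones(n)

    if method == "solve":
        if n_modes is not None:
            raise ValueError("n_modes truncation requires method='eigen'")
        L = complex_laplacian(conn, params.v, params.alpha, freqs, mode=mode)
        A = (1j * omega)[:, None, None] * np.eye(n)[None, :, :] + (fg / tg)[
            :, None, None
        ] * L
        x = np.linalg.solve(A, np.broadcast_to(ones[:, None], (freqs.size, n, 1)))
        response = (x[..., 0] * h_local[:, None]).T
    elif method == "eigen":
        k = n if n_modes is None else int(n_modes)
        if not 1 <= k <= n:
            raise ValueError(f"n_modes must be in [1, {n}], got {n_modes}")
        L = complex_laplacian(conn, params.v, params.alpha, freqs, mode=mode)
        response = np.empty((n, freqs.size), dtype=complex)
        for i, f in enumerate(freqs):
            es = eigensystem(L[i], f)
            rows = es.modes.conj().T if hermitian_modes else es.modes_inverse
            coeff = 1.0 / (1j * omega[i] + (es.eigenvalues / tg) * fg[i])
            weights = coeff[:k] * (rows[:k] @ ones)
            response[:, i] = (es.modes[:, :k] @ weights) * h_local[i]
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(response.real)) or not np.all(np.isfinite(response.imag)):
        raise FloatingPointError(
            "non-finite model response; check parameter stability with is_stable()"
        )
    psd_db = 20.0 * np.log10(np.abs(response))
    return ModelSpectrum(freqs, response, psd_db)


def stability_polynomial(params: SGMParams) -> np.ndarray:
    """Degree-6 characteristic polynomial of the local E-I system.

    Substituting ``s`` for ``jw`` in ``Det(s)`` and clearing the kernel
    denominators ``(1 + s tau)^2`` gives

        P(s) = (s (1+s tau_e)^2 + g_ee/tau_e)
             * (s (1+s tau_i)^2 + g_ii/tau_i)
             + g_ei^2 / (tau_e tau_i)

    Returns coefficients, highest degree first.
    """
    te, ti = params.tau_e_s, params.tau_i_s
    pe = np.array([te**2, 2.0 * te, 1.0, params.g_ee / te])
    pi = np.array([ti**2, 2.0 * ti, 1.0, params.g_ii / ti])
    poly = np.polymul(pe, pi)
    poly[-1] += params.g_ei**2 / (te * ti)
    return poly


def is_stable(params: SGMParams) -> bool:
    """True iff every pole of the local system has negative real part."""
    roots = np.roots(stability_polynomial(params))
    return bool(np.all(roots.real < 0))


def euler_local_simulation(
    params: SGMParams,
    duration: float = 2.0,
    dt: float = 1e-4,
    rng: np.random.Generator | None = None,
    drive: str = "noise",
) -> np.ndarray:
    """Forward-Euler simulation of the local E-I convolution system.

    The Gamma kernel obeys ``tau^2 y'' + 2 tau y' + y = u``, so each
    filtered input becomes a pair of states; the full system is

        dx_e/dt = -y_e + p_e,  (1 + tau_e d/dt)^2 y_e = (g_ee x_e + g_ei x_i)/tau_e
        dx_i/dt = -y_i + p_i,  (1 + tau_i d/dt)^2 y_i = (-g_ei x_e + g_ii x_i)/tau_i

    Returns samples of ``x_e + x_i``. Serves as an independent check of
    both ``is_stable`` (boundedness) and ``local_transfer`` (spectrum).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(round(duration / dt))
    te, ti = params.tau_e_s, params.tau_i_s
    xe = xi = 0.0
    ye = dye = yi = dyi = 0.0
    out = np.empty(n)
    if drive == "noise":
        p = rng.standard_normal((n, 2)) / np.sqrt(dt)
    elif drive == "impulse":
        p = np.zeros((n, 2))
        p[0] = 1.0 / dt
    else:
        raise ValueError(f"unknown drive {drive!r}")
    for t in range(n):
        ue = (params.g_ee * xe + params.g_ei * xi) / te
        ui = (-params.g_ei * xe + params.g_ii * xi) / ti
        d2ye = (ue - ye - 2.0 * te * dye) / te**2
        d2yi = (ui - yi - 2.0 * ti * dyi) / ti**2
        xe += dt * (-ye + p[t, 0])
        xi += dt * (-yi + p[t, 1])
        ye += dt * dye
        dye += dt * d2ye
        yi += dt * dyi
        dyi += dt * d2yi
        out[t] = xe + xi
    return out
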