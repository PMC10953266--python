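"""Synthetic inputs with known ground truth for the whole pipeline.

Generates distance-embedded random connectomes, per-group biophysical
parameter draws (patients get longer tau_G and tau_e and higher g_ii by
default, mirroring the reported effect directions), model-consistent
regional spectra with additive dB noise, surrogate time series with the
model's spectral content, and cognition scores negatively coupled to
tau_G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from sgm.connectome import Connectome
from sgm.features import RegionalPSD
from sgm.model import (
    PARAM_BOUNDS,
    PARAM_NAMES,
    SGMParams,
    default_freq_grid,
    is_stable,
    model_spectrum,
    network_transfer_matrix,
)

__all__ = [
    "SynthCohortSpec",
    "SynthSubject",
    "gen_connectome",
    "gen_cohort",
    "gen_timeseries",
]


def _default_param_means() -> dict[str, dict[str, float]]:
    mid = {n: 0.5 * (lo + hi) for n, (lo, hi) in PARAM_BOUNDS.items()}
    means = {"control": dict(mid), "patient": dict(mid)}
    means["control"].update({"tau_G": 7.50, "tau_e": 11.88, "g_ii": 0.26})
    means["patient"].update({"tau_G": 13.90, "tau_e": 15.01, "g_ii": 0.46})
    return means


def _default_param_sds() -> dict[str, float]:
    sds = {n: 0.05 * (hi - lo) for n, (lo, hi) in PARAM_BOUNDS.items()}
    sds.update({"tau_G": 3.0, "tau_e": 3.0, "g_ii": 0.15})
    return sds


@dataclass(frozen=True)
class SynthCohortSpec:
    """Ground-truth distributions for a two-group synthetic cohort."""

    n_per_group: int = 20
    param_means: dict = field(default_factory=_default_param_means)
    param_sds: dict = field(default_factory=_default_param_sds)
    spectrum_noise_db: float = 1.0
    mmse_intercept: float = 28.0
    mmse_tau_g_coef: float = -0.45  # points per ms, negative coupling
    mmse_noise_sd: float = 2.0
    cdr_intercept: float = 0.0
    cdr_tau_g_coef: float = 0.35
    cdr_noise_sd: float = 1.0
    age_mean: dict = field(
        default_factory=lambda: {"control": 65.07, "patient": 62.73}
    )
    age_sd: dict = field(default_factory=lambda: {"control": 9.92, "patient": 8.64})
    seed: int = 0

    def __post_init__(self) -> None:
        for group, means in self.param_means.items():
            for name, mu in means.items():
                lo, hi = PARAM_BOUNDS[name]
                if not lo <= mu <= hi:
                    raise ValueError(
                        f"{group} mean {name}={mu} outside bounds [{lo}, {hi}]"
                    )
        if any(sd <= 0 for sd in self.param_sds.values()):
            raise ValueError("parameter SDs must be positive")


@dataclass(frozen=True)
class SynthSubject:
    """A generated subject: observed record plus its generating truth."""

    id: str
    group: str
    age: float
    true_params: SGMParams
    psd: RegionalPSD
    mmse: float
    cdr_sob: float | None


def gen_connectome(n_regions: int = 86, density: float = 0.3, seed: int = 0) -> Connectome:
    """Random distance-embedded connectome.

    Regions sit at uniform random positions inside a 140 mm-diameter
    sphere; distances are Euclidean (mm); weights follow an exponential
    distance rule ``exp(-d / 40 mm)`` thresholded to the target edge
    density and symmetrized. Any node isolated by thresholding is
    reconnected to its nearest neighbor. The cortical mask marks the
    leading 68/86 proportion of regions.
    """
    if n_regions < 3:
        raise ValueError("need at least 3 regions")
    rng = np.random.default_rng(seed)
    radius = 70.0
    pts = np.empty((n_regions, 3))
    count = 0
    while count < n_regions:
        cand = rng.uniform(-radius, radius, size=(n_regions, 3))
        keep = cand[np.linalg.norm(cand, axis=1) <= radius]
        take = min(len(keep), n_regions - count)
        pts[count : count + take] = keep[:take]
        count += take
    dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(dist, 0.0)
    weights = np.exp(-dist / 40.0)
    np.fill_diagonal(weights, 0.0)

    iu = np.triu_indices(n_regions, k=1)
    vals = weights[iu]
    n_keep = max(1, int(round(density * vals.size)))
    thr = np.sort(vals)[::-1][n_keep - 1]
    keep_mask = np.zeros_like(weights, dtype=bool)
    keep_mask[iu] = vals >= thr
    keep_mask |= keep_mask.T
    weights = np.where(keep_mask, weights, 0.0)

    deg = weights.sum(axis=1)
    for j in np.nonzero(deg == 0)[0]:
        order = np.argsort(dist[j])
        k = next(int(i) for i in order if i != j)
        weights[j, k] = weights[k, j] = np.exp(-dist[j, k] / 40.0)

    n_cortical = int(round(n_regions * 68.0 / 86.0))
    mask = np.zeros(n_regions, dtype=bool)
    mask[:n_cortical] = True
    labels = [f"region_{i:03d}" for i in range(n_regions)]
    return Connectome(weights, dist, labels, mask)


def draw_stable_params(
    spec: SynthCohortSpec, group: str, rng: np.random.Generator, max_draws: int = 1000
) -> SGMParams:
    """Truncated-normal parameter draw, rejection-sampled until stable."""
    means = spec.param_means[group]
    for _ in range(max_draws):
        vals = {}
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            mu, sd = means[name], spec.param_sds[name]
            a, b = (lo - mu) / sd, (hi - mu) / sd
            vals[name] = float(
                sps.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng)
            )
        params = SGMParams(**vals)
        if is_stable(params):
            return params
    raise RuntimeError(f"no stable draw for group {group!r} in {max_draws} attempts")


def gen_cohort(
    spec: SynthCohortSpec,
    conn: Connectome,
    freqs: np.ndarray | None = None,
) -> list[SynthSubject]:
    """Generate a full two-group cohort of subjects with spectra.

    Spectra are the forward model evaluated on the cortical mask plus
    i.i.d. Gaussian dB noise; age is drawn per group; MMSE is linear in
    the true tau_G (negative slope) plus noise, clipped to [0, 30];
    patients additionally receive a CDR-SOB score increasing in tau_G.
    """
    rng = np.random.default_rng(spec.seed)
    if freqs is None:
        freqs = default_freq_grid()
    mask = conn.cortical_mask
    subjects: list[SynthSubject] = []
    for group in ("control", "patient"):
        for i in range(spec.n_per_group):
            params = draw_stable_params(spec, group, rng)
            spectrum = model_spectrum(params, conn, freqs, method="solve")
            psd_db = spectrum.psd_db[mask]
            if spec.spectrum_noise_db > 0:
                psd_db = psd_db + spec.spectrum_noise_db * rng.standard_normal(
                    psd_db.shape
                )
            age = float(
                np.clip(
                    rng.normal(spec.age_mean[group], spec.age_sd[group]), 30.0, 100.0
                )
            )
            mmse = float(
                np.clip(
                    spec.mmse_intercept
                    + spec.mmse_tau_g_coef * params.tau_G
                    + spec.mmse_noise_sd * rng.standard_normal(),
                    0.0,
                    30.0,
                )
            )
            cdr = None
            if group == "patient":
                cdr = float(
                    max(
                        0.0,
                        spec.cdr_intercept
                        + spec.cdr_tau_g_coef * params.tau_G
                        + spec.cdr_noise_sd * rng.standard_normal(),
                    )
                )
            sid = f"{group}_{i:03d}"
            subjects.append(
                SynthSubject(
                    id=sid,
                    group=group,
                    age=age,
                    true_params=params,
                    psd=RegionalPSD(freqs, psd_db, subject_id=sid),
                    mmse=mmse,
                    cdr_sob=cdr,
                )
            )
    return subjects


def gen_timeseries(
    params: SGMParams,
    conn: Connectome,
    duration: float = 60.0,
    fs: float = 600.0,
    seed: int = 0,
    f_max: float = 60.0,
    drive: str = "common",
) -> np.ndarray:
    """Surrogate regional time series with the model's spectral content.

    Builds the full network frequency-response matrix at the FFT bin
    frequencies (up to ``f_max``; the response decays as 1/f so higher
    bins are negligible and are zeroed), applies it to complex Gaussian
    bin amplitudes, and inverse-transforms assuming Hermitian symmetry.
    ``drive='common'`` uses one scalar amplitude per bin shared by all
    regions, which reproduces the deterministic forward spectrum (the
    unit-drive convention) region by region; ``'iid'`` draws independent
    amplitudes per region, preserving the model's full cross-spectral
    structure instead. The DC bin is zeroed (the Laplacian can be
    singular at zero frequency for full coupling).
    """
    if duration < 10.0:
        raise ValueError("need at least 10 s")
    params.validate()
    if not is_stable(params):
        raise FloatingPointError("unstable parameters; refuse to synthesize")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * fs))
    bin_freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    active = (bin_freqs > 0) & (bin_freqs <= min(f_max, fs / 2.0))
    n = conn.n_regions
    spec = np.zeros((n, bin_freqs.size), dtype=complex)
    transfer = network_transfer_matrix(params, conn, bin_freqs[active])
    n_act = int(active.sum())
    if drive == "common":
        z = (rng.standard_normal(n_act) + 1j * rng.standard_normal(n_act)) / np.sqrt(2.0)
        spec[:, active] = (transfer.sum(axis=2) * z[:, None]).T
    elif drive == "iid":
        z = (
            rng.standard_normal((n_act, n)) + 1j * rng.standard_normal((n_act, n))
        ) / np.sqrt(2.0)
        spec[:, active] = np.einsum("fjk,fk->fj", transfer, z).T
    else:
        raise ValueError(f"unknown drive {drive!r} (use 'common' or 'iid')")
    out = np.fft.irfft(spec, n=n_samp, axis=1) * np.sqrt(n_samp * fs)
    return out
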