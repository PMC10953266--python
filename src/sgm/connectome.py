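"""Structural connectome: validation, normalization, complex Laplacian.

The connectome is the substrate of the long-range model: a symmetric
non-negative weight matrix plus a matrix of inter-region fiber distances
(mm). Delayed coupling at angular frequency ``w = 2*pi*f`` enters through
the phase factor ``exp(-1j*w*d/(1000*v))`` (distance mm, speed m/s), and
the frequency-dependent complex Laplacian is ``L(w) = I - alpha*C*(w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "EigenSystem",
    "ConnectomeValidationError",
    "load_connectome",
    "save_connectome",
    "degree_normalize",
    "complex_laplacian",
    "eigensystem",
]

_SYMMETRY_TOL = 1e-10


class ConnectomeValidationError(ValueError):
    """A connectome matrix violated a structural invariant."""


@dataclass(frozen=True)
class Connectome:
    """Validated structural connectome.

    Attributes
    ----------
    weights
        N x N symmetric non-negative connection strengths, zero diagonal.
    distances
        N x N symmetric inter-region distances in mm, zero diagonal.
    labels
        Region names, length N.
    cortical_mask
        Boolean length-N vector marking the regions that carry empirical
        spectra (e.g. the 68 cortical of 86 total regions).
    """

    weights: np.ndarray
    distances: np.ndarray
    labels: tuple[str, ...]
    cortical_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        distances = np.asarray(self.distances, dtype=float)
        labels = tuple(str(x) for x in self.labels)
        n = len(labels)
        if weights.shape != (n, n):
            raise ConnectomeValidationError(
                f"weights shape {weights.shape} does not match {n} labels"
            )
        if distances.shape != (n, n):
            raise ConnectomeValidationError(
                f"distances shape {distances.shape} does not match {n} labels"
            )
        mask = self.cortical_mask
        if mask is None:
            mask = np.ones(n, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n,):
            raise ConnectomeValidationError(
                f"cortical_mask length {mask.shape} does not match {n} labels"
            )
        _validate_matrix(weights, "weights")
        _validate_matrix(distances, "distances")
        row_sums = weights.sum(axis=1)
        if np.any(row_sums <= 0):
            j = int(np.argmin(row_sums))
            raise ConnectomeValidationError(
                f"isolated node: region {labels[j]!r} (index {j}) has zero weight degree"
            )
        weights = weights.copy()
        distances = distances.copy()
        weights.flags.writeable = False
        distances.flags.writeable = False
        mask = mask.copy()
        mask.flags.writeable = False
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "distances", distances)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "cortical_mask", mask)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def n_cortical(self) -> int:
        return int(self.cortical_mask.sum())

    @property
    def cortical_labels(self) -> tuple[str, ...]:
        return tuple(np.asarray(self.labels)[self.cortical_mask])


def _validate_matrix(m: np.ndarray, name: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ConnectomeValidationError(f"{name} is not square: shape {m.shape}")
    if not np.all(np.isfinite(m)):
        j, k = np.argwhere(~np.isfinite(m))[0]
        raise ConnectomeValidationError(f"non-finite {name} at entry ({j}, {k})")
    if np.any(m < 0):
        j, k = np.argwhere(m < 0)[0]
        raise ConnectomeValidationError(
            f"negative weight in {name} at entry ({j}, {k}): {m[j, k]}"
        )
    asym = np.abs(m - m.T)
    if asym.max(initial=0.0) > _SYMMETRY_TOL:
        j, k = np.unravel_index(np.argmax(asym), asym.shape)
        raise ConnectomeValidationError(
            f"{name} asymmetric beyond {_SYMMETRY_TOL} at entry ({j}, {k}): "
            f"{m[j, k]} vs {m[k, j]}"
        )
    diag = np.abs(np.diag(m))
    if diag.max(initial=0.0) > 0:
        j = int(np.argmax(diag))
        raise ConnectomeValidationError(f"nonzero diagonal in {name} at index {j}")


def load_connectome(
    weights_path: str | Path,
    distances_path: str | Path | None = None,
    labels: list[str] | None = None,
    cortical_mask: list[bool] | None = None,
) -> Connectome:
    """Load a connectome from CSV matrices or a single HDF5 file.

    CSV files are dense matrices with a header row of region labels.
    An HDF5 file (detected by suffix ``.h5``/``.hdf5``) holds datasets
    ``weights``, ``distances``, ``labels`` and ``cortical_mask``.
    """
    weights_path = Path(weights_path)
    if weights_path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(weights_path, "r") as fh:
            weights = fh["weights"][()]
            distances = fh["distances"][()]
            file_labels = [
                x.decode() if isinstance(x, bytes) else str(x) for x in fh["labels"][()]
            ]
            mask = fh["cortical_mask"][()].astype(bool)
        return Connectome(weights, distances, labels or file_labels, mask)
    if distances_path is None:
        raise ValueError("distances_path is required for CSV input")
    wdf = pd.read_csv(weights_path, index_col=None, float_precision="round_trip")
    ddf = pd.read_csv(distances_path, index_col=None, float_precision="round_trip")
    if labels is None:
        labels = list(wdf.columns)
    if wdf.shape[1] != len(labels) or ddf.shape[1] != len(labels):
        raise ConnectomeValidationError(
            f"matrix columns ({wdf.shape[1]}, {ddf.shape[1]}) do not match "
            f"{len(labels)} labels"
        )
    return Connectome(wdf.to_numpy(float), ddf.to_numpy(float), labels, cortical_mask)


def save_connectome(conn: Connectome, path: str | Path) -> None:
    """Write a connectome to HDF5 (datasets weights/distances/labels/cortical_mask)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("weights", data=conn.weights)
        fh.create_dataset("distances", data=conn.distances)
        fh.create_dataset(
            "labels", data=np.array([s.encode() for s in conn.labels])
        )
        fh.create_dataset("cortical_mask", data=conn.cortical_mask.astype(np.uint8))


def degree_normalize(weights: np.ndarray, mode: str = "row") -> np.ndarray:
    """Degree-normalize a weight matrix.

    ``row``: entry (j, k) becomes ``c_jk / sum_k c_jk`` so each row sums
    to one. ``symmetric``: ``c_jk / sqrt(deg_j * deg_k)``.
    """
    weights = np.asarray(weights, dtype=float)
    deg = weights.sum(axis=1)
    if np.any(deg <= 0):
        j = int(np.argmin(deg))
        raise ConnectomeValidationError(
            f"cannot normalize: region index {j} has zero degree"
        )
    if mode == "row":
        return weights / deg[:, None]
    if mode == "symmetric":
        scale = 1.0 / np.sqrt(deg)
        return weights * scale[:, None] * scale[None, :]
    raise ValueError(f"unknown normalization mode {mode!r} (use 'row' or 'symmetric')")


def complex_laplacian(
    conn: Connectome,
    v: float,
    alpha: float,
    f: float | np.ndarray,
    mode: str = "row",
) -> np.ndarray:
    """Frequency-dependent complex Laplacian ``L(w) = I - alpha * C*(w)``.

    ``C*(w)_jk = normalize(weights)_jk * exp(-1j * w * d_jk / (1000 v))``
    with ``w = 2 pi f``; distances in mm and speed in m/s give the delay
    ``d/(1000 v)`` in seconds.

    ``f`` may be a scalar (returns N x N) or a 1-D grid (returns
    F x N x N, one Laplacian per frequency).
    """
    if v <= 0:
        raise ValueError(f"transmission speed must be positive, got {v}")
    cnorm = degree_normalize(conn.weights, mode=mode)
    delay = conn.distances / (1000.0 * v)  # seconds
    f_arr = np.asarray(f, dtype=float)
    omega = 2.0 * np.pi * f_arr
    eye = np.eye(conn.n_regions)
    if f_arr.ndim == 0:
        out = eye - alpha * cnorm * np.exp(-1j * float(omega) * delay)
    else:
        phases = np.exp(-1j * omega[:, None, None] * delay[None, :, :])
        out = eye[None, :, :] - alpha * cnorm[None, :, :] * phases
    if not np.all(np.isfinite(out.real)) or not np.all(np.isfinite(out.imag)):
        raise FloatingPointError("non-finite complex Laplacian")
    return out


@dataclass(frozen=True)
class EigenSystem:
    """Eigendecomposition of a complex Laplacian at one frequency.

    Eigenvalues are sorted by ascending magnitude (ties by ascending
    phase); mode columns are unit-norm; ``modes_inverse`` is computed
    once at construction.
    """

    frequency: float
    eigenvalues: np.ndarray
    modes: np.ndarray
    modes_inverse: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Return ``U diag(lambda) U^-1``."""
        return (self.modes * self.eigenvalues[None, :]) @ self.modes_inverse


def eigensystem(L: np.ndarray, f: float = 0.0) -> EigenSystem:
    """Decompose a complex Laplacian into sorted, unit-norm eigenmodes."""
    L = np.asarray(L)
    if not np.all(np.isfinite(L.real)) or not np.all(np.isfinite(L.imag)):
        raise ValueError("non-finite Laplacian")
    lam, U = np.linalg.eig(L)
    order = np.lexsort((np.angle(lam), np.abs(lam)))
    lam = lam[order]
    U = U[:, order]
    U = U / np.linalg.norm(U, axis=0, keepdims=True)
    cond = np.linalg.cond(U)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"mode matrix numerically singular (condition number {cond:.3g})"
        )
    return EigenSystem(float(f), lam, U, np.linalg.inv(U))
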