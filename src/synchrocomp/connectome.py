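"""Structural connectome handling.

A connectome here is a weighted, symmetric, zero-diagonal adjacency matrix
over cortical regions together with inter-region (barycentric) distances in
millimetres. Node strengths (weighted degree) drive the assignment of
natural alpha frequencies, and distances divided by a conduction velocity
give pairwise transmission delays for the oscillator network model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "NaturalFrequencyMap",
    "validate_connectome",
    "load_connectome",
    "write_connectome",
    "average_and_log_transform",
    "node_strengths",
    "assign_natural_frequencies",
    "delays_from_velocity",
]

_SYMMETRY_TOL = 1e-6


@dataclass
class Connectome:
    """Weighted symmetric graph over brain regions.

    Attributes
    ----------
    weights
        ``(n, n)`` nonnegative symmetric matrix, zero diagonal, max entry 1.
    distances
        ``(n, n)`` symmetric inter-node distances in mm, zero diagonal.
    labels
        Region names, length ``n``.
    coordinates
        Optional ``(n, 3)`` region barycenters in mm. When present,
        ``distances`` equals their pairwise Euclidean distances.
    meta
        Free-form provenance notes (e.g. connectivity warnings).
    """

    weights: np.ndarray
    distances: np.ndarray
    labels: list[str]
    coordinates: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


class ConnectomeError(ValueError):
    """Raised when a connectivity matrix violates structural requirements."""


def validate_connectome(c: Connectome) -> Connectome:
    """Check all structural invariants, raising :class:`ConnectomeError`."""
    w, d = np.asarray(c.weights, float), np.asarray(c.distances, float)
    n = w.shape[0]
    if w.shape != (n, n) or d.shape != (n, n):
        raise ConnectomeError(f"weights {w.shape} / distances {d.shape} must be equal square matrices")
    if len(c.labels) != n:
        raise ConnectomeError(f"{len(c.labels)} labels for {n} nodes")
    if np.any(~np.isfinite(w)) or np.any(~np.isfinite(d)):
        raise ConnectomeError("non-finite entries")
    if np.any(w < 0):
        raise ConnectomeError("negative weights")
    if np.max(np.abs(w - w.T)) > _SYMMETRY_TOL:
        raise ConnectomeError("weights not symmetric")
    if np.max(np.abs(d - d.T)) > _SYMMETRY_TOL:
        raise ConnectomeError("distances not symmetric")
    if np.any(np.diag(w) != 0) or np.any(np.diag(d) != 0):
        raise ConnectomeError("diagonal must be zero")
    off = ~np.eye(n, dtype=bool)
    if n > 1 and np.any(d[off] <= 0):
        raise ConnectomeError("off-diagonal distances must be positive")
    if n > 1 and not np.isclose(w.max(), 1.0, atol=1e-9) and w.max() > 0:
        raise ConnectomeError(f"weights must be normalized to max 1 (max={w.max():g})")
    if c.coordinates is not None:
        coords = np.asarray(c.coordinates, float)
        dd = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        if np.max(np.abs(dd - d)) > 1e-9:
            raise ConnectomeError("distances disagree with coordinate geometry beyond 1e-9 mm")
    return c


def _read_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    """Read a square delimited matrix; a non-numeric first row is a label header."""
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    labels = None
    try:
        df.iloc[0].astype(float)
    except (ValueError, TypeError):
        labels = [str(x) for x in df.iloc[0]]
        df = df.iloc[1:]
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ConnectomeError(f"matrix in {path} is {mat.shape}, not square")
    return mat, labels


def load_connectome(weights_path, distances_path=None, coords_path=None,
                    labels_path=None) -> Connectome:
    """Load a connectome from delimited-text files.

    Either ``distances_path`` (square mm matrix) or ``coords_path``
    (3-column mm coordinates, from which Euclidean distances are computed)
    must be given. Near-symmetric weight matrices (max asymmetry ≤ 1e-6)
    are symmetrized by averaging.
    """
    w, labels = _read_matrix(weights_path)
    n = w.shape[0]
    if np.any(w < 0):
        raise ConnectomeError("negative weights in input")
    asym = np.max(np.abs(w - w.T))
    if asym > _SYMMETRY_TOL:
        raise ConnectomeError(f"weight asymmetry {asym:g} exceeds tolerance {_SYMMETRY_TOL:g}")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    if w.max() > 0:
        w = w / w.max()

    coords = None
    if coords_path is not None:
        coords = pd.read_csv(coords_path, sep=None, engine="python",
                             header=None, comment="#").to_numpy(dtype=float)
        if coords.shape != (n, 3):
            raise ConnectomeError(f"coordinates {coords.shape} do not match {n} nodes x 3")
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    elif distances_path is not None:
        d, _ = _read_matrix(distances_path)
        if d.shape != w.shape:
            raise ConnectomeError(f"distance matrix {d.shape} does not match weights {w.shape}")
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
    else:
        raise ConnectomeError("either distances_path or coords_path is required")

    if labels_path is not None:
        labels = [ln.strip() for ln in open(labels_path) if ln.strip()]
    if labels is None:
        labels = [f"node{i}" for i in range(n)]
    return validate_connectome(Connectome(w, d, labels, coords))


def write_connectome(c: Connectome, prefix: str) -> list[str]:
    """Write ``<prefix>_weights.tsv``, ``_distances.tsv`` and optionally ``_coords.tsv``."""
    parent = Path(prefix).parent
    if str(parent):
        parent.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, mat in [("weights", c.weights), ("distances", c.distances)]:
        p = f"{prefix}_{name}.tsv"
        pd.DataFrame(mat).to_csv(p, sep="\t", header=False, index=False, float_format="%.12g")
        paths.append(p)
    if c.coordinates is not None:
        p = f"{prefix}_coords.tsv"
        pd.DataFrame(c.coordinates).to_csv(p, sep="\t", header=False, index=False,
                                           float_format="%.12g")
        paths.append(p)
    with open(f"{prefix}_labels.txt", "w") as fh:
        fh.write("\n".join(c.labels) + "\n")
    paths.append(f"{prefix}_labels.txt")
    return paths


def average_and_log_transform(matrices: list[np.ndarray]) -> np.ndarray:
    """Average raw adjacency matrices and compress their dynamic range.

    Tract-count adjacency matrices span orders of magnitude; after
    element-wise averaging, weights are rescaled so the maximum maps to
    ``e - 1``, passed through ``log1p`` (making the largest post-log weight
    exactly 1), and max-normalized. Zero weights stay zero and ordering is
    preserved.
    """
    mats = [np.asarray(m, float) for m in matrices]
    if not mats:
        raise ValueError("need at least one matrix")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("matrices differ in shape")
    stack = np.stack(mats)
    if np.any(np.isnan(stack)):
        raise ValueError("NaN entries in input matrices")
    if np.any(stack < 0):
        raise ValueError("negative entries in input matrices")
    mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 0.0)
    mx = mean.max()
    if mx == 0:
        return mean
    out = np.log1p(mean * ((np.e - 1.0) / mx))
    out = out / out.max()
    np.fill_diagonal(out, 0.0)
    return out


def node_strengths(c: Connectome | np.ndarray) -> np.ndarray:
    """Weighted degree ``s_j = sum_i c_ij`` of each node."""
    w = c.weights if isinstance(c, Connectome) else np.asarray(c, float)
    return w.sum(axis=0)


@dataclass
class NaturalFrequencyMap:
    """Per-node natural frequencies (Hz) derived from node strengths.

    Strong hubs oscillate slowly: frequency falls quadratically from
    ``omega_max`` at the weakest node to ``omega_min`` at the strongest.
    """

    omega: np.ndarray            # Hz
    omega_max: float
    omega_min: float
    strengths: np.ndarray
    s_min: float
    s_max: float


def assign_natural_frequencies(strengths: np.ndarray, omega_max: float = 12.0,
                               omega_min: float = 8.0) -> NaturalFrequencyMap:
    """Map node strengths to natural frequencies.

    ``omega_i = omega_max - (omega_max - omega_min) * ((s_j - s_min) / (s_max - s_min))**2``
    so the least-connected node sits at ``omega_max`` (default 12 Hz) and the
    hub with maximal strength at ``omega_min`` (default 8 Hz).
    """
    s = np.asarray(strengths, float)
    s_min, s_max = float(s.min()), float(s.max())
    if s_max <= s_min:
        raise ValueError("all node strengths equal; frequency assignment undefined")
    if omega_max <= omega_min:
        raise ValueError("omega_max must exceed omega_min")
    omega = omega_max - (omega_max - omega_min) * ((s - s_min) / (s_max - s_min)) ** 2
    return NaturalFrequencyMap(omega, omega_max, omega_min, s, s_min, s_max)


def delays_from_velocity(distances_mm: np.ndarray, velocity_m_s: float) -> np.ndarray:
    """Pairwise conduction delays ``tau_ij = D_ij / v`` in seconds.

    ``distances_mm`` in mm, ``velocity_m_s`` in m/s; typical cortical
    conduction velocities span 1-30 m/s.
    """
    if velocity_m_s <= 0:
        raise ValueError("conduction velocity must be positive")
    tau = np.asarray(distances_mm, float) * 1e-3 / velocity_m_s
    if tau.ndim == 2:
        np.fill_diagonal(tau, 0.0)
    return tau
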