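"""Spatial statistics of detected particles.

Two analyses: (i) neighbor-density maps — for every particle the vectors to
its n closest neighbors (beyond an exclusion radius guarding against
clashes) are rotated into the particle's own reference frame and
accumulated on a 3D histogram, revealing preferred neighbor geometries such
as the leading/trailing ribosomes of membrane-bound polysomes; (ii) score
profiles through the ice layer — particle coordinates are rotated onto
their principal axes so the thinnest direction lies along z, centered on
the median z, and each particle's LCCmax is reported against its depth,
which exposes the damaged surface zones of FIB-milled lamellae as a score
drop-off towards the layer edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import euler_to_matrix
from .io import ParticleList

__all__ = ["NeighborDensity", "neighbor_density", "plane_align", "lamella_profile"]

DEFAULT_N_NEIGHBORS = 4
DEFAULT_EXCLUSION_RADIUS = 100.0  # Angstrom
DEFAULT_HIST_VOXEL = 20.0  # Angstrom
DEFAULT_HIST_EXTENT = 1000.0  # Angstrom per half-axis


@dataclass
class NeighborDensity:
    """Probability of finding a neighbor per (hist_voxel)^3 bin, centered on
    the reference particle."""

    histogram: np.ndarray
    hist_voxel: float
    n_neighbors: int
    exclusion_radius: float
    total_neighbors: int

    def projection(self, plane: str) -> np.ndarray:
        """Sum projection onto 'xy', 'xz' or 'yz'."""
        axis = {"xy": 2, "xz": 1, "yz": 0}[plane]
        return self.histogram.sum(axis=axis)


def neighbor_density(
    particles: ParticleList,
    n_neighbors: int = DEFAULT_N_NEIGHBORS,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
    hist_voxel: float = DEFAULT_HIST_VOXEL,
    extent: float = DEFAULT_HIST_EXTENT,
    plane_align_flag: bool = False,
) -> NeighborDensity:
    """Accumulate neighbor vectors in the particle frame on a 3D histogram.

    For each particle the vectors to its ``n_neighbors`` nearest neighbors
    farther than ``exclusion_radius`` (Angstrom) are rotated by the inverse
    of the particle's orientation; with ``plane_align_flag`` the pooled
    vectors are additionally rotated so their least-variation axis lies
    along z.  The histogram is normalized by the number of accumulated
    neighbors, so each bin holds a probability.  Neighbors are counted
    directionally (a pair contributes once per member).
    """
    if particles.voxel_size is None:
        raise ValueError("particle list lacks a voxel size; cannot convert to Angstrom")
    n_bins = 2 * int(np.ceil(extent / hist_voxel)) + 1
    hist = np.zeros((n_bins, n_bins, n_bins))
    if len(particles) < 2:
        return NeighborDensity(hist, hist_voxel, n_neighbors, exclusion_radius, 0)

    pos = particles.positions() * particles.voxel_size  # Angstrom
    vectors = []
    for i, p in enumerate(particles):
        d = np.linalg.norm(pos - pos[i], axis=1)
        d[i] = np.inf
        eligible = np.flatnonzero((d >= exclusion_radius) & np.isfinite(d))
        if eligible.size == 0:
            continue
        order = eligible[np.argsort(d[eligible], kind="stable")][:n_neighbors]
        rot_inv = euler_to_matrix(p.orientation).T
        for j in order:
            vectors.append(rot_inv @ (pos[j] - pos[i]))
    if not vectors:
        return NeighborDensity(hist, hist_voxel, n_neighbors, exclusion_radius, 0)
    vecs = np.asarray(vectors)
    if plane_align_flag and len(vecs) >= 3:
        vecs, _ = plane_align(vecs)

    idx = np.round(vecs / hist_voxel).astype(int) + n_bins // 2
    inside = np.all((idx >= 0) & (idx < n_bins), axis=1)
    idx = idx[inside]
    np.add.at(hist, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    total = int(inside.sum())
    if total > 0:
        hist /= total
    return NeighborDensity(hist, hist_voxel, n_neighbors, exclusion_radius, total)


def plane_align(coordinates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotate a point cloud so its least-variation principal axis lies on z.

    Returns the rotated (centered-then-unshifted) coordinates and the proper
    rotation matrix applied.  Raises for collinear or degenerate inputs.
    """
    pts = np.asarray(coordinates, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise ValueError("plane fitting needs at least 3 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    if eigval[1] <= 1e-12 * max(eigval[2], 1e-300):
        raise ValueError("degenerate (collinear) point configuration")
    # rows: principal axes ordered largest..smallest variance -> x, y, z
    rot = eigvec[:, ::-1].T
    if np.linalg.det(rot) < 0:
        rot[2] = -rot[2]
    rotated = centered @ rot.T + pts.mean(axis=0)
    return rotated, rot


def lamella_profile(particles: ParticleList) -> np.ndarray:
    """Per-particle (z_centered, score) pairs through the ice layer.

    Coordinates (in Angstrom) are plane-aligned, then the median z is
    subtracted so the layer center sits at z = 0.  One row per particle, in
    input order.
    """
    if len(particles) < 3:
        raise ValueError("profile needs at least 3 particles")
    voxel = particles.voxel_size if particles.voxel_size is not None else 1.0
    pos = particles.positions() * voxel
    aligned, _ = plane_align(pos)
    z = aligned[:, 2] - np.median(aligned[:, 2])
    return np.column_stack([z, particles.scores()])
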