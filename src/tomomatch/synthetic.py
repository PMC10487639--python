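"""Phantom tomograms with planted particles for end-to-end validation.

A phantom is built by pasting rotated copies of a known template at
rejection-sampled positions, filtering the whole volume with the binary
missing-wedge mask (which produces the characteristic elongation along the
beam axis), and adding white Gaussian noise scaled to a requested
signal-to-noise ratio, defined as the variance of the wedge-filtered signal
divided by the noise variance.  The ground-truth positions and orientations
are returned as a particle list, so detection, extraction and orientation
assignment can all be checked without external data.

Noise is added after wedge filtering; this is the simplest model that
exercises the score normalization, and deliberately omits CTF modulation of
the phantom itself, correlated noise and molecular crowding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .geometry import EulerConvention, EulerTriplet, euler_to_matrix, matrix_to_euler
from .io import DensityVolume, ParticleAnnotation, ParticleList
from .matching import _rotate_array
from .template import WedgeSpec, build_wedge_mask

__all__ = ["PhantomSpec", "generate_phantom", "random_rotations", "make_blob_template"]

_PLACEMENT_BUDGET = 10000


@dataclass
class PhantomSpec:
    """Recipe for a synthetic tomogram.

    ``snr`` is signal variance over noise variance; ``numpy.inf`` disables
    noise.  ``min_separation`` is in Angstrom.
    """

    template: DensityVolume
    box: tuple[int, int, int] = (128, 128, 128)
    n_particles: int = 25
    min_separation: float = 350.0
    snr: float = 0.5
    wedge: WedgeSpec | None = field(default_factory=WedgeSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValueError("need at least one particle")
        if not self.snr > 0:
            raise ValueError("snr must be positive (numpy.inf for noise-free)")
        if any(t > b for t, b in zip(self.template.shape, self.box)):
            raise ValueError("template box exceeds the phantom box")


def random_rotations(n: int, rng: np.random.Generator) -> list[EulerTriplet]:
    """n orientations drawn uniformly on SO(3) via random unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    out = []
    for w, x, y, z in q:
        r = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        out.append(matrix_to_euler(r, EulerConvention.ZXZ_ANTICLOCKWISE))
    return out


def make_blob_template(
    box_size: int = 16, voxel_size: float = 14.0, seed: int = 7, n_lumps: int = 12
) -> DensityVolume:
    """Asymmetric smooth multi-lump density standing in for a macromolecule.

    Synthetic stand-in: a sum of Gaussian lumps confined to roughly half the
    box diameter, with no symmetry so orientations are identifiable.
    """
    rng = np.random.default_rng(seed)
    c = box_size // 2
    grid = np.arange(box_size, dtype=float)
    x, y, z = np.meshgrid(grid, grid, grid, indexing="ij")
    data = np.zeros((box_size,) * 3)
    radius = 0.30 * box_size
    centers = rng.normal(scale=radius * 0.55, size=(n_lumps, 3))
    centers = np.clip(centers, -radius, radius)
    widths = rng.uniform(0.08, 0.16, size=n_lumps) * box_size
    weights = rng.uniform(0.5, 1.0, size=n_lumps)
    for (cx, cy, cz), w, a in zip(centers, widths, weights):
        r2 = (x - c - cx) ** 2 + (y - c - cy) ** 2 + (z - c - cz) ** 2
        data += a * np.exp(-0.5 * r2 / w**2)
    return DensityVolume(data, voxel_size=voxel_size)


def generate_phantom(spec: PhantomSpec) -> tuple[DensityVolume, ParticleList]:
    """Build the phantom tomogram and its ground-truth particle list.

    Positions keep pairwise distances >= ``min_separation`` and at least
    half a template box clear of every border; orientations are uniform on
    SO(3).  The same seed reproduces the phantom bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    box = np.array(spec.box, dtype=int)
    t_box = spec.template.shape[0]
    margin = t_box // 2
    voxel = spec.template.voxel_size
    min_sep_vox = spec.min_separation / voxel

    lo = margin
    hi = box - (t_box - margin)  # room for the full template box
    if np.any(hi <= lo):
        raise ValueError("phantom box too small for the template margin")

    positions: list[np.ndarray] = []
    for _ in range(_PLACEMENT_BUDGET):
        cand = rng.integers(lo, hi, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep_vox for p in positions):
            positions.append(cand)
        if len(positions) == spec.n_particles:
            break
    else:
        raise RuntimeError(
            f"placed only {len(positions)}/{spec.n_particles} particles within the "
            "sampling budget; reduce the count or the minimum separation"
        )

    orientations = random_rotations(spec.n_particles, rng)
    volume = np.zeros(tuple(box))
    for pos, ori in zip(positions, orientations):
        rotated = _rotate_array(
            spec.template.data, euler_to_matrix(ori), interpolation="cubic_bspline"
        )
        sl = tuple(slice(int(p) - margin, int(p) - margin + t_box) for p in pos)
        volume[sl] += rotated

    if spec.wedge is not None:
        w = build_wedge_mask(volume.shape, spec.wedge)[..., : volume.shape[2] // 2 + 1]
        volume = scipy.fft.irfftn(scipy.fft.rfftn(volume) * w, s=volume.shape)

    if np.isfinite(spec.snr):
        signal_var = float(volume.var())
        noise_std = np.sqrt(signal_var / spec.snr)
        volume = volume + rng.normal(scale=noise_std, size=volume.shape)

    truth = ParticleList(
        [
            ParticleAnnotation(
                tomogram_id="phantom",
                position=tuple(int(c) for c in pos),
                orientation=ori,
                score=0.0,
            )
            for pos, ori in zip(positions, orientations)
        ],
        tomogram_dims=tuple(int(b) for b in box),
        voxel_size=voxel,
    )
    return DensityVolume(volume, voxel_size=voxel), truth
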