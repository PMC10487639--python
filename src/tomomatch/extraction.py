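"""Iterative peak extraction from score volumes.

Candidates are read off the LCCmax volume in order of decreasing score: the
global maximum inside the valid region is recorded together with the
orientation stored in the angle volume, then a spherical region of the
masking radius around it is invalidated, and the search repeats.  This is
plain non-maximum suppression; no sub-voxel interpolation is applied, since
positional refinement belongs to subtomogram averaging downstream.
"""

from __future__ import annotations

import numpy as np

from .geometry import OrientationSet
from .io import ParticleAnnotation, ParticleList
from .matching import _INVALID_SCORE, ScoreVolumes

__all__ = ["extract_candidates"]


def extract_candidates(
    scores: ScoreVolumes,
    orientations: OrientationSet,
    n: int,
    radius: float,
    tomogram_id: str = "",
) -> ParticleList:
    """Extract up to ``n`` ranked candidates with a spherical masking radius.

    Stops early once every remaining position is masked or invalid; ties in
    score are broken by lexicographic (z, y, x) position order.  Returned
    scores are exactly the LCCmax values present before masking.
    """
    if n < 1:
        raise ValueError("candidate count must be >= 1")
    if radius < 1:
        raise ValueError("masking radius must be >= 1 voxel")

    work = scores.lcc_max.data.astype(np.float64, copy=True)
    work[~scores.valid_mask()] = _INVALID_SCORE
    shape = work.shape

    r_int = int(np.ceil(radius))
    grid = np.arange(-r_int, r_int + 1)
    bx, by, bz = np.meshgrid(grid, grid, grid, indexing="ij")
    ball = bx**2 + by**2 + bz**2 <= radius**2

    particles: list[ParticleAnnotation] = []
    for _ in range(n):
        flat = np.argmax(work)
        peak = float(work.flat[flat])
        if peak <= _INVALID_SCORE:
            break
        # np.argmax returns the first maximum in C order on the [x, y, z]
        # grid; re-resolve ties lexicographically by (z, y, x)
        ties = np.argwhere(work == peak)
        if len(ties) > 1:
            order = np.lexsort((ties[:, 0], ties[:, 1], ties[:, 2]))
            pos = tuple(int(c) for c in ties[order[0]])
        else:
            pos = tuple(int(c) for c in ties[0])
        angle_idx = int(scores.angle_index[pos])
        particles.append(
            ParticleAnnotation(
                tomogram_id=tomogram_id,
                position=pos,
                orientation=orientations[angle_idx],
                score=min(1.0, max(-1.0, peak)),
            )
        )
        lo = [max(0, pos[d] - r_int) for d in range(3)]
        hi = [min(shape[d], pos[d] + r_int + 1) for d in range(3)]
        ball_sl = tuple(
            slice(lo[d] - (pos[d] - r_int), ball.shape[d] - ((pos[d] + r_int + 1) - hi[d]))
            for d in range(3)
        )
        region = tuple(slice(lo[d], hi[d]) for d in range(3))
        work[region][ball[ball_sl]] = _INVALID_SCORE

    return ParticleList(
        particles,
        tomogram_dims=shape,
        voxel_size=scores.lcc_max.voxel_size,
    )
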