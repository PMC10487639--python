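"""Masked local-correlation template matching over an orientation set.

At every tomogram position x and template rotation v the engine evaluates
the local correlation coefficient

    LCC(x, v) = sum_i M_v(i) (T_v*W(i) - Tbar) (V(x+i) - Vbar(x))
                / (P * sigma_T * sigma_MV(x)),

where T_v and M_v are the rotated template and mask, W the missing-wedge
weighting applied to the rotated template in the tomogram frame, Tbar the
template mean under the mask, sigma_T its standard deviation under the mask,
P the mask mass and sigma_MV(x) the local standard deviation of the tomogram
under the mask placed at x.  Translations are exhaustive via FFT
cross-correlation; the per-voxel maximum over the searched orientations and
the index of the maximizing orientation form the score and angle volumes.

The FFT wrap-around contaminates a margin of half a template box at the
volume faces; scores there are set to -1 and flagged invalid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage

from .geometry import EulerTriplet, OrientationSet, euler_to_matrix
from .io import DensityVolume
from .template import MaskVolume, WedgeSpec, build_wedge_mask

__all__ = [
    "ScoreVolumes",
    "MatchJob",
    "rotate_volume",
    "local_std",
    "lcc_single_orientation",
    "run_match",
    "split_and_merge",
    "score_at_positions",
]

logger = logging.getLogger(__name__)

# Positions whose local standard deviation falls below this fraction of the
# global tomogram std score zero rather than dividing by noise.
_LOCAL_STD_FLOOR_FRACTION = 1e-8

_INVALID_SCORE = -1.0


@dataclass
class ScoreVolumes:
    """Paired LCCmax volume and best-orientation-index volume."""

    lcc_max: DensityVolume
    angle_index: np.ndarray
    valid_margin: int

    def __post_init__(self) -> None:
        if self.lcc_max.shape != self.angle_index.shape:
            raise ValueError("score and angle volumes must share one shape")

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of positions unaffected by FFT wrap-around."""
        m = np.zeros(self.lcc_max.shape, dtype=bool)
        b = self.valid_margin
        if all(n > 2 * b for n in self.lcc_max.shape):
            m[b:-b or None, b:-b or None, b:-b or None] = True
        return m


@dataclass
class MatchJob:
    """Everything needed for one matching run."""

    tomogram: DensityVolume
    template: DensityVolume
    mask: MaskVolume
    orientations: OrientationSet
    wedge: WedgeSpec | None = None
    split: tuple[int, int, int] = (1, 1, 1)
    spherical_mask: bool = True
    interpolation: str = "cubic_bspline"
    precision: str = "double"

    def __post_init__(self) -> None:
        b = self.template.shape[0]
        if self.template.shape != (b, b, b):
            raise ValueError("template must be cubic")
        if self.mask.data.shape != self.template.shape:
            raise ValueError("mask and template must share one box size")
        if any(n < b for n in self.tomogram.shape):
            raise ValueError("template box exceeds a tomogram dimension")
        if len(self.orientations) == 0:
            raise ValueError("empty orientation set")
        if self.precision not in ("single", "double"):
            raise ValueError("precision must be 'single' or 'double'")

    @property
    def dtype(self):
        return np.float32 if self.precision == "single" else np.float64


# --------------------------------------------------------------------------
# Rotation


def rotate_volume(
    volume: DensityVolume, t: EulerTriplet, interpolation: str = "cubic_bspline"
) -> DensityVolume:
    """Actively rotate a cubic volume about its center voxel floor(n/2).

    ``cubic_bspline`` uses prefiltered cubic b-spline interpolation (the
    default, most accurate for non-smooth densities); ``linear`` trilinear.
    Voxels mapped from outside the box are zero.
    """
    n = volume.shape[0]
    if volume.shape != (n, n, n):
        raise ValueError("rotation requires a cubic volume")
    return DensityVolume(
        _rotate_array(volume.data, euler_to_matrix(t), interpolation), volume.voxel_size
    )


def _rotate_array(data: np.ndarray, rot: np.ndarray, interpolation: str) -> np.ndarray:
    if interpolation == "cubic_bspline":
        order = 3
    elif interpolation == "linear":
        order = 1
    else:
        raise ValueError(f"unknown interpolation: {interpolation!r}")
    center = np.array([n // 2 for n in data.shape], dtype=float)
    inv = rot.T  # output(x) = input(R^-1 (x - c) + c)
    offset = center - inv @ center
    return ndimage.affine_transform(
        data, inv, offset=offset, order=order, mode="constant", cval=0.0, prefilter=order > 1
    )


# --------------------------------------------------------------------------
# FFT correlation plumbing


def _pad_kernel(kernel: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=kernel.dtype)
    b = kernel.shape
    out[: b[0], : b[1], : b[2]] = kernel
    return out


def _correlate(ft_volume: np.ndarray, kernel: np.ndarray, shape, center: int) -> np.ndarray:
    """Centered cross-correlation: result(x) = sum_j K(j) V(x - c + j)."""
    ft_k = scipy.fft.rfftn(_pad_kernel(kernel, shape))
    raw = scipy.fft.irfftn(ft_volume * np.conj(ft_k), s=shape)
    return np.roll(raw, (center, center, center), axis=(0, 1, 2))


def local_std(volume: DensityVolume, mask: MaskVolume) -> DensityVolume:
    """Local standard deviation of the volume under the mask footprint.

    At each position x: ``sqrt(mean_M(v^2) - mean_M(v)^2)`` with the mask
    centered at x, computed by FFT cross-correlation; clamped at >= 0.
    """
    if mask.sum_p <= 0:
        raise ValueError("mask has zero mass")
    if any(bn > vn for bn, vn in zip(mask.data.shape, volume.shape)):
        raise ValueError("mask box exceeds the volume")
    v = volume.data.astype(np.float64, copy=False)
    ft_v = scipy.fft.rfftn(v)
    ft_v2 = scipy.fft.rfftn(v * v)
    sigma = _local_std_from_ffts(ft_v, ft_v2, mask.data, volume.shape, mask.sum_p)
    return DensityVolume(sigma, volume.voxel_size)


def _local_std_from_ffts(ft_v, ft_v2, mask_data, shape, p) -> np.ndarray:
    center = mask_data.shape[0] // 2
    m1 = _correlate(ft_v, mask_data, shape, center) / p
    m2 = _correlate(ft_v2, mask_data, shape, center) / p
    return np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))


def _normalized_template(
    template_data: np.ndarray, mask_data: np.ndarray, p: float
) -> tuple[np.ndarray, float]:
    """Mask-weighted, mean-free template and its masked std sigma_T."""
    t_mean = float((mask_data * template_data).sum() / p)
    centered = template_data - t_mean
    sigma_t = float(np.sqrt((mask_data * centered * centered).sum() / p))
    if sigma_t <= 0:
        raise ValueError("degenerate template: zero variance under the mask")
    return mask_data * centered, sigma_t


def _wedge_filter_box(template_data: np.ndarray, wedge: WedgeSpec | None) -> np.ndarray:
    if wedge is None:
        return template_data
    w = build_wedge_mask(template_data.shape, wedge)[..., : template_data.shape[2] // 2 + 1]
    return scipy.fft.irfftn(scipy.fft.rfftn(template_data) * w, s=template_data.shape)


def lcc_single_orientation(
    volume: DensityVolume,
    template: DensityVolume,
    mask: MaskVolume,
    wedge: WedgeSpec | None = None,
) -> DensityVolume:
    """Masked, locally normalized cross-correlation for one (already
    rotated) template/mask pair, evaluated at every position by FFT."""
    v = volume.data.astype(np.float64, copy=False)
    ft_v = scipy.fft.rfftn(v)
    ft_v2 = scipy.fft.rfftn(v * v)
    p = mask.sum_p
    sigma_mv = _local_std_from_ffts(ft_v, ft_v2, mask.data, volume.shape, p)
    floor = _LOCAL_STD_FLOOR_FRACTION * float(v.std())
    t_w = _wedge_filter_box(template.data.astype(np.float64, copy=False), wedge)
    t_norm, sigma_t = _normalized_template(t_w, mask.data, p)
    center = template.shape[0] // 2
    num = _correlate(ft_v, t_norm, volume.shape, center)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = num / (p * sigma_t * sigma_mv)
    scores[sigma_mv <= floor] = 0.0
    return DensityVolume(scores, volume.voxel_size)


# --------------------------------------------------------------------------
# Full search


def _match_core(job: MatchJob, orientation_indices: np.ndarray | None = None,
                log_every: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Run the orientation loop; returns raw (lcc_max, angle_index) without
    border invalidation."""
    dtype = job.dtype
    v = job.tomogram.data.astype(dtype, copy=False)
    shape = v.shape
    ft_v = scipy.fft.rfftn(v)
    ft_v2 = scipy.fft.rfftn(v * v)
    floor = _LOCAL_STD_FLOOR_FRACTION * float(v.std())

    mask_data = job.mask.data.astype(dtype, copy=False)
    p = float(mask_data.sum())
    box = job.template.shape[0]
    center = box // 2
    wedge_r = None
    if job.wedge is not None:
        wedge_r = build_wedge_mask(job.template.shape, job.wedge)[..., : box // 2 + 1]

    sigma_mv = None
    if job.spherical_mask:
        sigma_mv = _local_std_from_ffts(ft_v, ft_v2, mask_data, shape, p)
        invalid_std = sigma_mv <= floor

    best = np.full(shape, -np.inf, dtype=dtype)
    best_idx = np.zeros(shape, dtype=np.int32)
    indices = (
        np.arange(len(job.orientations)) if orientation_indices is None else orientation_indices
    )
    template_data = job.template.data.astype(np.float64, copy=False)

    for count, i in enumerate(indices):
        rot = euler_to_matrix(job.orientations[int(i)])
        t_rot = _rotate_array(template_data, rot, job.interpolation)
        if wedge_r is not None:
            t_rot = scipy.fft.irfftn(scipy.fft.rfftn(t_rot) * wedge_r, s=t_rot.shape)
        if job.spherical_mask:
            m_rot, p_i, s_mv = mask_data, p, sigma_mv
        else:
            m_rot = np.clip(_rotate_array(job.mask.data, rot, "linear"), 0.0, 1.0).astype(dtype)
            p_i = float(m_rot.sum())
            s_mv = _local_std_from_ffts(ft_v, ft_v2, m_rot, shape, p_i)
            invalid_std = s_mv <= floor
        t_norm, sigma_t = _normalized_template(t_rot.astype(dtype), m_rot, p_i)
        num = _correlate(ft_v, t_norm, shape, center)
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = num / (p_i * sigma_t * s_mv)
        scores[invalid_std] = 0.0
        better = scores > best
        best[better] = scores[better]
        best_idx[better] = i
        if log_every and (count + 1) % log_every == 0:
            logger.info("matched %d / %d orientations", count + 1, len(indices))
    return np.asarray(best, dtype=dtype), best_idx


def _invalidate_margin(lcc: np.ndarray, idx: np.ndarray, margin: int) -> None:
    if margin <= 0:
        return
    sl_all = slice(None)
    for axis in range(3):
        lo = [sl_all] * 3
        hi = [sl_all] * 3
        lo[axis] = slice(0, margin)
        hi[axis] = slice(lcc.shape[axis] - margin, None)
        lcc[tuple(lo)] = _INVALID_SCORE
        lcc[tuple(hi)] = _INVALID_SCORE
        idx[tuple(lo)] = 0
        idx[tuple(hi)] = 0


def run_match(job: MatchJob, log_every: int = 0) -> ScoreVolumes:
    """Exhaustive translational and rotational search.

    For each orientation in order the template (and, unless the mask is
    flagged spherical, the mask) is rotated, wedge-filtered and correlated;
    the per-voxel running maximum and the index of the orientation achieving
    it are kept.  Ties keep the lowest orientation index.  Deterministic.
    """
    lcc, idx = _match_core(job, log_every=log_every)
    margin = job.template.shape[0] // 2
    _invalidate_margin(lcc, idx, margin)
    return ScoreVolumes(
        lcc_max=DensityVolume(lcc, job.tomogram.voxel_size),
        angle_index=idx,
        valid_margin=margin,
    )


def _merge_partial(best, best_idx, lcc, idx):
    """Pointwise max with lowest-orientation-index tie-break."""
    take = (lcc > best) | ((lcc == best) & (idx < best_idx))
    best[take] = lcc[take]
    best_idx[take] = idx[take]


def split_and_merge(job: MatchJob, angle_partitions: int = 1) -> ScoreVolumes:
    """Matching with subvolume and/or angular-search splitting.

    Subvolumes overlap by one full template box on shared faces; each piece
    is matched independently and cropped back to its interior, so the merged
    result equals the unsplit ``run_match`` everywhere in the valid region.
    Angular splitting partitions the orientation list and merges by pointwise
    maximum with the lowest-index tie-break, which reproduces the serial
    loop exactly.
    """
    nx, ny, nz = job.split
    box = job.template.shape[0]
    shape = job.tomogram.shape
    if angle_partitions < 1:
        raise ValueError("angle_partitions must be >= 1")
    bounds = []
    for n_chunks, n in zip((nx, ny, nz), shape):
        if n_chunks < 1:
            raise ValueError("split counts must be >= 1")
        edges = np.linspace(0, n, n_chunks + 1).astype(int)
        if np.any(np.diff(edges) < 1):
            raise ValueError("split produces empty subvolumes")
        bounds.append(edges)

    all_indices = np.arange(len(job.orientations))
    angle_chunks = np.array_split(all_indices, angle_partitions)

    lcc_full = np.empty(shape, dtype=job.dtype)
    idx_full = np.empty(shape, dtype=np.int32)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                lo = [bounds[0][ix], bounds[1][iy], bounds[2][iz]]
                hi = [bounds[0][ix + 1], bounds[1][iy + 1], bounds[2][iz + 1]]
                # extend by one template box on shared faces
                ext_lo = [max(0, l - (box if l > 0 else 0)) for l in lo]
                ext_hi = [min(n, h + (box if h < n else 0)) for h, n in zip(hi, shape)]
                if any(h - l < box for l, h in zip(ext_lo, ext_hi)):
                    raise ValueError("subvolume smaller than the template box")
                sub = job.tomogram.data[
                    ext_lo[0] : ext_hi[0], ext_lo[1] : ext_hi[1], ext_lo[2] : ext_hi[2]
                ]
                sub_job = MatchJob(
                    tomogram=DensityVolume(sub, job.tomogram.voxel_size),
                    template=job.template,
                    mask=job.mask,
                    orientations=job.orientations,
                    wedge=job.wedge,
                    spherical_mask=job.spherical_mask,
                    interpolation=job.interpolation,
                    precision=job.precision,
                )
                best = np.full(sub.shape, -np.inf, dtype=job.dtype)
                best_idx = np.zeros(sub.shape, dtype=np.int32)
                for chunk in angle_chunks:
                    if chunk.size == 0:
                        continue
                    lcc_c, idx_c = _match_core(sub_job, orientation_indices=chunk)
                    _merge_partial(best, best_idx, lcc_c, idx_c)
                interior = tuple(
                    slice(l - el, h - el) for l, h, el in zip(lo, hi, ext_lo)
                )
                target = tuple(slice(l, h) for l, h in zip(lo, hi))
                lcc_full[target] = best[interior]
                idx_full[target] = best_idx[interior]
    margin = box // 2
    _invalidate_margin(lcc_full, idx_full, margin)
    return ScoreVolumes(
        lcc_max=DensityVolume(lcc_full, job.tomogram.voxel_size),
        angle_index=idx_full,
        valid_margin=margin,
    )


# --------------------------------------------------------------------------
# Direct evaluation at selected positions


def score_at_positions(job: MatchJob, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LCCmax and best orientation index at selected voxel positions.

    Evaluates the same masked local correlation as ``run_match`` but only at
    the given (n, 3) integer voxel positions, by direct summation over the
    mask footprint per orientation.  Useful for scoring known annotations
    under large orientation sets where full score volumes are not needed.
    """
    positions = np.asarray(positions, dtype=int).reshape(-1, 3)
    box = job.template.shape[0]
    center = box // 2
    shape = job.tomogram.shape
    for p_ in positions:
        if np.any(p_ - center < 0) or np.any(p_ - center + box > np.array(shape)):
            raise ValueError(f"position {tuple(p_)} footprint leaves the tomogram")
    v = job.tomogram.data.astype(np.float64, copy=False)
    patches = np.stack(
        [
            v[
                p_[0] - center : p_[0] - center + box,
                p_[1] - center : p_[1] - center + box,
                p_[2] - center : p_[2] - center + box,
            ].ravel()
            for p_ in positions
        ]
    )
    mask_flat = job.mask.data.ravel().astype(np.float64)
    p = float(mask_flat.sum())
    m1 = patches @ mask_flat / p
    m2 = (patches * patches) @ mask_flat / p
    sigma_mv = np.sqrt(np.clip(m2 - m1 * m1, 0.0, None))
    floor = _LOCAL_STD_FLOOR_FRACTION * float(v.std())

    wedge_r = None
    if job.wedge is not None:
        wedge_r = build_wedge_mask(job.template.shape, job.wedge)[..., : box // 2 + 1]

    best = np.full(len(positions), -np.inf)
    best_idx = np.zeros(len(positions), dtype=np.int32)
    template_data = job.template.data.astype(np.float64, copy=False)
    for i in range(len(job.orientations)):
        rot = euler_to_matrix(job.orientations[i])
        t_rot = _rotate_array(template_data, rot, job.interpolation)
        if wedge_r is not None:
            t_rot = scipy.fft.irfftn(scipy.fft.rfftn(t_rot) * wedge_r, s=t_rot.shape)
        if job.spherical_mask:
            m_flat, p_i, s_mv = mask_flat, p, sigma_mv
        else:
            m_rot = np.clip(_rotate_array(job.mask.data, rot, "linear"), 0.0, 1.0)
            m_flat = m_rot.ravel()
            p_i = float(m_flat.sum())
            mm1 = patches @ m_flat / p_i
            mm2 = (patches * patches) @ m_flat / p_i
            s_mv = np.sqrt(np.clip(mm2 - mm1 * mm1, 0.0, None))
        t_norm, sigma_t = _normalized_template(t_rot, m_flat.reshape(job.mask.data.shape), p_i)
        num = patches @ t_norm.ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = num / (p_i * sigma_t * s_mv)
        scores[s_mv <= floor] = 0.0
        better = scores > best
        best[better] = scores[better]
        best_idx[better] = i
    return best, best_idx
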