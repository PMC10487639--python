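"""Construction of matching inputs: modulated template, masks, wedge.

The reference density is made comparable to a tomogram by modulating its
Fourier transform with the microscope contrast transfer function (CTF,
truncated after its first zero so only same-sign contrast survives), a
low-pass filter at the target resolution, and Fourier-crop downsampling to
the tomogram voxel size.  The spherical mask defines the local-normalization
footprint around the particle, and the binary missing-wedge mask encodes the
Fourier-space region left unsampled by the limited tilt range (tilt axis y,
beam axis z).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.optimize import brentq

from .io import DensityVolume

__all__ = [
    "CtfParams",
    "TemplateSpec",
    "MaskVolume",
    "WedgeSpec",
    "electron_wavelength",
    "ctf_modulation",
    "ctf_first_zero",
    "build_template",
    "build_spherical_mask",
    "build_wedge_mask",
]

# CODATA constants
_H = 6.62607015e-34  # J s
_M0 = 9.1093837015e-31  # kg
_E = 1.602176634e-19  # C
_C = 2.99792458e8  # m/s


@dataclass(frozen=True)
class CtfParams:
    """Microscope parameters of the weak-phase contrast transfer function.

    defocus — micrometres, positive for underfocus
    voltage — kilovolts
    spherical_aberration — millimetres (Cs)
    amplitude_contrast — fraction in [0, 1]
    """

    defocus: float = 3.0
    voltage: float = 200.0
    spherical_aberration: float = 2.7
    amplitude_contrast: float = 0.08

    def __post_init__(self) -> None:
        if not self.voltage > 0:
            raise ValueError("voltage must be positive")
        if not math.isfinite(self.defocus):
            raise ValueError("defocus must be finite")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must lie in [0, 1]")


@dataclass(frozen=True)
class TemplateSpec:
    """Processing recipe applied to a reference map.

    Filtering happens at ``input_voxel`` (Angstrom), then the map is
    Fourier-cropped to ``output_voxel`` and centered in a cubic box of
    ``box_size`` voxels.  ``lowpass_cutoff`` is in Angstrom (the filter
    passes frequencies below 1/cutoff).
    """

    ctf: CtfParams
    lowpass_cutoff: float | None
    input_voxel: float
    output_voxel: float
    box_size: int
    truncate_ctf_after_first_zero: bool = True
    apply_ctf: bool = True

    def __post_init__(self) -> None:
        if self.output_voxel < self.input_voxel:
            raise ValueError("output voxel must be >= input voxel")
        if self.lowpass_cutoff is not None and self.lowpass_cutoff < 2.0 * self.output_voxel:
            raise ValueError("low-pass cutoff must be at or below the output Nyquist")


@dataclass
class MaskVolume:
    """Soft mask with values in [0, 1]; ``sum_p`` is the mask mass P."""

    volume: DensityVolume
    diameter: float
    soft_edge_sigma: float

    def __post_init__(self) -> None:
        d = self.volume.data
        if d.min() < 0 or d.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if d.sum() <= 0:
            raise ValueError("mask must have positive mass")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def sum_p(self) -> float:
        return float(self.volume.data.sum())


@dataclass(frozen=True)
class WedgeSpec:
    """Missing-wedge half-angles in degrees, measured from the tilt plane.

    A symmetric tilt series over +-t degrees leaves a double wedge of
    ``90 - t`` degrees on both sides; e.g. +-51 degrees gives 39/39.  The
    tilt axis is the y grid axis and the beam axis is z.
    """

    angle_low: float = 39.0
    angle_high: float = 39.0

    def __post_init__(self) -> None:
        for a in (self.angle_low, self.angle_high):
            if not 0.0 <= a <= 90.0:
                raise ValueError("wedge angles must lie in [0, 90] degrees")

    @classmethod
    def from_tilt_range(cls, tilt_low: float, tilt_high: float) -> "WedgeSpec":
        """Wedge angles from the covered tilt range (degrees)."""
        return cls(angle_low=90.0 - abs(tilt_low), angle_high=90.0 - abs(tilt_high))


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom at ``voltage_kv`` kV."""
    if not voltage_kv > 0:
        raise ValueError("voltage must be positive")
    u = voltage_kv * 1e3
    lam = _H / math.sqrt(2.0 * _M0 * _E * u * (1.0 + _E * u / (2.0 * _M0 * _C**2)))
    return lam * 1e10


def _chi(k: np.ndarray, ctf: CtfParams) -> np.ndarray:
    """Aberration phase shift at spatial frequency k (1/Angstrom)."""
    lam = electron_wavelength(ctf.voltage)
    dz = ctf.defocus * 1e4  # um -> Angstrom
    cs = ctf.spherical_aberration * 1e7  # mm -> Angstrom
    return math.pi * lam * dz * k**2 - 0.5 * math.pi * cs * lam**3 * k**4


def _ctf_raw(k: np.ndarray, ctf: CtfParams) -> np.ndarray:
    a = ctf.amplitude_contrast
    chi = _chi(np.asarray(k, dtype=float), ctf)
    return -(math.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_first_zero(ctf: CtfParams, k_max: float = 1.0) -> float:
    """Smallest positive spatial frequency (1/Angstrom) where the CTF
    crosses zero, or ``inf`` if there is none below ``k_max``."""
    k = np.linspace(0.0, k_max, 20000)
    v = _ctf_raw(k, ctf)
    sign_change = np.nonzero(np.sign(v[1:]) * np.sign(v[:-1]) < 0)[0]
    if sign_change.size == 0:
        return math.inf
    i = sign_change[0]
    return brentq(lambda kk: float(_ctf_raw(np.array([kk]), ctf)[0]), k[i], k[i + 1])


def ctf_modulation(
    k: float | np.ndarray, ctf: CtfParams, truncate_after_first_zero: bool = True
) -> np.ndarray:
    """Weak-phase CTF value at spatial frequency ``k`` (1/Angstrom).

    ``-(sqrt(1 - A^2) sin(chi) + A cos(chi))`` with
    ``chi = pi lambda dz k^2 - (pi/2) Cs lambda^3 k^4``; with truncation the
    value is zero for every frequency beyond the first zero crossing of the
    full (amplitude-contrast-shifted) curve.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("spatial frequencies must be non-negative")
    v = _ctf_raw(k, ctf)
    if truncate_after_first_zero:
        v = np.where(k > ctf_first_zero(ctf), 0.0, v)
    return v


# --------------------------------------------------------------------------
# Template construction


def _radial_frequencies(shape: tuple[int, ...], voxel: float) -> np.ndarray:
    """|k| on the rfftn grid, in 1/Angstrom (last axis halved)."""
    axes = [scipy.fft.fftfreq(n, d=voxel) for n in shape[:-1]]
    axes.append(scipy.fft.rfftfreq(shape[-1], d=voxel))
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)
    return np.sqrt(sum(g**2 for g in grids))


def _raised_cosine_lowpass(k: np.ndarray, cutoff_freq: float, edge_width: float) -> np.ndarray:
    """Near-hard low-pass: 1 below the cutoff, raised-cosine edge of the
    given width (1/Angstrom) centered on the cutoff, 0 above."""
    lo = cutoff_freq - 0.5 * edge_width
    hi = cutoff_freq + 0.5 * edge_width
    filt = np.ones_like(k)
    if edge_width > 0:
        ramp = (k - lo) / edge_width
        filt = np.where(k >= lo, 0.5 * (1.0 + np.cos(np.pi * np.clip(ramp, 0.0, 1.0))), filt)
    filt[k > hi] = 0.0
    return filt


def _fourier_crop(data: np.ndarray, new_shape: tuple[int, int, int]) -> np.ndarray:
    """Alias-free downsampling by cropping the centered Fourier transform."""
    ft = scipy.fft.fftshift(scipy.fft.fftn(data))
    slices = []
    for n_old, n_new in zip(data.shape, new_shape):
        start = n_old // 2 - n_new // 2
        slices.append(slice(start, start + n_new))
    cropped = ft[tuple(slices)]
    out = scipy.fft.ifftn(scipy.fft.ifftshift(cropped)).real
    # keep mean intensity: forward/inverse FFT pair rescales by the size ratio
    out *= np.prod(new_shape) / np.prod(data.shape)
    return out


def build_template(reference: DensityVolume, spec: TemplateSpec) -> DensityVolume:
    """Produce the matching template from a reference map.

    At the input voxel size the map's Fourier transform is multiplied
    radially by the (optionally truncated) CTF and by a soft-edged low-pass
    at ``spec.lowpass_cutoff``; the result is Fourier-cropped to the output
    voxel size and centered in a ``box_size^3`` box.  No normalization is
    applied here — the matching engine normalizes under the mask.
    """
    if abs(reference.voxel_size - spec.input_voxel) > 1e-6 * spec.input_voxel:
        raise ValueError(
            f"reference voxel size {reference.voxel_size} does not match spec input voxel {spec.input_voxel}"
        )
    n = reference.shape[0]
    if reference.shape != (n, n, n):
        raise ValueError("reference map must be cubic")
    if spec.lowpass_cutoff is not None and spec.lowpass_cutoff < 2.0 * spec.input_voxel:
        raise ValueError("low-pass cutoff beyond the input Nyquist frequency")

    k = _radial_frequencies(reference.shape, spec.input_voxel)
    ft = scipy.fft.rfftn(reference.data)
    if spec.apply_ctf:
        ft = ft * ctf_modulation(k, spec.ctf, spec.truncate_ctf_after_first_zero)
    if spec.lowpass_cutoff is not None:
        edge_width = 2.0 / (n * spec.input_voxel)  # two Fourier voxels
        ft = ft * _raised_cosine_lowpass(k, 1.0 / spec.lowpass_cutoff, edge_width)
    filtered = scipy.fft.irfftn(ft, s=reference.shape)

    n_out = int(round(n * spec.input_voxel / spec.output_voxel))
    if n_out < 1:
        raise ValueError("output voxel too large for the reference map")
    if n_out > n:
        n_out = n
    resampled = _fourier_crop(filtered, (n_out, n_out, n_out)) if n_out < n else filtered
    actual_voxel = n * spec.input_voxel / n_out

    box = spec.box_size
    if box < n_out:
        raise ValueError(f"box size {box} smaller than the resampled map ({n_out})")
    out = np.zeros((box, box, box), dtype=resampled.dtype)
    start = box // 2 - n_out // 2
    out[start : start + n_out, start : start + n_out, start : start + n_out] = resampled
    return DensityVolume(out, voxel_size=actual_voxel)


def build_spherical_mask(
    box_size: int, diameter: float, voxel_size: float, soft_edge_sigma: float = 1.5
) -> MaskVolume:
    """Spherical mask of the given diameter (Angstrom) centered at
    ``box_size // 2`` with a Gaussian soft edge of ``soft_edge_sigma``
    voxels; exactly zero beyond radius + 3 sigma."""
    radius = 0.5 * diameter / voxel_size
    if 2.0 * radius > box_size:
        raise ValueError("sphere does not fit in the box")
    c = box_size // 2
    grid = np.arange(box_size, dtype=float) - c
    x, y, z = np.meshgrid(grid, grid, grid, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    data = np.ones_like(r)
    if soft_edge_sigma > 0:
        outside = r > radius
        data[outside] = np.exp(-0.5 * ((r[outside] - radius) / soft_edge_sigma) ** 2)
        data[r > radius + 3.0 * soft_edge_sigma] = 0.0
    else:
        data[r > radius] = 0.0
    return MaskVolume(
        DensityVolume(data, voxel_size=voxel_size),
        diameter=diameter,
        soft_edge_sigma=soft_edge_sigma,
    )


def build_wedge_mask(
    shape: tuple[int, int, int], wedge: WedgeSpec, smooth_sigma: float = 0.0
) -> np.ndarray:
    """Binary missing-wedge mask on the unshifted FFT grid of ``shape``.

    Value 1 where the Fourier voxel was covered by the tilt series (tilt
    axis y, beam axis z): the direction of (kx, kz) lies within
    ``90 - wedge angle`` of the kx axis on the corresponding side.  The
    kx = kz = 0 line is always passed.  Hermitian-symmetric by construction;
    an optional Gaussian smoothing (in Fourier voxels) can soften the edge.
    """
    nx, ny, nz = shape
    kx = scipy.fft.fftfreq(nx)[:, None]
    kz = scipy.fft.fftfreq(nz)[None, :]
    # angle of the (kx, kz) direction from the kx axis, folded to (-90, 90]
    ang = np.degrees(np.arctan2(kz, kx + np.zeros_like(kz)))
    ang = np.where(ang > 90.0, ang - 180.0, ang)
    ang = np.where(ang <= -90.0, ang + 180.0, ang)
    passed = np.where(ang >= 0, ang <= 90.0 - wedge.angle_high, -ang <= 90.0 - wedge.angle_low)
    passed = passed | ((kx == 0) & (kz == 0))
    # unpaired Nyquist rows represent both +-0.5: symmetrize explicitly so
    # the mask is exactly Hermitian on the discrete grid
    flip = passed[(-np.arange(nx)) % nx][:, (-np.arange(nz)) % nz]
    mask2d = (passed | flip).astype(float)
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        mask2d = gaussian_filter(mask2d, smooth_sigma, mode="wrap")
    return np.broadcast_to(mask2d[:, None, :], (nx, ny, nz)).copy()
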