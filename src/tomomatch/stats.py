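"""Score classification: bimodal Gaussian fit, sensitivity/FDR, RUC.

The LCCmax values of extracted candidates are modelled as draws from two
Gaussian populations — background noise and true-positive particles.  A
least-squares fit of the sum of two Gaussians to the score histogram (bin
width 0.015 by default) yields the component parameters; the background
component is initialized and bounded by the mean and standard deviation of
the score volume itself, with the peak height initialized as
``N / (w * sigma * sqrt(2 pi))`` for N scores, bin width w and score-volume
standard deviation sigma.

Sliding a cutoff over the fitted model traces a sensitivity-versus-FDR
curve; its best operating point is the cutoff maximizing the rectangle
``sensitivity * (1 - FDR)`` under the curve (RUC).  A perfect classifier
reaches RUC 1, a random one 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as _scipy_stats

__all__ = [
    "ScoreHistogram",
    "BimodalFitResult",
    "RocCurve",
    "RucPoint",
    "make_histogram",
    "gaussian_peak_height",
    "fit_bimodal",
    "sensitivity_fdr",
    "roc_curve",
    "ruc_point",
]

DEFAULT_BIN_WIDTH = 0.015
ROC_SAMPLES = 500

# how far the background component may stray from the score-volume
# statistics during the fit
_BG_MEAN_SLACK_STD = 2.0  # mean within +- 2 sigma of the volume mean
_BG_STD_FACTORS = (0.5, 2.0)  # std within [0.5x, 2x] of the volume std
# identifiability guards for the particle component: its mean must sit clear
# of the background peak and its width cannot collapse onto single noisy bins
_TP_MEAN_MIN_STD = 2.0
_TP_STD_MIN_BINS = 2.0


@dataclass
class ScoreHistogram:
    """Histogram of candidate scores at a fixed bin width."""

    bin_width: float
    bin_centers: np.ndarray
    counts: np.ndarray
    total_n: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if int(self.counts.sum()) != self.total_n:
            raise ValueError("histogram counts do not sum to the total")


def make_histogram(scores: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> ScoreHistogram:
    scores = np.asarray(scores, dtype=float)
    lo = math.floor(scores.min() / bin_width) * bin_width
    hi = math.ceil(scores.max() / bin_width) * bin_width
    n_bins = max(1, int(round((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(scores, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return ScoreHistogram(
        bin_width=bin_width, bin_centers=centers, counts=counts, total_n=len(scores)
    )


def gaussian_peak_height(n: int, bin_width: float, sigma: float) -> float:
    """Histogram peak height of n Gaussian draws: ``n / (w sigma sqrt(2 pi))``."""
    return n / (bin_width * sigma * math.sqrt(2.0 * math.pi))


@dataclass
class BimodalFitResult:
    """Two-Gaussian model of a score histogram (amplitudes in count units)."""

    bg_mean: float
    bg_std: float
    bg_amplitude: float
    tp_mean: float
    tp_std: float
    tp_amplitude: float
    bin_width: float
    residual_norm: float = float("nan")

    def __post_init__(self) -> None:
        if self.bg_std <= 0 or self.tp_std <= 0:
            raise ValueError("component standard deviations must be positive")
        if self.bg_amplitude < 0 or self.tp_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")

    @property
    def estimated_tp_count(self) -> float:
        """Integral of the particle Gaussian in candidate counts."""
        return self.tp_amplitude * self.tp_std * math.sqrt(2.0 * math.pi) / self.bin_width

    @property
    def estimated_bg_count(self) -> float:
        return self.bg_amplitude * self.bg_std * math.sqrt(2.0 * math.pi) / self.bin_width

    def model(self, x: np.ndarray) -> np.ndarray:
        return _two_gaussians(
            np.asarray(x, dtype=float),
            self.bg_amplitude,
            self.bg_mean,
            self.bg_std,
            self.tp_amplitude,
            self.tp_mean,
            self.tp_std,
        )


def _two_gaussians(x, a1, m1, s1, a2, m2, s2):
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(-0.5 * ((x - m2) / s2) ** 2)


def fit_bimodal(
    scores: np.ndarray,
    score_volume_mean: float,
    score_volume_std: float,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> BimodalFitResult:
    """Least-squares fit of two Gaussians to the score histogram.

    The background component is initialized at the score-volume mean and
    standard deviation and constrained to stay near them; its height starts
    at the all-background value ``N / (w sigma sqrt(2 pi))``.  The particle
    component is seeded from the upper quartile of the scores.  Components
    are re-ordered after the fit so that ``tp_mean > bg_mean``.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 50:
        raise ValueError("need at least 50 scores for a stable bimodal fit")
    if score_volume_std <= 0:
        raise ValueError("score-volume standard deviation must be positive")
    hist = make_histogram(scores, bin_width)
    if np.count_nonzero(hist.counts) < 2:
        raise ValueError("degenerate histogram: fewer than two occupied bins")

    n = hist.total_n
    bg_amp0 = gaussian_peak_height(n, bin_width, score_volume_std)
    top = np.sort(scores)[int(0.75 * n) :]
    tp_mean0 = float(top.mean())
    tp_std0 = max(float(top.std()), _TP_STD_MIN_BINS * bin_width)
    tp_amp0 = max(float(hist.counts.max()) * 0.5, 1.0)

    m, s = score_volume_mean, score_volume_std
    lower = [
        0.0, m - _BG_MEAN_SLACK_STD * s, _BG_STD_FACTORS[0] * s,
        0.0, m + _TP_MEAN_MIN_STD * s, _TP_STD_MIN_BINS * bin_width,
    ]
    upper = [
        2.0 * bg_amp0, m + _BG_MEAN_SLACK_STD * s, _BG_STD_FACTORS[1] * s,
        2.0 * bg_amp0, float(scores.max()) + s, float(scores.max() - scores.min()) + s,
    ]
    p0 = np.clip(
        [bg_amp0, m, s, tp_amp0, tp_mean0, tp_std0],
        lower,
        upper,
    )
    try:
        popt, _ = optimize.curve_fit(
            _two_gaussians,
            hist.bin_centers,
            hist.counts.astype(float),
            p0=p0,
            bounds=(lower, upper),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"bimodal fit did not converge: {err}") from err

    a1, m1, s1, a2, m2, s2 = (float(v) for v in popt)
    if m1 > m2:  # enforce tp_mean > bg_mean
        a1, m1, s1, a2, m2, s2 = a2, m2, s2, a1, m1, s1
    resid = float(np.linalg.norm(_two_gaussians(hist.bin_centers, a1, m1, s1, a2, m2, s2) - hist.counts))
    return BimodalFitResult(
        bg_mean=m1, bg_std=s1, bg_amplitude=a1,
        tp_mean=m2, tp_std=s2, tp_amplitude=a2,
        bin_width=bin_width, residual_norm=resid,
    )


def sensitivity_fdr(fit: BimodalFitResult, cutoff: float) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and FDR FP/(FP+TP) at a score cutoff.

    TP and FP are the upper-tail masses of the fitted particle and
    background components, scaled to counts through the Gaussian integrals.
    """
    tp_total = fit.estimated_tp_count
    bg_total = fit.estimated_bg_count
    tp = tp_total * float(_scipy_stats.norm.sf(cutoff, fit.tp_mean, fit.tp_std))
    fp = bg_total * float(_scipy_stats.norm.sf(cutoff, fit.bg_mean, fit.bg_std))
    sensitivity = tp / tp_total if tp_total > 0 else 0.0
    fdr = fp / (fp + tp) if fp + tp > 0 else 0.0
    return sensitivity, fdr


@dataclass
class RocCurve:
    """Sensitivity-versus-FDR curve over an ordered cutoff grid."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    fdr: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.cutoffs) == len(self.sensitivity) == len(self.fdr)):
            raise ValueError("curve arrays must share one length")
        if len(self.cutoffs) == 0:
            raise ValueError("empty ROC curve")


@dataclass(frozen=True)
class RucPoint:
    """Operating point with the largest rectangle sensitivity * (1 - FDR)."""

    cutoff: float
    sensitivity: float
    fdr: float
    ruc_value: float


def roc_curve(
    fit: BimodalFitResult,
    cutoff_lo: float | None = None,
    cutoff_hi: float | None = None,
    n_samples: int = ROC_SAMPLES,
) -> RocCurve:
    """Evaluate the fitted model on a grid of evenly spaced cutoffs.

    Defaults span the fitted components out to four standard deviations.
    """
    if cutoff_lo is None:
        cutoff_lo = fit.bg_mean - 4.0 * fit.bg_std
    if cutoff_hi is None:
        cutoff_hi = fit.tp_mean + 4.0 * fit.tp_std
    cutoffs = np.linspace(cutoff_lo, cutoff_hi, n_samples)
    sens = np.empty(n_samples)
    fdr = np.empty(n_samples)
    for i, c in enumerate(cutoffs):
        sens[i], fdr[i] = sensitivity_fdr(fit, float(c))
    return RocCurve(cutoffs=cutoffs, sensitivity=sens, fdr=fdr)


def ruc_point(curve: RocCurve) -> RucPoint:
    """Best operating point: maximum of sensitivity * (1 - FDR).

    Ties are broken in favor of the higher cutoff.
    """
    rect = curve.sensitivity * (1.0 - curve.fdr)
    best = int(np.flatnonzero(rect == rect.max())[-1])
    return RucPoint(
        cutoff=float(curve.cutoffs[best]),
        sensitivity=float(curve.sensitivity[best]),
        fdr=float(curve.fdr[best]),
        ruc_value=float(rect[best]),
    )
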