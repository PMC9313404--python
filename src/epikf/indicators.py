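"""Conventional severity indicators for 5-s EEG segments.

Three quantities commonly used to grade epileptiform activity, computed on
the same windows as the filter-based excitability estimate so the four can
be compared like for like:

* **band power** ``P_b`` — spectral power integrated over 4-50 Hz,
  reported on a log10 scale;
* **Teager energy** ``E_T`` — the log10 mean of a quadratic local energy
  operator that grows with both amplitude and frequency of spiking;
* **sample entropy** ``SEn`` — the negative log conditional probability
  that runs matching for m points (Chebyshev distance within r*SD) still
  match at m+1 points; regular (seizure-like) signals score low.

Degenerate inputs (flat segments, empty template counts, non-positive
energy averages) are flagged rather than returned as infinities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .model import Segment

__all__ = [
    "IndicatorConfig",
    "IndicatorResult",
    "band_power",
    "band_power_linear",
    "teager_energy",
    "sample_entropy",
    "compute_all",
]


@dataclass(frozen=True)
class IndicatorConfig:
    band: tuple[float, float] = (4.0, 50.0)
    sampen_m: int = 4
    sampen_r: float = 0.1
    sampen_N: int = 2400
    window_s: float = 5.0
    spectral_estimator: str = "welch"  # or "periodogram"
    welch_window_s: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.band[0] < self.band[1]:
            raise ValueError("band edges must satisfy 0 <= low < high")
        if self.sampen_m < 1:
            raise ValueError("embedding length m must be >= 1")
        if self.sampen_r <= 0:
            raise ValueError("tolerance coefficient r must be positive")


@dataclass
class IndicatorResult:
    p_b: float
    e_t: float
    sen: float
    label: str = "unknown"
    kind: str = "z"
    seed: int | None = None
    flags: tuple[str, ...] = ()

    @property
    def degenerate(self) -> bool:
        return bool(self.flags)


class DegenerateSegment(ValueError):
    """Raised internally when an indicator is undefined on the input."""


def band_power_linear(seg: Segment, cfg: IndicatorConfig | None = None) -> float:
    """Band power in linear units (mV^2), integrated over the configured band."""
    cfg = cfg or IndicatorConfig()
    lo, hi = cfg.band
    if seg.fs <= 2 * hi:
        raise ValueError(f"band edge {hi} Hz must lie below Nyquist ({seg.fs / 2} Hz)")
    x = seg.samples
    if cfg.spectral_estimator == "welch":
        nper = min(len(x), int(round(cfg.welch_window_s * seg.fs)))
        f, psd = sps.welch(x, fs=seg.fs, window="hann", nperseg=nper)
    else:
        f, psd = sps.periodogram(x, fs=seg.fs, window="boxcar")
    mask = (f >= lo) & (f <= hi)
    return float(np.trapezoid(psd[mask], f[mask]))


def band_power(seg: Segment, cfg: IndicatorConfig | None = None) -> tuple[float, tuple[str, ...]]:
    """log10 band power; a flagged NaN for segments with no in-band power."""
    p = band_power_linear(seg, cfg)
    if p <= 0:
        return float("nan"), ("zero_band_power",)
    return float(np.log10(p)), ()


def teager_energy(seg: Segment) -> tuple[float, tuple[str, ...]]:
    """log10 mean of the Teager-type energy operator.

    Over an (N+3)-sample buffer x[1..N+3] (1-based), the operator sums
    x[k-1]*x[k-2] - x[k]*x[k-3] for k = 4..N+3 and divides by N.  For a
    sinusoid the average is 0.5*A^2*(cos w - cos 3w), which grows with both
    amplitude and frequency at EEG rates.  A non-positive average has no
    logarithm and is flagged.
    """
    x = seg.samples
    if len(x) < 7:
        raise ValueError("Teager energy needs at least 7 samples")
    N = len(x) - 3
    # 1-based k=4..N+3 maps to 0-based j=3..N+2
    acc = x[2 : N + 2] * x[1 : N + 1] - x[3 : N + 3] * x[0:N]
    mean = float(acc.sum() / N)
    if mean <= 0:
        return float("nan"), ("nonpositive_teager",)
    return float(np.log10(mean)), ()


def _sampen_counts(x: np.ndarray, m: int, tol: float) -> tuple[int, int]:
    """Ordered-pair template counts at lengths m and m+1 (self-matches excluded).

    Chebyshev distance, strict inequality; both counts are taken over the
    same N - m template start positions so the ratio is a conditional
    probability.
    """
    N = len(x)
    n_templates = N - m  # start positions usable at both lengths
    if n_templates < 2:
        return 0, 0
    diff = np.abs(x[:, None] - x[None, :])
    within = None
    for k in range(m):
        d = diff[k : k + n_templates, k : k + n_templates]
        within = d if within is None else np.maximum(within, d)
    mask_m = within < tol
    d = diff[m : m + n_templates, m : m + n_templates]
    mask_m1 = np.maximum(within, d) < tol
    np.fill_diagonal(mask_m, False)
    np.fill_diagonal(mask_m1, False)
    return int(mask_m.sum()), int(mask_m1.sum())


def sample_entropy(
    seg: Segment, cfg: IndicatorConfig | None = None
) -> tuple[float, tuple[str, ...]]:
    """Sample entropy SEn = ln(B_m / A_{m+1}) on the first N samples.

    The tolerance is r times the segment standard deviation, making the
    measure invariant to amplitude scaling.
    """
    cfg = cfg or IndicatorConfig()
    x = np.asarray(seg.samples, dtype=float)
    N = min(len(x), cfg.sampen_N)
    if N <= cfg.sampen_m + 1:
        raise ValueError(f"need more than m+1={cfg.sampen_m + 1} samples, got {N}")
    x = x[:N]
    sd = float(x.std())
    if sd == 0:
        return float("nan"), ("zero_variance",)
    B_m, A_m1 = _sampen_counts(x, cfg.sampen_m, cfg.sampen_r * sd)
    if A_m1 == 0 or B_m == 0:
        return float("nan"), ("no_template_matches",)
    return float(np.log(B_m / A_m1)), ()


def _resample_to(seg: Segment, fs_target: float) -> Segment:
    from fractions import Fraction

    frac = Fraction(fs_target / seg.fs).limit_denominator(1000)
    y = sps.resample_poly(seg.samples, frac.numerator, frac.denominator)
    return replace(seg, samples=y, fs=fs_target)


def compute_all(seg: Segment, cfg: IndicatorConfig | None = None) -> IndicatorResult:
    """All three indicators on one window, resampled to 480 Hz if needed
    so the sample-entropy length N covers the full 5 s."""
    cfg = cfg or IndicatorConfig()
    fs_target = cfg.sampen_N / cfg.window_s
    work = seg if abs(seg.fs - fs_target) < 1e-9 else _resample_to(seg, fs_target)
    p_b, f1 = band_power(work, cfg)
    e_t, f2 = teager_energy(work)
    sen, f3 = sample_entropy(work, cfg)
    return IndicatorResult(
        p_b=p_b, e_t=e_t, sen=sen, label=seg.label, kind=seg.kind, seed=seg.seed,
        flags=f1 + f2 + f3,
    )
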