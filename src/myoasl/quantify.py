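"""Perfusion quantification from FAIR control/label pairs.

Myocardial blood flow is obtained by inverting the single-compartment
general kinetic model for a FAIR preparation read out after a post-labeling
delay of ``n_rr_delay`` cardiac cycles:

    F = (C - L) / (2 * B * T_D * exp(-T_D / T1_blood))

where C, L and B are the (segment- or pixel-) mean signals of the control,
label and base images, T_D is the post-labeling delay and T1_blood the
longitudinal relaxation time of blood.  With T_D in ms and F reported in
ml/g/min a factor 60000 ms/min converts the units; the blood-tissue
partition coefficient is absorbed as 1 ml/g.

The scan's six control/label pairs give six repeated MBF measurements per
segment.  Their sample standard deviation is the physiological noise (PN);
the ratio tSNR = MBF / PN is the quality-control statistic — segments with
tSNR < 2 are flagged for exclusion (a flag, not a deletion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ASLSeries
from .segmentation import SegmentLabels, region_of, segment_name, spatial_temporal_filter

__all__ = [
    "MS_PER_MIN",
    "TSNR_THRESHOLD",
    "SegmentPerfusion",
    "TimingParams",
    "compute_td",
    "mbf_from_pair",
    "segment_mbf_repeats",
    "physiological_noise",
    "tsnr_and_exclude",
    "mbf_map",
    "quantify_slice",
]

MS_PER_MIN = 60000.0
TSNR_THRESHOLD = 2.0


@dataclass(frozen=True)
class TimingParams:
    """Post-labeling-delay bookkeeping for one scan."""

    t_d: float  # ms
    t1_blood: float  # ms
    n_rr_delay: int
    heart_rate: float  # bpm

    def __post_init__(self) -> None:
        if not (self.t_d > 0 and self.t1_blood > 0 and self.heart_rate > 0):
            raise ValueError("timing parameters must be positive")

    @classmethod
    def from_series(cls, series: ASLSeries) -> "TimingParams":
        return cls(
            t_d=compute_td(series.heart_rate, series.n_rr_delay),
            t1_blood=series.t1_blood,
            n_rr_delay=series.n_rr_delay,
            heart_rate=series.heart_rate,
        )


@dataclass
class SegmentPerfusion:
    """Per-segment quantification result for one scan."""

    segment: int
    name: str
    region: str
    mbf_repeats: np.ndarray  # six per-pair MBF values, ml/g/min
    mbf_mean: float
    pn: float
    tsnr: float
    included: bool


def compute_td(heart_rate: float, n_rr_delay: int = 2) -> float:
    """Post-labeling delay in ms: ``n_rr_delay`` RR intervals at ``heart_rate`` bpm."""
    if heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    if n_rr_delay < 1:
        raise ValueError("n_rr_delay must be >= 1")
    return n_rr_delay * MS_PER_MIN / heart_rate


def buxton_denominator(B, t_d: float, t1_blood: float):
    """2 * B * T_D * exp(-T_D/T1_blood), the model's normalization term."""
    return 2.0 * B * t_d * np.exp(-t_d / t1_blood)


def mbf_from_pair(C, L, B, t_d: float, t1_blood: float):
    """MBF (ml/g/min) from control, label and base signals.

    Accepts scalars or arrays (broadcast).  Values may be negative under
    noise; no clipping is applied, since clipping would bias both PN and
    group means.
    """
    if t_d <= 0 or t1_blood <= 0:
        raise ValueError("t_d and t1_blood must be positive")
    B = np.asarray(B, dtype=float)
    if np.any(B <= 0):
        raise ValueError("base signal B must be positive (normalization undefined otherwise)")
    return MS_PER_MIN * (np.asarray(C, dtype=float) - np.asarray(L, dtype=float)) / buxton_denominator(B, t_d, t1_blood)


def segment_mbf_repeats(series: ASLSeries, labels: SegmentLabels) -> np.ndarray:
    """Per-segment, per-pair MBF: a 6x6 matrix (segment index 1..6 -> row 0..5).

    Each entry uses the segment-mean control, label and base signals; the
    post-labeling delay comes from the series' recorded heart rate.
    """
    if labels.labels.shape != series.shape:
        raise ValueError("label map grid does not match series grid")
    timing = TimingParams.from_series(series)
    out = np.empty((6, len(series.pairs)))
    for s in range(1, 7):
        idx = labels.pixels(s)
        if not idx.any():
            raise ValueError(f"segment {s} ({segment_name(s)}) has no pixels")
        b_bar = series.base_image[idx].mean()
        for i, (c, l) in enumerate(series.pairs):
            out[s - 1, i] = mbf_from_pair(
                c[idx].mean(), l[idx].mean(), b_bar, timing.t_d, timing.t1_blood
            )
    return out


def physiological_noise(mbf_repeats) -> float:
    """Sample SD (n-1 denominator) of the six repeated MBF measurements."""
    r = np.asarray(mbf_repeats, dtype=float)
    if r.shape != (6,):
        raise ValueError(f"expected exactly 6 MBF repeats, got shape {r.shape}")
    return float(np.std(r, ddof=1))


def tsnr_and_exclude(
    mbf_mean: float, pn: float, threshold: float = TSNR_THRESHOLD
) -> tuple[float, bool]:
    """Temporal SNR (MBF/PN) and the inclusion flag (tSNR >= threshold).

    PN of exactly zero is the noise-free limit: tSNR is +inf for positive
    MBF (included) and -inf otherwise (excluded).  A segment sitting exactly
    at the threshold is included.
    """
    if pn < 0:
        raise ValueError("pn must be >= 0")
    if pn == 0:
        tsnr = float(np.inf if mbf_mean > 0 else -np.inf)
    else:
        tsnr = float(mbf_mean / pn)
    return tsnr, bool(tsnr >= threshold)


def mbf_map(
    series: ASLSeries,
    mask,
    spatial_radius: float = 1.0,
    temporal: bool = False,
    base_mode: str = "pixel",
    labels: SegmentLabels | None = None,
) -> np.ndarray:
    """Pixelwise MBF image over the myocardium; background is NaN.

    The control and label stacks are smoothed with the spatial-temporal
    filter, averaged across the six pairs, and inverted per pixel.  The
    base normalization is per-pixel by default; ``base_mode='segment'``
    normalizes by the segment-mean base signal instead (``labels``
    required), which matches the segment-level quantification exactly on
    piecewise-uniform input.
    """
    m = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    timing = TimingParams.from_series(series)
    c_mean = spatial_temporal_filter(series.control_stack(), m, spatial_radius, temporal).mean(axis=0)
    l_mean = spatial_temporal_filter(series.label_stack(), m, spatial_radius, temporal).mean(axis=0)
    base = spatial_temporal_filter(series.base_image, m, spatial_radius, False)
    if base_mode == "segment":
        if labels is None:
            raise ValueError("segment base_mode requires a label map")
        b_norm = np.full(m.shape, np.nan)
        for s in range(1, 7):
            idx = labels.pixels(s)
            if idx.any():
                b_norm[idx] = series.base_image[idx].mean()
    elif base_mode == "pixel":
        b_norm = base
    else:
        raise ValueError("base_mode must be 'pixel' or 'segment'")

    out = np.full(m.shape, np.nan)
    bvals = b_norm[m]
    if np.any(~(bvals > 0)):
        raise ValueError("base signal must be positive inside the mask")
    out[m] = mbf_from_pair(c_mean[m], l_mean[m], bvals, timing.t_d, timing.t1_blood)
    return out


def quantify_slice(
    series: ASLSeries,
    labels: SegmentLabels,
    exclusion_enabled: bool = True,
    tsnr_threshold: float = TSNR_THRESHOLD,
) -> list[SegmentPerfusion]:
    """Full per-segment quantification of one scan.

    Returns six :class:`SegmentPerfusion` records.  With
    ``exclusion_enabled=False`` (the post-infarct comparison policy, where
    the infarcted segment is known in advance and expected to have low
    tSNR) every segment is included regardless of its tSNR.
    """
    repeats = segment_mbf_repeats(series, labels)
    results = []
    for s in range(1, 7):
        r = repeats[s - 1]
        mean = float(r.mean())
        pn = physiological_noise(r)
        tsnr, included = tsnr_and_exclude(mean, pn, tsnr_threshold)
        if not exclusion_enabled:
            included = True
        results.append(
            SegmentPerfusion(
                segment=s,
                name=segment_name(s),
                region=region_of(s),
                mbf_repeats=r.copy(),
                mbf_mean=mean,
                pn=pn,
                tsnr=tsnr,
                included=included,
            )
        )
    return results
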