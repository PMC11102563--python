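"""Calcium-imaging analysis.

ROI fluorescence time series (~10 Hz, typically 1800 frames) are
classified into active neurons, active astrocytes and inactive cells:

* an ROI is an **active neuron** when the lag-6 difference of its trace,
  normalized by the recording's maximum amplitude, exceeds 0.05 — fast
  transients complete their rise well inside six frames, whereas the slow
  astrocytic waves do not;
* the remaining ROIs are split by fluorescence ratio Δf/f0 (peak-to-trough
  amplitude over the trace minimum, the baseline): **inactive** when the
  ratio is below 10% of the most active non-neuronal ROI, otherwise an
  **active astrocyte**.

Downstream summaries: per-neuron event counts (peak detection), the mean
fluorescence ratio of the three most active astrocytes, a windowed
pairwise-correlation synchrony score (35-frame windows on moving-average
filtered traces, summed per ROI, reported as the mean of the top 10), and
the whole-spectrum over >0.1 Hz band ratio of the power spectral density,
again averaged over the top ROIs after sorting by event count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, welch

from .config import CalciumConfig
from .io import FluorMatrix

logger = logging.getLogger(__name__)

LABEL_NEURON = "active_neuron"
LABEL_ASTRO = "active_astrocyte"
LABEL_INACTIVE = "inactive"


@dataclass
class SynchronyReport:
    """Per-ROI summed windowed correlations and the top-k summary."""

    roi_ids: List[str]
    corr_sum: np.ndarray          # raw sum over partners and windows
    corr_norm: np.ndarray         # sum / ((n_roi - 1) * n_windows), in [-1, 1]
    ranking: List[str]            # ROI ids sorted by decreasing corr_sum
    top_k_mean_raw: float
    top_k_mean_norm: float
    n_windows: int
    n_zero_variance_windows: int = 0


@dataclass
class PsdRatioReport:
    """Per-ROI full-spectrum / high-band PSD area ratios."""

    roi_ids: List[str]            # sorted by decreasing event count
    ratios: np.ndarray            # >= 1; inf when the high band is empty
    top_k_mean: float
    has_infinite: bool = False


def classify_rois(fm: FluorMatrix, cfg: CalciumConfig) -> pd.DataFrame:
    """Label every ROI as active_neuron / active_astrocyte / inactive.

    Returns a DataFrame with roi_id, label, max_norm_delta (the lag
    statistic) and fluor_ratio (Δf/f0; reported for every ROI).
    """
    F = fm.F
    if fm.n_frames <= cfg.lag_frames:
        raise ValueError("recording shorter than the classification lag")
    amp = F.max(axis=1) - F.min(axis=1)

    lag = cfg.lag_frames
    delta = np.abs(F[:, lag:] - F[:, :-lag]).max(axis=1)
    if cfg.delta_norm == "recording":
        ref = amp.max() if amp.size else 0.0
        denom = np.full(fm.n_roi, ref)
    elif cfg.delta_norm == "trace":
        denom = amp
    else:  # "max"
        denom = F.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        max_norm_delta = np.where(denom > 0, delta / denom, 0.0)
    is_neuron = max_norm_delta > cfg.neuron_threshold

    baseline = F.min(axis=1)
    if np.any(baseline[~is_neuron] <= 0):
        raise ValueError(
            "non-positive baseline fluorescence; apply an offset correction "
            "before classification"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fluor_ratio = np.where(baseline > 0, amp / baseline, 0.0)

    labels = np.full(fm.n_roi, LABEL_INACTIVE, dtype=object)
    labels[is_neuron] = LABEL_NEURON
    rest = ~is_neuron
    if rest.any():
        ref_ratio = fluor_ratio[rest].max()
        active = rest & (fluor_ratio >= cfg.inactive_fraction * ref_ratio) & (ref_ratio > 0)
        labels[active] = LABEL_ASTRO
    return pd.DataFrame(
        {
            "roi_id": fm.roi_ids,
            "label": labels,
            "max_norm_delta": max_norm_delta,
            "fluor_ratio": fluor_ratio,
        }
    )


def count_neuron_events(
    trace: np.ndarray, frame_rate_hz: float, cfg: CalciumConfig
) -> Tuple[int, float]:
    """Count fast calcium transients of one active-neuron trace.

    Peaks must rise by at least ``prominence_fraction`` of the trace's
    amplitude and be separated by ``min_event_sep_frames``. Returns
    ``(count, rate_hz)``.
    """
    x = np.asarray(trace, dtype=float)
    amp = x.max() - x.min()
    if amp == 0:
        return 0, 0.0
    peaks, _ = find_peaks(
        x,
        prominence=cfg.prominence_fraction * amp,
        distance=cfg.min_event_sep_frames,
    )
    rate = peaks.size / (x.size / frame_rate_hz)
    return int(peaks.size), float(rate)


def astrocyte_summary(
    classification: pd.DataFrame, cfg: CalciumConfig
) -> Tuple[Optional[float], int]:
    """Mean fluorescence ratio of the most active astrocytes.

    Averages the top ``n_top_astrocytes`` ratios; with fewer astrocytes all
    are averaged (the count is returned so callers can flag it); with none,
    ``(None, 0)`` is returned with a warning rather than an error.
    """
    ratios = classification.loc[
        classification.label == LABEL_ASTRO, "fluor_ratio"
    ].to_numpy()
    if ratios.size == 0:
        logger.warning("no astrocytes in recording; astrocyte summary missing")
        return None, 0
    top = np.sort(ratios)[::-1][: cfg.n_top_astrocytes]
    return float(top.mean()), int(top.size)


def _windowed_pearson(x: np.ndarray, y: np.ndarray, w: int) -> np.ndarray:
    """Pearson correlation over every length-w window (stride 1).

    Zero-variance windows yield NaN; the caller decides the convention.
    """
    def roll(a):
        c = np.concatenate([[0.0], np.cumsum(a)])
        return c[w:] - c[:-w]

    sx, sy = roll(x), roll(y)
    sxx, syy, sxy = roll(x * x), roll(y * y), roll(x * y)
    cov = w * sxy - sx * sy
    varx = w * sxx - sx * sx
    vary = w * syy - sy * sy
    denom = np.sqrt(np.clip(varx, 0, None) * np.clip(vary, 0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / denom
    r[denom <= 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(np.pad(x, w // 2, mode="edge"), kernel, mode="valid")[: x.size]


def synchrony(
    fm: FluorMatrix, cfg: CalciumConfig, roi_ids: Optional[List[str]] = None
) -> SynchronyReport:
    """Windowed-correlation synchrony of an active-neuron population.

    For every unordered ROI pair, Pearson correlations are computed over
    all 35-frame windows (stride 1) of moving-average-filtered traces and
    summed into both ROIs' scores. ROIs are ranked by their summed score;
    the top-k mean is reported both raw and normalized by
    (n_roi - 1) * n_windows, the latter lying in [-1, 1].
    """
    F = fm.F
    n, T = F.shape
    w = cfg.corr_window_frames
    if n < 2:
        raise ValueError("synchrony requires at least 2 neuron ROIs")
    if T < w:
        raise ValueError("recording shorter than the correlation window")
    ids = roi_ids if roi_ids is not None else fm.roi_ids
    sm = np.vstack([_moving_average(F[i], cfg.ma_filter_frames) for i in range(n)])
    n_windows = T - w + 1
    scores = np.zeros(n)
    n_bad = 0
    for i in range(n):
        for j in range(i + 1, n):
            r = _windowed_pearson(sm[i], sm[j], w)
            bad = np.isnan(r)
            n_bad += int(bad.sum())
            s = float(np.where(bad, 0.0, r).sum())
            scores[i] += s
            scores[j] += s
    if n_bad:
        logger.info("synchrony: %d zero-variance windows contributed 0", n_bad)
    norm = scores / ((n - 1) * n_windows)
    order = np.argsort(-scores, kind="stable")
    k = min(cfg.top_k, n)
    top = order[:k]
    return SynchronyReport(
        roi_ids=list(ids),
        corr_sum=scores,
        corr_norm=norm,
        ranking=[ids[i] for i in order],
        top_k_mean_raw=float(scores[top].mean()),
        top_k_mean_norm=float(norm[top].mean()),
        n_windows=n_windows,
        n_zero_variance_windows=n_bad,
    )


def psd_ratio(
    fm: FluorMatrix,
    event_counts: np.ndarray,
    cfg: CalciumConfig,
    roi_ids: Optional[List[str]] = None,
) -> PsdRatioReport:
    """Whole-spectrum over high-band PSD area ratio per neuron.

    Neurons are sorted by event count (descending); each trace's PSD is
    estimated by Welch's averaged periodogram and integrated by the
    trapezoidal rule over the full frequency axis and over frequencies
    strictly above ``psd_high_cutoff_hz``. A trace with no high-band power
    reports an infinite ratio and is flagged.
    """
    F = fm.F
    n, T = F.shape
    if n < 1:
        raise ValueError("psd_ratio requires at least 1 neuron ROI")
    ids = roi_ids if roi_ids is not None else fm.roi_ids
    counts = np.asarray(event_counts)
    if counts.size != n:
        raise ValueError("event_counts length must match number of ROIs")
    order = np.argsort(-counts, kind="stable")
    nper = min(cfg.psd_nperseg, T)
    ratios = np.empty(n)
    has_inf = False
    for rank, i in enumerate(order):
        f, p = welch(F[i], fs=fm.frame_rate_hz, nperseg=nper, detrend="constant")
        full = np.trapezoid(p, f)
        high = f > cfg.psd_high_cutoff_hz
        high_area = np.trapezoid(p[high], f[high]) if high.sum() >= 2 else 0.0
        if high_area <= 0:
            ratios[rank] = np.inf
            has_inf = True
            logger.warning("ROI %s: no high-band power; ratio set to inf", ids[i])
        else:
            ratios[rank] = max(1.0, full / high_area)
    k = min(cfg.top_k, n)
    return PsdRatioReport(
        roi_ids=[ids[i] for i in order],
        ratios=ratios,
        top_k_mean=float(ratios[:k].mean()),
        has_infinite=has_inf,
    )


def analyze_recording(fm: FluorMatrix, cfg: CalciumConfig) -> dict:
    """Full single-recording calcium analysis.

    Classifies ROIs, counts neuronal events, summarizes astrocytes, and —
    when at least two active neurons are present — computes synchrony and
    PSD-ratio reports. Returns a dict with the per-ROI table and summary
    scalars.
    """
    cls = classify_rois(fm, cfg)
    neuron_mask = (cls.label == LABEL_NEURON).to_numpy()
    counts = np.zeros(fm.n_roi, dtype=int)
    rates = np.zeros(fm.n_roi)
    for i in np.flatnonzero(neuron_mask):
        counts[i], rates[i] = count_neuron_events(fm.F[i], fm.frame_rate_hz, cfg)
    cls = cls.assign(event_count=counts, event_rate_hz=rates)
    astro_mean, astro_n = astrocyte_summary(cls, cfg)

    out = {
        "roi_table": cls,
        "n_neurons": int(neuron_mask.sum()),
        "n_astrocytes": int((cls.label == LABEL_ASTRO).sum()),
        "n_inactive": int((cls.label == LABEL_INACTIVE).sum()),
        "astro_top_mean_ratio": astro_mean,
        "astro_n_averaged": astro_n,
        "neuron_mean_event_rate_hz": float(rates[neuron_mask].mean())
        if neuron_mask.any()
        else None,
        "synchrony": None,
        "psd": None,
    }
    if neuron_mask.sum() >= 2:
        sub = FluorMatrix(
            F=fm.F[neuron_mask],
            frame_rate_hz=fm.frame_rate_hz,
            roi_ids=[r for r, m in zip(fm.roi_ids, neuron_mask) if m],
        )
        out["synchrony"] = synchrony(sub, cfg)
        out["psd"] = psd_ratio(sub, counts[neuron_mask], cfg)
    return out
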