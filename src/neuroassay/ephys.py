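"""Patch-clamp feature extraction.

Four procedures:

* **Evoked spike counting** — spikes summed over the first 30 (hippocampal)
  or 32 (dopaminergic) depolarization steps of the 3-pA ladder; cells
  needing more than 50 pA of holding current to sit at -60 mV are excluded.
* **Spike shape** — features of the rheobase spike (the first spike evoked
  with the least injected current): threshold at the first maximum of
  d2V/dt2 on the rising phase, amplitude above threshold, full width at
  half amplitude, and the fast afterhyperpolarization 5 ms after the
  potential re-crosses threshold.
* **Na / K current extraction** — capacitance-normalized peak inward sodium
  current, peak early outward (fast) potassium current and sustained
  end-of-step (slow) potassium current per voltage step, with one-way ANOVA
  group comparisons restricted to the [-20, 0] mV (Na) and [40, 80] mV (K)
  windows.
* **EPSC statistics** — threshold detection of spontaneous negative-going
  synaptic currents; rate counts silent cells as zero, mean amplitude is
  taken over detected events, and amplitudes pool into per-group empirical
  cumulative distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import AnalysisConfig
from .io import CURRENT_CLAMP, VOLTAGE_CLAMP, SweepSet, Trace
from .stats import anova_oneway, mean_se


class NoSpikeError(ValueError):
    """No sweep of the set contains a detectable spike."""


@dataclass
class SpikeFeatures:
    """Rheobase-spike descriptors plus the evoked-spike total."""

    total_evoked_aps: Optional[int] = None
    threshold_mv: Optional[float] = None
    amplitude_mv: Optional[float] = None
    width_ms: Optional[float] = None
    fahp5_mv: Optional[float] = None
    rheobase_step: Optional[int] = None
    excluded: bool = False
    exclusion_reason: Optional[str] = None


@dataclass
class SynapticSummary:
    """Per-cell spontaneous-EPSC summary; silent cells keep rate 0."""

    n_events: int
    rate_hz: float
    mean_amplitude_pa: Optional[float]  # undefined when n_events == 0
    amplitudes_pa: np.ndarray
    event_times_s: np.ndarray


# ---------------------------------------------------------------------------
# spike detection and counting
# ---------------------------------------------------------------------------

def detect_spikes(
    trace: np.ndarray,
    sampling_rate_hz: float,
    level_mv: float = -10.0,
    refractory_ms: float = 3.0,
) -> np.ndarray:
    """Spike apexes: local maxima above ``level_mv`` pruned to a minimum
    separation of ``refractory_ms``, keeping the larger (then earlier) of
    any conflicting pair. Returns apex sample indices in time order."""
    v = np.asarray(trace, dtype=float)
    if v.size < 3:
        return np.array([], dtype=int)
    cand, _ = find_peaks(v, height=level_mv)
    if cand.size == 0:
        return cand
    refractory = int(round(refractory_ms / 1000.0 * sampling_rate_hz))
    # greedy pruning: biggest first, earlier wins ties
    order = sorted(range(cand.size), key=lambda i: (-v[cand[i]], cand[i]))
    accepted: List[int] = []
    for i in order:
        idx = cand[i]
        if all(abs(idx - a) >= refractory for a in accepted):
            accepted.append(idx)
    return np.array(sorted(accepted), dtype=int)


def count_evoked_aps(sweeps: SweepSet, cfg: AnalysisConfig) -> SpikeFeatures:
    """Total spikes over the first ``n_steps_counted`` depolarization steps.

    Cells whose holding current exceeds ``holding_current_max_pa`` in
    magnitude are excluded rather than counted.
    """
    if sweeps.protocol.mode != CURRENT_CLAMP:
        raise ValueError("count_evoked_aps requires a current-clamp sweep set")
    if abs(sweeps.holding_current_pa) > cfg.holding_current_max_pa:
        return SpikeFeatures(
            excluded=True,
            exclusion_reason=f"holding>{cfg.holding_current_max_pa:g}pA",
        )
    if sweeps.n_steps < cfg.n_steps_counted:
        raise ValueError(
            f"sweep set has {sweeps.n_steps} steps; "
            f"{cfg.n_steps_counted} are required for counting"
        )
    total = 0
    for s in range(cfg.n_steps_counted):
        total += detect_spikes(
            sweeps.traces[s],
            sweeps.sampling_rate_hz,
            cfg.spike_detect_level_mv,
            cfg.spike_refractory_ms,
        ).size
    return SpikeFeatures(total_evoked_aps=int(total))


# ---------------------------------------------------------------------------
# spike shape
# ---------------------------------------------------------------------------

def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    return np.convolve(np.pad(x, w // 2, mode="edge"), kernel, mode="valid")[: x.size]


def _interp_crossing(t0: int, x0: float, x1: float, level: float) -> float:
    """Sub-sample index where a line from x0 to x1 crosses ``level``."""
    if x1 == x0:
        return float(t0)
    return t0 + (level - x0) / (x1 - x0)


def spike_shape(sweeps: SweepSet, cfg: AnalysisConfig) -> SpikeFeatures:
    """Shape features of the rheobase spike.

    The first spike of the lowest step that evokes any spike is analyzed.
    The second derivative is computed by central differences on a 5-sample
    moving mean of the trace; "first maximum" is the first (possibly
    plateau-leading) local maximum of d2V/dt2 in the 10 ms preceding the
    apex.
    """
    fs = sweeps.sampling_rate_hz
    dt_ms = 1000.0 / fs
    apex = None
    rheo_step = None
    for s in range(sweeps.n_steps):
        idx = detect_spikes(
            sweeps.traces[s], fs, cfg.spike_detect_level_mv, cfg.spike_refractory_ms
        )
        if idx.size:
            apex = int(idx[0])
            rheo_step = s
            break
    if apex is None:
        raise NoSpikeError("no rheobase spike: no sweep evokes a spike")

    v = sweeps.traces[rheo_step]
    vs = _moving_mean(v, 5)
    d2 = np.zeros_like(vs)
    d2[1:-1] = vs[2:] - 2 * vs[1:-1] + vs[:-2]

    win = int(round(10.0 / dt_ms))
    lo = max(1, apex - win)
    # only curvature maxima comparable to the window's peak count; the
    # rising phase is otherwise dominated by numerically flat segments
    d2_floor = 0.05 * d2[lo:apex].max() if apex > lo else 0.0
    thr_idx = None
    for j in range(lo + 1, apex):
        if d2[j] > d2[j - 1] and d2[j] >= d2[j + 1] and d2[j] >= d2_floor:
            # smoothing turns a sharp kink into a short curvature plateau;
            # its midpoint, not its left edge, marks the threshold
            b = j
            while b + 1 < apex and d2[b + 1] >= 0.999 * d2[j]:
                b += 1
            thr_idx = (j + b) // 2
            break
    if thr_idx is None:  # monotone curvature: fall back to the steepest point
        thr_idx = lo + int(np.argmax(d2[lo:apex])) if apex > lo else lo
    threshold = float(v[thr_idx])
    amplitude = float(v[apex] - threshold)
    if amplitude <= 0:
        raise NoSpikeError("degenerate spike: apex does not exceed threshold")

    half = threshold + amplitude / 2.0
    # rising crossing: last sub-half sample before the apex
    i = apex
    while i > 0 and v[i - 1] >= half:
        i -= 1
    rise_t = _interp_crossing(i - 1, v[i - 1], v[i], half) if i > 0 else float(i)
    # falling crossing: first sub-half sample after the apex
    j = apex
    while j < v.size - 1 and v[j + 1] >= half:
        j += 1
    fall_t = (
        _interp_crossing(j, v[j], v[j + 1], half) if j < v.size - 1 else float(j)
    )
    width_ms = (fall_t - rise_t) * dt_ms

    # post-apex downward threshold crossing
    k = apex
    while k < v.size - 1 and v[k + 1] > threshold:
        k += 1
    if k >= v.size - 1:
        fahp5 = None
    else:
        t_return = _interp_crossing(k, v[k], v[k + 1], threshold)
        t_meas = t_return + cfg.fahp_delay_ms / dt_ms
        if t_meas >= v.size - 1:
            fahp5 = None
        else:
            m = int(math.floor(t_meas))
            frac = t_meas - m
            v_meas = v[m] * (1 - frac) + v[m + 1] * frac
            fahp5 = float(threshold - v_meas)

    return SpikeFeatures(
        threshold_mv=threshold,
        amplitude_mv=amplitude,
        width_ms=float(width_ms),
        fahp5_mv=fahp5,
        rheobase_step=rheo_step,
    )


# ---------------------------------------------------------------------------
# voltage-clamp currents
# ---------------------------------------------------------------------------

def extract_iv(sweeps: SweepSet, cfg: AnalysisConfig) -> pd.DataFrame:
    """Capacitance-normalized current table, one row per voltage step.

    na_peak: most negative current within ``na_search_ms`` of step onset
    (clipped at <= 0; inward convention). kfast: largest current within
    ``fast_k_window_ms`` of onset. kslow: mean current over the final
    ``slow_k_tail_ms`` of the step. All in pA/pF.
    """
    if sweeps.protocol.mode != VOLTAGE_CLAMP:
        raise ValueError("extract_iv requires a voltage-clamp sweep set")
    cap = sweeps.capacitance_pf
    if cap is None or cap <= 0:
        raise ValueError("positive capacitance required for normalization")
    fs = sweeps.sampling_rate_hz
    onset = sweeps.step_onset_index()
    end = sweeps.step_end_index()
    na_n = int(round(cfg.na_search_ms / 1000.0 * fs))
    kf_n = int(round(cfg.fast_k_window_ms / 1000.0 * fs))
    tail_n = int(round(cfg.slow_k_tail_ms / 1000.0 * fs))

    rows = []
    for s, v_step in enumerate(sweeps.protocol.step_voltages_mv()):
        i = sweeps.traces[s]
        rows.append(
            {
                "test_potential_mv": float(v_step),
                "na_peak_pa_per_pf": min(0.0, float(i[onset : onset + na_n].min()) / cap),
                "kfast_pa_per_pf": float(i[onset : onset + kf_n].max()) / cap,
                "kslow_pa_per_pf": float(i[end - tail_n : end].mean()) / cap,
            }
        )
    return pd.DataFrame(rows)


_WINDOWS = {
    "na_peak_pa_per_pf": "na_window_mv",
    "kfast_pa_per_pf": "k_window_mv",
    "kslow_pa_per_pf": "k_window_mv",
}


def iv_window_stats(
    tables: Dict[str, Sequence[pd.DataFrame]], cfg: AnalysisConfig
) -> pd.DataFrame:
    """Group comparison of Na / fast-K / slow-K densities.

    Rows are restricted to the analysis windows ([-20, 0] mV for sodium,
    [40, 80] mV for potassium, both inclusive); a one-way ANOVA across
    groups is run at every retained test potential, plus a pooled row using
    each cell's mean density over its window.
    """
    if len(tables) < 2 or any(len(cells) < 2 for cells in tables.values()):
        raise ValueError("iv_window_stats requires >= 2 groups with >= 2 cells each")
    records = []
    for current, window_attr in _WINDOWS.items():
        lo, hi = getattr(cfg, window_attr)
        potentials = None
        for cells in tables.values():
            for tab in cells:
                sel = tab[(tab.test_potential_mv >= lo) & (tab.test_potential_mv <= hi)]
                if sel.empty:
                    raise ValueError(
                        f"no test potentials inside [{lo}, {hi}] mV for {current}"
                    )
                pots = tuple(sel.test_potential_mv)
                if potentials is None:
                    potentials = pots
                elif pots != potentials:
                    raise ValueError("cells disagree on retained test potentials")
        for v in potentials:
            groups = {
                g: [
                    float(tab.loc[tab.test_potential_mv == v, current].iloc[0])
                    for tab in cells
                ]
                for g, cells in tables.items()
            }
            cmp = anova_oneway(list(groups.values()))
            rec = {
                "current": current,
                "test_potential_mv": v,
                "F": cmp.statistic,
                "p": cmp.p_value,
            }
            for g, vals in groups.items():
                m, se = mean_se(vals)
                rec[f"mean_{g}"] = m
                rec[f"se_{g}"] = se
            records.append(rec)
        # pooled: per-cell mean over the window
        pooled = {
            g: [
                float(
                    tab[(tab.test_potential_mv >= lo) & (tab.test_potential_mv <= hi)][
                        current
                    ].mean()
                )
                for tab in cells
            ]
            for g, cells in tables.items()
        }
        cmp = anova_oneway(list(pooled.values()))
        rec = {
            "current": current,
            "test_potential_mv": np.nan,
            "F": cmp.statistic,
            "p": cmp.p_value,
        }
        for g, vals in pooled.items():
            m, se = mean_se(vals)
            rec[f"mean_{g}"] = m
            rec[f"se_{g}"] = se
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# spontaneous EPSCs
# ---------------------------------------------------------------------------

def _block_median_baseline(x: np.ndarray, block: int) -> np.ndarray:
    """Baseline as block medians linearly interpolated between block
    centers; cheap and drift-tracking at the >= 1 s scales that matter."""
    n = x.size
    if block >= n:
        return np.full(n, np.median(x))
    n_blocks = n // block
    centers = np.arange(n_blocks) * block + block / 2.0
    meds = np.array([np.median(x[i * block : (i + 1) * block]) for i in range(n_blocks)])
    return np.interp(np.arange(n), centers, meds)


def detect_epscs(trace: Trace, cfg: AnalysisConfig) -> SynapticSummary:
    """Detect spontaneous EPSCs in a gap-free voltage-clamp trace.

    The trace is box-smoothed (``smooth_ms``); the baseline is a piecewise
    median (``baseline_window_s`` blocks); the noise scale is the MAD-based
    robust SD of the baseline-subtracted smoothed trace. Events are
    negative deflections exceeding ``threshold_sd`` noise SDs, at least
    ``min_interval_ms`` apart; amplitudes are |baseline - trough| on the
    smoothed trace.
    """
    fs = trace.sampling_rate_hz
    x = trace.samples
    ecfg = cfg.epsc
    smooth_n = max(1, int(round(ecfg.smooth_ms / 1000.0 * fs)))
    xs = _moving_mean(x, smooth_n)
    base = _block_median_baseline(xs, max(1, int(round(ecfg.baseline_window_s * fs))))
    resid = xs - base
    mad = np.median(np.abs(resid - np.median(resid)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0.0:
        noise_sd = max(resid.std(), np.finfo(float).tiny)
    thr = ecfg.threshold_sd * noise_sd
    distance = max(1, int(round(ecfg.min_interval_ms / 1000.0 * fs)))
    # prominence keeps noise ripples riding on an event's decay tail from
    # re-triggering; a genuine event always rises by its own amplitude
    peaks, props = find_peaks(-resid, height=thr, distance=distance, prominence=thr)
    amplitudes = props["peak_heights"] if peaks.size else np.array([])
    duration = trace.duration_s
    n_events = int(peaks.size)
    return SynapticSummary(
        n_events=n_events,
        rate_hz=n_events / duration if duration > 0 else 0.0,
        mean_amplitude_pa=float(amplitudes.mean()) if n_events else None,
        amplitudes_pa=np.asarray(amplitudes, dtype=float),
        event_times_s=peaks / fs,
    )


def pooled_ecdf(amplitudes: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Right-continuous empirical CDF of pooled event amplitudes.

    Returns ``(x, F)`` with x the sorted unique amplitudes and
    F(x_i) = P(X <= x_i); F at the largest amplitude is exactly 1.
    """
    a = np.asarray(amplitudes, dtype=float)
    if a.size == 0:
        raise ValueError("pooled_ecdf requires at least one amplitude")
    x = np.unique(a)
    F = np.searchsorted(np.sort(a), x, side="right") / a.size
    return x, F


def ecdf_at(x: np.ndarray, F: np.ndarray, q: float) -> float:
    """Evaluate a right-continuous step ECDF at an arbitrary point."""
    i = np.searchsorted(x, q, side="right") - 1
    return 0.0 if i < 0 else float(F[i])
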