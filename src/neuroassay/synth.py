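"""Synthetic recordings and gene sets with exact ground truth.

Each generator emulates one input modality of the analysis pipeline and
returns, alongside the data, a :class:`GroundTruth` record sufficient to
score every downstream operation without re-simulation:

* evoked spike trains on the 3-pA / 400-ms current-step ladder, built from
  a parametric spike template whose threshold, amplitude, width and fast
  afterhyperpolarization are exact by construction;
* voltage-clamp sweeps as a sum of an inward transient sodium term, a fast
  decaying outward potassium term and a sustained potassium plateau;
* gap-free EPSC traces as a homogeneous Poisson train of negative-going
  biexponential events in Gaussian noise;
* calcium-imaging ROI populations mixing fast-transient neurons,
  slow-wave astrocytes and inactive (noise-only) cells, with a shared
  event stream as the synchrony knob;
* gene-set collections with exact pairwise overlap coefficients and a DEG
  table with a controlled fraction of significant genes.

All randomness flows through one ``numpy.random.Generator`` seeded per
call, so every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import (
    CURRENT_CLAMP,
    VOLTAGE_CLAMP,
    FluorMatrix,
    StimulusProtocol,
    SweepSet,
    Trace,
)


@dataclass
class GroundTruth:
    """Latent values a generator commits to; keys depend on the modality."""

    kind: str
    values: dict = field(default_factory=dict)

    def __getitem__(self, key):
        return self.values[key]


# ---------------------------------------------------------------------------
# current-clamp: evoked spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeTemplate:
    """Parametric action-potential waveform.

    Piecewise linear: a gentle ramp from the inter-spike level to
    ``threshold_mv`` (duration ``ramp_ms``), a linear rise to the apex and a
    linear fall back to threshold (each lasting ``width_ms``, so the full
    width at half amplitude equals ``width_ms`` exactly), a linear sag to
    ``threshold - fahp5_mv`` over exactly 5 ms, and a linear recovery to the
    inter-spike level over ``decay_ms``. Features recovered by the shape
    analysis are therefore exact up to sampling discretization.
    """

    threshold_mv: float = -40.0
    amplitude_mv: float = 80.0
    width_ms: float = 2.0
    fahp5_mv: float = 8.0
    decay_ms: float = 8.0
    ramp_ms: float = 9.0  # ramp-onset kink stays outside the 10-ms d2V window

    def __post_init__(self) -> None:
        if self.width_ms <= 0 or self.amplitude_mv <= 0:
            raise ValueError("width_ms and amplitude_mv must be > 0")

    @property
    def footprint_ms(self) -> float:
        return self.ramp_ms + 2 * self.width_ms + 5.0 + self.decay_ms

    def waveform(self, sampling_rate_hz: float, v_rest_mv: float) -> Tuple[np.ndarray, int]:
        """Sampled waveform starting at ramp onset; returns (v, apex index)."""
        dt = 1000.0 / sampling_rate_hz
        t = np.arange(0.0, self.footprint_ms + dt / 2, dt)
        knots_t = np.array(
            [
                0.0,
                self.ramp_ms,
                self.ramp_ms + self.width_ms,
                self.ramp_ms + 2 * self.width_ms,
                self.ramp_ms + 2 * self.width_ms + 5.0,
                self.footprint_ms,
            ]
        )
        apex_v = self.threshold_mv + self.amplitude_mv
        knots_v = np.array(
            [
                v_rest_mv,
                self.threshold_mv,
                apex_v,
                self.threshold_mv,
                self.threshold_mv - self.fahp5_mv,
                v_rest_mv,
            ]
        )
        v = np.interp(t, knots_t, knots_v)
        apex_idx = int(round((self.ramp_ms + self.width_ms) / dt))
        return v, apex_idx


@dataclass
class EphysSimParams:
    """Evoked-spiking simulation settings."""

    rheobase_step: int = 4
    fi_slope: float = 0.35  # additional spikes per step past rheobase
    template: SpikeTemplate = field(default_factory=SpikeTemplate)
    noise_sd_mv: float = 0.0
    holding_current_pa: float = 20.0
    capacitance_pf: float = 30.0
    subthreshold_depol_mv: float = 5.0

    def __post_init__(self) -> None:
        if self.rheobase_step < 0:
            raise ValueError("rheobase_step must be >= 0")


def spikes_per_step(params: EphysSimParams, n_steps: int) -> np.ndarray:
    """Closed-form spike count ladder: 0 below rheobase, then a unit spike
    plus ``round(fi_slope * steps_past_rheobase)`` extra."""
    counts = np.zeros(n_steps, dtype=int)
    for s in range(n_steps):
        if s >= params.rheobase_step:
            counts[s] = 1 + int(round(params.fi_slope * (s - params.rheobase_step)))
    return counts


def gen_current_clamp(
    params: EphysSimParams,
    protocol: Optional[StimulusProtocol] = None,
    seed: int = 0,
) -> Tuple[SweepSet, GroundTruth]:
    """Simulate a current-clamp sweep set on the 3-pA step ladder."""
    protocol = protocol or StimulusProtocol.current_step_ladder(pre_ms=50.0, post_ms=50.0)
    if protocol.mode != CURRENT_CLAMP:
        raise ValueError("gen_current_clamp requires a current-clamp protocol")
    rng = np.random.default_rng(seed)
    fs = 20_000.0
    dt = 1000.0 / fs
    total_ms = protocol.pre_ms + protocol.step_duration_ms + protocol.post_ms
    n_samp = int(round(total_ms / dt))
    onset = int(round(protocol.pre_ms / dt))
    step_n = int(round(protocol.step_duration_ms / dt))
    rest = protocol.holding_potential_mv

    counts = spikes_per_step(params, protocol.n_steps)
    tpl = params.template
    wave_rest, _apex = tpl.waveform(fs, rest + params.subthreshold_depol_mv)
    footprint_n = wave_rest.size

    traces = np.full((protocol.n_steps, n_samp), rest)
    apex_times: List[np.ndarray] = []
    for s in range(protocol.n_steps):
        v = traces[s]
        # subthreshold depolarization during the step
        v[onset : onset + step_n] = rest + params.subthreshold_depol_mv
        n_sp = counts[s]
        apexes = []
        if n_sp:
            if n_sp * footprint_n > step_n:
                raise ValueError(
                    f"step {s}: {n_sp} spikes do not fit into the "
                    f"{protocol.step_duration_ms:.0f} ms step"
                )
            # evenly spaced, non-overlapping placements
            slot = step_n // n_sp
            for k in range(n_sp):
                start = onset + k * slot + (slot - footprint_n) // 2
                wave, apex_idx = tpl.waveform(fs, rest + params.subthreshold_depol_mv)
                v[start : start + wave.size] = wave
                apexes.append(start + apex_idx)
        apex_times.append(np.array(apexes, dtype=int))
    if params.noise_sd_mv > 0:
        traces = traces + rng.normal(0.0, params.noise_sd_mv, traces.shape)

    ss = SweepSet(
        traces=traces,
        sampling_rate_hz=fs,
        protocol=protocol,
        holding_current_pa=params.holding_current_pa,
        capacitance_pf=params.capacitance_pf,
    )
    gt = GroundTruth(
        kind="current_clamp",
        values={
            "spike_counts": counts,
            "apex_indices": apex_times,
            "template": tpl,
            "rheobase_step": params.rheobase_step,
        },
    )
    return ss, gt


# ---------------------------------------------------------------------------
# voltage-clamp: Na / K currents
# ---------------------------------------------------------------------------

def piecewise_linear(points: Sequence[Tuple[float, float]]) -> Callable[[float], float]:
    """Build a density map V -> pA/pF by linear interpolation through
    (voltage, value) points; flat (zero) outside the covered range."""
    pts = sorted(points)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])

    def f(v: float) -> float:
        return float(np.interp(v, xs, ys, left=0.0, right=0.0))

    return f


def default_na_map() -> Callable[[float], float]:
    # inward transient: activates near -40 mV, peaks around -10 mV,
    # reverses near +60 mV
    return piecewise_linear([(-40, 0), (-10, -110), (60, 0)])


def default_kfast_map() -> Callable[[float], float]:
    return piecewise_linear([(-30, 0), (80, 70)])


def default_kslow_map() -> Callable[[float], float]:
    return piecewise_linear([(-30, 0), (80, 50)])


@dataclass
class VCSimParams:
    """Voltage-clamp simulation settings (current densities in pA/pF)."""

    na_map: Callable[[float], float] = field(default_factory=default_na_map)
    kfast_map: Callable[[float], float] = field(default_factory=default_kfast_map)
    kslow_map: Callable[[float], float] = field(default_factory=default_kslow_map)
    na_latency_ms: float = 1.5
    na_decay_ms: float = 2.0
    kfast_decay_ms: float = 3.0
    noise_sd_pa: float = 0.0


def _na_shape(t_ms: np.ndarray, latency_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak transient: smooth rise peaking exactly at ``latency_ms``,
    exponential decay afterwards."""
    rise_sd = latency_ms / 3.0
    s = np.where(
        t_ms < latency_ms,
        np.exp(-((t_ms - latency_ms) ** 2) / (2 * rise_sd**2)),
        np.exp(-(t_ms - latency_ms) / decay_ms),
    )
    s[t_ms < 0] = 0.0
    return s


def gen_voltage_clamp(
    params: VCSimParams,
    protocol: Optional[StimulusProtocol] = None,
    capacitance_pf: float = 30.0,
    seed: int = 0,
) -> Tuple[SweepSet, GroundTruth]:
    """Simulate a voltage-clamp sweep set over the -90..80 mV ladder."""
    protocol = protocol or StimulusProtocol.voltage_step_ladder()
    if protocol.mode != VOLTAGE_CLAMP:
        raise ValueError("gen_voltage_clamp requires a voltage-clamp protocol")
    if capacitance_pf <= 0:
        raise ValueError("capacitance_pf must be > 0")
    rng = np.random.default_rng(seed)
    fs = 20_000.0
    dt = 1000.0 / fs
    total_ms = protocol.pre_ms + protocol.step_duration_ms + protocol.post_ms
    n_samp = int(round(total_ms / dt))
    onset = int(round(protocol.pre_ms / dt))
    step_n = int(round(protocol.step_duration_ms / dt))
    t_rel = (np.arange(n_samp) - onset) * dt  # ms relative to step onset

    voltages = protocol.step_voltages_mv()
    traces = np.zeros((protocol.n_steps, n_samp))
    na_true = np.zeros(protocol.n_steps)
    kfast_true = np.zeros(protocol.n_steps)
    kslow_true = np.zeros(protocol.n_steps)
    in_step = (t_rel >= 0) & (t_rel < protocol.step_duration_ms)

    for s, v in enumerate(voltages):
        na = params.na_map(v)
        kf = params.kfast_map(v)
        ks = params.kslow_map(v)
        if na > 0:
            raise ValueError("sodium density must be inward (<= 0)")
        if kf < 0 or ks < 0:
            raise ValueError("potassium densities must be outward (>= 0)")
        i = np.zeros(n_samp)
        i += na * capacitance_pf * _na_shape(t_rel, params.na_latency_ms, params.na_decay_ms) * in_step
        i += kf * capacitance_pf * np.where(in_step, np.exp(-np.clip(t_rel, 0, None) / params.kfast_decay_ms), 0.0)
        i += ks * capacitance_pf * in_step
        traces[s] = i
        # noiseless per-step densities, measured as the analysis would
        sl_step = slice(onset, onset + step_n)
        na_win = slice(onset, onset + int(round(10.0 / dt)))
        tail = slice(onset + step_n - int(round(5.0 / dt)), onset + step_n)
        na_true[s] = min(0.0, i[na_win].min() / capacitance_pf)
        kfast_true[s] = i[na_win].max() / capacitance_pf
        kslow_true[s] = i[tail].mean() / capacitance_pf
    if params.noise_sd_pa > 0:
        traces = traces + rng.normal(0.0, params.noise_sd_pa, traces.shape)

    ss = SweepSet(
        traces=traces,
        sampling_rate_hz=fs,
        protocol=protocol,
        capacitance_pf=capacitance_pf,
    )
    gt = GroundTruth(
        kind="voltage_clamp",
        values={
            "test_potentials_mv": voltages,
            "na_peak_pa_per_pf": na_true,
            "kfast_pa_per_pf": kfast_true,
            "kslow_pa_per_pf": kslow_true,
        },
    )
    return ss, gt


# ---------------------------------------------------------------------------
# spontaneous EPSCs
# ---------------------------------------------------------------------------

@dataclass
class EpscSimParams:
    """Poisson EPSC train settings."""

    rate_hz: float = 2.0
    amp_mean_pa: float = 30.0
    amp_sd_pa: float = 5.0
    rise_ms: float = 1.0
    decay_ms: float = 5.0
    duration_s: float = 60.0
    noise_sd_pa: float = 2.0
    sampling_rate_hz: float = 20_000.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if not (self.decay_ms > self.rise_ms > 0):
            raise ValueError("require decay_ms > rise_ms > 0")


def epsc_kernel(params: EpscSimParams) -> np.ndarray:
    """Unit-peak biexponential kernel (positive; events are subtracted)."""
    dt = 1000.0 / params.sampling_rate_hz
    t = np.arange(0.0, params.decay_ms * 8, dt)
    k = np.exp(-t / params.decay_ms) - np.exp(-t / params.rise_ms)
    return k / k.max()


def gen_epsc(params: EpscSimParams, seed: int = 0) -> Tuple[Trace, GroundTruth]:
    """Simulate a gap-free EPSC recording at a -60 mV hold."""
    rng = np.random.default_rng(seed)
    n = int(round(params.duration_s * params.sampling_rate_hz))
    n_events = rng.poisson(params.rate_hz * params.duration_s)
    times_s = np.sort(rng.uniform(0.0, params.duration_s, n_events))
    amps = np.maximum(rng.normal(params.amp_mean_pa, params.amp_sd_pa, n_events), 0.0)
    if params.amp_sd_pa == 0:
        amps = np.full(n_events, params.amp_mean_pa)
    trace = (
        rng.normal(0.0, params.noise_sd_pa, n)
        if params.noise_sd_pa > 0
        else np.zeros(n)
    )
    kernel = epsc_kernel(params)
    for t0, a in zip(times_s, amps):
        i0 = int(round(t0 * params.sampling_rate_hz))
        seg = min(kernel.size, n - i0)
        if seg > 0:
            trace[i0 : i0 + seg] -= a * kernel[:seg]
    tr = Trace(samples=trace, sampling_rate_hz=params.sampling_rate_hz)
    gt = GroundTruth(
        kind="epsc",
        values={"event_times_s": times_s, "amplitudes_pa": amps, "rate_hz": params.rate_hz},
    )
    return tr, gt


# ---------------------------------------------------------------------------
# calcium-imaging populations
# ---------------------------------------------------------------------------

@dataclass
class CalciumSimParams:
    """Mixed neuron / astrocyte / inactive ROI population.

    Neurons fire fast transients (full rise within ``transient_rise_frames``
    <= 2 frames, well inside the 6-frame lag of the classifier); astrocytes
    follow a slow raised-cosine wave whose period keeps their lag-6
    statistic below the 0.05 neuronal threshold; inactive ROIs are baseline
    plus noise. ``shared_drive_fraction`` is the synchrony knob: each event
    of a common Poisson stream is adopted by every neuron with that
    probability, with independent events making up the remaining rate.
    """

    n_neurons: int = 15
    n_astrocytes: int = 5
    n_inactive: int = 5
    neuron_event_rate_hz: float = 0.2
    transient_rise_frames: int = 2
    transient_decay_frames: int = 8
    astro_period_s: float = 60.0
    astro_amplitude_ratio: float = 1.0  # peak delta-f over baseline f0
    neuron_amplitude_ratio: float = 0.5
    baseline_f0: float = 100.0
    shared_drive_fraction: float = 0.0
    noise_sd: float = 0.3
    n_frames: int = 1800
    frame_rate_hz: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_drive_fraction <= 1.0):
            raise ValueError("shared_drive_fraction must lie in [0, 1]")
        if self.transient_rise_frames > 2:
            raise ValueError("transient_rise_frames must be <= 2")
        if self.n_frames < 2 * self.transient_decay_frames:
            raise ValueError("n_frames must be >= 2 * transient_decay_frames")


def _transient_kernel(rise: int, decay: int) -> np.ndarray:
    up = np.linspace(0.0, 1.0, rise + 1)[1:]
    down = np.exp(-np.arange(1, decay * 5) / decay)
    return np.concatenate([up, down])


def gen_calcium_population(
    params: CalciumSimParams, seed: int = 0
) -> Tuple[FluorMatrix, GroundTruth]:
    """Simulate an ROI x frame fluorescence matrix with known labels."""
    rng = np.random.default_rng(seed)
    T = params.n_frames
    fr = params.frame_rate_hz
    duration_s = T / fr
    kernel = _transient_kernel(params.transient_rise_frames, params.transient_decay_frames)
    amp = params.neuron_amplitude_ratio * params.baseline_f0

    # one common event stream shared (probabilistically) by all neurons
    n_common = rng.poisson(params.neuron_event_rate_hz * duration_s)
    common_frames = np.sort(rng.integers(0, T, n_common))

    rows = []
    labels = []
    event_frames: List[np.ndarray] = []
    for i in range(params.n_neurons):
        adopted = common_frames[
            rng.random(n_common) < params.shared_drive_fraction
        ]
        indep_rate = params.neuron_event_rate_hz * (1.0 - params.shared_drive_fraction)
        n_ind = rng.poisson(indep_rate * duration_s)
        indep = rng.integers(0, T, n_ind)
        frames = np.sort(np.concatenate([adopted, indep]))
        x = np.full(T, params.baseline_f0)
        for f0 in frames:
            seg = min(kernel.size, T - f0)
            x[f0 : f0 + seg] += amp * kernel[:seg]
        rows.append(x)
        labels.append("active_neuron")
        event_frames.append(frames)
    for i in range(params.n_astrocytes):
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(T) / fr
        wave = (1.0 - np.cos(2 * np.pi * t / params.astro_period_s + phase)) / 2.0
        rows.append(params.baseline_f0 * (1.0 + params.astro_amplitude_ratio * wave))
        labels.append("active_astrocyte")
        event_frames.append(np.array([], dtype=int))
    for i in range(params.n_inactive):
        rows.append(np.full(T, params.baseline_f0))
        labels.append("inactive")
        event_frames.append(np.array([], dtype=int))

    F = np.array(rows) if rows else np.zeros((0, T))
    if F.shape[0] and params.noise_sd > 0:
        F = F + rng.normal(0.0, params.noise_sd, F.shape)
    fm = FluorMatrix(F=F, frame_rate_hz=fr)
    gt = GroundTruth(
        kind="calcium",
        values={
            "labels": labels,
            "event_frames": event_frames,
            "event_rate_hz": params.neuron_event_rate_hz,
            "shared_drive_fraction": params.shared_drive_fraction,
        },
    )
    return fm, gt


# ---------------------------------------------------------------------------
# gene sets with controlled overlaps
# ---------------------------------------------------------------------------

class InfeasibleOverlapError(ValueError):
    """The requested overlap matrix cannot be realized exactly."""


def gen_genesets(
    n_sets: int,
    universe_size: int,
    overlap_matrix,
    deg_fraction: float,
    seed: int = 0,
    set_size: int = 40,
    set_deg_fraction: Optional[float] = None,
):
    """Construct gene sets whose pairwise overlap coefficients match
    ``overlap_matrix`` exactly, plus a DEG table.

    All sets have ``set_size`` genes, so a target coefficient c requires
    exactly ``c * set_size`` shared genes (must be integral). Shared genes
    are allocated in pair-exclusive blocks, which realizes every pairwise
    overlap independently provided each set's shared quota fits.

    Returns ``(sets, deg_table, GroundTruth)`` where ``sets`` maps set id to
    a set of gene ids and ``deg_table`` is a DataFrame (gene_id, log2fc,
    fdr) in which a ``deg_fraction`` share of the universe passes the
    FDR < 0.05 and |log2FC| > 1.1 inclusion rule. ``set_deg_fraction``, when
    given, overrepresents DEGs inside the sets at that per-set rate (with
    ``deg_fraction`` applying to the background) so enrichment is present
    by construction.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    oc = np.asarray(overlap_matrix, dtype=float)
    if oc.shape != (n_sets, n_sets):
        raise ValueError("overlap_matrix must be n_sets x n_sets")
    if not np.allclose(oc, oc.T) or np.any((oc < 0) | (oc > 1)):
        raise InfeasibleOverlapError("overlap matrix must be symmetric in [0, 1]")

    shared_counts = oc * set_size
    if not np.allclose(shared_counts, np.round(shared_counts), atol=1e-9):
        raise InfeasibleOverlapError(
            f"overlap * set_size ({set_size}) must be integral for exact construction"
        )
    shared_counts = np.round(shared_counts).astype(int)
    np.fill_diagonal(shared_counts, 0)
    if np.any(shared_counts.sum(axis=1) > set_size):
        raise InfeasibleOverlapError("a set's total shared quota exceeds its size")

    counter = [0]

    def new_genes(k: int) -> List[str]:
        out = [f"G{counter[0] + j:06d}" for j in range(k)]
        counter[0] += k
        return out

    sets: Dict[str, set] = {f"set{i:02d}": set() for i in range(n_sets)}
    names = list(sets)
    for i in range(n_sets):
        for j in range(i + 1, n_sets):
            block = new_genes(shared_counts[i, j])
            sets[names[i]].update(block)
            sets[names[j]].update(block)
    for name in names:
        sets[name].update(new_genes(set_size - len(sets[name])))
    if counter[0] > universe_size:
        raise InfeasibleOverlapError(
            f"universe_size {universe_size} too small; need >= {counter[0]}"
        )
    universe = [f"G{j:06d}" for j in range(universe_size)]

    if set_deg_fraction is None:
        n_deg = int(round(deg_fraction * universe_size))
        deg_genes = (
            set(rng.choice(universe, size=n_deg, replace=False)) if n_deg else set()
        )
    else:
        deg_genes = set()
        for name in names:
            members = sorted(sets[name])
            k = int(round(set_deg_fraction * len(members)))
            if k:
                deg_genes.update(rng.choice(members, size=k, replace=False))
        in_sets = set().union(*sets.values()) if sets else set()
        background = sorted(set(universe) - in_sets)
        k_bg = int(round(deg_fraction * len(background)))
        if k_bg:
            deg_genes.update(rng.choice(background, size=k_bg, replace=False))
    is_deg = np.array([g in deg_genes for g in universe])
    log2fc = np.where(
        is_deg,
        rng.choice([-1.0, 1.0], universe_size) * rng.uniform(1.2, 4.0, universe_size),
        rng.uniform(-1.0, 1.0, universe_size),
    )
    fdr = np.where(
        is_deg,
        rng.uniform(1e-6, 0.049, universe_size),
        rng.uniform(0.06, 1.0, universe_size),
    )
    deg_table = pd.DataFrame({"gene_id": universe, "log2fc": log2fc, "fdr": fdr})

    gt = GroundTruth(
        kind="genesets",
        values={
            "overlap_matrix": oc,
            "shared_counts": shared_counts,
            "deg_genes": deg_genes,
            "universe": set(universe),
            "hits": {name: len(sets[name] & deg_genes) for name in names},
        },
    )
    return sets, deg_table, gt
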