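"""Analysis configuration.

Every tunable numeric threshold used by the pipeline lives here, grouped by
stage. Defaults reproduce the recording and analysis conditions of the
whole-cell / calcium-imaging workflow the package implements: a 3-pA,
400-ms current-step ladder counted over the first 30 (hippocampal) or 32
(dopaminergic) depolarization steps, a 50-pA holding-current exclusion rule,
a 5-ms fast-afterhyperpolarization delay, sodium statistics on the
[-20, 0] mV window and potassium on [40, 80] mV, a lag-6 / 0.05 neuronal
activity rule with a 10% inactivity cut for calcium ROIs, 35-frame
correlation windows with top-10 averaging, a 0.1-Hz PSD band split, and
gene-set network edges at overlap coefficient >= 0.3 with DEGs defined by
FDR < 0.05 and |log2FC| > 1.1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Tuple


@dataclass
class EpscDetectionConfig:
    """Spontaneous-EPSC detector settings.

    The detector works on a lightly smoothed trace (box filter of
    ``smooth_ms``); events are negative deflections below the local baseline
    exceeding ``threshold_sd`` robust (MAD-based) noise SDs, separated by at
    least ``min_interval_ms``. The baseline is a piecewise median over
    ``baseline_window_s`` blocks.
    """

    threshold_sd: float = 4.5
    min_interval_ms: float = 5.0
    smooth_ms: float = 1.0
    baseline_window_s: float = 1.0


@dataclass
class CalciumConfig:
    """Calcium-imaging classification / synchrony / PSD settings."""

    lag_frames: int = 6
    neuron_threshold: float = 0.05
    inactive_fraction: float = 0.10
    corr_window_frames: int = 35
    top_k: int = 10
    psd_high_cutoff_hz: float = 0.1
    n_top_astrocytes: int = 3
    #: normalization of the lag difference: "recording" divides by the
    #: largest peak-to-trough amplitude among all ROIs of the recording,
    #: "trace" by the ROI's own amplitude, "max" by the ROI's own maximum.
    delta_norm: str = "recording"
    prominence_fraction: float = 0.2
    min_event_sep_frames: int = 5
    ma_filter_frames: int = 5
    psd_nperseg: int = 256


@dataclass
class NetworkConfig:
    """Enrichment-network thresholds."""

    oc_min: float = 0.3
    fdr_max: float = 0.05
    log2fc_min: float = 1.1


@dataclass
class AnalysisConfig:
    """Top-level configuration shared by all pipeline stages."""

    n_steps_counted: int = 32  # 30 for hippocampal, 32 for dopaminergic
    holding_current_max_pa: float = 50.0
    fahp_delay_ms: float = 5.0
    na_window_mv: Tuple[float, float] = (-20.0, 0.0)
    k_window_mv: Tuple[float, float] = (40.0, 80.0)
    na_search_ms: float = 10.0
    fast_k_window_ms: float = 10.0
    slow_k_tail_ms: float = 5.0
    spike_detect_level_mv: float = -10.0
    spike_refractory_ms: float = 3.0
    epsc: EpscDetectionConfig = field(default_factory=EpscDetectionConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_steps_counted < 1:
            raise ValueError("n_steps_counted must be >= 1")
        for name in (
            "holding_current_max_pa",
            "fahp_delay_ms",
            "na_search_ms",
            "fast_k_window_ms",
            "slow_k_tail_ms",
            "spike_refractory_ms",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.epsc.threshold_sd <= 0 or self.epsc.min_interval_ms <= 0:
            raise ValueError("EPSC detection thresholds must be strictly positive")
        cal = self.calcium
        if cal.lag_frames < 1 or cal.neuron_threshold <= 0:
            raise ValueError("calcium lag/threshold must be strictly positive")
        if not (0 < cal.inactive_fraction < 1):
            raise ValueError("inactive_fraction must lie in (0, 1)")
        if cal.delta_norm not in ("recording", "trace", "max"):
            raise ValueError("delta_norm must be 'recording', 'trace' or 'max'")
        net = self.network
        if not (0 <= net.oc_min <= 1):
            raise ValueError("oc_min must lie in [0, 1]")
        if net.fdr_max <= 0 or net.log2fc_min <= 0:
            raise ValueError("network thresholds must be strictly positive")

    # -- (de)serialization for the CLI ------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "epsc" in d:
            d["epsc"] = EpscDetectionConfig(**d["epsc"])
        if "calcium" in d:
            d["calcium"] = CalciumConfig(**d["calcium"])
        if "network" in d:
            d["network"] = NetworkConfig(**d["network"])
        if "na_window_mv" in d:
            d["na_window_mv"] = tuple(d["na_window_mv"])
        if "k_window_mv" in d:
            d["k_window_mv"] = tuple(d["k_window_mv"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
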