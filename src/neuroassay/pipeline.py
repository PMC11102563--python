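"""End-to-end pipeline: manifest in, report bundle out.

The manifest is a TSV with columns ``cell_id``, ``group``, ``modality``
and ``path``; modalities are ``evoked`` (current-clamp sweep bundle),
``vc`` (voltage-clamp sweep bundle), ``epsc`` (gap-free trace bundle) and
``calcium`` (fluorescence bundle). Every stage writes tidy text tables so
runs are diff-able: per-cell features (TSV), group comparisons (TSV),
pooled EPSC-amplitude ECDFs (TSV per group) and a JSON summary. The
pipeline is deterministic: identical manifest + config give byte-identical
numeric tables.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import calcium as ca
from . import ephys
from .config import AnalysisConfig
from .io import read_fluor, read_sweepset, read_trace
from .stats import mann_whitney, two_sample_t

logger = logging.getLogger(__name__)

MODALITIES = ("evoked", "vc", "epsc", "calcium")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError("manifest is empty")
    missing = {"cell_id", "group", "modality", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["group"].isna().any() or (df["group"].astype(str).str.strip() == "").any():
        raise ValueError("manifest contains rows with an empty group")
    bad = set(df["modality"]) - set(MODALITIES)
    if bad:
        raise ValueError(f"unknown modality: {sorted(bad)}")
    return df


def _compare_scalar(
    per_group: Dict[str, List[float]], analyte: str, test: str = "student_t"
) -> List[dict]:
    """Two-group comparison rows for the tidy comparisons table."""
    groups = {g: [v for v in vals if v is not None and np.isfinite(v)]
              for g, vals in per_group.items()}
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    if len(groups) != 2:
        logger.info("skipping comparison of %s: need exactly 2 groups with n>=2", analyte)
        return []
    (ga, xa), (gb, xb) = sorted(groups.items())
    if test == "mann_whitney":
        cmp = mann_whitney(xa, xb)
    else:
        cmp = two_sample_t(xa, xb, welch=(test == "welch_t"))
    return [
        {
            "analyte": analyte,
            "test": cmp.test_name,
            "groups": f"{ga} vs {gb}",
            "n": f"{len(xa)},{len(xb)}",
            f"mean_{ga}": cmp.groups[0].mean,
            f"mean_{gb}": cmp.groups[1].mean,
            "statistic": cmp.statistic,
            "p": cmp.p_value,
        }
    ]


def run_pipeline(config: AnalysisConfig, manifest_path, out_dir, seed: int = 0) -> Path:
    """Run every applicable stage over the manifest and write the report.

    Returns the output directory. ``seed`` is recorded for provenance;
    the analysis itself is deterministic.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = read_manifest(manifest_path)

    feature_rows: List[dict] = []
    iv_tables: Dict[str, List[pd.DataFrame]] = {}
    epsc_amplitudes: Dict[str, List[float]] = {}
    calcium_rows: List[dict] = []
    stage_log: Dict[str, dict] = {
        m: {"analyzed": 0, "excluded": 0, "reasons": []} for m in MODALITIES
    }

    for _, row in manifest.iterrows():
        cell, group, modality, path = (
            str(row.cell_id),
            str(row.group),
            str(row.modality),
            row.path,
        )
        rec = {"cell_id": cell, "group": group, "modality": modality}
        if modality == "evoked":
            ss = read_sweepset(path)
            counted = ephys.count_evoked_aps(ss, config)
            if counted.excluded:
                stage_log[modality]["excluded"] += 1
                stage_log[modality]["reasons"].append(
                    {"cell_id": cell, "reason": counted.exclusion_reason}
                )
                rec.update(excluded=True, reason=counted.exclusion_reason)
            else:
                stage_log[modality]["analyzed"] += 1
                rec["total_evoked_aps"] = counted.total_evoked_aps
                try:
                    shape = ephys.spike_shape(ss, config)
                    rec.update(
                        threshold_mv=shape.threshold_mv,
                        amplitude_mv=shape.amplitude_mv,
                        width_ms=shape.width_ms,
                        fahp5_mv=shape.fahp5_mv,
                        rheobase_step=shape.rheobase_step,
                    )
                except ephys.NoSpikeError:
                    logger.info("cell %s: no rheobase spike", cell)
                rec["capacitance_pf"] = ss.capacitance_pf
        elif modality == "vc":
            ss = read_sweepset(path)
            tab = ephys.extract_iv(ss, config)
            iv_tables.setdefault(group, []).append(tab)
            stage_log[modality]["analyzed"] += 1
            lo, hi = config.na_window_mv
            sel = tab[(tab.test_potential_mv >= lo) & (tab.test_potential_mv <= hi)]
            rec["na_peak_window_mean"] = float(sel.na_peak_pa_per_pf.mean())
            lo, hi = config.k_window_mv
            sel = tab[(tab.test_potential_mv >= lo) & (tab.test_potential_mv <= hi)]
            rec["kfast_window_mean"] = float(sel.kfast_pa_per_pf.mean())
            rec["kslow_window_mean"] = float(sel.kslow_pa_per_pf.mean())
        elif modality == "epsc":
            tr = read_trace(path)
            summ = ephys.detect_epscs(tr, config)
            stage_log[modality]["analyzed"] += 1
            rec.update(
                epsc_n_events=summ.n_events,
                epsc_rate_hz=summ.rate_hz,
                epsc_mean_amp_pa=summ.mean_amplitude_pa,
            )
            epsc_amplitudes.setdefault(group, []).extend(summ.amplitudes_pa.tolist())
        elif modality == "calcium":
            fm = read_fluor(path)
            res = ca.analyze_recording(fm, config.calcium)
            stage_log[modality]["analyzed"] += 1
            crow = {
                "cell_id": cell,
                "group": group,
                "n_neurons": res["n_neurons"],
                "n_astrocytes": res["n_astrocytes"],
                "n_inactive": res["n_inactive"],
                "astro_top_mean_ratio": res["astro_top_mean_ratio"],
                "neuron_mean_event_rate_hz": res["neuron_mean_event_rate_hz"],
            }
            if res["synchrony"] is not None:
                crow["synchrony_top_k_norm"] = res["synchrony"].top_k_mean_norm
            if res["psd"] is not None and not res["psd"].has_infinite:
                crow["psd_ratio_top_k"] = res["psd"].top_k_mean
            calcium_rows.append(crow)
            rec.update(crow)
        feature_rows.append(rec)

    features = pd.DataFrame(feature_rows)
    features.to_csv(out / "features.tsv", sep="\t", index=False, float_format="%.9g")

    # group comparisons
    comparisons: List[dict] = []

    def collect(frame: pd.DataFrame, column: str, test: str = "student_t"):
        if column not in frame.columns:
            return
        per_group = {
            g: sub[column].dropna().tolist() for g, sub in frame.groupby("group")
        }
        comparisons.extend(_compare_scalar(per_group, column, test))

    evoked = features[features.modality == "evoked"] if not features.empty else features
    if isinstance(evoked, pd.DataFrame) and not evoked.empty:
        for col in ("total_evoked_aps", "threshold_mv", "amplitude_mv",
                    "width_ms", "fahp5_mv", "capacitance_pf"):
            collect(evoked, col)
    epsc_feat = features[features.modality == "epsc"] if not features.empty else features
    if isinstance(epsc_feat, pd.DataFrame) and not epsc_feat.empty:
        collect(epsc_feat, "epsc_rate_hz", test="mann_whitney")
        collect(epsc_feat, "epsc_mean_amp_pa")
    if calcium_rows:
        cal = pd.DataFrame(calcium_rows)
        for col in ("astro_top_mean_ratio", "neuron_mean_event_rate_hz",
                    "synchrony_top_k_norm", "psd_ratio_top_k"):
            collect(cal, col)

    if len(iv_tables) >= 2 and all(len(v) >= 2 for v in iv_tables.values()):
        iv_stats = ephys.iv_window_stats(iv_tables, config)
        iv_stats.to_csv(out / "iv_comparisons.tsv", sep="\t", index=False,
                        float_format="%.9g")

    pd.DataFrame(comparisons).to_csv(
        out / "comparisons.tsv", sep="\t", index=False, float_format="%.9g"
    )

    for group, amps in epsc_amplitudes.items():
        if amps:
            x, F = ephys.pooled_ecdf(amps)
            pd.DataFrame({"amplitude_pa": x, "cumulative_fraction": F}).to_csv(
                out / f"ecdf_{group}.tsv", sep="\t", index=False, float_format="%.9g"
            )

    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "seed": seed,
                "n_cells": int(len(manifest)),
                "groups": sorted(manifest.group.astype(str).unique()),
                "stages": stage_log,
            },
            fh,
            indent=2,
        )
    return out
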