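"""Data model and file formats.

Units are fixed package-wide: membrane potential in mV, current in pA,
capacitance in pF, time in ms (durations) or s (recordings), rates in Hz.
Converters belong at the I/O boundary, never inside analysis code.

The native interchange format is one directory per recording containing
``traces.csv`` (wide; one column per sweep or ROI) plus ``meta.json``.
An HDF5 container is supported as a convenience; Axon ABF import requires
the optional ``pyabf`` dependency.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file is missing required metadata or is otherwise unreadable."""


class StructuralError(ValueError):
    """A file's contents contradict its declared structure."""


# ---------------------------------------------------------------------------
# protocols and recordings
# ---------------------------------------------------------------------------

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"


@dataclass
class StimulusProtocol:
    """Step-ladder stimulation protocol.

    Current-clamp default: 38 depolarization steps of 3 pA over 400 ms,
    starting 12 pA below the holding current that keeps the cell at -60 mV.
    Voltage-clamp default: 400-ms steps from -90 to 80 mV in 10-mV
    increments while holding at -60 mV.
    """

    mode: str = CURRENT_CLAMP
    step_duration_ms: float = 400.0
    n_steps: int = 38
    current_start_offset_pa: float = -12.0
    current_increment_pa: float = 3.0
    voltage_min_mv: float = -90.0
    voltage_max_mv: float = 80.0
    voltage_increment_mv: float = 10.0
    holding_potential_mv: float = -60.0
    pre_ms: float = 0.0   # baseline recorded before the step
    post_ms: float = 0.0  # baseline recorded after the step

    def __post_init__(self) -> None:
        if self.mode not in (CURRENT_CLAMP, VOLTAGE_CLAMP):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.step_duration_ms <= 0:
            raise ValueError("step_duration_ms must be > 0")

    @classmethod
    def current_step_ladder(cls, **kw) -> "StimulusProtocol":
        return cls(mode=CURRENT_CLAMP, **kw)

    @classmethod
    def voltage_step_ladder(cls, **kw) -> "StimulusProtocol":
        kw.setdefault("voltage_min_mv", -90.0)
        kw.setdefault("voltage_max_mv", 80.0)
        kw.setdefault("voltage_increment_mv", 10.0)
        if "n_steps" not in kw:
            span = kw["voltage_max_mv"] - kw["voltage_min_mv"]
            kw["n_steps"] = int(round(span / kw["voltage_increment_mv"])) + 1
        kw.setdefault("pre_ms", 50.0)
        kw.setdefault("post_ms", 50.0)
        return cls(mode=VOLTAGE_CLAMP, **kw)

    def step_currents_pa(self, holding_current_pa: float) -> np.ndarray:
        """Injected current of each step (current-clamp)."""
        steps = np.arange(self.n_steps)
        return (
            holding_current_pa
            + self.current_start_offset_pa
            + steps * self.current_increment_pa
        )

    def step_voltages_mv(self) -> np.ndarray:
        """Test potential of each step (voltage-clamp)."""
        return self.voltage_min_mv + np.arange(self.n_steps) * self.voltage_increment_mv


@dataclass
class SweepSet:
    """A stimulus-aligned stack of traces, one per protocol step."""

    traces: np.ndarray  # [n_steps, n_samples]; mV (CC) or pA (VC)
    sampling_rate_hz: float
    protocol: StimulusProtocol
    holding_current_pa: float = 0.0
    capacitance_pf: Optional[float] = None
    cell_id: str = "cell"
    group_id: str = "group"

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise StructuralError("traces must be a 2-D [n_steps, n_samples] array")
        if self.traces.shape[0] != self.protocol.n_steps:
            raise StructuralError(
                f"{self.traces.shape[0]} sweeps found but protocol declares "
                f"{self.protocol.n_steps} steps"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    @property
    def n_steps(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def step_onset_index(self) -> int:
        return int(round(self.protocol.pre_ms / 1000.0 * self.sampling_rate_hz))

    def step_end_index(self) -> int:
        return self.step_onset_index() + int(
            round(self.protocol.step_duration_ms / 1000.0 * self.sampling_rate_hz)
        )


@dataclass
class Trace:
    """A single gap-free recording (e.g. spontaneous EPSCs at -60 mV)."""

    samples: np.ndarray
    sampling_rate_hz: float
    cell_id: str = "cell"
    group_id: str = "group"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass
class FluorMatrix:
    """ROI x frame fluorescence matrix from a calcium-imaging video."""

    F: np.ndarray  # [n_roi, n_frames], arbitrary units
    frame_rate_hz: float
    roi_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise StructuralError("F must be a 2-D [n_roi, n_frames] array")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence values must all be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        if not self.roi_ids:
            self.roi_ids = [f"roi{i:03d}" for i in range(self.F.shape[0])]
        if len(self.roi_ids) != self.F.shape[0]:
            raise StructuralError("roi_ids length must match number of rows")

    @property
    def n_roi(self) -> int:
        return self.F.shape[0]

    @property
    def n_frames(self) -> int:
        return self.F.shape[1]


# ---------------------------------------------------------------------------
# sweep-set I/O
# ---------------------------------------------------------------------------

def _protocol_to_dict(p: StimulusProtocol) -> dict:
    return {k: getattr(p, k) for k in p.__dataclass_fields__}


def write_sweepset(ss: SweepSet, path) -> Path:
    """Write a sweep set as a ``traces.csv`` + ``meta.json`` directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cols = {f"sweep_{i:02d}": ss.traces[i] for i in range(ss.n_steps)}
    pd.DataFrame(cols).to_csv(path / "traces.csv", index=False, float_format="%.17g")
    meta = {
        "kind": "sweepset",
        "sampling_rate_hz": ss.sampling_rate_hz,
        "holding_current_pa": ss.holding_current_pa,
        "capacitance_pf": ss.capacitance_pf,
        "cell_id": ss.cell_id,
        "group_id": ss.group_id,
        "protocol": _protocol_to_dict(ss.protocol),
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return path


def _load_meta(path: Path) -> dict:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing metadata file {meta_path}")
    with open(meta_path) as fh:
        return json.load(fh)


def read_sweepset(path, format: str = "csv_bundle") -> SweepSet:
    """Read a sweep set.

    Supported formats: ``csv_bundle`` (directory with traces.csv +
    meta.json), ``hdf5_container``. ``abf`` requires the optional pyabf
    dependency.
    """
    if format == "csv_bundle":
        return _read_sweepset_csv(Path(path))
    if format == "hdf5_container":
        return _read_sweepset_hdf5(Path(path))
    if format == "abf":
        try:
            import pyabf  # noqa: F401
        except ImportError as exc:
            raise FormatError(
                "ABF import requires the optional 'pyabf' dependency"
            ) from exc
        raise NotImplementedError("ABF import not implemented in this build")
    raise FormatError(f"unknown sweep-set format {format!r}")


def _read_sweepset_csv(path: Path) -> SweepSet:
    meta = _load_meta(path)
    for fld in ("sampling_rate_hz", "protocol"):
        if fld not in meta:
            raise FormatError(f"metadata missing required field '{fld}'")
    traces = pd.read_csv(path / "traces.csv", float_precision="round_trip").to_numpy(dtype=float).T
    proto_d = dict(meta["protocol"])
    rate = float(meta["sampling_rate_hz"])
    if proto_d.get("step_duration_ms") is None:
        # infer: total duration minus any recorded pre/post baseline
        total_ms = traces.shape[1] / rate * 1000.0
        proto_d["step_duration_ms"] = (
            total_ms - proto_d.get("pre_ms", 0.0) - proto_d.get("post_ms", 0.0)
        )
    protocol = StimulusProtocol(**proto_d)
    if traces.shape[0] != protocol.n_steps:
        raise StructuralError(
            f"found {traces.shape[0]} sweeps but metadata declares "
            f"{protocol.n_steps}"
        )
    return SweepSet(
        traces=traces,
        sampling_rate_hz=rate,
        protocol=protocol,
        holding_current_pa=float(meta.get("holding_current_pa", 0.0)),
        capacitance_pf=meta.get("capacitance_pf"),
        cell_id=meta.get("cell_id", "cell"),
        group_id=meta.get("group_id", "group"),
    )


def write_sweepset_hdf5(ss: SweepSet, path) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("traces", data=ss.traces)
        fh.attrs["sampling_rate_hz"] = ss.sampling_rate_hz
        fh.attrs["holding_current_pa"] = ss.holding_current_pa
        if ss.capacitance_pf is not None:
            fh.attrs["capacitance_pf"] = ss.capacitance_pf
        fh.attrs["cell_id"] = ss.cell_id
        fh.attrs["group_id"] = ss.group_id
        fh.attrs["protocol_json"] = json.dumps(_protocol_to_dict(ss.protocol))
    return path


def _read_sweepset_hdf5(path: Path) -> SweepSet:
    import h5py

    with h5py.File(path, "r") as fh:
        if "traces" not in fh:
            raise FormatError("HDF5 container missing 'traces' dataset")
        for fld in ("sampling_rate_hz", "protocol_json"):
            if fld not in fh.attrs:
                raise FormatError(f"metadata missing required field '{fld}'")
        protocol = StimulusProtocol(**json.loads(fh.attrs["protocol_json"]))
        cap = fh.attrs.get("capacitance_pf")
        return SweepSet(
            traces=fh["traces"][()],
            sampling_rate_hz=float(fh.attrs["sampling_rate_hz"]),
            protocol=protocol,
            holding_current_pa=float(fh.attrs.get("holding_current_pa", 0.0)),
            capacitance_pf=float(cap) if cap is not None else None,
            cell_id=str(fh.attrs.get("cell_id", "cell")),
            group_id=str(fh.attrs.get("group_id", "group")),
        )


# ---------------------------------------------------------------------------
# single-trace and fluorescence I/O
# ---------------------------------------------------------------------------

def write_trace(trace: Trace, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"current_pa": trace.samples}).to_csv(
        path / "trace.csv", index=False, float_format="%.17g"
    )
    with open(path / "meta.json", "w") as fh:
        json.dump(
            {
                "kind": "trace",
                "sampling_rate_hz": trace.sampling_rate_hz,
                "cell_id": trace.cell_id,
                "group_id": trace.group_id,
            },
            fh,
            indent=2,
        )
    return path


def read_trace(path) -> Trace:
    path = Path(path)
    meta = _load_meta(path)
    if "sampling_rate_hz" not in meta:
        raise FormatError("metadata missing required field 'sampling_rate_hz'")
    samples = pd.read_csv(path / "trace.csv", float_precision="round_trip")["current_pa"].to_numpy(dtype=float)
    return Trace(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        cell_id=meta.get("cell_id", "cell"),
        group_id=meta.get("group_id", "group"),
    )


def write_fluor(fm: FluorMatrix, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(fm.F.T, columns=fm.roi_ids)
    df.to_csv(path / "traces.csv", index=False, float_format="%.17g")
    with open(path / "meta.json", "w") as fh:
        json.dump({"kind": "fluor", "frame_rate_hz": fm.frame_rate_hz}, fh, indent=2)
    return path


def read_fluor(path) -> FluorMatrix:
    path = Path(path)
    meta = _load_meta(path)
    if "frame_rate_hz" not in meta:
        raise FormatError("metadata missing required field 'frame_rate_hz'")
    df = pd.read_csv(path / "traces.csv", float_precision="round_trip")
    return FluorMatrix(
        F=df.to_numpy(dtype=float).T,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        roi_ids=list(df.columns),
    )


def read_fluor_stack(stack_path, roi_mask) -> FluorMatrix:
    """Average a TIFF stack over labeled ROIs.

    Parameters
    ----------
    stack_path : path to a [frames, height, width] TIFF stack.
    roi_mask : path to a JSON label image (nested lists; 0 = background,
        k = ROI k) or an equivalent 2-D array.

    Returns the per-frame mean pixel intensity of each ROI. Frame rate is
    read from an optional ``meta.json`` next to the stack (default 10 Hz).
    """
    import tifffile

    stack_path = Path(stack_path)
    stack = tifffile.imread(stack_path)
    if stack.ndim == 2:
        stack = stack[None]
    if isinstance(roi_mask, (str, os.PathLike)):
        with open(roi_mask) as fh:
            mask = np.asarray(json.load(fh), dtype=int)
    else:
        mask = np.asarray(roi_mask, dtype=int)
    if mask.shape != stack.shape[1:]:
        raise StructuralError(
            f"mask shape {mask.shape} does not match frame shape {stack.shape[1:]}"
        )
    labels = [int(k) for k in np.unique(mask) if k > 0]
    if not labels:
        raise StructuralError("ROI mask contains no labeled pixels")
    rows = []
    for k in labels:
        sel = mask == k
        if not sel.any():
            raise StructuralError(f"ROI {k} covers zero pixels")
        rows.append(stack[:, sel].mean(axis=1))
    frame_rate = 10.0
    meta_path = stack_path.with_name("meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            frame_rate = float(json.load(fh).get("frame_rate_hz", 10.0))
    return FluorMatrix(
        F=np.vstack(rows),
        frame_rate_hz=frame_rate,
        roi_ids=[f"roi{k:03d}" for k in labels],
    )


# ---------------------------------------------------------------------------
# gene sets and DEG tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT file: one gene set per line (id, description, genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"GMT line has {len(parts)} fields; expected id, "
                    "description and at least one gene"
                )
            sets[parts[0]] = set(parts[2:])
    return sets


def write_gmt(sets: dict, path, descriptions: Optional[dict] = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc] + sorted(genes)) + "\n")
    return path


def read_deg_table(path) -> pd.DataFrame:
    """Read a differential-expression TSV with gene_id, log2fc, fdr."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise FormatError(f"DEG table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise StructuralError("DEG table contains duplicate gene ids")
    if not np.isfinite(df[["log2fc", "fdr"]].to_numpy()).all():
        raise ValueError("log2fc and fdr must be finite")
    return df


def write_deg_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path
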