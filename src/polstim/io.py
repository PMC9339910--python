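"""Readers/writers and provenance records shared by the CLI pipelines.

Conventions: CSV is comma-separated with a header row, '.' decimal,
UTF-8; angles are stored in degrees and times in seconds.  Maps go to
32-bit float TIFF, synthetic camera frames to 16-bit TIFF.  Every output
file written through :func:`write_provenance` is accompanied by a JSON
record of the inputs, parameters and seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from polstim import __version__
from polstim.rf_photoreceptor import IntracellularTrace

__all__ = [
    "read_config",
    "write_csv",
    "read_csv",
    "write_map_tiff",
    "read_map_tiff",
    "write_frames_tiff",
    "read_stack_tiffs",
    "write_trace",
    "read_trace",
    "read_spike_times",
    "write_json",
    "write_provenance",
]


def read_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — valid YAML) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def write_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map_tiff(arr: np.ndarray, path: str | Path) -> None:
    """Analysis maps: 32-bit float TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))


def read_map_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_frames_tiff(frames: np.ndarray, path: str | Path) -> None:
    """Synthetic camera frames / packed video: 8- or 16-bit TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(frames)
    if arr.dtype not in (np.uint8, np.uint16):
        arr = arr.astype(np.uint16)
    tifffile.imwrite(path, arr)


def read_stack_tiffs(paths: Mapping[str, str | Path]) -> dict[str, np.ndarray]:
    return {k: tifffile.imread(p) for k, p in paths.items()}


def write_trace(trace: IntracellularTrace, prefix: str | Path) -> tuple[Path, Path]:
    """Voltage trace as single-column CSV plus a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    sidecar = prefix.with_suffix(".json")
    pd.DataFrame({"voltage_mV": trace.samples}).to_csv(csv_path, index=False)
    write_json(
        {"sample_rate_hz": trace.sample_rate, "t0_s": trace.t0}, sidecar
    )
    return csv_path, sidecar


def read_trace(prefix: str | Path) -> IntracellularTrace:
    prefix = Path(prefix)
    samples = pd.read_csv(prefix.with_suffix(".csv"))["voltage_mV"].to_numpy()
    with open(prefix.with_suffix(".json"), "r", encoding="utf-8") as fh:
        meta = json.load(fh)
    return IntracellularTrace(
        samples=samples,
        sample_rate=meta["sample_rate_hz"],
        t0=meta["t0_s"],
    )


def read_spike_times(path: str | Path) -> np.ndarray:
    """Single-column CSV of spike times in seconds."""
    df = pd.read_csv(path)
    return df[df.columns[0]].to_numpy(dtype=float)


def _jsonable(obj: Any):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, default=_jsonable)
        fh.write("\n")


def write_provenance(
    output_path: str | Path,
    inputs: Mapping,
    parameters: Mapping,
    seed: int | None,
) -> Path:
    """Write ``<output>.provenance.json`` next to an output file."""
    out = Path(output_path)
    record = {
        "output": out.name,
        "inputs": dict(inputs),
        "parameters": dict(parameters),
        "seed": seed,
        "version": __version__,
    }
    prov_path = out.with_name(out.name + ".provenance.json")
    write_json(record, prov_path)
    return prov_path
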