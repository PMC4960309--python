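"""Reading and writing traces, spike lists, configs and run manifests.

Interchange formats are plain text: delimited trace tables (one column
per neuron), spike-time lists in seconds (one time per line), CSV
matrices for probabilities and latent paths, and YAML for configuration
and run manifests.  Every run is replayable from its manifest, which
records parameters, seed and package version.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .engine import EngineConfig, MapResult, PosteriorArrays
from .model import ModelParams, SpikeTrain, Trace

__all__ = [
    "read_traces",
    "write_traces",
    "read_spike_times",
    "write_spike_times",
    "read_config",
    "write_manifest",
    "write_map_result",
    "write_posterior",
    "params_from_dict",
    "engine_config_from_dict",
]


def read_traces(
    path: Union[str, Path],
    rate: Optional[float] = None,
    dt: Optional[float] = None,
    normalize: bool = False,
) -> List[Trace]:
    """Read fluorescence traces from a delimited text file.

    One column per trace, optional header.  The frame rate is taken
    from a ``# rate = <Hz>`` comment on the first line if present,
    otherwise from the ``rate`` or ``dt`` argument.  With
    ``normalize=True`` raw counts are converted to dF/F as
    (F - F0)/F0 with F0 the 10th percentile.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#") and "rate" in first:
        rate = float(first.split("=")[1])
    if rate is not None:
        dt = 1.0 / rate
    if dt is None:
        raise ValueError("frame rate not given (no header comment, rate or dt)")
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    # a file without header yields numeric-looking column names; retry raw
    try:
        [float(c) for c in df.columns]
        df = pd.read_csv(path, sep=sep, comment="#", header=None)
    except (TypeError, ValueError):
        pass
    if df.isnull().values.any():
        raise ValueError(f"non-numeric or missing cells in {path}")
    traces = []
    for col in df.columns:
        v = pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float)
        if normalize:
            f0 = np.percentile(v, 10)
            if f0 <= 0:
                raise ValueError("cannot normalize: 10th percentile <= 0")
            v = (v - f0) / f0 + 1.0  # relative units, resting baseline ~1
        traces.append(Trace(values=v, dt=dt))
    return traces


def write_traces(traces: Sequence[Trace], path: Union[str, Path]) -> None:
    path = Path(path)
    rate = traces[0].rate
    arr = np.column_stack([t.values for t in traces])
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    with open(path, "w") as fh:
        fh.write(f"# rate = {rate:.10g}\n")
        fh.write(sep.join(f"trace{i}" for i in range(arr.shape[1])) + "\n")
        np.savetxt(fh, arr, delimiter=sep, fmt="%.17g")


def read_spike_times(path: Union[str, Path]) -> SpikeTrain:
    """Read a plain-text spike list (seconds, one time per line)."""
    times = np.loadtxt(path, ndmin=1) if Path(path).stat().st_size else np.array([])
    return SpikeTrain(times=times)


def write_spike_times(spikes: SpikeTrain, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for t in spikes.times:
            fh.write(f"{t:.6f}\n")


def read_config(path: Union[str, Path]) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def params_from_dict(d: dict) -> ModelParams:
    fields = {f.name for f in dataclasses.fields(ModelParams)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    return ModelParams(**d)


def engine_config_from_dict(d: dict) -> EngineConfig:
    fields = {f.name for f in dataclasses.fields(EngineConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown engine options: {sorted(unknown)}")
    return EngineConfig(**d)


def write_manifest(path: Union[str, Path], **entries) -> None:
    """Write a YAML run manifest (parameters, seed, version)."""
    from . import __version__

    out = {"spikemap_version": __version__}
    for k, v in entries.items():
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            v = dataclasses.asdict(v)
        out[k] = v
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(out), fh, sort_keys=False)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_map_result(result: MapResult, stem: Union[str, Path], dt: float) -> None:
    """Write spikes (text list), latent path and fit (CSV) for one trace."""
    stem = Path(stem)
    write_spike_times(result.spikes, stem.with_suffix(".spikes.txt"))
    df = pd.DataFrame(
        {
            "time": (np.arange(len(result.counts)) + 0.5) * dt,
            "counts": result.counts,
            "calcium": result.path.c,
            "baseline": result.path.B,
            "fit": result.fit,
        }
    )
    df.to_csv(stem.with_suffix(".path.csv"), index=False)


def write_posterior(post: PosteriorArrays, stem: Union[str, Path], dt: float) -> None:
    stem = Path(stem)
    T, K = post.spike_marginals.shape
    df = pd.DataFrame(
        post.spike_marginals, columns=[f"p_{k}_spikes" for k in range(K)]
    )
    df.insert(0, "time", (np.arange(T) + 0.5) * dt)
    df["expected_count"] = post.expected_counts
    df.to_csv(stem.with_suffix(".proba.csv"), index=False)
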