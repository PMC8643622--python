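"""File formats: photon streams (HDF5), traces and curves (CSV), fits (JSON).

Photon streams use a Photon-HDF5-compatible layout: datasets
``/photon_data/{macrotime, microtime, channel}`` plus root attributes
``sync_period_ns``, ``duration_s``, ``config_json`` and ``seed``.
Traces and correlation curves are plain CSV with a ``#``-prefixed header
block carrying their metadata, so every container round-trips through
text.  All writers record the config digest and seed that produced the
data where available (provenance).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import h5py
import numpy as np
import pandas as pd

from .correlator import CorrelationCurve
from .fcs_models import FcsFit
from .simkit import IntensityTraces, PhotonStream, CHANNELS

PathLike = Union[str, Path]


class SchemaError(ValueError):
    """A file does not match the expected layout; names the offender."""


# ---------------------------------------------------------------------------
# photon streams


def write_photon_stream(path: PathLike, stream: PhotonStream) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("macrotime", data=stream.macrotimes)
        g.create_dataset("microtime", data=stream.microtimes)
        g.create_dataset("channel", data=stream.channels)
        f.attrs["sync_period_ns"] = stream.sync_period
        f.attrs["duration_s"] = stream.duration
        meta = dict(stream.metadata)
        f.attrs["seed"] = int(meta.pop("seed", -1))
        f.attrs["config_json"] = json.dumps(meta.pop("config", {}))
        f.attrs["metadata_json"] = json.dumps(meta, default=str)


def read_photon_stream(path: PathLike) -> PhotonStream:
    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise SchemaError("missing group 'photon_data'")
        g = f["photon_data"]
        for ds in ("macrotime", "microtime", "channel"):
            if ds not in g:
                raise SchemaError(f"missing dataset 'photon_data/{ds}'")
        for attr in ("sync_period_ns", "duration_s"):
            if attr not in f.attrs:
                raise SchemaError(f"missing attribute '{attr}'")
        meta = json.loads(f.attrs.get("metadata_json", "{}"))
        cfg = json.loads(f.attrs.get("config_json", "{}"))
        if cfg:
            meta["config"] = cfg
        seed = int(f.attrs.get("seed", -1))
        if seed >= 0:
            meta["seed"] = seed
        return PhotonStream(
            macrotimes=g["macrotime"][()],
            microtimes=g["microtime"][()],
            channels=g["channel"][()],
            sync_period=float(f.attrs["sync_period_ns"]),
            duration=float(f.attrs["duration_s"]),
            metadata=meta)


# ---------------------------------------------------------------------------
# CSV helpers


def _write_header_block(fh, meta: dict) -> None:
    for k, v in meta.items():
        fh.write(f"# {k}: {json.dumps(v, default=str)}\n")


def _read_header_block(path: PathLike) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            try:
                meta[key.strip()] = json.loads(val.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = val.strip()
    return meta


# ---------------------------------------------------------------------------
# intensity traces


def write_traces(path: PathLike, traces: IntensityTraces) -> None:
    meta = {"bin_width_us": traces.bin_width, "duration_s": traces.duration}
    meta.update({k: v for k, v in traces.metadata.items() if k != "config"})
    if "config" in traces.metadata:
        meta["config"] = traces.metadata["config"]
    with open(path, "w") as fh:
        _write_header_block(fh, meta)
        fh.write("time_s," + ",".join(CHANNELS) + "\n")
        df = pd.DataFrame({"time_s": traces.time_s,
                           **{ch: getattr(traces, ch) for ch in CHANNELS}})
        df.to_csv(fh, index=False, header=False,
                  float_format="%.9f")


def read_traces(path: PathLike) -> IntensityTraces:
    meta = _read_header_block(path)
    df = pd.read_csv(path, comment="#")
    expected = ["time_s"] + list(CHANNELS)
    for col in expected:
        if col not in df.columns:
            raise SchemaError(f"missing column '{col}' in traces CSV")
    if "bin_width_us" not in meta:
        if len(df) > 1:
            meta["bin_width_us"] = float(np.diff(df["time_s"][:2])[0] * 1e6)
        else:
            raise SchemaError("missing header field 'bin_width_us'")
    duration = meta.get("duration_s",
                        len(df) * meta["bin_width_us"] * 1e-6)
    extra = {k: v for k, v in meta.items()
             if k not in ("bin_width_us", "duration_s")}
    return IntensityTraces(
        bin_width=float(meta["bin_width_us"]),
        DexDem=df["DexDem"].to_numpy(),
        DexAem=df["DexAem"].to_numpy(),
        AexAem=df["AexAem"].to_numpy(),
        AexDem=df["AexDem"].to_numpy(),
        duration=float(duration), metadata=extra)


# ---------------------------------------------------------------------------
# correlation curves


def write_curve(path: PathLike, curve: CorrelationCurve) -> None:
    meta = {"channel_pair": curve.channel_pair}
    meta.update(curve.meta)
    with open(path, "w") as fh:
        _write_header_block(fh, meta)
        fh.write("lag_s,G,stderr\n")
        se = curve.stderr if curve.stderr is not None \
            else np.full_like(curve.G, np.nan)
        for lag, g, s in zip(curve.lags, curve.G, se):
            fh.write(f"{lag:.9e},{g:.9e},{s:.9e}\n")


def read_curve(path: PathLike) -> CorrelationCurve:
    meta = _read_header_block(path)
    df = pd.read_csv(path, comment="#")
    for col in ("lag_s", "G"):
        if col not in df.columns:
            raise SchemaError(f"missing column '{col}' in curve CSV")
    se = df["stderr"].to_numpy() if "stderr" in df.columns else None
    if se is not None and np.all(np.isnan(se)):
        se = None
    pair = meta.pop("channel_pair", "")
    return CorrelationCurve(lags=df["lag_s"].to_numpy(),
                            G=df["G"].to_numpy(), stderr=se,
                            channel_pair=pair, meta=meta)


# ---------------------------------------------------------------------------
# fits and reports


def write_fit(path: PathLike, fit: FcsFit) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2) + "\n")


def read_fit(path: PathLike) -> FcsFit:
    d = json.loads(Path(path).read_text())
    for key in ("model", "params", "stderr", "fixed", "redchi", "success"):
        if key not in d:
            raise SchemaError(f"missing field '{key}' in fit JSON")
    return FcsFit.from_dict(d)


def write_json(path: PathLike, payload: dict) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=False, default=_jsonable)
        + "\n")


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "_asdict"):
        return obj._asdict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
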