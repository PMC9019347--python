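"""WAV, config and table I/O.

Audio goes through RIFF WAV via scipy: floats in [-1, 1] are rendered to
16-bit PCM (the simulation's analog-to-digital convention); 16-, 24- and
32-bit PCM files are read back to float.  Scene/array configuration is a
flat YAML mapping; events and ground-truth intervals are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .array_scene import MultichannelSignal, SceneConfig
from .call_synth import Waveform
from .tracking import SourceEvent

__all__ = [
    "write_wav",
    "read_wav",
    "read_multichannel_wav",
    "write_scene_config",
    "read_scene_config",
    "write_events_csv",
    "write_intervals_csv",
    "read_intervals_csv",
]

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def write_wav(path, data: np.ndarray | Waveform | MultichannelSignal, sample_rate: int | None = None) -> None:
    """Write float audio as 16-bit PCM WAV (channels-last on disk)."""
    if isinstance(data, Waveform):
        arr, sample_rate = data.samples, data.sample_rate
    elif isinstance(data, MultichannelSignal):
        arr, sample_rate = data.channels.T, data.sample_rate
    else:
        arr = np.asarray(data)
        if sample_rate is None:
            raise ValueError("sample_rate required for raw arrays")
    peak = np.max(np.abs(arr)) if arr.size else 0.0
    if peak > 1.0:
        raise ValueError(f"samples exceed full scale (peak {peak:.3f}); attenuate before writing")
    wavfile.write(path, sample_rate, np.round(arr * (2**15 - 1)).astype(np.int16))


def _to_float(data: np.ndarray) -> np.ndarray:
    if data.dtype.kind == "f":
        return data.astype(np.float64)
    scale = _PCM_SCALE.get(data.dtype)
    if scale is None:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return data.astype(np.float64) / scale


def read_wav(path) -> Waveform:
    """Read a mono WAV file to a float Waveform."""
    fs, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError(f"{path} is not mono ({data.shape[1]} channels)")
    return Waveform(_to_float(data), fs)


def read_multichannel_wav(path) -> MultichannelSignal:
    """Read a multichannel WAV file (channels-last on disk) to (M, N) float."""
    fs, data = wavfile.read(path)
    data = np.atleast_2d(data)
    if data.shape[0] > data.shape[1]:
        data = data.T
    return MultichannelSignal(_to_float(data), fs)


def write_scene_config(path, config: dict) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_scene_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path} is not a mapping")
    return cfg


def scene_from_config(cfg: dict) -> SceneConfig:
    return SceneConfig(
        source_azimuth=float(cfg.get("source_azimuth_deg", 0.0)),
        source_distance=float(cfg.get("source_distance_m", 30.0)),
        speed_of_sound=float(cfg.get("speed_of_sound", 340.0)),
        sample_rate=int(cfg.get("sample_rate", 16000)),
        snr_db=cfg.get("snr_db", None),
    )


def write_events_csv(path, events: list[SourceEvent]) -> None:
    rows = [
        {
            "onset_s": ev.onset_s,
            "offset_s": ev.offset_s,
            "mean_azimuth_deg": ev.mean_azimuth,
            "n_frames": ev.n_frames,
            "peak_P": max(ev.peak_powers) if ev.peak_powers else float("nan"),
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=["onset_s", "offset_s", "mean_azimuth_deg", "n_frames", "peak_P"]).to_csv(
        path, index=False
    )


def write_intervals_csv(path, intervals: list[tuple[float, float]]) -> None:
    pd.DataFrame(
        [{"onset_s": a, "offset_s": b, "phrase_id": i} for i, (a, b) in enumerate(intervals)],
        columns=["onset_s", "offset_s", "phrase_id"],
    ).to_csv(path, index=False)


def read_intervals_csv(path) -> list[tuple[float, float]]:
    df = pd.read_csv(path)
    return [(float(a), float(b)) for a, b in zip(df["onset_s"], df["offset_s"])]
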