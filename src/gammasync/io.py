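"""Readers and writers for the package's on-disk formats.

Recordings travel as HDF5 (``/lfp`` channels x samples in microvolts,
``/channels`` metadata, ``rate_hz`` attribute), decompositions as HDF5
(``/mixing``, ``/activations``, ``/variance_share``), spike trains as
CSV (``unit_id,class,time_s``), wave tables and pair tables as CSV, and
summaries / ground truth as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .pairing import WavePairing
from .recording import LfpRecording
from .separate import GeneratorDecomposition
from .waves import GammaWave

__all__ = [
    "write_recording",
    "read_recording",
    "write_decomposition",
    "read_decomposition",
    "write_spikes",
    "read_spikes",
    "waves_to_frame",
    "write_waves",
    "read_waves",
    "write_pairs",
    "write_ground_truth",
]


def write_recording(path: str | Path, rec: LfpRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=rec.voltages)
        f.attrs["rate_hz"] = rec.rate
        grp = f.create_group("channels")
        grp.create_dataset("shank", data=rec.channel_meta["shank"].to_numpy(dtype=int))
        grp.create_dataset(
            "side", data=np.array(rec.channel_meta["side"], dtype="S1")
        )
        grp.create_dataset("depth_um", data=rec.channel_meta["depth_um"].to_numpy(dtype=float))
        if rec.epoch_masks:
            f.create_dataset("epoch_masks", data=np.asarray(rec.epoch_masks))


def read_recording(path: str | Path) -> LfpRecording:
    with h5py.File(path, "r") as f:
        volts = f["lfp"][...]
        rate = float(f.attrs["rate_hz"])
        if "channels" in f:
            meta = pd.DataFrame(
                {
                    "shank": f["channels/shank"][...],
                    "side": [s.decode() for s in f["channels/side"][...]],
                    "depth_um": f["channels/depth_um"][...],
                }
            )
        else:  # bare channels x samples matrix
            meta = pd.DataFrame(
                {"shank": 0, "side": "L", "depth_um": np.arange(volts.shape[0], dtype=float)}
            )
        masks = [tuple(m) for m in f["epoch_masks"][...]] if "epoch_masks" in f else []
    return LfpRecording(volts, rate, meta, masks)


def write_decomposition(path: str | Path, dec: GeneratorDecomposition) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("mixing", data=dec.mixing)
        f.create_dataset("activations", data=dec.activations)
        f.create_dataset("variance_share", data=dec.variance_share)
        f.attrs["rate_hz"] = dec.rate
        if dec.labels:
            f.create_dataset("labels", data=np.array(dec.labels, dtype="S32"))


def read_decomposition(path: str | Path) -> GeneratorDecomposition:
    with h5py.File(path, "r") as f:
        labels = (
            [s.decode() for s in f["labels"][...]] if "labels" in f else None
        )
        return GeneratorDecomposition(
            mixing=f["mixing"][...],
            activations=f["activations"][...],
            variance_share=f["variance_share"][...],
            rate=float(f.attrs["rate_hz"]),
            labels=labels,
        )


def write_spikes(path: str | Path, trains: dict, classes: dict[str, str]) -> None:
    """Spike CSV with columns unit_id, class, time_s."""
    rows = []
    for uid, times in trains.items():
        for t in np.asarray(times):
            rows.append({"unit_id": uid, "class": classes.get(uid, ""), "time_s": float(t)})
    pd.DataFrame(rows, columns=["unit_id", "class", "time_s"]).to_csv(path, index=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def waves_to_frame(waves: list[GammaWave], retained: list[bool] | None = None) -> pd.DataFrame:
    rows = [
        {
            "generator": w.generator_label,
            "side": w.side,
            "site": w.site,
            "start_s": w.start,
            "scale_s": w.scale,
            "amp_uV": w.peak_amplitude,
            "dur_s": w.duration,
            "retained": bool(retained[i]) if retained is not None else True,
        }
        for i, w in enumerate(waves)
    ]
    return pd.DataFrame(
        rows,
        columns=["generator", "side", "site", "start_s", "scale_s", "amp_uV", "dur_s", "retained"],
    )


def write_waves(path: str | Path, waves: list[GammaWave], retained=None) -> None:
    waves_to_frame(waves, retained).to_csv(path, index=False)


def read_waves(path: str | Path) -> list[GammaWave]:
    df = pd.read_csv(path)
    return [
        GammaWave(
            start=row.start_s, scale=row.scale_s, peak_amplitude=row.amp_uV,
            duration=row.dur_s, side=str(row.side) if not pd.isna(row.side) else "",
            site=str(row.site) if not pd.isna(row.site) else "",
            generator_label=str(row.generator) if not pd.isna(row.generator) else "",
        )
        for row in df.itertuples()
        if getattr(row, "retained", True)
    ]


def write_pairs(path: str | Path, pairing: WavePairing) -> None:
    rows = [
        {
            "start_a": p.wave_a.start, "start_b": p.wave_b.start, "omega": p.omega,
            "lag_ms": p.lag_ms, "amp_a": p.wave_a.peak_amplitude,
            "amp_b": p.wave_b.peak_amplitude, "dur_a": p.wave_a.duration,
            "dur_b": p.wave_b.duration, "longer": p.longer_side,
        }
        for p in pairing.pairs
    ]
    pd.DataFrame(
        rows,
        columns=["start_a", "start_b", "omega", "lag_ms", "amp_a", "amp_b",
                 "dur_a", "dur_b", "longer"],
    ).to_csv(path, index=False)


def write_ground_truth(path: str | Path, truth) -> None:
    payload = {
        "true_mixing": np.asarray(truth.true_mixing).tolist(),
        "generator_keys": [list(k) for k in truth.generator_keys],
        "true_waves": {
            f"{side}:{label}": [[w.start, w.scale, w.amplitude] for w in waves]
            for (side, label), waves in truth.true_waves.items()
        },
        "true_pairs": {
            label: [[p.left_index, p.right_index, p.lag_ms] for p in pairs]
            for label, pairs in truth.true_pairs.items()
        },
        "unit_params": [
            {
                "unit_id": u.unit_id, "cell_class": u.cell_class, "side": u.side,
                "base_rate_hz": u.base_rate_hz,
                "coupling_latency_ms": u.coupling_latency_ms,
                "coupling_strength": u.coupling_strength,
            }
            for u in truth.unit_params
        ],
    }
    Path(path).write_text(json.dumps(payload))
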