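"""Plain-text input/output for traces, cycles, and result tables."""

from __future__ import annotations

import json
import pickle
from pathlib import Path

import numpy as np
import pandas as pd

from .model import EnsembleModel
from .preprocess import CardiacCycle, RawRecording

__all__ = [
    "read_waveform",
    "write_cycles",
    "read_cycles",
    "save_model",
    "load_model",
]


def read_waveform(
    path: str | Path, fs: float | None = None, subject_id: str | None = None
) -> RawRecording:
    """Read a trace from delimited text.

    Two columns are read as (time_s, amplitude) with the sampling rate
    inferred from the time column; one column is amplitude only and
    requires an explicit ``fs``.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter=None if path.suffix != ".csv" else ",",
                      ndmin=2, comments="#", skiprows=_header_rows(path))
    if data.shape[1] >= 2:
        t, s = data[:, 0], data[:, 1]
        steps = np.diff(t)
        if len(steps) < 1 or not np.allclose(steps, steps[0], rtol=1e-3):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        fs_eff = 1.0 / float(steps[0])
    else:
        if fs is None:
            raise ValueError(f"{path}: single-column trace needs an explicit fs")
        s, fs_eff = data[:, 0], fs
    return RawRecording(
        samples=s, fs=fs_eff, subject_id=subject_id or path.stem
    )


def _header_rows(path: Path) -> int:
    with open(path) as fh:
        first = fh.readline()
    try:
        [float(tok) for tok in first.replace(",", " ").split()]
        return 0
    except ValueError:
        return 1


def write_cycles(cycles: list[CardiacCycle], out_dir: str | Path) -> Path:
    """Write per-cycle sample files plus a JSON manifest; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, cyc in enumerate(cycles):
        fname = f"cycle_{i:03d}.csv"
        np.savetxt(out / fname, np.column_stack([cyc.times, cyc.samples]),
                   delimiter=",", header="time_s,amplitude", comments="")
        manifest.append({
            "file": fname,
            "subject_id": cyc.subject_id,
            "fs": cyc.fs,
            "T": cyc.T,
            "T0": cyc.T0,
            "accepted": cyc.accepted,
            "reject_reason": cyc.reject_reason,
        })
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cycles(cycles_dir: str | Path) -> list[CardiacCycle]:
    """Load cycles written by :func:`write_cycles`."""
    cycles_dir = Path(cycles_dir)
    entries = json.loads((cycles_dir / "manifest.json").read_text())
    cycles = []
    for e in entries:
        data = np.loadtxt(cycles_dir / e["file"], delimiter=",", skiprows=1, ndmin=2)
        cyc = CardiacCycle(
            samples=data[:, 1], fs=e["fs"], T=e["T"], T0=e["T0"],
            accepted=e["accepted"], reject_reason=e["reject_reason"],
            subject_id=e["subject_id"],
        )
        cycles.append(cyc)
    return cycles


def save_model(model: EnsembleModel, path: str | Path) -> None:
    """Persist a trained ensemble (pickle bundle)."""
    with open(path, "wb") as fh:
        pickle.dump(model, fh)


def load_model(path: str | Path) -> EnsembleModel:
    with open(path, "rb") as fh:
        model = pickle.load(fh)
    if not isinstance(model, EnsembleModel):
        raise TypeError(f"{path} does not contain an EnsembleModel")
    return model
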