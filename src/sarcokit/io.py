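"""File-format adapters shared by all analysis stages.

Plain-text formats only: FASTA for sequences (via Biopython), headered
CSV/TSV for profiles, decays, domain intervals and trajectories, WAV or
two-column CSV for audio, JSON for summaries and run manifests. Writers
are atomic (write to a temporary file, then rename) and every run can be
accompanied by a JSON manifest recording inputs, parameters, seed and
package version.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import wavfile

from .domains import DomainInterval, ProteinRecord
from .synth import AudioTrace, DecayHistogram, IntensityProfile

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_profile_csv",
    "write_profile_csv",
    "read_decay_csv",
    "write_decay_csv",
    "read_audio",
    "write_audio",
    "read_intervals_tsv",
    "write_intervals_tsv",
    "read_config",
    "write_manifest",
    "atomic_write_text",
]


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to path via a temporary file + rename (no partial files)."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# --- sequences -------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: str | Path, records: Iterable[ProteinRecord]) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".tmp")
    os.close(fd)
    try:
        SeqIO.write(seqs, tmp, "fasta")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# --- tabular ---------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def read_profile_csv(path: str | Path) -> IntensityProfile:
    """CSV with columns position_um,intensity; positions at pixel centers."""
    df = pd.read_csv(path)
    _require_columns(df, ["position_um", "intensity"], path)
    pos = df["position_um"].to_numpy(dtype=float)
    steps = np.diff(pos)
    if len(steps) == 0 or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError(f"{path}: positions must be uniformly spaced")
    return IntensityProfile(
        samples=df["intensity"].to_numpy(dtype=float), pixel_size=float(steps[0])
    )


def write_profile_csv(path: str | Path, profile: IntensityProfile) -> None:
    df = pd.DataFrame(
        {"position_um": profile.positions, "intensity": profile.samples}
    )
    atomic_write_text(path, df.to_csv(index=False))


def read_decay_csv(path: str | Path) -> DecayHistogram:
    df = pd.read_csv(path)
    _require_columns(df, ["time_ns", "counts"], path)
    return DecayHistogram(
        bin_centers=df["time_ns"].to_numpy(dtype=float),
        counts=df["counts"].to_numpy(dtype=float),
    )


def write_decay_csv(path: str | Path, hist: DecayHistogram) -> None:
    df = pd.DataFrame({"time_ns": hist.bin_centers, "counts": hist.counts})
    atomic_write_text(path, df.to_csv(index=False))


def read_intervals_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["protein_id", "class", "start", "end"], path)
    return df


def write_intervals_tsv(
    path: str | Path, protein_id: str, intervals: Iterable[DomainInterval]
) -> None:
    rows = [
        {
            "protein_id": protein_id,
            "class": d.domain_class,
            "start": d.start,
            "end": d.end,
            "source": d.source,
        }
        for d in intervals
    ]
    df = pd.DataFrame(rows, columns=["protein_id", "class", "start", "end", "source"])
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


# --- audio -----------------------------------------------------------------


def read_audio(path: str | Path) -> AudioTrace:
    """WAV (any integer/float mono PCM) or CSV with time_s,amplitude."""
    path = Path(path)
    if path.suffix.lower() == ".wav":
        fs, data = wavfile.read(str(path))
        data = np.asarray(data)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if np.issubdtype(data.dtype, np.integer):
            data = data / float(np.iinfo(data.dtype).max)
        return AudioTrace(samples=data.astype(float), fs=float(fs))
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "amplitude"], path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: time stamps must be uniformly spaced")
    return AudioTrace(
        samples=df["amplitude"].to_numpy(dtype=float), fs=1.0 / float(dt[0])
    )


def write_audio(path: str | Path, trace: AudioTrace) -> None:
    path = Path(path)
    if path.suffix.lower() == ".wav":
        peak = np.max(np.abs(trace.samples)) or 1.0
        data = (trace.samples / peak).astype(np.float32)
        fd, tmp = tempfile.mkstemp(dir=path.parent or ".", suffix=".wav")
        os.close(fd)
        try:
            wavfile.write(tmp, int(round(trace.fs)), data)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise
        return
    t = np.arange(len(trace.samples)) / trace.fs
    df = pd.DataFrame({"time_s": t, "amplitude": trace.samples})
    atomic_write_text(path, df.to_csv(index=False))


# --- config & manifests ----------------------------------------------------


def read_config(path: str | Path, known_keys: Sequence[str] | None = None) -> dict:
    """Flat key = value config; '#' starts a comment; values auto-typed."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (part.strip() for part in line.split("=", 1))
        if known_keys is not None and key not in known_keys:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        for cast in (int, float):
            try:
                out[key] = cast(val)
                break
            except ValueError:
                continue
        else:
            out[key] = {"true": True, "false": False, "none": None}.get(
                val.lower(), val
            )
    return out


def write_manifest(
    path: str | Path,
    command: str,
    inputs: dict,
    parameters: dict,
    seed: int | None,
) -> None:
    from . import __version__

    manifest = {
        "tool": "sarcokit",
        "version": __version__,
        "command": command,
        "inputs": inputs,
        "parameters": parameters,
        "seed": seed,
    }
    atomic_write_text(path, json.dumps(manifest, indent=2, default=str) + "\n")
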