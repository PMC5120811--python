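"""BrainVision Core Data Format I/O.

Writing produces a standard ``.vhdr`` / ``.vmrk`` / ``.eeg`` triplet
(multiplexed IEEE float32, unit uV, resolution 1) so the files are readable
by any BrainVision-aware tool.  Reading delegates to
``mne.io.read_raw_brainvision`` after a light structural validation of the
header that reports problems with their line number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ContinuousRecording", "write_brainvision", "read_brainvision"]


@dataclass
class ContinuousRecording:
    """A continuous multichannel record with stimulus markers (uV)."""

    labels: list[str]
    data: np.ndarray  # (n_channels, n_samples), uV
    srate: float
    markers: list[tuple[str, int]]  # (description, 1-based sample position)

    def marker_times_ms(self) -> list[tuple[str, float]]:
        return [(d, p * 1000.0 / self.srate) for d, p in self.markers]


def write_brainvision(rec: ContinuousRecording, path) -> Path:
    """Write a triplet ``<path>.vhdr/.vmrk/.eeg``; returns the header path."""
    base = Path(path).with_suffix("")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    n_ch = len(rec.labels)
    if rec.data.shape[0] != n_ch:
        raise ValueError("labels and data channel count disagree")
    interval_us = 1e6 / rec.srate
    with open(vhdr, "w", newline="\r\n") as f:
        f.write("Brain Vision Data Exchange Header File Version 1.0\n")
        f.write("[Common Infos]\nCodepage=UTF-8\n")
        f.write(f"DataFile={eeg.name}\nMarkerFile={vmrk.name}\n")
        f.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        f.write(f"NumberOfChannels={n_ch}\n")
        f.write(f"SamplingInterval={interval_us:.10g}\n")
        f.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
        f.write("[Channel Infos]\n")
        for i, label in enumerate(rec.labels, start=1):
            f.write(f"Ch{i}={label},,1,µV\n")
    with open(vmrk, "w", newline="\r\n") as f:
        f.write("Brain Vision Data Exchange Marker File, Version 1.0\n")
        f.write("[Common Infos]\nCodepage=UTF-8\n")
        f.write(f"DataFile={eeg.name}\n")
        f.write("[Marker Infos]\n")
        f.write("Mk1=New Segment,,1,1,0,0\n")
        for k, (desc, pos) in enumerate(rec.markers, start=2):
            f.write(f"Mk{k}=Stimulus,{desc},{pos},1,0\n")
    rec.data.astype("<f4").T.tofile(eeg)  # multiplexed: sample-major
    return vhdr


_REQUIRED_HEADER_KEYS = ("DataFile", "NumberOfChannels", "SamplingInterval")


def _validate_vhdr(vhdr: Path) -> None:
    text = vhdr.read_text(errors="replace").splitlines()
    if not text or "Brain Vision Data Exchange Header File" not in text[0]:
        raise ValueError(f"{vhdr}:1: not a BrainVision header (bad magic line)")
    seen = {}
    section = None
    for lineno, line in enumerate(text, start=1):
        s = line.strip()
        if not s or s.startswith(";"):
            continue
        if s.startswith("["):
            if not s.endswith("]"):
                raise ValueError(f"{vhdr}:{lineno}: unterminated section header {s!r}")
            section = s[1:-1]
            continue
        if section in ("Common Infos", "Binary Infos", "Channel Infos"):
            if "=" not in s:
                raise ValueError(f"{vhdr}:{lineno}: expected 'Key=Value', got {s!r}")
            key, val = s.split("=", 1)
            seen[key] = (val, lineno)
    for key in _REQUIRED_HEADER_KEYS:
        if key not in seen:
            raise ValueError(f"{vhdr}: missing required header key {key!r}")
    for key in ("NumberOfChannels", "SamplingInterval"):
        val, lineno = seen[key]
        try:
            float(val)
        except ValueError:
            raise ValueError(f"{vhdr}:{lineno}: non-numeric {key}={val!r}") from None
    datafile = vhdr.parent / seen["DataFile"][0]
    if not datafile.exists():
        raise FileNotFoundError(f"{vhdr}: data file {datafile.name!r} not found")


def read_brainvision(path) -> ContinuousRecording:
    """Read a BrainVision triplet into a continuous recording (uV)."""
    import mne

    vhdr = Path(path)
    if vhdr.suffix != ".vhdr":
        vhdr = vhdr.with_suffix(".vhdr")
    if not vhdr.exists():
        raise FileNotFoundError(f"missing header file {vhdr}")
    _validate_vhdr(vhdr)
    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    markers = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("Stimulus/"):
            pos = int(round(ann["onset"] * raw.info["sfreq"])) + 1
            markers.append((desc.split("/", 1)[1], pos))
    return ContinuousRecording(labels=list(raw.ch_names), data=data_uv,
                               srate=float(raw.info["sfreq"]), markers=markers)
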