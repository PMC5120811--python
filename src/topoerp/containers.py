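"""In-memory containers and the native HDF5 dataset format.

Conventions used throughout the package:

* amplitudes in microvolts (uV),
* time in milliseconds relative to the true stimulus onset,
* epoched data as ``(n_epochs, n_channels, n_times)`` arrays,
* condition labels as ``"<gaze>/<freq>"`` strings (e.g. ``"direct/BB"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from .montage import ElectrodeMontage

__all__ = [
    "Segment",
    "GroundTruth",
    "EpochedRecording",
    "Evoked",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class Segment:
    """One planted microstate segment: a template active inside a window.

    ``shape`` is ``"cosine"`` (raised-cosine GFP bump, the default ERP-like
    morphology) or ``"flat"`` (constant envelope, useful for exactness
    checks).
    """

    onset_ms: float
    offset_ms: float
    template: int
    peak_uv: float
    shape: str = "cosine"

    def envelope(self, times_ms: np.ndarray) -> np.ndarray:
        """GFP envelope over ``times_ms`` (uV)."""
        t = np.asarray(times_ms, dtype=float)
        width = self.offset_ms - self.onset_ms
        x = (t - self.onset_ms) / width
        inside = (x >= 0.0) & (x <= 1.0)
        if self.shape == "flat":
            env = np.where(inside, self.peak_uv, 0.0)
        elif self.shape == "cosine":
            env = 0.5 * self.peak_uv * (1.0 - np.cos(2.0 * np.pi * np.clip(x, 0.0, 1.0)))
            env[~inside] = 0.0
        else:
            raise ValueError(f"unknown envelope shape {self.shape!r}")
        return env


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset.

    ``templates`` are zero-mean unit-norm topographies; ``segments`` maps each
    condition label to the microstate sequence active in that condition;
    ``dipoles`` optionally records (location, orientation, moment time course)
    triples used for source-space simulations.
    """

    templates: list[np.ndarray]
    segments: dict[str, list[Segment]]
    noise_sd: float
    seed: int
    dipoles: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, t in enumerate(self.templates):
            t = np.asarray(t, dtype=float)
            if abs(t.mean()) > 1e-8 or abs(np.linalg.norm(t) - 1.0) > 1e-8:
                raise ValueError(f"template {k} must be zero-mean and unit-norm")
            self.templates[k] = t
        for cond, segs in self.segments.items():
            segs = sorted(segs, key=lambda s: s.onset_ms)
            for a, b in zip(segs, segs[1:]):
                if b.onset_ms < a.offset_ms - 1e-9:
                    raise ValueError(f"overlapping segments in condition {cond!r}")
            for s in segs:
                if s.template >= len(self.templates):
                    raise ValueError(f"segment refers to missing template {s.template}")
            self.segments[cond] = segs

    def condition_signal(self, cond: str, times_ms: np.ndarray) -> np.ndarray:
        """Noise-free (channels, times) signal for one condition.

        Segment peaks are *GFP* envelopes: a unit-norm template map has GFP
        1/sqrt(n_ch), so maps are scaled by sqrt(n_ch) to make the signal's
        GFP trace equal the envelope (uV).
        """
        n_ch = len(self.templates[0])
        sig = np.zeros((n_ch, len(times_ms)))
        for seg in self.segments[cond]:
            sig += np.outer(self.templates[seg.template] * np.sqrt(n_ch),
                            seg.envelope(times_ms))
        return sig

    def has_condition_effect(self) -> bool:
        seqs = {
            cond: tuple((s.onset_ms, s.offset_ms, s.template, s.peak_uv) for s in segs)
            for cond, segs in self.segments.items()
        }
        return len(set(seqs.values())) > 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "templates": [t.tolist() for t in self.templates],
                "segments": {
                    c: [asdict(s) for s in segs] for c, segs in self.segments.items()
                },
                "noise_sd": self.noise_sd,
                "seed": self.seed,
                "dipoles": [
                    {"location": list(map(float, l)), "orientation": list(map(float, o)),
                     "moment": np.asarray(m).tolist()}
                    for l, o, m in self.dipoles
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            templates=[np.asarray(t) for t in d["templates"]],
            segments={
                c: [Segment(**s) for s in segs] for c, segs in d["segments"].items()
            },
            noise_sd=d["noise_sd"],
            seed=d["seed"],
            dipoles=[
                (np.asarray(p["location"]), np.asarray(p["orientation"]), np.asarray(p["moment"]))
                for p in d.get("dipoles", [])
            ],
        )


def _check_times(times_ms: np.ndarray, srate: float) -> None:
    step = np.diff(times_ms)
    if len(step) and not np.allclose(step, 1000.0 / srate, atol=1e-6):
        raise ValueError("times must increase uniformly with step 1000/srate ms")


@dataclass
class EpochedRecording:
    """Per-subject epochs x electrodes x time (uV), stimulus-locked."""

    subject: str
    data: np.ndarray  # (n_epochs, n_channels, n_times)
    srate: float
    times: np.ndarray  # ms
    conditions: list[str]  # per epoch, "<gaze>/<freq>"
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (epochs, channels, times)")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per epoch required")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")
        _check_times(self.times, self.srate)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def condition_set(self) -> list[str]:
        return sorted(set(self.conditions))

    def copy(self) -> "EpochedRecording":
        return EpochedRecording(
            self.subject,
            self.data.copy(),
            self.srate,
            self.times.copy(),
            list(self.conditions),
            dict(self.info),
        )


@dataclass
class Evoked:
    """One condition-averaged ERP (channels x times, uV)."""

    subject: str
    condition: str
    data: np.ndarray  # (n_channels, n_times)
    srate: float
    times: np.ndarray  # ms
    nave: int
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.times):
            raise ValueError("data must be (channels, times) matching the time axis")
        _check_times(self.times, self.srate)

    def time_mask(self, tmin_ms: float, tmax_ms: float) -> np.ndarray:
        return (self.times >= tmin_ms - 1e-9) & (self.times <= tmax_ms + 1e-9)

    def crop(self, tmin_ms: float, tmax_ms: float) -> "Evoked":
        m = self.time_mask(tmin_ms, tmax_ms)
        if not m.any():
            raise ValueError(f"window ({tmin_ms}, {tmax_ms}) ms is outside the epoch")
        return Evoked(self.subject, self.condition, self.data[:, m], self.srate,
                      self.times[m], self.nave, dict(self.info))


# ---------------------------------------------------------------------------
# native HDF5 container
# ---------------------------------------------------------------------------

def save_dataset(path, recordings: list[EpochedRecording], montage: ElectrodeMontage,
                 truth: GroundTruth | None = None) -> None:
    """Write a multi-subject dataset to the native HDF5 layout.

    Layout: ``/subjects/<id>/{data,conditions}``, ``/times``, ``/montage``.
    The ground truth, when given, is stored as a JSON sidecar dataset so it
    survives round-trips without a separate file.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=recordings[0].times)
        f.attrs["srate"] = recordings[0].srate
        g = f.create_group("montage")
        g.create_dataset("labels", data=np.array(montage.labels, dtype="S"))
        g.create_dataset("positions", data=montage.positions)
        g.attrs["scale"] = montage.scale
        subj = f.create_group("subjects")
        for rec in recordings:
            sg = subj.create_group(rec.subject)
            sg.create_dataset("data", data=rec.data)
            sg.create_dataset("conditions", data=np.array(rec.conditions, dtype="S"))
            sg.attrs["info"] = json.dumps(rec.info, default=str)
        if truth is not None:
            f.create_dataset("ground_truth", data=truth.to_json())


def load_dataset(path):
    """Read back a dataset written by :func:`save_dataset`.

    Returns ``(recordings, montage, truth_or_None)``.
    """
    with h5py.File(path, "r") as f:
        times = f["times"][()]
        srate = float(f.attrs["srate"])
        labels = tuple(l.decode() for l in f["montage/labels"][()])
        montage = ElectrodeMontage(labels, f["montage/positions"][()],
                                   scale=float(f["montage"].attrs["scale"]))
        recs = []
        for sid in sorted(f["subjects"]):
            sg = f["subjects"][sid]
            recs.append(
                EpochedRecording(
                    subject=sid,
                    data=sg["data"][()],
                    srate=srate,
                    times=times,
                    conditions=[c.decode() for c in sg["conditions"][()]],
                    info=json.loads(sg.attrs["info"]),
                )
            )
        truth = None
        if "ground_truth" in f:
            raw = f["ground_truth"][()]
            truth = GroundTruth.from_json(raw.decode() if isinstance(raw, bytes) else raw)
    return recs, montage, truth
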