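"""Ground-truth-annotated synthetic EEG for a 2 (gaze) x 3 (spatial
frequency) within-subject ERP design.

Every epoch is generated by an explicit linear model,

    epoch = sum over active segments of envelope(t) * template
          + subject-level spatially correlated noise (shared across epochs)
          + epoch-level spatially correlated Gaussian noise,

so downstream stages can be tested against a recoverable truth.  Segment
envelopes are raised cosines (a single GFP bump per microstate, the typical
ERP morphology); condition differences are planted by assigning different
templates to different conditions inside a declared window.  Between-subject
variability rotates each template by a small angle in sensor space and draws
a log-normal amplitude gain, giving the back-fitting ANOVA realistic
subject variance without changing the planted map identities.

Sensor noise is Gaussian with spatial covariance ``exp(-d / 0.5)`` over the
inter-electrode chord distance ``d`` (volume conduction makes white sensor
noise unrealistically easy to remove) and is white in time.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochedRecording, Evoked, GroundTruth, Segment
from .montage import ElectrodeMontage

__all__ = [
    "DEFAULT_DESIGN", "default_truth", "random_templates",
    "make_montage",  # re-export for convenience
    "simulate_dataset", "simulate_null_dataset", "inject_artifacts",
    "simulate_dipole_evoked", "noise_cholesky", "blink_topography",
]

from .montage import make_montage  # noqa: E402  (re-export)

GAZES = ("direct", "averted")
FREQS = ("BB", "HSF", "LSF")
DEFAULT_DESIGN = tuple(f"{g}/{f}" for g in GAZES for f in FREQS)

NOISE_RANGE = 0.5  # chord-distance scale of the spatial noise covariance


def noise_cholesky(montage: ElectrodeMontage, length: float = NOISE_RANGE) -> np.ndarray:
    """Cholesky factor of the exp(-d/length) spatial noise covariance."""
    cov = np.exp(-montage.chord_distances() / length)
    cov.flat[:: cov.shape[0] + 1] += 1e-9
    return np.linalg.cholesky(cov)


def random_templates(montage: ElectrodeMontage, n_templates: int, seed: int,
                     orthogonal: bool = True) -> list[np.ndarray]:
    """Random zero-mean unit-norm topographies (mutually orthogonal by default)."""
    rng = np.random.default_rng(seed)
    n = montage.n_channels
    X = rng.standard_normal((n, n_templates))
    X -= X.mean(axis=0, keepdims=True)
    if orthogonal:
        q, _ = np.linalg.qr(X)
        X = q[:, :n_templates]
        X -= X.mean(axis=0, keepdims=True)  # re-center (QR can drift off zero-mean)
    X /= np.linalg.norm(X, axis=0, keepdims=True)
    return [X[:, k].copy() for k in range(n_templates)]


def default_truth(montage: ElectrodeMontage, seed: int = 0, noise_sd: float = 8.0,
                  effect_freq: str = "BB", peak_uv: float = 4.0) -> GroundTruth:
    """The reference study conditions: shared P1/N170-like maps in every
    condition, plus an early 41-80 ms map that differs between direct and
    averted gaze in the ``effect_freq`` condition only."""
    templates = random_templates(montage, 5, seed)
    late = [
        Segment(90.0, 150.0, 2, 1.25 * peak_uv),    # P1-like
        Segment(150.0, 210.0, 3, 1.5 * peak_uv),    # N170-like
        Segment(210.0, 340.0, 4, peak_uv),          # late component
    ]
    segments: dict[str, list[Segment]] = {}
    for cond in DEFAULT_DESIGN:
        gaze, freq = cond.split("/")
        if freq == effect_freq:
            early_tpl = 0 if gaze == "direct" else 1
        else:
            early_tpl = 0
        segments[cond] = [Segment(41.0, 80.0, early_tpl, 0.75 * peak_uv)] + list(late)
    return GroundTruth(templates=templates, segments=segments,
                       noise_sd=noise_sd, seed=seed)


def _rotate_template(t: np.ndarray, angle_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate a zero-mean unit-norm map by ``angle_rad`` toward a random
    direction orthogonal to it (and to the constant vector)."""
    if angle_rad == 0.0:
        return t.copy()
    u = rng.standard_normal(t.shape)
    u -= u.mean()
    u -= (u @ t) * t
    u /= np.linalg.norm(u)
    return np.cos(angle_rad) * t + np.sin(angle_rad) * u


def simulate_dataset(montage: ElectrodeMontage, design=DEFAULT_DESIGN,
                     n_subjects: int = 15, n_epochs_per_cond: int = 96,
                     truth: GroundTruth | None = None,
                     between_subject_sd: float = 0.0, seed: int = 0,
                     srate: float = 1024.0,
                     epoch_ms: tuple[float, float] = (-200.0, 350.0),
                     rotation_deg: float = 5.0, gain_sigma: float = 0.1,
                     ) -> tuple[list[EpochedRecording], GroundTruth]:
    """Simulate a multi-subject epoched dataset with planted microstates.

    Returns the recordings and the (unchanged) ground truth.  ``seed`` fully
    determines the output.  ``between_subject_sd`` (uV) adds a subject-level
    spatially correlated noise field shared by all epochs of a subject.
    """
    if truth is None:
        truth = default_truth(montage, seed=seed)
    n_ch = montage.n_channels
    for k, t in enumerate(truth.templates):
        if len(t) != n_ch:
            raise ValueError(
                f"template {k} has {len(t)} channels, montage has {n_ch}")
    missing = [c for c in design if c not in truth.segments]
    if missing:
        raise ValueError(f"truth defines no segments for condition(s) {missing}")
    dt = 1000.0 / srate
    times = np.arange(epoch_ms[0], epoch_ms[1] + dt / 2, dt)
    L = noise_cholesky(montage)
    rng = np.random.default_rng(seed)
    recordings = []
    for s in range(n_subjects):
        gains = np.exp(rng.normal(0.0, gain_sigma))
        subj_templates = [
            _rotate_template(t, np.deg2rad(rotation_deg) * rng.standard_normal(), rng)
            for t in truth.templates
        ]
        subj_bias = (between_subject_sd *
                     (L @ rng.standard_normal((n_ch, len(times))))
                     if between_subject_sd > 0 else 0.0)
        signals = {}
        scale = gains * np.sqrt(n_ch)  # segment peaks are GFP envelopes (uV)
        for cond in design:
            sig = np.zeros((n_ch, len(times)))
            for seg in truth.segments[cond]:
                sig += np.outer(subj_templates[seg.template] * scale,
                                seg.envelope(times))
            signals[cond] = sig + subj_bias
        n_ep = n_epochs_per_cond * len(design)
        data = np.empty((n_ep, n_ch, len(times)))
        conditions = []
        for i, cond in enumerate(design):
            for e in range(n_epochs_per_cond):
                noise = (truth.noise_sd *
                         (L @ rng.standard_normal((n_ch, len(times))))
                         if truth.noise_sd > 0 else 0.0)
                data[i * n_epochs_per_cond + e] = signals[cond] + noise
                conditions.append(cond)
        recordings.append(
            EpochedRecording(subject=f"S{s + 1:02d}", data=data, srate=srate,
                             times=times, conditions=conditions,
                             info={"seed": seed, "subject_index": s}))
    return recordings, truth


def simulate_null_dataset(montage: ElectrodeMontage, n_subjects: int,
                          n_epochs_per_cond: int, truth: GroundTruth,
                          seed: int = 0, design=("direct/BB", "averted/BB"),
                          **kwargs) -> list[EpochedRecording]:
    """Dataset whose conditions are exchangeable by construction.

    The supplied truth must assign identical segment sequences to all
    conditions; condition-specific effects are an error here.  Used for
    type-I-error calibration of the topographic randomization test.
    """
    seqs = {tuple((s.onset_ms, s.offset_ms, s.template, s.peak_uv)
                  for s in truth.segments[c]) for c in design if c in truth.segments}
    if len(seqs) > 1 or truth.has_condition_effect():
        raise ValueError("truth contains condition-specific segments; "
                         "a null dataset requires exchangeable conditions")
    recs, _ = simulate_dataset(montage, design=design, n_subjects=n_subjects,
                               n_epochs_per_cond=n_epochs_per_cond, truth=truth,
                               seed=seed, **kwargs)
    return recs


def blink_topography(montage: ElectrodeMontage, width: float = 0.45) -> np.ndarray:
    """Frontal-weighted blink spatial pattern (unit max, zero-mean removed
    downstream by referencing)."""
    front = np.array([0.0, 0.94, 0.34])
    front /= np.linalg.norm(front)
    d = np.linalg.norm(montage.positions - front, axis=1)
    w = np.exp(-(d / width) ** 2)
    return w / w.max()


def inject_artifacts(recording: EpochedRecording, montage: ElectrodeMontage,
                     blink_rate: float = 0.0, outlier_amplitude: float = 100.0,
                     spike_rate: float = 0.0, blink_amplitude: float = 120.0,
                     seed: int = 0) -> EpochedRecording:
    """Add blink-like frontal deflections and/or amplitude-outlier spikes.

    Each epoch independently receives a blink with probability ``blink_rate``
    and a spike (a ~60 ms single-channel burst peaking above
    ``outlier_amplitude`` uV, broad enough to survive the 30 Hz low-pass)
    with probability ``spike_rate``.  Injected epoch indices
    are recorded in the output's ``info`` under ``blink_epochs`` and
    ``spike_epochs``.
    """
    if outlier_amplitude <= 0:
        raise ValueError("outlier_amplitude must be positive")
    out = recording.copy()
    rng = np.random.default_rng(seed)
    n_ep, n_ch, n_t = out.data.shape
    blink_epochs = np.where(rng.random(n_ep) < blink_rate)[0]
    spike_epochs = np.where(rng.random(n_ep) < spike_rate)[0]
    if len(blink_epochs):
        topo = blink_topography(montage)
        dur = max(3, int(0.25 * recording.srate))  # ~250 ms blink
        for e in blink_epochs:
            start = rng.integers(0, max(1, n_t - dur))
            course = np.zeros(n_t)
            course[start:start + dur] = np.sin(
                np.linspace(0.0, np.pi, min(dur, n_t - start)))
            out.data[e] += blink_amplitude * np.outer(topo, course)
    burst = max(3, int(0.06 * recording.srate))  # ~60 ms: survives a 30 Hz low-pass
    for e in spike_epochs:
        ch = rng.integers(0, n_ch)
        t = rng.integers(0, max(1, n_t - burst))
        width = min(burst, n_t - t)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[e, ch, t:t + width] += (sign * 1.25 * outlier_amplitude *
                                         np.sin(np.linspace(0.0, np.pi, width)))
    out.info["blink_epochs"] = blink_epochs.tolist()
    out.info["spike_epochs"] = spike_epochs.tolist()
    return out


def simulate_dipole_evoked(montage: ElectrodeMontage, model, dipoles,
                           noise_sd: float = 0.0, seed: int = 0,
                           srate: float = 256.0,
                           window_ms: tuple[float, float] = (0.0, 100.0),
                           ) -> tuple[Evoked, GroundTruth]:
    """Sensor-level evoked response of known dipolar generators.

    ``dipoles`` is a list of ``(location, orientation, moment)`` with the
    moment either a scalar (flat time course) or a per-sample array; the
    ``model`` is a :class:`~topoerp.sourceloc.HeadModel` or anything with a
    ``model`` attribute (e.g. a :class:`~topoerp.sourceloc.LeadField`).
    Data = lead field x moment + spatially correlated noise,
    average-referenced.
    """
    from .sourceloc import HeadModel, forward_dipole

    head = model if isinstance(model, HeadModel) else model.model
    dt = 1000.0 / srate
    times = np.arange(window_ms[0], window_ms[1] + dt / 2, dt)
    n_t = len(times)
    locs = np.array([np.asarray(d[0], dtype=float) for d in dipoles])
    gain = forward_dipole(montage, locs, model=head)  # validates locations
    data = np.zeros((montage.n_channels, n_t))
    truth_dipoles = []
    for k, (loc, ori, moment) in enumerate(dipoles):
        ori = np.asarray(ori, dtype=float)
        ori = ori / np.linalg.norm(ori)
        course = (np.full(n_t, float(moment)) if np.ndim(moment) == 0
                  else np.asarray(moment, dtype=float))
        if len(course) != n_t:
            raise ValueError(f"dipole {k}: moment time course has wrong length")
        data += np.outer(gain[:, k, :] @ ori, course)
        truth_dipoles.append((np.asarray(loc, dtype=float), ori, course))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        L = noise_cholesky(montage)
        data = data + noise_sd * (L @ rng.standard_normal(data.shape))
    data -= data.mean(axis=0, keepdims=True)
    truth = GroundTruth(templates=[], segments={}, noise_sd=noise_sd, seed=seed,
                        dipoles=truth_dipoles)
    truth.templates = []  # no planted microstates for dipole runs
    ev = Evoked(subject="sim", condition="dipole", data=data, srate=srate,
                times=times, nave=1)
    return ev, truth
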