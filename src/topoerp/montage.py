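"""Electrode montages on the unit scalp sphere.

All geometry in this package is expressed in dimensionless head coordinates
with the scalp sphere at radius 1.  Sensors live on the upper part of the
sphere (z >= -0.2), mimicking an EEG cap that extends a little below the
equator over temporal/occipital regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ElectrodeMontage", "make_montage", "read_montage", "write_montage"]

_MIN_SENSORS = 16
_Z_FLOOR = -0.2


@dataclass(frozen=True)
class ElectrodeMontage:
    """A named sensor set with 3-D positions on the unit scalp sphere."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3), unit norm
    scale: float = 1.0  # physical radius the positions were normalized by

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(self.labels) != pos.shape[0]:
            raise ValueError("labels and positions disagree in length")
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise ValueError(f"duplicate electrode labels: {dup}")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must have unit norm (scalp radius 1)")
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown electrode label: {label!r}") from None

    def chord_distances(self) -> np.ndarray:
        """Pairwise straight-line (chord) distances between sensors."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)

    def posterior_pools(self, x_split: float = 0.25, y_max: float = -0.35) -> dict[str, list[str]]:
        """Left/right lateral posterior electrode pools.

        Used as the default occipito-temporal pools for ERP component
        measurement: posterior (y below ``y_max``) and lateral
        (|x| above ``x_split``).
        """
        x, y = self.positions[:, 0], self.positions[:, 1]
        left = [l for l, xi, yi in zip(self.labels, x, y) if yi < y_max and xi < -x_split]
        right = [l for l, xi, yi in zip(self.labels, x, y) if yi < y_max and xi > x_split]
        return {"left": left, "right": right}


def make_montage(n_electrodes: int, seed: int = 0) -> ElectrodeMontage:
    """Deterministic quasi-uniform cap layout (Fibonacci lattice).

    Points are spread over the spherical cap z in [-0.2, 1] using the golden
    angle, which gives a quasi-uniform sensor density like a high-density cap.
    The layout depends only on ``n_electrodes``; the ``seed`` argument is part
    of the reproducibility API and reserved for future stochastic layouts.
    """
    if n_electrodes < _MIN_SENSORS:
        raise ValueError(f"need at least {_MIN_SENSORS} electrodes, got {n_electrodes}")
    del seed  # layout is fully deterministic
    i = np.arange(n_electrodes)
    # evenly spaced heights inside the cap, avoiding the exact pole/rim
    z = 1.0 - (i + 0.5) * (1.0 - _Z_FLOOR) / n_electrodes
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    labels = tuple(f"E{k + 1:03d}" for k in range(n_electrodes))
    return ElectrodeMontage(labels=labels, positions=pos)


def read_montage(path) -> ElectrodeMontage:
    """Read a plain-text ``label x y z`` coordinate file (.sfp/.elc style).

    Positions are normalized to the unit sphere; the mean original radius is
    kept as ``scale``.  Duplicate labels are an error.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 'label x y z', got {line!r}")
            labels.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric coordinate in {line!r}") from None
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate electrode labels in {path}: {dup}")
    pos = np.asarray(rows, dtype=float)
    norms = np.linalg.norm(pos, axis=1)
    if np.any(norms == 0):
        raise ValueError(f"{path}: electrode at the origin cannot be normalized")
    scale = float(norms.mean())
    return ElectrodeMontage(tuple(labels), pos / norms[:, None], scale=scale)


def write_montage(montage: ElectrodeMontage, path) -> None:
    """Write a montage as a ``label x y z`` text file (unit-sphere coords)."""
    with open(path, "w") as fh:
        for label, p in zip(montage.labels, montage.positions):
            fh.write(f"{label} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
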