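"""P1 / N170 peak amplitude and latency over pooled electrode sites.

Peaks are simple extrema of the stated polarity inside a closed search
window on the pooled (averaged) occipito-temporal waveform — no local-peak
requirement.  Window edges are legal peak locations but are flagged in the
output (a monotone waveform peaks at an edge).  Default measurement windows
follow the study convention: P1 100-140 ms (positive), N170 140-160 ms
(negative); electrode pools are configuration, defaulting to the montage's
lateral posterior pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Evoked
from .montage import ElectrodeMontage

__all__ = ["ComponentSpec", "default_component_specs", "pool_waveform",
           "find_peak", "peak_table"]


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    polarity: str  # "positive" | "negative"
    window_ms: tuple[float, float]
    pools: dict  # hemisphere -> list of electrode labels

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        if not all(self.pools.values()):
            raise ValueError(f"component {self.name}: empty electrode pool")
        hemis = list(self.pools)
        for i, a in enumerate(hemis):
            for b in hemis[i + 1:]:
                both = set(self.pools[a]) & set(self.pools[b])
                if both:
                    raise ValueError(f"pools overlap across hemispheres: {sorted(both)}")


def default_component_specs(montage: ElectrodeMontage) -> list[ComponentSpec]:
    pools = montage.posterior_pools()
    return [
        ComponentSpec("P1", "positive", (100.0, 140.0), pools),
        ComponentSpec("N170", "negative", (140.0, 160.0), pools),
    ]


def pool_waveform(evoked: Evoked, labels: list[str],
                  montage: ElectrodeMontage) -> np.ndarray:
    """Arithmetic mean over the pooled electrodes at each time point."""
    idx = [montage.index(l) for l in labels]  # KeyError names unknown labels
    return evoked.data[idx].mean(axis=0)


def find_peak(times_ms: np.ndarray, waveform: np.ndarray,
              window_ms: tuple[float, float], polarity: str):
    """Extremum of the stated polarity within the closed window.

    Returns ``(latency_ms, amplitude_uv, at_edge)``; ties break to the
    earliest latency.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    m = (times_ms >= window_ms[0] - 1e-9) & (times_ms <= window_ms[1] + 1e-9)
    if not m.any():
        raise ValueError(f"window {window_ms} ms contains no samples")
    w = np.asarray(waveform, dtype=float)[m]
    t = times_ms[m]
    i = int(np.argmax(w)) if polarity == "positive" else int(np.argmin(w))
    return float(t[i]), float(w[i]), bool(i in (0, len(t) - 1))


def peak_table(evokeds_by_subject: dict, specs: list[ComponentSpec],
               montage: ElectrodeMontage) -> pd.DataFrame:
    """Long table of peak measures: one row per subject x condition x
    hemisphere x component, ready for the repeated-measures ANOVA."""
    subjects = sorted(evokeds_by_subject)
    conditions = sorted(evokeds_by_subject[subjects[0]])
    for s in subjects:
        missing = set(conditions) - set(evokeds_by_subject[s])
        if missing:
            raise ValueError(f"subject {s} missing condition(s) {sorted(missing)}")
    rows = []
    for s in subjects:
        for cond in conditions:
            ev = evokeds_by_subject[s][cond]
            gaze, freq = cond.split("/") if "/" in cond else (cond, "")
            for spec in specs:
                for hemi, labels in spec.pools.items():
                    wf = pool_waveform(ev, labels, montage)
                    lat, amp, edge = find_peak(ev.times, wf, spec.window_ms,
                                               spec.polarity)
                    rows.append({"subject": s, "gaze": gaze, "freq": freq,
                                 "hemisphere": hemi, "component": spec.name,
                                 "latency_ms": lat, "amplitude_uv": amp,
                                 "at_edge": edge})
    return pd.DataFrame(rows)
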