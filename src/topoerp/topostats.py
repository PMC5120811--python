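"""Global field power, global map dissimilarity, and its randomization test.

GFP is the spatial root-mean-square of an average-referenced map — field
strength independent of configuration.  DISS between two maps is the GFP of
the difference of the GFP-normalized maps; it ranges from 0 (identical
configuration) to 2 (polarity inversion) and satisfies the identity
``DISS = sqrt(2 (1 - r))`` with r the spatial Pearson correlation.

The TANOVA-style test compares two within-subject conditions: observed DISS
between the two condition grand means at each time point; the null swaps
the two condition ERPs within random subsets of subjects (the paired
design's exchangeability), recomputes grand means, and DISS.  p-values use
the +1 finite-sample correction, ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import Evoked

__all__ = ["DissResult", "gfp", "dissimilarity", "diss_test", "pointwise_ttests"]


def _avg_ref(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-2 if x.ndim > 1 else -1, keepdims=x.ndim > 1)
    if np.max(np.abs(mean)) > 1e-8:
        return x - mean
    return x


def gfp(x: np.ndarray) -> np.ndarray | float:
    """Spatial RMS of average-referenced potentials.

    For a single map (1-D) returns a scalar; for (channels, times) input a
    time series.  Inputs are re-referenced if needed.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x - x.mean()
        return float(np.sqrt(np.mean(x ** 2)))
    x = x - x.mean(axis=-2, keepdims=True)
    return np.sqrt(np.mean(x ** 2, axis=-2))


def dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """Global map dissimilarity between two average-referenced maps."""
    u = np.asarray(u, dtype=float) - np.mean(u)
    v = np.asarray(v, dtype=float) - np.mean(v)
    gu, gv = np.sqrt(np.mean(u ** 2)), np.sqrt(np.mean(v ** 2))
    if gu <= 0 or gv <= 0:
        raise ValueError("dissimilarity is undefined for a zero-GFP map")
    d = u / gu - v / gv
    return float(np.sqrt(np.mean(d ** 2)))


@dataclass
class DissResult:
    times: np.ndarray
    diss: np.ndarray
    p: np.ndarray
    alpha: float
    n_permutations: int
    seed: int
    significant_runs: list[tuple[float, float]] = field(default_factory=list)

    def runs_overlapping(self, tmin_ms: float, tmax_ms: float) -> list[tuple[float, float]]:
        return [(a, b) for a, b in self.significant_runs
                if b >= tmin_ms and a <= tmax_ms]


def _stack_conditions(evokeds_by_subject: dict, cond_a: str, cond_b: str):
    subjects = sorted(evokeds_by_subject)
    A, B = [], []
    for s in subjects:
        evs = evokeds_by_subject[s]
        if cond_a not in evs or cond_b not in evs:
            raise ValueError(f"subject {s} lacks condition "
                             f"{cond_a if cond_a not in evs else cond_b!r}")
        A.append(_avg_ref(evs[cond_a].data))
        B.append(_avg_ref(evs[cond_b].data))
    times = evokeds_by_subject[subjects[0]][cond_a].times
    return np.stack(A), np.stack(B), times


def _diss_series(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """DISS per time for stacked (..., channels, times) grand means."""
    U = U - U.mean(axis=-2, keepdims=True)
    V = V - V.mean(axis=-2, keepdims=True)
    gu = np.sqrt(np.mean(U ** 2, axis=-2, keepdims=True))
    gv = np.sqrt(np.mean(V ** 2, axis=-2, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        D = U / gu - V / gv
        out = np.sqrt(np.mean(D ** 2, axis=-2))
    return np.nan_to_num(out)


def diss_test(evokeds_by_subject: dict, cond_a: str, cond_b: str,
              window_ms: tuple[float, float] | None = None, n_perm: int = 1000,
              alpha: float = 0.05, seed: int = 0) -> DissResult:
    """Randomization test of topographic difference between two conditions.

    ``evokeds_by_subject`` maps subject -> {condition -> Evoked}.  The null
    distribution is built by randomly swapping, per subject, the two
    condition ERPs (sampled with replacement; the observed labeling is one
    of the 2^N relabelings).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    A, B, times = _stack_conditions(evokeds_by_subject, cond_a, cond_b)
    if window_ms is not None:
        m = (times >= window_ms[0] - 1e-9) & (times <= window_ms[1] + 1e-9)
        A, B, times = A[..., m], B[..., m], times[m]
    n_subj = A.shape[0]
    observed = _diss_series(A.mean(axis=0), B.mean(axis=0))

    rng = np.random.default_rng(seed)
    half_sum = 0.5 * (A + B).mean(axis=0)          # (C, T)
    half_diff = 0.5 * (A - B)                      # (S, C, T)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    # per permutation: grand mean A' = m + mean_s(sign_s * d_s), B' = m - ...
    e = np.einsum("ps,sct->pct", signs, half_diff) / n_subj
    perm_diss = _diss_series(half_sum[None] + e, half_sum[None] - e)  # (P, T)
    p = (1.0 + (perm_diss >= observed[None, :] - 1e-12).sum(axis=0)) / (1.0 + n_perm)

    runs = []
    sig = p < alpha
    start = None
    for i, s in enumerate(sig):
        if s and start is None:
            start = i
        if (not s or i == len(sig) - 1) and start is not None:
            end = i if s else i - 1
            runs.append((float(times[start]), float(times[end])))
            start = None
    return DissResult(times=times, diss=observed, p=p, alpha=alpha,
                      n_permutations=n_perm, seed=seed, significant_runs=runs)


def pointwise_ttests(evokeds_by_subject: dict, cond_a: str, cond_b: str,
                     alpha: float = 0.05,
                     query_window_ms: tuple[float, float] | None = None) -> dict:
    """Paired two-sided t-test per electrode and time point.

    Returns the t and p maps (electrodes x times), the per-time count of
    electrodes with p < alpha, and — if a query window is given — the
    electrode index of maximal |t| inside it.
    """
    A, B, times = _stack_conditions(evokeds_by_subject, cond_a, cond_b)
    if A.shape[0] < 3:
        raise ValueError("need at least 3 subjects for paired t-tests")
    t, p = sps.ttest_rel(A, B, axis=0)
    t, p = np.nan_to_num(t), np.nan_to_num(p, nan=1.0)
    count = (p < alpha).sum(axis=0)
    out = {"times": times, "t": t, "p": p, "count": count, "alpha": alpha}
    if query_window_ms is not None:
        m = (times >= query_window_ms[0] - 1e-9) & (times <= query_window_ms[1] + 1e-9)
        absmax = np.abs(t[:, m]).max(axis=1)
        out["max_t_electrode"] = int(np.argmax(absmax))
    return out
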