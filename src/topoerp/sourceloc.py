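"""Distributed EEG source imaging on a spherical head model.

Forward model: the analytic solution for a current dipole inside three
concentric spherical shells of different conductivity (brain, skull, scalp),
expanded in Legendre polynomials.  For each harmonic degree n the radial
solution in every shell is ``alpha r^n + beta r^-(n+1)``; the coefficients
follow from potential/current continuity at the interfaces and a vanishing
normal current at the scalp, solved as a small linear system per degree.
The series is truncated adaptively at a requested relative tolerance.

Sources live on a regular cubic grid restricted to a spherical shell that
stands in for grey matter.  The inverse is a weighted minimum norm with the
LAURA (local autoregressive average) prior: each solution point is penalized
by its deviation from the inverse-square-distance-weighted average of its
grid neighbors (<= 26-connectivity).  Dipole orientations are free; reported
source amplitude is the Euclidean norm of the 3-D moment estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .montage import ElectrodeMontage
from .containers import Evoked
from .stats import rm_anova_array

__all__ = [
    "HeadModel", "SourceSpace", "LeadField", "SourceEstimate",
    "build_source_grid", "leadfield_3shell", "forward_dipole",
    "laura_operator", "apply_inverse", "nodewise_anova",
]


@dataclass(frozen=True)
class HeadModel:
    """Concentric-shell conductor. Radii outermost-first, scalp radius 1."""

    radii: tuple[float, ...] = (1.0, 0.92, 0.87)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)  # S/m

    @property
    def inner_radius(self) -> float:
        return min(self.radii)


@dataclass
class SourceSpace:
    """Regular cubic grid restricted to a spherical 'grey matter' shell."""

    points: np.ndarray  # (n, 3)
    spacing: float
    shell_inner: float
    shell_outer: float
    neighbors: list[np.ndarray] = field(default_factory=list)  # <=26-connectivity

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class LeadField:
    """Sensor gain for unit dipole moments along x/y/z at every point (uV)."""

    gain: np.ndarray  # (n_sensors, n_points, 3)
    montage: ElectrodeMontage
    source_space: SourceSpace
    model: HeadModel


@dataclass
class SourceEstimate:
    """Nonnegative source amplitude (moment norm) per point per time frame."""

    amplitude: np.ndarray  # (n_points, n_times)
    times: np.ndarray
    source_space: SourceSpace

    def window_mean(self, tmin_ms: float, tmax_ms: float) -> np.ndarray:
        m = (self.times >= tmin_ms - 1e-9) & (self.times <= tmax_ms + 1e-9)
        if not m.any():
            raise ValueError(f"window ({tmin_ms}, {tmax_ms}) ms outside estimate")
        return self.amplitude[:, m].mean(axis=1)


# ---------------------------------------------------------------------------
# source grid
# ---------------------------------------------------------------------------

def build_source_grid(spacing: float, shell_inner: float = 0.70,
                      shell_outer: float = 0.85,
                      model: HeadModel | None = None) -> SourceSpace:
    """Cubic grid intersected with the grey-matter shell, with neighbor lists."""
    model = model or HeadModel()
    if not (0.0 < shell_inner < shell_outer < model.inner_radius):
        raise ValueError("need 0 < shell_inner < shell_outer < inner-skull radius")
    kmax = int(np.ceil(shell_outer / spacing))
    axis = np.arange(-kmax, kmax + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pts = idx * spacing
    r = np.linalg.norm(pts, axis=1)
    keep = (r >= shell_inner) & (r <= shell_outer)
    pts, idx = pts[keep], idx[keep]
    if pts.shape[0] < 50:
        raise ValueError(
            f"spacing {spacing} yields only {pts.shape[0]} solution points (< 50)")
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0]))
    pts, idx = pts[order], idx[order]
    lookup = {tuple(t): i for i, t in enumerate(idx)}
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1) for b in (-1, 0, 1) for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    neighbors = []
    for t in idx:
        nb = [lookup[(t[0] + a, t[1] + b, t[2] + c)]
              for a, b, c in offsets if (t[0] + a, t[1] + b, t[2] + c) in lookup]
        neighbors.append(np.asarray(nb, dtype=int))
    return SourceSpace(points=pts, spacing=spacing, shell_inner=shell_inner,
                       shell_outer=shell_outer, neighbors=neighbors)


# ---------------------------------------------------------------------------
# analytic multi-shell forward model
# ---------------------------------------------------------------------------

def _shell_coefficients(n: int, model: HeadModel) -> float:
    """Scalp-surface radial coefficient per unit source coefficient.

    For harmonic degree n, the potential in shell j is
    ``alpha_j r^n + beta_j r^-(n+1)``; the dipole contributes a known
    ``beta = 1`` term in the innermost shell.  Returns the scalp-surface
    value ``alpha_out + beta_out`` (scalp radius 1).
    """
    radii = sorted(model.radii)          # innermost first
    sig = [s for _, s in sorted(zip(model.radii, model.conductivities))]
    L = len(radii)
    # unknowns: alpha_1, then (alpha_j, beta_j) for j = 2..L
    n_unk = 1 + 2 * (L - 1)
    A = np.zeros((n_unk, n_unk))
    b = np.zeros(n_unk)

    def col_alpha(j):  # j: 0-based shell
        return 0 if j == 0 else 1 + 2 * (j - 1)

    def col_beta(j):
        return 1 + 2 * (j - 1) + 1

    row = 0
    for j in range(L - 1):
        R = radii[j]
        rp, rm = R ** n, R ** -(n + 1)
        drp, drm = n * R ** (n - 1), -(n + 1) * R ** -(n + 2)
        # potential continuity
        A[row, col_alpha(j)] += rp
        if j > 0:
            A[row, col_beta(j)] += rm
        A[row, col_alpha(j + 1)] -= rp
        A[row, col_beta(j + 1)] -= rm
        b[row] = -rm if j == 0 else 0.0  # source beta_1 = 1 moves to RHS
        row += 1
        # normal current continuity
        A[row, col_alpha(j)] += sig[j] * drp
        if j > 0:
            A[row, col_beta(j)] += sig[j] * drm
        A[row, col_alpha(j + 1)] -= sig[j + 1] * drp
        A[row, col_beta(j + 1)] -= sig[j + 1] * drm
        b[row] = -sig[j] * drm if j == 0 else 0.0
        row += 1
    # insulating scalp surface at r = 1
    A[row, col_alpha(L - 1)] = n
    A[row, col_beta(L - 1)] = -(n + 1)
    sol = np.linalg.solve(A, b)
    return float(sol[col_alpha(L - 1)] + sol[col_beta(L - 1)])


def forward_dipole(montage: ElectrodeMontage, locations: np.ndarray,
                   model: HeadModel | None = None, rtol: float = 1e-6,
                   n_max: int = 400, average_reference: bool = True) -> np.ndarray:
    """Scalp gain (n_sensors, n_locations, 3) for unit x/y/z dipole moments.

    The Legendre series is truncated when the running term falls below
    ``rtol`` of the accumulated value; a location too close to the inner
    skull for the series to converge within ``n_max`` terms is an error.
    """
    model = model or HeadModel()
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    b = np.linalg.norm(locs, axis=1)
    inner = model.inner_radius
    bad = np.where(b >= inner)[0]
    if len(bad):
        raise ValueError(
            f"dipole location(s) {bad.tolist()} at radius "
            f"{b[bad].round(4).tolist()} not strictly inside the inner shell "
            f"(radius {inner})")
    sens = montage.positions  # (S, 3), unit norm
    sigma_in = [s for _, s in sorted(zip(model.radii, model.conductivities))][0]
    n_s, n_p = sens.shape[0], locs.shape[0]

    e_hat = np.where(b[:, None] > 1e-12, locs / np.maximum(b, 1e-12)[:, None],
                     np.array([0.0, 0.0, 1.0]))
    c = sens @ e_hat.T                                # (S, P) cos(gamma)
    tang = sens[:, None, :] - c[:, :, None] * e_hat[None, :, :]  # (S, P, 3)

    K1 = np.zeros((n_s, n_p))
    K2 = np.zeros((n_s, n_p))
    P_nm1 = np.ones_like(c)      # P_0
    P_n = c.copy()               # P_1
    dP_n = np.ones_like(c)       # P_1'
    dP_nm1 = np.zeros_like(c)    # P_0'
    b_pow = np.ones(n_p)         # b^(n-1)
    peak = np.zeros(n_p)
    converged = np.zeros(n_p, dtype=bool)
    for n in range(1, n_max + 1):
        c_n = _shell_coefficients(n, model)
        t1 = c_n * b_pow * n      # multiplies P_n
        t2 = c_n * b_pow          # multiplies P_n'
        K1 += t1[None, :] * P_n
        K2 += t2[None, :] * dP_n
        term = np.maximum(np.abs(t1) * np.abs(P_n).max(axis=0),
                          np.abs(t2) * np.abs(dP_n).max(axis=0))
        peak = np.maximum(peak, term)
        converged |= term <= rtol * np.maximum(peak, 1e-300)
        if converged.all() and n > 2:
            break
        # three-term recurrences: (n+1) P_{n+1} = (2n+1) c P_n - n P_{n-1};
        # P'_{n+1} = P'_{n-1} + (2n+1) P_n
        P_np1 = ((2 * n + 1) * c * P_n - n * P_nm1) / (n + 1)
        dP_np1 = dP_nm1 + (2 * n + 1) * P_n
        P_nm1, P_n = P_n, P_np1
        dP_nm1, dP_n = dP_n, dP_np1
        b_pow = b_pow * b
    else:
        worst = int(np.argmin(converged))
        raise ValueError(
            f"Legendre series did not converge for point {worst} at radius "
            f"{b[worst]:.4f}; move it away from the inner shell")

    scale = 1.0 / (4.0 * np.pi * sigma_in)
    gain = scale * (K1[:, :, None] * e_hat[None, :, :] + K2[:, :, None] * tang)
    if average_reference:
        gain -= gain.mean(axis=0, keepdims=True)
    return gain


def leadfield_3shell(montage: ElectrodeMontage, source_space: SourceSpace,
                     radii: tuple[float, ...] = (1.0, 0.92, 0.87),
                     conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33),
                     rtol: float = 1e-6) -> LeadField:
    """Analytic 3-shell lead field on the source grid, average-referenced."""
    model = HeadModel(radii=tuple(radii), conductivities=tuple(conductivities))
    gain = forward_dipole(montage, source_space.points, model=model, rtol=rtol)
    if not np.all(np.isfinite(gain)):
        raise ValueError("non-finite lead field")
    return LeadField(gain=gain, montage=montage, source_space=source_space,
                     model=model)


# ---------------------------------------------------------------------------
# LAURA inverse
# ---------------------------------------------------------------------------

@dataclass
class InverseOperator:
    kernel: np.ndarray  # (n_points * 3, n_sensors)
    lam: float
    source_space: SourceSpace
    montage: ElectrodeMontage


def _laura_metric(source_space: SourceSpace, ridge: float = 1e-3) -> np.ndarray:
    """B^T B + ridge*I with B = I - W, W the inverse-square-distance
    row-normalized neighbor average (the local autoregressive prior)."""
    n = source_space.n_points
    pts = source_space.points
    W = np.zeros((n, n))
    for i, nb in enumerate(source_space.neighbors):
        if len(nb) == 0:
            continue
        d = np.linalg.norm(pts[nb] - pts[i], axis=1)
        w = 1.0 / d ** 2
        W[i, nb] = w / w.sum()
    B = np.eye(n) - W
    M = B.T @ B
    M.flat[:: n + 1] += ridge
    return M


def laura_operator(leadfield: LeadField, lam: float | None = None,
                   snr_power: float = 3.0, ridge: float = 1e-3) -> InverseOperator:
    """Weighted-minimum-norm inverse with the LAURA source prior.

    ``j = M^-1 G^T (G M^-1 G^T + lam I)^-1 x`` with M the (per-orientation)
    LAURA metric.  When ``lam`` is not given it is set from a fixed power
    signal-to-noise ratio: ``lam = tr(G M^-1 G^T) / (n_sensors * snr_power)``.
    """
    G = leadfield.gain  # (S, P, 3)
    n_s, n_p, _ = G.shape
    M = _laura_metric(leadfield.source_space, ridge=ridge)
    Gm = G.reshape(n_s, n_p * 3)
    # solve M X_o = G_o^T per orientation (M acts identically on orientations)
    X = np.empty((n_p, 3, n_s))
    for o in range(3):
        X[:, o, :] = np.linalg.solve(M, G[:, :, o].T)
    Minv_Gt = X.reshape(n_p * 3, n_s)
    K = Gm @ Minv_Gt  # (S, S), symmetric PSD
    if lam is None:
        lam = float(np.trace(K)) / (n_s * snr_power)
    A = K + lam * np.eye(n_s)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e13:
        raise np.linalg.LinAlgError(
            f"inverse system is near-singular (cond={cond:.2e}); "
            "increase lam or the LAURA ridge")
    kernel = Minv_Gt @ np.linalg.inv(A)
    return InverseOperator(kernel=kernel, lam=lam,
                           source_space=leadfield.source_space,
                           montage=leadfield.montage)


def apply_inverse(evoked: Evoked, operator: InverseOperator,
                  window_ms: tuple[float, float] | None = (41.0, 80.0)) -> SourceEstimate:
    """Estimate per-point moment norms over time (optionally cropped)."""
    n_s = operator.kernel.shape[1]
    if evoked.data.shape[0] != n_s:
        raise ValueError(
            f"evoked has {evoked.data.shape[0]} channels but the operator "
            f"expects {n_s}")
    ev = evoked if window_ms is None else evoked.crop(*window_ms)
    data = ev.data - ev.data.mean(axis=0, keepdims=True)  # average reference
    J = operator.kernel @ data  # (P*3, T)
    n_p = operator.source_space.n_points
    amp = np.linalg.norm(J.reshape(n_p, 3, -1), axis=1)
    return SourceEstimate(amplitude=amp, times=ev.times,
                          source_space=operator.source_space)


# ---------------------------------------------------------------------------
# node-wise ANOVA with cluster extent / duration criteria
# ---------------------------------------------------------------------------

def _clusters(node_set: np.ndarray, source_space: SourceSpace) -> list[np.ndarray]:
    """Connected components (26-connectivity) of a boolean node set."""
    nodes = np.where(node_set)[0]
    if len(nodes) == 0:
        return []
    pos = {n: i for i, n in enumerate(nodes)}
    rows, cols = [], []
    for n in nodes:
        for m in source_space.neighbors[n]:
            if m in pos:
                rows.append(pos[n])
                cols.append(pos[m])
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(len(nodes),) * 2)
    n_comp, lab = connected_components(adj, directed=False)
    return [nodes[lab == k] for k in range(n_comp)]


def nodewise_anova(amplitudes: dict, source_space: SourceSpace,
                   factors: list[str] | None = None, effect: str | None = None,
                   alpha: float = 0.05, min_cluster: int = 32,
                   min_duration_ms: float = 8.0, mode: str = "window_mean",
                   times: np.ndarray | None = None,
                   reference_n_points: int = 3005) -> dict:
    """Per-solution-point repeated-measures ANOVA with a cluster criterion.

    ``amplitudes``: ``{subject: {condition: array}}`` where each array is
    ``(n_points,)`` (mode ``window_mean``) or ``(n_points, n_times)`` (mode
    ``per_frame``).  Condition labels of the form ``"a/b"`` are split into
    two crossed factors.  A node is significant when the tested effect's
    uncorrected p falls below ``alpha`` (in ``per_frame`` mode: sustained for
    at least ``min_duration_ms``); significant nodes are grouped by grid
    26-connectivity and clusters smaller than the extent threshold -- 32
    points scaled by ``n_points / reference_n_points`` -- are discarded.
    """
    subjects = sorted(amplitudes)
    conds = sorted(set().union(*(amplitudes[s] for s in subjects)))
    for s in subjects:
        missing = set(conds) - set(amplitudes[s])
        if missing:
            raise ValueError(f"subject {s} missing condition(s) {sorted(missing)}")
    if "/" in conds[0]:
        f1 = sorted({c.split("/")[0] for c in conds})
        f2 = sorted({c.split("/")[1] for c in conds})
        factors = factors or ["gaze", "freq"]
        effect = effect or ":".join(factors)
        cond_grid = [[f"{a}/{b}" for b in f2] for a in f1]
        shape = (len(f1), len(f2))
    else:
        factors = factors or ["condition"]
        effect = effect or factors[0]
        cond_grid = [conds]
        shape = (len(conds),)

    first = np.asarray(amplitudes[subjects[0]][conds[0]])
    per_frame = mode == "per_frame"
    if per_frame and first.ndim != 2:
        raise ValueError("per_frame mode needs (n_points, n_times) amplitudes")
    n_pts = first.shape[0]
    n_t = first.shape[1] if per_frame else 1
    if per_frame:
        if times is None or len(times) != n_t:
            raise ValueError("per_frame mode requires a matching times axis")
        dt = float(np.mean(np.diff(times))) if n_t > 1 else np.inf
        min_frames = max(1, int(np.ceil(min_duration_ms / dt)))
    # assemble (subjects, *factor levels, points, times)
    flat_conds = [c for row in cond_grid for c in row]
    Y = np.stack([
        np.stack([np.asarray(amplitudes[s][c], dtype=float).reshape(n_pts, n_t)
                  for c in flat_conds])
        for s in subjects
    ])  # (S, C, P, T)
    Y = Y.reshape(len(subjects), *shape, n_pts, n_t)

    extent_thr = max(1, int(round(min_cluster * n_pts / reference_n_points)))
    warning = None
    if extent_thr > n_pts:
        warning = "extent threshold exceeds the grid size; no cluster can survive"

    p_map = np.ones((n_pts, n_t))
    F_map = np.zeros((n_pts, n_t))
    for pi in range(n_pts):
        for ti in range(n_t):
            res = rm_anova_array(Y[..., pi, ti], factors)[effect]
            p_map[pi, ti] = res["p"]
            F_map[pi, ti] = res["F"]
    sig = p_map < alpha
    if per_frame:
        # sustained significance: a run of >= min_frames consecutive frames
        node_sig = np.zeros(n_pts, dtype=bool)
        for pi in range(n_pts):
            run = 0
            for ti in range(n_t):
                run = run + 1 if sig[pi, ti] else 0
                if run >= min_frames:
                    node_sig[pi] = True
                    break
    else:
        node_sig = sig[:, 0]

    clusters = []
    for nodes in _clusters(node_sig, source_space):
        if len(nodes) < extent_thr:
            continue
        centroid = source_space.points[nodes].mean(axis=0)
        # post-hoc paired contrasts on cluster-mean amplitude
        cluster_amp = {
            s: {c: float(np.asarray(amplitudes[s][c]).reshape(n_pts, n_t)[nodes].mean())
                for c in flat_conds}
            for s in subjects
        }
        clusters.append({
            "nodes": nodes, "size": int(len(nodes)),
            "centroid": centroid, "peak_F": float(F_map[nodes].max()),
            "mean_amplitude": {c: float(np.mean([cluster_amp[s][c] for s in subjects]))
                               for c in flat_conds},
        })
    return {
        "clusters": clusters, "p": p_map.squeeze(), "F": F_map.squeeze(),
        "effect": effect, "alpha": alpha, "extent_threshold": extent_thr,
        "mode": mode, "warning": warning,
    }
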