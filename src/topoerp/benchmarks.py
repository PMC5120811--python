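"""Property-based validation scenarios with recoverable ground truth.

Each function simulates a study-like condition, runs the corresponding
pipeline stage, and returns the measured quantity (plus the problem size).
They power both the validation test suite and ``scripts/acceptance.py``.

Scale notes: scenarios run at desk scale — 32-64 sensor caps (128 where the
sensor density itself matters, as in dipole localization), ~350-point source
grids, and 6-12 subjects — chosen so the full battery completes in minutes
on one CPU while every planted effect remains recoverable.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats as sps

from . import microstates as ms
from . import preprocess as pp
from . import sourceloc as sl
from . import synth, topostats
from .containers import Evoked, GroundTruth, Segment
from .montage import ElectrodeMontage, make_montage
from .preprocess import average_epochs
from .stats import rm_anova_array

__all__ = [
    "diss_identity", "tanova_null_calibration", "microstate_recovery",
    "taahc_vs_bruteforce", "backfit_recovery", "leadfield_homogeneous_check",
    "laura_localization", "cluster_statistics", "rm_anova_oracle_check",
    "preprocessing_fidelity",
]


def _noise_gfp_per_unit_sd(montage: ElectrodeMontage) -> float:
    """Analytic GFP of unit-sd spatially correlated noise after average
    reference: sqrt((tr C - 1'C1/n)/n)."""
    C = np.exp(-montage.chord_distances() / synth.NOISE_RANGE)
    n = montage.n_channels
    ones = np.ones(n)
    return float(np.sqrt((np.trace(C) - ones @ C @ ones / n) / n))


# ---------------------------------------------------------------------------
# dissimilarity identity
# ---------------------------------------------------------------------------

def diss_identity(seed: int = 0, n_pairs: int = 1000, n_ch: int = 32) -> dict:
    """Max |DISS - sqrt(2(1-r))| over random average-referenced map pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        u = rng.standard_normal(n_ch)
        v = rng.standard_normal(n_ch)
        u -= u.mean()
        v -= v.mean()
        r = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
        worst = max(worst, abs(topostats.dissimilarity(u, v)
                               - np.sqrt(2.0 * (1.0 - r))))
    return {"max_abs_deviation": worst, "n": n_pairs}


# ---------------------------------------------------------------------------
# TANOVA null calibration
# ---------------------------------------------------------------------------

def tanova_null_calibration(seed: int = 0, n_datasets: int = 200,
                            n_subjects: int = 6, n_electrodes: int = 32,
                            n_epochs: int = 8, n_perm: int = 500,
                            alpha: float = 0.05) -> dict:
    """Pointwise rejection rate of the dissimilarity randomization test on
    exchangeable-condition data, with the exact central binomial interval
    for the nominal level at dataset granularity (the independent unit:
    time points within a dataset share the permutation draws).
    """
    montage = make_montage(n_electrodes, 0)
    tpls = synth.random_templates(montage, 2, seed=seed + 1)
    segs = [Segment(20.0, 100.0, 0, 3.0), Segment(100.0, 180.0, 1, 3.0)]
    truth = GroundTruth(templates=tpls,
                        segments={"direct/BB": segs, "averted/BB": segs},
                        noise_sd=10.0, seed=seed)
    rej = tot = 0
    for d in range(n_datasets):
        recs = synth.simulate_null_dataset(montage, n_subjects, n_epochs,
                                           truth, seed=seed + 10_000 + d,
                                           srate=256.0, epoch_ms=(0.0, 185.0))
        evokeds = {r.subject: average_epochs(r, crop_ms=(0.0, 185.0))
                   for r in recs}
        res = topostats.diss_test(evokeds, "direct/BB", "averted/BB",
                                  n_perm=n_perm, alpha=alpha,
                                  seed=seed + 50_000 + d)
        rej += int((res.p < alpha).sum())
        tot += len(res.p)
    lo = float(sps.binom.ppf(0.025, n_datasets, alpha)) / n_datasets
    hi = float(sps.binom.ppf(0.975, n_datasets, alpha)) / n_datasets
    return {"rejection_rate": rej / tot, "ci_low": lo, "ci_high": hi,
            "n": n_datasets, "n_tests": tot}


# ---------------------------------------------------------------------------
# microstate template recovery + KL model-order selection
# ---------------------------------------------------------------------------

def _five_map_truth(montage, seed):
    tpls = synth.random_templates(montage, 5, seed=seed)
    segs = [Segment(k * 70.0, (k + 1) * 70.0, k, 5.0) for k in range(5)]
    return GroundTruth(templates=tpls, segments={"c": segs},
                       noise_sd=0.0, seed=seed)


def microstate_recovery(seed: int = 0, n_seeds: int = 50, snr: float = 5.0,
                        n_electrodes: int = 32) -> dict:
    """Noise-free recovery of 5 planted maps at q=5, and the fraction of
    noisy grand means (GFP-peak SNR = ``snr``) where the KL criterion
    selects q=5 over the range 2..10."""
    montage = make_montage(n_electrodes, 0)
    truth = _five_map_truth(montage, seed + 1)
    dt = 1000.0 / 256.0
    times = np.arange(0.0, 350.0 + dt / 2, dt)
    sig = truth.condition_signal("c", times)
    ev = Evoked("g", "c", sig, 256.0, times, 1)
    cl = ms.taahc_segment([ev], range(2, 11))
    C = np.abs(cl[5].templates @ np.stack(truth.templates).T)
    min_corr = float(C.max(axis=0).min())

    noise_sd = 5.0 / (snr * _noise_gfp_per_unit_sd(montage))
    L = synth.noise_cholesky(montage)
    correct = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 100 + s)
        noisy = sig + noise_sd * (L @ rng.standard_normal(sig.shape))
        cln = ms.taahc_segment([Evoked("g", "c", noisy, 256.0, times, 1)],
                               range(2, 11))
        q, _ = ms.kl_select(cln, n_electrodes)
        correct += q == 5
    return {"min_abs_template_corr": min_corr,
            "kl_correct_fraction": correct / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# T-AAHC vs exhaustive-partition optimum
# ---------------------------------------------------------------------------

def _exhaustive_best_gev(U: np.ndarray, q: int) -> float:
    """Best GEV over all partitions of the frames into exactly q clusters,
    with the same template rule the clustering uses (reference bound)."""
    V, gfp = ms._normalize_frames(U - U.mean(axis=1, keepdims=True))
    n = U.shape[0]
    best = -1.0
    codes = np.zeros(n, dtype=int)

    def rec(i, maxc):
        if i == n:
            if maxc + 1 == q:
                yield codes.copy()
            return
        for c in range(min(maxc + 1, q - 1) + 1):
            codes[i] = c
            yield from rec(i + 1, max(maxc, c))

    for labels in rec(1, 0):
        T = np.stack([ms._template_of(V[labels == k]) for k in range(q)])
        best = max(best, ms.gev_of_labeling(V, gfp, labels, T)[1])
    return best


def taahc_vs_bruteforce(seed: int = 0, n_toys: int = 50) -> dict:
    """Mean (and minimum) ratio of T-AAHC's GEV to the exhaustive optimum
    on random template-plus-noise toys of <= 8 frames."""
    rng = np.random.default_rng(seed)
    achieved, optimal = [], []
    for _ in range(n_toys):
        n_frames = int(rng.integers(6, 9))
        q = int(rng.integers(2, 4))
        n_ch = 10
        T = rng.standard_normal((q, n_ch))
        T -= T.mean(axis=1, keepdims=True)
        T /= np.linalg.norm(T, axis=1, keepdims=True)
        labels = rng.integers(0, q, size=n_frames)
        amps = rng.uniform(1.0, 2.0, size=n_frames)
        U = amps[:, None] * T[labels] + 0.2 * rng.standard_normal((n_frames, n_ch))
        times = np.arange(n_frames) * 1000.0 / 256.0
        ev = Evoked("g", "c", U.T, 256.0, times, 1)
        cl = ms.taahc_segment([ev], [q])[q]
        achieved.append(cl.gev_total)
        optimal.append(_exhaustive_best_gev(U, q))
    ratios = np.array(achieved) / np.array(optimal)
    return {"mean_ratio": float(ratios.mean()), "min_ratio": float(ratios.min()),
            "n": n_toys}


# ---------------------------------------------------------------------------
# back-fitting recovery and MAP x CONDITION interaction power
# ---------------------------------------------------------------------------

def backfit_recovery(seed: int = 0, n_seeds: int = 25, n_subjects: int = 12,
                     snr: float = 5.0, n_electrodes: int = 32,
                     n_epochs: int = 20) -> dict:
    """Condition A expresses map 1 and condition B map 2 in 41-80 ms; count
    the fraction of simulations reproducing the group GEV pattern and
    detecting the MAP x CONDITION interaction at alpha = .05."""
    from .stats import rm_anova

    montage = make_montage(n_electrodes, 0)
    tpls = synth.random_templates(montage, 4, seed=seed + 2)
    late = [Segment(100.0, 170.0, 2, 5.0), Segment(170.0, 260.0, 3, 5.0)]
    peak = 4.0
    # per-epoch noise sd giving an evoked-level GFP SNR of `snr`
    noise_sd = peak * np.sqrt(n_epochs) / (snr * _noise_gfp_per_unit_sd(montage))
    truth = GroundTruth(
        templates=tpls,
        segments={"direct/BB": [Segment(41.0, 80.0, 0, peak)] + late,
                  "averted/BB": [Segment(41.0, 80.0, 1, peak)] + late},
        noise_sd=noise_sd, seed=seed)
    pattern = detected = 0
    for s in range(n_seeds):
        recs, _ = synth.simulate_dataset(
            montage, design=("direct/BB", "averted/BB"),
            n_subjects=n_subjects, n_epochs_per_cond=n_epochs, truth=truth,
            seed=seed + 3000 + s, srate=256.0, epoch_ms=(-50.0, 300.0))
        evokeds = {r.subject: average_epochs(r, crop_ms=(-50.0, 300.0))
                   for r in recs}
        fit = ms.backfit(evokeds, np.stack(tpls[:2]), (41.0, 80.0))
        tab = ms.gev_anova_table(fit)
        g = tab.groupby(["map", "gaze"], observed=True)["gev"].mean()
        pattern += int(g[0, "direct"] > g[0, "averted"]
                       and g[1, "averted"] > g[1, "direct"])
        res = rm_anova(tab.rename(columns={"gaze": "cond"}), "gev",
                       ["map", "cond"])
        detected += int(res.reported("map:cond")["p_reported"] < 0.05)
    return {"pattern_fraction": pattern / n_seeds,
            "interaction_detection_rate": detected / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# 3-shell lead field vs homogeneous closed form
# ---------------------------------------------------------------------------

def _closed_form_homogeneous(sens, loc, q, sigma):
    b = np.linalg.norm(loc)
    e = loc / b
    c = sens @ e
    f = b
    D = np.sqrt(1.0 - 2.0 * f * c + f * f)
    g = 1.0 / D
    A = 2.0 * (c - f) * g ** 3 + (g - 1.0) / f
    B = 2.0 * g ** 3 + (1.0 + D) / (D * (1.0 - f * c + D))
    tang = sens - c[:, None] * e[None, :]
    return ((q @ e) * A + tang @ q * B) / (4.0 * np.pi * sigma)


def leadfield_homogeneous_check(seed: int = 0, n_cases: int = 100) -> dict:
    """Relative error of the equal-conductivity 3-shell series against the
    closed-form single-sphere potential, over random dipole/sensor draws."""
    rng = np.random.default_rng(seed)
    model = sl.HeadModel(conductivities=(0.33, 0.33, 0.33))
    worst = 0.0
    for _ in range(n_cases):
        mont = make_montage(int(rng.integers(32, 128)), 0)
        loc = rng.standard_normal(3)
        loc = loc / np.linalg.norm(loc) * rng.uniform(0.1, 0.8)
        q = rng.standard_normal(3)
        gain = sl.forward_dipole(mont, loc[None], model=model,
                                 average_reference=False)
        v = gain[:, 0, :] @ q
        ref = _closed_form_homogeneous(mont.positions, loc, q, 0.33)
        worst = max(worst, float(np.abs(v - ref).max() / np.abs(ref).max()))
    return {"max_rel_error": worst, "n": n_cases}


# ---------------------------------------------------------------------------
# LAURA single-dipole localization
# ---------------------------------------------------------------------------

def laura_localization(seed: int = 0, n_dipoles: int = 50,
                       spacing: float = 0.155) -> dict:
    """Noise-free single-dipole data on a ~350-point grid, 128-channel cap,
    lambda -> 0: fraction of superficial dipoles whose LAURA amplitude peak
    lies within 2 grid spacings of the truth."""
    grid = sl.build_source_grid(spacing)
    lf = sl.leadfield_3shell(make_montage(128, 0), grid)
    op = sl.laura_operator(lf, snr_power=1e6)
    rng = np.random.default_rng(seed)
    r = np.linalg.norm(grid.points, axis=1)
    superficial = np.where(r >= 0.78)[0]
    hits = 0
    for i in rng.choice(superficial, n_dipoles, replace=False):
        ori = rng.standard_normal(3)
        ori /= np.linalg.norm(ori)
        x = lf.gain[:, i, :] @ ori
        amp = np.linalg.norm((op.kernel @ x[:, None]).reshape(grid.n_points, 3),
                             axis=1)
        d = np.linalg.norm(grid.points[int(np.argmax(amp))] - grid.points[i])
        hits += int(d <= 2 * spacing + 1e-9)
    return {"hit_rate": hits / n_dipoles, "n_points": grid.n_points,
            "n": n_dipoles}


# ---------------------------------------------------------------------------
# node-wise cluster statistics: planted recovery and null specificity
# ---------------------------------------------------------------------------

def _simulate_source_amplitudes(lf, op, patch, effect, seed, n_subjects=8,
                                bg_sd=0.6, sensor_sd=0.1):
    """Per-subject, per-condition source amplitudes in the early window:
    condition-specific background dipole mixtures (trial-average residue)
    plus a patch source whose strength carries the planted interaction."""
    grid = op.source_space
    rng = np.random.default_rng(seed)
    dt = 1000.0 / 256.0
    times = np.arange(41.0, 80.0 + dt / 2, dt)
    n_t = len(times)
    amps = {}
    est_times = None
    pgain_ref = lf.gain[:, patch, :].mean(axis=1)
    for s in range(n_subjects):
        amps_s = {}
        patch_ori = rng.standard_normal(3)
        patch_ori /= np.linalg.norm(patch_ori)
        for g in ("direct", "averted"):
            for f in ("BB", "HSF", "LSF"):
                a = 1.0 + (effect if (g == "direct" and f == "BB") else 0.0)
                nbg = 8
                bg_idx = rng.choice(grid.n_points, nbg, replace=False)
                bg_ori = rng.standard_normal((nbg, 3))
                bg_ori /= np.linalg.norm(bg_ori, axis=1, keepdims=True)
                bg_course = rng.standard_normal((nbg, n_t)) * bg_sd
                x = np.einsum("ck,kt->ct",
                              np.einsum("cko,ko->ck", lf.gain[:, bg_idx, :],
                                        bg_ori), bg_course)
                x = x + np.outer(pgain_ref @ patch_ori,
                                 a * np.sin(np.linspace(0.0, np.pi, n_t)))
                x += sensor_sd * rng.standard_normal(x.shape)
                ev = Evoked(f"S{s}", f"{g}/{f}", x, 256.0, times, 1)
                est = sl.apply_inverse(ev, op, (41.0, 80.0))
                est_times = est.times
                amps_s[f"{g}/{f}"] = est.amplitude
        amps[f"S{s}"] = amps_s
    return amps, est_times


def cluster_statistics(seed: int = 0, n_null: int = 10, effect: float = 1.2,
                       spacing: float = 0.155, n_sensors: int = 64) -> dict:
    """Planted GAZE x FREQ interaction at a superficial patch: centroid
    error of the surviving cluster (in grid spacings), and the fraction of
    null simulations with no surviving cluster.  Uses the sustained-
    significance mode (p < .05 for >= 8 ms, scaled 32/3005 extent)."""
    grid = sl.build_source_grid(spacing)
    lf = sl.leadfield_3shell(make_montage(n_sensors, 0), grid)
    op = sl.laura_operator(lf)
    r = np.linalg.norm(grid.points, axis=1)
    rng = np.random.default_rng(seed)
    center = int(rng.choice(np.where(r >= 0.80)[0]))
    patch = np.where(np.linalg.norm(grid.points - grid.points[center], axis=1)
                     <= 1.6 * spacing)[0]

    amps, times = _simulate_source_amplitudes(lf, op, patch, effect,
                                              seed + 100)
    res = sl.nodewise_anova(amps, grid, mode="per_frame", times=times)
    if res["clusters"]:
        best = max(res["clusters"], key=lambda c: c["size"])
        err = float(np.linalg.norm(best["centroid"]
                                   - grid.points[patch].mean(axis=0)) / spacing)
        recovered = err <= 3.0
    else:
        err, recovered = np.inf, False

    clean = 0
    for s in range(n_null):
        amps_n, times_n = _simulate_source_amplitudes(lf, op, patch, 0.0,
                                                      seed + 200 + s)
        res_n = sl.nodewise_anova(amps_n, grid, mode="per_frame", times=times_n)
        clean += int(len(res_n["clusters"]) == 0)
    return {"recovered": bool(recovered), "centroid_err_spacings": err,
            "null_clean_fraction": clean / n_null, "n": n_null,
            "extent_threshold": res["extent_threshold"]}


# ---------------------------------------------------------------------------
# repeated-measures ANOVA vs textbook sums of squares
# ---------------------------------------------------------------------------

def _textbook_two_way(Y):
    n, a, b = Y.shape
    gm = Y.mean()
    mA, mB, mS = Y.mean(axis=(0, 2)), Y.mean(axis=(0, 1)), Y.mean(axis=(1, 2))
    mAB, mAS, mBS = Y.mean(axis=0), Y.mean(axis=2), Y.mean(axis=1)
    ss = {
        "A": n * b * np.sum((mA - gm) ** 2),
        "B": n * a * np.sum((mB - gm) ** 2),
        "AB": n * np.sum((mAB - mA[:, None] - mB[None, :] + gm) ** 2),
        "AS": b * np.sum((mAS - mS[:, None] - mA[None, :] + gm) ** 2),
        "BS": a * np.sum((mBS - mS[:, None] - mB[None, :] + gm) ** 2),
        "ABS": np.sum((Y - mAB[None] - mAS[:, :, None] - mBS[:, None, :]
                       + mA[None, :, None] + mB[None, None, :]
                       + mS[:, None, None] - gm) ** 2),
    }
    out = {}
    for eff, err, d1, d2 in (("A", "AS", a - 1, (n - 1) * (a - 1)),
                             ("B", "BS", b - 1, (n - 1) * (b - 1)),
                             ("AB", "ABS", (a - 1) * (b - 1),
                              (n - 1) * (a - 1) * (b - 1))):
        out[eff] = (ss[eff] / d1) / (ss[err] / d2)
    return out


def _box_epsilon(Y2):
    S = np.cov(Y2, rowvar=False, ddof=1)
    k = S.shape[0]
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    lam = np.linalg.eigvalsh(Sc)
    return float(lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum()))


def rm_anova_oracle_check(seed: int = 0) -> dict:
    """Max |F - F_textbook| over exhaustive small two-way designs, plus the
    max |epsilon - Box epsilon| on one-factor tables."""
    rng = np.random.default_rng(seed)
    worst_f = 0.0
    n_cases = 0
    for n, a, b in itertools.product((3, 4), (2, 3), (2, 3)):
        Y = rng.standard_normal((n, a, b))
        effects = rm_anova_array(Y, ["A", "B"])
        ref = _textbook_two_way(Y)
        for eff, key in (("A", "A"), ("B", "B"), ("A:B", "AB")):
            worst_f = max(worst_f, abs(effects[eff]["F"] - ref[key]))
            n_cases += 1
    worst_eps = 0.0
    for k in (3, 4, 5):
        Y2 = rng.standard_normal((8, k)) * rng.uniform(0.3, 2.0, size=k)
        eff = rm_anova_array(Y2, ["A"])["A"]
        worst_eps = max(worst_eps, abs(eff["epsilon"] - _box_epsilon(Y2)))
        n_cases += 1
    return {"max_abs_f_diff": worst_f, "max_abs_epsilon_diff": worst_eps,
            "n": n_cases}


# ---------------------------------------------------------------------------
# preprocessing chain fidelity + exact outlier rejection
# ---------------------------------------------------------------------------

def preprocessing_fidelity(seed: int = 0, n_electrodes: int = 32) -> dict:
    """Noise-free full-chain error against a band-limited biphasic truth
    (away from epoch edges), and whether threshold rejection removes exactly
    the injected outlier epochs."""
    montage = make_montage(n_electrodes, 0)
    t = synth.random_templates(montage, 1, seed=seed + 3)[0]
    segs = [Segment(35.0, 190.0, 0, 2.0), Segment(190.0, 345.0, 1, 2.0)]
    truth = GroundTruth(templates=[t, -t],
                        segments={"direct/BB": segs, "averted/BB": segs},
                        noise_sd=0.0, seed=seed)
    recs, _ = synth.simulate_dataset(montage, design=("direct/BB", "averted/BB"),
                                     n_subjects=1, n_epochs_per_cond=2,
                                     truth=truth, seed=seed, srate=1024.0,
                                     rotation_deg=0.0, gain_sigma=0.0)
    evs, _ = pp.preprocess_recording(recs[0], montage)
    ev = evs["direct/BB"]
    gt = truth.condition_signal("direct/BB", ev.times)
    gt -= gt.mean(axis=0)
    interior = (ev.times >= -80.0) & (ev.times <= 330.0)
    max_err = float(np.abs(ev.data - gt)[:, interior].max())

    noisy = GroundTruth(templates=[t, -t], segments=truth.segments,
                        noise_sd=5.0, seed=seed)
    recs2, _ = synth.simulate_dataset(montage, design=("direct/BB", "averted/BB"),
                                      n_subjects=1, n_epochs_per_cond=10,
                                      truth=noisy, seed=seed + 1, srate=1024.0)
    dirty = synth.inject_artifacts(recs2[0], montage, spike_rate=0.25,
                                   outlier_amplitude=100.0, seed=seed + 2)
    _, report = pp.preprocess_recording(dirty, montage)
    exact = sorted(report.rejected_epochs) == sorted(dirty.info["spike_epochs"])
    return {"max_abs_error_uv": max_err, "rejection_exact": bool(exact),
            "n_injected": len(dirty.info["spike_epochs"]),
            "n": recs[0].n_epochs}
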