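"""Repeated-measures statistics for fully within-subject designs.

Implements the balanced within-subject ANOVA decomposition (all main effects
and interactions, each tested against its own effect-by-subject error term),
Mauchly's sphericity test and the Greenhouse-Geisser epsilon per effect,
Bonferroni / Wilcoxon post-hoc contrasts with paired Cohen's d, and the
reaction-time summarization rules (bound filtering, per-cell medians of
correct trials, log transform).

The ANOVA is computed from sums of squares via inclusion-exclusion over
marginal means, which is exact for balanced complete designs (the only kind
this package produces).  Sphericity quantities are computed from the
covariance of orthonormal-contrast scores:

    eps_GG = tr(S)^2 / (p * tr(S^2)),   W = det(S) / (tr(S)/p)^p

with S the (p x p) covariance of the per-subject contrast scores and p the
effect's degrees of freedom.  Following the source study's rule, the
Greenhouse-Geisser correction is applied only when Mauchly's test rejects
sphericity at .05 (configurable).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "rm_anova", "posthoc", "summarize_rt"]


# ---------------------------------------------------------------------------
# core array-level ANOVA (also used by sourceloc's node-wise tests)
# ---------------------------------------------------------------------------

def _margin_mean(Y: np.ndarray, keep: tuple[int, ...]) -> np.ndarray:
    """Mean over all axes not in ``keep``, keeping dims for broadcasting."""
    axes = tuple(a for a in range(Y.ndim) if a not in keep)
    return Y.mean(axis=axes, keepdims=True)


def rm_anova_array(Y: np.ndarray, factor_names: list[str]) -> dict[str, dict]:
    """Within-subject ANOVA on ``Y`` of shape (subjects, l1, ..., lk).

    Returns a dict keyed by effect name (e.g. ``"gaze"``, ``"gaze:freq"``)
    with F, df, p, sums of squares, partial eta squared, Mauchly's W/p and
    the GG epsilon (and GG-corrected p) where the effect has > 1 df.
    """
    Y = np.asarray(Y, dtype=float)
    n_subj = Y.shape[0]
    if n_subj < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    k = Y.ndim - 1
    if k != len(factor_names):
        raise ValueError("factor_names must match the trailing dims of Y")
    levels = Y.shape[1:]
    total_cells = int(np.prod(levels))

    # inclusion-exclusion effect estimates per subset of {subject, factors}
    def effect(term: tuple[int, ...]) -> np.ndarray:
        e = np.zeros_like(Y)
        for r in range(len(term) + 1):
            for sub in itertools.combinations(term, r):
                e += (-1) ** (len(term) - r) * _margin_mean(Y, sub)
        return e

    # SS below the square of float rounding noise on this data's scale are
    # genuine zeros (constant dv), not effects
    ss_floor = 1e-24 * (float(np.abs(Y).max()) ** 2 + 1.0) * Y.size

    def ss_df(term: tuple[int, ...]) -> tuple[float, int]:
        e = effect(term)
        # e is constant over the collapsed axes, so the full-grid sum of
        # squares equals the sum over the whole array
        ss = float((e ** 2).sum())
        if ss < ss_floor:
            ss = 0.0
        df = 1
        for a in term:
            df *= Y.shape[a] - 1
        return ss, df

    Ycells = Y.reshape(n_subj, total_cells)

    results: dict[str, dict] = {}
    factor_axes = list(range(1, k + 1))
    for r in range(1, k + 1):
        for combo in itertools.combinations(factor_axes, r):
            name = ":".join(factor_names[a - 1] for a in combo)
            ss_eff, df_eff = ss_df(combo)
            ss_err, df_err = ss_df((0,) + combo)
            ms_eff = ss_eff / df_eff
            ms_err = ss_err / df_err
            F = ms_eff / ms_err if ms_err > 0 else 0.0
            p = float(sps.f.sf(F, df_eff, df_err)) if ms_err > 0 else 1.0
            pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            rec = {
                "F": F, "df1": float(df_eff), "df2": float(df_err), "p": p,
                "ss_effect": ss_eff, "ss_error": ss_err, "partial_eta_sq": pes,
                "epsilon": 1.0, "mauchly_W": np.nan, "mauchly_p": np.nan,
                "p_gg": p, "df1_gg": float(df_eff), "df2_gg": float(df_err),
                "correction_applied": False,
            }
            if df_eff > 1:
                C = _contrast_matrix(levels, [a - 1 for a in combo])
                Z = Ycells @ C.T  # (n_subj, p_eff)
                S = np.cov(Z, rowvar=False, ddof=1)
                p_eff = df_eff
                trS = float(np.trace(S))
                trS2 = float(np.trace(S @ S))
                eps = trS ** 2 / (p_eff * trS2) if trS2 > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / p_eff, 1.0))
                rec["epsilon"] = eps
                rec["df1_gg"] = eps * df_eff
                rec["df2_gg"] = eps * df_err
                rec["p_gg"] = float(sps.f.sf(F, eps * df_eff, eps * df_err))
                if n_subj - 1 > p_eff and trS > 0:
                    detS = float(np.linalg.det(S))
                    denom = (trS / p_eff) ** p_eff
                    W = detS / denom if denom > 0 else 0.0
                    if W > 0:
                        f = (2 * p_eff ** 2 + p_eff + 2) / (6.0 * p_eff * (n_subj - 1))
                        chi2 = -(n_subj - 1) * (1 - f) * math.log(W)
                        ddl = p_eff * (p_eff + 1) // 2 - 1
                        rec["mauchly_W"] = W
                        rec["mauchly_p"] = float(sps.chi2.sf(chi2, ddl))
                    else:
                        rec["mauchly_W"] = 0.0
                        rec["mauchly_p"] = 0.0
            results[name] = rec
    return results


def _contrast_matrix(levels: tuple[int, ...], effect_factors: list[int]) -> np.ndarray:
    """Orthonormal contrast rows for one effect (Kronecker over factors)."""
    C = np.ones((1, 1))
    for f, l in enumerate(levels):
        if f in effect_factors:
            # orthonormal basis of the space orthogonal to the constant
            H = np.eye(l) - np.full((l, l), 1.0 / l)
            q, _ = np.linalg.qr(H.T)
            B = q[:, : l - 1].T  # (l-1, l)
        else:
            B = np.full((1, l), 1.0 / np.sqrt(l))
        C = np.kron(C, B)
    return C


# ---------------------------------------------------------------------------
# dataframe interface
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-effect repeated-measures ANOVA table with sphericity handling."""

    effects: dict[str, dict]
    factors: list[str]
    n_subjects: int
    gg_trigger_alpha: float = 0.05

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, r in self.effects.items():
            rows.append({"effect": name, **r})
        return pd.DataFrame(rows)

    def reported(self, effect: str) -> dict:
        """The quantities to report: GG-corrected iff Mauchly rejected."""
        r = dict(self.effects[effect])
        corrected = (
            not np.isnan(r["mauchly_p"]) and r["mauchly_p"] < self.gg_trigger_alpha
        )
        r["correction_applied"] = corrected
        if corrected:
            r["p_reported"] = r["p_gg"]
            r["df1_reported"], r["df2_reported"] = r["df1_gg"], r["df2_gg"]
        else:
            r["p_reported"] = r["p"]
            r["df1_reported"], r["df2_reported"] = r["df1"], r["df2"]
        return r


def _pivot_balanced(df: pd.DataFrame, dv: str, within: list[str], subject: str):
    subjects = sorted(df[subject].unique())
    levels = [sorted(df[f].unique()) for f in within]
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    cells = df.groupby([subject, *within], observed=True)[dv]
    sizes = cells.size()
    if len(sizes) != expected or (sizes != sizes.iloc[0]).any():
        full = pd.MultiIndex.from_product([subjects, *levels], names=[subject, *within])
        missing = full.difference(sizes.index)
        raise ValueError(f"unbalanced design; missing/unequal cells: {list(missing)[:10]}")
    means = cells.mean()
    shape = (len(subjects), *[len(l) for l in levels])
    full = pd.MultiIndex.from_product([subjects, *levels], names=[subject, *within])
    Y = means.reindex(full).to_numpy().reshape(shape)
    return Y, subjects, levels


def rm_anova(df: pd.DataFrame, dv: str, within: list[str], subject: str = "subject",
             gg_trigger_alpha: float = 0.05) -> AnovaResult:
    """Repeated-measures ANOVA on a long table; balanced designs only.

    Cells with replicates are averaged first (cell means).  Every main effect
    and interaction of the ``within`` factors is tested against its own
    effect-by-subject interaction.
    """
    Y, subjects, _ = _pivot_balanced(df, dv, within, subject)
    effects = rm_anova_array(Y, within)
    return AnovaResult(effects=effects, factors=within, n_subjects=len(subjects),
                       gg_trigger_alpha=gg_trigger_alpha)


def posthoc(df: pd.DataFrame, dv: str, effect: str, subject: str = "subject",
            method: str = "bonferroni_t") -> pd.DataFrame:
    """All pairwise contrasts of one factor's levels on subject cell means.

    ``method``: ``bonferroni_t`` (paired t, Bonferroni-corrected),
    ``paired_t`` (uncorrected), or ``wilcoxon`` (signed-rank,
    Bonferroni-corrected).  Cohen's d is the paired version,
    mean(diff) / sd(diff); the 0/0 case is reported as d = 0.
    """
    if effect not in df.columns:
        raise ValueError(f"unknown effect {effect!r}; columns: {list(df.columns)}")
    if method not in {"bonferroni_t", "paired_t", "wilcoxon"}:
        raise ValueError(f"unknown method {method!r}")
    cell = df.groupby([subject, effect], observed=True)[dv].mean().unstack(effect)
    levels = list(cell.columns)
    pairs = list(itertools.combinations(levels, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        d = (cell[a] - cell[b]).to_numpy()
        md, sd = float(d.mean()), float(d.std(ddof=1))
        if sd == 0.0:
            cohen = 0.0 if md == 0.0 else math.copysign(np.inf, md)
            t, p = (0.0, 1.0) if md == 0.0 else (math.copysign(np.inf, md), 0.0)
        else:
            cohen = md / sd
            t, p = sps.ttest_rel(cell[a], cell[b])
            t, p = float(t), float(p)
        if method == "wilcoxon":
            if np.allclose(d, 0.0):
                p = 1.0
                stat = np.nan
            else:
                stat, p = sps.wilcoxon(d)
                stat, p = float(stat), float(p)
            rows.append({"a": a, "b": b, "statistic": stat, "p_uncorrected": p,
                         "p_corrected": min(1.0, p * n_comp), "cohen_d": cohen,
                         "n_comparisons": n_comp})
        else:
            factor = n_comp if method == "bonferroni_t" else 1
            rows.append({"a": a, "b": b, "t": t, "p_uncorrected": p,
                         "p_corrected": min(1.0, p * factor), "cohen_d": cohen,
                         "n_comparisons": n_comp})
    return pd.DataFrame(rows)


def summarize_rt(trials: pd.DataFrame, min_ms: float = 200.0, max_ms: float = 1500.0,
                 subject: str = "subject", condition_cols: list[str] | None = None,
                 rt_col: str = "rt_ms", correct_col: str = "correct") -> pd.DataFrame:
    """Per subject x condition median RT of correct trials, log-median, accuracy.

    Trials *faster than* ``min_ms`` or *slower than* ``max_ms`` are excluded
    (strict inequalities, so RTs equal to a bound are retained).  Accuracy is
    computed over all trials before RT filtering; medians over correct,
    RT-filtered trials; the log transform is the natural log of the median.
    """
    condition_cols = condition_cols or ["condition"]
    keys = [subject, *condition_cols]
    acc = trials.groupby(keys, observed=True)[correct_col].mean().rename("accuracy")
    kept = trials[(trials[rt_col] >= min_ms) & (trials[rt_col] <= max_ms)]
    kept = kept[kept[correct_col].astype(bool)]
    med = kept.groupby(keys, observed=True)[rt_col].median().rename("median_rt_ms")
    out = pd.concat([med, acc], axis=1).reset_index()
    empty = out[out["median_rt_ms"].isna()]
    if len(empty):
        cells = empty[keys].to_records(index=False).tolist()
        raise ValueError(f"no correct in-bounds trials for cell(s): {cells}")
    out["log_median_rt"] = np.log(out["median_rt_ms"])
    return out
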