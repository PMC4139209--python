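"""Differential expression: permutation one-way ANOVA and a SAM-style test.

miRNAs are screened across all conditions with the classical one-way ANOVA F
statistic whose null distribution is obtained by permuting condition labels
(add-one permutation p-values, the same label permutations applied to every
feature within a call).  Calls combine significance with a linear fold-change
dead band (down < 0.8, up > 1.2).  mRNAs are screened two-class with a
moderated difference statistic d = (mean1 - mean2) / (s + s0) and a
permutation FDR, in the spirit of significance analysis of microarrays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np

from .matrix import ExpressionMatrix

__all__ = ["DEResult", "SAMResult", "permutation_anova", "fold_change",
           "classify_de", "sam_two_class"]


@dataclass
class DEResult:
    feature_id: str
    F_stat: float
    p_perm: float
    p_adj: float | None = None            # BH-adjusted p (opt-in)
    fc: float | None = None               # linear fold change vs control
    de_class: str | None = None           # up / down / unchanged
    tested: bool = True


@dataclass
class SAMResult:
    feature_id: str
    d_stat: float
    s0: float
    q_value: float
    tested: bool = True


def _group_indicator(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    uniq: list[str] = []
    for g in labels:
        if g not in uniq:
            uniq.append(g)
    G = np.zeros((len(labels), len(uniq)))
    for i, g in enumerate(labels):
        G[i, uniq.index(g)] = 1.0
    return G, uniq


def _anova_f(values: np.ndarray, mask: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F per feature, mask-aware.

    ``G`` is the samples x groups indicator.  Features with < 2 groups having
    >= 2 observations get NaN (untested).
    """
    X = np.where(mask, 0.0, values)
    O = (~mask).astype(float)
    n_g = O @ G                       # features x groups observation counts
    s_g = X @ G                       # per-group sums
    n = O.sum(axis=1)
    tot = X.sum(axis=1)
    k_eff = (n_g >= 1).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_g = np.where(n_g > 0, s_g / np.maximum(n_g, 1), 0.0)
        grand = tot / n
        ssb = (n_g * (mean_g - grand[:, None]) ** 2 * (n_g > 0)).sum(axis=1)
        sst = (np.where(mask, 0.0, (values - grand[:, None]) ** 2)).sum(axis=1)
        ssw = sst - ssb
        df_b = k_eff - 1
        df_w = n - k_eff
        F = np.where(ssw > 0, (ssb / np.maximum(df_b, 1)) / np.where(ssw > 0, ssw, 1.0)
                     * df_w, np.where(ssb > 0, np.inf, 0.0))
    # untestable: fewer than 2 groups with >= 2 observations, or df_w <= 0
    ok = ((n_g >= 2).sum(axis=1) >= 2) & (df_w > 0) & (df_b > 0)
    return np.where(ok, F, np.nan)


def _label_permutations(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Permutations of 0..n-1: full enumeration when cheap, else sampled."""
    if math.factorial(n) <= n_perm:
        return np.array(list(_iter_permutations(range(n))), dtype=int)
    return np.array([rng.permutation(n) for _ in range(n_perm)], dtype=int)


def permutation_anova(
    matrix: ExpressionMatrix,
    groups: list[str] | None = None,
    n_perm: int = 1000,
    rng_seed: int = 0,
    bh_adjust: bool = False,
) -> list[DEResult]:
    """Permutation one-way ANOVA across condition groups, per feature.

    p_perm = (1 + #{F* >= F}) / (n_perm + 1) with condition labels permuted;
    the same permutations are shared by all features in one call.  When the
    total number of distinct label orderings is <= n_perm the permutation set
    is enumerated exactly instead of sampled.  Features lacking two groups with
    two unmasked observations are reported as untested (never dropped).

    The screen is uncorrected by default (raw alpha, matching the original
    analysis); ``bh_adjust=True`` additionally fills ``p_adj`` with
    Benjamini-Hochberg values across the tested features.
    """
    labels = list(groups) if groups is not None else matrix.conditions()
    if len(labels) != len(matrix.sample_ids):
        raise ValueError("one group label per sample is required")
    G, uniq = _group_indicator(labels)
    if len(uniq) < 2:
        raise ValueError("permutation ANOVA needs >= 2 groups")
    rng = np.random.default_rng(rng_seed)
    F_obs = _anova_f(matrix.values, matrix.mask, G)
    perms = _label_permutations(len(labels), n_perm, rng)
    n_eff = perms.shape[0]
    exceed = np.zeros(len(matrix.feature_ids))
    for p in perms:
        F_p = _anova_f(matrix.values, matrix.mask, G[p])
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(F_p), 1.0, (F_p >= F_obs).astype(float))
    p_perm = (1.0 + exceed) / (n_eff + 1.0)
    out = []
    for i, fid in enumerate(matrix.feature_ids):
        if np.isnan(F_obs[i]):
            out.append(DEResult(fid, float("nan"), float("nan"), tested=False))
        else:
            out.append(DEResult(fid, float(F_obs[i]), float(min(p_perm[i], 1.0))))
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests
        tested = [r for r in out if r.tested]
        if tested:
            _, q, _, _ = multipletests([r.p_perm for r in tested],
                                       method="fdr_bh")
            for r, qi in zip(tested, q):
                r.p_adj = float(qi)
    return out


def fold_change(
    matrix: ExpressionMatrix, condition: str, control: str = "control"
) -> dict[str, float]:
    """Linear fold change of ``condition`` vs ``control`` per feature.

    On log2-ratio data fc = 2^(mean log2 in condition - mean log2 in control);
    when the matrix has no control columns (control ratios identically 0 by
    the two-channel design) the control mean is taken as 0.
    """
    labels = np.asarray(matrix.conditions())
    cond_cols = labels == condition
    if not cond_cols.any():
        raise ValueError(f"condition {condition!r} absent from the matrix")
    ctrl_cols = labels == control
    out: dict[str, float] = {}
    for i, fid in enumerate(matrix.feature_ids):
        obs_c = cond_cols & ~matrix.mask[i]
        m_cond = float(np.mean(matrix.values[i, obs_c])) if obs_c.any() else np.nan
        if ctrl_cols.any():
            obs_0 = ctrl_cols & ~matrix.mask[i]
            m_ctrl = float(np.mean(matrix.values[i, obs_0])) if obs_0.any() else np.nan
        else:
            m_ctrl = 0.0
        out[fid] = float(2.0 ** (m_cond - m_ctrl))
    return out


def classify_de(
    fc: float, p_perm: float, alpha: float = 0.05,
    down: float = 0.8, up: float = 1.2,
) -> str:
    """Regulation call from linear fold change and permutation p-value.

    up iff fc > up and p <= alpha; down iff fc < down and p <= alpha;
    otherwise unchanged (inside the dead band, or not significant).
    """
    if not fc > 0 or math.isnan(fc):
        raise ValueError("fold change must be positive")
    if p_perm <= alpha:
        if fc > up:
            return "up"
        if fc < down:
            return "down"
    return "unchanged"


# ---------------------------------------------------------------------------
# SAM-style two-class statistic


def _sam_d(values, mask, g1, g2, s0):
    X = np.where(mask, 0.0, values)
    O = (~mask).astype(float)
    n1, n2 = O[:, g1].sum(axis=1), O[:, g2].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        m1 = X[:, g1].sum(axis=1) / n1
        m2 = X[:, g2].sum(axis=1) / n2
        v1 = (np.where(mask[:, g1], 0.0, (values[:, g1] - m1[:, None]) ** 2)).sum(axis=1)
        v2 = (np.where(mask[:, g2], 0.0, (values[:, g2] - m2[:, None]) ** 2)).sum(axis=1)
        pooled = (v1 + v2) / np.maximum(n1 + n2 - 2.0, 1.0)
        s = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(ok & ((s + s0) > 0), (m1 - m2) / np.where(s + s0 > 0, s + s0, 1.0), 0.0)
    d = np.where(ok, d, np.nan)
    return d, s, ok


def sam_two_class(
    matrix: ExpressionMatrix,
    groups: list[str],
    group1: str,
    group2: str,
    n_perm: int = 200,
    rng_seed: int = 0,
    s0: float | None = None,
) -> list[SAMResult]:
    """Moderated two-class difference statistic with permutation FDR.

    d = (mean1 - mean2) / (s + s0); s is the pooled standard error and s0
    defaults to the median of per-feature s (a documented simplification of
    the original fudge-factor search).  Per-feature q is the estimated FDR at
    threshold |d|: median over permutations of the count of |d*| >= |d|,
    divided by the observed count, monotonized and capped at 1.
    """
    labels = np.asarray(groups)
    g1 = np.where(labels == group1)[0]
    g2 = np.where(labels == group2)[0]
    if len(g1) == 0 or len(g2) == 0:
        raise ValueError(f"groups {group1!r}/{group2!r} not both present")
    rng = np.random.default_rng(rng_seed)
    pool = np.concatenate([g1, g2])
    _, s_obs, _ = _sam_d(matrix.values, matrix.mask, g1, g2, 0.0)
    if s0 is None:
        s0 = float(np.nanmedian(s_obs))
    d_obs, _, ok = _sam_d(matrix.values, matrix.mask, g1, g2, s0)
    abs_obs = np.abs(d_obs[ok])
    order = np.sort(abs_obs)
    n1 = len(g1)
    counts = np.zeros((n_perm, len(order)))
    for b in range(n_perm):
        perm = rng.permutation(pool)
        d_p, _, _ = _sam_d(matrix.values, matrix.mask, perm[:n1], perm[n1:], s0)
        a = np.sort(np.abs(d_p[~np.isnan(d_p)]))
        # #{|d*| >= t} for each observed threshold t
        counts[b] = len(a) - np.searchsorted(a, order, side="left")
    med_false = np.median(counts, axis=0)
    n_called = len(order) - np.arange(len(order))  # #{|d| >= t} at each sorted t
    fdr_sorted = np.minimum(med_false / np.maximum(n_called, 1), 1.0)
    # q at threshold t = best FDR among thresholds <= t (all still call t);
    # running minimum over ascending thresholds, so q never rises with |d|
    fdr_sorted = np.minimum.accumulate(fdr_sorted)
    out: list[SAMResult] = []
    j_of = {}
    for t, f in zip(order, fdr_sorted):
        j_of[t] = f
    for i, fid in enumerate(matrix.feature_ids):
        if not ok[i]:
            out.append(SAMResult(fid, float("nan"), s0, float("nan"), tested=False))
        else:
            idx = np.searchsorted(order, abs(d_obs[i]), side="left")
            idx = min(idx, len(order) - 1)
            out.append(SAMResult(fid, float(d_obs[i]), s0, float(fdr_sorted[idx])))
    return out
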