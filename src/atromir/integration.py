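"""Expression-anticorrelation filtering of predicted miRNA targets.

The core inference: a predicted seed-site target is only believed when its
expression moves opposite to the miRNA across conditions (miRNA up, target
mRNA down).  Each miRNA's standardized per-condition profile is the template;
each candidate gene's per-condition profile is scored by Pearson correlation
against it, with a one-sided permutation test for anticorrelation.  A gene
passes for a miRNA when it is a predicted target, falls in the down-regulated
set, correlates at r <= r_max, and the permutation p is <= alpha.  The
high-confidence list is the intersection of the per-miRNA passing sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemplateMatch", "IntegrationResult", "build_template",
           "template_correlation", "template_match_test", "integrate"]


@dataclass
class TemplateMatch:
    gene_id: str
    r: float
    p_perm: float
    passes: bool
    tested: bool = True


@dataclass
class IntegrationResult:
    """Per-miRNA anticorrelated target sets and their intersection."""

    per_mirna: dict[str, set[str]]
    shared: set[str]
    venn: dict[str, int] = field(default_factory=dict)


def build_template(mirna_profile: np.ndarray) -> np.ndarray:
    """Standardize a per-condition mean profile to zero mean, unit variance.

    Uses the population standard deviation; masked (NaN) conditions are kept
    as NaN and excluded from the moments.
    """
    p = np.asarray(mirna_profile, dtype=float)
    obs = ~np.isnan(p)
    if obs.sum() < 3:
        raise ValueError("template needs >= 3 observed conditions")
    mu = p[obs].mean()
    sd = p[obs].std()
    if sd == 0:
        raise ValueError("template profile has zero variance")
    out = np.full_like(p, np.nan)
    out[obs] = (p[obs] - mu) / sd
    return out


def template_correlation(
    gene_profile: np.ndarray, template: np.ndarray, min_obs: int = 3
) -> float:
    """Pearson r between a gene profile and the template.

    Computed over jointly observed conditions; NaN when the gene profile has
    zero variance there (the gene is untestable) or fewer than ``min_obs``
    conditions are jointly observed.
    """
    g = np.asarray(gene_profile, dtype=float)
    t = np.asarray(template, dtype=float)
    if g.shape != t.shape:
        raise ValueError("profile and template must have equal length")
    obs = ~np.isnan(g) & ~np.isnan(t)
    if obs.sum() < min_obs:
        return float("nan")
    gv, tv = g[obs], t[obs]
    if gv.std() == 0 or tv.std() == 0:
        return float("nan")
    return float(np.corrcoef(gv, tv)[0, 1])


def template_match_test(
    gene_profile: np.ndarray,
    template: np.ndarray,
    n_perm: int = 1000,
    rng_seed: int = 0,
    r_max: float = -0.8,
    alpha: float = 0.05,
    min_obs: int = 3,
    gene_id: str = "",
) -> TemplateMatch:
    """One-sided permutation test for anticorrelation with the template.

    Condition labels of the gene profile are permuted; p_perm is the add-one
    fraction of permutations with r* <= r (more anticorrelated than
    observed).  ``passes`` requires both r <= r_max and p_perm <= alpha.
    """
    r = template_correlation(gene_profile, template, min_obs=min_obs)
    if np.isnan(r):
        return TemplateMatch(gene_id, float("nan"), float("nan"), False, tested=False)
    rng = np.random.default_rng(rng_seed)
    g = np.asarray(gene_profile, dtype=float)
    t = np.asarray(template, dtype=float)
    obs = ~np.isnan(g) & ~np.isnan(t)
    gv, tv = g[obs], t[obs]
    count = 0
    for _ in range(n_perm):
        r_p = float(np.corrcoef(rng.permutation(gv), tv)[0, 1])
        if r_p <= r:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    return TemplateMatch(gene_id, r, p, bool(r <= r_max and p <= alpha))


def integrate(
    predictions: dict[str, set[str]],
    down_regulated: set[str],
    matches: dict[str, dict[str, TemplateMatch]],
) -> IntegrationResult:
    """Intersect predicted targets, the down-regulated set and passing matches.

    ``predictions`` maps miRNA -> predicted target gene ids; ``matches`` maps
    miRNA -> gene -> :class:`TemplateMatch`.  The per-miRNA output set is
    predicted AND down-regulated AND passing; ``shared`` intersects across all
    miRNAs.  Venn-style counts are reported alongside.
    """
    if not down_regulated:
        warnings.warn("down-regulated gene set is empty; integration result "
                      "is empty", stacklevel=2)
    per: dict[str, set[str]] = {}
    for mirna, predicted in predictions.items():
        mm = matches.get(mirna, {})
        per[mirna] = {
            g for g in predicted
            if g in down_regulated and g in mm and mm[g].passes
        }
    shared: set[str] = set.intersection(*per.values()) if per else set()
    venn = {"down_regulated": len(down_regulated)}
    for mirna, s in per.items():
        venn[f"targets_{mirna}"] = len(s)
    venn["shared"] = len(shared)
    return IntegrationResult(per_mirna=per, shared=shared, venn=venn)
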