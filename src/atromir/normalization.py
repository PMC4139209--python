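"""Two-channel array preprocessing: M/A transform, lowess, centering, averaging.

Raw two-channel intensities become log2 ratios in four steps: (1) per-spot
M = log2(Cy5/Cy3) and A = mean log2 intensity; (2) within-array
intensity-dependent lowess detrending of M against A; (3) between-array
normalization so arrays are comparable (median centering, optionally loess
against a median pseudo-array); (4) averaging of within-array replicate spots
to feature level.  All steps are mask-preserving: a spot masked on input (a
nonpositive channel, below-detection) stays masked and is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .matrix import ExpressionMatrix

__all__ = ["MAArray", "compute_ma", "lowess_normalize", "between_array_center",
           "average_replicate_spots"]


@dataclass
class MAArray:
    """Per-spot M (log2 ratio) and A (mean log2 intensity) with a mask.

    ``spot_map[i]`` names the feature that spot i measures; replicate spots of
    one feature share a name.
    """

    M: np.ndarray
    A: np.ndarray
    mask: np.ndarray
    spot_map: list[str] | None = None

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not (self.M.shape == self.A.shape == self.mask.shape):
            raise ValueError("M, A and mask must have identical shapes")


def compute_ma(cy5: np.ndarray, cy3: np.ndarray, spot_map: list[str] | None = None) -> MAArray:
    """M/A transform of two channel-intensity vectors.

    Spots where either channel is <= 0 are masked, not errors: a dim channel is
    a below-detection event, routine on miRNA arrays.
    """
    cy5 = np.asarray(cy5, dtype=float)
    cy3 = np.asarray(cy3, dtype=float)
    if cy5.shape != cy3.shape:
        raise ValueError(f"channel length mismatch: {cy5.shape} vs {cy3.shape}")
    bad = ~((cy5 > 0) & (cy3 > 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        l5, l3 = np.log2(np.where(bad, 1.0, cy5)), np.log2(np.where(bad, 1.0, cy3))
    M = np.where(bad, np.nan, l5 - l3)
    A = np.where(bad, np.nan, 0.5 * (l5 + l3))
    return MAArray(M=M, A=A, mask=bad, spot_map=spot_map)


def lowess_normalize(arr: MAArray, frac: float = 0.3, iters: int = 3) -> MAArray:
    """Subtract the lowess fit of M on A (intensity-dependent dye-bias removal).

    The fitted curve is locally linear with tricube weights and ``iters``
    robustifying iterations.  Output mask equals input mask.
    """
    obs = ~arr.mask
    n_obs = int(obs.sum())
    if n_obs < 10:
        raise ValueError(
            f"only {n_obs} unmasked spots; too few for lowess — "
            "fall back to global median centering"
        )
    fit = _sm_lowess(arr.M[obs], arr.A[obs], frac=frac, it=iters,
                     return_sorted=False)
    M2 = np.array(arr.M, copy=True)
    M2[obs] = arr.M[obs] - fit
    return MAArray(M=M2, A=np.array(arr.A, copy=True), mask=np.array(arr.mask, copy=True),
                   spot_map=arr.spot_map)


def between_array_center(
    matrix: ExpressionMatrix, method: str = "median", frac: float = 0.3, iters: int = 3
) -> ExpressionMatrix:
    """Make arrays (columns) comparable.

    ``method="median"`` subtracts each array's median of unmasked values.
    ``method="loess_pseudo"`` first detrends each array's values against the
    across-array median pseudo-profile with lowess, then median-centers; this
    is a documented local stand-in for published pseudo-array loess schemes.
    Either way every output array has median 0 (to 1e-9).
    """
    if len(matrix.sample_ids) < 2:
        raise ValueError("between-array normalization needs >= 2 arrays")
    values = np.array(matrix.values, copy=True)
    mask = matrix.mask
    for j, sid in enumerate(matrix.sample_ids):
        if mask[:, j].all():
            raise ValueError(f"array {sid!r} is entirely masked")
    if method not in ("median", "loess_pseudo"):
        raise ValueError(f"unknown between-array method {method!r}")
    if method == "loess_pseudo":
        with np.errstate(invalid="ignore"):
            pseudo = np.nanmedian(np.where(mask, np.nan, values), axis=1)
        for j in range(values.shape[1]):
            obs = ~mask[:, j] & ~np.isnan(pseudo)
            if obs.sum() >= 10:
                fit = _sm_lowess(values[obs, j], pseudo[obs], frac=frac, it=iters,
                                 return_sorted=False)
                values[obs, j] = values[obs, j] - fit + pseudo[obs]
    for j in range(values.shape[1]):
        obs = ~mask[:, j]
        values[obs, j] -= np.median(values[obs, j])
    return ExpressionMatrix(
        feature_ids=list(matrix.feature_ids), sample_ids=list(matrix.sample_ids),
        values=values, mask=np.array(mask, copy=True),
        sample_meta=dict(matrix.sample_meta), value_kind=matrix.value_kind,
    )


def average_replicate_spots(arr: MAArray) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Collapse replicate spots to feature level by the mask-aware mean.

    Returns (feature_ids, values, mask); a feature is masked iff every one of
    its spots is masked.  Feature order follows first appearance in the spot
    map.
    """
    if arr.spot_map is None:
        raise ValueError("spot_map is required to average replicate spots")
    if len(arr.spot_map) != arr.M.shape[0]:
        raise ValueError("spot_map length does not match number of spots")
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, f in enumerate(arr.spot_map):
        if f is None:
            raise ValueError(f"spot {i} is not mapped to a feature")
        if f not in groups:
            groups[f] = []
            order.append(f)
        groups[f].append(i)
    vals = np.empty(len(order))
    mask = np.zeros(len(order), dtype=bool)
    for k, f in enumerate(order):
        idx = groups[f]
        obs = [i for i in idx if not arr.mask[i]]
        if obs:
            vals[k] = float(np.mean(arr.M[obs]))
        else:
            vals[k], mask[k] = np.nan, True
    return order, vals, mask
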