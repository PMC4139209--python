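"""Dense expression matrix with an explicit missing-value mask.

The whole pipeline operates on features x samples matrices of either raw
intensities or log2(atrophy/control) ratios.  Values below the detection limit
of the array scanner carry no number at all, so the container keeps a boolean
mask alongside the dense value matrix rather than relying on NaN conventions
scattered through calling code (NaN is still used as the on-disk and in-memory
placeholder under masked cells, but the mask is authoritative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "SampleMeta"]


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample annotation: condition label and timepoint in days.

    ``timepoint`` is the number of days since the catabolic insult (0 for
    controls); ``channel_design`` records the two-channel layout, by default a
    competitive atrophy-vs-control hybridisation.
    """

    condition: str
    timepoint: float = 0.0
    channel_design: str = "atrophy_vs_control"


@dataclass
class ExpressionMatrix:
    """Features x samples matrix of intensities or log2 ratios.

    Parameters
    ----------
    feature_ids : list of str
        Unique probe or gene identifiers (row labels).
    sample_ids : list of str
        Unique sample identifiers (column labels).
    values : ndarray, shape (n_features, n_samples)
        Numeric values; entries under the mask are ignored (stored as NaN).
    mask : ndarray of bool, same shape
        True where the value is missing (below detection limit).
    sample_meta : dict, optional
        sample_id -> :class:`SampleMeta`.
    value_kind : {"intensity", "log_ratio"}
        What the numbers mean.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None
    sample_meta: dict[str, SampleMeta] = field(default_factory=dict)
    value_kind: str = "log_ratio"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_f, n_s = self.values.shape
        if len(self.feature_ids) != n_f or len(self.sample_ids) != n_s:
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        for name, ids in (("feature", self.feature_ids), ("sample", self.sample_ids)):
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicate {name} ids: {dupes}")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values")
        # masked entries carry no numeric value
        self.values = np.where(self.mask, np.nan, self.values)

    # -- convenience ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """Dense DataFrame with NaN in masked cells."""
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    def conditions(self) -> list[str]:
        """Per-sample condition labels, in column order."""
        return [self.sample_meta[s].condition if s in self.sample_meta else s
                for s in self.sample_ids]

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(feature_id) from None

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_index(feature_id)]

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            feature_ids=list(self.feature_ids),
            sample_ids=list(sample_ids),
            values=self.values[:, idx].copy(),
            mask=self.mask[:, idx].copy(),
            sample_meta={s: self.sample_meta[s] for s in sample_ids if s in self.sample_meta},
            value_kind=self.value_kind,
        )

    def condition_means(self, conditions: list[str] | None = None) -> pd.DataFrame:
        """Features x conditions matrix of mask-aware per-condition means.

        A (feature, condition) cell is NaN when every replicate is masked.
        """
        labels = np.asarray(self.conditions())
        if conditions is None:
            seen: list[str] = []
            for c in labels:
                if c not in seen:
                    seen.append(c)
            conditions = seen
        out = np.full((len(self.feature_ids), len(conditions)), np.nan)
        for j, cond in enumerate(conditions):
            cols = labels == cond
            if not cols.any():
                continue
            vals = self.values[:, cols]
            obs = ~self.mask[:, cols]
            cnt = obs.sum(axis=1)
            with np.errstate(invalid="ignore"):
                s = np.where(obs, vals, 0.0).sum(axis=1)
                out[:, j] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
        return pd.DataFrame(out, index=self.feature_ids, columns=conditions)

    def equals(self, other: "ExpressionMatrix", atol: float = 0.0) -> bool:
        if self.feature_ids != other.feature_ids or self.sample_ids != other.sample_ids:
            return False
        if not np.array_equal(self.mask, other.mask):
            return False
        a, b = self.values[~self.mask], other.values[~other.mask]
        return bool(np.allclose(a, b, atol=atol, rtol=0.0))
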