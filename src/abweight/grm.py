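"""Genomic relationship matrices and inverse-importance marker weights.

The unweighted GRM is VanRaden-style, ``G = MM'/p`` on the centered,
population-SD-standardized marker matrix ``M``, which fixes the mean of
``diag(G)`` at exactly 1.  The weighted variant ``G* = MDM'/p`` carries a
diagonal matrix ``D`` of squared per-marker weights; weights come from
inverting per-marker importance scores and normalizing to sum ``p``, so
markers that strongly discriminate the held-out family are attenuated and
uninformative markers are boosted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class GRM:
    """Symmetric line-by-line genomic relationship matrix."""

    values: np.ndarray
    kind: str  # "unweighted" | "weighted"
    line_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("unweighted", "weighted"):
            raise ValueError(f"unknown GRM kind {self.kind!r}")
        n, m = self.values.shape
        if n != m:
            raise ValueError("GRM must be square")
        if np.abs(self.values - self.values.T).max() > 1e-10:
            raise ValueError("GRM must be symmetric")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        ids = self.line_ids or [str(i) for i in range(self.n)]
        pd.DataFrame(self.values, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "unweighted") -> "GRM":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), kind, [str(i) for i in df.index])


@dataclass
class WeightVector:
    """Per-marker weights ``w`` (sum ``p``) and the implied ``D = diag(w^2)``."""

    w: np.ndarray
    floor_applied: int = 0
    degenerate: bool = False  # all-nonpositive importances -> uniform fallback

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or self.w.size < 1:
            raise ValueError("weight vector must be 1-D and non-empty")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        p = self.w.size
        if abs(self.w.sum() - p) > 1e-8 * p:
            raise ValueError("weights must sum to the marker count p")

    @property
    def p(self) -> int:
        return self.w.size

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.w**2)

    def to_csv(self, path: str | Path, marker_ids: list[str] | None = None) -> None:
        ids = marker_ids or [f"m{i}" for i in range(self.p)]
        pd.DataFrame({"marker_id": ids, "weight": self.w}).to_csv(path, index=False)


def compute_grm(M: np.ndarray, line_ids: list[str] | None = None) -> GRM:
    """Unweighted GRM ``G = MM'/p``; trace is exactly n under our scaling."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] == 0:
        raise ValueError("M must be an n x p matrix with p >= 1")
    p = M.shape[1]
    G = (M @ M.T) / p
    G = (G + G.T) / 2.0
    return GRM(G, "unweighted", line_ids)


def weights_from_importance(
    IS: np.ndarray, floor_fraction: float = 1e-3
) -> WeightVector:
    """Invert importance scores into normalized marker weights.

    ``Inv_IS = 1/IS`` and ``w = Inv_IS * p / sum(Inv_IS)``, so the most
    family-discriminating markers receive the smallest weights.  Raw
    forest importances of irrelevant markers can be zero (or, for other
    backends, negative), where the inverse explodes; scores at or below
    ``eps = floor_fraction * median(positive scores)`` are floored at
    ``eps``, which caps the weight ratio while preserving the ordering.
    If no score is positive there is no mismatch signal at all and the
    weights degenerate to uniform (AB reduces exactly to GBLUP).
    """
    IS = np.asarray(IS, dtype=float)
    if IS.ndim != 1 or IS.size < 1:
        raise ValueError("importance scores must be a 1-D vector, p >= 1")
    if not np.all(np.isfinite(IS)):
        raise ValueError("importance scores must be finite")
    p = IS.size
    positive = IS[IS > 0]
    if positive.size == 0:
        msg = "no positive importance score: uniform weights (AB = GBLUP)"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return WeightVector(np.ones(p), floor_applied=0, degenerate=True)
    eps = floor_fraction * float(np.median(positive))
    floored = np.maximum(IS, eps)
    n_floored = int((IS <= eps).sum())
    inv = 1.0 / floored
    w = inv * p / inv.sum()
    return WeightVector(w, floor_applied=n_floored)


def compute_weighted_grm(
    M: np.ndarray, weights: WeightVector | np.ndarray, line_ids: list[str] | None = None
) -> GRM:
    """Weighted GRM ``G* = MDM'/p`` with ``D = diag(w^2)``.

    Implemented by scaling columns of M by w, so unit weights reproduce
    the unweighted GRM bit-for-bit.
    """
    M = np.asarray(M, dtype=float)
    w = weights.w if isinstance(weights, WeightVector) else np.asarray(weights, float)
    if M.ndim != 2 or M.shape[1] != w.size:
        raise ValueError(
            f"weight length {w.size} does not match marker count {M.shape[1]}"
        )
    Mw = M * w
    p = M.shape[1]
    G = (Mw @ Mw.T) / p
    G = (G + G.T) / 2.0
    return GRM(G, "weighted", line_ids)
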