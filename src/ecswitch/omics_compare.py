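"""Cross-strain omics alignment and ordination.

Two strains sampled on their own clocks are paired by the expression
profile of a phosphate-starvation-responsive regulon: each strain's
mean Z-scored regulon profile over time is computed and the monotone
pairing minimizing total squared profile distance is found by dynamic
programming (no time reversal).  Proteome-wide structure is summarized
with PCA (features centered, unit-scaled by default) and per-gene
Z-scoring supports heatmap-style displays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ExpressionMatrix",
    "AlignmentMap",
    "PcaResult",
    "align_by_regulon",
    "pca_scores",
    "zscore_expression",
    "expression_from_proteomes",
]

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Features × samples abundances with per-sample metadata.

    ``values`` rows are features (genes/proteins), columns samples;
    ``samples`` carries strain/time/replicate per column, same order.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # columns: strain, time, replicate

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicated feature ids")
        if len(self.samples) != self.values.shape[1]:
            raise ValueError("sample metadata does not cover all columns")
        self.samples = self.samples.set_axis(self.values.columns)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def time_ordered(self, strain: Optional[str] = None) -> "ExpressionMatrix":
        meta = self.samples
        if strain is not None:
            meta = meta[meta["strain"] == strain]
        order = meta.sort_values("time").index
        return ExpressionMatrix(self.values[order], self.samples.loc[order].reset_index(drop=True))


@dataclass
class AlignmentMap:
    pairs: List[Tuple[int, int]]  # (index in A, index in B), monotone
    score: float
    times_a: Optional[np.ndarray] = None
    times_b: Optional[np.ndarray] = None


def _regulon_profile(expr: ExpressionMatrix, regulon: Set[str]) -> Tuple[np.ndarray, np.ndarray]:
    """Mean Z-scored regulon expression per time point (replicates averaged)."""
    present = [g for g in expr.features if g in regulon]
    if not present:
        raise ValueError("regulon does not overlap the expression features")
    sub = expr.values.loc[present]
    times = expr.samples["time"].to_numpy(dtype=float)
    unique_times = np.unique(times)
    by_time = np.column_stack(
        [sub.loc[:, times == t].mean(axis=1).to_numpy() for t in unique_times]
    )
    mean = by_time.mean(axis=1, keepdims=True)
    sd = by_time.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (by_time - mean) / sd
    return z.mean(axis=0), unique_times


def align_by_regulon(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    regulon: Set[str],
) -> AlignmentMap:
    """Monotone time-point pairing from regulon expression profiles.

    Dynamic programming over monotone maps (steps advance one or both
    series; diagonal preferred on ties) minimizing the total squared
    difference of the two strains' mean regulon profiles.  Identical
    inputs yield the identity pairing with score 0.
    """
    prof_a, times_a = _regulon_profile(expr_a, regulon)
    prof_b, times_b = _regulon_profile(expr_b, regulon)
    n, m = len(prof_a), len(prof_b)
    cost = (prof_a[:, None] - prof_b[None, :]) ** 2
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0 and j > 0:
                best = acc[i - 1, j - 1]
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            acc[i, j] = cost[i, j] + best
    # backtrack, preferring the diagonal on ties
    pairs = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        options = []
        if i > 0 and j > 0:
            options.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            options.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            options.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(options, key=lambda o: o[0])
        pairs.append((i, j))
    pairs.reverse()
    return AlignmentMap(pairs, float(acc[n - 1, m - 1]), times_a, times_b)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples × components
    percent_variance: np.ndarray
    loadings: pd.DataFrame  # features × components
    samples: pd.DataFrame


def pca_scores(
    expr: ExpressionMatrix,
    n_components: int = 2,
    scale: bool = True,
) -> PcaResult:
    """PCA of samples in feature space with variance-explained shares.

    Features are centered and (by default) unit-scaled; components are
    ordered by decreasing variance and sign-fixed so each component's
    largest-magnitude loading is positive.  ``n_components`` beyond the
    data rank is truncated with a warning.
    """
    X = expr.values.to_numpy(dtype=float).T  # samples × features
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > rank:
        logger.warning("n_components=%d exceeds rank %d; truncated", n_components, rank)
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features × components
    for k in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k+1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=expr.values.columns, columns=cols),
        percent_variance=100.0 * pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=expr.features, columns=cols),
        samples=expr.samples.copy(),
    )


def zscore_expression(
    expr: ExpressionMatrix,
    log_transform: bool = False,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """Per-feature Z-scores, optionally after log2(x + pseudocount).

    Zero-variance features come out as all-zero rows and are flagged on
    the result's ``zero_variance`` attribute.
    """
    values = expr.values.astype(float)
    if log_transform:
        if (values < 0).any().any():
            raise ValueError("log transform requires non-negative values")
        values = np.log2(values + pseudocount)
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flat = sd[(sd == 0) | ~np.isfinite(sd)].index
    sd = sd.replace(0, 1.0)
    z = values.sub(mean, axis=0).div(sd, axis=0)
    z.loc[flat] = 0.0
    out = ExpressionMatrix(z, expr.samples.copy())
    out.zero_variance = set(flat)  # type: ignore[attr-defined]
    return out


def expression_from_proteomes(samples: Sequence) -> ExpressionMatrix:
    """Stack ProteomeSample abundances into an ExpressionMatrix."""
    columns = {}
    meta = []
    for i, s in enumerate(samples):
        label = f"{s.strain_id}_t{s.time:g}_{i}"
        columns[label] = pd.Series(s.abundances, dtype=float)
        meta.append({"strain": s.strain_id, "time": s.time, "replicate": "r1"})
    values = pd.DataFrame(columns).fillna(0.0)
    return ExpressionMatrix(values, pd.DataFrame(meta))
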