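"""Variation partitioning of multivariate run summaries via redundancy analysis.

Redundancy analysis (RDA) on z-scored responses reduces, for the purpose of
explained variance, to multivariate least squares: the canonical R-squared is
the ratio of the fitted to the total sum of squares (traces), adjusted with
the Ezekiel formula.  Partitioning over three predictor blocks fits the seven
non-empty block subsets and solves the inclusion-exclusion system for the
unique, pairwise-shared and triple-shared fractions plus residual — the
procedure of vegan's ``varpart``.  Adjusted fractions can legitimately be
negative and are reported as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PartitionResult", "z_transform", "rda_adjusted_r2", "partition3", "partition2"]


@dataclass(frozen=True)
class PartitionResult:
    """Adjusted-R2 fractions of a three-block partition (vegan's [a]..[g])."""

    unique: dict  # block name -> unique fraction
    pairwise: dict  # frozenset of two names -> shared fraction
    triple: float
    residual: float
    subset_r2: dict  # frozenset of names -> adjusted R2 of that subset model

    def total(self) -> float:
        return 1.0 - self.residual

    def as_series(self) -> pd.Series:
        names = sorted(self.unique)
        out = {f"unique[{k}]": v for k, v in self.unique.items()}
        for pair, v in self.pairwise.items():
            a, b = sorted(pair)
            out[f"shared[{a}&{b}]"] = v
        out["shared[all]"] = self.triple
        out["residual"] = self.residual
        return pd.Series(out)


def z_transform(table) -> pd.DataFrame:
    """Column-wise standardisation to mean 0, sd 1 (so each response weighs equally).

    Uses the n-1 standard deviation; zero-variance columns are rejected with
    a diagnostic rather than silently producing NaN.
    """
    df = pd.DataFrame(table).astype(float)
    if df.isna().any().any():
        raise ValueError("response table contains missing values; drop those rows first")
    sd = df.std(ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise ValueError(f"zero-variance columns cannot be z-transformed: {bad}")
    return (df - df.mean()) / sd


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(pd.DataFrame(X), dtype=float)
    return X if X.ndim == 2 else X[:, None]


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Greedily drop columns that add no rank (after the intercept)."""
    n = X.shape[0]
    kept: list[int] = []
    base = np.ones((n, 1))
    for j in range(X.shape[1]):
        cand = np.column_stack([base] + [X[:, k] for k in kept] + [X[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            kept.append(j)
    if len(kept) < X.shape[1]:
        import warnings

        warnings.warn("dropping collinear predictor columns", stacklevel=3)
    return X[:, kept]


def rda_adjusted_r2(Y, X) -> float:
    """Ezekiel-adjusted canonical R2 of the redundancy analysis of Y on X.

    ``R2 = SS(fitted)/SS(total)`` from the multivariate regression of the
    (column-centred) responses on the predictors with intercept;
    ``R2_adj = 1 - (1 - R2) * (n - 1) / (n - p - 1)`` with p the number of
    (non-collinear) predictor columns.  For a single response column this is
    exactly the ordinary adjusted R2.
    """
    Y = _as_matrix(Y)
    X = _drop_collinear(_as_matrix(X))
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than predictors plus one")
    Yc = Y - Y.mean(axis=0)
    design = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(design, Yc, rcond=None)
    fitted = design @ beta
    ss_total = float((Yc**2).sum())
    if ss_total == 0:
        raise ValueError("response matrix has no variance")
    r2 = float((fitted**2).sum()) / ss_total
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def partition3(Y, blocks: dict) -> PartitionResult:
    """Three-block variation partitioning by inclusion-exclusion on adjusted R2.

    ``blocks`` maps three block names to predictor matrices (each n x p_k).
    Fits all seven subset models; unique fraction of block A is
    ``R2(ABC) - R2(BC)``, the triple intersection follows from the full
    inclusion-exclusion identity, and every subset R2 is exactly
    recoverable from the returned fractions.
    """
    names = list(blocks)
    if len(names) != 3:
        raise ValueError("partition3 needs exactly three predictor blocks")
    mats = {k: _as_matrix(v) for k, v in blocks.items()}
    r2: dict[frozenset, float] = {}
    for size in (1, 2, 3):
        for subset in _subsets(names, size):
            X = np.column_stack([mats[k] for k in names if k in subset])
            r2[subset] = rda_adjusted_r2(Y, X)
    a, b, c = names
    full = r2[frozenset(names)]
    unique = {k: full - r2[frozenset(set(names) - {k})] for k in names}
    triple = (
        r2[frozenset({a})] + r2[frozenset({b})] + r2[frozenset({c})]
        - r2[frozenset({a, b})] - r2[frozenset({a, c})] - r2[frozenset({b, c})]
        + full
    )
    pairwise = {}
    for x, y in ((a, b), (a, c), (b, c)):
        pairwise[frozenset({x, y})] = (
            r2[frozenset({x})] + r2[frozenset({y})] - r2[frozenset({x, y})] - triple
        )
    return PartitionResult(
        unique=unique,
        pairwise=pairwise,
        triple=triple,
        residual=1.0 - full,
        subset_r2=r2,
    )


def partition2(Y, blocks: dict) -> PartitionResult:
    """Two-block partition (uniques, one shared fraction, residual).

    Used per isolation level, where the factors are the movement-size
    coupling and the resource growth speed.  Requires at least three runs.
    """
    names = list(blocks)
    if len(names) != 2:
        raise ValueError("partition2 needs exactly two predictor blocks")
    Y = _as_matrix(Y)
    if Y.shape[0] < 3:
        raise ValueError("need at least three runs for a two-block partition")
    mats = {k: _as_matrix(v) for k, v in blocks.items()}
    a, b = names
    r2 = {
        frozenset({a}): rda_adjusted_r2(Y, mats[a]),
        frozenset({b}): rda_adjusted_r2(Y, mats[b]),
        frozenset({a, b}): rda_adjusted_r2(Y, np.column_stack([mats[a], mats[b]])),
    }
    full = r2[frozenset({a, b})]
    unique = {a: full - r2[frozenset({b})], b: full - r2[frozenset({a})]}
    shared = r2[frozenset({a})] + r2[frozenset({b})] - full
    return PartitionResult(
        unique=unique,
        pairwise={frozenset({a, b}): shared},
        triple=0.0,
        residual=1.0 - full,
        subset_r2=r2,
    )


def _subsets(names, size):
    from itertools import combinations

    for combo in combinations(names, size):
        yield frozenset(combo)
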