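"""Expression signatures: normalization, vehicle referencing, top-k, MDS.

Raw counts are depth-normalized with median-of-ratios size factors and
placed on a variance-stabilized log scale, ``log2(count/size_factor +
pseudocount)`` — a closed-form stand-in for a fitted-dispersion variance
stabilizing transform, adequate because everything downstream needs only a
monotone log-like scale. Per-sample signatures subtract the mean of the
vehicle-control (DMSO) wells gene-wise, so the vehicle columns become
residuals with an exactly-zero mean. Sample geometry is summarized by
classical (Torgerson) multidimensional scaling on Euclidean distances.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .demux import CountMatrix

logger = logging.getLogger(__name__)


def _frame(cm: Union[CountMatrix, pd.DataFrame]) -> pd.DataFrame:
    return cm.counts if isinstance(cm, CountMatrix) else cm


class NormalizationError(ValueError):
    pass


def size_factors(cm: Union[CountMatrix, pd.DataFrame]) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean one.

    Restricted to genes with a positive count in every sample (the usual
    convention: the per-gene geometric mean reference is only defined
    there). ``factor_j = median_g count_gj / geomean_g``.
    """
    counts = _frame(cm).astype(float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise NormalizationError(
            "no gene has nonzero counts in every sample; pool wells or filter "
            "samples before normalizing"
        )
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    factors = np.exp(ratios.median(axis=0))
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


@dataclass
class ExpressionMatrix:
    """Genes x samples values on a variance-stabilized log2 scale."""

    values: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float = 1.0
    method: str = "log2-sf-normalized"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("expression values must be finite")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be strictly positive")

    def linear(self) -> pd.DataFrame:
        """Back to the size-factor-normalized linear scale (pseudocount removed)."""
        return 2.0 ** self.values - self.pseudocount


def vst(
    cm: Union[CountMatrix, pd.DataFrame],
    pseudocount: float = 1.0,
    factors: Optional[pd.Series] = None,
) -> ExpressionMatrix:
    """Variance-stabilized expression: ``log2(count/size_factor + pseudocount)``.

    Monotone in counts within each sample; doubling a sample's counts and
    its size factor leaves its column unchanged.
    """
    counts = _frame(cm).astype(float)
    if factors is None:
        factors = size_factors(counts)
    values = np.log2(counts.div(factors, axis=1) + pseudocount)
    return ExpressionMatrix(values, factors, pseudocount)


@dataclass
class SignatureMatrix:
    """Vehicle-referenced per-sample signatures.

    The mean over ``control_samples`` columns is the zero vector by
    construction; control columns are retained as residuals.
    """

    values: pd.DataFrame
    control_samples: List[str] = field(default_factory=list)


def signature(
    expr: Union[ExpressionMatrix, pd.DataFrame],
    controls: Union[Sequence[str], "object"],
) -> SignatureMatrix:
    """Subtract the gene-wise mean of the vehicle-control columns.

    ``controls`` is a list of control sample labels or any object with a
    ``vehicle_wells`` attribute (e.g. a plate design).
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    control_samples = list(getattr(controls, "vehicle_wells", controls))
    if not control_samples:
        raise ValueError("at least one vehicle-control sample is required")
    missing = set(control_samples) - set(values.columns)
    if missing:
        raise ValueError(f"control samples absent from matrix: {sorted(missing)}")
    reference = values[control_samples].mean(axis=1)
    return SignatureMatrix(values.sub(reference, axis=0), control_samples)


def top_differential(
    sig: Union[SignatureMatrix, pd.DataFrame],
    conditions: Mapping[str, Sequence[str]],
    k: int = 40,
) -> List[str]:
    """Top-``k`` features by absolute mean signature within a condition.

    Each feature is scored by the largest ``|mean across replicates|`` over
    the given conditions (for a single condition this is simply the ranking
    by absolute mean signature); ties break deterministically by feature
    identifier. Truncates with a warning if fewer than ``k`` features exist.
    """
    values = sig.values if isinstance(sig, SignatureMatrix) else sig
    if not conditions:
        raise ValueError("at least one condition is required")
    scores = pd.DataFrame(
        {
            cond: values[list(samples)].mean(axis=1).abs()
            for cond, samples in conditions.items()
        }
    ).max(axis=1)
    if k > len(scores):
        warnings.warn(
            f"requested top {k} features but only {len(scores)} available; truncating"
        )
        k = len(scores)
    # stable sort after ordering the index makes ties break by identifier
    order = scores.loc[sorted(scores.index)].sort_values(
        ascending=False, kind="mergesort"
    )
    return list(order.index[:k])


def classical_mds(
    matrix: pd.DataFrame,
    dims: int = 2,
    eig_tol: float = 1e-8,
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of the samples (columns) of a feature matrix.

    Pairwise Euclidean distances between sample columns are double-centered
    into a Gram matrix whose top eigenvectors, scaled by root-eigenvalues,
    give the embedding. Deterministic up to orthogonal transforms and
    reflections; recovers genuinely ``dims``-dimensional configurations
    exactly. Warns if leading eigenvalues are negative beyond tolerance
    (non-Euclidean input cannot occur for a plain feature matrix, but
    precomputed distances may be supplied upstream).
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < dims + 1:
        raise ValueError(f"need at least {dims + 1} samples for a {dims}-D embedding")
    sq = (X * X).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = eigval[order]
    scale = float(np.abs(eigval).max()) or 1.0
    if (lam < -eig_tol * scale).any():
        warnings.warn(
            "negative leading eigenvalues in classical MDS; input distances are "
            "not Euclidean"
        )
    # eigenvalues within numerical noise of zero carry no geometry
    lam = np.where(lam < eig_tol * scale, 0.0, lam)
    coords = eigvec[:, order] * np.sqrt(lam)
    return pd.DataFrame(
        coords, index=matrix.columns, columns=[f"MDS{i + 1}" for i in range(dims)]
    )
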